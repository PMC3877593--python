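"""Per-position cross-species identity profiles of intron ends.

For the 5' end, position p is the p-th intron nucleotide; for the 3' end,
position p counts backwards from the intron's last nucleotide (position 1 is
the final G of the canonical AG). Couples shorter than p at either member
are excluded from both the numerator and the denominator at that position.
Positions carrying N in either member count as non-identical and stay in
the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .census import ENDS, FIVE_PRIME
from .io import OrthologousIntronPair

#: Plateau segmentation defaults: intron-body positions past the
#: hexanucleotide at the 5' end, and the near/far segments at the 3' end.
DEFAULT_PLATEAUS = {
    FIVE_PRIME: ((7, 50),),
    "three_prime": ((7, 21), (22, 50)),
}


@dataclass(frozen=True)
class PositionalIdentityProfile:
    end: str
    window: int
    identity: np.ndarray  # fraction identical per position, NaN when no couple reaches it
    denominators: np.ndarray  # couples contributing per position

    def __getitem__(self, position: int) -> float:
        """Identity at a 1-based position."""
        if not 1 <= position <= self.window:
            raise IndexError(f"position {position} outside 1..{self.window}")
        return float(self.identity[position - 1])

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "end": self.end,
                "position": np.arange(1, self.window + 1),
                "identity": self.identity,
                "denominator": self.denominators,
            }
        )


def identity_profile(
    pairs: Sequence[OrthologousIntronPair], end: str, window: int = 50
) -> PositionalIdentityProfile:
    """Fraction of couples with the identical base at each position."""
    if end not in ENDS:
        raise ValueError(f"unknown end {end!r}")
    if window < 1:
        raise ValueError("window must be >= 1")
    if not pairs:
        raise ValueError("empty pair list")
    same = np.zeros(window, dtype=np.int64)
    denom = np.zeros(window, dtype=np.int64)
    for pr in pairs:
        a, b = pr.seq_a, pr.seq_b
        reach = min(len(a), len(b), window)
        for p in range(1, reach + 1):
            ca = a[p - 1] if end == FIVE_PRIME else a[-p]
            cb = b[p - 1] if end == FIVE_PRIME else b[-p]
            denom[p - 1] += 1
            if ca == cb and ca != "N":
                same[p - 1] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        identity = np.where(denom > 0, same / np.maximum(denom, 1), np.nan)
    return PositionalIdentityProfile(
        end=end, window=window, identity=identity, denominators=denom
    )


def plateau_mean(
    profile: PositionalIdentityProfile, from_pos: int, to_pos: int
) -> float:
    """Unweighted mean identity over positions ``from_pos..to_pos``.

    Positions no couple reaches (NaN identity) are excluded from the mean.
    """
    if not 1 <= from_pos <= to_pos <= profile.window:
        raise ValueError(
            f"plateau range {from_pos}..{to_pos} outside 1..{profile.window}"
        )
    segment = profile.identity[from_pos - 1 : to_pos]
    if np.all(np.isnan(segment)):
        raise ValueError("no couple reaches any position in the plateau range")
    return float(np.nanmean(segment))
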