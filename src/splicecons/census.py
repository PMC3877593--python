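"""Hexanucleotide censuses of intron ends.

The intron's first six nucleotides form the 5' splice-site hexanucleotide
(positions 1-2 invariantly GT in canonical introns, positions 3-6 variable);
its last six form the 3' splice-site hexanucleotide, indexed left-to-right
h1..h6 so that h5h6 = AG (positions 1-4 variable). This module extracts the
hexanucleotides, tabulates per-species hexamer usage and per-position base
composition, summarises cross-species mismatch counts, and classifies the 16
"bifunctional" GT....AG hexamers.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import OrthologousIntronPair

FIVE_PRIME = "five_prime"
THREE_PRIME = "three_prime"
ENDS = (FIVE_PRIME, THREE_PRIME)

BASES = ("A", "C", "G", "T")

#: Variable hexanucleotide positions (1-based within the hexamer) per end.
VARIABLE_POSITIONS: dict[str, tuple[int, ...]] = {
    FIVE_PRIME: (3, 4, 5, 6),
    THREE_PRIME: (1, 2, 3, 4),
}

#: All 16 hexanucleotides of the form GT..AG, which could in principle act
#: as either a donor or an acceptor site.
BIFUNCTIONAL_HEXES = tuple(
    f"GT{b1}{b2}AG" for b1, b2 in product(BASES, repeat=2)
)


def _check_end(end: str) -> str:
    if end not in ENDS:
        raise ValueError(f"end must be one of {ENDS}, got {end!r}")
    return end


@dataclass(frozen=True)
class HexPair:
    """One couple's hexanucleotides at one intron end.

    ``n_mismatch`` is the Hamming distance restricted to the four variable
    positions (3-6 at the 5' end, 1-4 at the 3' end).
    """

    end: str
    hex_a: str
    hex_b: str
    n_mismatch: int

    def __post_init__(self) -> None:
        _check_end(self.end)
        if len(self.hex_a) != 6 or len(self.hex_b) != 6:
            raise ValueError("hexanucleotides must have length 6")
        expected = hex_mismatches(self.hex_a, self.hex_b, self.end)
        if self.n_mismatch != expected:
            raise ValueError(
                f"n_mismatch {self.n_mismatch} inconsistent with sequences "
                f"(expected {expected})"
            )


def hex_mismatches(hex_a: str, hex_b: str, end: str) -> int:
    """Hamming distance over the variable positions of one end."""
    return sum(hex_a[p - 1] != hex_b[p - 1] for p in VARIABLE_POSITIONS[_check_end(end)])


def extract_hexes(pair: OrthologousIntronPair) -> tuple[HexPair, HexPair]:
    """The initial and terminal hexanucleotide couple of one intron pair."""
    if len(pair.seq_a) < 12 or len(pair.seq_b) < 12:
        raise ValueError(
            f"({pair.gene_id}, intron {pair.intron_index}): introns must be "
            ">= 12 nt so the two hexanucleotides do not overlap"
        )
    h5a, h5b = pair.seq_a[:6], pair.seq_b[:6]
    h3a, h3b = pair.seq_a[-6:], pair.seq_b[-6:]
    return (
        HexPair(FIVE_PRIME, h5a, h5b, hex_mismatches(h5a, h5b, FIVE_PRIME)),
        HexPair(THREE_PRIME, h3a, h3b, hex_mismatches(h3a, h3b, THREE_PRIME)),
    )


def extract_all_hexes(
    pairs: Iterable[OrthologousIntronPair],
) -> tuple[list[HexPair], list[HexPair]]:
    """Hexanucleotide couples for every intron pair, split by end."""
    fives, threes = [], []
    for p in pairs:
        h5, h3 = extract_hexes(p)
        fives.append(h5)
        threes.append(h3)
    return fives, threes


@dataclass(frozen=True)
class HexCensus:
    """Per-species hexamer counts and per-position base composition."""

    end: str
    n: int
    counts_a: Mapping[str, int]
    counts_b: Mapping[str, int]
    composition_a: pd.DataFrame  # rows: variable positions; cols: A C G T
    composition_b: pd.DataFrame

    @property
    def distinct_a(self) -> int:
        return len(self.counts_a)

    @property
    def distinct_b(self) -> int:
        return len(self.counts_b)

    @property
    def distinct_union(self) -> int:
        """Distinct hexanucleotides pooled over both species."""
        return len(set(self.counts_a) | set(self.counts_b))

    def frequency_frame(self) -> pd.DataFrame:
        """Per-hexamer percentages per species, sorted by mean percentage."""
        hexes = sorted(set(self.counts_a) | set(self.counts_b))
        pct_a = [100.0 * self.counts_a.get(h, 0) / self.n for h in hexes]
        pct_b = [100.0 * self.counts_b.get(h, 0) / self.n for h in hexes]
        df = pd.DataFrame({"sequence": hexes, "pct_a": pct_a, "pct_b": pct_b})
        df["mean_pct"] = (df.pct_a + df.pct_b) / 2.0
        return df.sort_values(
            ["mean_pct", "sequence"], ascending=[False, True], ignore_index=True
        )


def position_composition(
    hex_pairs: Sequence[HexPair], end: str, species: str
) -> pd.DataFrame:
    """Base composition at each variable position for one species.

    Rows are the variable hexamer positions, columns the four bases; each
    row sums to 1.
    """
    _check_end(end)
    if species not in ("a", "b"):
        raise ValueError("species must be 'a' or 'b'")
    if not hex_pairs:
        raise ValueError("empty hexanucleotide list")
    hexes = [hp.hex_a if species == "a" else hp.hex_b for hp in hex_pairs]
    n = len(hexes)
    rows = {}
    for p in VARIABLE_POSITIONS[end]:
        col = Counter(h[p - 1] for h in hexes)
        rows[p] = [col.get(b, 0) / n for b in BASES]
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(BASES))


def hex_frequency_table(hex_pairs: Sequence[HexPair], end: str) -> HexCensus:
    """Census of hexanucleotide usage at one intron end."""
    _check_end(end)
    if not hex_pairs:
        raise ValueError("empty hexanucleotide list")
    if any(hp.end != end for hp in hex_pairs):
        raise ValueError("hex_pairs end does not match requested end")
    counts_a = Counter(hp.hex_a for hp in hex_pairs)
    counts_b = Counter(hp.hex_b for hp in hex_pairs)
    return HexCensus(
        end=end,
        n=len(hex_pairs),
        counts_a=dict(counts_a),
        counts_b=dict(counts_b),
        composition_a=position_composition(hex_pairs, end, "a"),
        composition_b=position_composition(hex_pairs, end, "b"),
    )


def mismatch_distribution(
    hex_pairs: Sequence[HexPair], end: str
) -> tuple[dict[int, float], float]:
    """Histogram (fractions over 0..4 changes) and mean changes per hexamer."""
    _check_end(end)
    if not hex_pairs:
        raise ValueError("empty hexanucleotide list")
    counts = Counter(hp.n_mismatch for hp in hex_pairs)
    n = len(hex_pairs)
    hist = {k: counts.get(k, 0) / n for k in range(5)}
    mean = float(np.sum([k * f for k, f in hist.items()]))
    return hist, mean


def bifunctional_classification(
    hex_pairs_5: Sequence[HexPair], hex_pairs_3: Sequence[HexPair]
) -> dict[str, str]:
    """Classify the 16 GT..AG hexamers by where they are actually used.

    Occurrence pools both species. Categories: ``five_only`` (seen among
    initial hexanucleotides, never terminal), ``three_only``, ``both``,
    ``unused``.
    """
    seen5 = {hp.hex_a for hp in hex_pairs_5} | {hp.hex_b for hp in hex_pairs_5}
    seen3 = {hp.hex_a for hp in hex_pairs_3} | {hp.hex_b for hp in hex_pairs_3}
    out = {}
    for h in BIFUNCTIONAL_HEXES:
        in5, in3 = h in seen5, h in seen3
        out[h] = (
            "both" if in5 and in3
            else "five_only" if in5
            else "three_only" if in3
            else "unused"
        )
    return out
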