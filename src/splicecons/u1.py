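"""U1 snRNA 5' element complementarity with donor splice sites.

The U1 snRNA's 5'-terminal recognition element (written ACTTAC in DNA
alphabet) base-pairs antiparallel with the donor site. Position i of the
5'ss hexanucleotide (5'->3') pairs with U1 position 7-i, so a position is a
match iff it is the Watson-Crick complement of its U1 partner; with the
default element this reduces to a position-wise comparison against the
template GTAAGT, the donor sequence that base-pairs perfectly. Pairing may
also slide up to three nucleotides into the exon tail (registers -3..0).

Strict Watson-Crick matching only by default; G.U wobble pairs (G.T in DNA
space) can be enabled with a flag but are not counted in the standard
scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .census import HexPair

#: Default U1 5' recognition element, written 5'->3' in DNA alphabet.
U1_ELEMENT = "ACTTAC"

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Donor-site positions not constrained to GT.
VARIABLE_SS_POSITIONS = (3, 4, 5, 6)


def _check_dna(seq: str, name: str, length: int) -> None:
    if len(seq) != length or any(c not in "ACGT" for c in seq):
        raise ValueError(f"{name} must be a {length}-mer over ACGT, got {seq!r}")


@dataclass(frozen=True)
class U1MatchResult:
    """Pairing of the 6-nt U1 element against one register of a donor site.

    ``register_shift`` 0 means the element spans the intronic
    hexanucleotide; negative shifts slide it into the exon tail.
    """

    register_shift: int
    matches: tuple[bool, ...]
    n_matches: int

    def __post_init__(self) -> None:
        if not -3 <= self.register_shift <= 0:
            raise ValueError("register_shift must be in -3..0")
        if self.n_matches != sum(self.matches):
            raise ValueError("n_matches inconsistent with match vector")


def pairing_template(u1: str = U1_ELEMENT) -> str:
    """The donor sequence that pairs perfectly with ``u1`` (its reverse
    complement), GTAAGT for the default element."""
    _check_dna(u1, "u1", 6)
    return "".join(_COMPLEMENT[c] for c in reversed(u1))


def _match_vector(segment: str, u1: str, wobble: bool) -> tuple[bool, ...]:
    out = []
    for i, s in enumerate(segment, start=1):
        u = u1[6 - i]  # antiparallel partner
        hit = s == _COMPLEMENT[u]
        if wobble and not hit:
            hit = (s == "G" and u == "T") or (s == "T" and u == "G")
        out.append(hit)
    return tuple(out)


def u1_match_vector(
    five_ss_hex: str, u1: str = U1_ELEMENT, wobble: bool = False
) -> U1MatchResult:
    """Watson-Crick match vector of a donor hexanucleotide at register 0."""
    _check_dna(five_ss_hex, "five_ss_hex", 6)
    _check_dna(u1, "u1", 6)
    matches = _match_vector(five_ss_hex, u1, wobble)
    return U1MatchResult(0, matches, sum(matches))


def u1_best_register(
    exon_tail: str, five_ss_hex: str, u1: str = U1_ELEMENT, wobble: bool = False
) -> U1MatchResult:
    """Best ungapped register over -3..0 within exon_tail + hexanucleotide.

    Ties are broken toward register 0 (the canonical placement over the
    intronic hexanucleotide).
    """
    _check_dna(exon_tail, "exon_tail", 3)
    _check_dna(five_ss_hex, "five_ss_hex", 6)
    _check_dna(u1, "u1", 6)
    window = exon_tail + five_ss_hex
    best: U1MatchResult | None = None
    for shift in (0, -1, -2, -3):
        segment = window[3 + shift : 9 + shift]
        matches = _match_vector(segment, u1, wobble)
        res = U1MatchResult(shift, matches, sum(matches))
        if best is None or res.n_matches > best.n_matches:
            best = res
    assert best is not None
    return best


def u1_aggregate(
    hex_pairs: Sequence[HexPair],
    exon_tails: Sequence[tuple[str, str]] | None = None,
    u1: str = U1_ELEMENT,
    wobble: bool = False,
) -> dict:
    """Population-level U1 pairing summary over donor hexanucleotides.

    Reports, per species and pooled: the match rate at each of the six
    donor positions, the mean match rate over the four variable positions,
    and the frequency of perfect (6/6) sites. When per-couple exon tails
    are supplied, also the fraction of sites whose best pairing uses a
    non-canonical register.
    """
    if not hex_pairs:
        raise ValueError("empty hexanucleotide list")
    species_hexes = {
        "a": [hp.hex_a for hp in hex_pairs],
        "b": [hp.hex_b for hp in hex_pairs],
    }
    out: dict = {"per_position": {}, "mean_variable": {}, "perfect_fraction": {}}
    pooled_rates = np.zeros(6)
    pooled_perfect = 0.0
    for sp, hexes in species_hexes.items():
        vectors = np.array(
            [u1_match_vector(h, u1, wobble).matches for h in hexes], dtype=float
        )
        rates = vectors.mean(axis=0)
        out["per_position"][sp] = rates.tolist()
        out["mean_variable"][sp] = float(
            rates[[p - 1 for p in VARIABLE_SS_POSITIONS]].mean()
        )
        out["perfect_fraction"][sp] = float((vectors.sum(axis=1) == 6).mean())
        pooled_rates += rates / 2.0
        pooled_perfect += out["perfect_fraction"][sp] / 2.0
    out["per_position"]["pooled"] = pooled_rates.tolist()
    out["mean_variable"]["pooled"] = float(
        pooled_rates[[p - 1 for p in VARIABLE_SS_POSITIONS]].mean()
    )
    out["perfect_fraction"]["pooled"] = pooled_perfect
    if exon_tails is not None:
        if len(exon_tails) != len(hex_pairs):
            raise ValueError("exon_tails must align with hex_pairs")
        shifted = 0
        total = 0
        for (tail_a, tail_b), hp in zip(exon_tails, hex_pairs):
            for tail, hexamer in ((tail_a, hp.hex_a), (tail_b, hp.hex_b)):
                total += 1
                if u1_best_register(tail, hexamer, u1, wobble).register_shift != 0:
                    shifted += 1
        out["noncanonical_register_fraction"] = shifted / total
    return out
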