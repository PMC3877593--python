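"""Seeded generator of orthologous intron couples with known ground truth.

Generative model, per couple: an ancestral hexanucleotide is drawn at each
intron end from a configurable usage distribution. At each variable
position, with probability equal to the configured per-position
conservation both descendant species keep the ancestral base; otherwise
species A keeps the ancestral base while species B is resampled uniformly
over the three other bases, so the realised cross-species identity at a
position equals the configured conservation exactly in expectation (no
identity-by-chance correction is needed because the non-conserved lineage is
forced off the ancestral base). The intron body is generated the same way
position by position, with identity set by the background plateau
parameters. Optional ``correlated_motifs`` give ancestors matching a
wildcard pattern an extra chance of retaining the whole hexanucleotide
intact in both species, creating the kind of whole-configuration
conservation excess the motif scan is designed to detect.

Defaults reproduce the study conditions of the 216-couple Mouse/Human
cytokine-receptor reference dataset: its printed hexamer usage
distributions, per-position conservation totals, and body-identity
plateaus.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Sequence

import numpy as np

from .census import BASES, FIVE_PRIME, THREE_PRIME, VARIABLE_POSITIONS
from .conservation import ConservationTable, MotifPattern
from .io import OrthologousIntronPair
from .reference import (
    REFERENCE_HEX3_USAGE,
    REFERENCE_HEX5_USAGE,
    REFERENCE_PLATEAUS,
    REFERENCE_POSITION_TOTALS,
)
from .variants import TranscriptStructure, VariantEvent

__all__ = ["GeneratorConfig", "GroundTruth", "generate_pairs", "generate_transcript_fixture"]

_ALL_HEX5 = tuple("GT" + "".join(t) for t in product(BASES, repeat=4))
_ALL_HEX3 = tuple("".join(t) + "AG" for t in product(BASES, repeat=4))


def _default_usage_5() -> dict[str, float]:
    return {k: v / 100.0 for k, v in REFERENCE_HEX5_USAGE.items()}


def _default_usage_3() -> dict[str, float]:
    return {k: v / 100.0 for k, v in REFERENCE_HEX3_USAGE.items()}


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the couple generator.

    Probabilities are fractions. ``hex5_usage``/``hex3_usage`` list explicit
    hexamer probabilities; leftover mass is spread uniformly over the other
    canonical hexamers of that end. ``correlated_motifs`` entries are
    ``(pattern_symbols, extra_retention)``: ancestors matching the pattern
    keep the whole hexanucleotide intact in both species with that extra
    probability before the per-position model applies.
    """

    n_pairs: int = 216
    seed: int = 0
    hex5_usage: Mapping[str, float] = field(default_factory=_default_usage_5)
    hex3_usage: Mapping[str, float] = field(default_factory=_default_usage_3)
    per_position_conservation_5: tuple[float, float, float, float] = REFERENCE_POSITION_TOTALS[FIVE_PRIME]
    per_position_conservation_3: tuple[float, float, float, float] = REFERENCE_POSITION_TOTALS[THREE_PRIME]
    body_identity_5: float = REFERENCE_PLATEAUS["five_body"]
    body_identity_3_near: float = REFERENCE_PLATEAUS["three_near"]
    body_identity_3_far: float = REFERENCE_PLATEAUS["three_far"]
    intron_length_range: tuple[int, int] = (120, 400)
    correlated_motifs: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        lo, hi = self.intron_length_range
        if lo < 12 or hi < lo:
            raise ValueError("intron_length_range must satisfy 12 <= min <= max")
        for name, usage in (("hex5_usage", self.hex5_usage), ("hex3_usage", self.hex3_usage)):
            total = sum(usage.values())
            if total > 1.0 + 1e-9 or any(v < 0 for v in usage.values()):
                raise ValueError(f"{name} probabilities must be >= 0 and sum to <= 1")
        probs = (
            list(self.per_position_conservation_5)
            + list(self.per_position_conservation_3)
            + [self.body_identity_5, self.body_identity_3_near, self.body_identity_3_far]
            + [w for _, w in self.correlated_motifs]
        )
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")

    def usage_distribution(self, end: str) -> tuple[tuple[str, ...], np.ndarray]:
        """Full 256-hexamer ancestor distribution at one end."""
        explicit = self.hex5_usage if end == FIVE_PRIME else self.hex3_usage
        universe = _ALL_HEX5 if end == FIVE_PRIME else _ALL_HEX3
        unknown = set(explicit) - set(universe)
        if unknown:
            raise ValueError(f"usage map contains non-canonical hexamers: {sorted(unknown)}")
        rest = [h for h in universe if h not in explicit]
        leftover = 1.0 - sum(explicit.values())
        probs = np.array(
            [explicit.get(h, leftover / len(rest) if rest else 0.0) for h in universe]
        )
        probs = probs / probs.sum()
        return universe, probs

    def conservation(self, end: str) -> tuple[float, float, float, float]:
        return (
            self.per_position_conservation_5
            if end == FIVE_PRIME
            else self.per_position_conservation_3
        )


@dataclass(frozen=True)
class GroundTruth:
    """Realised ancestors and retention masks, reproducible from the config.

    ``conserved_5``/``conserved_3`` hold, per couple, the four variable
    positions' retention flags (True = both species kept the ancestral
    base).
    """

    config: GeneratorConfig
    ancestors_5: tuple[str, ...]
    ancestors_3: tuple[str, ...]
    conserved_5: tuple[tuple[bool, ...], ...]
    conserved_3: tuple[tuple[bool, ...], ...]

    def expected_conservation_table(self, end: str) -> ConservationTable:
        """The TRUE per-position conservation implied by the config.

        actual_cons(p, b) = sum over ancestors of P(ancestor) * [base at p
        is b] * P(position retained), with retention boosted for ancestors
        matching a correlated motif. freq_a equals the ancestor marginal
        (species A always keeps the ancestral base); freq_b follows from
        the resampling model.
        """
        universe, probs = self.config.usage_distribution(end)
        cons = self.config.conservation(end)
        varpos = VARIABLE_POSITIONS[end]
        motifs = [
            (MotifPattern(end, s), w)
            for s, w in self.config.correlated_motifs
            if _pattern_end(s) == end
        ]
        freq_a: dict[tuple[int, str], float] = {(p, b): 0.0 for p in varpos for b in BASES}
        freq_b: dict[tuple[int, str], float] = {(p, b): 0.0 for p in varpos for b in BASES}
        actual: dict[tuple[int, str], float] = {(p, b): 0.0 for p in varpos for b in BASES}
        for hexamer, pr in zip(universe, probs):
            boost = 0.0
            for pat, w in motifs:
                if pat.matches(hexamer):
                    boost = w
                    break
            for p, c in zip(varpos, cons):
                b = hexamer[p - 1]
                retain = boost + (1.0 - boost) * c
                freq_a[(p, b)] += pr
                actual[(p, b)] += pr * retain
                # species B carries b when retained; otherwise uniformly one
                # of the three other bases
                freq_b[(p, b)] += pr * retain
                for other in BASES:
                    if other != b:
                        freq_b[(p, other)] += pr * (1.0 - retain) / 3.0
        return ConservationTable.from_values(
            end=end,
            n=self.config.n_pairs,
            freq_a=freq_a,
            freq_b=freq_b,
            actual_cons=actual,
        )

    def true_pattern_probability(self, pattern: MotifPattern) -> float:
        """Exact probability that both species jointly match ``pattern``."""
        universe, probs = self.config.usage_distribution(pattern.end)
        cons = dict(zip(VARIABLE_POSITIONS[pattern.end], self.config.conservation(pattern.end)))
        motifs = [
            (MotifPattern(pattern.end, s), w)
            for s, w in self.config.correlated_motifs
            if _pattern_end(s) == pattern.end
        ]
        total = 0.0
        for hexamer, pr in zip(universe, probs):
            if not pattern.matches(hexamer):
                continue
            boost = 0.0
            for pat, w in motifs:
                if pat.matches(hexamer):
                    boost = w
                    break
            keep_all = 1.0
            for p, _ in pattern.fixed_variable:
                keep_all *= cons[p]
            total += pr * (boost + (1.0 - boost) * keep_all)
        return total

    def to_json(self, path) -> None:
        payload = {
            "config": {
                "n_pairs": self.config.n_pairs,
                "seed": self.config.seed,
                "hex5_usage": dict(self.config.hex5_usage),
                "hex3_usage": dict(self.config.hex3_usage),
                "per_position_conservation_5": list(self.config.per_position_conservation_5),
                "per_position_conservation_3": list(self.config.per_position_conservation_3),
                "body_identity_5": self.config.body_identity_5,
                "body_identity_3_near": self.config.body_identity_3_near,
                "body_identity_3_far": self.config.body_identity_3_far,
                "intron_length_range": list(self.config.intron_length_range),
                "correlated_motifs": [list(m) for m in self.config.correlated_motifs],
            },
            "ancestors_5": list(self.ancestors_5),
            "ancestors_3": list(self.ancestors_3),
            "conserved_5": [list(m) for m in self.conserved_5],
            "conserved_3": [list(m) for m in self.conserved_3],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _pattern_end(symbols: str) -> str:
    return FIVE_PRIME if symbols.startswith("GT") else THREE_PRIME


_OTHER_BASES = {b: tuple(o for o in BASES if o != b) for b in BASES}


def _mutate(ancestral: str, conserved: Sequence[bool], varpos: Sequence[int], rng) -> str:
    """Species-B hexanucleotide given the ancestor and retention flags."""
    out = list(ancestral)
    for p, keep in zip(varpos, conserved):
        if not keep:
            out[p - 1] = _OTHER_BASES[ancestral[p - 1]][rng.integers(3)]
    return "".join(out)


def _body(identities: np.ndarray, rng) -> tuple[str, str]:
    """Ancestor-derived body for both species with per-position identity."""
    m = len(identities)
    if m == 0:
        return "", ""
    anc = rng.integers(4, size=m)
    keep = rng.random(m) < identities
    b = anc.copy()
    off = (anc[~keep] + 1 + rng.integers(3, size=int((~keep).sum()))) % 4
    b[~keep] = off
    lut = np.array(list("ACGT"))
    return "".join(lut[anc]), "".join(lut[b])


def generate_pairs(
    config: GeneratorConfig,
) -> tuple[list[OrthologousIntronPair], GroundTruth]:
    """Generate ``config.n_pairs`` orthologous intron couples.

    Output is bit-reproducible from (config, seed): a single generator
    stream drives every draw.
    """
    rng = np.random.default_rng(config.seed)
    hex5_universe, hex5_probs = config.usage_distribution(FIVE_PRIME)
    hex3_universe, hex3_probs = config.usage_distribution(THREE_PRIME)
    cons5 = np.array(config.per_position_conservation_5)
    cons3 = np.array(config.per_position_conservation_3)
    motifs5 = [
        (MotifPattern(FIVE_PRIME, s), w)
        for s, w in config.correlated_motifs
        if _pattern_end(s) == FIVE_PRIME
    ]
    motifs3 = [
        (MotifPattern(THREE_PRIME, s), w)
        for s, w in config.correlated_motifs
        if _pattern_end(s) == THREE_PRIME
    ]

    lo, hi = config.intron_length_range
    idx5 = rng.choice(len(hex5_universe), size=config.n_pairs, p=hex5_probs)
    idx3 = rng.choice(len(hex3_universe), size=config.n_pairs, p=hex3_probs)
    lengths = rng.integers(lo, hi + 1, size=config.n_pairs)

    pairs: list[OrthologousIntronPair] = []
    anc5_list, anc3_list, mask5_list, mask3_list = [], [], [], []
    for i in range(config.n_pairs):
        anc5 = hex5_universe[idx5[i]]
        anc3 = hex3_universe[idx3[i]]
        keep5 = _retention_mask(anc5, cons5, motifs5, rng)
        keep3 = _retention_mask(anc3, cons3, motifs3, rng)
        hex5_b = _mutate(anc5, keep5, VARIABLE_POSITIONS[FIVE_PRIME], rng)
        hex3_b = _mutate(anc3, keep3, VARIABLE_POSITIONS[THREE_PRIME], rng)

        length = int(lengths[i])
        n_body = length - 12
        ids = np.array([_body_identity(config, k + 7, length) for k in range(n_body)])
        body_a, body_b = _body(ids, rng)

        seq_a = anc5 + body_a + anc3
        seq_b = hex5_b + body_b + hex3_b
        pairs.append(
            OrthologousIntronPair(
                gene_id=f"sim{i + 1:05d}", intron_index=1, seq_a=seq_a, seq_b=seq_b
            )
        )
        anc5_list.append(anc5)
        anc3_list.append(anc3)
        mask5_list.append(tuple(bool(x) for x in keep5))
        mask3_list.append(tuple(bool(x) for x in keep3))
    truth = GroundTruth(
        config=config,
        ancestors_5=tuple(anc5_list),
        ancestors_3=tuple(anc3_list),
        conserved_5=tuple(mask5_list),
        conserved_3=tuple(mask3_list),
    )
    return pairs, truth


def _retention_mask(ancestor: str, cons: np.ndarray, motifs, rng) -> np.ndarray:
    boost = 0.0
    for pat, w in motifs:
        if pat.matches(ancestor):
            boost = w
            break
    if boost and rng.random() < boost:
        return np.ones(4, dtype=bool)
    return rng.random(4) < cons


def _body_identity(config: GeneratorConfig, position: int, length: int) -> float:
    """Background identity for intron position ``position`` (1-based from
    the 5' end) in an intron of ``length`` nt. The 3' segmentation wins
    where the two 50-nt windows would overlap."""
    d = length - position + 1  # 1-based distance from the 3' end
    if d <= 21:
        return config.body_identity_3_near
    if d <= 50:
        return config.body_identity_3_far
    return config.body_identity_5


# --------------------------------------------------------------------------
# transcript fixtures


def generate_transcript_fixture(
    kind: str,
    *,
    gene_id: str = "GENE1",
    exon_lengths: Sequence[int] = (150, 120, 90, 216, 130, 100, 140, 110),
    intron_length: int = 300,
    exon_index: int = 4,
    last_exon_index: int | None = None,
    offset: int = -18,
) -> tuple[TranscriptStructure, TranscriptStructure, VariantEvent]:
    """Construct a canonical/variant transcript pair with a known event.

    ``kind``: ``exon_skipping`` (drops exons ``exon_index`` through
    ``last_exon_index``, default a single exon), ``alt_3ss`` (shifts the
    acceptor boundary of ``exon_index`` by ``offset``) or ``alt_5ss``
    (shifts its donor boundary). Returns (canonical, variant, expected
    event).
    """
    pos = 1
    exons = []
    for ln in exon_lengths:
        if ln < 1:
            raise ValueError("exon lengths must be positive")
        exons.append((pos, pos + ln - 1))
        pos += ln + intron_length
    canonical = TranscriptStructure(f"{gene_id}_canonical", gene_id, tuple(exons))
    n = len(exons)
    if not 1 <= exon_index <= n:
        raise ValueError("exon_index out of range")

    if kind == "exon_skipping":
        last = exon_index if last_exon_index is None else last_exon_index
        if not exon_index <= last <= n:
            raise ValueError("invalid skip range")
        vexons = tuple(e for k, e in enumerate(exons, start=1) if not exon_index <= k <= last)
        if not vexons:
            raise ValueError("cannot skip every exon")
        expected = VariantEvent(
            kind="exon_skipping",
            gene_id=gene_id,
            canonical_exons=(exon_index, last),
            length_change_nt=-sum(exon_lengths[exon_index - 1 : last]),
        )
    elif kind in ("alt_3ss", "alt_5ss"):
        if offset == 0:
            raise ValueError("offset must be nonzero")
        s, e = exons[exon_index - 1]
        if kind == "alt_3ss":
            new = (s + offset, e)
            if not s - intron_length < new[0] <= e:
                raise ValueError("offset degenerate for this exon geometry")
            expected = VariantEvent(
                kind="alt_3ss",
                gene_id=gene_id,
                canonical_exons=(exon_index, exon_index),
                offset_nt=offset,
                length_change_nt=-offset,
            )
        else:
            new = (s, e + offset)
            if not s <= new[1] < e + intron_length:
                raise ValueError("offset degenerate for this exon geometry")
            expected = VariantEvent(
                kind="alt_5ss",
                gene_id=gene_id,
                canonical_exons=(exon_index, exon_index),
                offset_nt=offset,
                length_change_nt=offset,
            )
        vexons = tuple(new if k == exon_index else e2 for k, e2 in enumerate(exons, start=1))
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    variant = TranscriptStructure(f"{gene_id}_variant_{kind}", gene_id, vexons)
    return canonical, variant, expected
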