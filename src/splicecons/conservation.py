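"""Random-association conservation model and exact binomial motif tests.

The model: for each variable hexanucleotide position p and base b, the
*random* conservation is the product of the two species' marginal base
frequencies, freq_A(p,b) * freq_B(p,b) — the chance both species carry b at
p if the two lineages were associated at random. The *actual* conservation
is the observed fraction of orthologous couples carrying b at p in both
species. The random probability of a multi-position motif (a wildcard
pattern such as GTGAGx or TTxxAG) is the product of the per-position actual
conservation values of its fixed bases, i.e. the joint conservation expected
if neighbouring positions were conserved independently. Over- or
under-representation of the motif's actual joint frequency relative to this
null is assessed with exact one-tailed binomial tests on the raw counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

from .census import BASES, ENDS, FIVE_PRIME, THREE_PRIME, VARIABLE_POSITIONS, HexPair

__all__ = [
    "ConservationTable",
    "MotifPattern",
    "MotifResult",
    "random_position_conservation",
    "actual_position_conservation",
    "conservation_table",
    "motif_random_probability",
    "motif_actual_frequency",
    "motif_count",
    "binomial_sd",
    "binomial_tail_test",
    "enumerate_patterns",
    "motif_scan",
    "species_composition_test",
]


def random_position_conservation(freq_a: float, freq_b: float) -> float:
    """Chance that both species carry a base present at marginal
    frequencies ``freq_a`` and ``freq_b`` under random association."""
    if not (0.0 <= freq_a <= 1.0 and 0.0 <= freq_b <= 1.0):
        raise ValueError("frequencies must lie in [0, 1]")
    return freq_a * freq_b


def actual_position_conservation(
    hex_pairs: Sequence[HexPair], position: int, base: str
) -> float:
    """Fraction of couples with ``base`` at ``position`` in both species."""
    if not hex_pairs:
        raise ValueError("empty hexanucleotide list")
    end = hex_pairs[0].end
    if position not in VARIABLE_POSITIONS[end]:
        raise ValueError(f"position {position} is not variable at the {end} end")
    i = position - 1
    hits = sum(1 for hp in hex_pairs if hp.hex_a[i] == base and hp.hex_b[i] == base)
    return hits / len(hex_pairs)


def binomial_sd(n: int, p: float) -> float:
    """Binomial standard deviation sqrt(n p (1-p)), in count units."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    return float(np.sqrt(n * p * (1.0 - p)))


def binomial_tail_test(k: int, n: int, p0: float, tail: str) -> float:
    """Exact one-tailed binomial test, observed value included in the tail.

    ``upper``: P(X >= k); ``lower``: P(X <= k) for X ~ Binomial(n, p0).
    Degenerate nulls (p0 of 0 or 1) return 1 when the observation is the
    forced value and 0 otherwise.
    """
    if not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n")
    if tail not in ("upper", "lower"):
        raise ValueError("tail must be 'upper' or 'lower'")
    if p0 <= 0.0:
        if p0 < 0.0:
            raise ValueError("p0 must lie in [0, 1]")
        return 1.0 if (tail == "lower" or k == 0) else 0.0
    if p0 >= 1.0:
        if p0 > 1.0:
            raise ValueError("p0 must lie in [0, 1]")
        return 1.0 if (tail == "upper" or k == n) else 0.0
    if tail == "upper":
        return float(binom.sf(k - 1, n, p0))
    return float(binom.cdf(k, n, p0))


@dataclass(frozen=True)
class ConservationTable:
    """Per (variable position, base) conservation at one intron end.

    ``freq_a``/``freq_b`` are marginal base frequencies per species,
    ``random_cons`` their product, ``actual_cons`` the observed both-species
    conservation. All are fractions keyed by ``(position, base)``. ``n`` is
    the number of couples behind the observed values (used for the exact
    tests); tables built from published percentages carry the published n.
    """

    end: str
    n: int
    freq_a: Mapping[tuple[int, str], float]
    freq_b: Mapping[tuple[int, str], float]
    random_cons: Mapping[tuple[int, str], float]
    actual_cons: Mapping[tuple[int, str], float]
    p_value: Mapping[tuple[int, str], float] = field(default_factory=dict)

    @property
    def positions(self) -> tuple[int, ...]:
        return VARIABLE_POSITIONS[self.end]

    def position_totals(self) -> pd.DataFrame:
        """Totals of random and actual conservation over bases, per position."""
        rows = []
        for p in self.positions:
            rows.append(
                {
                    "position": p,
                    "random_total": sum(self.random_cons[(p, b)] for b in BASES),
                    "actual_total": sum(self.actual_cons[(p, b)] for b in BASES),
                }
            )
        return pd.DataFrame(rows)

    def frame(self) -> pd.DataFrame:
        rows = []
        for p in self.positions:
            for b in BASES:
                rows.append(
                    {
                        "position": p,
                        "base": b,
                        "freq_a": self.freq_a[(p, b)],
                        "freq_b": self.freq_b[(p, b)],
                        "random_cons": self.random_cons[(p, b)],
                        "actual_cons": self.actual_cons[(p, b)],
                        "p_value": self.p_value.get((p, b), float("nan")),
                    }
                )
        return pd.DataFrame(rows)

    @classmethod
    def from_values(
        cls,
        end: str,
        n: int,
        freq_a: Mapping[tuple[int, str], float],
        freq_b: Mapping[tuple[int, str], float],
        actual_cons: Mapping[tuple[int, str], float],
        random_cons: Mapping[tuple[int, str], float] | None = None,
    ) -> "ConservationTable":
        """Build a table from externally supplied fractions (e.g. published
        per-position values); ``random_cons`` defaults to freq_a * freq_b."""
        if random_cons is None:
            random_cons = {
                k: random_position_conservation(freq_a[k], freq_b[k]) for k in freq_a
            }
        return cls(
            end=end,
            n=n,
            freq_a=dict(freq_a),
            freq_b=dict(freq_b),
            random_cons=dict(random_cons),
            actual_cons=dict(actual_cons),
        )


def conservation_table(hex_pairs: Sequence[HexPair], end: str) -> ConservationTable:
    """Estimate the per-position conservation table from hexamer couples.

    Each cell's p-value is the exact one-tailed test of the observed
    both-species count against the random-association probability
    freq_a * freq_b (upper tail when actual exceeds random, lower otherwise).
    """
    if not hex_pairs:
        raise ValueError("empty hexanucleotide list")
    if end not in ENDS:
        raise ValueError(f"unknown end {end!r}")
    if any(hp.end != end for hp in hex_pairs):
        raise ValueError("hex_pairs end does not match requested end")
    n = len(hex_pairs)
    freq_a: dict[tuple[int, str], float] = {}
    freq_b: dict[tuple[int, str], float] = {}
    random_cons: dict[tuple[int, str], float] = {}
    actual_cons: dict[tuple[int, str], float] = {}
    p_value: dict[tuple[int, str], float] = {}
    for p in VARIABLE_POSITIONS[end]:
        i = p - 1
        for b in BASES:
            ca = sum(1 for hp in hex_pairs if hp.hex_a[i] == b)
            cb = sum(1 for hp in hex_pairs if hp.hex_b[i] == b)
            k = sum(1 for hp in hex_pairs if hp.hex_a[i] == b and hp.hex_b[i] == b)
            fa, fb = ca / n, cb / n
            p0 = random_position_conservation(fa, fb)
            freq_a[(p, b)], freq_b[(p, b)] = fa, fb
            random_cons[(p, b)] = p0
            actual_cons[(p, b)] = k / n
            tail = "upper" if k / n > p0 else "lower"
            p_value[(p, b)] = binomial_tail_test(k, n, p0, tail)
    return ConservationTable(
        end=end,
        n=n,
        freq_a=freq_a,
        freq_b=freq_b,
        random_cons=random_cons,
        actual_cons=actual_cons,
        p_value=p_value,
    )


@dataclass(frozen=True)
class MotifPattern:
    """A wildcard hexanucleotide pattern, e.g. GTGAGx or TTxxAG.

    Six symbols over {A,C,G,T,x}; the invariant dinucleotide (GT at
    positions 1-2 for initial patterns, AG at positions 5-6 for terminal
    ones) must be spelled out, wildcards may appear only at variable
    positions, and at least one variable position must be fixed.
    """

    end: str
    symbols: str

    def __post_init__(self) -> None:
        if self.end not in ENDS:
            raise ValueError(f"unknown end {self.end!r}")
        s = self.symbols
        if len(s) != 6 or any(c not in "ACGTx" for c in s):
            raise ValueError(f"pattern must be 6 symbols over ACGTx, got {s!r}")
        if self.end == FIVE_PRIME and not s.startswith("GT"):
            raise ValueError("initial patterns must fix positions 1-2 as GT")
        if self.end == THREE_PRIME and not s.endswith("AG"):
            raise ValueError("terminal patterns must fix positions 5-6 as AG")
        if not self.fixed_variable:
            raise ValueError("at least one variable position must be fixed")

    @property
    def fixed_variable(self) -> tuple[tuple[int, str], ...]:
        """(position, base) for every fixed variable position."""
        return tuple(
            (p, self.symbols[p - 1])
            for p in VARIABLE_POSITIONS[self.end]
            if self.symbols[p - 1] != "x"
        )

    @property
    def n_fixed_variable(self) -> int:
        return len(self.fixed_variable)

    def matches(self, hexamer: str) -> bool:
        return all(hexamer[p - 1] == b for p, b in self.fixed_variable)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.symbols} ({self.end})"


def motif_random_probability(
    pattern: MotifPattern, actual_cons: ConservationTable
) -> float:
    """Random-association probability of joint conservation of a motif:
    the product of per-position actual conservation over its fixed bases."""
    if pattern.end != actual_cons.end:
        raise ValueError("pattern end does not match conservation table end")
    prob = 1.0
    for p, b in pattern.fixed_variable:
        try:
            prob *= actual_cons.actual_cons[(p, b)]
        except KeyError as exc:
            raise ValueError(
                f"conservation table lacks an entry for position {p}, base {b}"
            ) from exc
    return prob


def motif_count(hex_pairs: Sequence[HexPair], pattern: MotifPattern) -> int:
    """Number of couples whose hexanucleotides match the pattern in BOTH
    species at every fixed position (wildcards unconstrained)."""
    if hex_pairs and hex_pairs[0].end != pattern.end:
        raise ValueError("pattern end does not match hex_pairs end")
    return sum(
        1
        for hp in hex_pairs
        if pattern.matches(hp.hex_a) and pattern.matches(hp.hex_b)
    )


def motif_actual_frequency(hex_pairs: Sequence[HexPair], pattern: MotifPattern) -> float:
    """Observed fraction of couples jointly matching the pattern."""
    if not hex_pairs:
        raise ValueError("empty hexanucleotide list")
    return motif_count(hex_pairs, pattern) / len(hex_pairs)


@dataclass(frozen=True)
class MotifResult:
    """One motif's over/under-representation result."""

    pattern: MotifPattern
    random_prob: float
    binomial_sd_counts: float
    actual_freq: float
    excess: float
    p_value: float
    direction: str  # "over" iff excess > 0, else "under"
    flagged: bool
    q_value: float  # Benjamini-Hochberg adjusted p (extension beyond the raw scan)


def enumerate_patterns(end: str) -> list[MotifPattern]:
    """All wildcard patterns with 1-4 fixed variable positions at one end.

    Sum over k of C(4,k) * 4^k = 624 patterns per end.
    """
    varpos = VARIABLE_POSITIONS[end]
    inv = "GT" if end == FIVE_PRIME else "AG"
    patterns = []
    for k in range(1, 5):
        for posset in combinations(varpos, k):
            for bases in product(BASES, repeat=k):
                symbols = ["x"] * 6
                if end == FIVE_PRIME:
                    symbols[0], symbols[1] = inv[0], inv[1]
                else:
                    symbols[4], symbols[5] = inv[0], inv[1]
                for p, b in zip(posset, bases):
                    symbols[p - 1] = b
                patterns.append(MotifPattern(end, "".join(symbols)))
    return patterns


def _encode(hex_pairs: Sequence[HexPair]) -> tuple[np.ndarray, np.ndarray]:
    code = {b: i for i, b in enumerate(BASES)}
    code["N"] = 4
    a = np.array([[code.get(c, 4) for c in hp.hex_a] for hp in hex_pairs], dtype=np.int8)
    b = np.array([[code.get(c, 4) for c in hp.hex_b] for hp in hex_pairs], dtype=np.int8)
    return a, b


def motif_scan(
    hex_pairs: Sequence[HexPair],
    end: str,
    actual_cons: ConservationTable,
    alpha: float = 0.05,
) -> list[MotifResult]:
    """Exact binomial over/under-representation scan of all 624 motifs.

    For each pattern the null probability is the random-association product
    from ``actual_cons``; the observed count of jointly matching couples is
    tested one-tailed (upper when the observed frequency exceeds the null,
    lower otherwise) and flagged at level ``alpha``. A Benjamini-Hochberg
    adjusted p-value is reported alongside the raw p. Results sorted by p.
    """
    if not hex_pairs:
        raise ValueError("empty hexanucleotide list")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    n = len(hex_pairs)
    arr_a, arr_b = _encode(hex_pairs)
    code = {b: i for i, b in enumerate(BASES)}
    patterns = enumerate_patterns(end)
    ks = np.empty(len(patterns), dtype=np.int64)
    p0s = np.empty(len(patterns), dtype=np.float64)
    for i, pat in enumerate(patterns):
        mask = np.ones(n, dtype=bool)
        for p, b in pat.fixed_variable:
            c = code[b]
            mask &= (arr_a[:, p - 1] == c) & (arr_b[:, p - 1] == c)
        ks[i] = int(mask.sum())
        p0s[i] = motif_random_probability(pat, actual_cons)
    freqs = ks / n
    over = freqs > p0s
    # vectorised exact tails; degenerate p0 handled per the scalar contract
    pvals = np.ones(len(patterns))
    ok = (p0s > 0.0) & (p0s < 1.0)
    up = ok & over
    lo = ok & ~over
    pvals[up] = binom.sf(ks[up] - 1, n, p0s[up])
    pvals[lo] = binom.cdf(ks[lo], n, p0s[lo])
    deg0 = ~ok & (p0s <= 0.0)
    pvals[deg0 & over] = 0.0  # observed matches under an impossible null
    m = len(patterns)
    order = np.argsort(pvals, kind="stable")
    q = np.empty(m)
    q[order] = np.minimum.accumulate((pvals[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    q = np.minimum(q, 1.0)
    results = [
        MotifResult(
            pattern=pat,
            random_prob=float(p0s[i]),
            binomial_sd_counts=binomial_sd(n, float(p0s[i])),
            actual_freq=float(freqs[i]),
            excess=float(freqs[i] - p0s[i]),
            p_value=float(pvals[i]),
            direction="over" if freqs[i] > p0s[i] else "under",
            flagged=bool(pvals[i] <= alpha),
            q_value=float(q[i]),
        )
        for i, pat in enumerate(patterns)
    ]
    results.sort(key=lambda r: (r.p_value, r.pattern.symbols))
    return results


def motif_results_frame(results: Iterable[MotifResult]) -> pd.DataFrame:
    rows = [
        {
            "pattern": r.pattern.symbols,
            "random_pct": 100.0 * r.random_prob,
            "sd_counts": r.binomial_sd_counts,
            "actual_pct": 100.0 * r.actual_freq,
            "excess_pct": 100.0 * r.excess,
            "p_value": r.p_value,
            "q_value": r.q_value,
            "direction": r.direction,
            "flagged": r.flagged,
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def species_composition_test(count_a: int, count_b: int, n: int) -> float:
    """One-tailed exact test for a species difference in base usage.

    The larger species count is tested against the other species' observed
    proportion as the null; the test direction therefore follows the sign
    of ``count_a - count_b``.
    """
    if not (0 <= count_a <= n and 0 <= count_b <= n):
        raise ValueError("counts must lie in [0, n]")
    hi, lo = max(count_a, count_b), min(count_a, count_b)
    return binomial_tail_test(hi, n, lo / n, "upper")
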