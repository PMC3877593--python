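"""Random-association conservation model and exact binomial tests."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, strategies as st

import splicecons as sc
from splicecons.conservation import motif_results_frame
from splicecons.reference import reference_conservation_table


def brute_force_tail(k: int, n: int, p0: float, tail: str) -> float:
    """Independent oracle: direct summation of the binomial pmf."""
    p = Fraction(p0)  # exact value of the float, so the oracle is exact
    rng = range(k, n + 1) if tail == "upper" else range(0, k + 1)
    total = sum(
        Fraction(math.comb(n, j)) * p**j * (1 - p) ** (n - j) for j in rng
    )
    return float(total)


class TestRandomPositionConservation:
    def test_worked_single_position_example(self):
        assert sc.random_position_conservation(0.597, 0.570) == pytest.approx(
            0.3403, abs=5e-5
        )

    def test_invariant_positions_and_absent_bases(self):
        assert sc.random_position_conservation(1.0, 1.0) == 1.0
        assert sc.random_position_conservation(0.5, 0.0) == 0.0

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            sc.random_position_conservation(1.2, 0.5)


class TestActualPositionConservation:
    def test_all_conserved(self):
        hps = [sc.HexPair(sc.FIVE_PRIME, "GTAAGT", "GTAAGT", 0)] * 2
        assert sc.actual_position_conservation(hps, 3, "A") == 1.0

    def test_hand_count(self):
        hps = [
            sc.HexPair(sc.FIVE_PRIME, "GTAAGT", "GTAAGT", 0),
            sc.HexPair(sc.FIVE_PRIME, "GTAAGT", "GTGAGT", 1),
        ]
        assert sc.actual_position_conservation(hps, 3, "A") == 0.5

    def test_partition_identity_over_bases(self, sim_pairs):
        """Summing actual conservation over bases at a position gives the
        fraction of couples identical there."""
        hex5, _ = sc.extract_all_hexes(sim_pairs)
        for p in (3, 4, 5, 6):
            total = sum(sc.actual_position_conservation(hex5, p, b) for b in "ACGT")
            identical = sum(
                1 for hp in hex5 if hp.hex_a[p - 1] == hp.hex_b[p - 1]
            ) / len(hex5)
            assert total == pytest.approx(identical, abs=1e-12)

    def test_invariant_position_rejected(self):
        hps = [sc.HexPair(sc.FIVE_PRIME, "GTAAGT", "GTAAGT", 0)]
        with pytest.raises(ValueError):
            sc.actual_position_conservation(hps, 1, "G")


class TestMotifRandomProbability:
    """Recomputation of the published random probabilities from the
    published per-position actual-conservation values."""

    @pytest.mark.parametrize(
        "end, pattern, expected_pct",
        [
            (sc.FIVE_PRIME, "GTAAGT", 14.81),
            (sc.FIVE_PRIME, "GTAAGx", 32.65),
            (sc.FIVE_PRIME, "GTGAGx", 19.29),
            (sc.FIVE_PRIME, "GTGAGT", 8.75),
            (sc.FIVE_PRIME, "GTAAGG", 2.72),
            (sc.THREE_PRIME, "TTxxAG", 20.70),
            (sc.THREE_PRIME, "TTTxAG", 3.45),
            (sc.THREE_PRIME, "TTTCAG", 1.74),
            (sc.THREE_PRIME, "TTTTAG", 0.72),
            (sc.THREE_PRIME, "CTGCAG", 0.54),
        ],
    )
    def test_published_random_probabilities(self, end, pattern, expected_pct):
        table = reference_conservation_table(end)
        prob = sc.motif_random_probability(sc.MotifPattern(end, pattern), table)
        assert round(100 * prob, 2) == expected_pct

    def test_missing_table_entry_is_an_error(self):
        table = reference_conservation_table(sc.FIVE_PRIME)
        trimmed = sc.ConservationTable(
            end=sc.FIVE_PRIME, n=table.n, freq_a={}, freq_b={},
            random_cons={}, actual_cons={(3, "A"): 0.5},
        )
        with pytest.raises(ValueError, match="lacks an entry"):
            sc.motif_random_probability(
                sc.MotifPattern(sc.FIVE_PRIME, "GTAAGT"), trimmed
            )

    def test_pattern_validation(self):
        with pytest.raises(ValueError):
            sc.MotifPattern(sc.FIVE_PRIME, "GTxxxx")  # no fixed variable position
        with pytest.raises(ValueError):
            sc.MotifPattern(sc.FIVE_PRIME, "ATAAGT")  # wrong invariant dinucleotide
        with pytest.raises(ValueError):
            sc.MotifPattern(sc.THREE_PRIME, "TTTCAT")


class TestMotifActualFrequency:
    def test_all_matching(self):
        hps = [sc.HexPair(sc.FIVE_PRIME, "GTGAGT", "GTGAGT", 0)] * 2
        pat = sc.MotifPattern(sc.FIVE_PRIME, "GTGAGx")
        assert sc.motif_actual_frequency(hps, pat) == 1.0

    def test_both_species_must_match(self):
        hps = [
            sc.HexPair(sc.FIVE_PRIME, "GTGAGT", "GTGAGT", 0),
            sc.HexPair(sc.FIVE_PRIME, "GTGAGT", "GTAAGT", 1),
        ]
        pat = sc.MotifPattern(sc.FIVE_PRIME, "GTGAGx")
        assert sc.motif_actual_frequency(hps, pat) == 0.5

    def test_fully_fixed_pattern_equals_conserved_hexamer_frequency(self, sim_pairs):
        hex5, _ = sc.extract_all_hexes(sim_pairs)
        pat = sc.MotifPattern(sc.FIVE_PRIME, "GTGAGT")
        direct = sum(
            1 for hp in hex5 if hp.hex_a == "GTGAGT" and hp.hex_b == "GTGAGT"
        ) / len(hex5)
        assert sc.motif_actual_frequency(hex5, pat) == pytest.approx(direct, abs=1e-12)

    def test_equivalence_with_brute_force_on_all_624_patterns(self):
        """The vectorised scan counts agree with naive per-couple string
        matching for every enumerable pattern on a small input."""
        cfg = sc.GeneratorConfig(n_pairs=20, seed=5, intron_length_range=(12, 12))
        pairs, _ = sc.generate_pairs(cfg)
        hex5, _ = sc.extract_all_hexes(pairs)
        table = sc.conservation_table(hex5, sc.FIVE_PRIME)
        results = {r.pattern.symbols: r for r in sc.motif_scan(hex5, sc.FIVE_PRIME, table)}
        assert len(results) == 624
        for symbols, res in results.items():
            naive = sum(
                1
                for hp in hex5
                if all(
                    s == "x" or (hp.hex_a[i] == s and hp.hex_b[i] == s)
                    for i, s in enumerate(symbols)
                )
            ) / len(hex5)
            assert res.actual_freq == pytest.approx(naive, abs=1e-12)

    @given(st.data())
    def test_refinement_monotonicity(self, data):
        """Fixing an additional position never increases the random
        probability or the actual frequency."""
        cfg = sc.GeneratorConfig(n_pairs=30, seed=9, intron_length_range=(12, 12))
        pairs, _ = sc.generate_pairs(cfg)
        hex5, _ = sc.extract_all_hexes(pairs)
        table = sc.conservation_table(hex5, sc.FIVE_PRIME)
        base = data.draw(
            st.lists(st.sampled_from("ACGT"), min_size=1, max_size=3), label="fixed"
        )
        positions = data.draw(st.permutations([3, 4, 5, 6]), label="order")
        symbols = ["G", "T", "x", "x", "x", "x"]
        for p, b in zip(positions, base):
            symbols[p - 1] = b
        coarse = sc.MotifPattern(sc.FIVE_PRIME, "".join(symbols))
        extra_pos = positions[len(base)]
        symbols[extra_pos - 1] = data.draw(st.sampled_from("ACGT"), label="extra")
        fine = sc.MotifPattern(sc.FIVE_PRIME, "".join(symbols))
        assert sc.motif_random_probability(fine, table) <= sc.motif_random_probability(
            coarse, table
        ) + 1e-15
        assert sc.motif_actual_frequency(hex5, fine) <= sc.motif_actual_frequency(
            hex5, coarse
        ) + 1e-15


class TestBinomialSD:
    @pytest.mark.parametrize(
        "n, p, expected",
        [(216, 0.2070, 5.95), (216, 0.0345, 2.68), (100, 0.0, 0.0)],
    )
    def test_count_scale_sd(self, n, p, expected):
        assert round(sc.binomial_sd(n, p), 2) == expected


class TestBinomialTailTest:
    def test_full_support_lower_tail(self):
        assert sc.binomial_tail_test(30, 30, 0.3, "lower") == 1.0

    def test_closed_form_at_k_zero(self):
        p = sc.binomial_tail_test(0, 216, 0.1929, "lower")
        assert p == pytest.approx((1 - 0.1929) ** 216, rel=1e-9)

    def test_upper_tail_example_against_oracle(self):
        # the comparison behind the GTGAGx over-representation call
        p = sc.binomial_tail_test(55, 216, 0.1929, "upper")
        assert p == pytest.approx(brute_force_tail(55, 216, 0.1929, "upper"), rel=1e-9)
        assert 0.01 < p < 0.05

    @pytest.mark.parametrize("n", [1, 7, 23, 50])
    @pytest.mark.parametrize("p0", [0.02, 0.1929, 0.5, 0.83])
    def test_exact_for_all_k_small_n(self, n, p0):
        """Agreement with direct pmf summation for every k at n <= 50."""
        for k in range(n + 1):
            for tail in ("upper", "lower"):
                assert sc.binomial_tail_test(k, n, p0, tail) == pytest.approx(
                    brute_force_tail(k, n, p0, tail), rel=1e-9, abs=1e-300
                )

    def test_degenerate_nulls(self):
        assert sc.binomial_tail_test(0, 10, 0.0, "upper") == 1.0
        assert sc.binomial_tail_test(3, 10, 0.0, "upper") == 0.0
        assert sc.binomial_tail_test(10, 10, 1.0, "lower") == 1.0
        assert sc.binomial_tail_test(9, 10, 1.0, "lower") == 0.0


class TestSpeciesCompositionTest:
    def test_matches_oracle_for_published_style_counts(self):
        p = sc.species_composition_test(25, 16, 216)
        assert p == pytest.approx(brute_force_tail(25, 216, 16 / 216, "upper"), rel=1e-9)

    def test_equal_counts_not_significant(self):
        assert sc.species_composition_test(20, 20, 216) >= 0.5

    def test_symmetric_contract(self):
        assert sc.species_composition_test(25, 16, 216) == sc.species_composition_test(
            16, 25, 216
        )


class TestConservationTable:
    def test_random_bounded_by_marginals_and_totals(self, sim_pairs):
        hex5, _ = sc.extract_all_hexes(sim_pairs)
        table = sc.conservation_table(hex5, sc.FIVE_PRIME)
        for key, rc in table.random_cons.items():
            assert 0.0 <= rc <= min(table.freq_a[key], table.freq_b[key]) + 1e-12
        totals = table.position_totals()
        assert (totals.random_total <= 1.0 + 1e-12).all()
        assert (totals.actual_total <= 1.0 + 1e-12).all()

    def test_independence_data_agree_random_vs_actual(self):
        """With uniform usage and conservation at the chance-identity level
        (0.25), the two species are genuinely independent, so actual and
        random conservation agree within sampling error."""
        cfg = sc.GeneratorConfig(
            n_pairs=3000, seed=21, intron_length_range=(12, 12),
            hex5_usage={}, hex3_usage={},
            per_position_conservation_5=(0.25, 0.25, 0.25, 0.25),
        )
        pairs, _ = sc.generate_pairs(cfg)
        hex5, _ = sc.extract_all_hexes(pairs)
        table = sc.conservation_table(hex5, sc.FIVE_PRIME)
        for p in (3, 4, 5, 6):
            for b in "ACGT":
                diff = abs(table.actual_cons[(p, b)] - table.random_cons[(p, b)])
                assert diff < 3 * np.sqrt(0.25 * 0.75 / 3000)

    def test_ancestral_correlation_makes_actual_exceed_random(self, sim_pairs_and_truth):
        pairs, _ = sim_pairs_and_truth
        hex5, _ = sc.extract_all_hexes(pairs)
        table = sc.conservation_table(hex5, sc.FIVE_PRIME)
        totals = table.position_totals()
        assert (totals.actual_total > totals.random_total).all()


class TestMotifScan:
    def test_single_couple_fully_fixed_pattern(self):
        hps = [sc.HexPair(sc.FIVE_PRIME, "GTAAGT", "GTAAGT", 0)]
        table = sc.conservation_table(hps, sc.FIVE_PRIME)
        res = {r.pattern.symbols: r for r in sc.motif_scan(hps, sc.FIVE_PRIME, table)}
        assert res["GTAAGT"].actual_freq == 1.0

    def test_results_sorted_and_bh_monotone(self, sim_pairs):
        hex5, _ = sc.extract_all_hexes(sim_pairs)
        table = sc.conservation_table(hex5, sc.FIVE_PRIME)
        results = sc.motif_scan(hex5, sc.FIVE_PRIME, table)
        ps = [r.p_value for r in results]
        assert ps == sorted(ps)
        qs = [r.q_value for r in results]
        assert all(q2 >= q1 - 1e-12 for q1, q2 in zip(qs, qs[1:]))
        assert all(r.q_value >= r.p_value - 1e-12 for r in results)
        frame = motif_results_frame(results)
        assert len(frame) == 624

    def test_direction_follows_excess_sign(self, sim_pairs):
        hex5, _ = sc.extract_all_hexes(sim_pairs)
        table = sc.conservation_table(hex5, sc.FIVE_PRIME)
        for r in sc.motif_scan(hex5, sc.FIVE_PRIME, table):
            assert (r.direction == "over") == (r.excess > 0)

    def test_type_one_error_calibrated_under_true_null(self):
        """Null simulations: uniform, position-independent hexamer usage and
        the generator's TRUE conservation table as the null input. Exact
        one-sided tests reject at most alpha per direction; well-populated
        patterns reject at close to alpha."""
        alpha = 0.05
        reps = 200
        monitored = ["GTAxxx", "GTxAGx", "GTGAGx", "GTxxGT"]
        over = {m: 0 for m in monitored}
        under = {m: 0 for m in monitored}
        for rep in range(reps):
            cfg = sc.GeneratorConfig(
                n_pairs=1000, seed=20000 + rep, intron_length_range=(12, 12),
                hex5_usage={}, hex3_usage={},
            )
            pairs, truth = sc.generate_pairs(cfg)
            hex5, _ = sc.extract_all_hexes(pairs)
            true_table = truth.expected_conservation_table(sc.FIVE_PRIME)
            res = {
                r.pattern.symbols: r
                for r in sc.motif_scan(hex5, sc.FIVE_PRIME, true_table, alpha)
            }
            for m in monitored:
                over[m] += res[m].flagged and res[m].direction == "over"
                under[m] += res[m].flagged and res[m].direction == "under"
        margin = 3 * np.sqrt(alpha * (1 - alpha) / reps)
        for m in monitored:
            assert over[m] / reps <= alpha + margin
            assert under[m] / reps <= alpha + margin
        # the scan does reject under the null at a rate consistent with alpha
        total = sum(over.values()) + sum(under.values())
        assert 0 < total / (2 * reps * len(monitored)) <= alpha + margin

    def test_power_against_injected_whole_hexamer_conservation(self):
        """A correlated-retention boost on GTGAGx ancestors produces a
        positive actual-random excess that the scan flags as
        over-represented in nearly every replicate at n = 216."""
        reps = 30
        flags = 0
        excesses = []
        for rep in range(reps):
            cfg = sc.GeneratorConfig(
                n_pairs=216, seed=30000 + rep, intron_length_range=(12, 12),
                correlated_motifs=(("GTGAGx", 0.3),),
            )
            pairs, _ = sc.generate_pairs(cfg)
            hex5, _ = sc.extract_all_hexes(pairs)
            table = sc.conservation_table(hex5, sc.FIVE_PRIME)
            res = {
                r.pattern.symbols: r
                for r in sc.motif_scan(hex5, sc.FIVE_PRIME, table, 0.05)
            }
            r = res["GTGAGx"]
            excesses.append(r.excess)
            flags += r.flagged and r.direction == "over"
        assert np.mean(excesses) > 0.04
        assert flags / reps >= 0.9
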