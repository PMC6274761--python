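"""Statistical kernels and the random-pair distance null."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from idpcoev.interface import Interface
from idpcoev.stats import (NullDistanceSample, compare_ec_distances,
                           composition_analysis, composition_table,
                           distance_histogram, equal_proportions_test,
                           flag_outliers, mann_whitney_u,
                           null_summary_variation, random_pair_null,
                           ss_preference, summary_stats)


def enumeration_p_value(x, y):
    """Exact two-sided Mann-Whitney p by full enumeration over all
    assignments of the pooled values to the two groups (tie-free inputs)."""
    x, y = list(x), list(y)
    pooled = x + y
    n1 = len(x)

    def u_stat(xs, ys):
        return sum(1 for a in xs for b in ys if a > b)

    u_obs = u_stat(x, y)
    mean_u = n1 * len(y) / 2
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(len(pooled)) if i not in combo]
        u = u_stat(xs, ys)
        total += 1
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            count += 1
    return count / total


class TestMannWhitney:
    def test_extreme_ordering_gives_zero_u(self):
        u, _ = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0

    def test_identical_samples_give_high_p(self):
        _, p = mann_whitney_u([1, 2, 3, 4], [1, 2, 3, 4])
        assert p >= 0.99

    def test_textbook_exact_case(self):
        # fully separated 3-vs-3: two extreme assignments out of C(6,3)=20
        _, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    @pytest.mark.parametrize("n1,n2", [(n1, n2) for n1 in range(1, 5)
                                       for n2 in range(n1, 5) if n1 + n2 <= 8])
    def test_exact_branch_equals_enumeration(self, n1, n2, rng):
        for _ in range(3):
            pooled = rng.choice(1000, size=n1 + n2, replace=False).astype(float)
            x, y = pooled[:n1], pooled[n1:]
            _, p = mann_whitney_u(x, y)
            assert p == pytest.approx(enumeration_p_value(x, y), abs=1e-12)

    def test_large_samples_use_tie_corrected_normal(self, rng):
        x = rng.integers(0, 5, size=30).astype(float)
        y = rng.integers(1, 6, size=25).astype(float)
        _, p = mann_whitney_u(x, y)
        assert 0 < p <= 1


class TestEqualProportions:
    def test_identical_proportions(self):
        assert equal_proportions_test(5, 10, 50, 100) >= 0.9

    def test_maximal_separation(self):
        assert equal_proportions_test(0, 10, 10, 10) < 0.001

    def test_hand_computed_continuity_corrected_chi_square(self):
        # 8/28 vs 80/551: Yates-corrected 2x2 chi-square done by hand
        a, b = 8, 20
        c, d = 80, 471
        n = a + b + c + d
        expected = [[(a + b) * (a + c) / n, (a + b) * (b + d) / n],
                    [(c + d) * (a + c) / n, (c + d) * (b + d) / n]]
        obs = [[a, b], [c, d]]
        chi2 = sum((abs(obs[i][j] - expected[i][j]) - 0.5) ** 2 / expected[i][j]
                   for i in range(2) for j in range(2))
        from scipy.stats import chi2 as chi2_dist

        p_hand = float(chi2_dist.sf(chi2, df=1))
        assert equal_proportions_test(8, 28, 80, 551) == pytest.approx(
            p_hand, abs=1e-6)

    def test_zero_margin_warns_p_one(self):
        with pytest.warns(UserWarning, match="zero margin"):
            assert equal_proportions_test(0, 5, 0, 7) == 1.0


class TestOutliers:
    def test_constant_values_unflagged(self):
        kept, out = flag_outliers([5.0] * 6)
        assert len(kept) == 6 and len(out) == 0

    def test_quartile_arithmetic_case(self):
        vals = [4, 5, 5, 6, 6, 7, 30]
        q1, q3 = np.quantile(vals, [0.25, 0.75])
        fence = q3 + 1.5 * (q3 - q1)
        assert 30 > fence
        kept, out = flag_outliers(vals)
        assert list(out) == [30]
        assert len(kept) == 6

    def test_fewer_than_four_values_unflagged(self):
        kept, out = flag_outliers([1.0, 100.0, 1000.0])
        assert len(out) == 0

    def test_single_pass_flagging(self):
        # distances on the scale of the visible-coupling analysis: one
        # far value flagged; re-running on the kept set flags nothing new
        vals = [3.1, 3.5, 4.0, 4.2, 4.8, 5.0, 5.1, 5.5, 5.9, 6.0, 6.2, 6.6,
                6.9, 7.0, 7.3, 7.5, 7.9, 8.4, 9.6, 9.9, 13.9, 17.5]
        kept, out = flag_outliers(vals)
        assert set(out) == {13.9, 17.5}
        kept2, out2 = flag_outliers(kept)
        assert len(out2) == 0

    @given(st.lists(st.floats(0, 50, allow_nan=False), min_size=4, max_size=30))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_matches_boxplot_fences(self, vals):
        kept, out = flag_outliers(vals)
        q1, q3 = np.quantile(vals, [0.25, 0.75])
        lo, hi = q1 - 1.5 * (q3 - q1), q3 + 1.5 * (q3 - q1)
        assert sorted(out) == sorted(v for v in vals if v < lo or v > hi)
        assert len(kept) + len(out) == len(vals)


class TestHistogram:
    def test_boundary_assignment(self):
        assert distance_histogram([7.9, 8.0, 10.0, 10.1]) == (1, 2, 1)

    def test_empty(self):
        assert distance_histogram([]) == (0, 0, 0)

    def test_close_pairs_land_in_first_bin(self, synth_complex, synth_msa):
        from idpcoev.structure import residue_min_distance

        _, truth = synth_msa
        d = []
        for (i, j) in truth.pairs:
            ri = synth_complex.residue_index("A", i)
            rj = synth_complex.residue_index("B", j)
            d.append(residue_min_distance(synth_complex, ri, rj))
        hist = distance_histogram(d)
        assert hist == (len(d), 0, 0)


class TestRandomPairNull:
    def test_degenerate_interface_repeats_single_pair(self, synth_complex):
        iface = Interface(idp_if_residues={0}, partner_if_residues={30},
                          total_area=100.0)
        samples = random_pair_null(synth_complex, iface, [(0, 30)],
                                   n_resamples=20, seed=1)
        draws = np.array([s.draws[0] for s in samples])
        assert len(samples) == 20
        assert np.all(draws == draws[0])

    def test_same_seed_reproducible(self, synth_complex):
        from idpcoev.interface import assign_interface

        iface = assign_interface(synth_complex)
        ecs = [(0, 30), (5, 40)]
        s1 = random_pair_null(synth_complex, iface, ecs, 10, seed=7)
        s2 = random_pair_null(synth_complex, iface, ecs, 10, seed=7)
        for a, b in zip(s1, s2):
            assert np.array_equal(a.draws, b.draws)

    def test_summary_variation_finite(self, synth_complex):
        from idpcoev.interface import assign_interface

        iface = assign_interface(synth_complex)
        ecs = [(0, 30), (5, 40), (2, 35)]
        samples = random_pair_null(synth_complex, iface, ecs, 50, seed=3)
        var = null_summary_variation(samples)
        assert np.isfinite(var["average_sd"])
        assert set(var) >= {"min", "q1", "mean", "median", "q3", "max"}

    def test_empty_interface_side_warns(self, synth_complex):
        iface = Interface(idp_if_residues=set(), partner_if_residues={30},
                          total_area=0.0)
        with pytest.warns(UserWarning):
            samples = random_pair_null(synth_complex, iface, [(0, 30)], 5, 1)
        assert samples == []

    def test_outliers_excluded_from_comparison(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(3, 7, size=20)
        ecs = np.concatenate([base, [40.0]])  # one absurd distance
        samples = [NullDistanceSample(rng.uniform(3, 7, size=21),
                                      {}) for _ in range(10)]
        res = compare_ec_distances(ecs, samples)
        assert res["outliers"] == [40.0]
        assert res["n_ecs"] == 20


class TestComposition:
    def test_pure_negative_multiset(self):
        table = composition_table({"EC_residues": ["D", "E"]})
        assert table.loc["negative", "EC_residues"] == pytest.approx(1.0)

    def test_positive_fraction(self):
        table = composition_table({"all_IF": ["K", "R", "H", "A"]})
        assert table.loc["positive", "all_IF"] == pytest.approx(0.75)

    def test_group_fractions_partition(self, rng):
        residues = list(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=200))
        table = composition_table({"all_IF": residues})
        groups = ["hydrophobic", "aromatic", "polar", "negative", "positive"]
        assert table.loc[groups, "all_IF"].sum() == pytest.approx(1.0)

    def test_order_and_duplicate_chain_invariance(self, rng):
        residues = list(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=60))
        t1 = composition_table({"all_IF": residues})
        t2 = composition_table({"all_IF": residues[::-1]})
        assert np.allclose(t1.values.astype(float), t2.values.astype(float))

    def test_enrichment_detected_by_power_simulation(self):
        # EC-carrying interfaces enriched 2x in D/E versus background: the
        # negative-group comparison should reject at n >= 150 per side
        rng = np.random.default_rng(42)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        base_p = np.ones(20) / 20
        enriched_p = base_p.copy()
        for aa in "DE":
            enriched_p[aas.index(aa)] *= 2.2
        enriched_p /= enriched_p.sum()
        rejections = 0
        n_sim = 40
        for _ in range(n_sim):
            ec_if = list(rng.choice(aas, size=150, p=enriched_p))
            no_ec_if = list(rng.choice(aas, size=150, p=base_p))
            result = composition_analysis({
                "analyzed_range": ec_if + no_ec_if,
                "all_IF": ec_if + no_ec_if,
                "EC_IF": ec_if,
                "noEC_IF": no_ec_if,
                "EC_residues": ec_if[:30],
            })
            if result["p_values"][("EC_IF", "noEC_IF", "negative")] < 0.05:
                rejections += 1
        assert rejections / n_sim >= 0.6

    def test_empty_category_skips_comparison(self):
        with pytest.warns(UserWarning):
            result = composition_analysis({
                "analyzed_range": ["A"], "all_IF": ["A"], "EC_IF": [],
                "noEC_IF": ["A"], "EC_residues": ["D"]})
        assert ("EC_IF", "all_IF", "negative") not in result["p_values"]


class TestSsPreference:
    class FakeSS:
        def __init__(self, mapping):
            self.mapping = mapping

        def three_class(self, ri):
            return self.mapping[ri]

        def counts_by_class(self, idx):
            out = {"helix": 0, "strand": 0, "loop": 0}
            for ri in idx:
                out[self.mapping[ri]] += 1
            return out

    def test_same_distribution_high_p(self):
        ss = self.FakeSS({i: "helix" for i in range(40)})
        res = ss_preference(ss, list(range(10)), list(range(10, 40)))
        assert res["p_helix"] >= 0.9

    def test_maximal_separation_low_p(self):
        mapping = {i: ("helix" if i < 20 else "loop") for i in range(220)}
        ss = self.FakeSS(mapping)
        res = ss_preference(ss, list(range(20)), list(range(20, 220)))
        assert res["p_helix"] < 0.001

    def test_proportions_sum_to_one(self):
        mapping = {0: "helix", 1: "strand", 2: "loop", 3: "helix", 4: "loop"}
        ss = self.FakeSS(mapping)
        res = ss_preference(ss, [0, 1, 2], [3, 4])
        assert sum(res["ec_proportions"].values()) == pytest.approx(1.0)
        assert sum(res["other_proportions"].values()) == pytest.approx(1.0)

    def test_no_ec_residues_skipped(self):
        ss = self.FakeSS({})
        with pytest.warns(UserWarning):
            assert ss_preference(ss, [], [1, 2]) == {}


class TestSummaryStats:
    def test_type7_quantiles(self, rng):
        vals = rng.uniform(0, 10, size=17)
        s = summary_stats(vals)
        assert s["q1"] == pytest.approx(np.quantile(vals, 0.25))
        assert s["median"] == pytest.approx(np.median(vals))
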