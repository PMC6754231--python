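import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from grnqg import simdata
from grnqg.dataio import MISSING, GenotypeMatrix, MarkerMap
from grnqg.errors import ConfigurationError, DataError
from grnqg.qtlmap import (CrossPopulation, LodCurve, calc_genoprob,
                          genotype_group_summary, lod_support_interval,
                          map_to_recfrac, permutation_threshold, ril_recfrac,
                          scanone_em)


class TestMapFunctions:
    def test_haldane_closed_forms(self):
        assert map_to_recfrac(0.0) == 0.0
        assert map_to_recfrac(10.0) == pytest.approx((1 - np.exp(-0.2)) / 2)
        assert map_to_recfrac(1e6) == pytest.approx(0.5)
        with pytest.raises(ConfigurationError):
            map_to_recfrac(-1.0)

    def test_ril_expansion_closed_forms(self):
        assert ril_recfrac(0.0) == 0.0
        assert ril_recfrac(0.5) == pytest.approx(0.5)
        assert ril_recfrac(0.25) == pytest.approx(1.0 / 3.0)
        with pytest.raises(ConfigurationError):
            ril_recfrac(0.6)


def _toy_cross(genos, cms, chrom="I"):
    genos = np.asarray(genos, dtype=np.int8)
    m = genos.shape[1]
    mm = MarkerMap.from_arrays([f"{chrom}:{k + 1}" for k in range(m)],
                               [chrom] * m, [(k + 1) * 1000 for k in range(m)],
                               cms)
    gm = GenotypeMatrix([f"R{i}" for i in range(genos.shape[0])],
                        mm.marker_ids, genos)
    return CrossPopulation(gm, mm)


class TestCalcGenoprob:
    def test_observed_marker_is_certain_without_error(self):
        cross = _toy_cross([[0, 2]], [0.0, 10.0])
        gp = calc_genoprob(cross, step_cM=0.0, error_rate=0.0)
        np.testing.assert_allclose(gp.probs[0, 0], [1.0, 0.0])
        np.testing.assert_allclose(gp.probs[0, 1], [0.0, 1.0])

    def test_missing_marker_between_opposite_flanks_is_symmetric(self):
        cross = _toy_cross([[0, MISSING, 2]], [0.0, 10.0, 20.0])
        gp = calc_genoprob(cross, step_cM=0.0, error_rate=0.0)
        np.testing.assert_allclose(gp.probs[0, 1], [0.5, 0.5], atol=1e-12)

    def test_probabilities_sum_to_one_everywhere(self, ril_cross):
        gp = calc_genoprob(ril_cross, step_cM=2.0, error_rate=1e-3)
        np.testing.assert_allclose(gp.probs.sum(axis=2), 1.0, atol=1e-12)

    def test_matches_exhaustive_hidden_path_enumeration(self):
        """Five markers, one missing call: forward-backward equals a direct
        sum over all 2^5 hidden paths."""
        obs = [0, 2, MISSING, 2, 1]  # het treated as missing
        cms = [0.0, 5.0, 12.0, 20.0, 33.0]
        error = 0.02
        cross = _toy_cross([obs], cms)
        gp = calc_genoprob(cross, step_cM=0.0, error_rate=error)

        r = [ril_recfrac(map_to_recfrac(cms[k + 1] - cms[k])) for k in range(4)]

        def emit(state, o):
            if o in (MISSING, 1):
                return 1.0
            return 1.0 - error if (o == 0) == (state == 0) else error

        post = np.zeros((5, 2))
        for path in itertools.product([0, 1], repeat=5):
            w = 0.5
            for k in range(4):
                w *= r[k] if path[k] != path[k + 1] else 1 - r[k]
            for k in range(5):
                w *= emit(path[k], obs[k])
            for k in range(5):
                post[k, path[k]] += w
        post /= post.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(gp.probs[0], post, atol=1e-10)

    def test_unsorted_map_rejected(self):
        genos = np.array([[0, 2]], dtype=np.int8)
        frame = pd.DataFrame({"chrom": ["I", "I"], "bp": [2000, 1000],
                              "cM": [10.0, 0.0]}, index=["a", "b"])
        mm = MarkerMap(frame)
        gm = GenotypeMatrix(["R0"], ["a", "b"], genos)
        cross = CrossPopulation(gm, mm)
        with pytest.raises(DataError):
            # meiosis/HMM require map-sorted markers
            from grnqg.simdata import simulate_ril_population
            simulate_ril_population(np.zeros(2), np.ones(2), mm, 5, 1)


class TestScanoneEm:
    def test_constant_phenotype_gives_zero_curve(self, ril_cross):
        with pytest.warns(UserWarning, match="constant phenotype"):
            curve = scanone_em(ril_cross, np.full(ril_cross.n_rils, 0.3))
        assert (curve.frame["lod"] <= 1e-6).all()

    def test_marker_lod_equals_regression_formula_on_complete_data(self):
        rng = np.random.default_rng(23)
        n = 60
        g = (2 * rng.integers(0, 2, size=(n, 3))).astype(np.int8)
        cross = _toy_cross(g, [0.0, 20.0, 40.0])
        y = 0.5 * (g[:, 1] / 2) + rng.normal(size=n) * 0.7
        curve = scanone_em(cross, y, step_cM=0.0, error_rate=0.0)
        for k in range(3):
            gk = g[:, k].astype(float)
            X = np.column_stack([np.ones(n), gk])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            rss1 = ((y - X @ beta) ** 2).sum()
            rss0 = ((y - y.mean()) ** 2).sum()
            lod_expect = (n / 2) * np.log10(rss0 / rss1)
            assert curve.frame["lod"].iloc[k] == pytest.approx(lod_expect,
                                                               abs=1e-6)

    def test_simulated_qtl_recovered_on_correct_chromosome(self):
        mm = MarkerMap.from_arrays(
            [f"{c}:{k}" for c in ("I", "II") for k in range(1, 12)],
            ["I"] * 11 + ["II"] * 11,
            list(range(1000, 12000, 1000)) * 2,
            [5.0 * k for k in range(11)] * 2)
        gm = simdata.simulate_ril_population(np.zeros(22), np.ones(22), mm,
                                             100, 10, seed=9)
        rng = np.random.default_rng(10)
        g = gm.values[:, 16].astype(float)  # chromosome II marker
        y = (g / 2) * 1.0 + rng.normal(size=100)
        cross = CrossPopulation(gm, mm)
        curve = scanone_em(cross, y, step_cM=1.0)
        peak_row = curve.frame.loc[curve.frame["lod"].idxmax()]
        assert peak_row["chrom"] == "II"

    def test_affine_rescaling_leaves_lod_unchanged(self, ril_cross):
        rng = np.random.default_rng(11)
        y = rng.normal(size=ril_cross.n_rils)
        c1 = scanone_em(ril_cross, y)
        c2 = scanone_em(ril_cross, 10.0 * y + 3.0)
        np.testing.assert_allclose(c1.frame["lod"], c2.frame["lod"], atol=1e-6)

    def test_too_few_phenotyped_rils_rejected(self, ril_cross):
        y = np.full(ril_cross.n_rils, np.nan)
        y[:5] = 1.0
        with pytest.raises(DataError):
            scanone_em(ril_cross, y)


class TestPermutationThreshold:
    def test_constant_phenotype_gives_zero_threshold(self, ril_cross):
        thr = permutation_threshold(ril_cross, np.full(ril_cross.n_rils, 0.5),
                                    n_permutations=100, alpha=0.05, seed=0)
        assert thr <= 1e-6

    def test_threshold_monotone_in_alpha_on_fixed_permutations(self, ril_cross):
        rng = np.random.default_rng(13)
        y = rng.normal(size=ril_cross.n_rils)
        _, maxima = permutation_threshold(ril_cross, y, n_permutations=100,
                                          alpha=0.05, seed=5, return_maxima=True)
        thrs = [np.sort(maxima)[int(np.ceil((1 - a) * 100)) - 1]
                for a in (0.01, 0.05, 0.2, 0.5)]
        assert (np.diff(thrs) <= 1e-12).all()

    def test_alpha_out_of_range_rejected(self, ril_cross):
        with pytest.raises(ConfigurationError):
            permutation_threshold(ril_cross, np.zeros(ril_cross.n_rils),
                                  n_permutations=100, alpha=1.5)


class TestLodSupportInterval:
    @staticmethod
    def _curve_from(chrom, cms, lods):
        return LodCurve(pd.DataFrame({
            "chrom": chrom, "cM": cms, "is_pseudomarker": False, "marker": "",
            "lod": lods, "converged": True}))

    def test_triangular_curve_interval_arithmetic(self):
        cms = np.arange(0.0, 41.0, 1.0)
        lods = 5.0 - 0.5 * np.abs(cms - 20.0)
        curve = self._curve_from("I", cms, np.maximum(lods, 0.0))
        peak = lod_support_interval(curve, "I", drop=1.5)
        assert peak.peak_cM == 20.0 and peak.peak_lod == 5.0
        assert peak.interval_lo_cM == pytest.approx(17.0)
        assert peak.interval_hi_cM == pytest.approx(23.0)

    def test_peak_at_chromosome_end_clips_interval(self):
        cms = np.arange(0.0, 21.0, 1.0)
        curve = self._curve_from("I", cms, 4.0 - 0.1 * cms)
        peak = lod_support_interval(curve, "I", drop=1.5)
        assert peak.peak_cM == 0.0
        assert peak.interval_lo_cM == 0.0
        assert peak.interval_hi_cM == pytest.approx(15.0)

    def test_all_zero_curve_reports_no_peak(self):
        curve = self._curve_from("I", np.arange(5.0), np.zeros(5))
        peak = lod_support_interval(curve, "I")
        assert not peak.has_peak

    def test_interval_contains_true_position_in_most_replicates(self):
        """1.5-LOD coverage of a 1-SD QTL at n = 100 RILs (small replicate
        set here; the full-size run lives in the acceptance suite)."""
        mm = MarkerMap.from_arrays([f"I:{k}" for k in range(26)], ["I"] * 26,
                                   range(1000, 27000, 1000),
                                   [2.0 * k for k in range(26)])
        covered = 0
        n_rep = 40
        for rep in range(n_rep):
            gm = simdata.simulate_ril_population(np.zeros(26), np.ones(26), mm,
                                                 100, 10, seed=500 + rep)
            rng = np.random.default_rng(600 + rep)
            true_cm = 24.0
            g = gm.values[:, 12].astype(float)
            y = (g / 2) * 1.0 + rng.normal(size=100)
            curve = scanone_em(CrossPopulation(gm, mm), y, step_cM=1.0)
            peak = lod_support_interval(curve, "I", drop=1.5)
            if peak.interval_lo_cM <= true_cm <= peak.interval_hi_cM:
                covered += 1
        assert covered >= 0.85 * n_rep


class TestGenotypeGroupSummary:
    def test_median_and_quartiles_arithmetic(self):
        out = genotype_group_summary([10, 20, 30], ["a", "a", "a"])
        assert out.loc["a", "median"] == 20
        assert out.loc["a", "q1"] == 15 and out.loc["a", "q3"] == 25

    def test_identical_distributions_identical_summaries(self):
        y = [1, 2, 3, 4, 1, 2, 3, 4]
        cls = ["a"] * 4 + ["b"] * 4
        out = genotype_group_summary(y, cls)
        pd.testing.assert_series_equal(out.loc["a"], out.loc["b"],
                                       check_names=False)

    def test_matches_order_statistics_oracle(self):
        rng = np.random.default_rng(19)
        y = rng.normal(size=40)
        cls = rng.choice(["AA", "BB"], size=40)
        out = genotype_group_summary(y, cls)
        for c in ("AA", "BB"):
            v = np.sort(y[cls == c])
            assert out.loc[c, "median"] == pytest.approx(np.quantile(v, 0.5))
            assert out.loc[c, "q1"] == pytest.approx(np.quantile(v, 0.25))
            assert out.loc[c, "q3"] == pytest.approx(np.quantile(v, 0.75))
            sem = v.std(ddof=1) / np.sqrt(v.size)
            t = stats.t.ppf(0.975, v.size - 1)
            assert out.loc[c, "ci_lo"] == pytest.approx(v.mean() - t * sem)

    def test_single_observation_class_flagged(self):
        out = genotype_group_summary([1.0, 2.0, 3.0], ["a", "a", "b"])
        assert not out.loc["b", "ci_defined"]
        assert np.isnan(out.loc["b", "ci_lo"])
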