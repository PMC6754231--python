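import numpy as np
import pandas as pd
import pytest
from scipy import stats

from grnqg import simdata
from grnqg.dataio import (MISSING, GenotypeMatrix, MarkerMap, PhenotypeTable)
from grnqg.errors import ConfigurationError, DataError
from grnqg.reciprocity import (AllelicEffectTable, cross_trait_correlation,
                               ld_prune, per_snp_allelic_effect,
                               reciprocity_analysis, strain_level_correlation,
                               zscore_outlier_filter)


def _pheno(strains, t1, t2=None):
    t2 = t1 if t2 is None else t2
    return PhenotypeTable(pd.DataFrame({"trait1": t1, "trait2": t2},
                                       index=strains))


def _gm(vals, strains=None):
    vals = np.asarray(vals, dtype=np.int8)
    strains = strains or [f"s{i}" for i in range(vals.shape[0])]
    return GenotypeMatrix(strains, [f"m{j}" for j in range(vals.shape[1])], vals)


class TestPerSnpAllelicEffect:
    def test_median_difference_arithmetic(self):
        gm = _gm([[0], [0], [0], [2], [2], [2]])
        ph = _pheno(gm.strain_ids, [0.10, 0.20, 0.30, 0.40, 0.50, 0.60])
        table = per_snp_allelic_effect(gm, ph, "trait1", "trait2",
                                       min_class_size=3)
        assert table.frame["effect_trait1"].iloc[0] == pytest.approx(0.30)

    def test_constant_phenotype_gives_zero_effects(self):
        rng = np.random.default_rng(1)
        gm = _gm(2 * rng.integers(0, 2, size=(12, 6)))
        ph = _pheno(gm.strain_ids, np.full(12, 0.5))
        table = per_snp_allelic_effect(gm, ph, "trait1", "trait2")
        inc = table.included()
        assert (inc["effect_trait1"] == 0).all()

    def test_single_class_marker_excluded_not_error(self):
        gm = _gm([[0], [0], [0], [0], [0], [0]])
        ph = _pheno(gm.strain_ids, np.linspace(0, 1, 6))
        table = per_snp_allelic_effect(gm, ph, "trait1", "trait2")
        assert not table.frame["included"].iloc[0]
        assert table.frame["reason"].iloc[0] == "class_size"

    def test_matches_group_by_median_oracle(self):
        rng = np.random.default_rng(2)
        vals = rng.choice([0, 1, 2, MISSING], size=(30, 15),
                          p=[0.4, 0.05, 0.4, 0.15]).astype(np.int8)
        gm = _gm(vals)
        y1 = rng.uniform(size=30)
        y2 = rng.uniform(size=30)
        ph = _pheno(gm.strain_ids, y1, y2)
        table = per_snp_allelic_effect(gm, ph, "trait1", "trait2",
                                       min_class_size=3)
        for j, mid in enumerate(gm.marker_ids):
            for col, y in (("effect_trait1", y1), ("effect_trait2", y2)):
                ref = [y[i] for i in range(30) if vals[i, j] == 0]
                alt = [y[i] for i in range(30) if vals[i, j] == 2]
                got = table.frame.loc[mid, col]
                if len(ref) >= 3 and len(alt) >= 3:
                    assert got == pytest.approx(
                        np.median(alt) - np.median(ref), abs=1e-12)
                else:
                    assert np.isnan(got)

    def test_flipping_reference_allele_negates_effects(self):
        rng = np.random.default_rng(3)
        vals = (2 * rng.integers(0, 2, size=(20, 8))).astype(np.int8)
        gm = _gm(vals)
        ph = _pheno(gm.strain_ids, rng.uniform(size=20), rng.uniform(size=20))
        t_fwd = per_snp_allelic_effect(gm, ph, "trait1", "trait2")
        gm_flip = _gm(2 - vals)
        t_rev = per_snp_allelic_effect(gm_flip, ph, "trait1", "trait2")
        np.testing.assert_allclose(t_rev.frame["effect_trait1"],
                                   -t_fwd.frame["effect_trait1"], atol=1e-12)
        r_fwd = cross_trait_correlation(t_fwd).genome_wide_r
        r_rev = cross_trait_correlation(t_rev).genome_wide_r
        assert r_rev == pytest.approx(r_fwd, abs=1e-12)


class TestLdPrune:
    def test_identical_columns_leave_one_survivor(self):
        col = 2 * np.random.default_rng(4).integers(0, 2, size=12)
        gm = _gm(np.tile(col[:, None], (1, 6)))
        kept = ld_prune(gm, window_size=6, step=3, r2_threshold=0.8)
        assert len(kept) == 1

    def test_uncorrelated_columns_all_retained(self):
        rng = np.random.default_rng(5)
        # orthogonal-ish random columns at low correlation
        vals = 2 * rng.integers(0, 2, size=(200, 8))
        gm = _gm(vals.astype(np.int8))
        kept = ld_prune(gm, window_size=8, step=4, r2_threshold=0.8)
        assert len(kept) == 8

    def test_window_too_small_rejected(self):
        gm = _gm([[0, 2], [2, 0], [0, 2]])
        with pytest.raises(ConfigurationError):
            ld_prune(gm, window_size=1, step=1)

    def test_matches_exhaustive_greedy_oracle(self):
        rng = np.random.default_rng(6)
        base = 2 * rng.integers(0, 2, size=(40, 5))
        cols = [base[:, j % 5].copy() for j in range(20)]
        for j in range(20):  # perturb to create an LD gradient
            flip = rng.random(40) < 0.12 * (j % 4)
            cols[j] = np.where(flip, 2 - cols[j], cols[j])
        vals = np.column_stack(cols).astype(np.int8)
        gm = _gm(vals)
        window, step, thr = 8, 3, 0.5
        kept = ld_prune(gm, window, step, thr)

        # independent greedy oracle with the same published tie rules
        def r2(a, b):
            x, y = vals[:, a].astype(float), vals[:, b].astype(float)
            if x.std() == 0 or y.std() == 0:
                return 0.0
            return float(np.corrcoef(x, y)[0, 1] ** 2)

        maf = gm.maf()
        keep = set(range(20))
        start = 0
        while True:
            window_idx = [j for j in range(start, min(start + window, 20))
                          if j in keep]
            while True:
                worst = None
                for ai in range(len(window_idx)):
                    for bi in range(ai + 1, len(window_idx)):
                        a, b = window_idx[ai], window_idx[bi]
                        v = r2(a, b)
                        if v > thr and (worst is None or v > worst[0]):
                            worst = (v, a, b)
                if worst is None:
                    break
                _, a, b = worst
                drop = a if (maf[a] < maf[b] or (maf[a] == maf[b] and a > b)) \
                    else b
                keep.discard(drop)
                window_idx.remove(drop)
            if start + window >= 20:
                break
            start += step
        assert sorted(kept.tolist()) == sorted(keep)


class TestZscoreOutlierFilter:
    @staticmethod
    def _table(e1, e2=None):
        e1 = np.asarray(e1, float)
        e2 = e1.copy() if e2 is None else np.asarray(e2, float)
        frame = pd.DataFrame({
            "chrom": "I", "bp": np.arange(len(e1)), "n_ref": 5, "n_alt": 5,
            "effect_trait1": e1, "effect_trait2": e2,
            "included": True, "reason": "",
        }, index=[f"m{j}" for j in range(len(e1))])
        return AllelicEffectTable(frame, ("trait1", "trait2"))

    def test_moderate_spread_removes_nothing(self):
        out = zscore_outlier_filter(self._table([0.0, 0.0, 0.0, 10.0]))
        # sample sd = 5, largest |z| = 1.5 < 1.96
        assert out.frame["included"].all()

    def test_extreme_value_removed(self):
        e = [0.0] * 20 + [10.0]
        out = zscore_outlier_filter(self._table(e))
        assert not out.frame["included"].iloc[-1]
        assert out.frame["reason"].iloc[-1] == "outlier"
        assert out.frame["included"].iloc[:-1].all()

    def test_outlier_in_either_trait_is_excluded(self):
        e1 = [0.0] * 20 + [0.0]
        e2 = [0.0] * 20 + [10.0]
        out = zscore_outlier_filter(self._table(e1, e2))
        assert not out.frame["included"].iloc[-1]

    def test_single_pass_contract_second_application_may_remove_more(self):
        e = [0.0] * 30 + [5.0, 50.0]
        once = zscore_outlier_filter(self._table(e))
        twice = zscore_outlier_filter(once)
        assert int(once.frame["included"].sum()) >= int(
            twice.frame["included"].sum())

    def test_zero_variance_warns_and_removes_nothing(self):
        with pytest.warns(UserWarning, match="zero variance"):
            out = zscore_outlier_filter(self._table([0.5, 0.5, 0.5, 0.5]))
        assert out.frame["included"].all()


class TestCrossTraitCorrelation:
    def test_exact_negatives_give_minus_one(self):
        rng = np.random.default_rng(7)
        e = rng.normal(size=10)
        table = TestZscoreOutlierFilter._table(e, -e)
        rep = cross_trait_correlation(table)
        assert rep.genome_wide_r == pytest.approx(-1.0)

    def test_two_marker_group_undefined_not_error(self):
        frame = pd.DataFrame({
            "chrom": ["I", "I", "I", "II", "II"], "bp": range(5),
            "n_ref": 5, "n_alt": 5,
            "effect_trait1": [0.1, 0.2, 0.3, 0.4, 0.5],
            "effect_trait2": [0.2, 0.1, 0.25, 0.1, 0.3],
            "included": True, "reason": "",
        }, index=[f"m{j}" for j in range(5)])
        rep = cross_trait_correlation(AllelicEffectTable(frame, ("t1", "t2")))
        row = rep.per_chromosome.set_index("chrom").loc["II"]
        assert np.isnan(row["r"]) and row["n"] == 2

    def test_all_excluded_is_error(self):
        table = TestZscoreOutlierFilter._table([0.1, 0.2, 0.3])
        table.frame["included"] = False
        with pytest.raises(DataError):
            cross_trait_correlation(table)

    def test_stage_counts_nonincreasing(self):
        cfg = simdata.SimulationConfig(seed=71, n_strains=60,
                                       markers_per_chromosome=40,
                                       chromosomes=(("I", 50.0), ("II", 50.0)))
        gm, mm, _ = simdata.simulate_isolate_panel(cfg)
        arch = simdata.TraitArchitecture(
            qtls=(simdata.QtlEffect("I", 25.0, 0.5, -0.5),))
        ph = simdata.simulate_phenotypes(gm, mm, arch, seed=72)
        _, rep = reciprocity_analysis(gm, mm, ph, "trait1", "trait2")
        c = rep.stage_counts
        assert c["raw"] >= c["class_size_pass"] >= c["after_prune"] \
            >= c["included"]


class TestStrainLevelCorrelation:
    def test_monotone_and_antimonotone_pairings(self):
        strains = [f"s{i}" for i in range(6)]
        up = _pheno(strains, np.linspace(0.1, 0.6, 6),
                    np.linspace(0.2, 0.9, 6))
        rho, _ = strain_level_correlation(up, "trait1", "trait2")
        assert rho == pytest.approx(1.0)
        down = _pheno(strains, np.linspace(0.1, 0.6, 6),
                      np.linspace(0.9, 0.2, 6))
        rho, _ = strain_level_correlation(down, "trait1", "trait2")
        assert rho == pytest.approx(-1.0)

    def test_ties_match_rank_then_pearson_oracle(self):
        strains = [f"s{i}" for i in range(8)]
        y1 = np.array([0.1, 0.1, 0.3, 0.3, 0.5, 0.6, 0.6, 0.9])
        y2 = np.array([0.2, 0.4, 0.4, 0.1, 0.8, 0.8, 0.5, 0.7])
        ph = _pheno(strains, y1, y2)
        rho, _ = strain_level_correlation(ph, "trait1", "trait2")
        r1 = stats.rankdata(y1)  # average ranks
        r2 = stats.rankdata(y2)
        oracle = np.corrcoef(r1, r2)[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_too_few_pairs_rejected(self):
        ph = _pheno(["a", "b", "c"], [0.1, 0.2, 0.3])
        with pytest.raises(DataError):
            strain_level_correlation(ph, "trait1", "trait2")


class TestArchitectureRecovery:
    def test_opposite_sign_shared_qtl_drives_negative_genome_wide_r(self):
        negative = 0
        n_rep = 15
        for rep in range(n_rep):
            cfg = simdata.SimulationConfig(
                seed=5000 + rep, n_strains=80, markers_per_chromosome=30,
                chromosomes=(("I", 50.0), ("II", 50.0), ("III", 50.0)))
            gm, mm, _ = simdata.simulate_isolate_panel(cfg)
            arch = simdata.TraitArchitecture(
                qtls=(simdata.QtlEffect("II", 25.0, 0.5, -0.5),),
                strain_noise_sd=0.15)
            ph = simdata.simulate_phenotypes(gm, mm, arch, seed=6000 + rep)
            _, rep_out = reciprocity_analysis(gm, mm, ph, "trait1", "trait2")
            if rep_out.genome_wide_r < 0:
                negative += 1
        assert negative >= 0.9 * n_rep

    def test_independent_architectures_center_r_on_zero(self):
        rs = []
        for rep in range(15):
            cfg = simdata.SimulationConfig(
                seed=7000 + rep, n_strains=80, markers_per_chromosome=30,
                chromosomes=(("I", 50.0), ("II", 50.0), ("III", 50.0)))
            gm, mm, _ = simdata.simulate_isolate_panel(cfg)
            arch = simdata.TraitArchitecture(
                qtls=(simdata.QtlEffect("I", 25.0, 0.5, 0.0),
                      simdata.QtlEffect("III", 25.0, 0.0, 0.5)),
                strain_noise_sd=0.15)
            ph = simdata.simulate_phenotypes(gm, mm, arch, seed=8000 + rep)
            _, rep_out = reciprocity_analysis(gm, mm, ph, "trait1", "trait2")
            rs.append(rep_out.genome_wide_r)
        m = np.mean([abs(r) for r in rs])
        # mean |R| stays near the null sampling scale
        assert abs(np.mean(rs)) < 0.2
        assert m < 0.35
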