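"""QTL scan: oracle equivalences, null calibration, thresholds and calls."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gggqtl import qtl, simulate
from gggqtl.types import DRY, IMBIBED, QtlTruthTable
from conftest import even_split, make_geno


def ols_oracle(y, x):
    """Normal-equations OLS: coefficients, RSS, per-coefficient two-sided p."""
    xtx = x.T @ x
    beta = np.linalg.solve(xtx, x.T @ y)
    resid = y - x @ beta
    rss = float(resid @ resid)
    dof = len(y) - x.shape[1]
    sigma2 = rss / dof
    se2 = sigma2 * np.diag(np.linalg.inv(xtx))
    t2 = beta**2 / se2
    p = stats.f.sf(t2, 1, dof)
    return beta, rss, p


def partial_f_oracle(y, x_full, col):
    """p-value from the explicit reduced-vs-full RSS F test dropping one column."""
    _, rss_full, _ = ols_oracle(y, x_full)
    x_red = np.delete(x_full, col, axis=1)
    beta_r = np.linalg.lstsq(x_red, y, rcond=None)[0]
    rss_red = float(((y - x_red @ beta_r) ** 2).sum())
    dof = len(y) - x_full.shape[1]
    f = (rss_red - rss_full) / (rss_full / dof)
    return stats.f.sf(f, 1, dof)


class TestFitSingleEnv:
    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(0)
        g = rng.choice([-1.0, 1.0], 20)
        y = 0.7 * g + rng.normal(size=20)
        lod, effect = qtl.fit_single_env(y, g)
        x = np.column_stack([np.ones(20), g])
        beta, _, p = ols_oracle(y, x)
        assert effect == pytest.approx(beta[1], abs=1e-10)
        assert lod == pytest.approx(-np.log10(p[1]), abs=1e-8)

    def test_lod_is_minus_log10_p(self):
        rng = np.random.default_rng(1)
        g = rng.choice([-1.0, 1.0], 30)
        y = rng.normal(size=30)
        lod, _ = qtl.fit_single_env(y, g)
        x = np.column_stack([np.ones(30), g])
        _, _, p = ols_oracle(y, x)
        assert lod == pytest.approx(-np.log10(p[1]), abs=1e-8)

    def test_perfect_fit_capped_at_ceiling(self):
        g = np.array([-1.0, -1.0, -1.0, 1.0, 1.0, 1.0])
        lod, effect = qtl.fit_single_env(g.copy(), g)
        assert lod == pytest.approx(qtl.LOD_CEILING)
        assert effect == pytest.approx(1.0)

    def test_monomorphic_marker_missing(self):
        lod, effect = qtl.fit_single_env(np.arange(6.0), np.ones(6))
        assert np.isnan(lod) and np.isnan(effect)


class TestFitCombined:
    def test_partial_f_equals_full_model_t2(self):
        rng = np.random.default_rng(2)
        n = 40
        e = np.repeat([0.0, 1.0], n // 2)
        g = rng.choice([-1.0, 1.0], n)
        y = 0.5 * e + 0.8 * g + 0.4 * e * g + rng.normal(size=n)
        res = qtl.fit_combined(y, g, e)
        x = np.column_stack([np.ones(n), e, g, e * g])
        for term, col in [("lod_e", 1), ("lod_g", 2), ("lod_gxe", 3)]:
            p = partial_f_oracle(y, x, col)
            assert res[term] == pytest.approx(-np.log10(p), abs=1e-8)

    def test_effects_per_condition_from_coding(self):
        rng = np.random.default_rng(3)
        n = 60
        e = np.repeat([0.0, 1.0], n // 2)
        g = rng.choice([-1.0, 1.0], n)
        y = 1.0 * g + 0.5 * e * g + 0.1 * rng.normal(size=n)
        res = qtl.fit_combined(y, g, e)
        assert res["effect_cond0"] == pytest.approx(res["beta"][2])
        assert res["effect_cond1"] == pytest.approx(res["beta"][2] + res["beta"][3])
        assert res["effect_cond0"] == pytest.approx(1.0, abs=0.1)
        assert res["effect_cond1"] == pytest.approx(1.5, abs=0.1)

    def test_null_interaction_lod_median_near_point_three(self):
        rng = np.random.default_rng(4)
        n = 100
        e = np.repeat([0.0, 1.0], n // 2)
        g = rng.choice([-1.0, 1.0], n)
        lods = []
        for _ in range(1000):
            y = 0.5 * e + 0.5 * g + rng.normal(size=n)
            lods.append(qtl.fit_combined(y, g, e)["lod_gxe"])
        assert np.median(lods) == pytest.approx(-np.log10(0.5), abs=0.05)

    def test_pure_environment_trait(self):
        rng = np.random.default_rng(5)
        n = 40
        e = np.repeat([0.0, 1.0], n // 2)
        g = rng.choice([-1.0, 1.0], n)
        res = qtl.fit_combined(e.astype(float), g, e)
        assert res["lod_e"] == pytest.approx(qtl.LOD_CEILING)

    def test_empty_cell_marked_missing(self):
        # genotype constant within one condition -> interaction collinear
        e = np.repeat([0.0, 1.0], 10)
        g = np.concatenate([np.ones(10), np.repeat([-1.0, 1.0], 5)])
        res = qtl.fit_combined(np.random.default_rng(6).normal(size=20), g, e)
        assert np.isnan(res["lod_g"]) and np.isnan(res["lod_gxe"])


class TestScan:
    @staticmethod
    @pytest.fixture(scope="class")
    def scan_setup():
        rng = np.random.default_rng(7)
        geno = make_geno(rng.choice([-1.0, 1.0], (40, 20)),
                         positions=np.tile(np.arange(10) * 10.0, 2),
                         chrom=np.repeat([1, 2], 10))
        alloc = even_split(geno.lines)
        e = (alloc.assignment.loc[geno.lines] == IMBIBED).to_numpy(float)
        y = np.column_stack([
            1.2 * geno.calls["m3"] + rng.normal(size=40),
            0.8 * e + rng.normal(size=40),
            rng.normal(size=40),
        ])
        traits = pd.DataFrame(y, index=geno.lines, columns=["a", "b", "c"])
        from gggqtl.types import MetaboliteMatrix
        samples = pd.DataFrame({"line": geno.lines,
                                "condition": alloc.assignment.loc[geno.lines]},
                               index=traits.index)
        return MetaboliteMatrix(traits, samples), geno, alloc

    def test_matches_per_pair_loop(self, scan_setup):
        traits, geno, alloc = scan_setup
        sr = qtl.scan(traits, geno, alloc)
        e = (traits.samples["condition"] == IMBIBED).to_numpy(float)
        for trait in traits.values.columns:
            for marker in geno.map.marker_names():
                res = qtl.fit_combined(traits.values[trait], geno.calls[marker], e)
                for attr, key in [("lod_e", "lod_e"), ("lod_g", "lod_g"),
                                  ("lod_gxe", "lod_gxe")]:
                    got = getattr(sr, attr).loc[trait, marker]
                    assert got == pytest.approx(res[key], abs=1e-8)

    def test_duplicate_traits_identical_rows(self, scan_setup):
        traits, geno, alloc = scan_setup
        dup = traits.values.copy()
        dup["a2"] = dup["a"]
        from gggqtl.types import MetaboliteMatrix
        sr = qtl.scan(MetaboliteMatrix(dup, traits.samples), geno, alloc)
        pd.testing.assert_series_equal(sr.lod_g.loc["a"], sr.lod_g.loc["a2"],
                                       check_names=False)

    def test_missing_trait_values_fit_on_observed_rows(self, scan_setup):
        traits, geno, alloc = scan_setup
        holed = traits.values.copy()
        holed.iloc[[0, 5], 0] = np.nan
        from gggqtl.types import MetaboliteMatrix
        sr = qtl.scan(MetaboliteMatrix(holed, traits.samples), geno, alloc)
        keep = holed["a"].notna().to_numpy()
        e = (traits.samples["condition"] == IMBIBED).to_numpy(float)[keep]
        res = qtl.fit_combined(holed["a"].to_numpy()[keep],
                               geno.calls["m4"].to_numpy()[keep], e)
        assert sr.lod_g.loc["a", "m4"] == pytest.approx(res["lod_g"], abs=1e-8)

    def test_study_scale_dimensions(self, study_map):
        geno = simulate.simulate_ril_genotypes(study_map, 100, seed=8)
        alloc = even_split(geno.lines)
        truth = simulate.default_truth_table(study_map, 20, seed=9)
        metab = simulate.plant_metabolome(geno, alloc, truth, seed=10)
        sr = qtl.scan(metab, geno, alloc)
        assert sr.lod_g.shape == (20, 865)
        assert sr.lod_gxe.notna().all().all()


class TestNormalizedEffect:
    def test_fraction_of_range(self):
        assert qtl.normalized_effect([0.0, 4.0, 1.0], 1.0) == pytest.approx(0.25)

    def test_zero_effect(self):
        assert qtl.normalized_effect([0.0, 2.0], 0.0) == pytest.approx(0.0)

    def test_effect_equal_to_range(self):
        assert qtl.normalized_effect([1.0, 3.0], 2.0) == pytest.approx(1.0)

    def test_flat_trait_missing(self):
        assert np.isnan(qtl.normalized_effect([2.0, 2.0], 1.0))


class TestPermutationThreshold:
    @staticmethod
    @pytest.fixture(scope="class")
    def null_setup():
        gm = simulate.simulate_map(3, 60, 100.0, seed=20)
        geno = simulate.simulate_ril_genotypes(gm, 60, seed=21)
        alloc = even_split(geno.lines)
        truth = simulate.default_truth_table(gm, 10, n_qtl=0, beta_e=0.0, seed=22)
        metab = simulate.plant_metabolome(geno, alloc, truth, block_spec=(), seed=23)
        return metab, geno, alloc

    def test_alpha_one_gives_min_of_maxima(self, null_setup):
        metab, geno, alloc = null_setup
        thr = qtl.permutation_threshold(metab, geno, alloc, n_perm=100,
                                        alpha=1.0, seed=24)
        assert thr.threshold == pytest.approx(thr.null_max_lod.min())

    def test_monotone_nonincreasing_in_alpha(self, null_setup):
        metab, geno, alloc = null_setup
        thr = qtl.permutation_threshold(metab, geno, alloc, n_perm=100, seed=25)
        qs = [np.quantile(thr.null_max_lod, 1 - a) for a in (0.01, 0.05, 0.2, 1.0)]
        assert all(x >= y - 1e-12 for x, y in zip(qs, qs[1:]))

    def test_monte_carlo_stability(self, null_setup):
        metab, geno, alloc = null_setup
        t1 = qtl.permutation_threshold(metab, geno, alloc, n_perm=200,
                                       alpha=0.05, seed=26).threshold
        t2 = qtl.permutation_threshold(metab, geno, alloc, n_perm=600,
                                       alpha=0.05, seed=27).threshold
        assert abs(t1 - t2) < 0.2

    def test_invariant_to_trait_relabeling(self, null_setup):
        metab, geno, alloc = null_setup
        shuffled = metab.with_values(
            metab.values[list(reversed(metab.values.columns))])
        a = qtl.permutation_threshold(metab, geno, alloc, n_perm=100, seed=28)
        b = qtl.permutation_threshold(shuffled, geno, alloc, n_perm=100, seed=28)
        assert a.threshold == pytest.approx(b.threshold)

    def test_deterministic_for_seed(self, null_setup):
        metab, geno, alloc = null_setup
        a = qtl.permutation_threshold(metab, geno, alloc, n_perm=100, seed=29)
        b = qtl.permutation_threshold(metab, geno, alloc, n_perm=100, seed=29)
        np.testing.assert_array_equal(a.null_max_lod, b.null_max_lod)


class TestCallsHotspotsOverlap:
    @staticmethod
    @pytest.fixture(scope="class")
    def planted_scan():
        gm = simulate.simulate_map(4, 80, 100.0, seed=30)
        geno = simulate.simulate_ril_genotypes(gm, 100, seed=31)
        alloc = even_split(geno.lines)
        markers = gm.marker_names()
        causal1 = markers[10]   # chromosome 1
        causal2 = markers[30]   # chromosome 2
        rows = [("t1", causal1, 0.0, 0.0, 1.5, 0.0, 0.5),
                ("t2", causal2, 0.0, 0.0, -1.5, 0.0, 0.5),
                ("both", causal1, 0.0, 0.0, 1.5, 0.0, 0.5)]
        truth = QtlTruthTable(pd.DataFrame(rows, columns=list(QtlTruthTable.COLUMNS)))
        metab = simulate.plant_metabolome(geno, alloc, truth, block_spec=(), seed=32)
        sr = qtl.scan(metab, geno, alloc)
        return gm, geno, sr, causal1, causal2

    def test_planted_qtl_called_at_causal_marker(self, planted_scan):
        gm, geno, sr, causal1, _ = planted_scan
        calls = qtl.call_qtl(sr, 4.0, terms=("G",))
        t1 = calls[calls["trait"] == "t1"]
        assert len(t1) == 1
        peak_cm = t1["peak_cm"].iloc[0]
        causal_cm = gm.markers.loc[causal1, "cm"]
        assert t1["chrom"].iloc[0] == gm.markers.loc[causal1, "chrom"]
        assert abs(peak_cm - causal_cm) <= 10.0
        assert t1["allele_sign"].iloc[0] == "MM"

    def test_negative_effect_signed_pimp(self, planted_scan):
        sr = planted_scan[2]
        calls = qtl.call_qtl(sr, 4.0, terms=("G",))
        t2 = calls[calls["trait"] == "t2"]
        assert (t2["allele_sign"] == "Pimp").all()

    def test_two_chromosomes_two_calls(self, planted_scan):
        gm, _, sr, _, _ = planted_scan
        calls = qtl.call_qtl(sr, 4.0, terms=("G",))
        assert set(calls[calls["trait"].isin(["t1", "t2"])]["chrom"]) == {1, 2}

    def test_support_interval_contains_peak(self, planted_scan):
        _, _, sr, _, _ = planted_scan
        calls = qtl.call_qtl(sr, 4.0, terms=("G",))
        assert ((calls["ci_lo_cm"] <= calls["peak_cm"])
                & (calls["peak_cm"] <= calls["ci_hi_cm"])).all()

    def test_hotspot_flags_shared_location(self, planted_scan):
        gm, _, sr, causal1, _ = planted_scan
        calls = qtl.call_qtl(sr, 4.0, terms=("G",))
        hs = qtl.hotspot_table(calls, gm, window_cm=10.0)
        causal_chrom = gm.markers.loc[causal1, "chrom"]
        causal_cm = gm.markers.loc[causal1, "cm"]
        bin_row = hs[(hs["chrom"] == causal_chrom)
                     & (hs["bin_lo_cm"] <= causal_cm)
                     & (causal_cm < hs["bin_hi_cm"])]
        assert bin_row["n_traits"].iloc[0] >= 2

    def test_empty_calls_empty_hotspots(self, planted_scan):
        gm = planted_scan[0]
        hs = qtl.hotspot_table(pd.DataFrame(columns=qtl.CALL_COLUMNS), gm, 10.0)
        assert (hs["n_traits"] == 0).all() and (~hs["hotspot"]).all()

    def test_overlap_counts_shared_architecture(self, planted_scan):
        _, _, sr, _, _ = planted_scan
        calls = qtl.call_qtl(sr, 4.0, terms=("G",))
        mq = calls[calls["trait"].isin(["t1", "both"])]
        ph = calls[calls["trait"] == "t1"]
        ov = qtl.qtl_overlap(mq, ph, window_cm=10.0)
        assert ov["n_mqtl"].iloc[0] == 2

    def test_overlap_zero_when_far(self, planted_scan):
        _, _, sr, _, _ = planted_scan
        calls = qtl.call_qtl(sr, 4.0, terms=("G",))
        mq = calls[calls["trait"] == "t1"]
        ph = calls[calls["trait"] == "t2"]
        ov = qtl.qtl_overlap(mq, ph, window_cm=10.0)
        assert (ov["n_mqtl"] == 0).all()
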