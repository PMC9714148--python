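"""RPM/Escore arithmetic and the interaction GLM."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from epicrosstalk.errors import ConfigError, DataError, InsufficientDataError
from epicrosstalk.interaction import (benjamini_hochberg, escore, escore_table,
                                      fit_interaction_glm, rpm,
                                      screen_interaction_regions)
from epicrosstalk.io import PeakCountTable, SampleInfo
from epicrosstalk.simulate import SimulationConfig, simulate_interaction_study
from epicrosstalk.cooccurrence import peak_methylation


class TestRPM:
    def test_examples(self):
        assert rpm(100, 10**6) == 100.0
        assert rpm(0, 12345) == 0.0
        assert rpm(50, 2 * 10**6) == 25.0

    def test_invalid_total(self):
        with pytest.raises(DataError):
            rpm(10, 0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(count=st.integers(0, 10**6), total=st.integers(1, 10**9),
           scale=st.integers(1, 1000))
    def test_scale_invariance(self, count, total, scale):
        assert rpm(count * scale, total * scale) == \
            pytest.approx(rpm(count, total), rel=1e-12)


class TestEscore:
    def test_identity_and_hand_case(self):
        assert escore(10, 1000, 10, 1000) == pytest.approx(1.0, abs=1e-12)
        assert escore(100, 10**6, 50, 2 * 10**6) == pytest.approx(4.0,
                                                                  abs=1e-12)

    def test_zero_input_flagged_not_raised(self):
        assert np.isnan(escore(10, 1000, 0, 1000))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(ip=st.integers(1, 10**5), inp=st.integers(1, 10**5),
           t1=st.integers(10**5, 10**8), t2=st.integers(10**5, 10**8),
           c=st.integers(1, 500))
    def test_proportional_depth_invariance(self, ip, inp, t1, t2, c):
        base = escore(ip, t1, inp, t2)
        scaled = escore(ip * c, t1 * c, inp * c, t2 * c)
        assert scaled == pytest.approx(base, rel=1e-12)


class TestEscoreTable:
    @pytest.fixture
    def toy_counts(self):
        sheet = []
        rows = []
        totals = {}
        for st_, rep, assay, count, total in [
            (30, 1, "merip_ip", 100, 10**6), (30, 2, "merip_ip", 200, 10**6),
            (30, 1, "merip_input", 50, 10**6), (30, 2, "merip_input", 100, 10**6),
        ]:
            sid = f"{assay}_s{st_}_r{rep}"
            sheet.append(SampleInfo(sid, st_, rep, assay))
            rows.append({"peak_id": "p1", "sample_id": sid, "count": count})
            totals[sid] = total
        return PeakCountTable(pd.DataFrame(rows), totals), sheet

    def test_stage_pooled_sums_counts_and_totals(self, toy_counts):
        table, sheet = toy_counts
        out = escore_table(table, sheet, mode="stage_pooled")
        assert len(out) == 1
        # pooled: ip 300/2e6 vs input 150/2e6 -> escore 2.0
        assert out.iloc[0]["escore"] == pytest.approx(2.0, abs=1e-12)

    def test_replicate_mode_matches_pairs(self, toy_counts):
        table, sheet = toy_counts
        out = escore_table(table, sheet, mode="replicate").sort_values(
            "replicate")
        np.testing.assert_allclose(out["escore"], [2.0, 2.0])


class TestFitInteractionGLM:
    @staticmethod
    def design(n, seed):
        rng = np.random.default_rng(seed)
        s = np.repeat([30.0, 60, 120, 180], int(np.ceil(n / 4)))[:n]
        x = np.exp(rng.uniform(np.log(2), np.log(16), n))
        y = rng.uniform(0.1, 0.9, n)
        return s, x, y

    def test_exact_interpolation_recovers_coefficients(self):
        s, x, y = self.design(10, 0)
        resp = 1 + 0.1 * s + 0.5 * x - 2 * y + 0.3 * x * y
        with pytest.warns(UserWarning, match="perfect fit"):
            fit = fit_interaction_glm(resp, s, x, y)
        assert fit.perfect_fit
        np.testing.assert_allclose(
            [fit.coef[t] for t in ("intercept", "stage", "escore", "meth",
                                   "interaction")],
            [1, 0.1, 0.5, -2, 0.3], atol=1e-8)
        assert np.isnan(fit.p_interaction)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        from scipy import stats as sps
        for seed in range(25):
            s, x, y = self.design(12, seed)
            resp = 2 + 0.05 * s + 0.3 * x + y + 0.5 * x * y + \
                rng.normal(0, 0.5, 12)
            fit = fit_interaction_glm(resp, s, x, y)
            d = np.column_stack([np.ones(12), s, x, y, x * y])
            beta = np.linalg.solve(d.T @ d, d.T @ resp)
            resid = resp - d @ beta
            sigma2 = resid @ resid / (12 - 5)
            se = np.sqrt(sigma2 * np.diag(np.linalg.inv(d.T @ d)))
            p = 2 * sps.t.sf(np.abs(beta / se), 12 - 5)
            terms = ("intercept", "stage", "escore", "meth", "interaction")
            np.testing.assert_allclose([fit.coef[t] for t in terms], beta,
                                       atol=1e-8)
            np.testing.assert_allclose([fit.pvalue[t] for t in terms], p,
                                       atol=1e-6)

    def test_matches_statsmodels(self):
        statsmodels = pytest.importorskip("statsmodels.api")
        s, x, y = self.design(16, 3)
        rng = np.random.default_rng(4)
        resp = 1 + 0.02 * s + 0.1 * x + 0.4 * y - 0.2 * x * y + \
            rng.normal(0, 0.3, 16)
        fit = fit_interaction_glm(resp, s, x, y)
        d = np.column_stack([np.ones(16), s, x, y, x * y])
        ref = statsmodels.OLS(resp, d).fit()
        terms = ("intercept", "stage", "escore", "meth", "interaction")
        np.testing.assert_allclose([fit.coef[t] for t in terms], ref.params,
                                   atol=1e-8)
        np.testing.assert_allclose([fit.pvalue[t] for t in terms],
                                   ref.pvalues, atol=1e-8)
        assert fit.r2 == pytest.approx(ref.rsquared, abs=1e-8)

    def test_rank_deficient_column_dropped(self):
        s, x, _ = self.design(10, 5)
        y = np.full(10, 0.5)  # constant methylation -> meth collinear with 1
        rng = np.random.default_rng(6)
        resp = 1 + 0.1 * s + 0.2 * x + rng.normal(0, 0.1, 10)
        with pytest.warns(UserWarning, match="rank-deficient"):
            fit = fit_interaction_glm(resp, s, x, y)
        assert fit.dropped  # some term had to go
        assert fit.df_resid == 10 - (5 - len(fit.dropped))

    def test_too_few_observations(self):
        with pytest.raises(InsufficientDataError):
            fit_interaction_glm(np.ones(5), np.ones(5), np.ones(5),
                                np.ones(5))

    def test_type_one_error_calibrated(self):
        """Null interaction rejected at ~alpha for the exact t test (n=8)."""
        rng = np.random.default_rng(7)
        rejections = 0
        reps = 400
        for _ in range(reps):
            s = np.repeat([30.0, 60, 120, 180], 2)
            x = np.exp(rng.uniform(np.log(2), np.log(16), 8))
            y = rng.uniform(0.1, 0.9, 8)
            resp = 3 + 0.01 * s + 0.5 * x + y + rng.normal(0, 0.2, 8)
            fit = fit_interaction_glm(resp, s, x, y)
            rejections += fit.p_interaction < 0.05
        assert rejections / reps == pytest.approx(0.05, abs=0.035)


class TestBenjaminiHochberg:
    def test_known_example(self):
        p = np.array([0.01, 0.04, 0.03, 0.005])
        adj = benjamini_hochberg(p)
        # sorted p: .005,.01,.03,.04 -> adj .02,.02,.04,.04
        np.testing.assert_allclose(sorted(adj), [0.02, 0.02, 0.04, 0.04])

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=100)
        adj = benjamini_hochberg(p)
        assert (adj >= p - 1e-15).all() and (adj <= 1).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()


class TestScreen:
    def test_gene_rollup_counts_gene_once(self):
        study = simulate_interaction_study(SimulationConfig(
            seed=20, n_interaction_genes=2, n_null_genes=10))
        # give the first gene a second, duplicated region
        peaks = study.peaks.peaks.copy()
        extra = peaks.iloc[[0]].assign(peak_id="region_dup")
        peaks = pd.concat([peaks, extra], ignore_index=True)
        from epicrosstalk.io import PeakSet
        from epicrosstalk.interaction import escore_table
        esc = escore_table(study.counts, study.sample_sheet, mode="replicate")
        esc_dup = pd.concat([esc, esc[esc.peak_id == "region_0001"]
                             .assign(peak_id="region_dup")], ignore_index=True)
        pm = peak_methylation(PeakSet(peaks), study.methylation)
        screen = screen_interaction_regions(
            study.expression, PeakSet(peaks), esc_dup, pm,
            study.sample_sheet)
        g = screen.genes.set_index("gene_id").loc["gene_0001"]
        assert g["n_regions"] == 2
        # both duplicated regions carry the same fit -> same significance
        sub = screen.fits[screen.fits.gene_id == "gene_0001"]
        assert len(sub) == 2
        assert sub["significant"].nunique() == 1
        assert bool(g["significant"]) == bool(sub["significant"].iloc[0])

    def test_regions_without_gene_are_skipped(self):
        study = simulate_interaction_study(SimulationConfig(
            seed=21, n_interaction_genes=1, n_null_genes=5))
        peaks = study.peaks.peaks.copy()
        peaks.loc[0, "gene_id"] = "unknown_gene"
        from epicrosstalk.io import PeakSet
        from epicrosstalk.interaction import escore_table
        esc = escore_table(study.counts, study.sample_sheet, mode="replicate")
        pm = peak_methylation(PeakSet(peaks), study.methylation)
        screen = screen_interaction_regions(
            study.expression, PeakSet(peaks), esc, pm, study.sample_sheet)
        assert "no_gene_expression" in set(screen.skipped["reason"])
        assert len(screen.fits) == 5

    def test_bh_correction_is_more_conservative(self):
        study = simulate_interaction_study(SimulationConfig(seed=22))
        from epicrosstalk.interaction import escore_table
        esc = escore_table(study.counts, study.sample_sheet, mode="replicate")
        pm = peak_methylation(study.peaks, study.methylation)
        raw = screen_interaction_regions(study.expression, study.peaks, esc,
                                         pm, study.sample_sheet)
        bh = screen_interaction_regions(study.expression, study.peaks, esc,
                                        pm, study.sample_sheet,
                                        correction="benjamini_hochberg")
        assert bh.n_significant_regions <= raw.n_significant_regions

    def test_invalid_alpha(self):
        study = simulate_interaction_study(SimulationConfig(
            seed=23, n_interaction_genes=1, n_null_genes=5))
        with pytest.raises(ConfigError):
            screen_interaction_regions(study.expression, study.peaks,
                                       pd.DataFrame(), pd.DataFrame(),
                                       study.sample_sheet, alpha=1.5)
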