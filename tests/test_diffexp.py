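import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.stats import chi2

from apomir.datasets import load_de_reference
from apomir.diffexp import (
    DEResult,
    bh_adjust,
    classify_dysregulated,
    fit_paired_nb,
    run_de,
    run_subgroup_de,
    summarize_fc,
)
from apomir.io import (
    ExpressionMatrix,
    MatrixKind,
    PathwayGeneList,
    Phenotype,
    ValidationError,
)
from apomir.normalize import rpmpcg_normalize
from apomir.simulate import SimulationConfig, simulate_paired_counts


def _offsets(counts, meta):
    order = [m.sample_id for m in meta]
    return order, np.log(counts.values.sum(axis=0)[order].to_numpy(dtype=float))


class TestFitPairedNB:
    def test_symmetric_data_gives_zero_logfc(self, small_cohort):
        _, counts, meta, _ = small_cohort
        order, off = _offsets(counts, meta)
        # force tumor == normal per subject (and equal offsets)
        y = counts.values.loc["G0002", order].to_numpy(dtype=float)
        subjects = sorted({m.subject_id for m in meta})
        pos = {s: i for i, s in enumerate(order)}
        for s in subjects:
            y[pos[f"{s}_T"]] = y[pos[f"{s}_N"]]
            off[pos[f"{s}_T"]] = off[pos[f"{s}_N"]]
        fit = fit_paired_nb(y, meta, off)
        assert fit.log_fc_estimate == pytest.approx(0.0, abs=1e-6)
        assert fit.raw_p >= 0.99

    def test_matches_dense_statsmodels_glm(self, small_cohort):
        """The O(n) arrowhead IRLS equals a dense NB GLM at the same dispersion."""
        _, counts, meta, _ = small_cohort
        order, off = _offsets(counts, meta)
        y = counts.values.loc["G0000", order].to_numpy(dtype=float)
        fit = fit_paired_nb(y, meta, off)
        subj = pd.get_dummies([m.subject_id for m in meta], dtype=float).to_numpy()
        tis = np.array([1.0 if m.tissue.value == "tumor" else 0.0 for m in meta])
        X = np.column_stack([tis, subj])
        fam = sm.families.NegativeBinomial(alpha=fit.alpha)
        r1 = sm.GLM(y, X, family=fam, offset=off).fit()
        r0 = sm.GLM(y, X[:, 1:], family=fam, offset=off).fit()
        assert fit.log_fc_estimate == pytest.approx(r1.params[0], abs=1e-4)
        assert fit.loglik_full == pytest.approx(r1.llf, abs=1e-6)
        assert fit.raw_p == pytest.approx(chi2.sf(2 * (r1.llf - r0.llf), 1), rel=1e-3)

    def test_poisson_limit_matches_paired_poisson_oracle(self):
        cfg = SimulationConfig(
            n_subjects=40, n_genes=6, rng_seed=9, nb_dispersion=0.0, subject_effect_sd=0.0
        )
        counts, meta, _ = simulate_paired_counts(cfg)
        order, off = _offsets(counts, meta)
        subj = pd.get_dummies([m.subject_id for m in meta], dtype=float).to_numpy()
        tis = np.array([1.0 if m.tissue.value == "tumor" else 0.0 for m in meta])
        X = np.column_stack([tis, subj])
        n_floor = 0
        for g in cfg.gene_ids()[:4]:
            y = counts.values.loc[g, order].to_numpy(dtype=float)
            # dispersion -> 0 limit: fit at the Poisson boundary
            fit = fit_paired_nb(y, meta, off, alpha=0.0)
            r1 = sm.GLM(y, X, family=sm.families.Poisson(), offset=off).fit()
            r0 = sm.GLM(y, X[:, 1:], family=sm.families.Poisson(), offset=off).fit()
            p_oracle = chi2.sf(2 * (r1.llf - r0.llf), 1)
            assert abs(fit.raw_p - p_oracle) < 0.01
            # the default estimator should also land on the boundary for
            # most Poisson-generated genes
            n_floor += fit_paired_nb(y, meta, off).alpha < 1e-7
        assert n_floor >= 3

    def test_all_zero_gene_flagged_untestable(self, small_cohort):
        _, counts, meta, _ = small_cohort
        order, off = _offsets(counts, meta)
        fit = fit_paired_nb(np.zeros(len(meta)), meta, off)
        assert fit.status == "untestable"

    def test_recovers_planted_logfc(self, small_cohort):
        _, counts, meta, truth = small_cohort
        order, off = _offsets(counts, meta)
        y = counts.values.loc["G0000", order].to_numpy(dtype=float)
        fit = fit_paired_nb(y, meta, off)
        assert fit.log_fc_estimate == pytest.approx(np.log(2), abs=0.4)
        y = counts.values.loc["G0001", order].to_numpy(dtype=float)
        fit = fit_paired_nb(y, meta, off)
        assert fit.log_fc_estimate == pytest.approx(-np.log(2), abs=0.4)


class TestSummarizeFC:
    def test_reference_mean_ratios(self, paired_meta):
        # printed tumor/normal means reproduce the printed fold changes
        cols = {}
        for m in paired_meta:
            cols[m.sample_id] = (
                [35.63, 27.82] if m.tissue.value == "tumor" else [11.31, 73.57]
            )
        mat = ExpressionMatrix(pd.DataFrame(cols, index=["BIRC5", "CSF2RB"]), MatrixKind.RPMPCG)
        tm, nm, fc = summarize_fc(mat, paired_meta, "BIRC5")
        assert round(fc, 2) == 3.15
        tm, nm, fc = summarize_fc(mat, paired_meta, "CSF2RB")
        assert round(fc, 2) == 0.38

    def test_equal_means_give_unit_fc(self, paired_meta):
        cols = {m.sample_id: [4.2] for m in paired_meta}
        mat = ExpressionMatrix(pd.DataFrame(cols, index=["g"]), MatrixKind.RPMPCG)
        assert summarize_fc(mat, paired_meta, "g")[2] == pytest.approx(1.0)

    def test_zero_normal_mean_flagged_nan(self, paired_meta):
        cols = {
            m.sample_id: [1.0 if m.tissue.value == "tumor" else 0.0]
            for m in paired_meta
        }
        mat = ExpressionMatrix(pd.DataFrame(cols, index=["g"]), MatrixKind.RPMPCG)
        assert np.isnan(summarize_fc(mat, paired_meta, "g")[2])


class TestBHAdjust:
    def test_single_value_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.05]), [0.05])

    def test_largest_p_maps_to_itself(self):
        ref = load_de_reference()
        adj = bh_adjust(ref["raw_p"].to_numpy())
        i = int(np.argmax(ref["raw_p"].to_numpy()))
        assert adj[i] == pytest.approx(ref["raw_p"].iloc[i])
        assert ref["raw_p"].iloc[i] == pytest.approx(0.915)

    def test_matches_brute_force_step_up_oracle(self):
        rng = np.random.default_rng(17)
        p = rng.uniform(size=100)
        # independently coded step-up: sort, p*m/rank, enforce monotonicity
        order = np.argsort(p)
        m = len(p)
        adj_sorted = [p[order[i]] * m / (i + 1) for i in range(m)]
        for i in range(m - 2, -1, -1):
            adj_sorted[i] = min(adj_sorted[i], adj_sorted[i + 1])
        oracle = np.empty(m)
        for i, o in enumerate(order):
            oracle[o] = min(adj_sorted[i], 1.0)
        np.testing.assert_allclose(bh_adjust(p), oracle, rtol=1e-12)

    def test_monotone_in_sorted_order(self):
        rng = np.random.default_rng(23)
        p = rng.uniform(size=57)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.2])


class TestClassifyDysregulated:
    @staticmethod
    def _reference_results():
        ref = load_de_reference()
        return [
            DEResult(
                r.gene,
                r.tumor_mean,
                r.normal_mean,
                r.tumor_mean / r.normal_mean,  # unrounded mean ratio
                np.nan,
                r.raw_p,
                r.adjusted_p,
            )
            for r in ref.itertuples()
        ]

    def test_reference_counts_at_default_thresholds(self):
        summary = classify_dysregulated(self._reference_results())
        assert (summary.n_down, summary.n_up) == (23, 18)
        assert "EIF2AK3" in summary.down_genes  # ratio 0.6656 counts as < 0.67
        assert "MAPK3" not in summary.down_genes  # ratio 0.6723 does not
        assert "HRAS" not in summary.up_genes  # ratio 1.4972 prints as 1.50

    def test_reference_counts_at_strong_thresholds(self):
        summary = classify_dysregulated(self._reference_results(), lower=0.4, upper=2.0)
        assert (summary.n_down, summary.n_up) == (5, 9)
        assert summary.down_genes == sorted(["SPTA1", "MAPK10", "TUBAL3", "CSF2RB", "BCL2"])

    def test_empty_input(self):
        s = classify_dysregulated([])
        assert (s.n_down, s.n_up) == (0, 0)


class TestRunDE:
    def test_full_run_produces_coherent_results(self, small_cohort):
        _, counts, meta, truth = small_cohort
        pathway = PathwayGeneList(tuple(g for g in counts.feature_ids if g != "PC_BACKGROUND"))
        results = run_de(counts, meta, pathway)
        assert len(results) == len(pathway)
        for r in results:
            assert r.adjusted_p >= r.raw_p - 1e-15
            norm_means_fc = r.tumor_mean / r.normal_mean
            assert r.fold_change == pytest.approx(norm_means_fc, abs=1e-9)
        sig = [r for r in results if r.adjusted_p < 0.05]
        for r in sig:
            assert np.sign(r.log_fc_estimate) == np.sign(np.log(r.fold_change))

    def test_subgroup_planted_only_in_msi(self):
        rng_fc = np.r_[np.zeros(10)]
        cfg = SimulationConfig(
            n_subjects=80, n_genes=10, rng_seed=31, true_log_fc=rng_fc, frac_mss=0.5
        )
        counts, meta, _ = simulate_paired_counts(cfg)
        # plant a strong tumor shift for gene G0000 in MSI subjects only
        msi = {m.subject_id for m in meta if m.phenotype is Phenotype.MSI}
        vals = counts.values.copy()
        for s in msi:
            vals.loc["G0000", f"{s}_T"] = np.round(vals.loc["G0000", f"{s}_T"] * 3)
        counts = ExpressionMatrix(vals, MatrixKind.MRNA_COUNTS)
        pathway = PathwayGeneList(tuple(cfg.gene_ids()))
        msi_res = {r.gene: r for r in run_subgroup_de(counts, meta, pathway, "MSI")}
        mss_res = {r.gene: r for r in run_subgroup_de(counts, meta, pathway, "MSS")}
        assert msi_res["G0000"].raw_p < 0.05
        assert mss_res["G0000"].raw_p > 0.05
        assert all(r.subgroup == "MSI" for r in msi_res.values())

    def test_empty_subgroup_errors(self, small_cohort):
        from dataclasses import replace

        _, counts, meta, _ = small_cohort
        all_mss = [replace(m, phenotype=Phenotype.MSS) for m in meta]
        with pytest.raises(ValidationError):
            run_subgroup_de(
                counts, all_mss, PathwayGeneList(("G0000",)), "MSI"
            )

    def test_single_phenotype_subgroup_equals_full_run(self, small_cohort):
        from dataclasses import replace

        _, counts, meta, _ = small_cohort
        all_mss = [replace(m, phenotype=Phenotype.MSS) for m in meta]
        pathway = PathwayGeneList(("G0000", "G0003"))
        full = run_de(counts, all_mss, pathway)
        sub = run_subgroup_de(counts, all_mss, pathway, "MSS")
        for a, b in zip(full, sub):
            assert a.gene == b.gene
            assert a.raw_p == pytest.approx(b.raw_p, rel=1e-9)
            assert a.log_fc_estimate == pytest.approx(b.log_fc_estimate, abs=1e-9)
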