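import warnings

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

from apomir.io import (
    ExpressionMatrix,
    MatrixKind,
    Sex,
    Site,
    ValidationError,
)
from apomir.survival import (
    SurvivalInput,
    build_survival_records,
    cox_fit,
    estimate_pi0,
    iqr_scaled_hr,
    permutation_lrt_p,
    q_values,
    run_survival,
)
from tests.conftest import make_meta


def _records(seed=0, n=120, beta_expo=0.0, round_times=False):
    rng = np.random.default_rng(seed)
    age = rng.normal(65, 10, n)
    sexf = rng.random(n) < 0.45
    stage = rng.integers(1, 5, n)
    expo = rng.normal(0, 1.5, n)
    lp = 0.02 * (age - 65) + 0.25 * stage + beta_expo * expo
    t = rng.exponential(np.exp(-lp) * 40)
    c = rng.exponential(60, n)
    time_obs = np.minimum(t, c)
    if round_times:
        time_obs = np.ceil(time_obs)
    event = t <= c
    return [
        SurvivalInput(
            f"s{i}", float(time_obs[i]), bool(event[i]), float(age[i]),
            Sex.FEMALE if sexf[i] else Sex.MALE, int(stage[i]),
            Site.COLON if i % 3 else Site.RECTAL, float(expo[i]),
        )
        for i in range(n)
    ]


class TestBuildRecords:
    def _meta(self):
        rows = []
        specs = [
            # (vital, crc_death, months) exercising each censoring rule
            ("dead", False, 40.0),   # other-cause death -> censored
            ("alive", False, 120.0), # alive at last contact -> censored
            ("dead", True, 18.0),    # CRC (primary or secondary) -> event
        ]
        for i, (vital, crc, months) in enumerate(specs):
            for t in ("tumor", "normal"):
                from apomir.io import Vital

                rows.append(
                    make_meta(
                        f"s{i}", t, vital=Vital(vital), crc_death=crc,
                        survival_months=months,
                        site=Site.COLON if i < 2 else Site.RECTAL,
                    )
                )
        return rows

    def _exposure(self):
        return ExpressionMatrix(
            pd.DataFrame({"s0": [1.0], "s1": [2.0], "s2": [3.0]}, index=["mir-1"]),
            MatrixKind.DIFFERENTIAL,
        )

    def test_censoring_rules(self):
        recs = build_survival_records(self._meta(), self._exposure(), "mir-1")
        by_id = {r.subject_id: r for r in recs}
        assert (by_id["s0"].time, by_id["s0"].event) == (40.0, False)
        assert (by_id["s1"].time, by_id["s1"].event) == (120.0, False)
        assert (by_id["s2"].time, by_id["s2"].event) == (18.0, True)

    def test_cohort_filter_and_pooling(self):
        meta = self._meta()
        expo = self._exposure()
        all_r = build_survival_records(meta, expo, "mir-1", "all")
        colon = build_survival_records(meta, expo, "mir-1", "colon")
        rectal = build_survival_records(meta, expo, "mir-1", "rectal")
        assert {r.subject_id for r in colon} | {r.subject_id for r in rectal} == {
            r.subject_id for r in all_r
        }
        assert {r.subject_id for r in colon} == {"s0", "s1"}

    def test_one_record_per_subject(self):
        recs = build_survival_records(self._meta(), self._exposure(), "mir-1")
        assert len(recs) == 3


class TestCoxFit:
    @pytest.mark.parametrize("round_times", [False, True], ids=["no-ties", "ties"])
    def test_matches_lifelines(self, round_times):
        recs = _records(5, beta_expo=0.4, round_times=round_times)
        fit = cox_fit(recs)
        df = pd.DataFrame(
            {
                "t": [r.time for r in recs],
                "e": [r.event for r in recs],
                "expo": [r.exposure for r in recs],
                "age": [r.age for r in recs],
                "sexf": [1.0 if r.sex is Sex.FEMALE else 0.0 for r in recs],
                "stage": [float(r.stage) for r in recs],
            }
        )
        cph = CoxPHFitter()
        cph.fit(df, duration_col="t", event_col="e")
        assert fit.beta_exposure == pytest.approx(cph.params_["expo"], abs=1e-5)
        assert fit.se == pytest.approx(cph.standard_errors_["expo"], abs=1e-5)
        assert fit.loglik_full == pytest.approx(cph.log_likelihood_, abs=1e-6)

    def test_null_lrt_behaves_like_chi2(self):
        lrts = []
        for seed in range(60):
            recs = _records(100 + seed, n=120, beta_expo=0.0)
            lrts.append(cox_fit(recs).lrt)
        assert np.mean(lrts) == pytest.approx(1.0, abs=0.45)  # E[chi2_1] = 1

    def test_tied_subjects_handled(self):
        # identical covariates and times, one event: must not fail
        recs = [
            SurvivalInput("a", 10.0, True, 60.0, Sex.MALE, 2, Site.COLON, 1.0),
            SurvivalInput("b", 10.0, False, 60.0, Sex.MALE, 2, Site.COLON, 2.0),
            SurvivalInput("c", 12.0, True, 61.0, Sex.FEMALE, 3, Site.COLON, 0.5),
            SurvivalInput("d", 15.0, True, 62.0, Sex.MALE, 1, Site.COLON, 3.0),
        ]
        fit = cox_fit(recs)
        assert np.isfinite(fit.beta_exposure)

    def test_requires_events_and_variance(self):
        recs = _records(6, n=30)
        censored = [
            SurvivalInput(r.subject_id, r.time, False, r.age, r.sex, r.stage, r.site, r.exposure)
            for r in recs
        ]
        with pytest.raises(ValidationError, match="events"):
            cox_fit(censored)
        flat = [
            SurvivalInput(r.subject_id, r.time, r.event, r.age, r.sex, r.stage, r.site, 1.0)
            for r in recs
        ]
        with pytest.raises(ValidationError, match="variance"):
            cox_fit(flat)


class TestIqrScaledHR:
    @pytest.mark.parametrize(
        "beta,q1,q3,expected",
        [(0.0, -1.0, 1.0, 1.0), (np.log(2), 0.0, 1.0, 2.0), (np.log(2), 0.0, 2.0, 4.0)],
    )
    def test_formula(self, beta, q1, q3, expected):
        hr, lo, hi = iqr_scaled_hr(beta, 0.1, q1, q3)
        assert hr == pytest.approx(expected)
        assert lo <= hr <= hi

    def test_q3_below_q1_rejected(self):
        with pytest.raises(ValidationError):
            iqr_scaled_hr(0.5, 0.1, 2.0, 1.0)

    def test_invariant_to_affine_exposure_rescaling(self):
        recs = _records(7, beta_expo=0.5)
        fit = cox_fit(recs)
        e = np.array([r.exposure for r in recs])
        q1, q3 = np.quantile(e, [0.25, 0.75])
        hr, _, _ = iqr_scaled_hr(fit.beta_exposure, fit.se, q1, q3)
        k, c = 7.3, -2.1
        scaled = [
            SurvivalInput(r.subject_id, r.time, r.event, r.age, r.sex, r.stage, r.site,
                          k * r.exposure + c)
            for r in recs
        ]
        fit2 = cox_fit(scaled)
        q1b, q3b = np.quantile(k * e + c, [0.25, 0.75])
        hr2, _, _ = iqr_scaled_hr(fit2.beta_exposure, fit2.se, q1b, q3b)
        assert hr2 == pytest.approx(hr, rel=1e-6)


class TestPermutationLRT:
    def test_constant_exposure_gives_p_one(self):
        recs = _records(8, n=40)
        flat = [
            SurvivalInput(r.subject_id, r.time, r.event, r.age, r.sex, r.stage, r.site, 5.0)
            for r in recs
        ]
        assert permutation_lrt_p(flat, 99, 0) == 1.0

    def test_strong_effect_saturates_at_floor(self):
        recs = _records(9, n=200, beta_expo=1.5)
        assert permutation_lrt_p(recs, 999, 1) == pytest.approx(1 / 1000)

    def test_deterministic_and_never_zero(self):
        recs = _records(10, n=60, beta_expo=0.3)
        p1 = permutation_lrt_p(recs, 199, 7)
        p2 = permutation_lrt_p(recs, 199, 7)
        assert p1 == p2 and p1 >= 1 / 200

    def test_invalid_n_perm(self):
        with pytest.raises(ValueError):
            permutation_lrt_p(_records(11, n=30), 0, 0)


class TestQValues:
    def test_all_ones(self):
        np.testing.assert_allclose(q_values(np.ones(15)), 1.0)

    def test_matches_brute_force_storey_oracle(self):
        rng = np.random.default_rng(21)
        p = np.sort(rng.uniform(0.01, 1.0, 20))
        pi0 = estimate_pi0(p)
        m = len(p)
        # brute force: q_i = min over j with p_j >= p_i of pi0*m*p_j/rank_j
        oracle = np.empty(m)
        order = np.argsort(p)
        for i in range(m):
            candidates = [
                pi0 * m * p[order[j]] / (j + 1) for j in range(m) if p[order[j]] >= p[i]
            ]
            oracle[i] = min(1.0, min(candidates))
        np.testing.assert_allclose(q_values(p), oracle, rtol=1e-12)

    def test_pi0_zero_returns_undefined_with_warning(self):
        with pytest.warns(UserWarning, match="true null"):
            q = q_values(np.full(25, 1e-4))
        assert np.isnan(q).all()

    def test_rejects_zero_pvalues(self):
        with pytest.raises(ValidationError):
            q_values([0.0, 0.5])


class TestRunSurvival:
    def test_cohort_all_equals_pooled_sites(self, small_cohort):
        from apomir.simulate import simulate_mirna_with_associations, simulate_survival

        cfg, counts, meta, truth = small_cohort
        _, _ = simulate_mirna_with_associations(cfg, truth, meta)
        D = ExpressionMatrix(truth.mirna_differential, MatrixKind.DIFFERENTIAL)
        meta2 = simulate_survival(meta, D, cfg, truth=truth)
        all_r = build_survival_records(meta2, D, "mir-000", "all")
        pooled = build_survival_records(
            meta2, D, "mir-000", "colon"
        ) + build_survival_records(meta2, D, "mir-000", "rectal")
        key = lambda r: r.subject_id
        assert sorted(all_r, key=key) == sorted(pooled, key=key)

    def test_results_table_fields_coherent(self, small_cohort):
        from apomir.simulate import simulate_mirna_with_associations, simulate_survival

        cfg, counts, meta, truth = small_cohort
        simulate_mirna_with_associations(cfg, truth, meta)
        D = ExpressionMatrix(truth.mirna_differential, MatrixKind.DIFFERENTIAL)
        meta2 = simulate_survival(meta, D, cfg, truth=truth)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            res = run_survival(meta2, D, mirnas=D.feature_ids[:3], n_perm=99, rng_seed=4)
        assert len(res) == 3
        for r in res:
            assert r.ci_low <= r.hr_iqr <= r.ci_high
            assert r.q1 <= r.q3
            assert 1 / 100 <= r.perm_p <= 1.0
            assert r.fdr_p >= r.perm_p - 1e-12
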