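"""R-score construction, Cox fitting, model building, cutoff selection."""

import numpy as np
import pandas as pd
import pytest

import oracles
from radsurv.scoring import (
    RScoreDefinition,
    build_models,
    compute_rscore,
    fit_cox,
    published_rscore_definition,
    select_cutoff,
)
from radsurv.synthdata import generate_feature_table


class TestRScore:
    def test_published_definition_loads(self):
        d = published_rscore_definition()
        assert len(d.terms) == 15 and d.provenance == "published"
        coefs = dict(d.terms)
        assert coefs["AP|N|glcm|joint_entropy"] == 0.656
        assert coefs["VOI|N|morph|volume"] == -0.047

    def test_zero_vector_scores_zero(self):
        d = published_rscore_definition()
        fv = {fid: 0.0 for fid in d.feature_ids}
        assert compute_rscore(fv, d) == 0.0

    def test_unit_joint_entropy_scores_its_coefficient(self):
        d = published_rscore_definition()
        fv = {fid: 0.0 for fid in d.feature_ids}
        fv["AP|N|glcm|joint_entropy"] = 1.0
        assert compute_rscore(fv, d) == 0.656

    def test_all_ones_equals_coefficient_sum(self):
        d = published_rscore_definition()
        fv = {fid: 1.0 for fid in d.feature_ids}
        # independent manual summation of the published coefficients
        manual = sum(
            [-0.047, -0.075, -0.027, -0.196, 0.049, -0.069, 0.085, -0.106,
             0.656, 0.104, 0.251, 0.028, -0.013, 0.116, -0.112]
        )
        assert compute_rscore(fv, d) == pytest.approx(manual, abs=1e-12)

    def test_linearity(self, rng):
        d = published_rscore_definition()
        x = {fid: rng.normal() for fid in d.feature_ids}
        y = {fid: rng.normal() for fid in d.feature_ids}
        combo = {fid: 2.0 * x[fid] + 3.0 * y[fid] for fid in d.feature_ids}
        assert compute_rscore(combo, d) == pytest.approx(
            2.0 * compute_rscore(x, d) + 3.0 * compute_rscore(y, d), rel=1e-9
        )

    def test_missing_feature_named_in_error(self):
        d = published_rscore_definition()
        fv = {fid: 0.0 for fid in d.feature_ids[:-1]}
        with pytest.raises(KeyError, match="high_dependence_high_gray_level_emphasis"):
            compute_rscore(fv, d)

    def test_duplicate_terms_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            RScoreDefinition([("a", 1.0), ("a", 2.0)])

    def test_json_round_trip(self, tmp_path):
        d = published_rscore_definition()
        d.to_json(tmp_path / "def.json")
        d2 = RScoreDefinition.from_json(tmp_path / "def.json")
        assert d2.terms == d.terms


def _cox_data(n, beta, seed=0, censor_scale=2.0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    t = rng.exponential(scale=np.exp(-beta * x))
    c = rng.exponential(scale=censor_scale, size=n)
    df = pd.DataFrame({"x": x}, index=[f"S{i}" for i in range(n)])
    out = pd.DataFrame(
        {"subject_id": df.index, "time_months": np.minimum(t, c), "event": (t <= c).astype(int)}
    )
    return df, out


class TestFitCox:
    def test_parameter_recovery_within_3se(self):
        cov, out = _cox_data(1000, 0.7, seed=1)
        fit = fit_cox(cov, out)
        assert abs(fit.params["x"] - 0.7) < 3 * fit.bse["x"]

    def test_null_covariate_ci_covers_zero(self):
        # coverage across repeated simulations; wide tolerance around 95%
        covered = 0
        n_sim = 60
        for s in range(n_sim):
            cov, out = _cox_data(120, 0.0, seed=100 + s)
            fit = fit_cox(cov, out)
            lo, hi = fit.conf_int.loc["x"]
            covered += lo <= 0 <= hi
        assert covered / n_sim >= 0.85

    def test_duplicated_dataset_same_estimate(self):
        cov, out = _cox_data(150, 0.5, seed=2)
        fit1 = fit_cox(cov, out)
        cov2 = pd.concat([cov, cov.set_index(cov.index + "_b")])
        out2 = pd.concat([out, out.assign(subject_id=out["subject_id"] + "_b")])
        fit2 = fit_cox(cov2, out2)
        assert fit2.params["x"] == pytest.approx(fit1.params["x"], abs=1e-6)

    def test_tiny_instance_matches_grid_search(self):
        # brute-force partial-likelihood grid search, n=8, p=1
        cov, out = _cox_data(8, 1.0, seed=3, censor_scale=10.0)
        fit = fit_cox(cov, out)
        from radsurv.selection import breslow_partial_loglik

        grid = np.linspace(-4, 4, 8001)
        x = cov["x"].to_numpy()
        t = out["time_months"].to_numpy()
        e = out["event"].to_numpy()
        plls = [breslow_partial_loglik(b * x, t, e) for b in grid]
        b_star = grid[int(np.argmax(plls))]
        assert fit.params["x"] == pytest.approx(b_star, abs=1e-3)

    def test_newton_oracle_agreement_multivariate(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(120, 2))
        t = rng.exponential(scale=np.exp(-(0.6 * X[:, 0] - 0.3 * X[:, 1])))
        c = rng.exponential(scale=2.0, size=120)
        cov = pd.DataFrame(X, columns=["a", "b"], index=[f"S{i}" for i in range(120)])
        out = pd.DataFrame({"subject_id": cov.index, "time_months": np.minimum(t, c),
                            "event": (t <= c).astype(int)})
        fit = fit_cox(cov, out)
        beta = oracles.newton_cox(X, out["time_months"].to_numpy(), out["event"].to_numpy())
        np.testing.assert_allclose(fit.params.to_numpy(), beta, atol=1e-5)

    def test_constant_covariate_rejected(self):
        cov, out = _cox_data(50, 0.5, seed=4)
        cov["flat"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            fit_cox(cov, out)

    def test_baseline_hazard_monotone(self):
        cov, out = _cox_data(200, 0.5, seed=5)
        fit = fit_cox(cov, out)
        assert np.all(np.diff(fit.baseline_cumhaz) >= 0)
        # predicted survival decreases with time and with risk
        s1 = fit.predict_survival(cov, 0.5)
        s2 = fit.predict_survival(cov, 2.0)
        assert (s2 <= s1 + 1e-12).all()


class TestBuildModels:
    def _cohort(self, n=400, beta_r=1.0, seed=0):
        from radsurv.synthdata import CohortSpec, generate_cohort

        spec = CohortSpec(n_subjects=n, true_beta={"amplitude": beta_r, "stage": 0.5}, seed=seed)
        cohort = generate_cohort(spec, with_images=False)
        rscore = pd.Series(
            cohort.latents["z_amplitude"].to_numpy(),
            index=cohort.clinical["subject_id"], name="rscore",
        )
        return cohort, rscore

    def test_cr_nests_c_model(self):
        cohort, rscore = self._cohort()
        models = build_models(cohort.clinical, rscore, cohort.survival)
        assert models["CR_model"].covariates == models["C_model"].covariates + ["rscore"]
        # nested partial likelihood: CR fit is at least as good
        assert models["CR_model"].log_likelihood >= models["C_model"].log_likelihood - 1e-9

    def test_null_rscore_hr_near_one(self):
        cohort, _ = self._cohort(n=600, beta_r=0.0, seed=3)
        rng = np.random.default_rng(1)
        noise = pd.Series(rng.normal(size=600), index=cohort.clinical["subject_id"])
        models = build_models(cohort.clinical, noise, cohort.survival)
        hr = np.exp(models["CR_model"].params["rscore"])
        lo, hi = np.exp(models["CR_model"].conf_int.loc["rscore"])
        assert lo < 1.0 < hi and 0.7 < hr < 1.4

    def test_single_stage_cohort_drops_indicators(self):
        cohort, rscore = self._cohort(n=200, seed=5)
        clin = cohort.clinical.copy()
        clin["stage"] = "I"
        with pytest.warns(UserWarning, match="absent"):
            models = build_models(clin, rscore, cohort.survival)
        assert models["C_model"].covariates == ["age"]


class TestSelectCutoff:
    def test_perfect_separation(self):
        scores = pd.Series([0.0] * 10 + [10.0] * 10, index=[f"S{i}" for i in range(20)])
        out = pd.DataFrame({
            "subject_id": scores.index,
            "time_months": [100.0] * 10 + [12.0] * 10,
            "event": [0] * 10 + [1] * 10,
        })
        cut, sens, spec = select_cutoff(scores, out, horizon=36)
        assert sens == 1.0 and spec == 1.0 and 0 < cut < 10

    def test_matches_exhaustive_scan(self, rng):
        n = 20
        scores = pd.Series(rng.normal(size=n), index=[f"S{i}" for i in range(n)])
        risk = 1 / (1 + np.exp(-2 * scores.to_numpy()))
        time = np.where(rng.random(n) < risk, 20.0, 80.0)
        event = (time < 36).astype(int)
        out = pd.DataFrame({"subject_id": scores.index, "time_months": time, "event": event})
        case = (event == 1) & (time <= 36)
        ctrl = time > 36
        if case.sum() == 0 or ctrl.sum() == 0:
            pytest.skip("degenerate draw")
        best, best_tot = None, -1
        s = scores.to_numpy()
        uniq = np.sort(np.unique(s))
        for c in (uniq[:-1] + uniq[1:]) / 2:
            sens = ((s > c) & case).sum() / case.sum()
            spec = ((s <= c) & ctrl).sum() / ctrl.sum()
            if sens > 0.6 and spec > 0.6 and sens + spec > best_tot + 1e-12:
                best, best_tot = c, sens + spec
        if best is None:
            with pytest.raises(ValueError, match="unconstrained"):
                select_cutoff(scores, out, horizon=36)
        else:
            cut, sens, spec = select_cutoff(scores, out, horizon=36)
            assert cut == pytest.approx(best)
            assert sens + spec == pytest.approx(best_tot)

    def test_censored_before_horizon_excluded(self):
        # 'a' is censored before the horizon: its extreme score must not
        # count toward specificity
        scores = pd.Series([5.0, 2.0, 4.0, 3.0], index=list("abcd"))
        out = pd.DataFrame({
            "subject_id": list("abcd"),
            "time_months": [10.0, 50.0, 20.0, 60.0],
            "event": [0, 0, 1, 0],
        })
        cut, sens, spec = select_cutoff(scores, out, horizon=36)
        assert sens == 1.0 and spec == 1.0  # based on b, c, d only

    def test_unreachable_floors_reported(self):
        scores = pd.Series([1.0, 1.0, 1.0, 1.0], index=list("abcd"))
        out = pd.DataFrame({
            "subject_id": list("abcd"),
            "time_months": [10.0, 50.0, 20.0, 60.0],
            "event": [1, 0, 1, 0],
        })
        with pytest.raises(ValueError, match="best unconstrained"):
            select_cutoff(scores, out, horizon=36)
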