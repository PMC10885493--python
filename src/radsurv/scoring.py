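"""Risk scores and Cox proportional-hazards model fitting.

The radiomics score is a fixed linear combination of standardized features
(:class:`RScoreDefinition`); the clinical model (C-model) regresses outcome
on age and AJCC stage, and the clinical-radiomics model (CR-model) adds the
radiomics score as one more covariate.  Fits use the partial likelihood
with the Breslow tie approximation and carry a Breslow baseline cumulative
hazard so absolute survival probabilities can be predicted and new
outcomes simulated from the fitted model.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from statsmodels.duration.hazard_regression import PHReg

__all__ = [
    "RScoreDefinition",
    "published_rscore_definition",
    "compute_rscore",
    "CoxFit",
    "fit_cox",
    "build_models",
    "select_cutoff",
]

STAGES = ("I", "II", "III", "IV")


@dataclass
class RScoreDefinition:
    """A linear risk score: ordered (feature id, coefficient) terms."""

    terms: list[tuple[str, float]]
    provenance: str = "fitted"  # or "published"

    def __post_init__(self):
        ids = [t[0] for t in self.terms]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate feature ids in score definition")
        if not all(np.isfinite(c) for _, c in self.terms):
            raise ValueError("non-finite coefficient")

    @property
    def feature_ids(self) -> list[str]:
        return [t[0] for t in self.terms]

    @classmethod
    def from_lasso(cls, nonzero: pd.Series) -> "RScoreDefinition":
        return cls([(str(k), float(v)) for k, v in nonzero.items()], provenance="fitted")

    def to_json(self, path) -> None:
        payload = {
            "provenance": self.provenance,
            "terms": [{"feature_id": f, "coefficient": c} for f, c in self.terms],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path_or_payload) -> "RScoreDefinition":
        if isinstance(path_or_payload, dict):
            payload = path_or_payload
        else:
            with open(path_or_payload) as fh:
                payload = json.load(fh)
        return cls(
            [(t["feature_id"], float(t["coefficient"])) for t in payload["terms"]],
            provenance=payload.get("provenance", "fitted"),
        )

    def score_table(self, table: pd.DataFrame) -> pd.Series:
        """Score every row of a standardized feature table."""
        missing = [f for f, _ in self.terms if f not in table.columns]
        if missing:
            raise KeyError(f"feature table is missing score terms: {missing}")
        out = sum(c * table[f] for f, c in self.terms)
        return pd.Series(out, index=table.index, name="rscore")


def published_rscore_definition() -> RScoreDefinition:
    """The published 15-term radiomics score shipped as a package asset."""
    payload = json.loads(
        resources.files("radsurv").joinpath("data/published_rscore.json").read_text()
    )
    return RScoreDefinition.from_json(payload)


def compute_rscore(feature_vector, definition: RScoreDefinition) -> float:
    """Sum of each (standardized) feature value times its coefficient."""
    fv = dict(feature_vector)
    total = 0.0
    for fid, coef in definition.terms:
        if fid not in fv:
            raise KeyError(f"feature vector is missing score term {fid!r}")
        total += coef * float(fv[fid])
    return float(total)


# ---------------------------------------------------------------------------
# Cox proportional-hazards fitting
# ---------------------------------------------------------------------------

@dataclass
class CoxFit:
    """A fitted proportional-hazards model.

    Carries coefficient estimates with standard errors and Wald CIs, the
    Breslow baseline cumulative hazard, and prediction/simulation helpers.
    """

    covariates: list[str]
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame  # columns lo, hi on the log-hazard scale
    baseline_times: np.ndarray
    baseline_cumhaz: np.ndarray
    n: int
    n_events: int
    log_likelihood: float

    @property
    def hazard_ratios(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "HR": np.exp(self.params),
                "HR_lo": np.exp(self.conf_int["lo"]),
                "HR_hi": np.exp(self.conf_int["hi"]),
                "p": self.pvalues,
            }
        )

    def summary(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "coef": self.params,
                "se": self.bse,
                "HR": np.exp(self.params),
                "HR 95% lo": np.exp(self.conf_int["lo"]),
                "HR 95% hi": np.exp(self.conf_int["hi"]),
                "p": self.pvalues,
            }
        )
        out.index.name = "covariate"
        return out

    def _design(self, covariate_table: pd.DataFrame) -> np.ndarray:
        missing = set(self.covariates) - set(covariate_table.columns)
        if missing:
            raise ValueError(f"missing covariates: {sorted(missing)}")
        return covariate_table[self.covariates].to_numpy(float)

    def predict_lp(self, covariate_table: pd.DataFrame) -> pd.Series:
        lp = self._design(covariate_table) @ self.params.to_numpy()
        return pd.Series(lp, index=covariate_table.index, name="lp")

    def cumhaz_at(self, t: float) -> float:
        """Baseline cumulative hazard H0(t) (right-continuous step)."""
        i = np.searchsorted(self.baseline_times, t, side="right") - 1
        return float(self.baseline_cumhaz[i]) if i >= 0 else 0.0

    def predict_survival(self, covariate_table: pd.DataFrame, t: float) -> pd.Series:
        lp = self.predict_lp(covariate_table)
        s = np.exp(-self.cumhaz_at(t) * np.exp(lp.to_numpy()))
        return pd.Series(s, index=covariate_table.index, name=f"S({t})")

    def simulate(
        self,
        covariate_table: pd.DataFrame,
        rng,
        censor_time: float | None = None,
    ) -> pd.DataFrame:
        """Draw censored outcomes from this fitted model.

        Times are drawn by inverting the Breslow baseline step function;
        draws falling beyond the last baseline step are administratively
        censored there (or at ``censor_time`` if smaller).
        """
        lp = self.predict_lp(covariate_table).to_numpy()
        n = len(lp)
        target = rng.exponential(size=n) / np.exp(lp)  # required baseline cum. hazard
        idx = np.searchsorted(self.baseline_cumhaz, target, side="left")
        t_max = self.baseline_times[-1]
        times = np.where(idx < len(self.baseline_times), self.baseline_times[np.minimum(idx, len(self.baseline_times) - 1)], t_max)
        event = (idx < len(self.baseline_times)).astype(int)
        horizon = t_max if censor_time is None else min(censor_time, t_max)
        event = np.where(times > horizon, 0, event)
        times = np.minimum(times, horizon)
        return pd.DataFrame(
            {"subject_id": covariate_table.index, "time_months": times, "event": event}
        )


def _align_outcomes(covariates: pd.DataFrame, outcomes: pd.DataFrame) -> pd.DataFrame:
    out = outcomes.set_index("subject_id") if "subject_id" in outcomes.columns else outcomes
    try:
        return out.loc[covariates.index]
    except KeyError as err:
        raise ValueError("outcome table does not cover all subjects") from err


def fit_cox(covariates: pd.DataFrame, outcomes: pd.DataFrame) -> CoxFit:
    """Partial-likelihood MLE with Breslow ties and Breslow baseline hazard.

    Raises on degenerate designs (constant columns), too few events, or
    non-convergence/separation (non-finite estimates or standard errors).
    """
    out = _align_outcomes(covariates, outcomes)
    time = out["time_months"].to_numpy(float)
    event = out["event"].to_numpy(int)
    if event.sum() < 2:
        raise ValueError("need at least 2 events")
    sds = covariates.std(ddof=0)
    const = list(sds.index[sds == 0])
    if const:
        raise ValueError(f"constant covariates: {const}")
    X = covariates.to_numpy(float)
    model = PHReg(time, X, status=event, ties="breslow")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(disp=False)
    params = np.asarray(res.params)
    bse = np.asarray(res.bse)
    if not (np.all(np.isfinite(params)) and np.all(np.isfinite(bse))) or np.max(np.abs(params)) > 50:
        raise ValueError(
            "Cox fit did not converge (possible separation); "
            f"params={params}, se={bse}"
        )
    cols = list(covariates.columns)
    ci = res.conf_int()
    bt, bch, _ = res.baseline_cumulative_hazard[0]
    return CoxFit(
        covariates=cols,
        params=pd.Series(params, index=cols),
        bse=pd.Series(bse, index=cols),
        pvalues=pd.Series(np.asarray(res.pvalues), index=cols),
        conf_int=pd.DataFrame(ci, index=cols, columns=["lo", "hi"]),
        baseline_times=np.asarray(bt, float),
        baseline_cumhaz=np.asarray(bch, float),
        n=len(time),
        n_events=int(event.sum()),
        log_likelihood=float(res.llf),
    )


def clinical_design(clinical: pd.DataFrame) -> pd.DataFrame:
    """Age plus stage indicator columns (reference stage I).

    Indicator columns absent from the cohort (e.g. a stage I-only cohort)
    are dropped with a warning so the design stays full-rank.
    """
    df = clinical.set_index("subject_id") if "subject_id" in clinical.columns else clinical
    bad = set(df["stage"]) - set(STAGES)
    if bad:
        raise ValueError(f"unknown stages: {sorted(bad)}")
    design = pd.DataFrame({"age": df["age"].astype(float)}, index=df.index)
    for s in STAGES[1:]:
        col = (df["stage"] == s).astype(float)
        if col.sum() == 0:
            warnings.warn(f"stage {s} absent from cohort; indicator dropped")
        else:
            design[f"stage_{s}"] = col
    if design.shape[1] == 1 and df["stage"].nunique() == 1:
        warnings.warn("single-stage cohort: model reduces to age only")
    return design


def build_models(
    clinical: pd.DataFrame,
    rscores: pd.Series,
    outcomes: pd.DataFrame,
) -> dict[str, CoxFit]:
    """Fit the C-model (age + stage) and CR-model (age + stage + R-score)."""
    design = clinical_design(clinical)
    if not design.index.equals(rscores.index):
        rscores = rscores.reindex(design.index)
        if rscores.isna().any():
            raise ValueError("rscores missing for some subjects")
    c_model = fit_cox(design, outcomes)
    cr_design = design.assign(rscore=rscores.astype(float))
    cr_model = fit_cox(cr_design, outcomes)
    return {"C_model": c_model, "CR_model": cr_model}


def select_cutoff(
    scores: pd.Series,
    outcomes: pd.DataFrame,
    horizon: float = 36.0,
    min_sens: float = 0.6,
    min_spec: float = 0.6,
) -> tuple[float, float, float]:
    """Optimal risk cutoff at a fixed horizon.

    Subjects with an event at or before the horizon are cases; subjects
    followed beyond the horizon are controls; subjects censored before the
    horizon have unknown status and are excluded.  Candidate cutoffs are
    midpoints of sorted unique scores; among those with sensitivity and
    specificity both above the floors, the cutoff maximizing their sum is
    returned (ties resolved toward the lower cutoff).
    """
    out = _align_outcomes(scores.to_frame("score"), outcomes)
    time = out["time_months"].to_numpy(float)
    event = out["event"].to_numpy(int)
    s = scores.to_numpy(float)
    case = (event == 1) & (time <= horizon)
    control = time > horizon
    known = case | control
    if case[known].sum() == 0 or control[known].sum() == 0:
        raise ValueError("need both events and non-events observable at the horizon")
    s, case, control = s[known], case[known], control[known]
    uniq = np.unique(s)
    cands = (uniq[:-1] + uniq[1:]) / 2.0 if len(uniq) > 1 else uniq
    best = None
    best_any = None
    for c in cands:
        pos = s > c
        sens = (pos & case).sum() / case.sum()
        spec = (~pos & control).sum() / control.sum()
        tot = sens + spec
        if best_any is None or tot > best_any[1] + 1e-12:
            best_any = (c, tot, sens, spec)
        if sens > min_sens and spec > min_spec:
            if best is None or tot > best[1] + 1e-12:
                best = (c, tot, sens, spec)
    if best is None:
        c, tot, sens, spec = best_any
        raise ValueError(
            "no cutoff achieves the sensitivity/specificity floors; best "
            f"unconstrained cutoff {c:.4g} (sens {sens:.3f}, spec {spec:.3f})"
        )
    return best[0], best[2], best[3]
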