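"""Survival-model performance metrics and model comparison.

Discrimination is measured by Harrell's concordance index and by the
cumulative-case / dynamic-control time-dependent ROC AUC with inverse
probability of censoring weights (IPCW).  Incremental value of a new model
over an old one at a fixed horizon is quantified by the category-free net
reclassification improvement (NRI) and the integrated discrimination
improvement (IDI), both estimated under right censoring with IPCW from the
reverse Kaplan-Meier censoring distribution.  Calibration compares
model-predicted survival at the horizon to the observed Kaplan-Meier
estimate in predicted-risk quantile groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from sksurv.metrics import concordance_index_censored, cumulative_dynamic_auc
from sksurv.util import Surv

from .scoring import CoxFit

__all__ = [
    "EvalConfig",
    "EvalReport",
    "harrell_cindex",
    "compare_cindex",
    "time_dependent_auc",
    "survival_nri_idi",
    "calibration_table",
    "evaluate_models",
]


@dataclass
class EvalConfig:
    horizon_months: float = 36.0
    n_bootstrap: int = 1000
    calibration_groups: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.horizon_months <= 0:
            raise ValueError("horizon must be positive")
        if self.calibration_groups < 2:
            raise ValueError("need at least 2 calibration groups")


def _extract(outcomes: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    time = outcomes["time_months"].to_numpy(float)
    event = outcomes["event"].to_numpy(int)
    return time, event


def _cindex_point(lp, time, event) -> float:
    try:
        c, concordant, discordant, tied_risk, _ = concordance_index_censored(
            event.astype(bool), time, np.asarray(lp, float)
        )
    except ValueError as err:
        raise ValueError(f"no comparable pairs ({err})") from err
    if concordant + discordant + tied_risk == 0:
        raise ValueError("no comparable pairs")
    return float(c)


def harrell_cindex(
    lp, outcomes: pd.DataFrame, n_bootstrap: int = 1000, seed: int = 0
) -> tuple[float, tuple[float, float]]:
    """Harrell's C over usable pairs, with a subject-bootstrap percentile CI.

    Pairs are usable when the shorter time carries an event (or exactly one
    of two tied times does); concordant pairs score 1 and risk ties 0.5.
    """
    time, event = _extract(outcomes)
    lp = np.asarray(lp, float)
    c = _cindex_point(lp, time, event)
    rng = np.random.default_rng(seed)
    boots = []
    n = len(lp)
    for _ in range(n_bootstrap):
        idx = rng.integers(0, n, n)
        try:
            boots.append(_cindex_point(lp[idx], time[idx], event[idx]))
        except ValueError:
            continue
    if boots:
        lo, hi = np.percentile(boots, [2.5, 97.5])
    else:
        lo = hi = float("nan")
    return c, (float(lo), float(hi))


def compare_cindex(
    lp_a, lp_b, outcomes: pd.DataFrame, n_bootstrap: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """Paired-bootstrap comparison of two models' C-indices.

    Returns ``delta = C(b) - C(a)`` and a two-sided p-value from the normal
    approximation to the bootstrap distribution of delta.
    """
    from scipy import stats

    time, event = _extract(outcomes)
    lp_a = np.asarray(lp_a, float)
    lp_b = np.asarray(lp_b, float)
    if lp_a.shape != lp_b.shape:
        raise ValueError("both models must score the same subjects")
    delta = _cindex_point(lp_b, time, event) - _cindex_point(lp_a, time, event)
    rng = np.random.default_rng(seed)
    n = len(lp_a)
    boots = []
    for _ in range(n_bootstrap):
        idx = rng.integers(0, n, n)
        try:
            boots.append(
                _cindex_point(lp_b[idx], time[idx], event[idx])
                - _cindex_point(lp_a[idx], time[idx], event[idx])
            )
        except ValueError:
            continue
    sd = float(np.std(boots, ddof=1)) if len(boots) > 1 else float("nan")
    if not np.isfinite(sd) or sd == 0:
        p = 1.0 if delta == 0 else 0.0
    else:
        p = float(2 * stats.norm.sf(abs(delta) / sd))
    return float(delta), p


def time_dependent_auc(lp, outcomes: pd.DataFrame, t: float) -> float:
    """Cumulative-case / dynamic-control AUC(t) with IPCW.

    Cases are subjects with an event by ``t``, controls those still at risk
    past ``t``; weights come from the reverse Kaplan-Meier estimate of the
    censoring distribution.
    """
    time, event = _extract(outcomes)
    if not ((event == 1) & (time <= t)).any():
        raise ValueError(f"no cases by t={t}")
    if not (time > t).any():
        raise ValueError(f"no controls at risk past t={t}")
    y = Surv.from_arrays(event=event.astype(bool), time=time)
    auc, _ = cumulative_dynamic_auc(y, y, np.asarray(lp, float), [t])
    return float(auc[0])


# ---------------------------------------------------------------------------
# NRI / IDI under censoring
# ---------------------------------------------------------------------------

def _ipcw_weights(time: np.ndarray, event: np.ndarray, t: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Case/control indicator and IPCW weight per subject at horizon t.

    Reverse-KM convention: the censoring distribution G is the KM estimate
    treating censorings as events.  Cases (event by t) weigh 1/G(T-);
    controls (followed past t) weigh 1/G(t); censored-before-t subjects
    have unknown status and weight 0.
    """
    if t >= time.max():
        raise ValueError("horizon lies beyond the last observed time")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=1 - event)
    case = (event == 1) & (time <= t)
    control = time > t
    g_tminus = kmf.survival_function_at_times(np.maximum(time - 1e-9, 0.0)).to_numpy()
    g_t = float(kmf.survival_function_at_times(t).iloc[0])
    w = np.zeros(len(time))
    w[case] = 1.0 / np.clip(g_tminus[case], 1e-12, None)
    w[control] = 1.0 / max(g_t, 1e-12)
    return case, control, w


def _nri_idi_point(p_old, p_new, time, event, t) -> tuple[float, float]:
    case, control, w = _ipcw_weights(time, event, t)
    up = p_new > p_old
    down = p_new < p_old
    w_case, w_ctrl = w[case].sum(), w[control].sum()
    if w_case == 0 or w_ctrl == 0:
        raise ValueError("no weighted cases or controls at the horizon")
    nri = (
        (w[case & up].sum() - w[case & down].sum()) / w_case
        + (w[control & down].sum() - w[control & up].sum()) / w_ctrl
    )
    diff = p_new - p_old
    idi = (w[case] * diff[case]).sum() / w_case - (w[control] * diff[control]).sum() / w_ctrl
    return float(nri), float(idi)


@dataclass
class NriIdiResult:
    nri: float
    idi: float
    nri_ci: tuple[float, float]
    idi_ci: tuple[float, float]
    nri_p: float
    idi_p: float


def survival_nri_idi(
    prob_old,
    prob_new,
    outcomes: pd.DataFrame,
    t: float = 36.0,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> NriIdiResult:
    """Category-free NRI and IDI at horizon ``t`` under censoring.

    ``prob_old``/``prob_new`` are each model's predicted event
    probabilities by ``t`` (1 - S(t|x), typically from the model's own
    Breslow baseline).  CIs are percentile bootstrap over subjects; p-values
    are two-sided bootstrap tail probabilities of the null value 0.
    """
    time, event = _extract(outcomes)
    p_old = np.asarray(prob_old, float)
    p_new = np.asarray(prob_new, float)
    nri, idi = _nri_idi_point(p_old, p_new, time, event, t)
    rng = np.random.default_rng(seed)
    n = len(time)
    b_nri, b_idi = [], []
    for _ in range(n_bootstrap):
        idx = rng.integers(0, n, n)
        try:
            a, b = _nri_idi_point(p_old[idx], p_new[idx], time[idx], event[idx], t)
        except ValueError:
            continue
        b_nri.append(a)
        b_idi.append(b)

    def _ci_p(boots, point):
        if len(boots) < 10:
            return (float("nan"), float("nan")), float("nan")
        lo, hi = np.percentile(boots, [2.5, 97.5])
        arr = np.asarray(boots)
        frac = min((arr <= 0).mean(), (arr >= 0).mean())
        p = min(1.0, 2 * max(frac, 1.0 / len(arr)))
        return (float(lo), float(hi)), float(p)

    nri_ci, nri_p = _ci_p(b_nri, nri)
    idi_ci, idi_p = _ci_p(b_idi, idi)
    return NriIdiResult(nri, idi, nri_ci, idi_ci, nri_p, idi_p)


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def calibration_table(
    model: CoxFit,
    covariates: pd.DataFrame,
    outcomes: pd.DataFrame,
    t: float = 36.0,
    groups: int = 4,
) -> pd.DataFrame:
    """Predicted vs observed survival at ``t`` in predicted-risk quantiles.

    Subjects are binned by predicted S(t) quantiles; per bin the mean
    prediction is compared with the Kaplan-Meier estimate at ``t`` and its
    Greenwood 95% CI.  Bins with no subjects at risk before ``t`` are merged
    with their neighbor (logged as a warning).
    """
    pred = model.predict_survival(covariates, t)
    out = outcomes.set_index("subject_id") if "subject_id" in outcomes.columns else outcomes
    out = out.loc[covariates.index]
    try:
        bins = pd.qcut(pred, groups, labels=False, duplicates="drop")
        if bins.isna().all():  # all predictions identical: one pooled bin
            raise ValueError
        bins = bins.fillna(0).astype(int)
    except ValueError:
        bins = pd.Series(np.zeros(len(pred), dtype=int), index=pred.index)
    rows = []
    labels = sorted(bins.unique())
    i = 0
    while i < len(labels):
        members = bins.isin(labels[i : i + 1])
        # merge forward until the KM estimate at t is defined for the group
        while True:
            sub = out[members.to_numpy()]
            tt, ee = sub["time_months"].to_numpy(), sub["event"].to_numpy()
            if (tt >= t).any() or (ee[tt <= t] == 1).any():
                break
            if i + 1 >= len(labels):
                break
            warnings.warn(f"calibration bin {labels[i]} empty at t={t}; merged with neighbor")
            i += 1
            members = members | bins.isin(labels[i : i + 1])
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time_months"], sub["event"])
        km = float(kmf.survival_function_at_times(t).iloc[0])
        ci = kmf.confidence_interval_survival_function_
        pos = ci.index.searchsorted(t, side="right") - 1
        lo, hi = (ci.iloc[pos, 0], ci.iloc[pos, 1]) if pos >= 0 else (np.nan, np.nan)
        rows.append(
            {
                "bin": len(rows),
                "n": int(members.sum()),
                "mean_predicted": float(pred[members].mean()),
                "km_observed": km,
                "km_lo": float(lo),
                "km_hi": float(hi),
            }
        )
        i += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Assembled report
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Comparison metrics for the R-score / C-model / CR-model family."""

    c_index: dict = field(default_factory=dict)  # name -> (c, lo, hi)
    delta_c: float | None = None
    delta_c_p: float | None = None
    auc_t: dict = field(default_factory=dict)
    nri_idi: NriIdiResult | None = None
    calibration: pd.DataFrame | None = None
    horizon_months: float = 36.0

    def to_dict(self) -> dict:
        d = {
            "horizon_months": self.horizon_months,
            "c_index": {k: list(v) for k, v in self.c_index.items()},
            "delta_c": self.delta_c,
            "delta_c_p": self.delta_c_p,
            "auc_t": self.auc_t,
        }
        if self.nri_idi is not None:
            d["nri"] = {
                "value": self.nri_idi.nri,
                "ci": list(self.nri_idi.nri_ci),
                "p": self.nri_idi.nri_p,
            }
            d["idi"] = {
                "value": self.nri_idi.idi,
                "ci": list(self.nri_idi.idi_ci),
                "p": self.nri_idi.idi_p,
            }
        if self.calibration is not None:
            d["calibration"] = self.calibration.to_dict(orient="records")
        return d

    def text_table(self) -> str:
        lines = [f"Model performance (horizon {self.horizon_months:g} months)"]
        lines.append(f"{'Model':<12}{'C-index':>9}{'95% CI':>20}")
        for name, (c, lo, hi) in self.c_index.items():
            lines.append(f"{name:<12}{c:>9.3f}{f'({lo:.3f}-{hi:.3f})':>20}")
        if self.delta_c is not None:
            lines.append(f"Delta C (CR - C): {self.delta_c:.3f}, p = {self.delta_c_p:.4f}")
        if self.nri_idi is not None:
            r = self.nri_idi
            lines.append(
                f"NRI {r.nri:.3f} ({r.nri_ci[0]:.3f}-{r.nri_ci[1]:.3f}), p = {r.nri_p:.4f}"
            )
            lines.append(
                f"IDI {r.idi:.3f} ({r.idi_ci[0]:.3f}-{r.idi_ci[1]:.3f}), p = {r.idi_p:.4f}"
            )
        return "\n".join(lines)


def evaluate_models(
    models: dict[str, CoxFit],
    designs: dict[str, pd.DataFrame],
    outcomes: pd.DataFrame,
    rscore: pd.Series | None = None,
    config: EvalConfig | None = None,
) -> EvalReport:
    """Assemble the full comparison report for fitted models on one cohort.

    ``models``/``designs`` map model names (``"C_model"``, ``"CR_model"``)
    to fits and their covariate tables; ``rscore`` optionally adds the raw
    score as a model-free ranking.  NRI/IDI and calibration compare
    ``CR_model`` against ``C_model`` on the probability scale at the
    configured horizon.
    """
    config = config or EvalConfig()
    report = EvalReport(horizon_months=config.horizon_months)
    lps = {}
    if rscore is not None:
        lps["R_score"] = np.asarray(rscore, float)
    for name, fit in models.items():
        lps[name] = fit.predict_lp(designs[name]).to_numpy()
    for name, lp in lps.items():
        report.c_index[name] = None
    for i, (name, lp) in enumerate(lps.items()):
        c, ci = harrell_cindex(lp, outcomes, config.n_bootstrap, seed=config.seed + i)
        report.c_index[name] = (c, ci[0], ci[1])
        try:
            report.auc_t[name] = time_dependent_auc(lp, outcomes, config.horizon_months)
        except ValueError:
            report.auc_t[name] = float("nan")
    if "C_model" in models and "CR_model" in models:
        report.delta_c, report.delta_c_p = compare_cindex(
            lps["C_model"], lps["CR_model"], outcomes, config.n_bootstrap, config.seed
        )
        t = config.horizon_months
        p_old = 1.0 - models["C_model"].predict_survival(designs["C_model"], t).to_numpy()
        p_new = 1.0 - models["CR_model"].predict_survival(designs["CR_model"], t).to_numpy()
        try:
            report.nri_idi = survival_nri_idi(
                p_old, p_new, outcomes, t, config.n_bootstrap, config.seed
            )
        except ValueError as err:
            warnings.warn(f"NRI/IDI unavailable: {err}")
        report.calibration = calibration_table(
            models["CR_model"], designs["CR_model"], outcomes, t, config.calibration_groups
        )
    return report
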