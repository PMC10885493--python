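"""Three-stage prognostic feature selection.

Stage 1 removes features whose inter-reader reliability (Lin's concordance
correlation coefficient between two readers' segmentations) falls below a
threshold; stage 2 greedily removes redundant features until no pairwise
Pearson correlation exceeds a threshold; stage 3 fits an L1-penalized Cox
proportional-hazards model with the penalty chosen by cross-validated
partial-likelihood deviance, yielding the sparse coefficient set that
defines the radiomics risk score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

__all__ = [
    "SelectionConfig",
    "SelectionReport",
    "LassoCoxResult",
    "lin_ccc",
    "reliability_filter",
    "redundancy_filter",
    "Standardizer",
    "standardize",
    "fit_lasso_cox",
    "select_features",
]


@dataclass
class SelectionConfig:
    ccc_threshold: float = 0.8
    pearson_threshold: float = 0.9
    n_folds: int = 10
    lambda_rule: str = "min"  # or "1se"
    seed: int = 0

    def __post_init__(self):
        for th in (self.ccc_threshold, self.pearson_threshold):
            if not 0 < th < 1:
                raise ValueError("thresholds must lie in (0, 1)")
        if self.n_folds < 2:
            raise ValueError("need at least 2 CV folds")
        if self.lambda_rule not in ("min", "1se"):
            raise ValueError("lambda_rule must be 'min' or '1se'")


@dataclass
class SelectionReport:
    """Bookkeeping of the selection cascade.

    The accounting identity ``n_retained == n_total - n_removed_ccc -
    n_removed_corr`` is enforced structurally: ``n_retained`` is computed,
    never stored.
    """

    n_total: int
    n_removed_ccc: int
    n_removed_corr: int
    retained_ids: list[str] = field(default_factory=list)
    ccc: dict[str, float] = field(default_factory=dict)
    chosen_lambda: float | None = None
    n_signature: int | None = None

    @property
    def n_retained(self) -> int:
        return self.n_total - self.n_removed_ccc - self.n_removed_corr

    def __post_init__(self):
        if self.retained_ids and len(self.retained_ids) != self.n_retained:
            raise ValueError("retained_ids inconsistent with stage counts")

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_removed_ccc": self.n_removed_ccc,
            "n_removed_corr": self.n_removed_corr,
            "n_retained": self.n_retained,
            "retained_ids": list(self.retained_ids),
            "ccc": self.ccc,
            "chosen_lambda": self.chosen_lambda,
            "n_signature": self.n_signature,
        }


def lin_ccc(x, y) -> float:
    """Lin's concordance correlation coefficient (population moments).

    ``2 cov(x, y) / (var(x) + var(y) + (mean(x) - mean(y))^2)``; penalizes
    both decorrelation and location/scale bias, so it is stricter than
    Pearson correlation as an agreement measure.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length 1D vectors, length >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()
    denom = vx + vy + (mx - my) ** 2
    if denom == 0:
        raise ValueError("CCC undefined: zero variance in both vectors with equal means")
    cov = ((x - mx) * (y - my)).mean()
    return float(2.0 * cov / denom)


def reliability_filter(
    table_reader1: pd.DataFrame,
    table_reader2: pd.DataFrame,
    threshold: float = 0.8,
) -> tuple[list[str], list[str], dict[str, float]]:
    """Remove features whose inter-reader CCC falls below ``threshold``.

    Removal is strict (CCC < threshold removed; exactly at the boundary
    retained).  Features whose CCC is undefined (constant and identical in
    both readers) carry no reliability information and are removed with a
    warning, recorded as NaN.
    """
    if list(table_reader1.columns) != list(table_reader2.columns):
        raise ValueError("reader tables must share identical feature columns")
    if not table_reader1.index.equals(table_reader2.index):
        raise ValueError("reader tables must share identical subjects")
    retained, removed, ccc_map = [], [], {}
    for col in table_reader1.columns:
        try:
            c = lin_ccc(table_reader1[col].to_numpy(), table_reader2[col].to_numpy())
        except ValueError:
            warnings.warn(f"feature {col}: CCC undefined (constant in both readers); removed")
            ccc_map[col] = float("nan")
            removed.append(col)
            continue
        ccc_map[col] = c
        (removed if c < threshold else retained).append(col)
    return retained, removed, ccc_map


def redundancy_filter(
    table: pd.DataFrame, threshold: float = 0.9
) -> tuple[list[str], list[str]]:
    """Greedy removal of highly correlated features.

    While any pairwise ``|r| > threshold`` remains, the worst pair is found
    and the member with the larger mean absolute correlation to all other
    remaining features is dropped (ties keep the earlier column).  The
    retained set therefore has max ``|r| <= threshold``.  Zero-variance
    features are removed first with a warning.
    """
    if table.shape[1] < 2:
        raise ValueError("need at least 2 features")
    removed: list[str] = []
    sd = table.std(ddof=1)
    constant = list(sd.index[(sd == 0) | sd.isna()])
    if constant:
        warnings.warn(f"removing zero-variance features: {constant}")
        removed.extend(constant)
    cols = [c for c in table.columns if c not in constant]
    corr = table[cols].corr().abs().to_numpy()
    np.fill_diagonal(corr, 0.0)
    active = list(range(len(cols)))
    while True:
        sub = corr[np.ix_(active, active)]
        mx = sub.max() if len(active) > 1 else 0.0
        if mx <= threshold:
            break
        i_loc, j_loc = np.unravel_index(np.argmax(sub), sub.shape)
        mean_i = sub[i_loc].sum() / (len(active) - 1)
        mean_j = sub[j_loc].sum() / (len(active) - 1)
        # drop the feature more correlated with everything else on average
        if mean_j > mean_i or (mean_j == mean_i and j_loc > i_loc):
            drop_loc = j_loc
        else:
            drop_loc = i_loc
        removed.append(cols[active[drop_loc]])
        del active[drop_loc]
    retained = [cols[i] for i in active]
    return retained, removed


class Standardizer:
    """Column-wise centering/scaling with frozen train parameters.

    Uses the sample standard deviation (ddof=1).  Frozen means/SDs are
    applied verbatim to held-out tables so no test-set information leaks
    into the transform.
    """

    def __init__(self):
        self.means_: pd.Series | None = None
        self.sds_: pd.Series | None = None

    def fit(self, table: pd.DataFrame) -> "Standardizer":
        sds = table.std(ddof=1)
        bad = list(sds.index[(sds == 0) | sds.isna()])
        if bad:
            raise ValueError(f"zero-variance columns cannot be standardized: {bad}")
        self.means_ = table.mean()
        self.sds_ = sds
        return self

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        if self.means_ is None:
            raise ValueError("Standardizer is not fitted")
        missing = set(self.means_.index) - set(table.columns)
        if missing:
            raise ValueError(f"table is missing standardized columns: {sorted(missing)[:5]}")
        cols = list(self.means_.index)
        return (table[cols] - self.means_) / self.sds_

    def fit_transform(self, table: pd.DataFrame) -> pd.DataFrame:
        return self.fit(table).transform(table)


def standardize(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Convenience wrapper: standardized table plus the frozen means/SDs."""
    sc = Standardizer().fit(table)
    return sc.transform(table), sc.means_.copy(), sc.sds_.copy()


# ---------------------------------------------------------------------------
# LASSO-Cox
# ---------------------------------------------------------------------------

def breslow_partial_loglik(lp: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Cox partial log-likelihood with the Breslow tie approximation."""
    lp = np.asarray(lp, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    order = np.argsort(-time, kind="stable")
    lp_s, t_s, e_s = lp[order], time[order], event[order]
    # running log-sum-exp of the risk set (all subjects with time >= t)
    run = np.logaddexp.accumulate(lp_s)
    # subjects tied on time share the largest risk set among them
    risk_log = np.empty(len(lp_s))
    i = 0
    while i < len(t_s):
        j = i
        while j + 1 < len(t_s) and t_s[j + 1] == t_s[i]:
            j += 1
        risk_log[i : j + 1] = run[j]
        i = j + 1
    ev = e_s == 1
    return float((lp_s[ev] - risk_log[ev]).sum())


@dataclass
class LassoCoxResult:
    coefficients: pd.Series  # at the chosen penalty, all features
    chosen_lambda: float
    cv_curve: pd.DataFrame  # lambda, mean_deviance, se_deviance
    path_lambdas: np.ndarray
    path_coefs: np.ndarray  # (n_features, n_lambdas)

    @property
    def nonzero(self) -> pd.Series:
        return self.coefficients[self.coefficients != 0.0]


def fit_lasso_cox(
    table: pd.DataFrame,
    outcomes: pd.DataFrame,
    config: SelectionConfig | None = None,
    alphas: list[float] | None = None,
) -> LassoCoxResult:
    """L1-penalized Cox regression with cross-validated penalty choice.

    The penalty path is the glmnet-style log-spaced grid; per fold the model
    is refit on the training subjects and scored by the
    Verweij–van Houwelingen cross-validated partial-likelihood deviance
    ``-2 (pll(all, beta) - pll(train, beta))``.  Folds are stratified by
    event status and seeded.  ``lambda_rule='min'`` picks the
    deviance-minimizing penalty; ``'1se'`` the largest penalty within one
    standard error of it.
    """
    config = config or SelectionConfig()
    out = outcomes.set_index("subject_id") if "subject_id" in outcomes.columns else outcomes
    out = out.loc[table.index]
    time = out["time_months"].to_numpy(float)
    event = out["event"].to_numpy(int)
    if event.sum() < 2:
        raise ValueError("need at least 2 events for a Cox fit")
    X = table.to_numpy(float)
    mu, sd = X.mean(axis=0), X.std(axis=0, ddof=1)
    if np.abs(mu).max() > 1e-6 or np.abs(sd - 1).max() > 1e-6:
        warnings.warn("features do not look standardized (mean 0, SD 1)")
    y = Surv.from_arrays(event=event.astype(bool), time=time)

    est = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas, n_alphas=100, tol=1e-8)
    est.fit(X, y)
    grid = np.asarray(est.alphas_)

    if len(grid) > 1:
        rng_folds = StratifiedKFold(
            n_splits=config.n_folds, shuffle=True, random_state=config.seed
        )
        dev = np.full((config.n_folds, len(grid)), np.nan)
        for k, (tr, _te) in enumerate(rng_folds.split(X, event)):
            m = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=list(grid), tol=1e-8)
            m.fit(X[tr], y[tr])
            fitted = np.asarray(m.alphas_)
            coefs = m.coef_  # (p, n_fitted)
            for a_idx, a in enumerate(grid):
                j = int(np.argmin(np.abs(fitted - a)))
                beta = coefs[:, j]
                pll_all = breslow_partial_loglik(X @ beta, time, event)
                pll_tr = breslow_partial_loglik(X[tr] @ beta, time[tr], event[tr])
                dev[k, a_idx] = -2.0 * (pll_all - pll_tr)
        mean_dev = dev.mean(axis=0)
        se_dev = dev.std(axis=0, ddof=1) / np.sqrt(config.n_folds)
        i_min = int(np.argmin(mean_dev))
        if config.lambda_rule == "min":
            i_best = i_min
        else:
            ok = np.where(mean_dev <= mean_dev[i_min] + se_dev[i_min])[0]
            i_best = int(ok[0])  # grid is descending in lambda
        cv_curve = pd.DataFrame(
            {"lambda": grid, "mean_deviance": mean_dev, "se_deviance": se_dev}
        )
    else:
        i_best = 0
        cv_curve = pd.DataFrame(
            {"lambda": grid, "mean_deviance": [np.nan], "se_deviance": [np.nan]}
        )

    coefs = pd.Series(est.coef_[:, i_best], index=table.columns, name="coefficient")
    return LassoCoxResult(
        coefficients=coefs,
        chosen_lambda=float(grid[i_best]),
        cv_curve=cv_curve,
        path_lambdas=grid,
        path_coefs=np.asarray(est.coef_),
    )


def select_features(
    dev_table: pd.DataFrame,
    outcomes: pd.DataFrame,
    reader1: pd.DataFrame,
    reader2: pd.DataFrame,
    config: SelectionConfig | None = None,
) -> tuple[SelectionReport, LassoCoxResult, Standardizer]:
    """Full cascade: reliability filter, redundancy filter, LASSO-Cox.

    The reliability filter is computed on the reader-pair tables (typically
    a subset of subjects segmented twice) and applied to the development
    table; the redundancy filter and the penalized fit run on the
    development table.  Features are standardized (frozen parameters
    returned) before the penalized fit.
    """
    config = config or SelectionConfig()
    n_total = dev_table.shape[1]
    keep_ccc, drop_ccc, ccc_map = reliability_filter(
        reader1, reader2, config.ccc_threshold
    )
    stage2 = dev_table[keep_ccc]
    keep_corr, drop_corr = redundancy_filter(stage2, config.pearson_threshold)
    report = SelectionReport(
        n_total=n_total,
        n_removed_ccc=len(drop_ccc),
        n_removed_corr=len(drop_corr),
        retained_ids=list(keep_corr),
        ccc=ccc_map,
    )
    scaler = Standardizer().fit(dev_table[keep_corr])
    z = scaler.transform(dev_table[keep_corr])
    lasso = fit_lasso_cox(z, outcomes, config)
    report.chosen_lambda = lasso.chosen_lambda
    report.n_signature = int((lasso.coefficients != 0).sum())
    return report, lasso, scaler
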