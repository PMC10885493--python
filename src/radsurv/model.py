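"""Model/Results front for the clinical-radiomics survival analysis.

:class:`ClinicalRadiomicsModel` is built from per-subject tables (clinical
covariates, a radiomics risk score, censored outcomes); ``fit()`` returns a
:class:`ClinicalRadiomicsResults` carrying the clinical-only Cox fit
(C-model), the combined fit (CR-model), their uncertainties, and a
``summary()`` table.  Evaluation on held-out cohorts, simulation from the
fitted model, and calibration plotting hang off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import EvalConfig, EvalReport, calibration_table, evaluate_models
from .scoring import CoxFit, RScoreDefinition, build_models, clinical_design, select_cutoff

__all__ = ["ClinicalRadiomicsModel", "ClinicalRadiomicsResults"]


class ClinicalRadiomicsModel:
    """Cox modelling of survival from clinical covariates plus a radiomics score.

    Parameters
    ----------
    clinical : DataFrame
        Columns ``age`` and ``stage`` (I-IV), indexed by subject id (or with
        a ``subject_id`` column).
    rscore : Series
        Radiomics risk score per subject.
    outcomes : DataFrame
        Columns ``time_months`` and ``event`` (1 = event, 0 = censored).
    """

    def __init__(self, clinical: pd.DataFrame, rscore: pd.Series, outcomes: pd.DataFrame):
        self.clinical = clinical.set_index("subject_id") if "subject_id" in clinical.columns else clinical.copy()
        self.rscore = rscore.reindex(self.clinical.index)
        if self.rscore.isna().any():
            raise ValueError("rscore missing for some subjects")
        self.outcomes = outcomes.set_index("subject_id") if "subject_id" in outcomes.columns else outcomes.copy()
        self.outcomes = self.outcomes.loc[self.clinical.index]

    @classmethod
    def from_feature_table(
        cls,
        clinical: pd.DataFrame,
        features: pd.DataFrame,
        outcomes: pd.DataFrame,
        definition: RScoreDefinition,
        scaler=None,
    ) -> "ClinicalRadiomicsModel":
        """Build the model from a raw feature table and a score definition."""
        z = scaler.transform(features) if scaler is not None else features
        return cls(clinical, definition.score_table(z), outcomes)

    def fit(self) -> "ClinicalRadiomicsResults":
        models = build_models(self.clinical, self.rscore, self.outcomes.reset_index())
        design_c = clinical_design(self.clinical)
        design_cr = design_c.assign(rscore=self.rscore)
        return ClinicalRadiomicsResults(
            model=self,
            c_model=models["C_model"],
            cr_model=models["CR_model"],
            design_c=design_c,
            design_cr=design_cr,
        )


@dataclass
class ClinicalRadiomicsResults:
    model: ClinicalRadiomicsModel
    c_model: CoxFit
    cr_model: CoxFit
    design_c: pd.DataFrame
    design_cr: pd.DataFrame

    def summary(self) -> str:
        lines = ["Clinical-radiomics Cox models (Breslow ties)"]
        lines.append(
            f"n = {self.cr_model.n}, events = {self.cr_model.n_events}"
        )
        for name, fit in (("C-model", self.c_model), ("CR-model", self.cr_model)):
            lines.append("")
            lines.append(f"{name}  (partial log-likelihood {fit.log_likelihood:.2f})")
            tab = fit.summary()
            lines.append(tab.to_string(float_format=lambda v: f"{v:8.3f}"))
        return "\n".join(lines)

    def _designs_for(self, clinical: pd.DataFrame, rscore: pd.Series):
        c = clinical.set_index("subject_id") if "subject_id" in clinical.columns else clinical
        d_c = clinical_design(c)
        for col in self.c_model.covariates:  # held-out cohort may miss a stage
            if col not in d_c.columns:
                d_c[col] = 0.0
        d_cr = d_c.assign(rscore=rscore.reindex(d_c.index))
        return d_c, d_cr

    def evaluate(
        self,
        clinical: pd.DataFrame | None = None,
        rscore: pd.Series | None = None,
        outcomes: pd.DataFrame | None = None,
        config: EvalConfig | None = None,
    ) -> EvalReport:
        """Evaluate on a cohort (defaults to the development data).

        No refitting happens: frozen coefficients and baselines score the
        given subjects.
        """
        if clinical is None:
            clinical, rscore, outcomes = (
                self.model.clinical,
                self.model.rscore,
                self.model.outcomes.reset_index(),
            )
        d_c, d_cr = self._designs_for(clinical, rscore)
        return evaluate_models(
            {"C_model": self.c_model, "CR_model": self.cr_model},
            {"C_model": d_c, "CR_model": d_cr},
            outcomes,
            rscore=rscore,
            config=config,
        )

    def optimal_cutoff(self, horizon: float = 36.0):
        lp = self.cr_model.predict_lp(self.design_cr)
        return select_cutoff(lp, self.model.outcomes.reset_index(), horizon)

    def simulate(self, rng, censor_time: float | None = None) -> pd.DataFrame:
        """Draw a new outcome table from the fitted CR-model."""
        return self.cr_model.simulate(self.design_cr, rng, censor_time)

    def plot_calibration(self, t: float = 36.0, groups: int = 4, ax=None):
        """Predicted vs observed survival at ``t`` (KM with Greenwood CI)."""
        import matplotlib.pyplot as plt

        tab = calibration_table(
            self.cr_model, self.design_cr, self.model.outcomes.reset_index(), t, groups
        )
        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        yerr = np.abs(
            np.vstack([tab.km_observed - tab.km_lo, tab.km_hi - tab.km_observed])
        )
        ax.errorbar(tab.mean_predicted, tab.km_observed, yerr=yerr, fmt="o", capsize=3)
        lim = [0, 1]
        ax.plot(lim, lim, "k--", lw=0.8)
        ax.set_xlabel(f"Predicted S({t:g})")
        ax.set_ylabel(f"Observed S({t:g}) (Kaplan-Meier)")
        return ax
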