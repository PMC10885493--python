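"""End-to-end orchestration: simulate, extract, select, fit, evaluate.

A development run executes the full cascade on one cohort and freezes every
artifact needed to validate externally without refitting: the selection
report, the standardization parameters, the score definition, and the Cox
fits with their Breslow baselines.  All randomness is funneled through one
master seed expanded into independent per-stage streams.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import EvalConfig, EvalReport
from .features import FeatureRegistry, extract_table
from .model import ClinicalRadiomicsModel, ClinicalRadiomicsResults
from .preprocess import PrepConfig
from .scoring import CoxFit, RScoreDefinition
from .selection import LassoCoxResult, SelectionConfig, SelectionReport, Standardizer, select_features
from .synthdata import CohortData, CohortSpec, PhantomSpec, generate_cohort, perturb_mask

log = logging.getLogger("radsurv")

__all__ = ["RunConfig", "DevelopmentArtifacts", "run_development", "run_external_validation"]


def _stage_seed(seed: int, stage: int) -> int:
    return int(np.random.SeedSequence([seed, stage]).generate_state(1)[0] % (2**31 - 1))


@dataclass
class RunConfig:
    """Per-stage configuration of an end-to-end run."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    prep: PrepConfig = field(default_factory=PrepConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)
    phases: tuple[str, ...] = ("AP",)
    transforms: tuple[str, ...] = ("N", "G", "LOG")
    n_reader_pairs: int = 30
    reader_jitter_mm: float = 1.0
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self):
        # one master seed expanded into per-stage streams
        self.cohort.seed = _stage_seed(self.seed, 1)
        self.selection.seed = _stage_seed(self.seed, 2)
        self.eval.seed = _stage_seed(self.seed, 3)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key, klass in (
            ("cohort", CohortSpec),
            ("phantom", PhantomSpec),
            ("prep", PrepConfig),
            ("selection", SelectionConfig),
            ("eval", EvalConfig),
        ):
            if key in raw:
                section = dict(raw[key])
                for tup_key in ("grid_shape", "spacing_mm", "semi_axes_mm",
                                "amplitude_range_hu", "target_spacing_mm"):
                    if tup_key in section:
                        section[tup_key] = tuple(section[tup_key])
                kwargs[key] = klass(**section)
        for key in ("phases", "transforms"):
            if key in raw:
                kwargs[key] = tuple(raw[key])
        for key in ("n_reader_pairs", "reader_jitter_mm", "seed", "out_dir"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)

    def config_hash(self) -> str:
        def default(o):
            return str(o)

        payload = json.dumps(asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def cohort_feature_tables(
    cohort: CohortData, config: RunConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Extract development features plus the two-reader tables.

    The second reader is simulated by boundary-jittering the masks of the
    first ``n_reader_pairs`` subjects and re-extracting their features.
    """
    registry = FeatureRegistry.default(phases=config.phases, transforms=config.transforms)
    ids = cohort.clinical["subject_id"].tolist()
    subjects = {
        sid: (vol, None, mask) if config.phases == ("AP",) else (vol, vol, mask)
        for sid, (vol, mask) in zip(ids, cohort.subjects)
    }
    log.info("extracting %d features for %d subjects", len(registry), len(subjects))
    table = extract_table(subjects, registry=registry, prep=config.prep)

    n_pairs = min(config.n_reader_pairs, len(ids))
    jitter_seed = _stage_seed(config.seed, 4)
    reader2_subjects = {}
    for k, sid in enumerate(ids[:n_pairs]):
        vol, mask = cohort.subjects[k]
        m2 = perturb_mask(mask, config.reader_jitter_mm, seed=jitter_seed + k)
        reader2_subjects[sid] = (vol, None, m2) if config.phases == ("AP",) else (vol, vol, m2)
    reader2 = extract_table(reader2_subjects, registry=registry, prep=config.prep)
    reader1 = table.loc[reader2.index]
    return table, reader1, reader2


@dataclass
class DevelopmentArtifacts:
    """Everything a frozen external validation needs."""

    config: RunConfig
    selection_report: SelectionReport
    lasso: LassoCoxResult
    scaler: Standardizer
    rscore_definition: RScoreDefinition
    results: ClinicalRadiomicsResults
    eval_report: EvalReport
    feature_table: pd.DataFrame
    rscores: pd.Series

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        meta = {"seed": self.config.seed, "config_hash": self.config.config_hash()}
        (out / "provenance.json").write_text(json.dumps(meta, indent=2))
        (out / "selection_report.json").write_text(
            json.dumps(self.selection_report.to_dict(), indent=2)
        )
        self.rscore_definition.to_json(out / "rscore_definition.json")
        scaler_payload = {
            "means": self.scaler.means_.to_dict(),
            "sds": self.scaler.sds_.to_dict(),
        }
        (out / "standardizer.json").write_text(json.dumps(scaler_payload, indent=2))
        fits = {
            "C_model": _cox_to_dict(self.results.c_model),
            "CR_model": _cox_to_dict(self.results.cr_model),
        }
        (out / "cox_models.json").write_text(json.dumps(fits, indent=2))
        (out / "evaluation.json").write_text(
            json.dumps(self.eval_report.to_dict(), indent=2, default=float)
        )
        self.feature_table.to_csv(out / "features.csv")


def _cox_to_dict(fit: CoxFit) -> dict:
    return {
        "covariates": fit.covariates,
        "coef": fit.params.to_dict(),
        "se": fit.bse.to_dict(),
        "p": fit.pvalues.to_dict(),
        "conf_int": {k: list(v) for k, v in fit.conf_int.T.items()},
        "baseline_times": list(map(float, fit.baseline_times)),
        "baseline_cumhaz": list(map(float, fit.baseline_cumhaz)),
        "n": fit.n,
        "n_events": fit.n_events,
        "log_likelihood": fit.log_likelihood,
    }


def run_development(config: RunConfig, cohort: CohortData | None = None) -> DevelopmentArtifacts:
    """Execute the full development cascade on one synthetic cohort.

    Stages: cohort simulation, feature extraction (plus the simulated
    second reader), three-stage selection, score construction, C/CR Cox
    fits, and the development-set evaluation report.  Artifacts are written
    to ``config.out_dir`` when set.
    """
    if cohort is None:
        log.info("simulating cohort (n=%d)", config.cohort.n_subjects)
        cohort = generate_cohort(config.cohort, config.phantom)
    table, reader1, reader2 = cohort_feature_tables(cohort, config)

    report, lasso, scaler = select_features(
        table, cohort.survival, reader1, reader2, config.selection
    )
    nonzero = lasso.nonzero
    if nonzero.empty:
        # fall back to the densest end of the path so a score always exists
        warnings.warn("CV-chosen penalty produced an empty signature; "
                      "falling back to the smallest penalty on the path")
        dense = pd.Series(lasso.path_coefs[:, -1], index=lasso.coefficients.index)
        nonzero = dense[dense != 0]
    rscore_def = RScoreDefinition.from_lasso(nonzero)

    z = scaler.transform(table)
    rscores = rscore_def.score_table(z)
    results = ClinicalRadiomicsModel(cohort.clinical, rscores, cohort.survival).fit()
    eval_report = results.evaluate(config=config.eval)

    artifacts = DevelopmentArtifacts(
        config=config,
        selection_report=report,
        lasso=lasso,
        scaler=scaler,
        rscore_definition=rscore_def,
        results=results,
        eval_report=eval_report,
        feature_table=table,
        rscores=rscores,
    )
    if config.out_dir:
        artifacts.save(config.out_dir)
    return artifacts


def run_external_validation(
    artifacts: DevelopmentArtifacts,
    test_features: pd.DataFrame,
    test_clinical: pd.DataFrame,
    test_outcomes: pd.DataFrame,
    config: EvalConfig | None = None,
) -> EvalReport:
    """Score and evaluate a held-out cohort with frozen development artifacts.

    Test features are standardized with the development means/SDs; no model
    or score parameter is refit.
    """
    missing = set(artifacts.scaler.means_.index) - set(test_features.columns)
    if missing:
        raise ValueError(f"test table is missing frozen features: {sorted(missing)[:5]}")
    z = artifacts.scaler.transform(test_features)
    rscores = artifacts.rscore_definition.score_table(z)
    return artifacts.results.evaluate(
        clinical=test_clinical,
        rscore=rscores,
        outcomes=test_outcomes,
        config=config or artifacts.config.eval,
    )
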