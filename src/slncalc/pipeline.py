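"""End-to-end experiment orchestration.

One experiment reproduces the full evaluation protocol on a cohort (loaded
from CSV or simulated): an 80/20 hold-out split, per-variant two-phase fit on
the training portion, repeated stratified 10-fold cross-validation on the
training portion, Youden threshold selection on the full refitted training
scores, transfer of that threshold to the held-out test set, and a clinical
subgroup report on the test set. Variants are A (base covariates),
B (+HER2), C (+Ki67), D (+both).

Per variant the run writes: fitted parameters (JSON), a fit report, a CV
summary, hold-out test metrics, and the stratified report (CSV). Outputs are
deterministic given the config; partial outputs are removed on failure.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
import pandas as pd

from .cohort import build_scheme, read_cohort
from .errors import ConfigurationError, SlncalcError
from .evaluation import (
    EvalMetrics,
    CVSummary,
    evaluate_scores,
    holdout_split,
    repeated_cv,
    stratified_performance,
    youden_threshold,
)
from .model import score_cohort
from .simulate import CohortConfig, generate_cohort
from .training import DEFAULT_MIN_STRATUM, FitReport, fit_model

logger = logging.getLogger(__name__)


@dataclass
class ExperimentConfig:
    """Declarative description of one experiment run."""

    outdir: str
    cohort_csv: str | None = None
    simulate: CohortConfig | None = None
    variants: tuple[str, ...] = ("A", "B", "C", "D")
    split_fraction: float = 0.8
    split_seed: int = 0
    cv_rounds: int = 100
    cv_folds: int = 10
    cv_seed: int = 0
    z: float = 1.0
    min_stratum: int = DEFAULT_MIN_STRATUM

    def __post_init__(self) -> None:
        if not self.variants:
            raise ConfigurationError("at least one variant must be requested")
        if not 0 < self.split_fraction < 1:
            raise ConfigurationError("split_fraction must be in (0, 1)")
        if (self.cohort_csv is None) == (self.simulate is None):
            raise ConfigurationError("exactly one of cohort_csv / simulate must be set")

    def to_dict(self) -> dict:
        d = {
            "outdir": self.outdir,
            "cohort_csv": self.cohort_csv,
            "simulate": self.simulate.to_dict() if self.simulate else None,
            "variants": list(self.variants),
            "split_fraction": self.split_fraction,
            "split_seed": self.split_seed,
            "cv_rounds": self.cv_rounds,
            "cv_folds": self.cv_folds,
            "cv_seed": self.cv_seed,
            "z": self.z,
            "min_stratum": self.min_stratum,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        if d.get("simulate") is not None:
            d["simulate"] = CohortConfig.from_dict(d["simulate"])
        if "variants" in d:
            d["variants"] = tuple(d["variants"])
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "ExperimentConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class VariantResult:
    variant: str
    fit: FitReport
    cv: CVSummary
    threshold: float
    test_metrics: EvalMetrics
    stratified: pd.DataFrame
    files: dict[str, Path] = field(default_factory=dict)


@dataclass
class ExperimentReport:
    config: ExperimentConfig
    n_train: int
    n_test: int
    variants: dict[str, VariantResult]


def _fmt_quartiles(q) -> str:
    return f"{100 * q.median:.1f} ({100 * q.q1:.1f}-{100 * q.q3:.1f})"


def _cv_frame(variant: str, cv: CVSummary) -> pd.DataFrame:
    rows = []
    for metric in ("auc", "accuracy", "sensitivity", "specificity"):
        q = getattr(cv, metric)
        rows.append({"model": variant, "metric": metric,
                     "median": q.median, "q1": q.q1, "q3": q.q3,
                     "formatted_pct": _fmt_quartiles(q)})
    return pd.DataFrame(rows)


def _metrics_frame(variant: str, m: EvalMetrics) -> pd.DataFrame:
    return pd.DataFrame([
        {"model": variant, "auc": m.auc, "threshold": m.threshold,
         "accuracy": m.accuracy, "sensitivity": m.sensitivity,
         "specificity": m.specificity, "tp": m.counts.tp, "tn": m.counts.tn,
         "fp": m.counts.fp, "fn": m.counts.fn}
    ])


def _fit_frame(report: FitReport) -> pd.DataFrame:
    return pd.DataFrame(
        [{"factor": s.factor, "level": s.level, "w": s.w, "rate": s.observed_rate,
          "g": s.g, "clamped": s.clamped, "skipped": s.skipped} for s in report.strata]
    )


def run_experiment(config: ExperimentConfig) -> ExperimentReport:
    """Execute the full protocol; see module docstring for the stage list."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"
    log_handler = logging.FileHandler(outdir / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("slncalc")
    prior_level = root.level
    root.addHandler(log_handler)
    root.setLevel(logging.INFO)
    try:
        stage = "cohort"
        if config.cohort_csv is not None:
            cohort = read_cohort(config.cohort_csv)
        else:
            cohort = generate_cohort(config.simulate)
        pos = sum(r.node_status for r in cohort)
        logger.info("cohort: n=%d, positives=%d (%.2f%%)", len(cohort), pos,
                    100 * pos / len(cohort))

        stage = "split"
        train, test = holdout_split(cohort, config.split_fraction, config.split_seed)
        logger.info("split: train=%d test=%d (seed=%d)", len(train), len(test),
                    config.split_seed)

        results: dict[str, VariantResult] = {}
        for variant in config.variants:
            stage = f"variant {variant}"
            scheme = build_scheme(variant)
            cv = repeated_cv(train, scheme, z=config.z, n_rounds=config.cv_rounds,
                             n_folds=config.cv_folds, base_seed=config.cv_seed,
                             min_stratum=config.min_stratum)
            fit = fit_model(train, scheme, z=config.z, min_stratum=config.min_stratum)
            for s in fit.strata:
                if s.clamped:
                    logger.warning("variant %s: stratum %s=%s clamped (rate %.3f)",
                                   variant, s.factor, s.level, s.observed_rate)
            train_scores = [p for _, p in score_cohort(fit.params, train)]
            train_labels = [r.node_status for r in train]
            threshold = youden_threshold(train_scores, train_labels)
            test_scores = [p for _, p in score_cohort(fit.params, test)]
            test_labels = [r.node_status for r in test]
            metrics = evaluate_scores(test_scores, test_labels, threshold=threshold)
            strat = stratified_performance(test, test_scores, threshold)

            files = {
                "params": outdir / f"params_{variant}.json",
                "fit_report": outdir / f"fit_report_{variant}.csv",
                "cv": outdir / f"cv_{variant}.csv",
                "test_metrics": outdir / f"test_metrics_{variant}.csv",
                "stratified": outdir / f"stratified_{variant}.csv",
            }
            fit.params.to_json(files["params"])
            _fit_frame(fit).to_csv(files["fit_report"], index=False)
            _cv_frame(variant, cv).to_csv(files["cv"], index=False)
            _metrics_frame(variant, metrics).to_csv(files["test_metrics"], index=False)
            strat.to_csv(files["stratified"], index=False)
            written.extend(files.values())
            logger.info("variant %s: cv median AUC=%.3f, youden threshold=%.4f, "
                        "test sens=%.3f spec=%.3f", variant, cv.auc.median, threshold,
                        metrics.sensitivity, metrics.specificity)
            results[variant] = VariantResult(variant=variant, fit=fit, cv=cv,
                                             threshold=threshold, test_metrics=metrics,
                                             stratified=strat, files=files)
        return ExperimentReport(config=config, n_train=len(train), n_test=len(test),
                                variants=results)
    except SlncalcError as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise type(exc)(f"experiment failed at stage '{stage}': {exc}") from exc
    finally:
        root.removeHandler(log_handler)
        root.setLevel(prior_level)
        log_handler.close()
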