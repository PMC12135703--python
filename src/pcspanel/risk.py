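"""Final panel risk model and its clinical-utility evaluation.

The locked risk model is a ridge-regularized logistic regression on the
selected panel genes plus clinical covariates (optionally including prostate
volume), with the regularization strength tuned by stratified 5-fold CV.
Coefficients are stored explicitly (with the standardization statistics)
so the model serializes to JSON and predicts without any fitted sklearn
state.

Deployment to a cohort with a different outcome prevalence uses logistic
recalibration: the linear predictor LP is held fixed and an intercept a and
slope b are refit by maximum likelihood, logit(p) = a + b * LP.  With b > 0
this is a strictly monotone transform, so discrimination (AUROC) is
untouched while calibration adapts.

Clinical utility is evaluated at a sensitivity-anchored threshold (e.g. the
largest threshold retaining 95% sensitivity for high-grade disease), with
confusion-matrix metrics in the form clinicians read them: specificity, NPV,
PPV, and unnecessary biopsies avoided per 1000 patients.  The minimum test
tradeoff (MTT) quantifies when a larger assay is worth its extra collection
cost: the minimum number of tests per true positive needed for the larger
panel's net benefit to exceed the smaller one's.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from sklearn.metrics import roc_auc_score

from .models import REGULARIZATION_GRID
from .prediction_check import _clinical_matrix, _join, _unpack
from .preprocess import PreprocessPipeline
from .stability import GenePanel

__all__ = [
    "RiskModel",
    "CalibrationParams",
    "ThresholdMetrics",
    "TradeoffResult",
    "ModelLockedError",
    "SeparationError",
    "fit_final_model",
    "recalibrate",
    "threshold_for_sensitivity",
    "clinical_metrics",
    "min_test_tradeoff",
]

CLINICAL_VARS = ("age", "race", "family_history", "abnormal_dre",
                 "prior_negative_biopsy", "psa")


class ModelLockedError(RuntimeError):
    """The model is locked; its coefficients and calibration are immutable."""


class SeparationError(RuntimeError):
    """Maximum-likelihood recalibration did not converge (perfect separation)."""


@dataclass(frozen=True)
class CalibrationParams:
    """Logistic recalibration parameters: logit(p) = intercept + slope * LP."""

    intercept: float = 0.0
    slope: float = 1.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.intercept) and math.isfinite(self.slope)):
            raise ValueError("calibration parameters must be finite")


@dataclass
class RiskModel:
    """A serializable linear risk model with logistic recalibration.

    The linear predictor is
    ``intercept + sum_j coef_j * (x_j - center_j) / scale_j`` over panel
    genes and clinical covariates; predicted risk is
    ``expit(a + b * LP)`` with recalibration parameters (a, b).
    """

    panel_genes: list[str]
    clinical_vars: list[str]
    pipeline_name: str
    coef: dict[str, float]
    intercept: float
    center: dict[str, float]
    scale: dict[str, float]
    chosen_C: float | None = None
    calibration: CalibrationParams = field(default_factory=CalibrationParams)
    locked: bool = False

    @property
    def features(self) -> list[str]:
        return self.panel_genes + self.clinical_vars

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        lp = np.full(len(X), self.intercept, dtype=float)
        for f in self.features:
            z = (X[f].to_numpy(dtype=float) - self.center[f]) / self.scale[f]
            lp += self.coef[f] * z
        return lp

    def predict_risk(self, X: pd.DataFrame) -> np.ndarray:
        a, b = self.calibration.intercept, self.calibration.slope
        return expit(a + b * self.linear_predictor(X))

    def lock(self) -> "RiskModel":
        self.locked = True
        return self

    def set_calibration(self, params: CalibrationParams) -> None:
        if self.locked:
            raise ModelLockedError("cannot recalibrate a locked model")
        self.calibration = params

    def to_json(self) -> str:
        d = {
            "panel_genes": self.panel_genes,
            "clinical_vars": self.clinical_vars,
            "pipeline_name": self.pipeline_name,
            "coef": self.coef,
            "intercept": self.intercept,
            "center": self.center,
            "scale": self.scale,
            "chosen_C": self.chosen_C,
            "calibration": {
                "intercept": self.calibration.intercept,
                "slope": self.calibration.slope,
            },
            "locked": self.locked,
        }
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RiskModel":
        d = json.loads(text)
        cal = d.pop("calibration")
        return cls(calibration=CalibrationParams(cal["intercept"], cal["slope"]), **d)


def fit_final_model(
    cohort,
    panel: GenePanel | list[str],
    clinical_vars: list[str] | None = None,
    include_volume: bool = False,
    pipeline: PreprocessPipeline | None = None,
    c_grid: list[float] | None = None,
    tune_folds: int = 5,
    seed: int = 0,
) -> RiskModel:
    """Ridge-logistic fit of the locked panel on the full provided cohort.

    The regularization strength C is tuned by stratified ``tune_folds``-fold
    CV (AUROC, ties toward stronger regularization).  Recalibration starts at
    the identity (a=0, b=1).
    """
    from .models import ModelSpec, _linear, tune_and_fit

    ct, clinical, y = _unpack(cohort)
    genes = panel.genes if isinstance(panel, GenePanel) else list(panel)
    missing = [g for g in genes if g not in ct.candidate_genes]
    if missing:
        raise KeyError(f"panel genes absent from cohort: {missing}")
    if pipeline is None:
        raise ValueError("a preprocessing pipeline must be specified")
    cvars = list(clinical_vars) if clinical_vars is not None else list(CLINICAL_VARS)
    if include_volume and "prostate_volume" not in cvars:
        cvars = cvars + ["prostate_volume"]
    clin = _clinical_matrix(clinical, cvars)

    expr = pipeline.fit_transform(ct)
    X = _join(expr[genes], clin)

    grid = c_grid if c_grid is not None else list(REGULARIZATION_GRID)
    spec = ModelSpec(
        "ridge-logistic", _linear("l2", solver="liblinear"), {"clf__C": grid}, "coef"
    )
    fitted = tune_and_fit(spec, X, y, seed=seed, cv_folds=tune_folds)
    scaler = fitted.estimator.named_steps["scale"]
    clf = fitted.estimator.named_steps["clf"]
    coef = dict(zip(fitted.feature_names, np.ravel(clf.coef_).astype(float)))
    center = dict(zip(fitted.feature_names, scaler.mean_.astype(float)))
    scale = dict(zip(fitted.feature_names, scaler.scale_.astype(float)))
    return RiskModel(
        panel_genes=genes,
        clinical_vars=cvars,
        pipeline_name=pipeline.name,
        coef=coef,
        intercept=float(clf.intercept_[0]),
        center=center,
        scale=scale,
        chosen_C=fitted.chosen_params.get("clf__C"),
    )


def recalibrate(
    model: RiskModel | None,
    linear_predictors: np.ndarray,
    outcomes: np.ndarray,
) -> CalibrationParams:
    """Fit logit(p) = a + b * LP by maximum likelihood; update the model.

    The model's original coefficients are untouched; only (a, b) change.
    Pass ``model=None`` to obtain the parameters without updating anything.
    """
    lp = np.asarray(linear_predictors, dtype=float)
    y = np.asarray(outcomes)
    if np.unique(y).size < 2:
        raise ValueError("outcomes must contain both classes")
    try:
        res = sm.Logit(y, sm.add_constant(lp)).fit(disp=0, maxiter=200)
        a, b = float(res.params[0]), float(res.params[1])
    except Exception as exc:  # statsmodels raises PerfectSeparationError et al.
        raise SeparationError(f"recalibration MLE failed: {exc}") from exc
    if not (math.isfinite(a) and math.isfinite(b)):
        raise SeparationError("recalibration produced non-finite parameters")
    params = CalibrationParams(intercept=a, slope=b)
    if model is not None:
        model.set_calibration(params)
    return params


def threshold_for_sensitivity(
    scores: np.ndarray, labels: np.ndarray, target: float = 0.95
) -> float:
    """Largest threshold whose sensitivity (score >= threshold positive) >= target.

    Maximizes specificity subject to the sensitivity floor; deterministic.
    """
    if not (0.0 < target <= 1.0):
        raise ValueError("target sensitivity must lie in (0, 1]")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = np.sort(scores[labels == 1])[::-1]
    if pos.size == 0:
        raise ValueError("no positive-class samples")
    # sensitivity at threshold pos[k-1] is >= k / n_pos; the largest threshold
    # with sensitivity >= target is the ceil(target * n)-th highest positive score
    need = int(np.ceil(target * pos.size))
    return float(pos[need - 1])


@dataclass(frozen=True)
class ThresholdMetrics:
    """Confusion-matrix metrics at a decision threshold (ties called positive).

    Percentages follow the conventional definitions: sensitivity TP/(TP+FN),
    specificity TN/(TN+FP), NPV TN/(TN+FN), PPV TP/(TP+FP).  Per-1000 counts
    are rounded to the nearest integer; undefined metrics (empty denominator)
    are reported as None rather than NaN.
    """

    threshold: float | None
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @staticmethod
    def _pct(num: int, den: int) -> float | None:
        return 100.0 * num / den if den else None

    @property
    def sensitivity_pct(self) -> float | None:
        return self._pct(self.tp, self.tp + self.fn)

    @property
    def specificity_pct(self) -> float | None:
        return self._pct(self.tn, self.tn + self.fp)

    @property
    def npv_pct(self) -> float | None:
        return self._pct(self.tn, self.tn + self.fn)

    @property
    def ppv_pct(self) -> float | None:
        return self._pct(self.tp, self.tp + self.fp)

    @property
    def biopsies_avoided_per_1000(self) -> int | None:
        den = self.tn + self.fp
        return round(1000 * self.tn / den) if den else None

    @property
    def cancers_missed_per_1000(self) -> int | None:
        den = self.fn + self.tp
        return round(1000 * self.fn / den) if den else None

    @classmethod
    def from_counts(cls, tp: int, fp: int, tn: int, fn: int,
                    threshold: float | None = None) -> "ThresholdMetrics":
        """Build directly from printed confusion counts (e.g. a published table)."""
        return cls(threshold=threshold, tp=tp, fp=fp, tn=tn, fn=fn)

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "sensitivity_pct": self.sensitivity_pct,
            "specificity_pct": self.specificity_pct,
            "npv_pct": self.npv_pct,
            "ppv_pct": self.ppv_pct,
            "biopsies_avoided_per_1000": self.biopsies_avoided_per_1000,
            "cancers_missed_per_1000": self.cancers_missed_per_1000,
        }

    def report(self, label: str = "model") -> str:
        def fmt(x):
            return "undefined" if x is None else f"{x:.1f}"

        return (
            f"{label}: sensitivity {fmt(self.sensitivity_pct)}% | "
            f"specificity {fmt(self.specificity_pct)}% "
            f"({self.tn}/{self.tn + self.fp}) | "
            f"NPV {fmt(self.npv_pct)}% ({self.tn}/{self.tn + self.fn}) | "
            f"PPV {fmt(self.ppv_pct)}% ({self.tp}/{self.tp + self.fp}) | "
            f"biopsies avoided per 1000: {self.biopsies_avoided_per_1000}"
        )


def clinical_metrics(
    scores: np.ndarray, labels: np.ndarray, threshold: float
) -> ThresholdMetrics:
    """Confusion counts and derived metrics at ``threshold`` (>= is positive)."""
    if not math.isfinite(threshold):
        raise ValueError("threshold must be finite")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    call = scores >= threshold
    return ThresholdMetrics(
        threshold=float(threshold),
        tp=int(np.sum(call & (labels == 1))),
        fp=int(np.sum(call & (labels == 0))),
        tn=int(np.sum(~call & (labels == 0))),
        fn=int(np.sum(~call & (labels == 1))),
    )


def inverse_gap_mtt(gap: float, prevalence: float) -> float:
    """Default MTT approximation: 1 / (prevalence * AUROC gap)."""
    if gap <= 0:
        return math.inf
    return 1.0 / (prevalence * gap)


@dataclass(frozen=True)
class TradeoffResult:
    """Minimum test tradeoff between a larger and a smaller panel."""

    prevalence: float
    auc_large: float
    auc_small: float
    mtt: float
    mtt_range: tuple[float, float] | None = None

    @property
    def gap(self) -> float:
        return self.auc_large - self.auc_small


def min_test_tradeoff(
    auc_large: float,
    auc_small: float,
    prevalence: float,
    auc_uncertainty: float = 0.0,
    formula: Callable[[float, float], float] = inverse_gap_mtt,
) -> TradeoffResult:
    """Minimum number of larger-panel tests per true positive for positive net
    benefit over the smaller panel.

    The approximation formula is pluggable; the default is inversely
    proportional to the prevalence-weighted AUROC gap, so the tradeoff blows
    up hyperbolically as the panels' discrimination converges.  With
    ``auc_uncertainty`` > 0 an MTT interval is computed by shifting the gap
    by +/- the uncertainty.
    """
    if not (0.0 < prevalence < 1.0):
        raise ValueError("prevalence must lie in (0, 1)")
    if auc_large < auc_small:
        raise ValueError("auc_large must be >= auc_small")
    gap = auc_large - auc_small
    mtt = formula(gap, prevalence)
    rng = None
    if auc_uncertainty > 0:
        rng = (formula(gap + auc_uncertainty, prevalence),
               formula(gap - auc_uncertainty, prevalence))
    return TradeoffResult(
        prevalence=prevalence,
        auc_large=auc_large,
        auc_small=auc_small,
        mtt=mtt,
        mtt_range=rng,
    )


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Convenience AUROC wrapper used by reports and examples."""
    return float(roc_auc_score(np.asarray(labels), np.asarray(scores)))
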