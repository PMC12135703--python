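"""Prediction-model zoo: candidate learners, CV tuning, gene importance.

Nine named model specs are declared, matching the grid used to develop the
simplified risk score: ordinary logistic regression, L1/L2/elastic-net
regularized logistic regression, random forest, gradient-boosted trees,
RuleFit, RF+ and FIGS.  The last three are backed by the third-party
``imodels`` package and are *optional*: their specs (and hyperparameter
grids) are declared so they can be plugged in when that package is present,
but the pipeline runs with any subset of two or more available specs.

Hyperparameters are tuned by stratified 5-fold cross-validation maximizing
AUROC; ties break toward stronger regularization (candidates are enumerated
strongest-first and the first maximizer wins).

Gene importance is extracted through one uniform contract:

* linear models — absolute standardized coefficient (models are fit behind a
  StandardScaler, so coefficients are per-SD log-odds);
* tree ensembles — seeded permutation importance measured as the AUROC drop
  when a gene's column is shuffled, averaged over repeats, negatives floored
  at zero.

Clinical covariates participate in every fit but are never scored or ranked.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

__all__ = [
    "ModelSpec",
    "FittedModel",
    "ModelUnavailableError",
    "default_model_grid",
    "available_models",
    "tune_and_fit",
    "gene_importance",
    "REGULARIZATION_GRID",
]

#: C = 10^i for i = -3, -2.5, ..., 2.5, 3 (13 candidates, strongest first)
REGULARIZATION_GRID: list[float] = [10.0 ** (i / 2.0) for i in range(-6, 7)]


class ModelUnavailableError(RuntimeError):
    """The spec's backing implementation is not installed."""


def _linear(penalty: str | None, **kw) -> Callable[[int], Pipeline]:
    """Logistic-regression factory behind a StandardScaler.

    ``penalty`` maps to the l1_ratio parametrization: None = unpenalized
    (C = inf), "l1"/"l2" = pure penalties, "elasticnet" = mixed.
    """
    if penalty is None:
        kw = {"C": np.inf, "l1_ratio": 0.0, **kw}
    elif penalty == "l1":
        kw = {"l1_ratio": 1.0, **kw}
    elif penalty == "l2":
        kw = {"l1_ratio": 0.0, **kw}
    elif penalty != "elasticnet":
        raise ValueError(f"unknown penalty {penalty!r}")

    def make(seed: int) -> Pipeline:
        clf = LogisticRegression(max_iter=5000, random_state=seed, **kw)
        return Pipeline([("scale", StandardScaler()), ("clf", clf)])

    return make


@dataclass(frozen=True)
class ModelSpec:
    """A named learner plus its hyperparameter grid and importance mechanism."""

    name: str
    make_estimator: Callable[[int], object] | None
    param_grid: dict[str, list] = field(default_factory=dict)
    importance: str = "coef"  # "coef" | "permutation"
    available: bool = True
    note: str = ""

    def with_grid(self, **grid: list) -> "ModelSpec":
        """Copy of the spec with a replacement hyperparameter grid (compute knob)."""
        return ModelSpec(
            self.name, self.make_estimator, dict(grid), self.importance,
            self.available, self.note,
        )

    def candidates(self) -> list[dict]:
        """Grid points in declaration order (strongest regularization first)."""
        if not self.param_grid:
            return []
        keys = list(self.param_grid)
        return [
            dict(zip(keys, combo))
            for combo in itertools.product(*(self.param_grid[k] for k in keys))
        ]


@dataclass
class FittedModel:
    """A tuned, fully refit predictor with its provenance."""

    spec_name: str
    chosen_params: dict
    estimator: object
    feature_names: list[str]
    importance: str

    def predict_proba1(self, X: pd.DataFrame) -> np.ndarray:
        """Probability of the positive class, features aligned by name."""
        return np.asarray(self.estimator.predict_proba(X[self.feature_names]))[:, 1]


def default_model_grid() -> list[ModelSpec]:
    """The nine-model grid with printed hyperparameter candidates.

    RuleFit, RF+ and FIGS require the optional ``imodels`` package; their
    specs are declared but flagged unavailable when it cannot be imported.
    """
    c_grid = {"clf__C": REGULARIZATION_GRID}
    specs = [
        ModelSpec("logistic", _linear(None), {}, "coef"),
        ModelSpec("lasso-logistic", _linear("l1", solver="liblinear"), dict(c_grid), "coef"),
        ModelSpec("ridge-logistic", _linear("l2", solver="liblinear"), dict(c_grid), "coef"),
        ModelSpec(
            "elasticnet-logistic",
            _linear("elasticnet", solver="saga"),
            {"clf__C": REGULARIZATION_GRID, "clf__l1_ratio": [0.1, 0.25, 0.5, 0.75, 0.9]},
            "coef",
        ),
        ModelSpec(
            "random-forest",
            lambda seed: RandomForestClassifier(n_estimators=500, random_state=seed),
            {"min_samples_leaf": [1, 3, 5, 10]},
            "permutation",
        ),
        ModelSpec(
            "gbdt",
            lambda seed: GradientBoostingClassifier(n_estimators=500, random_state=seed),
            {
                "learning_rate": [0.05, 0.1, 0.15],
                "min_samples_leaf": [1, 5, 10],
                "max_depth": [3, 5],
            },
            "permutation",
        ),
    ]
    try:  # optional third-party interpretable learners
        from imodels import FIGSClassifier, RuleFitClassifier  # type: ignore

        specs += [
            ModelSpec(
                "rulefit",
                lambda seed: RuleFitClassifier(random_state=seed),
                {"max_rules": [5, 10, 30, 50]},
                "permutation",
            ),
            ModelSpec(
                "figs",
                lambda seed: FIGSClassifier(random_state=seed),
                {"max_rules": [5, 10, 12, 15, 20, 30, 50]},
                "permutation",
            ),
        ]
        try:
            from imodels import RandomForestPlusClassifier  # type: ignore

            specs.append(
                ModelSpec(
                    "rf-plus",
                    lambda seed: RandomForestPlusClassifier(),
                    {},
                    "permutation",
                    note="default hyperparameter grid",
                )
            )
        except ImportError:
            specs.append(
                ModelSpec("rf-plus", None, {}, "permutation", available=False,
                          note="requires imodels with RF+")
            )
    except ImportError:
        specs += [
            ModelSpec("rulefit", None, {"max_rules": [5, 10, 30, 50]},
                      "permutation", available=False, note="requires imodels"),
            ModelSpec("rf-plus", None, {}, "permutation", available=False,
                      note="requires imodels"),
            ModelSpec("figs", None, {"max_rules": [5, 10, 12, 15, 20, 30, 50]},
                      "permutation", available=False, note="requires imodels"),
        ]
    # stable order: the six core specs, then the optional ones
    order = ["logistic", "lasso-logistic", "ridge-logistic", "elasticnet-logistic",
             "random-forest", "gbdt", "rulefit", "rf-plus", "figs"]
    specs.sort(key=lambda s: order.index(s.name))
    return specs


def available_models(specs: list[ModelSpec] | None = None) -> list[ModelSpec]:
    """Subset of specs whose backing implementation is importable."""
    return [s for s in (specs or default_model_grid()) if s.available]


def _set_params(estimator, params: dict, seed: int):
    est = estimator
    if params:
        est.set_params(**params)
    return est


def tune_and_fit(
    spec: ModelSpec,
    X: pd.DataFrame,
    y: np.ndarray,
    seed: int = 0,
    cv_folds: int = 5,
) -> FittedModel:
    """Stratified ``cv_folds``-fold CV over the spec's grid, refit on all rows.

    The selection metric is AUROC averaged over folds; ties keep the earliest
    candidate in grid order (strongest regularization / simplest model).
    An empty grid skips tuning and fits directly.
    """
    if spec.make_estimator is None:
        raise ModelUnavailableError(f"model {spec.name!r} is not available: {spec.note}")
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError(f"y must contain both classes, got {classes}")

    candidates = spec.candidates()
    chosen: dict = {}
    if candidates:
        skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        folds = list(skf.split(X, y))
        best_score = -np.inf
        for params in candidates:
            scores = []
            for tr, va in folds:
                est = _set_params(spec.make_estimator(seed), params, seed)
                est.fit(X.iloc[tr], y[tr])
                prob = np.asarray(est.predict_proba(X.iloc[va]))[:, 1]
                scores.append(roc_auc_score(y[va], prob))
            score = float(np.mean(scores))
            if score > best_score + 1e-12:
                best_score, chosen = score, params
    est = _set_params(spec.make_estimator(seed), chosen, seed)
    est.fit(X, y)
    return FittedModel(
        spec_name=spec.name,
        chosen_params=dict(chosen),
        estimator=est,
        feature_names=list(X.columns),
        importance=spec.importance,
    )


def _coef_importance(model: FittedModel, genes: list[str]) -> pd.Series:
    est = model.estimator
    clf = est.named_steps["clf"] if isinstance(est, Pipeline) else est
    coef = np.ravel(clf.coef_)
    by_name = dict(zip(model.feature_names, np.abs(coef)))
    missing = [g for g in genes if g not in by_name]
    if missing:
        raise KeyError(f"genes absent from model features: {missing}")
    return pd.Series({g: float(by_name[g]) for g in genes}, name=model.spec_name)


def _permutation_importance(
    model: FittedModel,
    genes: list[str],
    X: pd.DataFrame,
    y: np.ndarray,
    n_repeats: int,
    seed: int,
) -> pd.Series:
    missing = [g for g in genes if g not in X.columns]
    if missing:
        raise KeyError(f"genes absent from model features: {missing}")
    rng = np.random.default_rng(seed)
    y = np.asarray(y)
    base = roc_auc_score(y, model.predict_proba1(X))
    out = {}
    Xp = X.copy()
    for g in genes:
        original = Xp[g].to_numpy().copy()
        drops = []
        for _ in range(n_repeats):
            Xp[g] = rng.permutation(original)
            drops.append(base - roc_auc_score(y, model.predict_proba1(Xp)))
        Xp[g] = original
        out[g] = max(0.0, float(np.mean(drops)))
    return pd.Series(out, name=model.spec_name)


def gene_importance(
    model: FittedModel,
    genes: list[str],
    X: pd.DataFrame | None = None,
    y: np.ndarray | None = None,
    n_repeats: int = 5,
    seed: int = 0,
) -> pd.Series:
    """Non-negative importance score per candidate gene (clinical never scored).

    Linear models use |standardized coefficient|; tree ensembles use seeded
    permutation importance (AUROC drop over ``n_repeats`` shuffles, negatives
    floored at 0) evaluated on the supplied ``X, y``.
    """
    if model.importance == "coef":
        return _coef_importance(model, genes)
    if X is None or y is None:
        raise ValueError("permutation importance requires X and y")
    return _permutation_importance(model, genes, X, y, n_repeats, seed)
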