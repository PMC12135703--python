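"""Stage 1 of the stability-driven ranking: the prediction check.

Every (preprocessing pipeline, model) cell is scored by inner k-fold
cross-validation repeated over several independent development/test
partitions of the cohort.  Models whose cross-validated AUROC falls below a
simple reference model (ordinary logistic regression by default) are
filtered out before any importance is interpreted: a model that predicts
poorly is unlikely to capture the signal its importances would be read from.

The retention rule is deliberately forgiving of preprocessing uncertainty:
a model whose grand-mean AUROC is slightly below the reference is still kept
if at least one preprocessing pipeline lifts it above the reference, since in
that case the preprocessing perturbation alone outweighs the model gap.

Leakage discipline: for every fold evaluation, preprocessing statistics and
hyperparameter tuning see only the training-fold rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score, average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from .models import ModelSpec, tune_and_fit
from .preprocess import CtMatrix, PreprocessPipeline
from .synthetic import SyntheticCohort

__all__ = [
    "SplitPlan",
    "PerfSummary",
    "FilterResult",
    "make_splits",
    "evaluate_grid",
    "prediction_filter",
]


@dataclass(frozen=True)
class SplitPlan:
    """Repeated stratified development/test partitions with inner CV folds.

    ``splits[r]`` is a pair of positional row-index arrays (development, test)
    partitioning all rows; ``inner_fold_ids[r]`` assigns each development row
    of repeat ``r`` to one of ``inner_folds`` stratified folds.
    """

    n_repeats: int
    inner_folds: int
    test_fraction: float
    seed: int
    splits: tuple = ()
    inner_fold_ids: tuple = ()

    def __post_init__(self) -> None:
        for dev, test in self.splits:
            if np.intersect1d(dev, test).size:
                raise ValueError("development and test sets overlap")


def make_splits(
    n_rows: int,
    outcome: np.ndarray,
    n_repeats: int = 10,
    test_fraction: float = 0.25,
    inner_folds: int = 4,
    seed: int = 0,
) -> SplitPlan:
    """Build the repeated development/test split plan (deterministic in seed)."""
    outcome = np.asarray(outcome)
    counts = np.bincount(outcome)
    if (counts[counts > 0] < inner_folds).any() or counts.size < 2:
        raise ValueError("a class is too small to stratify into the inner folds")
    rows = np.arange(n_rows)
    splits, fold_ids = [], []
    for r in range(n_repeats):
        dev, test = train_test_split(
            rows,
            test_size=test_fraction,
            stratify=outcome,
            random_state=seed * 1000 + r,
        )
        dev = np.sort(dev)
        test = np.sort(test)
        skf = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed * 1000 + r)
        ids = np.empty(dev.size, dtype=int)
        for k, (_, fold) in enumerate(skf.split(dev, outcome[dev])):
            ids[fold] = k
        splits.append((dev, test))
        fold_ids.append(ids)
    return SplitPlan(
        n_repeats=n_repeats,
        inner_folds=inner_folds,
        test_fraction=test_fraction,
        seed=seed,
        splits=tuple(splits),
        inner_fold_ids=tuple(fold_ids),
    )


@dataclass
class PerfSummary:
    """Fold-level performance records for every (pipeline, model) cell.

    ``records`` is tidy: one row per (pipeline, model, repeat, fold) with
    auroc / auprc / accuracy columns.
    """

    records: pd.DataFrame

    def cell_means(self, metric: str = "auroc") -> pd.DataFrame:
        """Per-(pipeline, model) mean of a metric over all fold evaluations."""
        out = (
            self.records.groupby(["pipeline", "model"], sort=False)[metric]
            .mean()
            .reset_index()
        )
        return out.rename(columns={metric: f"mean_{metric}"})

    def summary_table(self) -> pd.DataFrame:
        """Tidy summary: mean and inner-95% quantiles per cell and metric."""
        rows = []
        for metric in ("auroc", "auprc", "accuracy"):
            grp = self.records.groupby(["pipeline", "model"], sort=False)[metric]
            agg = grp.agg(
                mean="mean",
                q2_5=lambda s: s.quantile(0.025),
                q97_5=lambda s: s.quantile(0.975),
            ).reset_index()
            agg.insert(2, "metric", metric)
            rows.append(agg)
        return pd.concat(rows, ignore_index=True)

    def model_grand_means(self, metric: str = "auroc") -> pd.Series:
        """Mean of per-pipeline cell means, per model."""
        cells = self.cell_means(metric)
        return cells.groupby("model", sort=False)[f"mean_{metric}"].mean()

    def pipeline_ranges(self, metric: str = "auroc") -> pd.Series:
        """Per model: range (max - min) of its per-pipeline mean AUROCs."""
        cells = self.cell_means(metric)
        grp = cells.groupby("model", sort=False)[f"mean_{metric}"]
        return grp.max() - grp.min()

    def gaps_to_best(self, metric: str = "auroc") -> pd.Series:
        """Per model: grand-mean gap to the best-performing model."""
        grand = self.model_grand_means(metric)
        return grand.max() - grand


def evaluate_grid(
    cohort: SyntheticCohort | tuple,
    pipelines: list[PreprocessPipeline],
    specs: list[ModelSpec],
    plan: SplitPlan,
    clinical_vars: list[str] | None = None,
    tune_folds: int = 5,
    seed: int = 0,
) -> PerfSummary:
    """Score every (pipeline, model) cell over every repeat and inner fold.

    ``cohort`` is a :class:`SyntheticCohort` or an ``(ct, clinical, outcome)``
    triple.  For each fold evaluation the pipeline is fit on the training
    folds only, the model is tuned (inner 5-fold CV) and refit on the
    training folds, and the held-out fold is scored.  Folds degenerating to a
    single outcome class are skipped with a warning and excluded from means.
    """
    if not pipelines or not specs:
        raise ValueError("need at least one pipeline and one model spec")
    ct, clinical, y = _unpack(cohort)
    clin = _clinical_matrix(clinical, clinical_vars)

    records = []
    for pipe in pipelines:
        for r, (dev, _test) in enumerate(plan.splits):
            fold_ids = plan.inner_fold_ids[r]
            for k in range(plan.inner_folds):
                tr = dev[fold_ids != k]
                va = dev[fold_ids == k]
                if np.unique(y[va]).size < 2 or np.unique(y[tr]).size < 2:
                    warnings.warn(
                        f"degenerate fold (pipeline={pipe.name}, repeat={r}, fold={k}); skipped"
                    )
                    continue
                fitted_pipe = pipe.fit(ct.subset_rows(tr))
                X_tr = _join(fitted_pipe.transform(ct.subset_rows(tr)), clin.iloc[tr])
                X_va = _join(fitted_pipe.transform(ct.subset_rows(va)), clin.iloc[va])
                for spec in specs:
                    model = tune_and_fit(spec, X_tr, y[tr], seed=seed, cv_folds=tune_folds)
                    prob = model.predict_proba1(X_va)
                    records.append(
                        {
                            "pipeline": pipe.name,
                            "model": spec.name,
                            "repeat": r,
                            "fold": k,
                            "auroc": roc_auc_score(y[va], prob),
                            "auprc": average_precision_score(y[va], prob),
                            "accuracy": accuracy_score(y[va], prob >= 0.5),
                        }
                    )
    return PerfSummary(records=pd.DataFrame.from_records(records))


@dataclass
class FilterResult:
    """Outcome of the reference-model prediction filter."""

    kept: list[str]
    dropped: list[str]
    reference_model: str
    reference_grand_mean: float
    reasons: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "kept": self.kept,
            "dropped": self.dropped,
            "reference_model": self.reference_model,
            "reference_grand_mean": self.reference_grand_mean,
            "reasons": self.reasons,
        }


def prediction_filter(
    perf: PerfSummary | pd.DataFrame,
    reference_model: str = "logistic",
) -> FilterResult:
    """Keep models not outperformed by the reference model.

    A model is kept iff its grand-mean AUROC (mean of per-pipeline means) is
    >= the reference's grand mean, OR at least one of its per-pipeline mean
    AUROCs exceeds the reference's grand mean.  The reference is always kept.

    ``perf`` may be a :class:`PerfSummary` or a tidy DataFrame with columns
    (pipeline, model, mean_auroc).
    """
    cells = perf.cell_means("auroc") if isinstance(perf, PerfSummary) else perf.copy()
    if reference_model not in set(cells["model"]):
        raise ValueError(f"reference model {reference_model!r} not present")
    grand = cells.groupby("model", sort=False)["mean_auroc"].mean()
    best_pipe = cells.groupby("model", sort=False)["mean_auroc"].max()
    ref = float(grand[reference_model])

    kept, dropped, reasons = [], [], {}
    for model in grand.index:
        if model == reference_model:
            kept.append(model)
            reasons[model] = "reference model (always kept)"
        elif grand[model] >= ref:
            kept.append(model)
            reasons[model] = (
                f"grand-mean AUROC {grand[model]:.4f} >= reference {ref:.4f}"
            )
        elif best_pipe[model] > ref:
            kept.append(model)
            reasons[model] = (
                f"best pipeline mean {best_pipe[model]:.4f} > reference {ref:.4f} "
                f"despite grand mean {grand[model]:.4f}"
            )
        else:
            dropped.append(model)
            reasons[model] = (
                f"all pipeline means <= reference grand mean {ref:.4f} "
                f"(grand mean {grand[model]:.4f})"
            )
    return FilterResult(
        kept=kept,
        dropped=dropped,
        reference_model=reference_model,
        reference_grand_mean=ref,
        reasons=reasons,
    )


def _unpack(cohort):
    if isinstance(cohort, SyntheticCohort):
        return cohort.ct, cohort.clinical, np.asarray(cohort.outcome)
    ct, clinical, y = cohort
    return ct, clinical, np.asarray(y)


def _clinical_matrix(clinical: pd.DataFrame, clinical_vars: list[str] | None) -> pd.DataFrame:
    if clinical_vars is None:
        clinical_vars = [c for c in clinical.columns if c not in ("outcome", "prostate_volume")]
    missing = [c for c in clinical_vars if c not in clinical.columns]
    if missing:
        raise KeyError(f"clinical covariates missing: {missing}")
    return clinical[clinical_vars].astype(float)


def _join(expr: pd.DataFrame, clin: pd.DataFrame) -> pd.DataFrame:
    clin = clin.copy()
    clin.index = expr.index
    return pd.concat([expr, clin], axis=1)
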