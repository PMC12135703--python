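"""Internal validation: panel-size sweep over ranking modes.

For each development/test repeat, each preprocessing pipeline, each kept
model, each ranking mode, and each panel size k, the top-k genes (per the
ranking derived from *that repeat's* development rows only) plus the
clinical covariates are used to retrain the model on the development rows
and score the held-out test rows.  Averaging over repeats gives the sweep
surface used to confirm the stability-selected panel size.

Rankings are always taken from the per-repeat slice of the rank tensor —
never from the pooled tensor — so the sweep's test AUROCs carry no
selection leakage from their own test rows.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score, average_precision_score, roc_auc_score

from .models import ModelSpec, tune_and_fit
from .prediction_check import SplitPlan, _clinical_matrix, _join, _unpack
from .preprocess import PreprocessPipeline
from .stability import RankTensor

__all__ = ["panel_size_sweep", "best_k_report"]

MODES = ("pcs_ensembled", "model_ensembled", "model_specific")


def _repeat_rankings(tensor: RankTensor, r: int, mode: str) -> dict:
    """Gene order (best first) per stratum, from repeat r's tensor slice only."""
    v = tensor.values[:, :, r, :]  # (P, M, G)
    genes = np.asarray(tensor.genes)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if mode == "pcs_ensembled":
            mean = np.nanmean(v, axis=(0, 1))
            return {None: genes[np.argsort(mean, kind="stable")]}
        if mode == "model_ensembled":
            mean = np.nanmean(v, axis=1)  # (P, G)
            return {
                p: genes[np.argsort(mean[i], kind="stable")]
                for i, p in enumerate(tensor.pipelines)
            }
        if mode == "model_specific":
            return {
                (p, m): genes[np.argsort(v[i, j], kind="stable")]
                for i, p in enumerate(tensor.pipelines)
                for j, m in enumerate(tensor.models)
            }
    raise ValueError(f"unknown ranking mode {mode!r}")


def _lookup(rankings: dict, mode: str, pipeline: str, model: str):
    if mode == "pcs_ensembled":
        return rankings[None]
    if mode == "model_ensembled":
        return rankings[pipeline]
    return rankings[(pipeline, model)]


def panel_size_sweep(
    cohort,
    plan: SplitPlan,
    tensor: RankTensor,
    kept_models: list[ModelSpec],
    pipelines: list[PreprocessPipeline],
    k_grid: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 10, 12, 15, 17, 20, 25, 30, 40, 54),
    modes: tuple[str, ...] = ("pcs_ensembled",),
    clinical_vars: list[str] | None = None,
    tune_folds: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean test AUROC/AUPRC/accuracy per (pipeline, model, mode, k).

    ``k = 0`` is permitted and evaluates the clinical-covariates-only model.
    Returns a tidy DataFrame averaged over repeats.
    """
    ct, clinical, y = _unpack(cohort)
    clin = _clinical_matrix(clinical, clinical_vars)
    genes = ct.candidate_genes
    if any(k > len(genes) or k < 0 for k in k_grid):
        raise ValueError(f"k_grid must lie within [0, {len(genes)}]")
    for mode in modes:
        if mode not in MODES:
            raise ValueError(f"unknown ranking mode {mode!r}")

    records = []
    for r, (dev, test) in enumerate(plan.splits):
        rankings = {mode: _repeat_rankings(tensor, r, mode) for mode in modes}
        for i, pipe in enumerate(pipelines):
            fitted_pipe = pipe.fit(ct.subset_rows(dev))
            expr_dev = fitted_pipe.transform(ct.subset_rows(dev))
            expr_test = fitted_pipe.transform(ct.subset_rows(test))
            for spec in kept_models:
                for mode in modes:
                    order = _lookup(rankings[mode], mode, pipe.name, spec.name)
                    for k in k_grid:
                        top = list(order[:k])
                        X_dev = _join(expr_dev[top], clin.iloc[dev])
                        X_test = _join(expr_test[top], clin.iloc[test])
                        model = tune_and_fit(
                            spec, X_dev, y[dev], seed=seed, cv_folds=tune_folds
                        )
                        prob = model.predict_proba1(X_test)
                        records.append(
                            {
                                "pipeline": pipe.name,
                                "model": spec.name,
                                "mode": mode,
                                "k": k,
                                "repeat": r,
                                "auroc": roc_auc_score(y[test], prob),
                                "auprc": average_precision_score(y[test], prob),
                                "accuracy": accuracy_score(y[test], prob >= 0.5),
                            }
                        )
    tidy = pd.DataFrame.from_records(records)
    return (
        tidy.groupby(["pipeline", "model", "mode", "k"], sort=False)[
            ["auroc", "auprc", "accuracy"]
        ]
        .mean()
        .reset_index()
    )


def best_k_report(sweep: pd.DataFrame) -> dict:
    """Summaries of the sweep surface.

    Returns a dict with:

    * ``best_k`` — per (pipeline, model, mode): the k maximizing mean AUROC
      and that AUROC;
    * ``range_across_pipelines`` — per (model, mode, k): max - min of mean
      AUROC across pipelines (the preprocessing-robustness diagnostic);
    * ``drop_from_best`` — per row of the sweep: best-k AUROC minus this k's
      AUROC within its (pipeline, model, mode) stratum.
    """
    if sweep.empty:
        raise ValueError("sweep is empty")
    idx = sweep.groupby(["pipeline", "model", "mode"], sort=False)["auroc"].idxmax()
    best = sweep.loc[idx, ["pipeline", "model", "mode", "k", "auroc"]].rename(
        columns={"k": "best_k", "auroc": "best_auroc"}
    )
    grp = sweep.groupby(["model", "mode", "k"], sort=False)["auroc"]
    rng = (grp.max() - grp.min()).reset_index().rename(columns={"auroc": "auroc_range"})
    merged = sweep.merge(
        best, on=["pipeline", "model", "mode"], how="left", validate="many_to_one"
    )
    merged["drop_from_best"] = merged["best_auroc"] - merged["auroc"]
    return {
        "best_k": best.reset_index(drop=True),
        "range_across_pipelines": rng,
        "drop_from_best": merged[
            ["pipeline", "model", "mode", "k", "auroc", "best_k", "drop_from_best"]
        ],
    }
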