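"""Stages 2 and 3: stability-driven gene ranking and panel selection.

For every combination of preprocessing pipeline, prediction-checked model,
and development/test split, the fitted model yields a gene-importance vector
which is converted to ranks (1 = most important, ties share the average
rank).  Stacking these gives a rank *tensor* indexed by
(pipeline, model, repeat); with 4 pipelines, 6 kept models and 10 splits
that is 240 rankings per gene.

Stability metrics summarize each gene's rank distribution over the tensor:
mean rank, rank standard deviation (population convention), and the
proportion of combinations in which the gene lands in the top 5 / 10 / 17.
The final panel keeps genes that are both highly ranked on average
(mean rank < 10 by default) and stably so (top-10 in > 70% of combinations),
then appends the reference gene needed by the assay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .models import ModelSpec, gene_importance, tune_and_fit
from .prediction_check import SplitPlan, _clinical_matrix, _join, _unpack
from .preprocess import PreprocessPipeline

__all__ = [
    "RankTensor",
    "GenePanel",
    "NoStableGenesError",
    "ranks_from_importance",
    "build_rank_tensor",
    "aggregate_ranks",
    "stability_summary",
    "select_panel",
]


class NoStableGenesError(RuntimeError):
    """No gene satisfied both panel-selection criteria."""


def ranks_from_importance(imp: pd.Series) -> pd.Series:
    """Descending-importance ranks with average-tie handling (1 = most important)."""
    if len(imp) == 0:
        raise ValueError("empty importance vector")
    if not np.isfinite(imp.to_numpy(dtype=float)).all():
        raise ValueError("importance scores must be finite")
    return pd.Series(rankdata(-imp.to_numpy(dtype=float), method="average"),
                     index=imp.index, name=imp.name)


@dataclass
class RankTensor:
    """Gene ranks over (pipeline, model, repeat) combinations.

    ``values`` has shape (n_pipelines, n_models, n_repeats, n_genes); failed
    combinations are NaN across their gene slice and excluded from every
    denominator downstream.
    """

    values: np.ndarray
    pipelines: list[str]
    models: list[str]
    genes: list[str]

    def __post_init__(self) -> None:
        p, m, r, g = self.values.shape
        if (p, m, g) != (len(self.pipelines), len(self.models), len(self.genes)):
            raise ValueError("tensor shape inconsistent with axis labels")

    @property
    def n_repeats(self) -> int:
        return self.values.shape[2]

    def flat(self) -> np.ndarray:
        """(n_combinations, n_genes) view, failed combinations included as NaN."""
        return self.values.reshape(-1, self.values.shape[3])

    def n_valid_combinations(self) -> int:
        return int((~np.isnan(self.flat()).any(axis=1)).sum())

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: one row per (pipeline, model, repeat, gene)."""
        rows = []
        for (i, p), (j, m), r in product(
            enumerate(self.pipelines), enumerate(self.models), range(self.n_repeats)
        ):
            for k, g in enumerate(self.genes):
                rows.append((p, m, r, g, self.values[i, j, r, k]))
        return pd.DataFrame(rows, columns=["pipeline", "model", "repeat", "gene", "rank"])


def build_rank_tensor(
    cohort,
    pipelines: list[PreprocessPipeline],
    kept_models: list[ModelSpec],
    plan: SplitPlan,
    clinical_vars: list[str] | None = None,
    tune_folds: int = 5,
    n_permutations: int = 5,
    seed: int = 0,
) -> RankTensor:
    """Fit every (pipeline, model, repeat) combination and record gene ranks.

    Each combination fits on that repeat's development rows under that
    pipeline (gene expression plus clinical covariates), extracts gene
    importance (permutation importance is evaluated on the development rows),
    and converts it to ranks.  Fit failures are warned about and left as NaN.
    """
    if not kept_models:
        raise ValueError("kept_models must be nonempty")
    ct, clinical, y = _unpack(cohort)
    clin = _clinical_matrix(clinical, clinical_vars)
    genes = ct.candidate_genes

    values = np.full(
        (len(pipelines), len(kept_models), plan.n_repeats, len(genes)), np.nan
    )
    for i, pipe in enumerate(pipelines):
        for r, (dev, _test) in enumerate(plan.splits):
            fitted_pipe = pipe.fit(ct.subset_rows(dev))
            X_dev = _join(fitted_pipe.transform(ct.subset_rows(dev)), clin.iloc[dev])
            for j, spec in enumerate(kept_models):
                try:
                    model = tune_and_fit(spec, X_dev, y[dev], seed=seed, cv_folds=tune_folds)
                    imp = gene_importance(
                        model, genes, X=X_dev, y=y[dev],
                        n_repeats=n_permutations, seed=seed + r,
                    )
                except Exception as exc:  # noqa: BLE001 - recorded, combo excluded
                    warnings.warn(
                        f"fit failed (pipeline={pipe.name}, model={spec.name}, "
                        f"repeat={r}): {exc}"
                    )
                    continue
                values[i, j, r] = ranks_from_importance(imp).to_numpy()
    return RankTensor(
        values=values,
        pipelines=[p.name for p in pipelines],
        models=[m.name for m in kept_models],
        genes=genes,
    )


def aggregate_ranks(tensor: RankTensor, mode: str = "pcs_ensembled"):
    """Mean gene ranks under one of three ensembling schemes.

    pcs_ensembled
        one Series: mean over every (pipeline, model, repeat) combination.
    model_ensembled
        DataFrame genes x pipelines: mean over models and repeats per pipeline.
    model_specific
        DataFrame genes x (pipeline, model) MultiIndex: mean over repeats.
    """
    if tensor.n_valid_combinations() == 0:
        raise ValueError("rank tensor has no valid combinations")
    v = tensor.values
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        if mode == "pcs_ensembled":
            return pd.Series(
                np.nanmean(v, axis=(0, 1, 2)), index=tensor.genes, name="mean_rank"
            )
        if mode == "model_ensembled":
            return pd.DataFrame(
                np.nanmean(v, axis=(1, 2)).T, index=tensor.genes, columns=tensor.pipelines
            )
        if mode == "model_specific":
            cols = pd.MultiIndex.from_product(
                [tensor.pipelines, tensor.models], names=["pipeline", "model"]
            )
            flat = np.nanmean(v, axis=2).reshape(-1, len(tensor.genes)).T
            return pd.DataFrame(flat, index=tensor.genes, columns=cols)
    raise ValueError(f"unknown aggregation mode {mode!r}")


def stability_summary(
    tensor: RankTensor, top_m: tuple[int, ...] = (5, 10, 17)
) -> pd.DataFrame:
    """Per-gene stability metrics over all valid combinations.

    Columns: mean_rank, rank_sd (population SD), and prop_top{m} for each m —
    the fraction of valid combinations in which the gene ranked <= m.
    Sorted by mean rank, best first.
    """
    flat = tensor.flat()
    valid = flat[~np.isnan(flat).any(axis=1)]
    if valid.shape[0] == 0:
        raise ValueError("rank tensor has no valid combinations")
    out = pd.DataFrame(
        {
            "mean_rank": valid.mean(axis=0),
            "rank_sd": valid.std(axis=0, ddof=0),
        },
        index=pd.Index(tensor.genes, name="gene"),
    )
    for m in top_m:
        out[f"prop_top{m}"] = (valid <= m).mean(axis=0)
    return out.sort_values("mean_rank")


@dataclass
class GenePanel:
    """An ordered selected-gene panel plus the assay's reference gene.

    ``measured_genes`` counts what the assay must measure: the selected genes
    plus the reference gene needed for normalization.  When the next-best
    gene narrowly misses one criterion, ``extended`` holds the panel with
    that borderline gene appended (the "one more gene" variant).
    """

    genes: list[str]
    reference_gene: str
    thresholds: dict = field(default_factory=dict)
    extended: list[str] | None = None

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("panel genes must be distinct")
        if self.reference_gene in self.genes:
            raise ValueError("reference gene cannot be a panel gene")

    @property
    def measured_genes(self) -> int:
        return len(self.genes) + 1

    def to_dict(self) -> dict:
        return {
            "genes": self.genes,
            "reference_gene": self.reference_gene,
            "measured_genes": self.measured_genes,
            "thresholds": self.thresholds,
            "extended": self.extended,
        }


def select_panel(
    summary: pd.DataFrame,
    reference_gene: str,
    max_mean_rank: float = 10.0,
    min_prop_top10: float = 0.7,
    borderline_slack: float = 0.0,
) -> GenePanel:
    """Select stably important genes: mean rank < threshold AND top-10 proportion
    > threshold (strict inequalities), ordered by mean rank.

    With ``borderline_slack`` > 0, if the best unselected gene meets one
    criterion outright and misses the other by at most the slack, an
    ``extended`` panel including it is also reported.
    """
    if max_mean_rank <= 0 or not (0 <= min_prop_top10 <= 1):
        raise ValueError("invalid selection thresholds")
    s = summary.sort_values("mean_rank")
    selected = s[(s["mean_rank"] < max_mean_rank) & (s["prop_top10"] > min_prop_top10)]
    if selected.empty:
        raise NoStableGenesError(
            f"no gene has mean rank < {max_mean_rank} and prop_top10 > {min_prop_top10}"
        )
    genes = list(selected.index)
    extended = None
    if borderline_slack > 0:
        rest = s.drop(index=genes)
        if len(rest):
            nxt = rest.iloc[0]
            rank_ok = nxt["mean_rank"] < max_mean_rank
            prop_ok = nxt["prop_top10"] > min_prop_top10
            rank_near = nxt["mean_rank"] < max_mean_rank + borderline_slack
            prop_near = nxt["prop_top10"] > min_prop_top10 - borderline_slack
            if (rank_ok and prop_near) or (prop_ok and rank_near):
                extended = genes + [rest.index[0]]
    return GenePanel(
        genes=genes,
        reference_gene=reference_gene,
        thresholds={
            "max_mean_rank": max_mean_rank,
            "min_prop_top10": min_prop_top10,
            "borderline_slack": borderline_slack,
        },
        extended=extended,
    )
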