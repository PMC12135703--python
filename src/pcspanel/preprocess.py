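"""Ct-to-expression preprocessing pipelines.

qPCR instruments report a cycle threshold (Ct) per sample and gene: the
number of amplification cycles needed for fluorescence to exceed background.
Lower Ct means higher expression, and transcripts that never amplify within
the instrument's cycle budget are reported as undetected.  Every model in
this package consumes *expression* values produced by a preprocessing
pipeline that (1) optionally truncates Ct values at a cycle limit,
(2) imputes undetected entries, and (3) normalizes against a designated
reference gene (delta-Ct), optionally followed by per-gene standardization.

Because many of these steps involve judgment calls with no single right
answer, the package treats the pipeline *set* as a perturbation: downstream
gene rankings are stress-tested across all pipelines in the set.  Four
documented defaults are provided by :func:`default_pipeline_set`; users can
register arbitrary additional pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "CtMatrix",
    "DegenerateGeneError",
    "PreprocessPipeline",
    "FittedPipeline",
    "truncate_ct",
    "impute_undetected",
    "delta_ct_normalize",
    "default_pipeline_set",
]


class DegenerateGeneError(ValueError):
    """A gene has no observed (detected) values, so gene-wise imputation is undefined."""


@dataclass
class CtMatrix:
    """Raw cycle-threshold values for samples x genes with an undetected mask.

    Parameters
    ----------
    values
        DataFrame indexed by sample id with one column per gene.  Entries whose
        mask is True (undetected) hold NaN.
    mask
        Boolean DataFrame of the same shape; True marks an undetected entry.
    reference_gene
        Name of the reference (housekeeping) gene column used for delta-Ct
        normalization, e.g. ``KLK3``.
    """

    values: pd.DataFrame
    mask: pd.DataFrame
    reference_gene: str

    def __post_init__(self) -> None:
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if not self.values.columns.equals(self.mask.columns):
            raise ValueError("values and mask columns differ")
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate gene names: {dupes}")
        if self.reference_gene not in self.values.columns:
            raise ValueError(f"reference gene {self.reference_gene!r} not in columns")
        # masked entries must not carry observed values
        self.values = self.values.where(~self.mask)

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)

    @property
    def candidate_genes(self) -> list[str]:
        """All genes except the reference gene."""
        return [g for g in self.values.columns if g != self.reference_gene]

    def subset_rows(self, idx) -> "CtMatrix":
        """Row subset by positional indices (keeps mask aligned)."""
        return CtMatrix(
            self.values.iloc[idx].copy(), self.mask.iloc[idx].copy(), self.reference_gene
        )

    def copy(self) -> "CtMatrix":
        return CtMatrix(self.values.copy(), self.mask.copy(), self.reference_gene)


def truncate_ct(ct: CtMatrix, limit: float) -> CtMatrix:
    """Clamp Ct values at ``limit`` and set undetected entries to ``limit``.

    Any observed value above the limit is replaced by the limit, and every
    undetected entry becomes an observed value equal to the limit (its mask
    flag is cleared).  The output therefore has an empty mask.
    """
    if limit <= 0:
        raise ValueError(f"limit must be positive, got {limit}")
    values = ct.values.clip(upper=limit)
    values = values.where(~ct.mask, other=limit)
    mask = pd.DataFrame(False, index=ct.mask.index, columns=ct.mask.columns)
    return CtMatrix(values, mask, ct.reference_gene)


def impute_undetected(
    ct: CtMatrix, strategy: str, limit: float | None = None
) -> CtMatrix:
    """Fill undetected Ct entries.

    ``limit-fill`` sets every undetected entry to ``limit`` (the instrument's
    cycle budget).  ``per-gene-max-fill`` sets undetected entries of a gene to
    that gene's maximum *observed* Ct, a conservative "as dim as the dimmest
    detected sample" convention.
    """
    if strategy == "limit-fill":
        if limit is None:
            raise ValueError("limit-fill requires a limit")
        fill = pd.DataFrame(limit, index=ct.values.index, columns=ct.values.columns)
    elif strategy == "per-gene-max-fill":
        gene_max = ct.values.max(axis=0, skipna=True)
        dead = gene_max.index[gene_max.isna() & ct.mask.any(axis=0)]
        if len(dead):
            raise DegenerateGeneError(
                f"gene(s) with all values undetected: {list(dead)}"
            )
        fill = pd.DataFrame(
            np.broadcast_to(gene_max.to_numpy(), ct.values.shape),
            index=ct.values.index,
            columns=ct.values.columns,
        )
    else:
        raise ValueError(f"unknown imputation strategy {strategy!r}")
    values = ct.values.where(~ct.mask, other=fill)
    mask = pd.DataFrame(False, index=ct.mask.index, columns=ct.mask.columns)
    return CtMatrix(values, mask, ct.reference_gene)


def delta_ct_normalize(ct: CtMatrix, reference_gene: str | None = None) -> pd.DataFrame:
    """Delta-Ct normalization: expression(s, g) = Ct(s, ref) - Ct(s, g).

    The sign convention makes higher expression correspond to lower Ct.  The
    reference-gene column is dropped from the output.  Requires a complete
    matrix (impute or truncate first).
    """
    ref = reference_gene or ct.reference_gene
    if ref not in ct.values.columns:
        raise ValueError(f"reference gene {ref!r} not present")
    if ct.mask.to_numpy().any() or ct.values.isna().to_numpy().any():
        raise ValueError("delta-Ct requires a complete matrix; impute undetected first")
    expr = ct.values.drop(columns=[ref]).rsub(ct.values[ref], axis=0)
    return expr


@dataclass(frozen=True)
class PreprocessPipeline:
    """A named, deterministic Ct -> expression pipeline.

    Steps run in a fixed order: truncation (if ``ct_limit`` is set), imputation
    of any remaining undetected entries, delta-Ct normalization, and optional
    per-gene standardization.  Standardization statistics are *fit* on the
    development rows passed to :meth:`fit` and reused on any rows passed to
    :meth:`FittedPipeline.transform`, so no test-set information leaks into
    the transform.
    """

    name: str
    ct_limit: float | None = None
    impute: str = "limit-fill"
    impute_limit: float = 40.0
    standardize: bool = False

    def _to_expression(self, ct: CtMatrix) -> pd.DataFrame:
        if self.ct_limit is not None:
            ct = truncate_ct(ct, self.ct_limit)
        if ct.mask.to_numpy().any():
            ct = impute_undetected(ct, self.impute, limit=self.impute_limit)
        return delta_ct_normalize(ct)

    def fit(self, ct_dev: CtMatrix) -> "FittedPipeline":
        expr = self._to_expression(ct_dev)
        if self.standardize:
            mean = expr.mean(axis=0)
            sd = expr.std(axis=0, ddof=0).replace(0.0, 1.0)
        else:
            mean = sd = None
        return FittedPipeline(pipeline=self, mean=mean, sd=sd)

    def fit_transform(self, ct_dev: CtMatrix) -> pd.DataFrame:
        return self.fit(ct_dev).transform(ct_dev)


@dataclass(frozen=True)
class FittedPipeline:
    """A pipeline bound to development-set standardization statistics."""

    pipeline: PreprocessPipeline
    mean: pd.Series | None = None
    sd: pd.Series | None = None

    def transform(self, ct: CtMatrix) -> pd.DataFrame:
        expr = self.pipeline._to_expression(ct)
        if self.pipeline.standardize:
            expr = (expr - self.mean) / self.sd
        return expr


def default_pipeline_set(ct_limit: float = 40.0) -> list[PreprocessPipeline]:
    """The default four-pipeline perturbation set.

    base
        undetected entries filled at the cycle limit, delta-Ct.
    ct-limit-40
        all Ct values (observed and undetected) truncated at the limit, delta-Ct.
    base-gene-max-fill
        undetected entries filled at each gene's maximum observed Ct, delta-Ct.
    ct-limit-40-standardized
        as ct-limit-40, plus per-gene standardization fit on development rows.
    """
    lim = ct_limit
    return [
        PreprocessPipeline(name="base", ct_limit=None, impute="limit-fill", impute_limit=lim),
        PreprocessPipeline(name=f"ct-limit-{lim:g}", ct_limit=lim),
        PreprocessPipeline(
            name="base-gene-max-fill", ct_limit=None, impute="per-gene-max-fill"
        ),
        PreprocessPipeline(
            name=f"ct-limit-{lim:g}-standardized", ct_limit=lim, standardize=True
        ),
    ]
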