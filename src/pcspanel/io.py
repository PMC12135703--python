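"""File I/O and run configuration.

Ct matrices travel as plain CSV with a ``sample_id`` column followed by one
column per gene; undetected entries carry the literal token ``Undetermined``
(the common qPCR export convention) or are left empty.  Clinical tables are
CSV with ``sample_id``, covariate columns and an optional ``outcome``
column.  Run configuration is declarative YAML that round-trips losslessly
and hashes stably, so every output artifact can embed the config hash that
produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .preprocess import CtMatrix

__all__ = [
    "UNDETECTED_TOKEN",
    "CohortJoinError",
    "RunConfig",
    "read_ct_csv",
    "write_ct_csv",
    "read_clinical_csv",
    "align_cohort",
]

UNDETECTED_TOKEN = "Undetermined"


class CohortJoinError(ValueError):
    """Sample ids of the Ct matrix and the clinical table disagree."""


def read_ct_csv(
    path: str | Path,
    reference_gene: str,
    undetected_token: str = UNDETECTED_TOKEN,
) -> CtMatrix:
    """Read a Ct matrix CSV (sample_id + gene columns; token/empty = undetected)."""
    with open(path) as fh:  # pandas mangles duplicate headers, so check raw
        header = fh.readline().rstrip("\n").split(",")
    dupes = [h for h in set(header) if header.count(h) > 1]
    if dupes:
        raise ValueError(f"{path}: duplicate gene names {sorted(dupes)}")
    raw = pd.read_csv(path, dtype=str)
    if "sample_id" not in raw.columns:
        raise ValueError(f"{path}: missing required 'sample_id' column")
    raw = raw.set_index("sample_id")
    mask = raw.isna() | raw.eq(undetected_token)
    cleaned = raw.mask(mask)
    try:
        values = cleaned.astype(float)
    except ValueError:
        for col in cleaned.columns:
            bad = cleaned[col].dropna()[
                pd.to_numeric(cleaned[col].dropna(), errors="coerce").isna()
            ]
            if len(bad):
                raise ValueError(
                    f"{path}: non-numeric Ct value {bad.iloc[0]!r} in column "
                    f"{col!r}, row {bad.index[0]!r}"
                ) from None
        raise
    return CtMatrix(values=values, mask=mask, reference_gene=reference_gene)


def write_ct_csv(
    ct: CtMatrix, path: str | Path, undetected_token: str = UNDETECTED_TOKEN
) -> None:
    out = ct.values.astype(object).where(~ct.mask, other=undetected_token)
    out.index.name = "sample_id"
    out.to_csv(path)


def read_clinical_csv(path: str | Path) -> pd.DataFrame:
    """Read a clinical covariate table (sample_id index, numeric validation)."""
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: missing required 'sample_id' column")
    df = df.set_index("sample_id")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df[col][coerced.isna() & df[col].notna()]
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric value {bad.iloc[0]!r} in column {col!r}, "
                f"row {bad.index[0]!r}"
            )
        df[col] = coerced
    return df


def align_cohort(ct: CtMatrix, clinical: pd.DataFrame):
    """Check sample ids match 1:1; return (ct, clinical, outcome) aligned.

    Raises :class:`CohortJoinError` naming the offending ids otherwise.
    """
    ct_ids = set(ct.sample_ids)
    cl_ids = set(clinical.index)
    if ct_ids != cl_ids:
        only_ct = sorted(ct_ids - cl_ids)[:10]
        only_cl = sorted(cl_ids - ct_ids)[:10]
        raise CohortJoinError(
            f"sample_id mismatch: only in ct.csv {only_ct}; only in clinical.csv {only_cl}"
        )
    clinical = clinical.loc[ct.sample_ids]
    outcome = None
    if "outcome" in clinical.columns:
        outcome = clinical["outcome"].to_numpy(dtype=int)
        clinical = clinical.drop(columns=["outcome"])
    return ct, clinical, outcome


@dataclass
class RunConfig:
    """Declarative configuration for the staged pipeline.

    Every stage's parameters are resolvable from documented defaults; the
    config round-trips through YAML losslessly and hashes stably.
    """

    # inputs: either file paths or a simulation block
    ct_csv: str | None = None
    clinical_csv: str | None = None
    reference_gene: str = "KLK3"
    simulate: dict = field(default_factory=dict)

    # perturbations and models
    ct_limit: float = 40.0
    models: list[str] = field(
        default_factory=lambda: [
            "logistic", "lasso-logistic", "ridge-logistic",
            "elasticnet-logistic", "random-forest", "gbdt",
        ]
    )
    reduced_grids: bool = False

    # split plan
    n_repeats: int = 10
    test_fraction: float = 0.25
    inner_folds: int = 4
    tune_folds: int = 5
    n_permutations: int = 5

    # ranking / selection
    top_m: list[int] = field(default_factory=lambda: [5, 10, 17])
    max_mean_rank: float = 10.0
    min_prop_top10: float = 0.7
    borderline_slack: float = 0.05

    # sweep
    k_grid: list[int] = field(
        default_factory=lambda: [1, 2, 3, 4, 5, 6, 7, 10, 12, 15, 17, 20, 25, 30, 40, 54]
    )
    modes: list[str] = field(default_factory=lambda: ["pcs_ensembled"])

    # final model / evaluation
    clinical_vars: list[str] = field(
        default_factory=lambda: [
            "age", "race", "family_history", "abnormal_dre",
            "prior_negative_biopsy", "psa",
        ]
    )
    include_volume: bool = False
    sensitivity_target: float = 0.95

    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def config_hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]
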