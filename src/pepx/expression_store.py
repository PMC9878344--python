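"""Ingestion and aggregation of gene- and transcript-level TPM tables.

Public expression resources (HPA, GTEx, TCGA, CCLE, ...) export wide
delimited tables: one feature-id column (ENSG or ENST) followed by one column
per tissue subtype, cancer type, cell line, or patient sample.  This module
loads such tables into an :class:`ExpressionTable`, collapses fine-grained
subtypes into main types (e.g. GTEx's 54 tissue subtypes into 31 main tissue
types via per-feature medians), and summarizes multi-sample cohorts into one
TPM per feature with the mean, median, or geometric mean.

Geometric mean convention: cohorts routinely contain zero TPMs, which would
force a plain geometric mean to zero, so the default is the zero-safe
``exp(mean(log1p(x))) - 1`` form; it is monotone, handles zeros gracefully,
and converges to the plain geometric mean for values much greater than 1.
The plain product form is available via ``zero_safe=False``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, IntegrityError, TableParseError
from .proteome_index import strip_version

GENE_LEVEL = "gene"
TRANSCRIPT_LEVEL = "transcript"
LEVELS = (GENE_LEVEL, TRANSCRIPT_LEVEL)

AGGREGATION_METHODS = ("mean", "median", "geometric_mean")

#: Column-1 headers commonly used by public exports for the feature id.
_KNOWN_ID_HEADERS = {"gene_id", "transcript_id", "name", "feature_id", ""}


@dataclass(frozen=True)
class ExpressionDataset:
    """Registry entry describing one expression dataset/subtype source."""

    dataset_id: str
    source: str  # e.g. "HPA", "GTEx", "TCGA", "CCLE", "custom"
    subtype: str = ""
    has_gene_level: bool = False
    has_transcript_level: bool = False

    def __post_init__(self):
        if not (self.has_gene_level or self.has_transcript_level):
            raise ValueError(
                "a dataset must provide gene- or transcript-level data (or both)"
            )


class DatasetRegistry:
    """Unique-id registry of :class:`ExpressionDataset` entries."""

    def __init__(self):
        self._datasets: dict[str, ExpressionDataset] = {}

    def register(self, dataset: ExpressionDataset) -> None:
        if dataset.dataset_id in self._datasets:
            raise IntegrityError(f"duplicate dataset_id {dataset.dataset_id!r}")
        self._datasets[dataset.dataset_id] = dataset

    def __getitem__(self, dataset_id: str) -> ExpressionDataset:
        return self._datasets[dataset_id]

    def __contains__(self, dataset_id: str) -> bool:
        return dataset_id in self._datasets

    def __len__(self) -> int:
        return len(self._datasets)

    def to_json(self, path) -> None:
        payload = [
            {
                "dataset_id": d.dataset_id,
                "source": d.source,
                "subtype": d.subtype,
                "has_gene_level": d.has_gene_level,
                "has_transcript_level": d.has_transcript_level,
            }
            for d in sorted(self._datasets.values(), key=lambda d: d.dataset_id)
        ]
        with open(path, "wt") as fh:
            json.dump(payload, fh, indent=2)


@dataclass
class ExpressionTable:
    """A feature x subtype TPM matrix at gene or transcript level.

    ``data`` is a DataFrame indexed by version-stripped feature ids with one
    float column per subtype.  NaN cells mean "no data for this feature in
    this subtype" and are distinct from TPM 0.
    """

    level: str
    dataset_id: str
    data: pd.DataFrame

    def __post_init__(self):
        if self.level not in LEVELS:
            raise ValueError(f"level must be one of {LEVELS}, got {self.level!r}")
        with np.errstate(invalid="ignore"):
            if (self.data.to_numpy(dtype=float) < 0).any():
                raise ValueError("TPM values must be non-negative")
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique()
            raise IntegrityError(f"duplicate feature id(s): {', '.join(map(str, dupes))}")

    @property
    def subtypes(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    @property
    def features(self) -> list[str]:
        return [str(i) for i in self.data.index]

    def get(self, feature_id: str, subtype: str):
        """TPM for a feature in a subtype, or None when the table has no data.

        Raises :class:`ConfigurationError` for an unknown subtype (a likely
        user error, unlike a feature simply missing from a filtered export).
        """
        if subtype not in self.data.columns:
            raise ConfigurationError(
                f"unknown subtype {subtype!r}; available: {', '.join(self.subtypes)}"
            )
        if feature_id not in self.data.index:
            return None
        value = self.data.at[feature_id, subtype]
        if pd.isna(value):
            return None
        return float(value)

    def to_tsv(self, path) -> None:
        out = self.data.copy()
        out.index.name = f"{self.level}_id"
        out.to_csv(path, sep="\t", float_format="%.6g")


def load_tpm_table(
    path,
    level: str,
    dataset_id: str = "custom",
    id_column: str | None = None,
) -> ExpressionTable:
    """Load a wide TPM table (TSV/CSV, plain or gzip) into an :class:`ExpressionTable`.

    The first column (or ``id_column``) holds feature ids, which are
    version-stripped on ingest.  Non-numeric cells and negative values raise
    :class:`TableParseError` naming the offending cell; duplicate feature ids
    after version-stripping raise :class:`IntegrityError`.
    """
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}, got {level!r}")
    raw = pd.read_csv(path, sep=None, engine="python", dtype=str, compression="infer")
    if raw.shape[1] < 2:
        raise TableParseError(f"{path}: expected an id column plus >=1 value column")

    if id_column is not None:
        if id_column not in raw.columns:
            raise ConfigurationError(
                f"id column {id_column!r} not found; columns: {list(raw.columns)}"
            )
        idc = id_column
    else:
        idc = raw.columns[0]
    raw = raw.set_index(idc)
    raw.index = [strip_version(str(i).strip()) for i in raw.index]

    if pd.Index(raw.index).has_duplicates:
        dupes = pd.Index(raw.index)[pd.Index(raw.index).duplicated()].unique()
        raise IntegrityError(
            f"duplicate feature id(s) after version stripping: "
            f"{', '.join(map(str, dupes[:10]))}"
        )

    values = pd.DataFrame(index=raw.index)
    for col in raw.columns:
        num = pd.to_numeric(raw[col], errors="coerce")
        bad = num.isna() & raw[col].notna() & (raw[col].str.strip() != "")
        if bad.any():
            feature = raw.index[bad.to_numpy().nonzero()[0][0]]
            cell = raw.at[feature, col]
            raise TableParseError(
                f"non-numeric TPM {cell!r} at feature {feature!r}, column {col!r}",
                row=feature,
                column=col,
            )
        if (num < 0).any():
            feature = raw.index[(num < 0).to_numpy().nonzero()[0][0]]
            raise TableParseError(
                f"negative TPM {raw.at[feature, col]!r} at feature {feature!r}, "
                f"column {col!r}",
                row=feature,
                column=col,
            )
        values[col] = num.astype(float)

    return ExpressionTable(level=level, dataset_id=dataset_id, data=values)


@dataclass
class CohortMatrix:
    """A feature x sample TPM matrix for one cohort (e.g. TCGA-SKCM patients)."""

    feature_ids: list
    sample_ids: list
    tpm: np.ndarray

    def __post_init__(self):
        self.tpm = np.asarray(self.tpm, dtype=float)
        if self.tpm.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"TPM matrix shape {self.tpm.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if (self.tpm < 0).any():
            raise ValueError("TPM values must be non-negative")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CohortMatrix":
        return cls(
            feature_ids=[str(i) for i in df.index],
            sample_ids=[str(c) for c in df.columns],
            tpm=df.to_numpy(dtype=float),
        )

    def subset(self, feature_ids: Sequence[str]) -> "CohortMatrix":
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        rows = [pos[f] for f in feature_ids]
        return CohortMatrix(list(feature_ids), list(self.sample_ids), self.tpm[rows])


def geometric_mean(values, zero_safe: bool = True) -> float:
    """Geometric mean of non-negative values.

    Default (``zero_safe``) uses the log1p convention
    ``exp(mean(log1p(x))) - 1``; the plain product form returns 0 whenever
    any value is 0.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("values must be non-empty")
    if (arr < 0).any():
        raise ValueError("values must be non-negative")
    if zero_safe:
        return float(np.expm1(np.mean(np.log1p(arr))))
    with np.errstate(divide="ignore"):
        return float(np.exp(np.mean(np.log(arr))))


def aggregate_samples(
    cohort: CohortMatrix, method: str, zero_safe: bool = True
) -> dict:
    """Summarize a cohort into one TPM per feature.

    ``method`` is ``mean``, ``median`` (even counts: midpoint of the two
    central values), or ``geometric_mean`` (see :func:`geometric_mean`).
    Returns ``{feature_id: TPM}``.
    """
    if cohort.tpm.size == 0:
        raise ValueError("cohort must be non-empty")
    if method == "mean":
        agg = cohort.tpm.mean(axis=1)
    elif method == "median":
        agg = np.median(cohort.tpm, axis=1)
    elif method == "geometric_mean":
        agg = np.array(
            [geometric_mean(row, zero_safe=zero_safe) for row in cohort.tpm]
        )
    else:
        raise ValueError(
            f"unknown aggregation method {method!r}; choose from "
            f"{', '.join(AGGREGATION_METHODS)}"
        )
    return {f: float(v) for f, v in zip(cohort.feature_ids, agg)}


def collapse_subtypes(
    table: ExpressionTable, grouping: Mapping[str, str]
) -> ExpressionTable:
    """Collapse subtypes into main types by per-feature medians.

    ``grouping`` maps every subtype in the table to a main type (e.g. GTEx
    tissue subtypes to main tissue types).  Subtypes missing from the
    grouping raise :class:`ConfigurationError` listing the offenders.
    """
    missing = [s for s in table.subtypes if s not in grouping]
    if missing:
        raise ConfigurationError(
            f"subtypes missing from grouping: {', '.join(missing)}"
        )
    members: dict[str, list[str]] = {}
    for subtype in table.subtypes:
        members.setdefault(grouping[subtype], []).append(subtype)
    out = pd.DataFrame(index=table.data.index)
    for main_type in sorted(members):
        out[main_type] = table.data[members[main_type]].median(axis=1)
    return ExpressionTable(level=table.level, dataset_id=table.dataset_id, data=out)
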