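"""Join peptide-to-proteome lookups with TPM tables.

The central computation: given a query peptide, find every gene (or
transcript) whose protein products contain it, attach each source's TPM for
the requested subtype, and summarize multi-source expression as the total
(sum), median (midpoint for even counts), and maximum TPM.

At gene level a *scaled TPM* is additionally computed per source gene::

    scaled_tpm = TPM * n_containing / n_total

where ``n_containing`` is the number of the gene's proteins that contain the
peptide and ``n_total`` the number of proteins the gene encodes.  This
down-weights genes in which the peptide is isoform-specific.  No transcript
analogue exists (the formula counts proteins per gene), so at transcript
level the scaled columns are left empty.

Sources present in the proteome but absent from the expression table are
"no data" (public tables often filter unexpressed features): by default they
are excluded from the summaries and counted in ``n_sources_without_data``;
``absent_as_zero=True`` treats them as TPM 0 instead.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    NoExpressionDataError,
    PeptideLengthError,
    PeptideValidationError,
)
from .expression_store import ExpressionTable, GENE_LEVEL, LEVELS, TRANSCRIPT_LEVEL
from .proteome_index import PeptideIndex

#: Peptide-level summary methods over multiple sources.
SUMMARY_METHODS = ("total", "median", "maximum")

#: Per-peptide annotation outcomes.
STATUS_OK = "ok"
STATUS_NOT_FOUND = "not_found"
STATUS_NO_DATA = "no_expression_data"
STATUS_INVALID_LENGTH = "invalid_length"
STATUS_INVALID_PEPTIDE = "invalid_peptide"

#: Fixed column order of the batch report.
REPORT_COLUMNS = (
    "peptide",
    "status",
    "level",
    "subtype",
    "source_ids",
    "source_tpms",
    "source_counts",
    "total_tpm",
    "median_tpm",
    "max_tpm",
    "total_scaled_tpm",
    "n_sources_without_data",
)


def scaled_tpm(tpm: float, n_containing: int, n_total: int) -> float:
    """Gene TPM scaled by the fraction of the gene's proteins containing the peptide."""
    if tpm < 0:
        raise ValueError("tpm must be non-negative")
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not (1 <= n_containing <= n_total):
        raise ValueError(
            f"n_containing ({n_containing}) must be in [1, n_total={n_total}]"
        )
    return tpm * n_containing / n_total


def aggregate(values: Sequence[float], method: str) -> float:
    """Summarize per-source TPMs: ``total`` (sum), ``median`` (midpoint for
    even counts), or ``maximum``."""
    if len(values) == 0:
        raise NoExpressionDataError("peptide has no expression data")
    arr = np.asarray(values, dtype=float)
    if (arr < 0).any():
        raise ValueError("TPM values must be non-negative")
    if method == "total":
        return float(arr.sum())
    if method == "median":
        return float(np.median(arr))
    if method == "maximum":
        return float(arr.max())
    raise ValueError(
        f"unknown method {method!r}; choose from {', '.join(SUMMARY_METHODS)}"
    )


@dataclass(frozen=True)
class SourceExpression:
    """Expression of one source feature (gene or transcript) of a peptide.

    ``tpm`` is None when the expression table has no entry for the feature.
    ``multiplicity`` is the number of occurrences credited to this source
    (1 unless multiplicity weighting was requested).
    """

    feature_id: str
    level: str
    tpm: float | None
    n_containing: int | None = None
    n_total: int | None = None
    scaled_tpm: float | None = None
    multiplicity: int = 1


@dataclass
class PeptideExpression:
    """Per-query result: status, per-source TPMs, and summaries."""

    peptide: str
    subtype: str
    level: str
    status: str
    sources: list = field(default_factory=list)
    total_tpm: float | None = None
    median_tpm: float | None = None
    max_tpm: float | None = None
    total_scaled_tpm: float | None = None
    n_sources_without_data: int = 0


def validate_peptide_string(peptide: str) -> None:
    """Require a non-empty uppercase alphabetic peptide.

    Lowercase input is rejected rather than silently folded, to avoid
    masking I/L or case confusion in user-supplied lists.
    """
    if not peptide or not peptide.isalpha():
        raise PeptideValidationError(
            f"peptide must be a non-empty amino-acid string, got {peptide!r}"
        )
    if peptide != peptide.upper():
        raise PeptideValidationError(
            f"peptide must be uppercase, got {peptide!r}"
        )


def count_multiplicity(index: PeptideIndex, peptide: str) -> dict:
    """Occurrence count of ``peptide`` within each protein containing it."""
    counts: Counter = Counter(o.protein_id for o in index.lookup(peptide))
    return dict(sorted(counts.items()))


def annotate_peptide(
    index: PeptideIndex,
    table: ExpressionTable,
    peptide: str,
    subtype: str,
    level: str,
    *,
    absent_as_zero: bool = False,
    multiplicity: bool = False,
) -> PeptideExpression:
    """Annotate one peptide with per-source and aggregated expression.

    Returns a :class:`PeptideExpression`; a peptide absent from the proteome
    yields status ``not_found`` (distinct from expressed-at-zero), and a
    peptide whose sources all lack table entries yields
    ``no_expression_data`` unless ``absent_as_zero`` is set.

    With ``multiplicity=True`` a source's contribution is weighted by the
    number of occurrences of the peptide in the source's proteins; by
    default repeated occurrences within a protein count once.
    """
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}, got {level!r}")
    if table.level != level:
        raise ConfigurationError(
            f"requested {level}-level annotation against a {table.level}-level table"
        )
    if subtype not in table.subtypes:
        raise ConfigurationError(
            f"unknown subtype {subtype!r}; available: {', '.join(table.subtypes)}"
        )
    validate_peptide_string(peptide)

    occurrences = index.lookup(peptide)
    result = PeptideExpression(peptide=peptide, subtype=subtype, level=level,
                              status=STATUS_OK)
    if not occurrences:
        result.status = STATUS_NOT_FOUND
        return result

    per_protein = Counter(o.protein_id for o in occurrences)

    sources: list[SourceExpression] = []
    if level == GENE_LEVEL:
        summary = index.gene_summary(peptide)
        for gene_id, (n_containing, n_total) in summary.items():
            weight = (
                sum(
                    c
                    for p, c in per_protein.items()
                    if index.proteins[p].gene_id == gene_id
                )
                if multiplicity
                else 1
            )
            tpm = table.get(gene_id, subtype)
            if tpm is None and absent_as_zero:
                tpm = 0.0
            scaled = (
                scaled_tpm(tpm, n_containing, n_total) if tpm is not None else None
            )
            sources.append(
                SourceExpression(
                    feature_id=gene_id,
                    level=level,
                    tpm=tpm,
                    n_containing=n_containing,
                    n_total=n_total,
                    scaled_tpm=scaled,
                    multiplicity=weight,
                )
            )
    else:
        per_transcript: Counter = Counter()
        for protein_id, count in per_protein.items():
            per_transcript[index.proteins[protein_id].transcript_id] += count
        for transcript_id in sorted(per_transcript):
            weight = per_transcript[transcript_id] if multiplicity else 1
            tpm = table.get(transcript_id, subtype)
            if tpm is None and absent_as_zero:
                tpm = 0.0
            sources.append(
                SourceExpression(
                    feature_id=transcript_id,
                    level=level,
                    tpm=tpm,
                    multiplicity=weight,
                )
            )

    result.sources = sources
    with_data = [s for s in sources if s.tpm is not None]
    result.n_sources_without_data = len(sources) - len(with_data)
    if not with_data:
        result.status = STATUS_NO_DATA
        return result

    values = [s.tpm * s.multiplicity for s in with_data]
    result.total_tpm = aggregate(values, "total")
    result.median_tpm = aggregate(values, "median")
    result.max_tpm = aggregate(values, "maximum")
    if level == GENE_LEVEL:
        result.total_scaled_tpm = float(
            sum(s.scaled_tpm * s.multiplicity for s in with_data)
        )
    return result


def _report_row(result: PeptideExpression) -> dict:
    sources = result.sources
    counts = ""
    if result.level == GENE_LEVEL:
        counts = ";".join(
            f"{s.n_containing}/{s.n_total}" for s in sources
        )
    return {
        "peptide": result.peptide,
        "status": result.status,
        "level": result.level,
        "subtype": result.subtype,
        "source_ids": ";".join(s.feature_id for s in sources),
        "source_tpms": ";".join(
            "" if s.tpm is None else f"{s.tpm:.4f}" for s in sources
        ),
        "source_counts": counts,
        "total_tpm": result.total_tpm,
        "median_tpm": result.median_tpm,
        "max_tpm": result.max_tpm,
        "total_scaled_tpm": result.total_scaled_tpm,
        "n_sources_without_data": result.n_sources_without_data,
    }


def annotate_batch(
    index: PeptideIndex,
    table: ExpressionTable,
    peptides: Iterable[str],
    subtype: str,
    level: str,
    *,
    absent_as_zero: bool = False,
    multiplicity: bool = False,
) -> pd.DataFrame:
    """Annotate a list of peptides into a tabular report.

    One row per input peptide in input order (duplicates are kept);
    per-row failures (bad length, lowercase input) are flagged in the
    ``status`` column and do not abort the batch.  Batch-level
    misconfiguration (unknown subtype, level mismatch) raises immediately.
    """
    if table.level != level:
        raise ConfigurationError(
            f"requested {level}-level annotation against a {table.level}-level table"
        )
    if subtype not in table.subtypes:
        raise ConfigurationError(
            f"unknown subtype {subtype!r}; available: {', '.join(table.subtypes)}"
        )
    rows = []
    for peptide in peptides:
        try:
            result = annotate_peptide(
                index,
                table,
                peptide,
                subtype,
                level,
                absent_as_zero=absent_as_zero,
                multiplicity=multiplicity,
            )
            rows.append(_report_row(result))
        except PeptideLengthError:
            rows.append(
                _report_row(
                    PeptideExpression(
                        peptide=peptide, subtype=subtype, level=level,
                        status=STATUS_INVALID_LENGTH,
                    )
                )
            )
        except PeptideValidationError:
            rows.append(
                _report_row(
                    PeptideExpression(
                        peptide=str(peptide), subtype=subtype, level=level,
                        status=STATUS_INVALID_PEPTIDE,
                    )
                )
            )
    return pd.DataFrame(rows, columns=list(REPORT_COLUMNS))


def write_report(report: pd.DataFrame, path_or_buf) -> None:
    """Write a batch report as TSV with floats rendered to 4 decimal places."""
    report.to_csv(path_or_buf, sep="\t", index=False, float_format="%.4f", na_rep="")
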