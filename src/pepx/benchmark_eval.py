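"""Ligand-vs-decoy benchmarking and cohort-concordance statistics.

Evaluates how well expression-derived scores separate eluted MHC ligands
from length-matched decoy peptides drawn at random from the proteome.  For
each tissue/dataset group, ligands are scored by one or more aggregation
metrics (total / median / maximum TPM over source features, plus the
gene-level total scaled TPM), decoys are scored identically, and the ROC AUC
(the Mann-Whitney probability that a random ligand outscores a random decoy,
ties counted half) measures separation; group AUCs are averaged unweighted.

Also provides the paired statistics used to compare metrics (Wilcoxon
signed-rank with an exact small-sample null, Kruskal-Wallis with tie
correction), tie-aware Spearman correlation, patient-vs-cohort concordance,
and the 2-D TPM-range matrix that tabulates how individual samples'
expression bins against a cohort reference.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    CapacityError,
    ConfigurationError,
    DegenerateDataError,
    PeptideLengthError,
    UndefinedCorrelationError,
)
from .expression_store import CohortMatrix, ExpressionTable, aggregate_samples
from .peptide_quant import STATUS_OK, annotate_peptide
from .proteome_index import PeptideIndex

#: Benchmarkable metrics -> the PeptideExpression attribute holding the score.
METRIC_ATTRS = {
    "total": "total_tpm",
    "median": "median_tpm",
    "maximum": "max_tpm",
    "total_scaled": "total_scaled_tpm",
}

#: Switch point between the exact and the normal-approximation Wilcoxon null.
WILCOXON_EXACT_MAX_N = 25


@dataclass
class LigandSet:
    """A named set of (peptide, tissue-or-dataset group) pairs."""

    name: str
    peptides: list  # list[(peptide, group)]

    def __post_init__(self):
        if not self.peptides:
            raise ValueError("ligand set must be non-empty")

    def groups(self) -> list[str]:
        return sorted({g for _, g in self.peptides})

    def peptides_in_group(self, group: str) -> list[str]:
        # once per group even if listed multiple times; input order kept
        return list(dict.fromkeys(p for p, g in self.peptides if g == group))

    @classmethod
    def from_tsv(cls, path, name: str | None = None) -> "LigandSet":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if not {"peptide", "group"}.issubset(df.columns):
            raise ConfigurationError(
                f"{path}: ligand TSV must have columns 'peptide' and 'group'"
            )
        return cls(
            name=name or str(path),
            peptides=list(zip(df["peptide"], df["group"])),
        )

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.peptides, columns=["peptide", "group"]).to_csv(
            path, sep="\t", index=False
        )


@dataclass
class BenchmarkResult:
    """Per-group AUCs for one scoring metric, plus drop statistics."""

    metric_name: str
    level: str
    per_group_auc: dict
    n_pos: dict
    n_neg: dict
    n_dropped_not_found: int = 0
    n_dropped_no_data: int = 0
    mean_auc: float = field(init=False)

    def __post_init__(self):
        aucs = list(self.per_group_auc.values())
        if not aucs:
            raise ValueError("no groups with scoreable ligands")
        if any(not (0.0 <= a <= 1.0) for a in aucs):
            raise ValueError("AUC outside [0, 1]")
        self.mean_auc = float(np.mean(aucs))


def roc_auc(positive_scores, negative_scores) -> float:
    """ROC AUC as the Mann-Whitney probability.

    Equals ``(#pairs with pos > neg + 0.5 * #tied pairs) / (n_pos * n_neg)``,
    computed via midranks so ties are counted half.
    """
    pos = np.asarray(positive_scores, dtype=float)
    neg = np.asarray(negative_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be non-empty")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    return float((r_pos - pos.size * (pos.size + 1) / 2) / (pos.size * neg.size))


def _normalize_length_counts(lengths, n: int) -> dict:
    """Turn a length multiset/mapping into per-length decoy counts summing to n."""
    if isinstance(lengths, Mapping):
        counts = {int(k): int(v) for k, v in lengths.items()}
    else:
        counts = dict(Counter(int(x) for x in lengths))
    if not counts or any(v < 0 for v in counts.values()) or sum(counts.values()) == 0:
        raise ValueError("length multiset must contain at least one length")
    total = sum(counts.values())
    if total == n:
        return counts
    # largest-remainder apportionment keeps the distribution proportional
    quotas = {k: v * n / total for k, v in counts.items()}
    out = {k: int(q) for k, q in quotas.items()}
    remainder = n - sum(out.values())
    by_frac = sorted(
        quotas, key=lambda k: (quotas[k] - int(quotas[k]), k), reverse=True
    )
    for k in by_frac[:remainder]:
        out[k] += 1
    return {k: v for k, v in out.items() if v > 0}


def generate_decoys(
    index: PeptideIndex,
    lengths,
    n: int,
    exclude=frozenset(),
    seed=None,
    distinct_peptides: bool = False,
) -> list[str]:
    """Draw ``n`` distinct length-matched decoy peptides from the proteome.

    ``lengths`` is a multiset (mapping length -> count, or an iterable of
    lengths, e.g. the lengths of a ligand set); the output length
    distribution is proportional to it.  Sampling is uniform over
    (protein, start) occurrence positions by default, so frequent peptides
    are drawn proportionally more often; ``distinct_peptides=True`` samples
    uniformly over distinct peptide strings instead.  No decoy is a member
    of ``exclude``; the draw is reproducible given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    counts = _normalize_length_counts(lengths, n)
    rng = np.random.default_rng(seed)
    exclude = set(exclude)

    decoys: list[str] = []
    for length in sorted(counts):
        need = counts[length]
        pool = index.positions_by_length(length)  # validates the length bound
        chosen: list[str] = []
        chosen_set: set[str] = set()
        if distinct_peptides:
            candidates = sorted(
                {occ.peptide for occ in pool} - exclude
            )
            if len(candidates) < need:
                raise CapacityError(
                    f"only {len(candidates)} distinct {length}-mers available "
                    f"after exclusion; {need} requested"
                )
            order = rng.permutation(len(candidates))
            chosen = [candidates[i] for i in order[:need]]
        else:
            order = rng.permutation(len(pool))
            for i in order:
                pep = pool[i].peptide
                if pep in exclude or pep in chosen_set:
                    continue
                chosen.append(pep)
                chosen_set.add(pep)
                if len(chosen) == need:
                    break
            if len(chosen) < need:
                raise CapacityError(
                    f"proteome supplies only {len(chosen)} distinct {length}-mers "
                    f"after exclusion; {need} requested"
                )
        decoys.extend(chosen)
    return decoys


def _score_peptides(index, table, peptides, subtype, level, absent_as_zero):
    """Annotate peptides and collect metric scores; returns (scored, drops)."""
    scored = []
    n_not_found = 0
    n_no_data = 0
    n_bad_length = 0
    for pep in peptides:
        try:
            res = annotate_peptide(
                index, table, pep, subtype, level, absent_as_zero=absent_as_zero
            )
        except PeptideLengthError:
            n_bad_length += 1
            continue
        if res.status == STATUS_OK:
            scored.append((pep, res))
        elif res.status == "not_found":
            n_not_found += 1
        else:
            n_no_data += 1
    return scored, n_not_found + n_bad_length, n_no_data


def evaluate_metrics(
    index: PeptideIndex,
    table: ExpressionTable,
    ligands: LigandSet,
    tissue_map: Mapping[str, str],
    metrics: Sequence[str],
    level: str,
    seed: int,
    *,
    decoy_ratio: float = 1.0,
    extra_exclude=frozenset(),
    absent_as_zero: bool = False,
) -> list[BenchmarkResult]:
    """Benchmark aggregation metrics on ligands vs length-matched decoys.

    For each ligand group (tissue or dataset), ligands are annotated against
    the expression subtype given by ``tissue_map``, unmatchable peptides are
    dropped and counted, and ``decoy_ratio`` length-matched decoys per
    ligand are drawn from the proteome excluding all ligand peptides (and
    ``extra_exclude``).  Each metric's AUC is computed per group; groups
    without scoreable ligands are skipped with a warning and excluded from
    the unweighted mean.
    """
    bad = [m for m in metrics if m not in METRIC_ATTRS]
    if bad:
        raise ValueError(
            f"unknown metric(s) {bad}; choose from {sorted(METRIC_ATTRS)}"
        )
    if "total_scaled" in metrics and level != "gene":
        raise ConfigurationError("total_scaled is defined at gene level only")
    groups = ligands.groups()
    unmapped = [g for g in groups if g not in tissue_map]
    if unmapped:
        raise ConfigurationError(
            f"ligand group(s) without a subtype mapping: {', '.join(unmapped)}"
        )
    if decoy_ratio <= 0:
        raise ValueError("decoy_ratio must be positive")

    exclude = {p for p, _ in ligands.peptides} | set(extra_exclude)
    group_seeds = np.random.SeedSequence(seed).spawn(len(groups))

    per_metric_auc: dict[str, dict] = {m: {} for m in metrics}
    n_pos: dict[str, dict] = {m: {} for m in metrics}
    n_neg: dict[str, dict] = {m: {} for m in metrics}
    dropped_not_found = 0
    dropped_no_data = 0

    for group, group_seed in zip(groups, group_seeds):
        subtype = tissue_map[group]
        scored_pos, nf, nd = _score_peptides(
            index, table, ligands.peptides_in_group(group), subtype, level,
            absent_as_zero,
        )
        dropped_not_found += nf
        dropped_no_data += nd
        if not scored_pos:
            warnings.warn(
                f"group {group!r} has no scoreable ligands; skipped", stacklevel=2
            )
            continue
        length_counts = Counter(len(p) for p, _ in scored_pos)
        n_decoys = max(1, round(decoy_ratio * len(scored_pos)))
        decoys = generate_decoys(
            index, length_counts, n_decoys, exclude=exclude, seed=group_seed
        )
        scored_neg, _, neg_no_data = _score_peptides(
            index, table, decoys, subtype, level, absent_as_zero
        )
        dropped_no_data += neg_no_data
        if not scored_neg:
            warnings.warn(
                f"group {group!r} has no scoreable decoys; skipped", stacklevel=2
            )
            continue
        for metric in metrics:
            attr = METRIC_ATTRS[metric]
            pos_scores = [getattr(r, attr) for _, r in scored_pos]
            neg_scores = [getattr(r, attr) for _, r in scored_neg]
            per_metric_auc[metric][group] = roc_auc(pos_scores, neg_scores)
            n_pos[metric][group] = len(pos_scores)
            n_neg[metric][group] = len(neg_scores)

    return [
        BenchmarkResult(
            metric_name=f"{metric}_{level}",
            level=level,
            per_group_auc=per_metric_auc[metric],
            n_pos=n_pos[metric],
            n_neg=n_neg[metric],
            n_dropped_not_found=dropped_not_found,
            n_dropped_no_data=dropped_no_data,
        )
        for metric in metrics
    ]


def _signed_rank_exact_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p for the signed-rank statistic, ties allowed.

    Enumerates the null distribution of W+ over all sign assignments by
    dynamic programming on doubled (hence integer) midranks.
    """
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(np.rint(2 * w_plus))
    p_le = counts[: w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return float(min(1.0, 2 * min(p_le, p_ge)))


def paired_wilcoxon(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are discarded; with all differences zero the test is
    undefined and :class:`DegenerateDataError` is raised.  The exact null
    distribution is enumerated for up to 25 nonzero differences (valid with
    tied ranks); larger samples use the normal approximation with tie and
    continuity corrections.  Returns ``(W+, p)`` where ``W+`` is the rank
    sum of positive differences.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be equal-length 1-D arrays with >= 2 pairs")
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        raise DegenerateDataError("all paired differences are zero")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if d.size <= WILCOXON_EXACT_MAX_N:
        p = _signed_rank_exact_p(ranks, w_plus)
    else:
        _, p = stats.wilcoxon(
            d, zero_method="wilcox", correction=True, method="approx",
            alternative="two-sided",
        )
    return w_plus, float(p)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis rank test across >= 2 groups, with tie correction.

    Returns ``(H, p)`` with p from the chi-square approximation on k-1
    degrees of freedom.  When every observation is identical the statistic
    is defined as 0 (p = 1).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group must be non-empty")
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    h = 0.0
    offset = 0
    for a in arrays:
        r = ranks[offset : offset + a.size]
        h += r.sum() ** 2 / a.size
        offset += a.size
    h = 12.0 / (n_total * (n_total + 1)) * h - 3 * (n_total + 1)
    _, tie_counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - (tie_counts**3 - tie_counts).sum() / (n_total**3 - n_total)
    if correction == 0.0:  # all observations identical
        return 0.0, 1.0
    h /= correction
    p = float(stats.chi2.sf(h, len(arrays) - 1))
    return float(h), p


def spearman(x, y) -> float:
    """Tie-aware Spearman correlation: Pearson correlation of midranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be equal-length 1-D arrays with >= 3 values")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedCorrelationError(
            "correlation undefined for a constant vector"
        )
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


@dataclass
class ConcordanceResult:
    """Patient-vs-cohort Spearman correlations per aggregation method."""

    correlations: dict  # method -> spearman r
    n_shared: int


def cohort_concordance(
    patient: Mapping[str, float],
    cohort: CohortMatrix,
    methods: Sequence[str] = ("mean", "median", "geometric_mean"),
) -> ConcordanceResult:
    """Correlate one sample's TPMs against cohort aggregates.

    For each aggregation method the cohort is collapsed to one TPM per
    feature and the Spearman correlation with the patient's TPMs is computed
    over the shared features (>= 3 required).
    """
    shared = sorted(set(patient) & set(cohort.feature_ids))
    if len(shared) < 3:
        raise ValueError(
            f"only {len(shared)} features shared between patient and cohort; "
            "need >= 3"
        )
    sub = cohort.subset(shared)
    patient_values = [float(patient[f]) for f in shared]
    correlations = {}
    for method in methods:
        agg = aggregate_samples(sub, method)
        correlations[method] = spearman(
            patient_values, [agg[f] for f in shared]
        )
    return ConcordanceResult(correlations=correlations, n_shared=len(shared))


def range_matrix(
    patient: Mapping[str, float],
    reference: Mapping[str, float],
    bin_edges: Sequence[float],
) -> np.ndarray:
    """2-D percentage matrix of patient-vs-reference TPM ranges.

    ``bin_edges`` are ascending and start at 0; bin i spans
    ``[edges[i], edges[i+1])`` with the last bin open-ended.  Cell (i, j)
    holds the percentage of shared features whose patient TPM falls in bin i
    and reference TPM in bin j; the matrix sums to 100 (up to rounding).
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.size < 1 or edges[0] != 0 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly ascending and start at 0")
    shared = sorted(set(patient) & set(reference))
    if not shared:
        raise ValueError("patient and reference share no features")
    p = np.asarray([patient[f] for f in shared], dtype=float)
    r = np.asarray([reference[f] for f in shared], dtype=float)
    pi = np.clip(np.searchsorted(edges, p, side="right") - 1, 0, edges.size - 1)
    ri = np.clip(np.searchsorted(edges, r, side="right") - 1, 0, edges.size - 1)
    matrix = np.zeros((edges.size, edges.size), dtype=float)
    for i, j in zip(pi, ri):
        matrix[i, j] += 1
    return matrix / len(shared) * 100.0
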