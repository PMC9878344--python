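"""Desk-scale synthetic proteomes, TPM tables, and planted benchmarks.

Real evaluations of peptide-abundance estimation need a reference proteome
and public expression matrices; this module generates miniature stand-ins
with known ground truth so every pipeline stage is testable offline.

The generated proteomes emulate the two structures that make peptide
quantification ambiguous in real data:

* **isoforms** — each gene's proteins are concatenations of shared "exon"
  segments, so isoforms of one gene share substrings and a peptide may occur
  in only a subset of a gene's proteins;
* **gene families** — designated groups of genes carry a common segment, so
  a peptide can map to several genes at once.

Benchmark builders plant a known expression effect: ligand peptides derive
from genes whose log-TPM is shifted by Δ relative to the background.  When
each scored peptide maps to a single feature with log-normal TPM (σ equal in
both classes), the expected ligand-vs-decoy AUC has the binormal closed form
Φ(Δ / (σ√2)), which serves as an exact oracle for parameter-recovery tests.
Amino acids are drawn uniformly over the 20 canonical letters: realistic
residue frequencies are irrelevant to the contracts under test, and a
uniform alphabet makes accidental cross-gene k-mer collisions vanishingly
rare.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import sqrt
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .benchmark_eval import LigandSet
from .errors import FixtureSpecError
from .expression_store import ExpressionTable
from .proteome_index import (
    CANONICAL_AA,
    PeptideIndex,
    ProteinRecord,
    build_index,
)

_AA = np.array(list(CANONICAL_AA))


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(_AA[rng.integers(0, len(_AA), size=length)])


@dataclass
class FixtureSpec:
    """Parameters of a synthetic proteome + expression fixture.

    ``gene_family_specs`` lists ``(family_size, shared_segment_length)``
    pairs; each family is a group of genes sharing one segment (hence
    sharing peptides).  ``tpm_lognormal`` maps each subtype to the (μ, σ) of
    the log-TPM distribution transcripts are drawn from.  ``planted_effect``
    is the additive shift in log-TPM applied to designated ligand source
    genes by the benchmark builders.
    """

    n_genes: int = 20
    isoform_range: tuple = (1, 4)  # inclusive bounds on isoforms per gene
    segments_per_gene: tuple = (2, 4)  # inclusive bounds, incl. the core segment
    segment_len_range: tuple = (12, 40)  # aa; segments hold many 8-15mers
    gene_family_specs: Sequence = ()  # [(family_size, shared_segment_length)]
    tpm_lognormal: Mapping = field(
        default_factory=lambda: {"tissueA": (1.0, 1.0), "tissueB": (0.5, 1.2)}
    )
    planted_effect: float = 0.0
    seed: int = 0
    kmin: int = 8
    kmax: int = 15
    probe_length: int = 9

    def validate(self) -> None:
        if self.n_genes < 1:
            raise FixtureSpecError("n_genes must be >= 1")
        if self.isoform_range[0] < 1 or self.isoform_range[1] < self.isoform_range[0]:
            raise FixtureSpecError("invalid isoform_range")
        if self.segments_per_gene[0] < 1:
            raise FixtureSpecError("segments_per_gene must be >= 1")
        if self.segment_len_range[0] < self.kmin:
            raise FixtureSpecError(
                f"segment lengths ({self.segment_len_range[0]}) must be >= kmin "
                f"({self.kmin}) so segments contain indexable peptides"
            )
        for size, shared_len in self.gene_family_specs:
            if size < 2:
                raise FixtureSpecError("gene families must have >= 2 members")
            if shared_len < self.kmin:
                raise FixtureSpecError("shared family segments must be >= kmin")
        for subtype, (_, sigma) in self.tpm_lognormal.items():
            if sigma <= 0:
                raise FixtureSpecError(f"sigma must be > 0 for subtype {subtype!r}")
        if not (self.kmin <= self.probe_length <= self.kmax):
            raise FixtureSpecError("probe_length must lie within [kmin, kmax]")


@dataclass
class ProteomeFixture:
    """A generated proteome with probe-peptide ground truth.

    ``probe_truth`` maps each probe peptide to
    ``{gene_id: (n_containing, n_total)}`` computed by a brute-force
    substring scan of the generated sequences — independent of the k-mer
    index that the truth is later checked against.
    """

    spec: FixtureSpec
    records: list
    probe_truth: dict
    gene_transcripts: dict  # gene_id -> [transcript_id, ...]

    @property
    def fasta_text(self) -> str:
        return records_to_fasta(self.records)


def records_to_fasta(records: Sequence[ProteinRecord], width: int = 60) -> str:
    """Render protein records as Ensembl-style pep FASTA text."""
    chunks = []
    for rec in records:
        symbol = f" gene_symbol:{rec.gene_symbol}" if rec.gene_symbol else ""
        chunks.append(
            f">{rec.protein_id} pep gene:{rec.gene_id} "
            f"transcript:{rec.transcript_id}{symbol}\n"
        )
        for i in range(0, len(rec.sequence), width):
            chunks.append(rec.sequence[i : i + width] + "\n")
    return "".join(chunks)


def _scan_truth(probes, records) -> dict:
    """Brute-force per-gene containment counts for each probe peptide."""
    n_total = {}
    for rec in records:
        n_total[rec.gene_id] = n_total.get(rec.gene_id, 0) + 1
    truth = {}
    for probe in probes:
        per_gene: dict[str, int] = {}
        for rec in records:
            if probe in rec.sequence:
                per_gene[rec.gene_id] = per_gene.get(rec.gene_id, 0) + 1
        truth[probe] = {
            g: (c, n_total[g]) for g, c in sorted(per_gene.items())
        }
    return truth


def make_proteome(spec: FixtureSpec) -> ProteomeFixture:
    """Generate a proteome of multi-isoform genes and gene families.

    Every isoform contains its gene's core segment (and any family segment),
    and includes each remaining segment independently with probability 0.6,
    so core-derived probes occur in all of a gene's proteins while
    optional-segment probes occur in a subset.  Probe peptides are cut from
    the core, the first optional segment, and each family segment; their
    ground truth is computed by brute-force scan.  Byte-identical output for
    identical specs.
    """
    spec.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0]))

    gene_ids = [f"ENSG{i + 1:011d}" for i in range(spec.n_genes)]
    symbols = {g: f"SYN{i + 1}" for i, g in enumerate(gene_ids)}

    # per-gene segment lists; index 0 is the always-included core
    segments: dict[str, list[str]] = {}
    always_included: dict[str, set] = {}
    for g in gene_ids:
        n_seg = int(rng.integers(spec.segments_per_gene[0], spec.segments_per_gene[1] + 1))
        lengths = rng.integers(
            spec.segment_len_range[0], spec.segment_len_range[1] + 1, size=n_seg
        )
        segments[g] = [_random_sequence(rng, int(L)) for L in lengths]
        always_included[g] = {0}

    # assign families to leading genes, in spec order
    family_segments: list[tuple[list[str], str]] = []
    cursor = 0
    for size, shared_len in spec.gene_family_specs:
        if cursor + size > spec.n_genes:
            raise FixtureSpecError(
                "gene_family_specs require more genes than n_genes provides"
            )
        members = gene_ids[cursor : cursor + size]
        cursor += size
        shared = _random_sequence(rng, int(shared_len))
        for g in members:
            segments[g].append(shared)
            always_included[g].add(len(segments[g]) - 1)
        family_segments.append((members, shared))

    records: list[ProteinRecord] = []
    protein_counter = 0
    gene_transcripts: dict[str, list[str]] = {g: [] for g in gene_ids}
    for g in gene_ids:
        n_iso = int(rng.integers(spec.isoform_range[0], spec.isoform_range[1] + 1))
        for _ in range(n_iso):
            protein_counter += 1
            include = [
                i in always_included[g] or rng.random() < 0.6
                for i in range(len(segments[g]))
            ]
            seq = "".join(s for i, s in enumerate(segments[g]) if include[i])
            protein_id = f"ENSP{protein_counter:011d}"
            transcript_id = f"ENST{protein_counter:011d}"
            gene_transcripts[g].append(transcript_id)
            records.append(
                ProteinRecord(
                    protein_id=protein_id,
                    transcript_id=transcript_id,
                    gene_id=g,
                    gene_symbol=symbols[g],
                    sequence=seq,
                )
            )

    k = spec.probe_length
    probes: list[str] = []
    for g in gene_ids:
        probes.append(segments[g][0][:k])  # core probe: in every isoform
        optional = [
            i for i in range(1, len(segments[g])) if i not in always_included[g]
        ]
        if optional:
            probes.append(segments[g][optional[0]][:k])
    for _, shared in family_segments:
        probes.append(shared[:k])
    probes = list(dict.fromkeys(probes))

    truth = _scan_truth(probes, records)
    truth = {p: t for p, t in truth.items() if t}  # drop unplaced probes

    return ProteomeFixture(
        spec=spec, records=records, probe_truth=truth,
        gene_transcripts=gene_transcripts,
    )


def make_tpm_tables(
    spec: FixtureSpec,
    proteome: ProteomeFixture,
    shifted_genes=frozenset(),
    shift: float | None = None,
) -> tuple[ExpressionTable, ExpressionTable]:
    """Draw transcript TPMs log-normally and sum them into gene TPMs.

    Gene TPM is by construction the sum of the gene's transcript TPMs, so
    gene/transcript consistency properties are testable exactly.  Genes in
    ``shifted_genes`` get ``shift`` (default: ``spec.planted_effect``) added
    to the log-TPM mean of all their transcripts.
    """
    if shift is None:
        shift = spec.planted_effect
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 1]))
    shifted = set(shifted_genes)

    subtypes = list(spec.tpm_lognormal)
    tx_rows: dict[str, dict[str, float]] = {}
    for g, transcripts in proteome.gene_transcripts.items():
        bump = shift if g in shifted else 0.0
        for t in transcripts:
            tx_rows[t] = {}
            for subtype in subtypes:
                mu, sigma = spec.tpm_lognormal[subtype]
                tx_rows[t][subtype] = float(rng.lognormal(mu + bump, sigma))

    tx_df = pd.DataFrame.from_dict(tx_rows, orient="index")[subtypes].sort_index()
    gene_rows = {
        g: tx_df.loc[transcripts].sum(axis=0)
        for g, transcripts in proteome.gene_transcripts.items()
    }
    gene_df = pd.DataFrame.from_dict(gene_rows, orient="index")[subtypes].sort_index()

    return (
        ExpressionTable(level="gene", dataset_id="synthetic", data=gene_df),
        ExpressionTable(level="transcript", dataset_id="synthetic", data=tx_df),
    )


def expected_auc_from_shift(delta: float, sigma: float) -> float:
    """Binormal closed form: AUC = Φ(Δ / (σ√2)) for equal-σ log-normal scores."""
    return float(ndtr(delta / (sigma * sqrt(2.0))))


def shift_for_target_auc(target_auc: float, sigma: float) -> float:
    """Invert the binormal closed form: Δ = σ√2 · Φ⁻¹(AUC)."""
    return float(sigma * sqrt(2.0) * ndtri(target_auc))


def make_benchmark(
    spec: FixtureSpec,
    proteome: ProteomeFixture,
    ligand_genes: Sequence[str],
    subtype: str,
    group: str = "synthetic_tissue",
) -> tuple[LigandSet, float, set]:
    """Build a ligand set from planted-effect genes, with its expected AUC.

    Ligand peptides are the single-source core probes of ``ligand_genes``
    (multi-source probes are excluded so the binormal oracle stays exact).
    Returns ``(ligand_set, expected_auc, exclude)`` where ``exclude`` is the
    set of every probe-length k-mer of the ligand genes — passed to decoy
    generation so decoys score the unshifted background distribution.
    """
    spec.validate()
    if subtype not in spec.tpm_lognormal:
        raise FixtureSpecError(f"unknown subtype {subtype!r}")
    _, sigma = spec.tpm_lognormal[subtype]
    expected = expected_auc_from_shift(spec.planted_effect, sigma)
    if spec.planted_effect == 0.0 and abs(expected - 0.5) > 1e-12:
        raise FixtureSpecError("zero planted effect must imply expected AUC 0.5")

    ligand_genes = list(ligand_genes)
    ligand_gene_set = set(ligand_genes)
    peptides = []
    for probe, truth in proteome.probe_truth.items():
        if len(truth) == 1:
            (gene,) = truth
            if gene in ligand_gene_set:
                peptides.append((probe, group))
    if not peptides:
        raise FixtureSpecError("no single-source probes found in ligand genes")

    k = spec.probe_length
    exclude = set()
    for rec in proteome.records:
        if rec.gene_id in ligand_gene_set:
            seq = rec.sequence
            for s in range(len(seq) - k + 1):
                exclude.add(seq[s : s + k])

    return LigandSet(name="planted", peptides=peptides), expected, exclude


@dataclass
class PlantedBenchmark:
    """A ready-to-run planted-effect benchmark bundle."""

    proteome: ProteomeFixture
    index: PeptideIndex
    gene_table: ExpressionTable
    transcript_table: ExpressionTable
    ligands: LigandSet
    tissue_map: dict
    exclude: set
    expected_auc: float
    subtype: str


def make_planted_benchmark(
    n_ligands: int = 500,
    target_auc: float = 0.8,
    sigma: float = 1.0,
    seed: int = 0,
    peptide_length: int = 9,
    subtype: str = "cohort",
    group: str = "synthetic_tissue",
) -> PlantedBenchmark:
    """Single-isoform benchmark whose expected AUC is exactly the binormal value.

    ``n_ligands`` ligand genes (log-TPM shifted by Δ = σ√2·Φ⁻¹(target AUC))
    and ``n_ligands`` background genes, one short single-isoform protein
    each; every ligand peptide maps to exactly one gene, and decoys are
    restricted to background genes, so scores on both sides are single
    log-normal draws and the recovered AUC estimates Φ(Δ/(σ√2)).
    """
    delta = shift_for_target_auc(target_auc, sigma) if target_auc != 0.5 else 0.0
    spec = FixtureSpec(
        n_genes=2 * n_ligands,
        isoform_range=(1, 1),
        segments_per_gene=(1, 1),
        segment_len_range=(peptide_length + 20, peptide_length + 30),
        gene_family_specs=(),
        tpm_lognormal={subtype: (1.5, sigma)},
        planted_effect=delta,
        seed=seed,
        kmin=peptide_length,
        kmax=peptide_length,
        probe_length=peptide_length,
    )
    proteome = make_proteome(spec)
    ligand_genes = sorted(proteome.gene_transcripts)[:n_ligands]
    gene_table, tx_table = make_tpm_tables(
        spec, proteome, shifted_genes=ligand_genes
    )
    ligands, expected, exclude = make_benchmark(
        spec, proteome, ligand_genes, subtype, group=group
    )
    index = build_index(proteome.records, kmin=spec.kmin, kmax=spec.kmax)
    return PlantedBenchmark(
        proteome=proteome,
        index=index,
        gene_table=gene_table,
        transcript_table=tx_table,
        ligands=ligands,
        tissue_map={group: subtype},
        exclude=exclude,
        expected_auc=expected,
        subtype=subtype,
    )


def make_family_benchmark(
    n_families: int = 300,
    family_size: int = 3,
    target_auc: float = 0.8,
    sigma: float = 1.0,
    seed: int = 0,
    peptide_length: int = 9,
    subtype: str = "cohort",
    group: str = "synthetic_tissue",
) -> PlantedBenchmark:
    """Benchmark where every ligand maps to a whole gene family.

    Each ligand peptide sits in a segment shared by ``family_size`` genes,
    all carrying the planted log-TPM shift, so its per-gene TPM list has
    several entries and the total / median / maximum aggregates genuinely
    differ.  Decoys come from single-gene background sequences.  Mirrors the
    situation where shared-peptide gene families dominate multi-gene hits.
    """
    delta = shift_for_target_auc(target_auc, sigma)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 10]))

    records: list[ProteinRecord] = []
    gene_transcripts: dict[str, list[str]] = {}
    counter = 0

    def add_gene(gene_id, sequence):
        nonlocal counter
        counter += 1
        tid = f"ENST{counter:011d}"
        pid = f"ENSP{counter:011d}"
        gene_transcripts[gene_id] = [tid]
        records.append(
            ProteinRecord(
                protein_id=pid, transcript_id=tid, gene_id=gene_id,
                gene_symbol=gene_id.replace("ENSG", "FAM"), sequence=sequence,
            )
        )

    ligand_genes: list[str] = []
    peptides = []
    k = peptide_length
    for f in range(n_families):
        shared = _random_sequence(rng, k + 6)
        peptides.append((shared[:k], group))
        for m in range(family_size):
            gene_id = f"ENSG{f * family_size + m + 1:011d}"
            ligand_genes.append(gene_id)
            add_gene(gene_id, _random_sequence(rng, 15) + shared + _random_sequence(rng, 15))

    n_background = n_families
    for b in range(n_background):
        gene_id = f"ENSG{n_families * family_size + b + 1:011d}"
        add_gene(gene_id, _random_sequence(rng, k + 30))

    exclude = set()
    ligand_gene_set = set(ligand_genes)
    for rec in records:
        if rec.gene_id in ligand_gene_set:
            for s in range(len(rec.sequence) - k + 1):
                exclude.add(rec.sequence[s : s + k])

    mu = 1.5
    gene_rows = {}
    tx_rows = {}
    for g, (tid,) in ((g, tuple(t)) for g, t in gene_transcripts.items()):
        bump = delta if g in ligand_gene_set else 0.0
        tpm = float(rng.lognormal(mu + bump, sigma))
        gene_rows[g] = {subtype: tpm}
        tx_rows[tid] = {subtype: tpm}

    gene_table = ExpressionTable(
        level="gene", dataset_id="synthetic",
        data=pd.DataFrame.from_dict(gene_rows, orient="index").sort_index(),
    )
    tx_table = ExpressionTable(
        level="transcript", dataset_id="synthetic",
        data=pd.DataFrame.from_dict(tx_rows, orient="index").sort_index(),
    )

    spec = FixtureSpec(
        n_genes=len(gene_transcripts), isoform_range=(1, 1),
        segments_per_gene=(1, 1), segment_len_range=(k + 20, k + 30),
        tpm_lognormal={subtype: (mu, sigma)}, planted_effect=delta, seed=seed,
        kmin=k, kmax=k, probe_length=k,
    )
    proteome = ProteomeFixture(
        spec=spec, records=records,
        probe_truth=_scan_truth([p for p, _ in peptides], records),
        gene_transcripts=gene_transcripts,
    )
    index = build_index(records, kmin=k, kmax=k)
    return PlantedBenchmark(
        proteome=proteome, index=index, gene_table=gene_table,
        transcript_table=tx_table,
        ligands=LigandSet(name="family", peptides=peptides),
        tissue_map={group: subtype}, exclude=exclude,
        expected_auc=expected_auc_from_shift(delta, sigma), subtype=subtype,
    )


def make_isoform_benchmark(
    n_ligand_genes: int = 400,
    n_background_genes: int = 400,
    isoforms_per_gene: int = 3,
    target_auc: float = 0.8,
    sigma: float = 1.0,
    seed: int = 0,
    peptide_length: int = 9,
    subtype: str = "cohort",
    group: str = "synthetic_tissue",
) -> PlantedBenchmark:
    """Benchmark with isoform-specific ligands.

    Every gene has ``isoforms_per_gene`` transcripts with *independent*
    sequences, so each peptide is specific to one transcript.  For ligand
    genes only the peptide-bearing transcript carries the planted shift; the
    sibling transcripts add unrelated expression that inflates the gene-level
    TPM.  Transcript-level scoring therefore recovers the planted AUC while
    gene-level scoring is diluted — the regime where transcript-level total
    TPM outperforms gene-level total TPM.
    """
    delta = shift_for_target_auc(target_auc, sigma)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 20]))
    k = peptide_length
    mu = 1.5

    records: list[ProteinRecord] = []
    gene_transcripts: dict[str, list[str]] = {}
    tx_rows: dict[str, dict[str, float]] = {}
    gene_rows: dict[str, dict[str, float]] = {}
    peptides = []
    counter = 0
    n_total_genes = n_ligand_genes + n_background_genes

    for gi in range(n_total_genes):
        gene_id = f"ENSG{gi + 1:011d}"
        is_ligand = gi < n_ligand_genes
        gene_transcripts[gene_id] = []
        gene_tpm = 0.0
        for iso in range(isoforms_per_gene):
            counter += 1
            tid = f"ENST{counter:011d}"
            pid = f"ENSP{counter:011d}"
            seq = _random_sequence(rng, k + 26)
            bump = delta if (is_ligand and iso == 0) else 0.0
            tpm = float(rng.lognormal(mu + bump, sigma))
            tx_rows[tid] = {subtype: tpm}
            gene_tpm += tpm
            gene_transcripts[gene_id].append(tid)
            records.append(
                ProteinRecord(
                    protein_id=pid, transcript_id=tid, gene_id=gene_id,
                    gene_symbol=f"ISO{gi + 1}", sequence=seq,
                )
            )
            if is_ligand and iso == 0:
                peptides.append((seq[:k], group))
        gene_rows[gene_id] = {subtype: gene_tpm}

    ligand_gene_set = {f"ENSG{gi + 1:011d}" for gi in range(n_ligand_genes)}
    exclude = set()
    for rec in records:
        if rec.gene_id in ligand_gene_set:
            for s in range(len(rec.sequence) - k + 1):
                exclude.add(rec.sequence[s : s + k])

    gene_table = ExpressionTable(
        level="gene", dataset_id="synthetic",
        data=pd.DataFrame.from_dict(gene_rows, orient="index").sort_index(),
    )
    tx_table = ExpressionTable(
        level="transcript", dataset_id="synthetic",
        data=pd.DataFrame.from_dict(tx_rows, orient="index").sort_index(),
    )
    spec = FixtureSpec(
        n_genes=n_total_genes, isoform_range=(isoforms_per_gene, isoforms_per_gene),
        segments_per_gene=(1, 1), segment_len_range=(k + 20, k + 30),
        tpm_lognormal={subtype: (mu, sigma)}, planted_effect=delta, seed=seed,
        kmin=k, kmax=k, probe_length=k,
    )
    proteome = ProteomeFixture(
        spec=spec, records=records,
        probe_truth=_scan_truth([p for p, _ in peptides], records),
        gene_transcripts=gene_transcripts,
    )
    index = build_index(records, kmin=k, kmax=k)
    return PlantedBenchmark(
        proteome=proteome, index=index, gene_table=gene_table,
        transcript_table=tx_table,
        ligands=LigandSet(name="isoform", peptides=peptides),
        tissue_map={group: subtype}, exclude=exclude,
        expected_auc=expected_auc_from_shift(delta, sigma), subtype=subtype,
    )


# -- hand-crafted two-gene example -------------------------------------------

#: Peptide shared between two genes (two of Gene A's three isoforms plus
#: Gene B's single protein).
PEPTIDE_A = "KLWAEDGYR"
#: Peptide present in all three isoforms of Gene A only.
PEPTIDE_B = "VYTWHGPLM"


@dataclass
class ToyProteome:
    """The worked two-gene example: shared peptides across isoforms and genes."""

    records: list
    gene_table: ExpressionTable
    transcript_table: ExpressionTable
    peptide_a: str
    peptide_b: str
    truth: dict
    subtype: str = "tissue"


def toy_shared_peptide_proteome() -> ToyProteome:
    """Deterministic two-gene fixture.

    Gene A encodes three isoforms built from shared segments; PEPTIDE_A
    occurs in two of them and in Gene B's single protein, while PEPTIDE_B
    occurs in all three Gene A isoforms.  Gene A's TPM is 10 (transcripts
    5 + 3 + 2) and Gene B's is 5, so the expected gene-level annotation of
    PEPTIDE_A is: sources {A: TPM 10, scaled 10·2/3; B: TPM 5, scaled 5},
    total 15, max 10, median 7.5, total scaled ≈ 11.667.
    """
    core_a = "MVYTWHGPLMSERK"  # carries PEPTIDE_B
    seg_a2 = "GGKLWAEDGYRPFN"  # carries PEPTIDE_A
    seg_a3 = "TTSINQCHVRDPEW"
    gene_a, gene_b = "ENSG00000000001", "ENSG00000000002"
    records = [
        ProteinRecord("ENSP00000000101", "ENST00000000101", gene_a, "GENEA",
                      core_a + seg_a2),
        ProteinRecord("ENSP00000000102", "ENST00000000102", gene_a, "GENEA",
                      seg_a2 + core_a),
        ProteinRecord("ENSP00000000103", "ENST00000000103", gene_a, "GENEA",
                      core_a + seg_a3),
        ProteinRecord("ENSP00000000201", "ENST00000000201", gene_b, "GENEB",
                      "MNDSKLWAEDGYRTQCV"),
    ]
    truth = _scan_truth([PEPTIDE_A, PEPTIDE_B], records)
    assert truth[PEPTIDE_A] == {gene_a: (2, 3), gene_b: (1, 1)}
    assert truth[PEPTIDE_B] == {gene_a: (3, 3)}

    gene_table = ExpressionTable(
        level="gene", dataset_id="toy",
        data=pd.DataFrame({"tissue": [10.0, 5.0]}, index=[gene_a, gene_b]),
    )
    transcript_table = ExpressionTable(
        level="transcript", dataset_id="toy",
        data=pd.DataFrame(
            {"tissue": [5.0, 3.0, 2.0, 5.0]},
            index=["ENST00000000101", "ENST00000000102", "ENST00000000103",
                   "ENST00000000201"],
        ),
    )
    return ToyProteome(
        records=records, gene_table=gene_table,
        transcript_table=transcript_table,
        peptide_a=PEPTIDE_A, peptide_b=PEPTIDE_B, truth=truth,
    )
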