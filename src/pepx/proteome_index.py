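"""Exact peptide-to-proteome lookup.

Parses a proteome FASTA with Ensembl-style ``pep`` headers, enumerates every
k-mer in a configurable length window (8-15 by default, matching the lengths
presented by MHC class I), and stores the peptide -> protein -> transcript ->
gene linkage so that any observed peptide can be traced back to all proteins
it may derive from.  The in-memory index mirrors a relational layout with
three tables: genes (id, symbol, number of encoded proteins), proteins
(sequence plus ENSG/ENST/ENSP identifiers), and peptide occurrences
(peptide, protein id, zero-based start offset).

Only the 20 canonical amino acids are indexable by default: k-mers containing
ambiguous residues (X, B, Z, U, O, ``*`` ...) cannot match an observed ligand
exactly, so windows overlapping them are skipped.
"""

from __future__ import annotations

import gzip
import json
import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio.SeqIO.FastaIO import SimpleFastaParser

from .errors import (
    IntegrityError,
    PeptideLengthError,
    ProteomeParseError,
)

#: The 20 canonical amino acids; the default indexable alphabet.
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

DEFAULT_KMIN = 8
DEFAULT_KMAX = 15
#: Hard upper bound on kmax (anticipates MHC class II-sized peptides).
MAX_KMAX = 25

_VERSION_SUFFIX = re.compile(r"\.\d+$")

#: Magic string identifying a serialized index file.
INDEX_MAGIC = "pepx-index"
INDEX_FORMAT_VERSION = 1


def strip_version(identifier: str) -> str:
    """Drop a trailing Ensembl ``.N`` version suffix (``ENSG0001.5`` -> ``ENSG0001``)."""
    return _VERSION_SUFFIX.sub("", identifier)


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with its gene/transcript/protein identifiers.

    Identifiers are stored version-stripped; ``source_header`` keeps the raw
    FASTA description line for provenance.
    """

    protein_id: str
    transcript_id: str
    gene_id: str
    gene_symbol: str = ""
    sequence: str = ""
    source_header: str = ""

    def __post_init__(self):
        if not self.protein_id or not self.transcript_id or not self.gene_id:
            raise ValueError("protein, transcript and gene ids must be non-empty")
        if not self.sequence:
            raise ValueError(f"empty sequence for protein {self.protein_id!r}")


@dataclass(frozen=True)
class GeneEntry:
    """A gene with its symbol and the number of proteins it encodes."""

    gene_id: str
    gene_symbol: str
    n_proteins: int

    def __post_init__(self):
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")


@dataclass(frozen=True, order=True)
class PeptideOccurrence:
    """One occurrence of a peptide within a protein (zero-based start)."""

    peptide: str
    protein_id: str
    start: int


def _parse_ensembl_header(header: str) -> dict:
    """Parse an Ensembl pep-FASTA description line into identifier fields.

    The first whitespace token is the protein id; the remainder carries
    ``key:value`` tokens from which ``gene:`` and ``transcript:`` are
    required and ``gene_symbol:`` optional.
    """
    tokens = header.split()
    if not tokens:
        raise ValueError("empty FASTA header")
    fields = {}
    for tok in tokens[1:]:
        key, sep, value = tok.partition(":")
        if sep and key not in fields:
            fields[key] = value
    missing = [k for k in ("gene", "transcript") if not fields.get(k)]
    if missing:
        raise ValueError(f"header missing required token(s): {', '.join(missing)}")
    return {
        "protein_id": strip_version(tokens[0]),
        "transcript_id": strip_version(fields["transcript"]),
        "gene_id": strip_version(fields["gene"]),
        "gene_symbol": fields.get("gene_symbol", ""),
    }


def _parse_with_pattern(header: str, pattern: re.Pattern) -> dict:
    m = pattern.search(header)
    if m is None:
        raise ValueError(f"header does not match the supplied pattern: {header!r}")
    groups = m.groupdict()
    for key in ("protein_id", "transcript_id", "gene_id"):
        if not groups.get(key):
            raise ValueError(f"pattern did not capture {key!r}")
    return {
        "protein_id": strip_version(groups["protein_id"]),
        "transcript_id": strip_version(groups["transcript_id"]),
        "gene_id": strip_version(groups["gene_id"]),
        "gene_symbol": groups.get("gene_symbol") or "",
    }


def _open_text(path):
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def scan_proteome_fasta(path, header_pattern=None):
    """Parse a proteome FASTA, collecting record-level errors.

    Returns ``(records, errors)`` where ``errors`` is a list of
    ``(line_number, record_id, message)`` tuples.  ``header_pattern`` is an
    optional compiled regex (or pattern string) with named groups
    ``protein_id``, ``transcript_id``, ``gene_id`` and optionally
    ``gene_symbol`` for non-Ensembl FASTA dialects.
    """
    if header_pattern is not None and isinstance(header_pattern, str):
        header_pattern = re.compile(header_pattern)

    with _open_text(path) as handle:
        lines = handle.readlines()
    header_lines = [i + 1 for i, ln in enumerate(lines) if ln.startswith(">")]

    records, errors = [], []
    import io

    for i, (title, seq) in enumerate(SimpleFastaParser(io.StringIO("".join(lines)))):
        line_no = header_lines[i]
        record_id = title.split()[0] if title.split() else "<no id>"
        try:
            if header_pattern is None:
                fields = _parse_ensembl_header(title)
            else:
                fields = _parse_with_pattern(title, header_pattern)
            records.append(
                ProteinRecord(sequence=seq.strip().upper(), source_header=title, **fields)
            )
        except ValueError as exc:
            errors.append((line_no, record_id, str(exc)))
    return records, errors


def parse_proteome_fasta(path, header_pattern=None) -> list[ProteinRecord]:
    """Parse a proteome FASTA (plain or gzip) into :class:`ProteinRecord` s.

    Raises :class:`ProteomeParseError` listing every malformed record with
    its line number.  An empty file yields an empty list.
    """
    records, errors = scan_proteome_fasta(path, header_pattern=header_pattern)
    if errors:
        raise ProteomeParseError(errors)
    return records


@dataclass
class PeptideIndex:
    """k-mer -> occurrence map over a proteome, with gene/protein link tables.

    Built by :func:`build_index`; supports exact lookup, per-gene
    containment summaries, decoy sampling pools, and (de)serialization.
    """

    kmin: int
    kmax: int
    alphabet: frozenset
    proteins: dict  # protein_id -> ProteinRecord
    genes: dict  # gene_id -> GeneEntry
    occurrences: dict  # peptide -> list[PeptideOccurrence], sorted
    _positions_cache: dict = field(default_factory=dict, repr=False)

    # -- queries ---------------------------------------------------------

    def _check_length(self, peptide: str) -> None:
        if not (self.kmin <= len(peptide) <= self.kmax):
            raise PeptideLengthError(
                f"peptide length {len(peptide)} outside accepted range "
                f"[{self.kmin}, {self.kmax}]"
            )

    def lookup(self, peptide: str) -> list[PeptideOccurrence]:
        """All occurrences of ``peptide``, ordered by (protein_id, start).

        Returns an empty list when the peptide is absent from the proteome;
        raises :class:`PeptideLengthError` for out-of-range query lengths.
        """
        self._check_length(peptide)
        return list(self.occurrences.get(peptide, ()))

    def gene_summary(self, peptide: str) -> dict:
        """Map gene_id -> (n_containing, n_total) for genes containing ``peptide``.

        ``n_containing`` counts the gene's distinct proteins that contain the
        peptide at least once; ``n_total`` is the number of proteins the gene
        encodes.  Genes without any containing protein are omitted.
        """
        containing = defaultdict(set)
        for occ in self.lookup(peptide):
            gene_id = self.proteins[occ.protein_id].gene_id
            containing[gene_id].add(occ.protein_id)
        return {
            g: (len(prots), self.genes[g].n_proteins)
            for g, prots in sorted(containing.items())
        }

    def positions_by_length(self, k: int) -> list[PeptideOccurrence]:
        """All occurrences of length-``k`` peptides, deterministically ordered.

        Used as the sampling pool for length-matched decoy generation.
        """
        if not (self.kmin <= k <= self.kmax):
            raise PeptideLengthError(
                f"length {k} outside indexed range [{self.kmin}, {self.kmax}]"
            )
        if k not in self._positions_cache:
            pool = [
                occ
                for pep in sorted(self.occurrences)
                if len(pep) == k
                for occ in self.occurrences[pep]
            ]
            self._positions_cache[k] = pool
        return self._positions_cache[k]

    @property
    def n_proteins(self) -> int:
        return len(self.proteins)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_distinct_peptides(self) -> int:
        return len(self.occurrences)

    # -- serialization ---------------------------------------------------

    def save(self, path) -> None:
        """Serialize to JSON (gzip when the path ends in ``.gz``).

        Only the protein records and parameters are stored; the occurrence
        map is rebuilt on load, which keeps the file compact and guarantees
        index/record consistency.
        """
        payload = {
            "magic": INDEX_MAGIC,
            "format_version": INDEX_FORMAT_VERSION,
            "kmin": self.kmin,
            "kmax": self.kmax,
            "alphabet": "".join(sorted(self.alphabet)),
            "proteins": [
                {
                    "protein_id": r.protein_id,
                    "transcript_id": r.transcript_id,
                    "gene_id": r.gene_id,
                    "gene_symbol": r.gene_symbol,
                    "sequence": r.sequence,
                    "source_header": r.source_header,
                }
                for r in sorted(self.proteins.values(), key=lambda r: r.protein_id)
            ],
        }
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "wt") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "PeptideIndex":
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "rt") as fh:
            payload = json.load(fh)
        if payload.get("magic") != INDEX_MAGIC:
            raise IntegrityError(f"{path}: not a pepx index file")
        if payload.get("format_version") != INDEX_FORMAT_VERSION:
            raise IntegrityError(
                f"{path}: unsupported index format version "
                f"{payload.get('format_version')!r}"
            )
        records = [
            ProteinRecord(
                protein_id=p["protein_id"],
                transcript_id=p["transcript_id"],
                gene_id=p["gene_id"],
                gene_symbol=p.get("gene_symbol", ""),
                sequence=p["sequence"],
                source_header=p.get("source_header", ""),
            )
            for p in payload["proteins"]
        ]
        return build_index(
            records,
            kmin=payload["kmin"],
            kmax=payload["kmax"],
            alphabet=payload["alphabet"],
        )

    def to_peptide2protein_tsv(self, path) -> None:
        """Dump the occurrence table as TSV: peptide, protein_id, start."""
        with open(path, "wt") as fh:
            fh.write("peptide\tprotein_id\tstart\n")
            for pep in sorted(self.occurrences):
                for occ in self.occurrences[pep]:
                    fh.write(f"{pep}\t{occ.protein_id}\t{occ.start}\n")


def build_index(
    records: Sequence[ProteinRecord],
    kmin: int = DEFAULT_KMIN,
    kmax: int = DEFAULT_KMAX,
    alphabet: Iterable[str] = CANONICAL_AA,
) -> PeptideIndex:
    """Enumerate every indexable k-mer of every protein into a :class:`PeptideIndex`.

    Windows overlapping a non-alphabet residue are skipped.  Duplicate
    occurrences within one protein are all stored (their start offsets
    differ); collapsing to per-protein presence happens downstream.
    """
    if kmin < 1:
        raise ValueError("kmin must be >= 1")
    if kmax < kmin:
        raise ValueError(f"kmax ({kmax}) must be >= kmin ({kmin})")
    if kmax > MAX_KMAX:
        raise ValueError(f"kmax must be <= {MAX_KMAX}")
    if not records:
        raise ValueError("records must be non-empty")

    seen = Counter(r.protein_id for r in records)
    dupes = [p for p, c in seen.items() if c > 1]
    if dupes:
        raise IntegrityError(f"duplicate protein id(s): {', '.join(sorted(dupes))}")

    alpha = frozenset(alphabet)
    run_re = re.compile(f"[{''.join(sorted(alpha))}]+")

    occurrences: dict[str, list[PeptideOccurrence]] = {}
    ordered = sorted(records, key=lambda r: r.protein_id)
    for rec in ordered:
        for run in run_re.finditer(rec.sequence):
            a, b = run.span()
            seq = rec.sequence
            for k in range(kmin, min(kmax, b - a) + 1):
                for s in range(a, b - k + 1):
                    pep = seq[s : s + k]
                    occurrences.setdefault(pep, []).append(
                        PeptideOccurrence(pep, rec.protein_id, s)
                    )

    per_gene: dict[str, set] = defaultdict(set)
    symbols: dict[str, str] = {}
    for rec in ordered:
        per_gene[rec.gene_id].add(rec.protein_id)
        symbols.setdefault(rec.gene_id, rec.gene_symbol)
    genes = {
        g: GeneEntry(gene_id=g, gene_symbol=symbols[g], n_proteins=len(prots))
        for g, prots in per_gene.items()
    }

    return PeptideIndex(
        kmin=kmin,
        kmax=kmax,
        alphabet=alpha,
        proteins={r.protein_id: r for r in ordered},
        genes=genes,
        occurrences=occurrences,
    )
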