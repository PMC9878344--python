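# Methods

This note documents the models, conventions, and numerical choices behind
`pepx`, and what the synthetic benchmarks do and do not demonstrate.

## Peptide-to-proteome index

The index enumerates every substring of every protein whose length lies in
`[kmin, kmax]` (default 8–15, the MHC class I presentation range; `kmax` is
configurable up to 25 to cover class II-sized peptides).  The logical schema
mirrors a relational design with three tables — genes (id, symbol, number of
encoded proteins), proteins (sequence plus ENSG/ENST/ENSP ids), and peptide
occurrences (peptide, protein id, zero-based start) — held in memory and
serialized as versioned JSON (only parameters and protein records are
stored; occurrences are rebuilt on load, which keeps files compact and makes
index/record inconsistency impossible).

**Indexable alphabet.** Only the 20 canonical amino acids are enumerated;
k-mer windows overlapping ambiguous residues (X, B, Z, U, O, `*`) are
skipped, because an ambiguous residue cannot match an observed eluted ligand
exactly.  Reference proteomes do not document a standard treatment of such
residues, so this rule is a package choice, and the alphabet is a
`build_index` argument.

**Identifier versions.** Ensembl `.N` version suffixes are stripped on
ingest from both FASTA headers and TPM-table feature ids, so the join works
across release sub-versions; the raw header is kept as provenance.

**Ordering.** Lookup output is sorted by (protein id, start) and every
report writer uses fixed column orders and float formats, so all outputs are
byte-stable across runs.

## Expression tables

TPM tables are wide delimited files (first column feature id, one column per
subtype or sample); the delimiter is sniffed and gzip is transparent.  Cells
must be non-negative numbers; empty cells are "no data".  A feature present
in the proteome but absent from a table is **no data**, distinct from TPM 0:
public exports routinely filter unexpressed features, and the two
interpretations genuinely differ.  By default such sources are excluded from
peptide summaries and counted in `n_sources_without_data`; `absent_as_zero`
flips this.

**Cohort aggregation.** Mean and median are the ordinary definitions (even
counts: midpoint of the two central values — the standard convention, used
consistently for cohort medians, subtype collapsing, and the per-peptide
median).  The geometric mean must handle zero TPMs, which annihilate the
plain product form; the default is

    geomean(x) = exp(mean(log(1 + x))) - 1

which is zero-safe, monotone, satisfies AM ≥ GM, and converges to the plain
geometric mean for values ≫ 1.  The plain form is available via
`zero_safe=False`.

**Subtype collapsing** (e.g. 54 GTEx tissue subtypes → 31 main tissue
types) takes the per-feature median over member subtypes.  Whether public
portals compute such medians over subtype aggregates or pooled samples is
generally unstated; the subtype-median definition is implemented because it
is what the grouping file expresses.

## Peptide expression

At gene level, sources are the distinct genes containing the peptide; each
carries its TPM, the containment counts `n_containing/n_total`, and

    scaled_tpm = TPM * n_containing / n_total,

which down-weights genes where the peptide is isoform-specific.  Scaled TPM
has no transcript analogue (it counts proteins per gene), so transcript-level
output leaves those columns empty; the total scaled TPM is the sum of
per-gene scaled values.  Summaries satisfy, by construction,
`total >= max >= median >= 0` and `total_scaled <= total` with equality iff
every source gene has all its proteins containing the peptide.

**Multiplicity.** A peptide occurring several times within one protein
counts once by default (presence/absence); an explicit `multiplicity`
option weights a source's contribution by its occurrence count instead.
The default reflects that repeated in-protein occurrences are rare in real
proteomes and presence is what MHC presentation requires.

**Input hygiene.** Peptide lists are not deduplicated or case-folded
silently; lowercase input raises a validation error to prevent masked I/L
or case confusion.  Batch annotation flags per-row failures in a status
column and never aborts mid-batch.

## Benchmarking

**Decoys** are drawn uniformly over (protein, start) occurrence positions of
the proteome — the simplest reading of "random proteome peptides" — with
length counts proportional to the ligand set's length multiset
(largest-remainder apportionment), excluding all ligand peptides by exact
string match, and deduplicated to distinct peptide strings.  Sampling
uniformly over distinct peptides instead is an option.  The decoy:ligand
ratio defaults to 1:1 (AUC is ratio-insensitive in expectation) and is
configurable.

**AUC** is computed in the Mann–Whitney form via midranks:
`(R_pos - n_pos(n_pos+1)/2) / (n_pos * n_neg)`, identical to the all-pairs
count with ties worth ½.  Group AUCs (per tissue or per dataset, whichever
the ligand set's `group` column encodes) are averaged unweighted; groups
with no scoreable ligands are skipped with a warning.  Peptides absent from
the proteome, or whose sources all lack expression data, are dropped from
scoring and counted — mirroring the fact that real ligand atlases contain
peptides unmappable to any given reference proteome.

**Paired Wilcoxon.**  Zero differences are discarded.  For up to 25 nonzero
differences the exact two-sided p-value is computed by dynamic programming
over sign assignments on doubled midranks — this remains exact in the
presence of tied |differences|, where textbook tables do not apply.  Above
25 the normal approximation with tie and continuity corrections is used
(via scipy).  The statistic reported is W⁺, the positive-rank sum.

**Kruskal–Wallis** uses the rank formula with the standard tie correction;
when every observation is identical the correction denominator vanishes and
H is defined as 0 (p = 1), a degenerate case scipy rejects.

**Spearman** is the Pearson correlation of midranks; it is undefined (and
raises) for constant vectors.

**Range matrix.** Bin edges default to `[0, 1, 10, 100, 1000)` with the last
bin open-ended — decade bins starting at the conventional "expressed"
threshold of 1 TPM; cell (i, j) is the percentage of shared features whose
patient TPM falls in bin i and reference TPM in bin j.

## Synthetic fixtures and planted benchmarks

The generator emulates exactly the structures that make peptide
quantification ambiguous: genes whose isoforms are concatenations of shared
"exon" segments (so a peptide can sit in a subset of a gene's proteins) and
gene families sharing a segment (so a peptide can map to several genes).
Segment lengths default to 12–40 aa so each segment holds many 8–15mers;
residues are uniform over the canonical alphabet — realistic amino-acid
frequencies are irrelevant to the contracts under test, and uniformity makes
accidental cross-gene k-mer collisions vanishingly rare (~n/20⁸ for an
8-mer).  Probe-peptide ground truth is computed by a brute-force substring
scan of the generated sequences, independent of the k-mer index it is later
checked against.  Transcript TPMs are log-normal per subtype and gene TPM is
defined as the sum of the gene's transcript TPMs, making gene/transcript
consistency checks exact.

**Planted-effect benchmarks** shift the log-TPM mean of ligand source genes
by Δ.  When every scored peptide maps to one feature and both classes have
log-normal scores with common σ, the expected AUC is the binormal closed
form Φ(Δ/(σ√2)); the builders invert it to hit a target AUC.  Three designs
are provided:

* *single-source* — one single-isoform gene per ligand; decoys are
  restricted to background genes (all k-mers of ligand genes are excluded
  from the decoy pool), so the closed form is exact and parameter-recovery
  tests can demand |recovered − target| ≤ 0.02 at 2,000 pairs;
* *gene-family* — each ligand sits in a segment shared by a family of
  shifted genes, so total/median/maximum genuinely differ; summing TPMs
  over family members separates best, reproducing the direction of the
  aggregation comparison on real ligand atlases;
* *isoform-specific* — every gene has several independent transcripts and
  only the ligand-bearing transcript carries the shift; gene-level TPM adds
  the sibling transcripts' unrelated expression, so transcript-level total
  TPM outperforms gene-level total TPM, again directionally.

Passing these benchmarks shows the pipeline recovers planted effects and
ranks aggregation strategies correctly under the generative model; it does
**not** certify performance numbers on real eluted-ligand data, which
depend on mass-spectrometry detectability, HLA binding motifs, and
proteome/annotation mismatches that the generator deliberately omits.

## Problem sizes and determinism

The shipped tests and `scripts/acceptance.py` use desk-scale problems chosen
to keep every statistical check well-powered: 100 random proteomes of ≤ 50
proteins for index-oracle equivalence, 10,000 randomized annotations for the
ordering invariants, 1,000 random instances for AUC-oracle equivalence,
5 × 2,000 ligand/decoy pairs for planted-effect recovery (SE of an AUC
estimate ≈ 0.009 at that size), and 2,000 simulated nulls for type-I-error
calibration against the binomial 99% interval.  Every stochastic operation
takes a mandatory seed (numpy `SeedSequence` spawning for per-group
streams); there is no hidden global randomness, and all file outputs are
byte-reproducible given identical inputs and seeds.

## Known limitations

* Exact matching only: no mismatch tolerance, no I/L equivalence classes.
* The embedded index targets desk-scale proteomes (up to a few Mb of
  sequence); a full mammalian proteome at 8–15mers would need an on-disk
  store.
* Expression ingestion trusts the supplied TPMs; no re-quantification,
  normalization, or batch correction is attempted.
* The synthetic generator does not model codon biology, realistic isoform
  structures, HLA binding motifs, or MS detectability (see above).
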