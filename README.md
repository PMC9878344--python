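# pepx — peptide expression annotation

Expression-aware MHC class I ligand and epitope predictors need, for every
candidate peptide, the abundance of the protein(s) the peptide can derive
from.  Getting that number from public RNA-Seq resources is not trivial: the
peptide must first be traced to **all** proteins that contain it (splice
isoforms of one gene, and often several genes of the same gene family), the
TPM values of those sources must be fetched for the right tissue or cohort,
and the multiple values must be aggregated into a single estimate.

`pepx` does this end to end for immunopeptidomics and T-cell epitope
discovery workflows:

* **Exact k-mer lookup** — a proteome FASTA (Ensembl `pep` headers, or any
  dialect via a regex) is enumerated into all 8–15mers, each linked to its
  protein (ENSP), transcript (ENST), and gene (ENSG) with the zero-based
  start position, so `lookup(peptide)` returns every occurrence and
  `gene_summary(peptide)` returns, per gene, how many of its proteins
  contain the peptide.
* **TPM annotation** — wide gene- or transcript-level TPM tables
  (HPA/GTEx/TCGA/CCLE-style exports, TSV/CSV, optionally gzipped) are
  joined to the lookup.  Multi-source expression is summarized as the
  **total** (sum), **median**, and **maximum** TPM over sources, and at gene
  level additionally as the **scaled TPM**

  $$\mathrm{scaled\ TPM} = \mathrm{TPM}\times\frac{n_\text{containing}}{n_\text{total}}$$

  where $n_\text{containing}$ of the gene's $n_\text{total}$ proteins
  contain the peptide.
* **Cohort summarization** — multi-sample cohorts collapse to one value per
  feature by mean, median, or a zero-safe geometric mean
  ($\exp(\overline{\log(1+x)})-1$); fine-grained subtypes collapse to main
  types by per-feature medians.
* **Benchmarking machinery** — length-matched decoy sampling from the
  proteome, ligand-vs-decoy ROC AUC (Mann–Whitney form, ties counted half),
  paired Wilcoxon signed-rank (exact small-sample null), Kruskal–Wallis with
  tie correction, tie-aware Spearman, patient-vs-cohort concordance, and the
  2-D TPM-range matrix.
* **Synthetic fixtures** — generators for proteomes with multi-isoform genes
  and shared-peptide gene families, matched TPM tables (gene TPM = sum of
  transcript TPMs), and ligand/decoy benchmarks with a *planted* log-normal
  expression effect whose expected AUC has the closed form
  $\Phi\!\left(\Delta/(\sigma\sqrt{2})\right)$.

## Worked example

The library ships a deterministic two-gene example: Gene A encodes three
isoforms and Gene B one protein; peptide `KLWAEDGYR` occurs in two of Gene
A's proteins and in Gene B's, while `VYTWHGPLM` occurs in all three Gene A
isoforms only.  Gene A's TPM is 10, Gene B's is 5.

```bash
python - <<'EOF'
from pepx.synthetic_fixtures import toy_shared_peptide_proteome, records_to_fasta
toy = toy_shared_peptide_proteome()
open("proteome.fasta", "w").write(records_to_fasta(toy.records))
toy.gene_table.to_tsv("gene_tpm.tsv")
open("peptides.txt", "w").write("KLWAEDGYR\nVYTWHGPLM\nWWWWWWWW\n")
EOF
pepx build-index --proteome proteome.fasta --out index.json
pepx annotate --index index.json --tpm gene_tpm.tsv --level gene \
              --subtype tissue --peptides peptides.txt
```

prints

```
indexed 4 proteins, 2 genes, 385 distinct peptides (8-15mers) -> index.json
peptide	status	level	subtype	source_ids	source_tpms	source_counts	total_tpm	median_tpm	max_tpm	total_scaled_tpm	n_sources_without_data
KLWAEDGYR	ok	gene	tissue	ENSG00000000001;ENSG00000000002	10.0000;5.0000	2/3;1/1	15.0000	7.5000	10.0000	11.6667	0
VYTWHGPLM	ok	gene	tissue	ENSG00000000001	10.0000	3/3	10.0000	10.0000	10.0000	10.0000	0
WWWWWWWW	not_found	gene	tissue								0
```

Reading the first row: `KLWAEDGYR` maps to two genes; summing their TPMs
gives a total of 15, the maximum is 10, the midpoint median of the two
values is 7.5, and the total scaled TPM is
$10\cdot\tfrac{2}{3} + 5\cdot\tfrac{1}{1} = 11.6667$ because the peptide
sits in only two of Gene A's three isoforms.  `WWWWWWWW` is absent from the
proteome, which is reported explicitly (`not_found`) rather than as zero
expression.

The same operations are available as library calls
(`pepx.annotate_peptide`, `pepx.annotate_batch`), and
`pepx benchmark` / `pepx.evaluate_metrics` score a ligand set against
length-matched decoys and report per-tissue and mean AUCs.

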