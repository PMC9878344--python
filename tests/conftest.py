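import numpy as np
import pytest

from pepx.proteome_index import CANONICAL_AA, ProteinRecord, build_index
from pepx.synthetic_fixtures import toy_shared_peptide_proteome

_AA = np.array(list(CANONICAL_AA))


def random_records(rng, n_proteins, min_len=10, max_len=60, n_genes=None):
    """Small random proteome: n_proteins sequences spread over n_genes genes."""
    if n_genes is None:
        n_genes = max(1, n_proteins // 2)
    records = []
    for i in range(n_proteins):
        length = int(rng.integers(min_len, max_len + 1))
        seq = "".join(_AA[rng.integers(0, len(_AA), size=length)])
        gene = int(rng.integers(0, n_genes))
        records.append(
            ProteinRecord(
                protein_id=f"ENSP{i + 1:09d}",
                transcript_id=f"ENST{i + 1:09d}",
                gene_id=f"ENSG{gene + 1:09d}",
                gene_symbol=f"G{gene + 1}",
                sequence=seq,
            )
        )
    return records


def brute_force_occurrences(records, peptide):
    """Reference oracle: scan every sequence for every occurrence position."""
    hits = []
    for rec in sorted(records, key=lambda r: r.protein_id):
        start = rec.sequence.find(peptide)
        while start != -1:
            hits.append((rec.protein_id, start))
            start = rec.sequence.find(peptide, start + 1)
    return hits


def brute_force_gene_summary(records, peptide):
    totals, containing = {}, {}
    for rec in records:
        totals[rec.gene_id] = totals.get(rec.gene_id, 0) + 1
        if peptide in rec.sequence:
            containing[rec.gene_id] = containing.get(rec.gene_id, 0) + 1
    return {g: (c, totals[g]) for g, c in sorted(containing.items())}


@pytest.fixture(scope="session")
def toy():
    return toy_shared_peptide_proteome()


@pytest.fixture(scope="session")
def toy_index(toy):
    return build_index(toy.records)
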