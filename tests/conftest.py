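import numpy as np
import pandas as pd
import pytest

from hybridca import (
    ParentGenotypeMatrix,
    PhenotypeTable,
    SnpSite,
    simulate_gene_models,
)
from hybridca.io import FEMALE, MALE


def make_matrix(calls, parents=None, roles=None, sites=None):
    """Build a small genotype matrix from a nested list of call codes."""
    calls = np.asarray(calls, dtype=np.int8)
    n_p, n_s = calls.shape
    if parents is None:
        half = n_p // 2
        parents = [f"F{i+1}" for i in range(half)] + [f"M{i+1}" for i in range(n_p - half)]
        roles = [FEMALE] * half + [MALE] * (n_p - half)
    if sites is None:
        sites = [SnpSite("chr1", 100 * (j + 1), "A", "G") for j in range(n_s)]
    return ParentGenotypeMatrix(parents, roles, sites, calls)


def make_pheno(cross_means, n_reps=2, trait="yield", noise=None, seed=0):
    """Phenotype table whose per-cross means equal ``cross_means`` exactly.

    ``cross_means`` maps (female, male) -> mean.  With ``noise`` set, a
    centred (per-cross zero-mean) perturbation of that scale is added so
    cross means stay exact while replicates differ.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for (f, m), mu in cross_means.items():
        eps = np.zeros(n_reps)
        if noise:
            eps = rng.normal(0, noise, n_reps)
            eps -= eps.mean()
        for k in range(n_reps):
            rows.append({"female": f, "male": m, "replicate": k + 1, trait: mu + eps[k]})
    return PhenotypeTable(pd.DataFrame(rows), [trait])


@pytest.fixture(scope="session")
def toy_genome(tmp_path_factory):
    """Toy reference + gene models written to disk once per session."""
    d = tmp_path_factory.mktemp("genome")
    fasta, gff = d / "ref.fasta", d / "genes.gff3"
    genes = simulate_gene_models(fasta, gff, n_genes=10, seed=42)
    return {"fasta": fasta, "gff": gff, "genes": genes}
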