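import numpy as np
import pytest

from strainvar import synthetic
from strainvar.variant_io import Genotype, GenotypeMatrix, VariantSite


@pytest.fixture(scope="session")
def small_ref():
    """200 kb random reference, fixed seed."""
    return synthetic.generate_reference(200_000, seed=101)


@pytest.fixture(scope="session")
def toy_gene_ref():
    """Single-exon toy gene ATG CAA TAG at positions 11-19 of a 40 nt contig."""
    seq = "A" * 10 + "ATGCAATAG" + "C" * 21
    return {"chr1": seq}


@pytest.fixture(scope="session")
def gene_bundle():
    """Gene models with planted HIGH-impact variants on a shared reference."""
    ref0 = synthetic.generate_reference(150_000, seed=55)
    models, planted, ref = synthetic.generate_gene_models(
        ref0, n_genes=30, exons_per_gene=3, seed=55, rescue_fraction=0.2
    )
    return models, planted, ref


def random_matrix(
    rng: np.random.Generator, n_samples: int = 4, n_sites: int = 12
) -> GenotypeMatrix:
    """Random sorted genotype matrix over one chromosome."""
    pos = np.sort(rng.choice(10_000, size=n_sites, replace=False)) + 1
    bases = "ACGT"
    sites = []
    for p in pos:
        r, a = rng.choice(list(bases), size=2, replace=False)
        sites.append(VariantSite("chr1", int(p), str(r), str(a)))
    calls = rng.choice(
        [Genotype.MISSING, Genotype.REF_HOM, Genotype.HET, Genotype.ALT_HOM],
        size=(n_samples, n_sites),
    ).astype(np.int8)
    return GenotypeMatrix([f"s{i}" for i in range(n_samples)], sites, calls)
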