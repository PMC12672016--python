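import numpy as np
import pytest

from dpgkit import simulate as sim
from dpgkit.annotation import GeneCatalog, GeneModel, filter_protein_coding
from dpgkit.pairs import identify_dpgs


def make_gene(
    gene_id,
    chrom="chr1",
    strand="+",
    tss=1000,
    length=1000,
    biotype="protein_coding",
    symbol=None,
):
    """Build a GeneModel from its TSS and length (TSS-anchored span)."""
    if strand == "+":
        start, end = tss, tss + length - 1
    else:
        start, end = tss - length + 1, tss
    return GeneModel(
        gene_id=gene_id,
        symbol=symbol,
        chrom=chrom,
        strand=strand,
        start=start,
        end=end,
        biotype=biotype,
        tss=tss,
        canonical_length=length,
    )


def catalog_of(*genes):
    return GeneCatalog(genes=list(genes))


@pytest.fixture(scope="session")
def spec30():
    return sim.FixtureSpec(seed=101, n_dpgs=30)


@pytest.fixture(scope="session")
def cohort30(spec30):
    """Shared synthetic cohort: catalog, pairs, truth manifest."""
    catalog, truth = sim.build_annotation(spec30)
    dpgset = identify_dpgs(filter_protein_coding(catalog))
    return catalog, dpgset, truth


@pytest.fixture(scope="session")
def expression30(spec30, cohort30):
    _, dpgset, _ = cohort30
    return sim.simulate_expression(spec30, dpgset)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2026)
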