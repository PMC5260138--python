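import numpy as np
import pytest
from hypothesis import settings

from methgene.formats import CytosineSite, GeneModel
from methgene.simulate import SimulationConfig, simulate_methylome

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


def make_site(pos, meth, total, chrom="Chr1", strand="+", context="CG"):
    return CytosineSite(chrom, pos, strand, context, meth, total)


def make_gene(gene_id="G1", chrom="Chr1", strand="+", start=10_000, end=12_000,
              biotype="protein_coding", upstream=2500, downstream=500):
    from methgene.core import derive_promoter

    tss = start if strand == "+" else end
    ps, pe = derive_promoter(tss, strand, upstream, downstream)
    return GeneModel(gene_id, biotype, chrom, strand, start, end, ps, pe)


@pytest.fixture(scope="session")
def sim_methylome(tmp_path_factory):
    """One default-parameter simulated methylome shared across tests."""
    outdir = tmp_path_factory.mktemp("sim")
    return simulate_methylome(SimulationConfig(seed=7, edge_cases=True), outdir)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
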