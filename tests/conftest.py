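import numpy as np
import pytest
from hypothesis import settings

from halosrna.genome_model import GeneFeature, GenomeAnnotation, GenomicInterval
from halosrna.synthetic_data import SimParams, simulate_dataset

settings.register_profile("ci", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("ci")


def small_params(seed: int = 0, **overrides) -> SimParams:
    """A reduced synthetic study used throughout the suite for speed."""
    base = dict(
        n_genes=25,
        replicon_length=70_000,
        n_asrna=12,
        n_intergenic=6,
        n_decoy_sense=3,
        n_decoy_subthreshold=3,
        seed=seed,
    )
    base.update(overrides)
    return SimParams(**base)


@pytest.fixture(scope="session")
def dataset_small():
    return simulate_dataset(small_params(seed=7))


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    from halosrna.pipeline import make_fixture

    outdir = tmp_path_factory.mktemp("bundle")
    config = make_fixture(small_params(seed=7), outdir)
    return config


@pytest.fixture()
def toy_annotation():
    """Two-gene hand-built annotation: a + gene with both UTRs and a
    leaderless - gene, separated by an intergenic gap."""
    g1 = GeneFeature(
        gene_id="geneA",
        interval=GenomicInterval("chr", 100, 500, "+"),
        cds=GenomicInterval("chr", 130, 460, "+"),
        utr5=GenomicInterval("chr", 100, 130, "+"),
        utr3=GenomicInterval("chr", 460, 500, "+"),
        product="catalase",
    )
    g2 = GeneFeature(
        gene_id="geneB",
        interval=GenomicInterval("chr", 900, 1400, "-"),
        cds=GenomicInterval("chr", 950, 1400, "-"),
        utr3=GenomicInterval("chr", 900, 950, "-"),
        product="transposase",
    )
    return GenomeAnnotation([g1, g2], {"chr": 2000})


def rng_for(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
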