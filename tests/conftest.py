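import numpy as np
import pytest

from ribostall.models import GeneModel, OccupancyProfile


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)


def make_profile(nt_counts, gene_id="g1"):
    nt_counts = np.asarray(nt_counts, dtype=np.int64)
    return OccupancyProfile(gene_id, len(nt_counts), nt_counts)


def random_cds(rng, n_codons):
    """A random CDS with ATG start, terminal stop, no internal stops."""
    from ribostall.models import SENSE_CODONS, STOP_CODONS

    codons = ["ATG"]
    codons += [SENSE_CODONS[i] for i in rng.integers(len(SENSE_CODONS), size=n_codons - 2)]
    codons.append(STOP_CODONS[rng.integers(3)])
    return "".join(codons)


@pytest.fixture
def toy_gene(rng):
    return GeneModel.from_cds("toy", random_cds(rng, 60))
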