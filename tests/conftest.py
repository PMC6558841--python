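import numpy as np
import pytest

from epildsim import founder_synth as fs
from epildsim.disease_model import EpistasisModel, PopulationFreqs, build_table


@pytest.fixture(scope="session")
def small_panel():
    """A QC'd two-segment block panel (100 + 100 sites, 91 founders)."""
    specs = fs.default_blockspecs(1, segment_sites=(100, 100))
    panel = fs.generate_panel(specs, 91, 1)
    keep = fs.qc_filter(panel.founder_genotypes(), panel.sites)
    return panel.subset(keep)


@pytest.fixture(scope="session")
def reference_table():
    """Penetrance table of the reference scenario (beta0=-5, beta3=0.90)."""
    return build_table(EpistasisModel(beta0=-5.0, beta3=0.90), PopulationFreqs(0.05, 0.60))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def hwe_genotypes(rng, maf, n_samples, n_sites):
    """Independent HWE dosage matrix, minor-allele frequency per site."""
    maf = np.broadcast_to(np.asarray(maf, dtype=float), (n_sites,))
    return (
        (rng.random((n_samples, n_sites)) < maf).astype(np.int8)
        + (rng.random((n_samples, n_sites)) < maf).astype(np.int8)
    )
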