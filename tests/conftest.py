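import numpy as np
import pytest

from inosinome import GenomicSite, SiteMeasurement, build_editing_matrix
from inosinome.model import SiteCatalog
from inosinome.simulate import SimulationConfig, simulate_cohort


def site(pos, chrom="chr1", strand="+", **kw):
    return GenomicSite(chrom=chrom, pos=pos, strand=strand, **kw)


def meas(pos, a, c, g, t, chrom="chr1", strand="+"):
    return SiteMeasurement(site=site(pos, chrom, strand), counts=(a, c, g, t))


@pytest.fixture(scope="session")
def small_cohort():
    """A compact but fully structured synthetic cohort shared across tests."""
    config = SimulationConfig(seed=11, n_tumor=14, n_normal=10,
                              n_alu_sites=60, n_rep_sites=15,
                              n_nonrep_sites=60)
    return simulate_cohort(config)


@pytest.fixture(scope="session")
def small_matrix(small_cohort):
    return build_editing_matrix(small_cohort.tables, small_cohort.catalog)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def toy_matrix(freq, cov, samples=None, region_class="NONREP"):
    """Build an EditingMatrix from dense arrays (NaN = missing)."""
    freq = np.asarray(freq, dtype=float)
    cov = np.asarray(cov, dtype=float)
    n, m = freq.shape
    samples = samples or [f"S{i}" for i in range(n)]
    sites = [GenomicSite(chrom="chr1", pos=100 + 10 * j, strand="+",
                         region_class=region_class, feature="exon")
             for j in range(m)]
    catalog = SiteCatalog(sites)
    measurements = {}
    for i, s in enumerate(samples):
        rows = []
        for j, st in enumerate(catalog.sites):
            if np.isnan(cov[i, j]):
                continue
            total = int(cov[i, j])
            f = freq[i, j]
            if np.isnan(f):
                rows.append(SiteMeasurement(site=st, counts=(0, total, 0, 0)))
            else:
                g = int(round(f * total))
                rows.append(SiteMeasurement(site=st, counts=(total - g, 0, g, 0)))
        measurements[s] = rows
    return build_editing_matrix(measurements, catalog)
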