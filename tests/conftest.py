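import numpy as np
import pandas as pd
import pytest

from mixploid.containers import AlleleDepthMatrix, GenotypeMatrix
from mixploid.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def two_cluster_dataset():
    """Two diploid clusters, F=0.2 each, 50+50 samples, 1000 loci."""
    cfg = SimulationConfig(
        n_clusters=2, cluster_sizes=(50, 50), cluster_ploidy=(2, 2),
        cluster_divergence=(0.2, 0.2), cluster_regions=(("a",), ("b",)),
        n_nuclear_sites=1000, n_cp_sites=30, hybrid_specs=(), n_clones=0,
        missing_rate=0.02, cp_pool_size=8, n_teams=6, seed=101)
    return simulate_dataset(cfg)


@pytest.fixture()
def toy_genotypes():
    """Six diploid samples x five loci with some missingness."""
    dosage = np.array([
        [0, 1, 2, 1, 0],
        [0, 1, 2, 1, 0],
        [1, 1, 0, np.nan, 2],
        [2, 0, 0, 0, 2],
        [np.nan, np.nan, np.nan, 1, 1],
        [1, 2, 1, 1, 0],
    ], dtype=float)
    loci = pd.DataFrame({
        "compartment": "nuclear", "chrom": "chr1",
        "pos": np.arange(1, 6) * 10, "ref": "A", "alt": "C"})
    return GenotypeMatrix(
        samples=[f"S{i}" for i in range(6)], loci=loci, dosage=dosage,
        ploidy=np.full(6, 2), provenance="initial_diploid")


def make_allele_depths(depth, alt, chrom="chr1", compartment="nuclear"):
    depth = np.asarray(depth)
    alt = np.asarray(alt)
    n, m = depth.shape
    sites = pd.DataFrame({
        "compartment": compartment, "chrom": chrom,
        "pos": np.arange(1, m + 1) * 10, "ref": "A", "alt": "C"})
    return AlleleDepthMatrix(
        samples=[f"S{i}" for i in range(n)], sites=sites,
        depth=depth, alt_depth=alt, missing=depth == 0)
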