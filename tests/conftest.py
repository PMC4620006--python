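import numpy as np
import pytest

from popdiff.genotype_io import GenotypeMatrix, make_snp_map
from popdiff.simdata import SimulationConfig, simulate_panel


@pytest.fixture(scope="session")
def structured_panel():
    """Three well-differentiated subpopulations of inbred lines (session-wide)."""
    cfg = SimulationConfig(
        n_subpops=3, sizes=(30, 30, 30), n_snps=2000, n_chromosomes=5,
        chrom_length_bp=600_000, differentiation=0.3, seed=5,
    )
    gm, snp_map, truth, _ = simulate_panel(cfg)
    return cfg, gm, snp_map, truth


@pytest.fixture(scope="session")
def two_island_panel():
    """Two-subpopulation panel at moderate drift for differentiation tests."""
    cfg = SimulationConfig(
        n_subpops=2, sizes=(100, 100), n_snps=3000, n_chromosomes=5,
        chrom_length_bp=1_200_000, differentiation=0.15, seed=3,
    )
    gm, snp_map, truth, _ = simulate_panel(cfg)
    return cfg, gm, snp_map, truth


@pytest.fixture()
def random_messy_panel():
    """Random dosage panel with missing calls (no population structure)."""
    rng = np.random.default_rng(42)
    n, m = 12, 60
    dosage = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    mask = rng.random((n, m)) < 0.1
    gm = GenotypeMatrix([f"a{i}" for i in range(n)], [f"s{j}" for j in range(m)], dosage, mask)
    snp_map = make_snp_map(
        gm.snp_ids,
        ["chr1"] * 30 + ["chr2"] * 30,
        list(range(1000, 31000, 1000)) * 2,
        ["A"] * m,
        ["G"] * m,
    )
    return gm, snp_map
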