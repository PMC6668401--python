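import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from clonotracer import GenotypeMatrix, PanelVariant

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


def make_small_panel(n_common=4, n_pathogenic=1, n_controls=3):
    variants = []
    for i in range(n_common):
        variants.append(PanelVariant(f"chr{i+1}", 100 + i, "A", "C",
                                     gene=f"G{i}", category="common"))
    for i in range(n_pathogenic):
        variants.append(PanelVariant(f"chr{i+1}", 500 + i, "G", "T",
                                     gene="TP53", category="pathogenic"))
    for i in range(n_controls):
        variants.append(PanelVariant(f"chr{i+1}", 900 + i, "C", "G",
                                     category="ado_control"))
    return variants


def make_matrix(genotypes, depth=None, quality=None, panel=None,
                timepoint="t0", sample_id="s0"):
    g = np.asarray(genotypes, dtype=np.int8)
    n, p = g.shape
    if panel is None:
        panel = [PanelVariant("chr1", 100 + j, "A", "C", category="common")
                 for j in range(p)]
    if depth is None:
        depth = np.full((n, p), 50, dtype=np.int32)
    if quality is None:
        quality = np.full((n, p), 60, dtype=np.int32)
    return GenotypeMatrix(
        cell_ids=[f"c{i:03d}" for i in range(n)],
        variants=list(panel), genotypes=g,
        depth=np.asarray(depth), quality=np.asarray(quality),
        sample_id=sample_id, timepoint=timepoint,
    )


def random_matrix(rng, n_cells, n_variants, missing_rate=0.1, panel=None):
    g = rng.choice([-1, 0, 1, 2], size=(n_cells, n_variants),
                   p=[missing_rate, (1 - missing_rate) * 0.5,
                      (1 - missing_rate) * 0.3, (1 - missing_rate) * 0.2])
    depth = rng.integers(0, 60, size=(n_cells, n_variants))
    quality = rng.integers(0, 80, size=(n_cells, n_variants))
    return make_matrix(g, depth=depth, quality=quality, panel=panel)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_experiment():
    """One defaults-condition simulated experiment shared across tests."""
    from clonotracer import SimulationConfig, simulate_experiment

    cfg = SimulationConfig(seed=11)
    matrices, truth = simulate_experiment(cfg)
    return cfg, matrices, truth
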