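"""Shared fixtures: session-scoped synthetic datasets reused across tests."""

import numpy as np
import pytest

import crossploidy as cp

#: canonical contact-zone model: the best-supported family with the fitted
#: migration levels, strong inbreeding, unequal present-day sizes
STUDY_MODEL = cp.DemographicModel(
    family="constant_gene_flow", nu_D=1.0, nu_T=0.8, T0=1.0,
    M_DT=0.3, M_TD=0.4, F_D=0.81, F_T=0.75,
)

#: deep isolation model used for diagnostic-enriched hybrid panels
PANEL_MODEL = cp.DemographicModel(
    family="no_gene_flow", nu_D=1.0, nu_T=0.8, T0=3.0, F_D=0.81, F_T=0.75,
)


@pytest.fixture(scope="session")
def study_dataset():
    """45 + 50 individuals, 356 unlinked SNPs under the study model."""
    cfg = cp.SimulationConfig(n_D=45, n_T=50, n_sites=356, seed=11)
    G, truth = cp.simulate_genotypes(STUDY_MODEL, cfg)
    return G, truth


@pytest.fixture(scope="session")
def pure_panel():
    """Diagnostic-enriched pure panel: deep split, 356 loci, no hybrids."""
    cfg = cp.SimulationConfig(n_D=45, n_T=50, n_sites=356, seed=21)
    return cp.simulate_genotypes(PANEL_MODEL, cfg)


@pytest.fixture(scope="session")
def hybrid_panel(pure_panel):
    """Pure panel plus 5 injected individuals of each hybrid category."""
    G, truth = pure_panel
    return cp.inject_hybrids(G, truth, {"F1": 5, "F2": 5, "BC_D": 5,
                                        "BC_T": 5}, seed=22)


@pytest.fixture(scope="session")
def diagnostic_matrix():
    """Two populations fixed for alternative alleles at every locus."""
    n, loci = 10, 60
    g = np.vstack([np.zeros((n, loci), dtype=np.int8),
                   np.full((n, loci), 2, dtype=np.int8)])
    return cp.GenotypeMatrix(
        g,
        [f"D_{i}" for i in range(n)] + [f"T_{i}" for i in range(n)],
        ["D"] * n + ["T"] * n,
        [f"sc{j}" for j in range(loci)],
        np.arange(1, loci + 1),
    )


def random_matrix(rng, n_ind=12, n_sites=30, missing=0.15, pops=("D", "T")):
    """Small random genotype matrix helper for oracle comparisons."""
    g = rng.integers(0, 3, size=(n_ind, n_sites)).astype(np.int8)
    mask = rng.random(g.shape) < missing
    g[mask] = -1
    half = n_ind // 2
    populations = [pops[0]] * half + [pops[1]] * (n_ind - half)
    scaffolds = [f"sc{rng.integers(0, max(2, n_sites // 2))}"
                 for _ in range(n_sites)]
    return cp.GenotypeMatrix(
        g, [f"s{i}" for i in range(n_ind)], populations, scaffolds,
        rng.integers(1, 1000, size=n_sites),
    )
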