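import numpy as np
import pytest
from shapely.geometry import box

from stcar.model import MCMCConfig, PriorSpec, run_mcmc
from stcar.region_graph import RegionGraph, build_queen_adjacency
from stcar.synthetic import CovariateRule, SimulationSpec, simulate_panel


def lattice_graph(rows: int, cols: int) -> RegionGraph:
    """Queen-contiguous rows x cols lattice of unit squares."""
    polys = [(f"r{r}c{c}", box(c, r, c + 1, r + 1))
             for r in range(rows) for c in range(cols)]
    return build_queen_adjacency(polys)


def rook_lattice_graph(rows: int, cols: int) -> RegionGraph:
    """Rook-adjacent lattice (shared edges only), via an explicit edge list."""
    from stcar.region_graph import graph_from_edge_list

    ids = [f"r{r}c{c}" for r in range(rows) for c in range(cols)]
    edges = []
    for r in range(rows):
        for c in range(cols):
            if c + 1 < cols:
                edges.append((f"r{r}c{c}", f"r{r}c{c + 1}"))
            if r + 1 < rows:
                edges.append((f"r{r}c{c}", f"r{r + 1}c{c}"))
    return graph_from_edge_list(ids, edges)


@pytest.fixture(scope="session")
def small_fit():
    """A fitted model on a small synthetic panel, shared across tests.

    6x6 lattice, 11 years, two covariates with known truth; short chains
    (enough for summaries/diagnostics plumbing, not for tight inference).
    """
    covs = (CovariateRule("x1", kind="varying", beta=0.2),
            CovariateRule("x2", kind="fixed", beta=-0.15))
    spec = SimulationSpec(rows=6, cols=6, n_remove=0, n_islands=0,
                          intercept=0.1, tau2=0.3, rho_s=0.8, rho_t=0.7,
                          covariates=covs, pop_range=(20_000, 60_000),
                          crude_rate=5e-4, seed=7)
    panel, truth, extras = simulate_panel(spec)
    config = MCMCConfig(iterations=3000, burn_in=1000, thin=10, chains=2, seed=42)
    samples = run_mcmc(panel, extras["graph"], PriorSpec(), config)
    return {"panel": panel, "truth": truth, "extras": extras,
            "graph": extras["graph"], "samples": samples, "config": config}
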