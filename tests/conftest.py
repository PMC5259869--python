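import numpy as np
import pytest

import comodule.netbuild as nb
from comodule.netbuild import Adjacency, CrossAdjacency
from comodule.spectral import IntegratedNetwork
from comodule.synth import PlantedParams, generate_planted_dataset


def network_from_expression(expr_g, expr_m, tau=0.6, gm_tau=0.6, lam=1.0,
                            known_pairs=None):
    """Integrated network from paired expression by hard thresholding."""
    gene_ids, mirna_ids = list(expr_g.index), list(expr_m.index)
    a_g = nb.threshold_adjacency(nb.correlation_matrix(expr_g), tau, gene_ids)
    a_m = nb.threshold_adjacency(nb.correlation_matrix(expr_m), tau, mirna_ids)
    c = nb.threshold_cross_adjacency(
        nb.correlation_matrix(expr_g, expr_m), gm_tau, gene_ids, mirna_ids
    )
    if known_pairs:
        c = nb.combine_cross_network(c, known_pairs)
    return IntegratedNetwork(a_g=a_g, a_m=a_m, c=c, lam=lam)


def random_symmetric(rng, n, p=0.5):
    a = (rng.random((n, n)) < p).astype(int)
    a = np.triu(a, 1)
    return a + a.T


def random_integrated(rng, max_side=5, k_choices=(2, 3), lam_choices=(0.0, 0.5, 1.0)):
    """A random small integrated network plus a K for enumeration checks."""
    ng = int(rng.integers(2, max_side + 1))
    nm = int(rng.integers(2, max_side + 1))
    a_g = Adjacency([f"g{i}" for i in range(ng)], random_symmetric(rng, ng))
    a_m = Adjacency([f"m{i}" for i in range(nm)], random_symmetric(rng, nm))
    c = CrossAdjacency(
        a_g.node_ids, a_m.node_ids, (rng.random((ng, nm)) < 0.4).astype(int)
    )
    net = IntegratedNetwork(
        a_g=a_g, a_m=a_m, c=c, lam=float(rng.choice(lam_choices))
    )
    return net, int(rng.choice(k_choices))


@pytest.fixture(scope="session")
def small_planted():
    """Well-separated 3-module dataset for clustering/equivariance tests."""
    return generate_planted_dataset(
        PlantedParams(
            n_modules=3, genes_per_module=10, mirnas_per_module=4,
            n_background_genes=8, n_background_mirnas=5, n_samples=100,
            loading=0.9, noise_sd=0.3, seed=7,
        )
    )


@pytest.fixture(scope="session")
def default_planted():
    """The standard study-condition preset (seed 11)."""
    return generate_planted_dataset()
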