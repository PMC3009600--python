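import numpy as np
import pytest

import nucleocomp as nc


@pytest.fixture(scope="session")
def three_leaf_tree() -> nc.Tree:
    return nc.Tree.from_newick("((cer,par)anc,mik)root;")


@pytest.fixture(scope="session")
def small_world(three_leaf_tree):
    """A 20 kb synthetic world shared by read-only tests."""
    return nc.default_world(genome_length=20_000, seed=3,
                            newick="((cer,par)anc,mik)root;", noise_sd=0.2)


@pytest.fixture(scope="session")
def small_truth(small_world):
    return nc.gen_alignment(small_world)


@pytest.fixture(scope="session")
def small_posteriors(small_world, small_truth):
    return nc.infer_posteriors(small_truth.block, small_world.tree,
                               small_world.true_rates, small_world.root_model,
                               nc.BPOptions(damping=0.0, tol=1e-8))


def random_context_free_rates(rng, lineages, diag=0.85):
    """A random context-free ContextRateSet (rows diagonal-dominant)."""
    out = {}
    for ln in lineages:
        m = rng.random((4, 4)) * 0.1
        np.fill_diagonal(m, 0.0)
        m = m / m.sum(axis=1, keepdims=True) * (1.0 - diag)
        np.fill_diagonal(m, diag)
        out[ln] = np.broadcast_to(m, (4, 4, 4, 4)).copy()
    return nc.ContextRateSet(out)
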