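import itertools

import numpy as np
import pytest

from specmed.discrete_model import CausalModel, Cpd, Dag, Variable


def random_dag_model(rng, n_nodes, edge_prob=0.5, max_alphabet=2):
    """A random DAG over V0..V{n-1} (edges only forward in index order)
    with Dirichlet(1) CPT rows."""
    names = [f"V{i}" for i in range(n_nodes)]
    sizes = {n: int(rng.integers(2, max_alphabet + 1)) for n in names}
    variables = {n: Variable(n, tuple(range(sizes[n]))) for n in names}
    edges = [(names[i], names[j])
             for i in range(n_nodes) for j in range(i + 1, n_nodes)
             if rng.random() < edge_prob]
    dag = Dag(variables, edges)
    cpds = {}
    for n in names:
        parents = dag.parents(n)
        table = {
            key: rng.dirichlet(np.ones(sizes[n]))
            for key in itertools.product(
                *[variables[p].alphabet for p in parents])
        }
        cpds[n] = Cpd(n, parents, table)
    return CausalModel(variables, dag, cpds)


def random_mediation_model(rng, confounded=False, max_alphabet=4):
    """Random X -> Z -> Y mediation triangle with X -> Y, optionally with a
    confounder U -> X, U -> Y."""
    names = ["X", "Z", "Y"] + (["U"] if confounded else [])
    sizes = {n: int(rng.integers(2, max_alphabet + 1)) for n in names}
    variables = {n: Variable(n, tuple(range(sizes[n]))) for n in names}
    edges = [("X", "Z"), ("X", "Y"), ("Z", "Y")]
    if confounded:
        edges += [("U", "X"), ("U", "Y")]
    dag = Dag(variables, edges)
    cpds = {}
    for n in names:
        parents = dag.parents(n)
        table = {
            key: rng.dirichlet(np.ones(sizes[n]))
            for key in itertools.product(
                *[variables[p].alphabet for p in parents])
        }
        cpds[n] = Cpd(n, parents, table)
    return CausalModel(variables, dag, cpds)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def example1():
    from specmed import example1_model
    return example1_model()


@pytest.fixture
def caused_uncertainty():
    from specmed import caused_uncertainty_model
    return caused_uncertainty_model()


@pytest.fixture
def chain01():
    from specmed import ChainParams, chain_model
    return chain_model(ChainParams(0.1))
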