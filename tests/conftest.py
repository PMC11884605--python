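import numpy as np
import pytest

from metajac.network import MetabolicNetwork, Reaction, Species, load_builtin
from metajac.table import MetaboliteTable


@pytest.fixture(scope="session")
def mannose_net():
    return load_builtin("mannose_core")


@pytest.fixture()
def scalar_net():
    """Single pool with constant inflow 10 and first-order decay k=1: an
    Ornstein-Uhlenbeck process around C* = 10."""
    return MetabolicNetwork([Species("A")], [], inflows=[("A", 10.0)], outflows=[("A", 1.0)])


@pytest.fixture()
def chain_net():
    """in -> A (k0=2), A -> B (k1=1), B -> out (k2=1); C* = (2, 2)."""
    return MetabolicNetwork(
        [Species("A"), Species("B")],
        [Reaction("R1", (("A", 1),), (("B", 1),), rate_constant=1.0)],
        inflows=[("A", 2.0)],
        outflows=[("B", 1.0)],
    )


def make_two_class_table(seed, n=40, p=10, shift=6.0):
    """Two balanced classes, one informative metabolite shifted by ``shift``."""
    rng = np.random.default_rng(seed)
    X = rng.normal(5.0, 1.0, size=(n, p))
    labels = ["A"] * (n // 2) + ["B"] * (n - n // 2)
    X[n // 2 :, 0] += shift
    return MetaboliteTable(
        sample_ids=[f"s{i}" for i in range(n)],
        conditions=labels,
        metabolites=[f"met{j}" for j in range(p)],
        values=np.abs(X),
    )


def random_stable_sparse_jacobian(rng, n, extra_margin=0.5):
    """Random Hurwitz J whose nonzero pattern has at most n(n+1)/2 entries.

    The pattern always contains the diagonal and a coupling chain
    (i+1, i), then random extra off-diagonals up to the count cap. The
    chain keeps the pattern irreducible: a pattern that decomposes into
    decoupled blocks is not identifiable from covariance even when the
    global entry count is below n(n+1)/2, because the cross-block
    covariances (and with them the cross-block equations) vanish.
    """
    max_entries = n * (n + 1) // 2
    base = {(i, i) for i in range(n)} | {(i + 1, i) for i in range(n - 1)}
    off = [(i, j) for i in range(n) for j in range(n) if i != j and (i, j) not in base]
    rng.shuffle(off)
    n_extra = int(rng.integers(0, max_entries - len(base) + 1))
    entries = sorted(base | set(off[:n_extra]))
    J = np.zeros((n, n))
    for i, j in entries:
        J[i, j] = rng.uniform(-1, 1)
    shift = max(np.linalg.eigvals(J).real.max(), 0.0) + extra_margin
    for i in range(n):
        J[i, i] -= shift
    return J, entries
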