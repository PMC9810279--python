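
import numpy as np
import pytest

from netreconfig import MultilayerNetwork, modularity_value


def restricted_growth_strings(n: int):
    """All set partitions of n items as canonical label sequences."""
    a = [0] * n
    while True:
        yield list(a)
        j = n - 1
        while j > 0:
            if a[j] <= max(a[:j]):
                a[j] += 1
                for k in range(j + 1, n):
                    a[k] = 0
                break
            j -= 1
        else:
            return


def enumerate_max_modularity(net: MultilayerNetwork) -> tuple[float, np.ndarray]:
    """Exhaustive-enumeration maximum of multilayer Q (oracle).

    Only feasible for small supra-node counts (N*L <= ~10).
    """
    L, N = net.n_layers, net.n_nodes
    best_q, best_labels = -np.inf, None
    for labels in restricted_growth_strings(L * N):
        arr = np.asarray(labels).reshape(L, N)
        q = modularity_value(net, arr)
        if q > best_q:
            best_q, best_labels = q, arr
    return best_q, best_labels


def random_small_network(rng: np.random.Generator) -> MultilayerNetwork:
    """A random sparse nonnegative multilayer network with N*L <= 10."""
    while True:
        N = int(rng.integers(2, 6))
        L = int(rng.integers(1, 4))
        if N * L <= 10:
            break
    layers = rng.random((L, N, N))
    layers = 0.5 * (layers + layers.transpose(0, 2, 1))
    layers = np.where(layers > 0.45, layers, 0.0)
    idx = np.arange(N)
    layers[:, idx, idx] = 0.0
    omega = float(rng.choice([0.0, 0.5, 1.0]))
    return MultilayerNetwork(layers, gamma=1.0, omega=omega)


@pytest.fixture(scope="session")
def fixture_cohort(tmp_path_factory):
    """A small synthetic cohort on disk (5 subjects, 20 nodes, 300 volumes)."""
    from netreconfig import make_fixtures

    directory = tmp_path_factory.mktemp("cohort")
    return make_fixtures(seed=7, directory=directory)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
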