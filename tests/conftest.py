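import itertools

import numpy as np
import pytest

import cortnet as cn


@pytest.fixture(scope="session")
def fixtures():
    return cn.fixture_library()


@pytest.fixture(scope="session")
def toy6(fixtures):
    return fixtures["anneal_toy6"]


@pytest.fixture(scope="session")
def planted40(fixtures):
    return fixtures["planted_ldc40"]


def random_digraph(n, k, seed, ensure_connected=False):
    """Uniform random directed binary graph with exactly k links."""
    rng = np.random.default_rng(seed)
    while True:
        A = np.zeros((n, n), dtype=np.int8)
        off = np.array([(i, j) for i in range(n) for j in range(n) if i != j])
        pick = rng.choice(len(off), size=k, replace=False)
        A[off[pick, 0], off[pick, 1]] = 1
        if not ensure_connected:
            return A
        from cortnet._graph import is_strongly_connected

        if is_strongly_connected(A):
            return A


def enumerate_degree_fixed(A):
    """All 0/1 matrices with A's row and column sums and a zero diagonal.

    Brute-force row-by-row enumeration; usable only for tiny instances.
    """
    n = A.shape[0]
    rowsums = list(np.asarray(A).sum(axis=1))
    colsums = list(np.asarray(A).sum(axis=0))
    out = []

    def rec(i, rows, colleft):
        if i == n:
            out.append(np.array(rows, dtype=np.int8))
            return
        avail = [j for j in range(n) if j != i and colleft[j] > 0]
        for comb in itertools.combinations(avail, rowsums[i]):
            row = [0] * n
            for j in comb:
                row[j] = 1
                colleft[j] -= 1
            rec(i + 1, rows + [row], colleft)
            for j in comb:
                colleft[j] += 1

    rec(0, [], colsums)
    return out


@pytest.fixture(scope="session")
def toy6_optima(toy6):
    """Exhaustive-search optima of the 6-node instance for alpha in {0, 1}."""
    from cortnet._graph import is_strongly_connected

    D = cn.distance_matrix(toy6)
    best_lp = np.inf
    best_lg = np.inf
    for M in enumerate_degree_fixed(toy6.A):
        if not is_strongly_connected(M):
            continue
        best_lp = min(best_lp, cn.wiring_cost(M, D))
        best_lg = min(best_lg, cn.graph_length(M)[0])
    return {"lp": best_lp, "lg": best_lg, "D": D}
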