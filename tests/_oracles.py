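"""Independent oracles used by the test suite.

These deliberately avoid the package's pruning/uniformization code paths:
likelihoods come from exhaustive enumeration over internal-node states, and
expected event counts from numerical quadrature of the endpoint-conditioned
occupancy integral.
"""

from __future__ import annotations

import itertools

import numpy as np
import scipy.linalg

from karyoevo.ctmc_model import StateSpace, TreeIndex, transition_probs
from karyoevo.karyodata import Phylogeny


def brute_force_likelihood(
    tip_states: dict[str, tuple[int, str]],
    tree: Phylogeny,
    Q: np.ndarray,
    space: StateSpace,
    root_mode="flat",
) -> float:
    """Tip-data likelihood by summing over every internal-state assignment."""
    index = TreeIndex(tree)
    n = space.size
    P = {
        i: transition_probs(Q, float(index.edge_length[i]))
        for i in range(index.n_nodes)
        if i != index.root
    }
    tips = {index.tip_index[t]: space.index_for_tip(k, s, t)
            for t, (k, s) in tip_states.items()}
    internals = [
        i for i in range(index.n_nodes)
        if index.children[i] and i != index.root
    ]

    def conditional_root_lik(root_state: int) -> float:
        total = 0.0
        for combo in itertools.product(range(n), repeat=len(internals)):
            assign = dict(zip(internals, combo))
            assign.update(tips)
            assign[index.root] = root_state
            p = 1.0
            for i in range(index.n_nodes):
                if i == index.root:
                    continue
                p *= P[i][assign[index.parent[i]], assign[i]]
            total += p
        return total

    L = np.array([conditional_root_lik(s) for s in range(n)])
    if isinstance(root_mode, (int, np.integer)):
        return float(L[int(root_mode)])
    if root_mode == "flat":
        return float(L.mean())
    if root_mode == "fitzjohn":
        return 0.0 if L.sum() == 0 else float((L**2).sum() / L.sum())
    raise ValueError(root_mode)


def expected_event_counts(
    Q: np.ndarray, a: int, b: int, t: float, n_grid: int = 400
) -> np.ndarray:
    """E[number of i->j events | X(0)=a, X(t)=b] for every ordered pair.

    Gauss-Legendre quadrature of
    ``q_ij * int_0^t P(u)[a,i] P(t-u)[j,b] du / P(t)[a,b]``.
    """
    n = Q.shape[0]
    nodes, weights = np.polynomial.legendre.leggauss(n_grid)
    u = 0.5 * t * (nodes + 1.0)
    w = 0.5 * t * weights
    p_ab = scipy.linalg.expm(Q * t)[a, b]
    counts = np.zeros((n, n))
    fwd = np.stack([scipy.linalg.expm(Q * ui)[a, :] for ui in u])
    bwd = np.stack([scipy.linalg.expm(Q * (t - ui))[:, b] for ui in u])
    for i in range(n):
        for j in range(n):
            if i == j or Q[i, j] == 0:
                continue
            integrand = fwd[:, i] * bwd[:, j]
            counts[i, j] = Q[i, j] * float((w * integrand).sum()) / p_ab
    return counts


def exhaustive_hpd(samples, mass: float) -> tuple[float, float]:
    """Shortest mass-covering window by scanning every candidate window."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    m = min(int(np.ceil(mass * n)), n)
    best = (np.inf, None, None)
    for j in range(n - m + 1):
        width = x[j + m - 1] - x[j]
        if width < best[0]:
            best = (width, x[j], x[j + m - 1])
    return best[1], best[2]
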