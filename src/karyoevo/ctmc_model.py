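"""Bounded Markov model of chromosome-number and sex-chromosome-system change.

States are pairs ``(k, system)`` with ``k`` the haploid autosome count on an
inclusive integer range and ``system`` either the single placeholder
``"none"`` (basic, count-only model) or one of ``{"simple", "neo"}``.
Allowed moves:

* fission       ``(k, s)   -> (k+1, s)``    rate ``fission``
* fusion        ``(k, s)   -> (k-1, s)``    rate ``fusion``
* SA-fusion     ``(k, simple) -> (k-1, neo)``  rate ``sa_fusion``
* reversion     ``(k, neo) -> (k, simple)``    rate ``reversion``

Moves that would leave the count range are simply absent (reflecting
bounds).  Rates are per tree unit (1 unit = 10^8 years).  Likelihoods are
computed by Felsenstein pruning with per-branch transition matrices from a
cached eigendecomposition of the generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import scipy.linalg

from karyoevo.karyodata import Phylogeny

BASIC_SYSTEMS = ("none",)
SCS_SYSTEMS = ("simple", "neo")

#: sex-chromosome-system label -> model system, XO treated as a simple
#: (undifferentiated-pairing) system by default.
SCS_TO_SYSTEM = {"XY": "simple", "XO": "simple", "neoXY": "neo"}


@dataclass(frozen=True)
class StateSpace:
    """Indexed product space of autosome counts and systems.

    Index order is system-major: all counts of the first system first, i.e.
    ``index(k, s) = systems.index(s) * n_counts + (k - k_min)``.
    """

    k_min: int
    k_max: int
    systems: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.k_min < 1:
            raise ValueError(f"k_min must be >= 1, got {self.k_min}")
        if self.k_max < self.k_min:
            raise ValueError("k_max must be >= k_min")
        if tuple(self.systems) not in (BASIC_SYSTEMS, SCS_SYSTEMS):
            raise ValueError(f"unsupported system set {self.systems}")

    @property
    def n_counts(self) -> int:
        return self.k_max - self.k_min + 1

    @property
    def size(self) -> int:
        return self.n_counts * len(self.systems)

    @property
    def scs_mode(self) -> bool:
        return self.systems == SCS_SYSTEMS

    def index(self, k: int, system: str = "none") -> int:
        if not (self.k_min <= k <= self.k_max):
            raise ValueError(
                f"count {k} outside [{self.k_min}, {self.k_max}]"
            )
        try:
            s = self.systems.index(system)
        except ValueError:
            raise ValueError(
                f"system {system!r} not in {self.systems}"
            ) from None
        return s * self.n_counts + (k - self.k_min)

    def state(self, index: int) -> tuple[int, str]:
        if not (0 <= index < self.size):
            raise ValueError(f"index {index} outside [0, {self.size})")
        s, r = divmod(index, self.n_counts)
        return self.k_min + r, self.systems[s]

    def states(self) -> list[tuple[int, str]]:
        return [self.state(i) for i in range(self.size)]

    def index_for_tip(self, k: int, scs: str, tip: str = "?") -> int:
        """Map an observed (count, SCS label) to a state index.

        In the basic model the SCS label is ignored.  Raises ``ValueError``
        naming the tip if the count falls outside the bounds.
        """
        if not (self.k_min <= k <= self.k_max):
            raise ValueError(
                f"tip {tip!r}: autosome count {k} outside state-space "
                f"bounds [{self.k_min}, {self.k_max}]"
            )
        if not self.scs_mode:
            return self.index(k, "none")
        system = SCS_TO_SYSTEM.get(scs)
        if system is None:
            raise ValueError(f"tip {tip!r}: unknown SCS label {scs!r}")
        return self.index(k, system)


@dataclass(frozen=True)
class RateParams:
    """The four transition rates, per tree unit (10^8 years).

    In the basic model only ``fission`` and ``fusion`` are active.
    """

    fission: float
    fusion: float
    sa_fusion: float = 0.0
    reversion: float = 0.0

    def __post_init__(self) -> None:
        for name in ("fission", "fusion", "sa_fusion", "reversion"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")

    def as_array(self, scs_mode: bool = True) -> np.ndarray:
        if scs_mode:
            return np.array(
                [self.fission, self.fusion, self.sa_fusion, self.reversion]
            )
        return np.array([self.fission, self.fusion])

    @staticmethod
    def param_names(scs_mode: bool = True) -> tuple[str, ...]:
        return (
            ("fission", "fusion", "sa_fusion", "reversion")
            if scs_mode
            else ("fission", "fusion")
        )

    @classmethod
    def from_array(cls, values: Sequence[float], scs_mode: bool = True
                   ) -> "RateParams":
        values = list(values)
        if scs_mode:
            return cls(*values)
        return cls(values[0], values[1], 0.0, 0.0)


def build_state_space(k_min: int, k_max: int, scs_mode: bool) -> StateSpace:
    """Construct the bounded state space (see :class:`StateSpace`)."""
    return StateSpace(
        k_min=int(k_min),
        k_max=int(k_max),
        systems=SCS_SYSTEMS if scs_mode else BASIC_SYSTEMS,
    )


def default_state_space(
    tip_counts: Sequence[int], scs_mode: bool, padding: int = 10
) -> StateSpace:
    """Default bounds: ``k_min = 1``, ``k_max = max(observed) + padding``."""
    return build_state_space(1, max(tip_counts) + padding, scs_mode)


def build_rate_matrix(params: RateParams, space: StateSpace) -> np.ndarray:
    """Dense generator matrix Q over the state space.

    Off-diagonals carry the four allowed moves; each diagonal is minus its
    row's off-diagonal sum, so rows sum to zero exactly.
    """
    n = space.size
    Q = np.zeros((n, n))
    for i in range(n):
        k, s = space.state(i)
        if k < space.k_max:
            Q[i, space.index(k + 1, s)] += params.fission
        if k > space.k_min:
            Q[i, space.index(k - 1, s)] += params.fusion
        if space.scs_mode:
            if s == "simple" and k > space.k_min:
                Q[i, space.index(k - 1, "neo")] += params.sa_fusion
            if s == "neo":
                Q[i, space.index(k, "simple")] += params.reversion
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def classify_move(
    space: StateSpace, from_index: int, to_index: int
) -> str:
    """Name the move between two adjacent states.

    Returns one of ``fission``, ``fusion``, ``sa_fusion``, ``reversion``;
    raises ``ValueError`` for any pair that is not an allowed move.
    """
    k0, s0 = space.state(from_index)
    k1, s1 = space.state(to_index)
    if s0 == s1 and k1 == k0 + 1:
        return "fission"
    if s0 == s1 and k1 == k0 - 1:
        return "fusion"
    if space.scs_mode and s0 == "simple" and s1 == "neo" and k1 == k0 - 1:
        return "sa_fusion"
    if space.scs_mode and s0 == "neo" and s1 == "simple" and k1 == k0:
        return "reversion"
    raise ValueError(
        f"disallowed transition ({k0},{s0}) -> ({k1},{s1})"
    )


def transition_probs(Q: np.ndarray, t: float) -> np.ndarray:
    """Transition-probability matrix ``expm(Q t)``; rows sum to 1."""
    if t < 0:
        raise ValueError(f"elapsed time must be >= 0, got {t}")
    P = scipy.linalg.expm(Q * t)
    np.clip(P, 0.0, 1.0, out=P)
    return P


class TransitionKernel:
    """Transition matrices for one generator at many elapsed times.

    ``method="expm"`` (default) evaluates ``scipy.linalg.expm`` per time —
    exact to machine precision relative to the Padé reference, which the
    enumeration oracles also use.  ``method="auto"`` tries an
    eigendecomposition (one factorization, two small matmuls per time;
    absolute accuracy ~1e-9) and falls back to ``expm`` when Q is close to
    defective; MCMC uses it for speed.  Results are cached per distinct
    time.
    """

    def __init__(self, Q: np.ndarray, method: str = "expm"):
        if method not in ("expm", "auto", "eig"):
            raise ValueError(f"unknown kernel method {method!r}")
        self.Q = np.asarray(Q, dtype=float)
        self._cache: dict[float, np.ndarray] = {}
        self._eig_ok = False
        self._fast = method != "expm"
        self._omega: float | None = None
        self._R: np.ndarray | None = None
        if method == "expm":
            return
        try:
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore", scipy.linalg.LinAlgWarning)
                w, V = scipy.linalg.eig(self.Q)
                Vinv = scipy.linalg.inv(V)
            # accept the factorization only if it reconstructs Q well
            # (a near-defective Q blows up Vinv and fails this)
            recon = np.real((V * w) @ Vinv)
            scale = max(np.abs(self.Q).max(), 1.0)
            if np.max(np.abs(recon - self.Q)) < 1e-9 * scale:
                self._w, self._V, self._Vinv = w, V, Vinv
                self._eig_ok = True
        except scipy.linalg.LinAlgError:  # pragma: no cover
            pass

    @staticmethod
    def _from_eig(w, V, Vinv, t: float) -> np.ndarray:
        P = (V * np.exp(w * t)) @ Vinv
        return np.real(P)

    def probs(self, t: float) -> np.ndarray:
        if t < 0:
            raise ValueError(f"elapsed time must be >= 0, got {t}")
        P = self._cache.get(t)
        if P is None:
            if self._eig_ok:
                P = self._from_eig(self._w, self._V, self._Vinv, t)
            else:
                P = scipy.linalg.expm(self.Q * t)
            np.clip(P, 0.0, 1.0, out=P)
            self._cache[t] = P
        return P

    def apply(self, t: float, v: np.ndarray) -> np.ndarray:
        """``expm(Q t) @ v`` without materializing the matrix when possible.

        With an accepted eigendecomposition this is two matvecs.  Otherwise
        fast-mode kernels use the uniformization series
        ``e^{-Omega t} sum_n (Omega t)^n / n! R^n v`` with
        ``R = I + Q / Omega`` — all terms non-negative for probability
        vectors, so there is no cancellation — truncated at a 1e-14 Poisson
        tail.  Exact-mode kernels multiply by the cached ``expm`` matrix.
        """
        if t < 0:
            raise ValueError(f"elapsed time must be >= 0, got {t}")
        if self._eig_ok:
            out = np.real(self._V @ (np.exp(self._w * t) * (self._Vinv @ v)))
            np.clip(out, 0.0, None, out=out)
            return out
        if not self._fast:
            return self.probs(t) @ v
        if self._omega is None:
            self._omega = float(np.max(-np.diag(self.Q)))
            if self._omega > 0:
                self._R = np.eye(self.Q.shape[0]) + self.Q / self._omega
        mu = self._omega * t
        if mu == 0.0:
            return v.copy()
        if mu > 200.0:  # pragma: no cover - extreme rate x time products
            return self.probs(t) @ v
        out = np.zeros_like(v, dtype=float)
        term = v.astype(float)
        log_w = -mu  # log Poisson weight, updated iteratively
        n = 0
        tail = 1.0
        while True:
            w = math.exp(log_w)
            out += w * term
            tail -= w
            if tail < 1e-14 or (n > mu and w < 1e-16):
                break
            n += 1
            log_w += math.log(mu) - math.log(n)
            term = self._R @ term
        np.clip(out, 0.0, None, out=out)
        return out

    def apply_batch(self, ts: np.ndarray, V: np.ndarray) -> np.ndarray:
        """Row-wise action: ``out[b] = expm(Q ts[b]) @ V[b]``.

        Batches the eigendecomposition or uniformization series across all
        rows so the cost is a handful of matmuls, not one series per row.
        """
        ts = np.asarray(ts, dtype=float)
        V = np.asarray(V, dtype=float)
        if np.any(ts < 0):
            raise ValueError("elapsed times must be >= 0")
        if self._eig_ok:
            X = (V @ self._Vinv.T) * np.exp(np.outer(ts, self._w))
            out = np.real(X @ self._V.T)
            np.clip(out, 0.0, None, out=out)
            return out
        if not self._fast:
            return np.stack([self.probs(t) @ v for t, v in zip(ts, V)])
        if self._omega is None:
            self._omega = float(np.max(-np.diag(self.Q)))
            if self._omega > 0:
                self._R = np.eye(self.Q.shape[0]) + self.Q / self._omega
        mus = self._omega * ts
        if self._omega == 0.0:
            return V.copy()
        if np.max(mus) > 200.0:  # pragma: no cover
            return np.stack([self.apply(t, v) for t, v in zip(ts, V)])
        Rt = self._R.T
        out = np.zeros_like(V)
        term = V.copy()
        w = np.exp(-mus)  # Poisson weights, updated iteratively per row
        cum = w.copy()
        n = 0
        mu_max = float(np.max(mus))
        n_cap = int(mu_max + 12 * math.sqrt(mu_max + 1) + 30)
        while True:
            out += w[:, None] * term
            if np.min(cum) > 1.0 - 1e-14 or n >= n_cap:
                break
            n += 1
            w = w * (mus / n)
            cum += w
            term = term @ Rt
        np.clip(out, 0.0, None, out=out)
        return out


class TreeIndex:
    """Array view of a phylogeny for postorder dynamic programming.

    Nodes are numbered in postorder (tips first within their subtrees, root
    last).  ``edge_length[i]`` is the branch above node ``i`` (NaN for the
    root).
    """

    def __init__(self, phylogeny: Phylogeny):
        tree = phylogeny.dendropy_tree
        nodes = list(tree.postorder_node_iter())
        self.n_nodes = len(nodes)
        self._node_of = {id(nd): i for i, nd in enumerate(nodes)}
        self.parent = np.full(self.n_nodes, -1, dtype=int)
        self.edge_length = np.full(self.n_nodes, np.nan)
        self.children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        self.tip_index: dict[str, int] = {}
        from karyoevo.karyodata import normalize_species

        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                p = self._node_of[id(nd.parent_node)]
                self.parent[i] = p
                self.children[p].append(i)
                self.edge_length[i] = float(nd.edge.length or 0.0)
            if nd.is_leaf():
                self.tip_index[normalize_species(nd.taxon.label)] = i
        self.root = self.n_nodes - 1
        self.postorder = np.arange(self.n_nodes)
        self.tips = np.array(sorted(self.tip_index.values()), dtype=int)
        # leaf-height waves: all of a node's children live in earlier waves,
        # so per-wave message passing can be batched
        height = np.zeros(self.n_nodes, dtype=int)
        for i in self.postorder:
            if self.children[i]:
                height[i] = 1 + max(height[c] for c in self.children[i])
        self.node_height = height
        self.waves = [
            np.flatnonzero(height == h) for h in range(height[self.root] + 1)
        ]

    @property
    def n_tips(self) -> int:
        return len(self.tip_index)


def _tip_likelihoods(
    tip_states: Mapping[str, tuple[int, str]],
    index: TreeIndex,
    space: StateSpace,
) -> np.ndarray:
    """Per-node partial likelihood array, tips set to point masses."""
    L = np.ones((index.n_nodes, space.size))
    seen = set()
    for tip, (k, scs) in tip_states.items():
        if tip not in index.tip_index:
            raise ValueError(f"tip {tip!r} not on the tree")
        j = space.index_for_tip(k, scs, tip=tip)
        row = np.zeros(space.size)
        row[j] = 1.0
        L[index.tip_index[tip]] = row
        seen.add(tip)
    missing = set(index.tip_index) - seen
    if missing:
        raise ValueError(f"no state for tip(s): {sorted(missing)}")
    return L


def compute_partials(
    tip_states: Mapping[str, tuple[int, str]],
    index: TreeIndex,
    space: StateSpace,
    kernel: TransitionKernel,
) -> tuple[np.ndarray, float]:
    """Felsenstein pruning pass.

    Returns (per-node scaled partial likelihoods, summed log scaling
    factors).  ``partials[root] * exp(log_scale)`` recovers the unscaled
    root conditional likelihoods.
    """
    L = _tip_likelihoods(tip_states, index, space)
    log_scale = 0.0
    for h, wave in enumerate(index.waves):
        if h > 0:
            # partials of this wave's internal nodes are now complete
            for i in wave:
                m = L[i].max()
                if m <= 0.0:
                    return L, -np.inf
                L[i] /= m
                log_scale += float(np.log(m))
        senders = wave[wave != index.root]
        if len(senders) == 0:
            continue
        msgs = kernel.apply_batch(index.edge_length[senders], L[senders])
        for row, i in enumerate(senders):
            L[index.parent[i]] *= msgs[row]
    return L, log_scale


def root_weights(root_partial: np.ndarray, root_mode: str | int) -> np.ndarray:
    """Prior weight over root states.

    ``"flat"`` — uniform; ``"fitzjohn"`` — each state weighted by its share
    of the conditional likelihood; an integer — all mass on that state.
    """
    n = len(root_partial)
    if isinstance(root_mode, (int, np.integer)):
        w = np.zeros(n)
        w[int(root_mode)] = 1.0
        return w
    if root_mode == "flat":
        return np.full(n, 1.0 / n)
    if root_mode == "fitzjohn":
        total = root_partial.sum()
        if total <= 0:
            return np.full(n, 1.0 / n)
        return root_partial / total
    raise ValueError(f"unknown root_mode {root_mode!r}")


def log_likelihood(
    tip_states: Mapping[str, tuple[int, str]],
    tree: Phylogeny | TreeIndex,
    Q: np.ndarray | TransitionKernel,
    space: StateSpace,
    root_mode: str | int = "fitzjohn",
) -> float:
    """Log-probability of the tip states under the model, by pruning.

    ``tip_states`` maps tip label to ``(haploid autosome count, SCS
    label)``; in the basic model the label is ignored.  Returns ``-inf``
    when the data have probability zero.
    """
    index = tree if isinstance(tree, TreeIndex) else TreeIndex(tree)
    kernel = Q if isinstance(Q, TransitionKernel) else TransitionKernel(Q)
    L, log_scale = compute_partials(tip_states, index, space, kernel)
    if not np.isfinite(log_scale):
        return -np.inf
    w = root_weights(L[index.root], root_mode)
    lik = float(w @ L[index.root])
    if lik <= 0.0:
        return -np.inf
    return float(np.log(lik) + log_scale)
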