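"""Stochastic character mapping: full histories conditional on tip states.

Node states are drawn first by a backward (pruning) pass followed by
forward conditional draws root-to-tips; branch interiors are then filled
with endpoint-conditioned CTMC paths sampled by uniformization (dominating
rate = max |diagonal of Q|), which terminates for any endpoint pair with
positive probability.  Each map carries its ordered per-branch segments and
a global event list; tallies classify events into the four moves and
accumulate per-state occupancy time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from karyoevo.ctmc_model import (
    StateSpace,
    TransitionKernel,
    TreeIndex,
    classify_move,
    compute_partials,
    root_weights,
)
from karyoevo.karyodata import Phylogeny


@dataclass(frozen=True)
class Event:
    """One state change: ``time`` is measured from the branch's rootward end."""

    branch: int
    time: float
    from_state: int
    to_state: int


@dataclass
class StochasticMap:
    """A sampled piecewise-constant history on one tree.

    ``segments[branch]`` is the ordered list of ``(state, duration)`` pairs
    along the branch above node ``branch``; durations sum to the branch
    length and consecutive segments differ in state.  ``node_states`` gives
    the sampled state at every node (postorder numbering of the TreeIndex).
    """

    segments: dict[int, list[tuple[int, float]]]
    events: list[Event]
    node_states: np.ndarray

    @property
    def n_events(self) -> int:
        return len(self.events)


@dataclass
class EventTally:
    """Event counts by class plus per-state occupancy durations."""

    n_fission: int = 0
    n_autosomal_fusion: int = 0
    n_sa_fusion: int = 0
    n_reversion: int = 0
    durations: dict[int, float] = field(default_factory=dict)

    @property
    def total_duration(self) -> float:
        return sum(self.durations.values())

    @property
    def n_total_fusions(self) -> int:
        """All chromosome-number-reducing fusions (autosomal + SA)."""
        return self.n_autosomal_fusion + self.n_sa_fusion


class _Uniformizer:
    """Endpoint-conditioned path sampler for one generator."""

    def __init__(self, Q: np.ndarray, kernel: TransitionKernel):
        self.Q = Q
        self.kernel = kernel
        self.omega = float(np.max(-np.diag(Q)))
        n = Q.shape[0]
        if self.omega > 0:
            self.R = np.eye(n) + Q / self.omega
        else:
            self.R = np.eye(n)
        self._R_pows = [np.eye(n), self.R]

    def _R_pow(self, n: int) -> np.ndarray:
        while len(self._R_pows) <= n:
            self._R_pows.append(self._R_pows[-1] @ self.R)
        return self._R_pows[n]

    def _sample_n_jumps(
        self, a: int, b: int, t: float, rng: np.random.Generator
    ) -> int:
        """Number of uniformized (possibly virtual) jumps on the bridge."""
        p_ab = self.kernel.probs(t)[a, b]
        if p_ab <= 0:
            raise ValueError(
                f"endpoint pair ({a}->{b}) has zero probability over t={t}"
            )
        mu = self.omega * t
        u = rng.random() * p_ab
        log_pois = -mu
        cum = 0.0
        n = 0
        while True:
            cum += np.exp(log_pois) * self._R_pow(n)[a, b]
            if u <= cum:
                return n
            n += 1
            log_pois += np.log(mu) - np.log(n)
            if n > 10 + 50 * max(mu, 1.0):  # pragma: no cover
                return n

    def sample_path(
        self, a: int, b: int, t: float, rng: np.random.Generator
    ) -> list[tuple[int, float]]:
        """Segments of an endpoint-conditioned path from ``a`` to ``b``.

        Returns ``(state, duration)`` pairs summing to ``t``; virtual
        (self) jumps are removed, so consecutive states differ.
        """
        if t <= 0:
            if a != b:
                raise ValueError("zero-length branch with differing endpoints")
            return [(a, 0.0)]
        if self.omega == 0.0:
            if a != b:
                raise ValueError("state change impossible under a zero generator")
            return [(a, t)]
        n = self._sample_n_jumps(a, b, t, rng)
        if n == 0:
            return [(a, t)]
        # jump times: order statistics of n uniforms on (0, t)
        times = np.sort(rng.random(n)) * t
        # state chain via backward products of R
        states = [a]
        for i in range(1, n):
            prev = states[-1]
            w = self.R[prev, :] * self._R_pow(n - i)[:, b]
            total = w.sum()
            if total <= 0:  # pragma: no cover - guarded by _sample_n_jumps
                raise ValueError("uniformization bridge has no support")
            states.append(int(rng.choice(len(w), p=w / total)))
        states.append(b)
        # collapse virtual jumps into segments
        segs: list[tuple[int, float]] = []
        bounds = np.concatenate([[0.0], times, [t]])
        cur_state = states[0]
        cur_start = 0.0
        for i in range(1, n + 1):
            if states[i] != cur_state:
                segs.append((cur_state, bounds[i] - cur_start))
                cur_state = states[i]
                cur_start = bounds[i]
        segs.append((cur_state, t - cur_start))
        return segs


def _sample_node_states(
    partials: np.ndarray,
    index: TreeIndex,
    kernel: TransitionKernel,
    root_mode: str | int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Joint draw of all node states given tip data (forward pass)."""
    n_states = partials.shape[1]
    states = np.full(index.n_nodes, -1, dtype=int)
    w = root_weights(partials[index.root], root_mode) * partials[index.root]
    total = w.sum()
    if total <= 0:
        raise ValueError("tip configuration has zero probability")
    states[index.root] = int(rng.choice(n_states, p=w / total))
    for i in range(index.n_nodes - 1, -1, -1):  # preorder = reverse postorder
        if i == index.root:
            continue
        parent_state = states[index.parent[i]]
        P = kernel.probs(float(index.edge_length[i]))
        w = P[parent_state, :] * partials[i]
        total = w.sum()
        if total <= 0:
            raise ValueError("conditional node draw has zero support")
        states[i] = int(rng.choice(n_states, p=w / total))
    return states


def sample_history(
    tip_states: Mapping[str, tuple[int, str]],
    tree: Phylogeny | TreeIndex,
    Q: np.ndarray,
    space: StateSpace,
    n_maps: int,
    seed: int | np.random.Generator,
    root_mode: str | int = "fitzjohn",
) -> list[StochasticMap]:
    """Draw ``n_maps`` histories conditional on tip states and ``Q``."""
    if n_maps < 1:
        raise ValueError("n_maps must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    index = tree if isinstance(tree, TreeIndex) else TreeIndex(tree)
    kernel = TransitionKernel(Q, method="auto")
    partials, log_scale = compute_partials(tip_states, index, space, kernel)
    if not np.isfinite(log_scale):
        raise ValueError("tip configuration has zero probability under Q")
    sampler = _Uniformizer(Q, kernel)
    maps: list[StochasticMap] = []
    for _ in range(n_maps):
        node_states = _sample_node_states(
            partials, index, kernel, root_mode, rng
        )
        segments: dict[int, list[tuple[int, float]]] = {}
        events: list[Event] = []
        for i in range(index.n_nodes):
            if i == index.root:
                continue
            a = node_states[index.parent[i]]
            b = node_states[i]
            segs = sampler.sample_path(a, b, float(index.edge_length[i]), rng)
            segments[i] = segs
            elapsed = 0.0
            for (s0, d0), (s1, _) in zip(segs[:-1], segs[1:]):
                elapsed += d0
                events.append(
                    Event(branch=i, time=elapsed, from_state=s0, to_state=s1)
                )
        maps.append(
            StochasticMap(
                segments=segments, events=events, node_states=node_states
            )
        )
    return maps


def tally_events(smap: StochasticMap, space: StateSpace) -> EventTally:
    """Classify a map's events and accumulate per-state occupancy times.

    Raises ``ValueError`` on any event that is not one of the four allowed
    moves (a corrupt map).
    """
    tally = EventTally()
    for ev in smap.events:
        move = classify_move(space, ev.from_state, ev.to_state)
        if move == "fission":
            tally.n_fission += 1
        elif move == "fusion":
            tally.n_autosomal_fusion += 1
        elif move == "sa_fusion":
            tally.n_sa_fusion += 1
        else:
            tally.n_reversion += 1
    for segs in smap.segments.values():
        for state, dur in segs:
            tally.durations[state] = tally.durations.get(state, 0.0) + dur
    return tally
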