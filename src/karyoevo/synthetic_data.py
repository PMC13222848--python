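"""Synthetic trees, true histories, and tip karyotype tables.

Emulates the statistical shape of the study inputs without any downloads:
birth--death trees with branch lengths in units of 10^8 years, karyotypes
evolved generatively under the same bounded Markov model the inference
uses (moves that would exit the count range are suppressed), and a
configurable fraction of tips carrying a second, conflicting record.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from karyoevo.ctmc_model import (
    RateParams,
    StateSpace,
    TreeIndex,
    build_rate_matrix,
    build_state_space,
)
from karyoevo.karyodata import KaryotypeRecord, Phylogeny, write_karyotype_table
from karyoevo.stochmap import Event, StochasticMap

#: model system -> SCS label used when writing tip tables
SYSTEM_TO_SCS = {"simple": "XY", "neo": "neoXY", "none": "XY"}


@dataclass
class SimConfig:
    """Everything needed to generate one reproducible synthetic dataset."""

    n_tips: int = 200
    birth: float = 1.0
    death: float = 0.0
    params: RateParams = field(
        default_factory=lambda: RateParams(0.3, 0.7, 0.6, 0.2)
    )
    root_k: int = 9
    root_system: str = "simple"
    k_min: int = 1
    k_max: int = 30
    scs_mode: bool = True
    multi_record_fraction: float = 0.0
    tree_depth: float | None = None  # rescale crown depth to this many units
    n_trees: int = 1
    jitter_sd: float = 0.1  # lognormal branch jitter for extra trees
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tips < 3:
            raise ValueError("n_tips must be >= 3")
        if self.birth <= self.death or self.death < 0:
            raise ValueError("need birth > death >= 0")
        if not (0 <= self.multi_record_fraction <= 1):
            raise ValueError("multi_record_fraction must be in [0, 1]")
        if not (self.k_min <= self.root_k <= self.k_max):
            raise ValueError("root_k outside [k_min, k_max]")

    @property
    def space(self) -> StateSpace:
        return build_state_space(self.k_min, self.k_max, self.scs_mode)


@dataclass
class SyntheticDataset:
    """Generated trees, the true history, tip records, and the truth record."""

    trees: list[Phylogeny]
    true_map: StochasticMap
    tip_states: dict[str, tuple[int, str]]
    records: list[KaryotypeRecord]
    space: StateSpace
    truth: dict


class _SimNode:
    __slots__ = ("start", "end", "children", "alive", "label")

    def __init__(self, start: float):
        self.start = start
        self.end: float | None = None
        self.children: list[_SimNode] = []
        self.alive = True
        self.label: str | None = None


def _prune_extinct(node: _SimNode) -> _SimNode | None:
    """Drop extinct subtrees, suppressing resulting unifurcations."""
    if not node.children:
        return node if node.alive else None
    kept = [c for c in (_prune_extinct(c) for c in node.children) if c]
    if not kept:
        return None
    if len(kept) == 1:
        child = kept[0]
        child.start = node.start
        return child
    node.children = kept
    return node


def _to_newick(node: _SimNode) -> str:
    length = (node.end if node.end is not None else node.start) - node.start
    if not node.children:
        return f"{node.label}:{length:.10g}"
    inner = ",".join(_to_newick(c) for c in node.children)
    return f"({inner}):{length:.10g}"


def simulate_tree(
    n_tips: int,
    birth: float,
    death: float,
    seed: int | np.random.Generator,
    duration: float | None = None,
    max_tries: int = 1000,
) -> Phylogeny:
    """Simulate a rooted ultrametric birth--death tree.

    By default the process starts from two crown lineages and stops the
    instant the extant count reaches ``n_tips`` would-be-exceeded (all tips
    extended to the time of the next scheduled event).  With ``duration``
    set, the process instead runs to that fixed time and ``n_tips`` acts as
    a minimum.  Full extinction triggers a retry, up to ``max_tries``.
    """
    if n_tips < 3:
        raise ValueError("n_tips must be >= 3")
    if not (birth > death >= 0):
        raise ValueError("need birth > death >= 0")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    p_birth = 1.0 if birth + death == 0 else birth / (birth + death)
    for _ in range(max_tries):
        root = _SimNode(0.0)
        root.end = 0.0
        active = [_SimNode(0.0), _SimNode(0.0)]
        root.children = list(active)
        t = 0.0
        failed = False
        while True:
            n = len(active)
            if n == 0:
                failed = True
                break
            dt = rng.exponential(1.0 / (n * (birth + death)))
            if duration is not None and t + dt > duration:
                t_end = duration
                break
            if duration is None and n == n_tips:
                t_end = t + dt
                break
            t += dt
            i = int(rng.integers(n))
            node = active.pop(i)
            node.end = t
            if rng.random() < p_birth:
                node.children = [_SimNode(t), _SimNode(t)]
                active.extend(node.children)
            else:
                node.alive = False
        if failed or len(active) < (3 if duration is not None else n_tips):
            continue
        for leaf in active:
            leaf.end = t_end
        pruned = _prune_extinct(root)
        if pruned is None or not pruned.children:
            continue
        leaves = [nd for nd in _iter_leaves(pruned)]
        for j, leaf in enumerate(leaves, start=1):
            leaf.label = f"t{j}"
        pruned.start = pruned.end = 0.0  # root stem suppressed
        newick = f"({','.join(_to_newick(c) for c in pruned.children)});"
        return Phylogeny.from_newick(newick)
    raise RuntimeError(
        f"birth-death simulation failed to reach {n_tips} tips in "
        f"{max_tries} attempts"
    )


def _iter_leaves(node: _SimNode):
    if not node.children:
        yield node
    else:
        for c in node.children:
            yield from _iter_leaves(c)


def simulate_history(
    tree: Phylogeny,
    params: RateParams,
    root_state: tuple[int, str],
    space: StateSpace,
    seed: int | np.random.Generator,
) -> tuple[StochasticMap, dict[str, tuple[int, str]]]:
    """Gillespie simulation of the model forward along every branch.

    Returns the full true history and the tip states it produced, as a
    mapping tip label -> ``(haploid autosome count, SCS label)``.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    Q = build_rate_matrix(params, space)
    index = TreeIndex(tree)
    root_index = space.index(*root_state)
    node_states = np.full(index.n_nodes, -1, dtype=int)
    node_states[index.root] = root_index
    segments: dict[int, list[tuple[int, float]]] = {}
    events: list[Event] = []
    for i in range(index.n_nodes - 1, -1, -1):  # preorder
        if i == index.root:
            continue
        state = int(node_states[index.parent[i]])
        remaining = float(index.edge_length[i])
        segs: list[tuple[int, float]] = []
        elapsed = 0.0
        while True:
            exit_rate = -Q[state, state]
            if exit_rate <= 0:
                segs.append((state, remaining))
                break
            wait = rng.exponential(1.0 / exit_rate)
            if wait >= remaining:
                segs.append((state, remaining))
                break
            segs.append((state, wait))
            elapsed += wait
            remaining -= wait
            probs = Q[state, :].clip(min=0.0)
            probs /= probs.sum()
            new_state = int(rng.choice(space.size, p=probs))
            events.append(
                Event(branch=i, time=elapsed, from_state=state,
                      to_state=new_state)
            )
            state = new_state
        node_states[i] = state
        segments[i] = segs
    smap = StochasticMap(
        segments=segments, events=events, node_states=node_states
    )
    tip_states = {}
    for label, node in index.tip_index.items():
        k, system = space.state(int(node_states[node]))
        tip_states[label] = (k, SYSTEM_TO_SCS[system])
    return smap, tip_states


def _jitter_tree(
    tree: Phylogeny, sd: float, rng: np.random.Generator
) -> Phylogeny:
    """Lognormal branch-length jitter (emulates posterior tree spread)."""
    clone = tree.dendropy_tree.clone(depth=1)
    for edge in clone.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= float(np.exp(rng.normal(0.0, sd)))
    return Phylogeny(clone)


def make_dataset(
    config: SimConfig, outdir: str | Path | None = None
) -> SyntheticDataset:
    """Generate a full synthetic dataset, optionally writing it to disk.

    The first tree carries the true history; additional trees are
    branch-length-jittered copies standing in for posterior tree
    uncertainty.  A configurable fraction of tips receives a second,
    conflicting record (count perturbed by one, system kept).  Output files
    are plain text: ``trees.nwk``, ``karyotypes.csv``, ``truth.json``.
    """
    rng = np.random.default_rng(config.seed)
    space = config.space
    tree = simulate_tree(config.n_tips, config.birth, config.death, rng)
    if config.tree_depth is not None:
        tree = tree.scaled(config.tree_depth / tree.depth)
    smap, tip_states = simulate_history(
        tree, config.params, (config.root_k, config.root_system), space, rng
    )
    trees = [tree] + [
        _jitter_tree(tree, config.jitter_sd, rng)
        for _ in range(config.n_trees - 1)
    ]
    records: list[KaryotypeRecord] = []
    n_multi = 0
    for tip in sorted(tip_states):
        k, scs = tip_states[tip]
        records.append(KaryotypeRecord(tip, k, scs, source="truth"))
        if rng.random() < config.multi_record_fraction:
            delta = 1 if rng.random() < 0.5 else -1
            k2 = int(np.clip(k + delta, max(1, config.k_min), config.k_max))
            if k2 != k:
                records.append(
                    KaryotypeRecord(tip, k2, scs, source="conflict")
                )
                n_multi += 1
    truth = {
        "seed": config.seed,
        "n_tips": config.n_tips,
        "params": {
            "fission": config.params.fission,
            "fusion": config.params.fusion,
            "sa_fusion": config.params.sa_fusion,
            "reversion": config.params.reversion,
        },
        "root_state": [config.root_k, config.root_system],
        "k_min": config.k_min,
        "k_max": config.k_max,
        "scs_mode": config.scs_mode,
        "tree_depth": tree.depth,
        "n_trees": config.n_trees,
        "n_multi_record_tips": n_multi,
        "tip_states": {t: list(s) for t, s in sorted(tip_states.items())},
    }
    dataset = SyntheticDataset(
        trees=trees,
        true_map=smap,
        tip_states=tip_states,
        records=records,
        space=space,
        truth=truth,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "trees.nwk", "w") as fh:
            for t in trees:
                fh.write(t.newick() + "\n")
        write_karyotype_table(records, outdir / "karyotypes.csv")
        with open(outdir / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)
    return dataset
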