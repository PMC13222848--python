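"""Bayesian MCMC over transition rates, replicated across a tree sample.

Each rate gets an independent exponential prior (default rate 2, prior mean
0.5 per tree unit).  Sampling is univariate slice sampling within Gibbs:
one recorded sample ("generation") per full sweep over the active
parameters.  The study design fits the model once per tree in a posterior
tree sample, discards a burn-in fraction per chain, and pools the retained
samples — 100 trees x 100 generations x 50% burn-in = 5,000 estimates.
Rates are internal in per-tree-unit form (10^8 yr) and reported also per
million years (divide by 100).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from karyoevo.ctmc_model import (
    RateParams,
    StateSpace,
    TransitionKernel,
    TreeIndex,
    build_rate_matrix,
    default_state_space,
    log_likelihood,
)
from karyoevo.karyodata import MatchedDataset, Phylogeny, match_tips, resolve_tip_states

logger = logging.getLogger(__name__)

#: conversion: rates are per 10^8 years internally, per 10^6 years in reports
PER_MY = 1.0 / 100.0


@dataclass(frozen=True)
class PriorSpec:
    """Independent exponential prior on every active rate."""

    rate: float = 2.0

    def __post_init__(self) -> None:
        if not (self.rate > 0):
            raise ValueError(f"prior rate must be > 0, got {self.rate}")

    @property
    def mean(self) -> float:
        return 1.0 / self.rate


@dataclass(frozen=True)
class HPDInterval:
    """Shortest interval containing at least ``mass`` of the samples."""

    lower: float
    upper: float
    mass: float
    mean: float

    def overlaps(self, other: "HPDInterval") -> bool:
        return not (self.upper < other.lower or other.upper < self.lower)


@dataclass
class PosteriorChain:
    """Posterior samples of the rates, possibly pooled across trees.

    ``samples`` has one row per retained generation with columns
    ``tree_index``, ``generation``, the active rate names, and
    ``log_posterior``.
    """

    samples: pd.DataFrame
    param_names: tuple[str, ...]
    seed: int | None = None
    burn_in: float = 0.0

    def __len__(self) -> int:
        return len(self.samples)

    def param(self, name: str) -> np.ndarray:
        return self.samples[name].to_numpy()

    def means(self) -> dict[str, float]:
        return {p: float(self.samples[p].mean()) for p in self.param_names}


def log_prior(params: RateParams | Sequence[float], prior: PriorSpec,
              scs_mode: bool = True) -> float:
    """Sum of exponential log-densities over the active rates.

    Negative rates get ``-inf`` (zero prior support).
    """
    values = (
        params.as_array(scs_mode)
        if isinstance(params, RateParams)
        else np.asarray(params, dtype=float)
    )
    if np.any(values < 0):
        return -np.inf
    r = prior.rate
    return float(len(values) * math.log(r) - r * values.sum())


def _slice_update(
    x0: float,
    logpost_at: Callable[[float], float],
    f0: float,
    rng: np.random.Generator,
    width: float,
    max_steps: int = 50,
) -> tuple[float, float]:
    """One stepping-out slice-sampling update of a single non-negative rate.

    Returns the new coordinate and its log-posterior.
    """
    log_y = f0 + math.log(rng.random())
    u = rng.random()
    left = x0 - u * width
    right = left + width
    j = int(rng.integers(max_steps))
    k = max_steps - 1 - j
    left = max(left, 0.0)
    while j > 0 and left > 0.0 and logpost_at(left) > log_y:
        left = max(left - width, 0.0)
        j -= 1
    while k > 0 and logpost_at(right) > log_y:
        right += width
        k -= 1
    for _ in range(1000):
        x1 = left + rng.random() * (right - left)
        f1 = logpost_at(x1)
        if f1 >= log_y:
            return x1, f1
        if x1 < x0:
            left = x1
        else:
            right = x1
    # interval collapsed numerically; keep the current point
    return x0, f0


def mcmc_run(
    tip_states: Mapping[str, tuple[int, str]],
    tree: Phylogeny | TreeIndex,
    space: StateSpace,
    n_generations: int,
    seed: int | np.random.Generator,
    prior: PriorSpec = PriorSpec(),
    root_mode: str | int = "fitzjohn",
    tree_index_label: int = 0,
    likelihood_enabled: bool = True,
    init_tries: int = 100,
) -> PosteriorChain:
    """Slice-sampling MCMC for the rates on one tree.

    One sample is recorded per generation (one sweep over the active
    parameters).  The initial state is drawn from the prior; if no draw
    with a finite posterior is found within ``init_tries`` attempts, raise.
    Setting ``likelihood_enabled=False`` samples the prior alone (used for
    sampler calibration).
    """
    if n_generations < 2:
        raise ValueError("n_generations must be >= 2")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    scs_mode = space.scs_mode
    names = RateParams.param_names(scs_mode)
    n_par = len(names)
    index = tree if isinstance(tree, TreeIndex) else TreeIndex(tree)

    def log_post(values: np.ndarray) -> float:
        lp = log_prior(values, prior, scs_mode)
        if not np.isfinite(lp):
            return -np.inf
        if not likelihood_enabled:
            return lp
        params = RateParams.from_array(values, scs_mode)
        Q = build_rate_matrix(params, space)
        kernel = TransitionKernel(Q, method="auto")
        ll = log_likelihood(tip_states, index, kernel, space, root_mode)
        return lp + ll if np.isfinite(ll) else -np.inf

    x = None
    for _ in range(init_tries):
        cand = rng.exponential(prior.mean, size=n_par)
        f = log_post(cand)
        if np.isfinite(f):
            x = cand
            break
    if x is None:
        raise RuntimeError(
            f"no finite-posterior initialization found in {init_tries} tries"
        )

    width = max(2.0 * prior.mean, 0.5)
    rows = np.empty((n_generations, n_par))
    lps = np.empty(n_generations)
    for g in range(n_generations):
        for d in range(n_par):
            def logpost_at(v: float, d: int = d) -> float:
                y = x.copy()
                y[d] = v
                return log_post(y)

            x[d], f = _slice_update(x[d], logpost_at, f, rng, width)
        rows[g] = x
        lps[g] = f
    df = pd.DataFrame(rows, columns=list(names))
    df.insert(0, "generation", np.arange(n_generations))
    df.insert(0, "tree_index", tree_index_label)
    df["log_posterior"] = lps
    return PosteriorChain(
        samples=df,
        param_names=names,
        seed=None if isinstance(seed, np.random.Generator) else int(seed),
    )


def retained_count(n_generations: int, burn_in: float) -> int:
    """Samples kept per chain: ``ceil((1 - burn_in) * n_generations)``."""
    if not (0 <= burn_in < 1):
        raise ValueError(f"burn_in must be in [0, 1), got {burn_in}")
    return math.ceil((1.0 - burn_in) * n_generations)


def discard_burn_in(chain: PosteriorChain, burn_in: float) -> PosteriorChain:
    keep = retained_count(len(chain.samples), burn_in)
    df = chain.samples.iloc[len(chain.samples) - keep:].reset_index(drop=True)
    return PosteriorChain(df, chain.param_names, chain.seed, burn_in)


def multi_tree_posterior(
    trees: Sequence[Phylogeny] | Sequence[MatchedDataset],
    records: Sequence | None,
    n_generations: int,
    burn_in: float,
    seed: int,
    space: StateSpace | None = None,
    scs_mode: bool = False,
    prior: PriorSpec = PriorSpec(),
    root_mode: str | int = "fitzjohn",
) -> PosteriorChain:
    """Fit the model on every tree and pool the post-burn-in samples.

    Per tree: a fresh uniform resolution of multi-record tips, a fresh
    chain, burn-in discarded.  Per-tree seeds are spawned deterministically
    from the master seed, so the pooled posterior is reproducible and
    per-tree runs are independent.  Pooled sample count is exactly
    ``n_trees * ceil((1 - burn_in) * n_generations)``.
    """
    if len(trees) == 0:
        raise ValueError("need at least one tree")
    retained_count(n_generations, burn_in)  # validates burn_in
    if isinstance(trees[0], MatchedDataset):
        datasets: list[MatchedDataset] = list(trees)  # type: ignore[arg-type]
    else:
        datasets = match_tips(trees, records)  # type: ignore[arg-type]
    if space is None:
        counts = [
            r.haploid_autosomes
            for ds in datasets
            for recs in ds.records_by_tip.values()
            for r in recs
        ]
        space = default_state_space(counts, scs_mode)
    streams = np.random.SeedSequence(seed).spawn(len(datasets))
    pooled: list[pd.DataFrame] = []
    for i, (ds, ss) in enumerate(zip(datasets, streams)):
        rng = np.random.default_rng(ss)
        try:
            tip_states = resolve_tip_states(ds, rng)
            chain = mcmc_run(
                tip_states,
                ds.phylogeny,
                space,
                n_generations,
                rng,
                prior=prior,
                root_mode=root_mode,
                tree_index_label=i,
            )
        except Exception as exc:
            raise RuntimeError(f"tree {i}: MCMC failed: {exc}") from exc
        pooled.append(discard_burn_in(chain, burn_in).samples)
        logger.info("tree %d/%d: chain done", i + 1, len(datasets))
    df = pd.concat(pooled, ignore_index=True)
    return PosteriorChain(
        df, RateParams.param_names(space.scs_mode), int(seed), burn_in
    )


def hpd_interval(samples: Sequence[float], mass: float = 0.95) -> HPDInterval:
    """Shortest contiguous window of the sorted samples holding
    ``ceil(mass * n)`` of them."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    if n == 0:
        raise ValueError("hpd_interval needs at least one sample")
    if not (0 < mass < 1):
        raise ValueError(f"mass must be in (0, 1), got {mass}")
    m = min(math.ceil(mass * n), n)
    if m == n:
        lo, hi = x[0], x[-1]
    else:
        widths = x[m - 1:] - x[: n - m + 1]
        j = int(np.argmin(widths))
        lo, hi = x[j], x[j + m - 1]
    return HPDInterval(
        lower=float(lo), upper=float(hi), mass=mass, mean=float(x.mean())
    )


def summarize_chain(
    chain: PosteriorChain, mass: float = 0.95
) -> dict[str, dict[str, float]]:
    """Per-parameter posterior mean and HPD, in tree units and per My."""
    out: dict[str, dict[str, float]] = {}
    for p in chain.param_names:
        iv = hpd_interval(chain.param(p), mass)
        out[p] = {
            "mean": iv.mean,
            "hpd_lower": iv.lower,
            "hpd_upper": iv.upper,
            "mean_per_my": iv.mean * PER_MY,
            "hpd_lower_per_my": iv.lower * PER_MY,
            "hpd_upper_per_my": iv.upper * PER_MY,
            "mass": mass,
        }
    return out


def compare_rates(
    chains: Mapping[str, PosteriorChain], mass: float = 0.95
) -> dict:
    """Per-group HPD intervals plus pairwise overlap verdicts per rate.

    Two groups are called ``different`` for a rate iff their HPD intervals
    are disjoint (the study's significance criterion).
    """
    if len(chains) < 2:
        raise ValueError("compare_rates needs at least two groups")
    groups = list(chains)
    params = chains[groups[0]].param_names
    intervals = {
        g: {p: hpd_interval(chains[g].param(p), mass) for p in params}
        for g in groups
    }
    verdicts: dict[str, dict[tuple[str, str], str] | dict] = {}
    for p in params:
        verdicts[p] = {}
        for a_i, a in enumerate(groups):
            for b in groups[a_i:]:
                disjoint = (a != b) and not intervals[a][p].overlaps(
                    intervals[b][p]
                )
                verdicts[p][(a, b)] = "different" if disjoint else "not different"
    return {"intervals": intervals, "verdicts": verdicts, "mass": mass}
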