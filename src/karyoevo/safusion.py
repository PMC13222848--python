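"""Excess test for sex-chromosome--autosome (SA) fusions.

The observed statistic per stochastic map is the share of all fusions that
involve a sex chromosome.  The null expectation assumes every fusion picks
a uniformly random chromosome pair; for a state with ``k`` autosome pairs
and a simple (XY/XO) system the haploid-complement formulation gives
``k / C(k+1, 2) = 2 / (k + 1)``.  The per-map null is the occupancy-time
weighted average of that expectation over the simple-system states the map
visits.  Two 95% HPD intervals (observed vs null, across maps) that do not
overlap constitute the excess/paucity verdict.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from karyoevo.bayes_infer import HPDInterval, hpd_interval
from karyoevo.ctmc_model import StateSpace
from karyoevo.stochmap import EventTally

FORMULATIONS = ("haploid", "diploid")


@dataclass
class SAFusionResult:
    """Observed vs null SA-fusion proportion distributions and the verdict.

    ``verdict`` is ``excess`` iff the observed HPD lies wholly above the
    null HPD, ``deficit`` iff wholly below, else ``indistinguishable``.
    """

    observed: np.ndarray
    null: np.ndarray
    observed_hpd: HPDInterval
    null_hpd: HPDInterval
    verdict: str
    n_maps_excluded: int = 0

    @property
    def observed_mean(self) -> float:
        return float(self.observed.mean())

    @property
    def null_mean(self) -> float:
        return float(self.null.mean())


def expected_sa_proportion(
    k: int, scs: str = "simple", formulation: str = "haploid"
) -> float:
    """Null share of fusions that involve a sex chromosome, for one state.

    ``haploid`` (default): one fusion picks an unordered pair from the
    haploid complement of ``k`` autosomes plus one sex element, so
    ``k / C(k+1, 2) = 2 / (k + 1)``.  ``diploid``: pairs are drawn from
    ``2k`` autosomes plus X plus Y, excluding the ``k`` homologous autosome
    pairs and the X--Y pair, giving ``4k / (C(2k+2, 2) - k - 1)``.  Both
    evaluate to 0.2 at ``k = 9``.  Neo-system states cannot undergo a
    further SA-fusion under the model and return 0.
    """
    if k < 1:
        raise ValueError(f"autosome count must be >= 1, got {k}")
    if formulation not in FORMULATIONS:
        raise ValueError(f"formulation must be one of {FORMULATIONS}")
    if scs == "neo":
        return 0.0
    if formulation == "haploid":
        return k / comb(k + 1, 2)
    return 4 * k / (comb(2 * k + 2, 2) - k - 1)


def weighted_null_proportion(
    tally: EventTally,
    space: StateSpace,
    formulation: str = "haploid",
    include_neo: bool = False,
) -> float:
    """Occupancy-weighted null SA-fusion share for one map.

    Averages :func:`expected_sa_proportion` over the states in the tally's
    duration map, weighted by time spent in each.  Neo-system states are
    excluded from both sums by default (no SA-fusion is possible there);
    ``include_neo=True`` keeps their durations in the denominator with a
    zero expectation.
    """
    if tally.total_duration <= 0:
        raise ValueError("tally has zero total duration")
    num = 0.0
    den = 0.0
    for state_index, dur in tally.durations.items():
        k, system = space.state(state_index)
        if system == "neo" and not include_neo:
            continue
        num += dur * expected_sa_proportion(k, system, formulation)
        den += dur
    if den <= 0:
        raise ValueError("no occupancy time in SA-fusion-eligible states")
    return num / den


def observed_sa_proportion(tally: EventTally) -> float | None:
    """Share of fusions that were SA-fusions; ``None`` if no fusions occurred."""
    total = tally.n_total_fusions
    if total == 0:
        return None
    return tally.n_sa_fusion / total


def sa_fusion_test(
    tallies: Sequence[EventTally],
    space: StateSpace,
    mass: float = 0.95,
    formulation: str = "haploid",
    include_neo: bool = False,
) -> SAFusionResult:
    """Observed-vs-null HPD comparison across a set of stochastic maps.

    Maps without any fusion have an undefined observed proportion; they are
    excluded from the observed distribution and counted in
    ``n_maps_excluded``.  At least two usable maps are required.
    """
    observed = []
    null = []
    excluded = 0
    for tally in tallies:
        obs = observed_sa_proportion(tally)
        if obs is None:
            excluded += 1
            continue
        observed.append(obs)
        null.append(weighted_null_proportion(tally, space, formulation, include_neo))
    if len(observed) < 2:
        raise ValueError(
            f"need >= 2 maps with defined observed proportion, got {len(observed)}"
        )
    obs_arr = np.asarray(observed)
    null_arr = np.asarray(null)
    obs_hpd = hpd_interval(obs_arr, mass)
    null_hpd = hpd_interval(null_arr, mass)
    if obs_hpd.lower > null_hpd.upper:
        verdict = "excess"
    elif obs_hpd.upper < null_hpd.lower:
        verdict = "deficit"
    else:
        verdict = "indistinguishable"
    return SAFusionResult(
        observed=obs_arr,
        null=null_arr,
        observed_hpd=obs_hpd,
        null_hpd=null_hpd,
        verdict=verdict,
        n_maps_excluded=excluded,
    )


def per_tree_tally(
    results: Mapping[int | str, SAFusionResult],
) -> tuple[int, pd.DataFrame]:
    """Count trees with an ``excess`` verdict; return count and a table."""
    if not results:
        raise ValueError("per_tree_tally needs at least one tree result")
    rows = []
    for tree, res in results.items():
        rows.append(
            {
                "tree": tree,
                "observed_mean": res.observed_mean,
                "observed_hpd_lower": res.observed_hpd.lower,
                "observed_hpd_upper": res.observed_hpd.upper,
                "null_mean": res.null_mean,
                "null_hpd_lower": res.null_hpd.lower,
                "null_hpd_upper": res.null_hpd.upper,
                "verdict": res.verdict,
                "n_maps_excluded": res.n_maps_excluded,
            }
        )
    table = pd.DataFrame(rows)
    n_excess = int((table["verdict"] == "excess").sum())
    return n_excess, table
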