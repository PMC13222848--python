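# karyoevo

Inference of chromosome-number and sex-chromosome-system evolution on
phylogenies. The package implements:

- a bounded continuous-time Markov model over states `(haploid autosome
  count, sex-chromosome system)` with four moves — fission (`k -> k+1`),
  autosomal fusion (`k -> k-1`), sex-chromosome–autosome (SA) fusion
  (`(k, XY) -> (k-1, neo-XY)`), and reversion (`(k, neo-XY) -> (k, XY)`) —
  plus a count-only "basic" variant;
- Felsenstein-pruning likelihoods and Bayesian slice-sampling MCMC of the
  rates, replicated over a posterior sample of trees (per-tree burn-in,
  pooled estimates, fresh random resolution of conflicting tip records per
  tree);
- stochastic character mapping by backward–forward node draws plus
  endpoint-conditioned uniformization, with event tallies and per-state
  occupancy durations;
- an SA-fusion excess test: the observed share of fusions that involve a
  sex chromosome is compared, via 95% HPD intervals across maps, against a
  duration-weighted random-fusion null (`2/(k+1)` per simple-system state
  with `k` autosome pairs);
- a synthetic-data generator (birth–death trees, Gillespie trait
  histories, conflicting-record perturbation) so the whole pipeline is
  testable without any external data.

Branch lengths are interpreted in units of 10^8 years; rates are reported
both per tree unit and per million years.

## CLI

Three subcommands, each driven by a YAML config plus a master seed:

```sh
# generate a synthetic dataset (trees.nwk, karyotypes.csv, truth.json)
karyoevo simulate --config src/karyoevo/scenarios/scarab_like.yaml --out run_sim

# fit fission/fusion (and SA) rates across the tree sample
karyoevo rates --config my_rates.yaml --seed 1

# per-tree SA-fusion excess test
karyoevo satest --config my_satest.yaml --seed 1
```

A `rates`/`satest` config names the inputs and run settings:

```yaml
trees: run_sim/trees.nwk          # Newick or Nexus, branch lengths required
karyotypes: run_sim/karyotypes.csv  # columns: species, haploid_autosomes, scs
outdir: run_rates
model: basic                      # basic | scs
generations: 100
burn_in: 0.5
prior_rate: 2.0                   # exponential prior on every rate
groups: groups.csv                # optional per-family grouping (species,group)
```

Each run directory receives a config copy, posterior/event tables as CSV,
and a `summary.json` (per-parameter means and 95% HPDs in both unit
systems, pairwise HPD-overlap verdicts, per-tree excess counts). Identical
config + seed reproduces byte-identical summaries.

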