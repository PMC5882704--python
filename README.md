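# fossilrange

Historical biogeography and diversification analysis for fossil-rich
phylogenies.

Palaeontological datasets come as a cladogram, a table of stratigraphic
ranges (first/last appearance data in Ma), and a presence/absence table of
taxa over discrete areas.  `fossilrange` turns these into a quantitative
biogeographic history: it time-scales the tree from the fossil ages,
fits time-stratified likelihood models of geographic-range evolution,
chooses among them, reconstructs ancestral ranges, counts biogeographic
events by stochastic mapping, and scores diversification shifts and
taxic/phyletic diversity curves on time-sliced trees.  Everything runs
end-to-end on synthetic data, so the whole pipeline is testable without
any external downloads.

## The models

A range is a subset of the area list.  Along a branch, ranges evolve by a
continuous-time Markov process: gain of area *b* at rate
`d · Σ_{a∈R} (dist(a,b)/d̄)^x` and loss of an occupied area at rate `e`
(single-area ranges decay to an absorbing, unobservable null range).
Time is cut into strata, each with its own inter-area distance matrix.
At a node the parent range is partitioned between the daughters by one of
the classic cladogenetic event sets:

* **DEC** — sympatric copy of single-area ranges, subset sympatry, and
  vicariance with one singleton daughter;
* **DIVALIKE** — sympatric copy of single-area ranges and unrestricted
  vicariance;
* **BAYAREA-like** — identity copy only.

Each family comes in tiers M0 (`d, e`), M1 (`+x`, the distance exponent)
and M2 (`+j`, founder-event speciation: a daughter jumps to a new single
area with event weight `j`, non-jump events re-weighted to `(3-j)/3`).
The tree likelihood is computed by Felsenstein pruning with cladogenetic
mixing; nested tiers are compared by likelihood-ratio tests and families
by `AICc = -2LnL + 2k + 2k(k+1)/(n-k-1)` (n = tips).  Biogeographical
stochastic mapping draws complete histories conditional on the tips via
endpoint-conditioned uniformization and tallies six event categories
(range expansion/contraction, founder, sympatry, subset speciation,
vicariance).  Diversification shifts are detected on time-sliced trees
with an equal-rates-Markov imbalance tail, `P(larger daughter ≥ L) =
2(n-L)/(n-1)`, calibrated family-wise by Monte-Carlo, with fossil-aware
artefact flagging.  See `docs/methods.md` for conventions and caveats.

## Worked example

Simulate a ~100-taxon study with the classic 10-area / 3-stratum design,
time-scale it, and fit the DIVALIKE tier ladder:

```python
from fossilrange import (RangeEvolutionModel, timescale_equal,
                         simulate_fossil_tree, simulate_ranges,
                         pleurodira_fixture, model_table)
from fossilrange.model import ModelSpec, ModelParams
from fossilrange.simulate import SimConfig

areas, strata, bins = pleurodira_fixture()
tree, ages = simulate_fossil_tree(
    SimConfig(birth=0.075, death=0.025, psi=0.12, origin=140.0, seed=1004))
geo, truth = simulate_ranges(
    tree, ModelSpec("DIVALIKE", "M2", max_range_size=2),
    ModelParams(d=0.012, e=0.002, x=-1.0, j=0.5),
    strata, root_range=1 << areas.index("AF"), areas=areas, seed=1005,
    max_rejections=5000)

timetree = timescale_equal(tree, ages, root_extension=10.0)
fits = [RangeEvolutionModel(timetree, geo,
                            ModelSpec("DIVALIKE", t, max_range_size=2),
                            strata).fit(n_starts=2, seed=1)
        for t in ("M0", "M1", "M2")]
print(fits[-1].summary())
print(model_table(fits).to_string(index=False))
```

On a 127-taxon realisation this prints

```
Range-evolution model DIVALIKE-M2
  tips: 127   areas: 10   states: 56 (m=2)
  LnL:  -474.8835   k: 4   AICc: 958.0950
  d: 0.00519196 /Myr   e: 3.25489e-08 /Myr
  x: -1.0217
  j: 0.322942
  converged: True

      model         LnL  df  null_model        LRT_p        AICc  delta_AICc  best
DIVALIKE-M2 -474.883547   4 DIVALIKE-M1 2.939039e-12  958.094963    0.000000  True
DIVALIKE-M1 -499.247996   3 DIVALIKE-M0 3.964647e-05 1004.691113   46.596150 False
DIVALIKE-M0 -507.692115   2                      NaN 1019.481005   61.386042 False
```

so adding the distance exponent and then founder-event speciation each
improves fit decisively (LRT p ≈ 4·10⁻⁵ and 3·10⁻¹²), the fitted distance
exponent is negative (dispersal decays with distance, x̂ ≈ −1.0), and the
founder weight is recovered in the right range (ĵ ≈ 0.32 against a
generating 0.5 — the two cladogenetic parameters trade off on a single
realisation).  Stochastic mapping under the winning model,

```python
print(fits[-1].summarize_bsm(n_maps=50, seed=3).round(2).to_string(index=False))
```

```
                  mode              type   mean   sd  percent
             dispersal   range_expansion  96.94 4.06    43.48
             dispersal range_contraction   0.00 0.00     0.00
             dispersal           founder 100.92 4.72    45.27
within-area speciation          sympatry   6.48 2.22     2.91
within-area speciation subset_speciation   0.00 0.00     0.00
            vicariance        vicariance  18.60 4.03     8.34
```

gives the event budget: means and standard deviations over 50 maps, with
percentages of the grand-total mean (they sum to 100).  Here dispersal
(expansions + founder events) accounts for ~89% of all events — the
signature of a jump-rich generating process.

A config-driven CLI wraps the same pipeline (`fossilrange run config.ini`,
plus `timescale`, `fit`, `bsm`, `shifts`, `curves`, `simulate`
subcommands); all outputs are CSV/Newick/JSON.

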