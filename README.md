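# nullnets

Permutation null models for multilayer directed information-sharing
networks.

## The problem

Fixed-choice sociometric surveys ("name up to ten people you exchange
useful information with, and tick which topics you discuss with each")
produce a *multilayer* directed network: one binary layer per topic on
a shared roster of respondents.  Questions like *is the bycatch
information network structured differently from the other fishing
topics?* or *which topic best predicts who discusses bycatch with
whom?* cannot be answered from raw summary statistics, because tie
counts and degree distributions alone push every statistic around.
The standard remedy from network ecology is the permutation null
model: randomize the observed data under controlled constraints,
recompute the statistic on each permuted network, and locate the
observed value in the null distribution.

`nullnets` implements that workflow end to end for nomination data:

* **data model** — nomination records → nine directed binary layers,
  their union, and the dyad-by-layer incidence matrix;
* **statistics** — degree assortativity (endpoint homophily, by in- or
  out-degree), in-eccentricity variance/mean, betweenness variance,
  and the unfolded dyadic correlation between two layers (phi over all
  n(n−1) ordered off-diagonal cells);
* **null models** — `edge1` (receivers redrawn, out-degrees kept),
  `edge2` (double-edge swaps, both degree sequences kept), `cross1`
  (each dyad's nominations reassigned to random distinct layers),
  `cross2` (checkerboard swaps keeping all row *and* column sums);
* **inference** — two-tailed add-one Monte-Carlo p-values and
  above/within/below classification against the central 95% null
  range;
* **synthetic generator** — fixed-choice surveys with tunable planted
  assortativity, cross-layer dependence and pairwise co-occurrence
  boosts, so the whole pipeline is testable without field data.

The core inferential quantity, for a statistic s, observed network G
and null ensemble {G*₁ … G*ₙ}:

    p = min(1, 2 · (min(#{s(G*) ≥ s(G)}, #{s(G*) ≤ s(G)}) + 1) / (n + 1))

## Worked example

Test per-layer degree assortativity against the edge nulls on a
synthetic survey with assortativity ≈ 0.3 planted in every layer
except the focal one:

```python
from nullnets import make_study_analogue, run_structural_comparison

net = make_study_analogue(seed=7)
df = run_structural_comparison(
    net, statistics=("in_degree_assortativity",),
    null_models=("edge1", "edge2"), n_perm=200, seed=7,
)
```

which prints (via `examples/02_structural_null_models.py`):

```
T.Bycatch   edge1:  obs=+0.065  null=-0.004±0.057  p=0.299  [within]
T.Bycatch   edge2:  obs=+0.065  null=-0.013±0.057  p=0.189  [within]
gear        edge1:  obs=+0.281  null=-0.005±0.052  p=0.010  [above]
weather     edge1:  obs=+0.288  null=-0.006±0.051  p=0.010  [above]
...
```

Reading: the planted layers sit far above their null range (rewiring
that preserves nomination counts destroys the planted homophily, so
the observed +0.28 is extreme at the add-one resolution 2/201 ≈ 0.01),
while the focal layer is statistically indistinguishable from its own
rewirings — exactly the planted contrast.

Cross-network correlation with a planted bycatch–regs co-occurrence
boost (`examples/03_cross_network_correlation.py`):

```
--- cross1 ---
T.Bycatch|regs        obs=0.914  null=0.881  gap=+0.033  p=0.010  [above]
T.Bycatch|activity    obs=0.879  null=0.880  gap=-0.001  p=0.965  [within]
...
```

All eight raw correlations are large (dyads that share one topic tend
to share many), but only the boosted partner exceeds what the shared
social structure explains — the observed-minus-null *gap* is the
meaningful quantity, not the raw correlation.

## Command line

    nullnets simulate --config sim.yaml --out simdir      # synthetic survey CSV
    nullnets analyze  --config run.yaml --out outdir      # comparisons + manifest
    nullnets version

`analyze` writes `structural.csv`, `cross_network.csv`, `summary.txt`
and `manifest.json`; rerunning from the manifest's seed reproduces
every table byte for byte.

## Layout

    src/nullnets/      data_model, metrics, null_models,
                       permutation_tests, synthetic, pipeline, cli
    examples/          narrative scripts, one per capability
    tests/             pytest suite incl. brute-force oracles
    docs/methods.md    modelling and numerical conventions
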