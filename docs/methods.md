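# Methods

`nullnets` analyses multilayer directed nomination networks — the data
produced by fixed-choice sociometric surveys in which each respondent
names up to ten information contacts and ticks, per contact, which of
nine discussion topics the tie covers.  Each topic induces a binary
directed layer on a shared roster; the package computes per-layer
structural statistics, compares them against four permutation null
models with two-tailed Monte-Carlo inference, and measures cross-layer
dyadic correlation against layer-shuffle nulls.

## Data model

A nomination record is (sender, receiver, topic subset); layers are
binary (duplicate nominations collapse) and self-loops are invalid.
Receivers who are not on the roster are dropped with a count — all
statistics are computed on respondent-to-respondent ties only.  The
dyad-by-layer incidence unfolds the multilayer network into a binary
matrix whose rows are the dyads connected in at least one layer
(lexicographic in roster order, so every export is deterministic and
diff-able) and whose columns are the nine layers.  Folding the
incidence back recovers the network exactly; this bijection is what
makes the cross-network nulls well defined.

## Statistics

**Degree assortativity** is the Pearson correlation of
(value(sender), value(receiver)) over the directed edge list, with the
value being in-degree or out-degree.  This is the *homophily* reading —
do similarly connected people link to each other — not the
Newman excess-degree coefficient for directed graphs (which correlates
the sender's out-side with the receiver's in-side); the two differ and
the endpoint-attribute form is the one matching the survey question
being asked.  Because the same attribute sits on both endpoints, the
coefficient is invariant under *any* affine rescaling of the values,
including negative ones.  Zero endpoint variance (e.g. a directed
cycle, where every in-degree is 1) makes the coefficient undefined;
undefined values are explicit markers and are never coerced to zero.

**In-eccentricity** of node v is the longest shortest-path distance
d(u → v) over all nodes u that can reach v.  Directed survey networks
are never strongly connected, so the convention for unreachable pairs
matters: unreachable pairs are ignored, and a node that nobody reaches
scores 0.  Eccentricity is computed over the full roster, not a
largest-component restriction; this inflates the variance relative to
a component-restricted variant and is stated in the run manifest.
Dispersion summaries use the sample variance (n−1 divisor).

**Betweenness variance** uses unnormalized directed shortest-path
betweenness (networkx) with the variance over all roster nodes.

**Dyadic correlation** between two layers is the Pearson correlation of
their adjacency matrices vectorized over all n(n−1) ordered
off-diagonal cells — the full matrix, because nominations are directed
and asymmetric; diagonals are excluded because self-nomination is
impossible.  On binary matrices this is the phi coefficient of the
2×2 co-occurrence table, and it reduces to margin counts of the
incidence columns, which is how the cross-network comparison computes
it (dyads absent from the incidence are 0 in every layer).  It is
undefined when a layer is empty or complete.

## Null models

* **edge1 — outgoing-edge permutation.**  Each sender keeps its number
  of nominations; its receivers are redrawn as a uniform k-subset of
  the roster minus itself.  Conserves the out-degree sequence and edge
  count; in-degrees are free.  This is an exact i.i.d. sampler, not a
  chain.
* **edge2 — degree-preserving double-edge swap.**  Two edges a→b, c→d
  are replaced by a→d, c→b.  Conserves both degree sequences.
* **cross1 — free layer shuffle.**  Each dyad's k nominations are
  reassigned to a uniform k-subset of the nine layers (binary rows
  force the k layers to be distinct).  Conserves row sums and the
  union network; column sums are free.  Exact i.i.d. sampler
  (vectorized rank trick: per-row uniform keys, smallest k win).
* **cross2 — margin-preserving checkerboard shuffle.**  2×2 blocks
  with pattern (1,0 / 0,1) are flipped; conserves all row *and* column
  sums.  On margin-rigid matrices (no checkerboard exists anywhere,
  verified by an exhaustive row-pair scan) the input is returned
  unchanged with a warning.

### Swap-chain design

edge2 and cross2 are Metropolis chains over their constrained
ensembles.  Proposals are drawn **with replacement** (two edge indices;
two 1-cell indices), and any invalid proposal — coincident picks,
self-loop, duplicate edge, missing checkerboard — is a rejection that
leaves the state unchanged.  `n_swaps` counts *attempted* moves.  Two
properties follow: the kernel is symmetric, so the stationary law is
uniform over the reachable ensemble; and the rejections make the chain
lazy, hence aperiodic.  Counting only *successful* swaps would make the
outcome on two-configuration instances a deterministic function of the
swap parity — such a sampler can never be uniform on small ensembles,
which is why attempt-counting was chosen.  cross2 proposals pick two
1-entries directly from the cell list rather than random row/column
pairs; both kernels are symmetric, but the cell-list form has a far
higher acceptance rate on sparse matrices and mixes in correspondingly
fewer attempts.

The default chain length is `max(5000, 10 × ones)` attempts, where
`ones` is the number of edges (edge2) or 1-entries (cross2).  The
linear term is the standard burn-in heuristic at scale; the floor
matters on small instances, where acceptance rates are low and a
size-proportional budget would leave the chain visibly unmixed.
Calibration was verified empirically: doubling the default chain
length leaves the type-I error of the downstream test unchanged.  The
chain kernels are JIT-compiled with numba when it is available and
fall back to pure Python otherwise; both paths consume the same
pre-generated proposal stream, so results are bit-identical either
way.

### Seeding

Every replicate uses `SeedSequence((master, model_code, layer_code,
replicate))`, so ensembles are reproducible, resumable, and invariant
to execution order.  The structural comparison evaluates *all*
requested statistics on one shared permutation stream per
(layer, null model) — the same permuted networks underlie every
statistic, which is both faster and the natural design (one null
ensemble of networks, many summaries).

## Inference

Two-tailed Monte-Carlo p-values use the add-one convention

    p = min(1, 2 · (min(#{null ≥ obs}, #{null ≤ obs}) + 1) / (n_perm + 1)),

with ties counted in both tails; p is therefore never 0 and valid at
any finite n_perm.  The above/within/below direction compares the
observed value with the central (1−α) empirical interval of the null
sample, using type-7 (linear-interpolation) quantiles and strict
inequality at the boundaries.  No multiple-testing correction is
applied across the layer × statistic × null-model grid; every results
table carries the number of simultaneous tests in a column so readers
can apply their own.

At n_perm = 200 the type-7 interval over-covers slightly (the
"outside" rate of an exchangeable draw is ≈0.059 rather than 0.050);
at n_perm = 1000 the discrepancy is negligible.  Statistics with very
discrete null support make the two-tailed p conservative because ties
count toward both tails; under cross2, where both margins are fixed,
the phi of a single layer pair is a monotone function of one integer
co-occurrence count and is the worst case.  Aggregated statistics (the
mean correlation of the focal layer with the other eight) have a much
finer support and restore nominal calibration; the calibration tests
use exactly that statistic.

## Synthetic generator

The generator emulates the survey's statistical structure so that
every stage is testable without field data:

* **Out-degree law**: point mass at zero (default 14/165 ≈ 0.085 of
  respondents nominate nobody on the roster) plus a geometric law
  truncated to {1..10} with conditional mean ≈ 2.83, giving ≈ 427
  within-roster ties on 165 nodes in expectation.
* **Topics per nomination**: reversed truncated geometric on {1..9}
  with mean 7.7 (mass piled at 9).
* **Layer prevalence**: relative inclusion weights (0.616 for the
  rarest, bycatch, up to 0.979 for location and activity; mean
  7.7/9).  Layer menus are drawn per nomination by weighted sampling
  without replacement (Efraimidis–Spirakis keys).
* **dependence ∈ [0, 1]**: probability that a nomination takes the
  top-m layers of a fixed nesting order instead of an independent
  draw, creating cross-layer correlation beyond what shared topic
  counts induce.  At the study's 7.7 topics per nomination the layers
  are nearly saturated and the knob has little headroom; its
  monotonicity is demonstrated with a sparser topic law.
* **focal_boost (focal, partner, multiplier)**: where the focal topic
  is present and the partner absent, the partner is swapped in for
  another included topic with probability 1 − 1/multiplier, raising
  the pairwise co-occurrence at constant topic count.
* **Receivers** are chosen uniformly by default (the package measures
  tie structure, it does not model tie formation); a Dirichlet
  concentration option exists for in-degree heterogeneity experiments.

What the defaults do *not* reproduce: the receiver-side concentration
of a real survey (mean received ties among the nominated ≈ 3.7 with a
range up to 15 in the study system; uniform receiver choice gives ≈
2.8 with a thinner tail).  Tests passing on synthetic data therefore
say nothing about mechanisms of receiver choice — only about the
correctness and calibration of the statistics, null models and
inference applied on top.

`plant_assortativity` rewires a layer toward a target in-degree
assortativity by hill-climbing over degree-preserving double swaps.
Because swaps change neither degree sequence, the in-degree values on
the endpoints are fixed and only the pairing term of the correlation
moves, so each accepted step is O(1); the climb stops within ±0.02 of
the target.  The study-analogue fixture (`make_study_analogue`) plants
0.30 in the eight non-focal layers, leaves the bycatch layer as
generated, and boosts bycatch–regs co-occurrence with multiplier 3 —
the qualitative pattern the method is designed to detect.  Planting
rewires layers independently and thus attenuates their co-occurrence
with the focal layer; the cross-network recovery experiments use the
boosted baseline (no planting) for that reason.

## Problem sizes used in the test suite

Conservation is asserted permutation-by-permutation on 50 generated
50-node networks × 1000 permutations per null model; oracle agreement
on ≥200 random instances per statistic (n ≤ 30; ≤ 12 for the
path-enumeration betweenness oracle); sampler uniformity on the
enumerable micro-instances over 10,000 seeded draws; type-I
calibration on 1000 null-generated datasets per model at n_perm = 200
(12-node layers for the edge nulls, a 40-node uniform-prevalence
incidence for the cross nulls); planted-signal and cross-dependence
recovery on 20 study-scale (165-node) fixtures; and one full
study-scale pipeline (n_perm = 1000, all four null models) run twice
from its manifest and compared byte-for-byte.

## Known limitations

* Margin-rigidity detection for edge2 scans edge pairs (O(m²)) and is
  only triggered when a whole chain makes no successful move.
* The cross-network comparison assumes the focal layer is compared
  against all other layers on the same incidence; arbitrary layer
  subsets would need a thin wrapper.
* p-values from conserved statistics (e.g. edge count under edge1) are
  identically 1 by construction; the pipeline reports them rather than
  filtering, since their appearance is itself a useful audit.
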