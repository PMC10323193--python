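# Methods

This note documents the models, conventions and numerical choices behind
`qpcrnet`, in the spirit of the methods appendices that accompany
simulation and statistics packages.

## Study design emulated

The package targets a four-arm rat heterotopic heart-transplant design:
donor hearts stored in cold preservation solution for 1 h or 5 h, with or
without alpha-1-antitrypsin (AAT) added, giving groups
`1h ischemia` (n=7), `1h ischemia+AAT` (n=7), `5h ischemia` (n=7) and
`5h ischemia+AAT` (n=9).  Expression of 88 inflammation / apoptosis /
oxidative-stress genes plus 5 stable reference genes (Rplp1, ACTB, B2m,
Hprt1, Ldha) is measured as qPCR threshold cycles (Ct) on an array.  The
raw Ct data behind the published study are not deposited, so every
quantitative pipeline stage is exercised against the packaged synthetic
generator and the published per-contrast summary tables.

## Relative quantification (ΔΔCt)

Per sample, ΔCt(g) = Ct(g) − mean(Ct of reference genes); the arithmetic
mean on the Ct scale is the geometric mean on the linear scale, the
standard multi-reference aggregation.  Linear relative expression is
2^(−ΔCt).  For a test-vs-control contrast:

- p-value: two-sided pooled-variance Student's t-test on the linear
  2^(−ΔCt) replicates (Welch is deliberately not used; the emulated
  workflow names Student's t-test, and no multiple-testing correction is
  applied because the published tables print raw p-values);
- fold change: FC = 2^(−ΔΔCt) with ΔΔCt = mean ΔCt(test) − mean
  ΔCt(control), i.e. log-domain averaging (the RT² Profiler convention),
  not the ratio of arithmetic means of linear values;
- fold regulation: FR = FC if FC ≥ 1 else −1/FC, so |FR| ≥ 1 always and
  FR is odd on the log scale;
- significance filter: p < 0.05 and |FR| > 2.0, both strict, matching the
  published "> 30", "greater than 2.0" phrasing; ties at the boundary do
  not pass.

QC flags follow the array convention for weakly expressed genes: flag A
when the group-mean raw Ct exceeds 30 cycles in exactly one of the two
groups (the fold estimate leans on one barely detected group), flag B
when both groups exceed 30.  The flag is computed from the Ct means
alone.  The published table footnote also mentions a p-value clause for
flag B, but the printed rows contradict it (a B-flagged gene prints
p = 0.004), so the p-clause is treated as a footnote error and ignored —
a deliberate, documented deviation rather than a silent reconciliation.

Undetermined wells are recorded at the panel ceiling (default 35 cycles)
and tracked in a missing mask; a gene undetermined in more than half of
either group's wells is excluded from that contrast with a warning.  An
undetermined reference-gene well invalidates the sample's normalizer and
is an error rather than a silent imputation.

## Boruta (all-relevant selection, regression mode)

Targets are continuous expression values, so Boruta runs in regression
mode: with ~7–9 samples per group a classification formulation over 87
features is hopeless, while pooled regression is workable.  Each
iteration appends an independently row-permuted shadow copy of every
feature, fits a bagged ensemble of randomized regression trees, and
scores a hit for every real feature whose importance exceeds the maximum
shadow importance.  After each iteration every undecided feature's hit
count is tested against Binomial(t, 1/2), two-sided, at alpha = 0.01
with Bonferroni correction over features × tests performed (each feature
is re-tested after every iteration, so the multiplicity grows with t;
correcting over features alone lets lucky early hit streaks through):
significantly above chance → Confirmed, below → Rejected.  The
iteration cap is 100 by default.

Features still undecided at the cap stay Tentative by default, mirroring
the canonical behavior in which the "rough fix" (compare a feature's
median importance to the median of the per-iteration shadow maxima) is
an explicit opt-in post-processing step, available here as
``tentative_resolution="median_vs_shadow"``.  The default matters for
error control: on pure-noise data the features that linger Tentative
are precisely the strongest chance correlates of the target, and the
rough fix would wave most of them through.

Importance is Z-scored out-of-bag permutation importance by default —
per tree, the OOB MSE with the feature shuffled minus the unshuffled
OOB MSE; the mean of these per-tree decreases divided by its standard
error over trees, the scaled variable importance of the classic random
forest.  The choice is not cosmetic: impurity (MDI) importance credits
splits that merely overfit the in-bag data, so a feature that happens
to correlate with the target in this one sample beats its shadow far
more consistently than under the OOB measure, and the false-confirm
rate on pure-noise data rises several-fold (both measures were
benchmarked on the same seeded simulations).  MDI remains available via
``importance="impurity"`` as a faster option for large panels.  The
permutation path stacks the unpermuted OOB block and one shuffled block
per feature the tree split on into a single predict call per tree,
which makes it cost-comparable to MDI at panel sizes up to a few dozen
genes.

Features still Tentative at the cap can be resolved by the canonical
rough fix (median importance vs the median of the per-iteration shadow
maxima) or left Tentative.  Decisions are seeded per (target, iteration)
from one master seed, so runs are reproducible and order-independent at
the level of the planted signal; exact invariance of every decision
under column permutation is not guaranteed, because tie-breaking inside
a joint tree ensemble depends on column order.

## CrossBoruta networks

Each gene in turn is the regression target; all other genes are
candidates.  A Confirmed predictor j for target i is a directed
association i←j; the undirected edge rule is `union` by default (either
direction suffices; all-relevant selection is already conservative at
these sample sizes), with `intersection` available for stringency.
Network edges are built from Confirmed predictors only; under the
default leave-tentative resolution, features still undecided at the
iteration cap — typically borderline in-sample correlates — contribute
no edge.

Edge weight is the mean of the confirming directions' median
importances, min–max normalized per network to [0, 1].  Every edge is
annotated with the Spearman rank correlation of its endpoints over the
pooled samples: positive / negative when significant at 0.05 (t
approximation with n−2 degrees of freedom), grey otherwise.  Grey edges
are retained and counted — they are the non-monotone associations that
motivate using trees rather than correlation thresholds.

Network summaries report edge-sign counts, degree-0 genes, mean |rho|
and a homogeneity score defined as 1 − s.d.(edge rho values) (the
maximum attainable s.d. for values in [−1, 1] is 1; homogeneity is 1
when fewer than 2 edges).  Homogeneity has no published definition; the
raw rho distribution is exported alongside so alternative definitions
can be recomputed.  Networks are built once per treatment arm pool
(placebo-preserved 1h+5h pooled, n=14; AAT-preserved 1h+5h pooled,
n=16); pool membership is configurable.

The machine-learning stages consume raw Ct values by default
(configurable to ΔCt or linear): the published tree thresholds (20–24)
are on a cycle-like scale, and rank-based methods are unaffected by the
monotone transforms between the three scales.

## Stress-majorization layout

Edge importance defines target geometry: an edge of normalized weight w
gets length 1/(w + 0.05); non-adjacent pairs within a component get the
shortest-path distance over those lengths; nodes in different components
are separated by 1.5× the largest finite distance (disconnected genes
drawn apart from the cluster; the multiplier is a declared convention).
Raw stress Σ_{i<j}(‖x_i−x_j‖ − d_ij)² is minimized by iterated Guttman
transforms (unit weights: X ← B(Z)Z/n) from a seeded uniform start,
stopping when the relative stress decrease drops below 1e−6 or at 500
iterations; stress is non-increasing along the iteration by
construction, and the layout keeps the best of 5 seeded restarts.
Coordinates are defined only up to rotation/translation/reflection; the
inter-point distances, not the coordinates, are the contract.

## Gain-ratio decision tree

Binary axis-aligned threshold trees with "≤ goes left".  Split quality
is the information gain ratio over candidate thresholds at midpoints of
consecutive distinct sorted values, with a min-leaf floor (default 2).
Near-ties in gain ratio are broken toward the larger absolute
information gain — gain ratio scores a lopsided pure cut and a balanced
two-class cut identically (ratio 1), and preferring gain is the classic
C4.5 stabilizer — then toward the smaller threshold, then panel column
order.  Leaves keep the full set of class labels present (published
leaves name up to three study arms); no majority-vote collapse, no
boosting, winnowing or pruning.  The published four-threshold
classification tree (Flt1 23.029 / Gpx3 20.448 / Cflar 21.651 / Bcl2
21.798) ships as a fixture with a JSON serialization and a rule-style
text rendering; its thresholds are data-dependent values from
unpublished training data, so tests target planted-topology recovery,
not threshold reproduction.

## Synthetic Ct generator

Ct(s, g) = baseline(g) − shift(g, group(s)) + Σ_m loading(g)·latent_sd·
f_m(s) + N(0, sd(g)), Gaussian on the cycle scale (multiplicative
log-normal on the linear scale, the standard qPCR error model).

- Baselines are drawn once per gene from U[18, 28] cycles unless
  overridden; reference genes get sd 0.15 cycles and no effects; all
  other wells get sd 0.5 cycles.
- A planted log2 fold change of δ lowers the test group's Ct by δ
  cycles, so planted truth maps exactly onto the ΔΔCt read-out.
- Co-expression modules share a standard-normal per-sample latent
  factor within a declared arm pool, scaled by latent_sd = 1.5 cycles
  and a signed per-gene loading in (0, 1]; loading 0.9 yields pairwise
  correlations near 0.88.  A single shared factor (rather than an
  explicit covariance matrix) guarantees positive semidefiniteness and
  gives directly tunable correlation strength.
- Silent genes (emulating unexpressed transcripts such as Il9, Gpx5,
  Gpx6) draw from N(35.5, 0.5) against a detection ceiling of 35:
  wells beyond the ceiling censor to the ceiling value and are flagged
  undetermined, leaving a near-constant profile.  Low-but-detectable
  genes are emulated with baseline overrides (e.g. 32.5 cycles) so the
  published QC flags re-emerge from the Ct means.
- The `study_preset` configuration plants the published qualitative
  structure: the six 5h-vs-1h genes at log2 fold changes matched to the
  printed fold regulations, Ccl11 up / Vcam1 down on the AAT contrast,
  a coherent positive module in the AAT pool versus a mixed-sign module
  in the placebo pool, and the three silent genes.

What the generator does *not* emulate: amplification-efficiency
variation, plate/batch effects, heavy-tailed or correlated technical
noise, and inter-gene correlation beyond single-factor modules.
Passing recovery tests therefore show that the pipeline detects the
planted structure under idealized Gaussian noise at the study's sample
sizes — not that it would behave identically on real arrays.

## Problem sizes in the test and acceptance suites

Simulation-based checks run at deliberately modest sizes chosen to make
the suites reproducible on a single CPU while keeping the relevant
power: Boruta behavior suites use 40 samples × 10 features with
50-tree ensembles and a 30–40 iteration cap; network recovery uses a
14-target panel (two 4-gene modules, three noise genes, three silent
genes) at 8 samples per arm; fold-change recovery uses 200 simulated
studies on a 4-target panel at n=7 per group.  Full-panel (93-gene)
runs are supported through the CLI and scale linearly in genes ×
iterations × trees.

## Known limitations

- At n ≈ 30–40, a handful of gene pairs will show spurious sample
  correlations of |r| ≈ 0.4; such in-sample associations are real to
  any resampling-based selector, so null networks carry a small number
  of false edges.  The binomial decision rule (and dropping Tentative
  features from networks) controls but cannot eliminate this.
- The Spearman p-value uses the t approximation, adequate for n ≥ 8 but
  approximate for the smallest pools.
- Gain-ratio trees are unpruned; they describe the training partition
  and are not intended as generalizing classifiers at these sample
  sizes.
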