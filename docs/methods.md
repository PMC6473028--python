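# Methods

`metabnet` implements a group-level metabolic covariance network analysis for
FDG-PET region-of-interest (ROI) data, together with a synthetic-cohort
generator that makes every stage testable without access to patient scans.
This note records the models, the parameters that matter, the numerical
choices, and what the synthetic data do and do not establish about behaviour
on real cohorts.

## Network construction

A group's metabolic network is built *across subjects*: node `i` is an
atlas region (the bundled AAL-style parcellation has 90 cerebral regions,
45 per hemisphere, cerebellum excluded), and the edge weight between nodes
`i` and `j` is the partial correlation of their mean-uptake columns over the
subjects of that group, controlling age and sex. The estimator is pairwise
residualization: each ROI column is regressed on `[1, age, sex]` by least
squares and the Pearson correlation of the residuals is taken. For linear
covariates this equals the textbook partial correlation. (The alternative
reading — partialling out all other 88 regions via the full precision
matrix — is a different estimator, implemented nowhere but checked as an
identity on 3-variable fixtures where the two coincide.) Entries whose
residuals have zero variance are left undefined (NaN) and reported; a
rank-deficient covariate design is rejected.

The symmetric matrix is binarized by a **sparsity threshold**: at sparsity
`s`, exactly `round(s · R(R−1)/2)` unordered pairs become edges, ranked by
*signed* correlation (strongest positive first); an absolute-value ranking is
available behind a flag. Rounding is round-half-to-even; ties at the
boundary break by lexicographic pair order, so the operation is exactly
deterministic. The default sweep is 6–40% in 1% steps (35 levels). Because
all levels share one ranking, edge sets are nested along the sweep by
construction. At the hub-analysis sparsity of 28% a 90-node matrix yields
`round(0.28 · 4005) = 1121` edges.

## Graph metrics

On each binary network the package computes the standard small-world
battery:

- **C** — mean clustering coefficient, `C_i = triangles_i / (k_i(k_i−1)/2)`,
  zero for degree < 2;
- **L** — characteristic path length, the mean shortest-path length over
  *connected* ordered pairs; the number of disconnected pairs is reported
  alongside rather than folded into the mean, keeping L finite on
  fragmented graphs;
- **Eglob / Eloc** — global efficiency (mean of 1/d over ordered pairs,
  0 for disconnected pairs) and local efficiency (mean over nodes of the
  global efficiency of the neighbour-induced subgraph, 0 for degree < 2);
- **γ = C/C_null, λ = L/L_null, σ = γ/λ** — normalized against
  degree-preserving surrogates (Maslov–Sneppen double edge swaps). Defaults:
  100 surrogates, 10 accepted swaps per edge, fully seeded. A graph whose
  degree sequence admits no swap (e.g. complete) returns γ = λ = σ = 1 with
  a warning. σ is computed as the exact quotient γ/λ.
- **betweenness / hubs** — Brandes shortest-path betweenness with even
  splitting over equal-length paths; `bi = BC / mean(BC)` over *all* nodes
  (zeros included), and a node is a candidate hub when `bi > 1.5`. Hub
  analysis runs at a single sparsity, default 28%, after a connectivity
  check (a disconnected network is analysed with a warning).

Distances are computed by breadth-first search expressed as boolean matrix
products, which on these dense 45–90-node graphs is roughly an order of
magnitude faster than sparse-graph library calls and makes the
resampling loops below affordable. The kernels are verified against
networkx and against brute-force enumeration oracles (explicit triple loops,
queue BFS, full shortest-path enumeration) on hundreds of random ≤12-node
graphs.

## Group comparison

Between-group differences in any metric, at every sparsity, are tested by
subject-relabelling permutation: subjects are pooled, reassigned to two
pseudo-groups of the original sizes, and both partial-correlation networks
and the metric are rebuilt per permutation (covariates travel with their
subjects). The two-tailed p-value uses add-one smoothing,
`p = (1 + #{|null| ≥ |obs|}) / (1 + n_perm)`, with 1000 permutations by
default. Maximal contiguous sparsity runs with `p < α` are reported as
closed percent intervals (e.g. `[[18, 33], [37, 40]]`). No multiplicity
correction is applied across the 35 levels; the output metadata says so.
For the small-world metrics each permutation uses a reduced 20-surrogate
null (configurable) — full-size nulls inside a permutation loop would cost
days of CPU for no change in the test's validity.

## Seed-based correlation

For a seed region (default `MTG.R`, the right middle temporal gyrus) the
per-group Pearson correlation with each of the other 89 regions is
variance-stabilized by Fisher's transform `z = ½·ln((1+r)/(1−r))` (natural
log), and two groups are compared per target with

    Z = (z₁ − z₂) / √(1/(n₁−3) + 1/(n₂−3)),

two-tailed against the standard normal, with Benjamini–Hochberg FDR over
the 89 targets at q = 0.05. Targets with |r| = 1 (e.g. a duplicated
column) are excluded from the transform and reported as NaN. ROI-level maps
replace voxelwise maps; the statistics are identical per element.

## Hemispheric asymmetry

Each hemisphere's 45-region network is built independently from that
hemisphere's columns and binarized at a common sparsity (default 28%). With
M_R and M_L the right/left efficiencies (global or local), the asymmetry
index is `AI = 200·|M_R − M_L|/(M_R + M_L)` — non-negative, zero iff equal,
invariant to a common rescaling. (On a published example of hemispheric
global efficiencies 0.6247/0.6253 this gives AI ≈ 0.096; note that
AI values quoted on scales near 1 are not reproducible from that formula
and those inputs — the package implements the formula as printed.)

Within-group inference uses a **hemisphere-swap permutation test**: each
permutation independently swaps every subject's left/right homologous ROI
vectors with probability ½ and recomputes M_R − M_L. Under the null
hypothesis that hemispheres are exchangeable this leaves the data
distribution invariant, so the two-tailed add-one p-value is exact up to
Monte-Carlo error; null simulations put its type-I error at the nominal
level. A subject-bootstrap alternative (`method='bootstrap'`, crossing
p-value) is provided but is conservative for threshold-network statistics —
bootstrap resampling inflates correlation noise, widening the resampled
difference distribution relative to the sampling distribution — and is not
the default. Bootstrap resamples are still drawn to supply sampling
distributions of M_L, M_R and AI; the between-group AI comparison is a
Welch two-sample t-test on two groups' AI bootstrap distributions.
Resamples that produce a zero-variance ROI or a constant covariate are
redrawn and counted. A significant within-group test sets the direction
(`rightward` when M_R > M_L, else `leftward`); otherwise `none`.

## The synthetic cohort generator

The generator emulates the study layout — four groups, HC/AD/PDD/DLB with
n = 22/22/18/22 — with 90-ROI signals drawn from a latent factor model,
`Σ = ΛΛᵀ + diag(ψ)` with unit variances, so positive definiteness holds by
construction (the smallest eigenvalue is bounded below by min ψ). Uptake
for a subject is `1.0 + 0.1·(z_f Λᵀ + √ψ ε) + β_age(age−65) + β_sex·sex +
0.02·η` in normalized-uptake units, with age uniform on [55, 75], sex
Bernoulli(½), and default confound slopes β_age = −0.003/yr, β_sex = 0.02
(uptake declines slightly with age; a small sex offset) — values on the
order of a few percent of the signal scale, enough that an unadjusted
analysis is visibly confounded while the partial-correlation stage removes
them.

The factor structure plants the ground truth that the downstream tests
recover:

- **Segments.** Each hemisphere's 45 ring positions split into three
  contiguous segments of 15; members share a segment factor giving uniform
  within-segment correlation 0.38, of which 0.22 is carried by a factor
  shared with the homologous segment on the other side (homotopic coupling).
  At 28% sparsity a hemisphere's 277-edge budget is smaller than its 315
  within-segment pairs, so the thresholded hemispheric network is three
  dense, mutually disconnected communities — a segregated baseline with low
  global efficiency.
- **Bridges.** Twenty mirrored inter-segment region pairs each share a
  private factor with base communality 0.12 per endpoint. The
  **hemispheric gain** multiplies one side's bridge loadings (correlations
  scale as gain²). Because binarized topology depends only on the ranking
  of a hemisphere's correlations, a *uniform* gain on all within-hemisphere
  weights provably changes nothing; acting on the bridge tier is what
  re-orders it. At gain 1 bridges rank below the segment tier and stay out;
  at gain 2 their correlations (0.48) outrank segment edges, integrate the
  network, and raise that hemisphere's global efficiency (population-level
  Eglob 0.28 → 0.55) while lowering its local efficiency. Gains multiply
  (g then 1/g restores the original exactly) and a gain that pushes any
  communality to 1 is rejected.
- **Hubs.** Two regions per hemisphere (ring positions 5 and 37) are
  excluded from their home segment and instead load on *two* segment
  factors (segments 0+1 and 1+2) at communality 0.33 each. Their edges
  (correlation ≈ 0.35) sit below the segment tier but far above noise, so
  in the whole-brain network they are the dominant inter-segment
  connectors and acquire normalized betweenness bi ≈ 9–20, versus the 1.5
  hub threshold.

With equal gains the two hemisphere blocks are exactly mirror images, so
hemispheric statistics are exchangeable — the basis of the null
simulations. The default disease groups carry gains 1.6 (AD, rightward),
1.6 (PDD, leftward) and 2.0 (DLB, rightward).

**Documented effect sizes.** Recovery suites run at n = 200 subjects,
sparsity 28%: planted hubs are recovered (all four with bi > 1.5) in 50/50
seeded replicates; a rightward bridge gain of 2.2 is recovered as a
significant rightward direction in 44/50 (88%) replicates. At the
study-like n ≈ 20 the same effects are mostly non-significant — consistent
with how noisy single-group networks of 20 subjects are; the generator
makes no attempt to hide that.

**What the generator does not emulate.** Gaussian signals with a
block-factor covariance, not PET count statistics; no spatial point-spread,
partial-volume mixing, or atlas misregistration; no per-scanner intensity
normalization issues; confounds are linear and identical across regions;
the "anatomy" is a ring with segments, not cortical geometry. Passing
tests therefore establish the *statistical machinery* — estimators,
thresholding, metrics, resampling inference — not fidelity of any specific
anatomical claim about real dementia cohorts.

## Numerical and design choices

- Signed-correlation ranking for binarization by default (strong positive
  covariance dominates at ≤40% sparsity); absolute ranking behind a flag.
- Round-half-to-even for edge counts; lexicographic tie-break.
- Disconnected pairs: excluded from L (count reported), contribute 0 to
  efficiency — matching common toolbox behaviour.
- bi normalizes by the mean betweenness over all nodes, zeros included;
  mean BC = 0 (complete graph) leaves bi undefined and flags no hubs.
- Null model: 100 surrogates × 10 swaps/edge for standalone curves; 20
  surrogates inside permutation loops; all seeded, with seeds derived from
  a master seed via `SeedSequence`.
- Small-world sanity fixtures are Watts–Strogatz graphs (n = 90, k = 8,
  p = 0.35): inside the small-world regime with margin on all three
  criteria (γ > 1, |λ−1| < 0.1, σ > 1) across seeds; at p ≤ 0.1 the ring is
  still lattice-dominated and λ exceeds 1.1.
- Permutation p-values use add-one smoothing and are two-tailed on the raw
  metric difference (no studentization).
- The pipeline writes only delimited text and JSON; rerunning with the same
  config and master seed reproduces outputs byte-for-byte.

## Known limitations

- Group-level networks mean there is one network per group; subject-level
  variability enters only through resampling.
- The permutation test reports per-sparsity significance without
  cross-sparsity correction, as noted in its output.
- The bootstrap within-group p-value is conservative (see above); it is
  retained for comparability, not recommended.
- Voxel-level seed maps and anatomical figure rendering are out of scope;
  ROI tables are the unit of analysis, with NIfTI support limited to
  extracting ROI means from a label volume.
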