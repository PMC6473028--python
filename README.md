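# metabnet

Group-level **metabolic covariance network** analysis for FDG-PET ROI data.

Across a group of subjects, the regional uptake of
18F-fluorodeoxyglucose covaries between brain regions; treating regions as
nodes and between-region covariation as edges yields a metabolic
connectivity network per group. `metabnet` builds these networks and runs
the graph-theoretic and asymmetry analyses used to compare dementia cohorts
(healthy controls vs. Alzheimer's disease, Parkinson's disease dementia,
and dementia with Lewy bodies):

- **Networks** — partial correlation between the 90 AAL regions
  (cerebellum excluded) across subjects, controlling age and sex;
  binarization by sparsity threshold over a 6–40% sweep (top *s* fraction
  of the R(R−1)/2 node pairs by signed correlation).
- **Graph metrics** — clustering coefficient *C*, characteristic path
  length *L*, global/local efficiency, and small-world indices
  γ = C/C_null, λ = L/L_null, σ = γ/λ against degree-preserving
  Maslov–Sneppen surrogates; shortest-path betweenness with the
  `bi = BC/mean(BC) > 1.5` hub rule.
- **Group comparison** — subject-relabelling permutation tests of any
  metric at every sparsity, with significant sparsity ranges reported.
- **Seed correlation** — per-group seed maps (default seed: right middle
  temporal gyrus), Fisher's r-to-z transform
  z = ½·ln((1+r)/(1−r)), the two-sample statistic
  Z = (z₁−z₂)/√(1/(n₁−3)+1/(n₂−3)), and Benjamini–Hochberg FDR.
- **Hemispheric asymmetry** — independent 45-region hemisphere networks,
  the asymmetry index AI = 200·|M_R−M_L|/(M_R+M_L) of global/local
  efficiency, an exact hemisphere-swap permutation test within groups, and
  a Welch t-test on AI bootstrap distributions between groups.
- **Synthetic cohorts** — a latent-factor generator that plants known
  structure (segregated segments, gain-controlled inter-segment bridges,
  high-betweenness hubs, age/sex confounds) so every stage is testable
  without patient data. See `docs/methods.md` for the model and its
  limitations.

## Worked example

Generate a 200-subject group whose right hemisphere carries a planted
bridge gain of 2.2, build its covariate-adjusted network, and run the hub
and asymmetry analyses:

```python
from metabnet.synthetic import (CohortConfig, default_structure,
                                plant_asymmetry, generate_cohort)
from metabnet.network import partial_correlation, binarize_at_sparsity
from metabnet.metrics import small_world_indices, betweenness_table
from metabnet.asymmetry import within_group_test

structure = plant_asymmetry(default_structure(), 2.2, "R")
cfg = CohortConfig(group_specs=(("DLB", 200),),
                   network_spec={"DLB": structure}, seed=42)
table = generate_cohort(cfg).tables["DLB"]

pc = partial_correlation(table)            # controls age and sex
adj = binarize_at_sparsity(pc, 0.28)       # 1121 of 4005 pairs kept
sw = small_world_indices(adj, n_null=20, seed=0)
bt = betweenness_table(adj, pc.roi_names)
res = within_group_test(table, n_rep=200, seed=0, with_bootstrap=False)
```

This prints (via the obvious f-strings):

```
C=0.754 L=1.862 gamma=2.53 lambda=1.08 sigma=2.34
planted hub bi: [9.9, 9.6, 9.3, 8.3]
M_L=0.5449 M_R=0.6034 AI=10.17 p=0.005 rightward
```

Read: the group network is small-world (clustering 2.5× its
degree-preserving null at near-null path length, σ > 1); the four planted
hub regions stand far above the bi > 1.5 hub threshold; and the right
hemisphere's global efficiency exceeds the left's (0.603 vs 0.545,
AI ≈ 10), which the hemisphere-swap permutation test calls as significant
rightward asymmetry (p = 0.005) — recovering exactly what was planted.

The same analyses are available from the shell:

```bash
metabnet simulate --out demo --seed 7
metabnet hubs demo/cohort_HC.csv --out hubs.csv
metabnet asymmetry demo/cohort_DLB.csv --reps 200 --seed 1 --out asym.csv
metabnet run-all config.yaml          # full pipeline from a YAML config
```

At the study-like group size of ~20 subjects the asymmetry test is usually
non-significant — single-group networks of 20 subjects are noisy — which is
the expected behaviour, not a defect.

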