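# Methods

## The model

`iscn` builds *individualized structural covariance networks*: one weighted,
undirected brain network per subject, derived from that subject's regional
cortical thickness profile rather than from across-subject correlations.
The input is a vector `t` of mean cortical thickness (mm) over the 148
regions of the Destrieux sulco-gyral parcellation (74 per hemisphere).

Construction proceeds in three steps.

1. **Within-subject standardization.** `z = (t - mean(t)) / sd(t)`, taken
   across the subject's own 148 regions. This removes global thickness
   scale (head size, scanner gain) and leaves the subject's regional
   *profile*.
2. **Normative deviation scoring.** A reference model stores the per-region
   mean `mu_i` and SD `sigma_i` of `z` over the control group. Each subject
   is scored as `n_i = (z_i - mu_i) / sigma_i`: how unusually thick or thin
   region *i* is, relative to controls, after profile standardization.
3. **Similarity kernel.** For every region pair,

       w_ij = exp(-(n_i - n_j)^2),  w_ii = 0.

   Two regions that deviate *in the same way* from the norm get weight 1;
   regions whose deviations disagree get exponentially smaller weights.
   The result is a symmetric 148 x 148 matrix with 10,878 unique pairs,
   entries in (0, 1].

Sample standard deviations (denominator `n - 1`) are used throughout.

### Leave-one-out scoring of controls

By default each control subject is scored against a reference refitted on
the *other* controls; patients are scored against the full-control
reference (which is also the model persisted to disk). The reason is
statistical, not cosmetic: a control scored against a reference containing
itself is standardized in-sample and its deviations have variance exactly 1
by construction, while an out-of-sample subject scored against a 32-subject
reference has deviation variance approximately
`(1 + 1/32) * 31/29 ≈ 1.10`. That 10% scale gap propagates through the
kernel into every network index and shows up as a spurious patient-control
difference even when the groups are statistically identical — in null
simulations at the default sample sizes it drove the familywise
false-positive rate of the global comparison from ~5% to ~60%. Leave-one-out
scoring makes controls and patients exchangeable to within a fraction of a
percent (32 vs 31 reference subjects) and restores nominal calibration.
The in-sample variant remains available
(`build_cohort_scns(..., reference_scoring="in_sample")`); under it, control
deviations have per-region mean 0 and SD 1 exactly.

### Normalization variants

The two-stage scheme (within-subject first, then per-region against
controls) is the default and the tested path. A single-stage variant
(per-region z-score of raw thickness against the control distribution) is
exposed via `normalization="single_stage"` for sensitivity analysis only;
it differs in that global thickness scale is *not* removed before scoring.

## Graph indices

All indices operate on the weighted matrix without thresholding.

* **Strength**: nodal strength is the sum of incident weights
  (at most 147 with unit weights); the global value is the *mean* nodal
  strength. On empirical-scale networks (mean weight ≈ 0.43-0.45) this
  lands in the 60s, the magnitude regime reported for cortical cohorts.
* **Clustering coefficient**: the Onnela geometric-mean-of-triangles
  formula on weights normalized by the global maximum,
  `C_i = sum_jh (w_ij w_ih w_jh)^(1/3) / (k_i (k_i - 1))`, with `C_i = 0`
  for nodes with fewer than two neighbours. The global value is the
  unweighted mean over nodes. This is the standard weighted clustering
  coefficient of the brain-connectivity toolbox tradition; it is isolated
  behind one function so an alternative convention can be swapped in.
* **Path length**: edge lengths are reciprocal weights `l = 1/w`; distances
  are all-pairs shortest paths; the characteristic path length is the mean
  over ordered finite pairs. Unreachable pairs (possible only after
  underflow, `|n_i - n_j|` ≳ 27) are excluded from the mean.
* **Global efficiency**: the mean reciprocal distance over ordered pairs,
  with unreachable pairs contributing 0. On a complete uniform-weight graph
  the closed forms are strength `(R-1)w`, clustering 1, path length `1/w`,
  efficiency `w`.

Shortest paths are computed with `scipy.sparse.csgraph.shortest_path`
(method `"auto"`; on these dense, essentially complete graphs that selects
Floyd-Warshall). The test suite verifies the distances against both a
literal Floyd-Warshall triple loop and networkx Dijkstra.

**A note on path-length tails.** Because edge length is `1/w` and
`w = exp(-gap^2)`, a single region whose deviation sits far from every
other region's deviation produces enormous lengths (`exp(gap^2)`), and the
characteristic path length is then dominated by that one node. This is a
genuine property of the method, not a bug; it is why patient path-length
distributions are heavy-tailed in simulation and why the acceptance script
reports group *median* path length alongside mean values of the other
indices.

## Statistics

* **Group comparison**: per-index one-way ANCOVA `value ~ group +
  premorbid_iq`, fitted by OLS; the group effect is tested by the
  extra-sum-of-squares F test (equivalent to Type II/III here since group
  is the only factor). With a constant or absent covariate this reduces
  exactly to one-way ANOVA. Effect size is partial eta squared
  `SS_group / (SS_group + SS_error)`.
* **Multiplicity**: Benjamini-Hochberg step-up FDR, applied across the
  family of 4 global indices or across the 148 regions. Zero-variance
  regions are excluded with a logged warning and the family size reduced.
* **Post-hoc**: LSD pairwise t tests on covariate-adjusted means, using the
  omnibus residual mean square and degrees of freedom, unadjusted p values
  (the LSD convention), computed only where the omnibus test survives FDR
  at alpha = 0.05 (two-tailed throughout).
* **Brain-behaviour correlations**: partial Pearson correlations (residual
  correlation after OLS adjustment) with parametric p from a t distribution
  on `n - 2 - k` degrees of freedom, plus a seeded bootstrap (default 5000
  resamples) giving a percentile 95% CI and a two-sided sign-based p value.
  Both p values are reported side by side. In the screen, patient groups
  partial out medication dose and illness duration; controls use plain
  Pearson. Degenerate resamples are redrawn and counted.
* **Optional omnibus**: a Wilks' lambda MANOVA pre-test (Rao's F
  approximation) is available but the per-index family is primary.

All randomness flows from a single root seed through
`numpy.random.SeedSequence` spawning, so identical configuration + seed
reproduces byte-identical outputs.

## The synthetic cohort generator

The generator emulates the data model the analysis assumes, at the level of
already-extracted thickness tables. It does **not** simulate images,
surfaces, spatial covariance between neighbouring regions, or non-Gaussian
biological outliers — so passing tests demonstrate correctness and
calibration of the *pipeline*, not validity of the method on real MRI data.

Control thickness is `t_s(i) = mu_i * a_s + eps_s(i)` with:

* `mu_i ~ Uniform(1.5, 4.5)` mm, one shared anatomical profile per cohort;
* `a_s = max(0.5, 1 + N(0, 0.05))`, per-subject global scale;
* `eps_s(i) = 0.2 mm * clip(N(0,1), ±2.5)`, between-subject regional
  variability. Clipping bounds the tails so that no single region can be
  isolated from all others in deviation space purely by simulation noise
  (see the path-length note above); per-region SDs of ~0.2 mm are in the
  range reported for regional cortical thickness.

Patient pathology is planted as **regional heterogeneity**: zero-mean
offsets `deviation_sd * a_s * sd(mu) * clip(N(0,1), ±2)` added on a
configured set of affected regions, resampled per subject. `deviation_sd`
is therefore expressed in within-subject z units. A uniform thinning would
be removed by the within-subject standardization, so heterogeneity is the
mechanism by which planted pathology reaches the kernel; it lowers
strength, clustering and efficiency and raises path length, reproducing the
qualitative group pattern (both patient groups worse than controls, the
milder group intermediate).

Defaults are `deviation_sd` 0.25 (schizophrenia-like) and 0.18
(bipolar-like) on 30 regions each, sample sizes 39/37/32. These were chosen
once, during generator design, to put the simulated control indices in the
empirically reported magnitude regime (strength ≈ 64, clustering ≈ 0.32,
path length ≈ 3.0, efficiency ≈ 0.51) with a clearly detectable but not
saturated group effect.

Covariates (premorbid IQ, medication dose, illness duration) and clinical
scores (PANSS positive, YMRS, verbal fluency, verbal learning) are
truncated Gaussians with group-specific means in clinically plausible
ranges; only the correlation machinery, not the clinical values themselves,
is under test. One named score (default: the mania scale in the
bipolar-like group) is constructed as
`rho * z(index) + sqrt(1 - rho^2) * noise` around the *actually computed*
network index (default: nodal clustering of the left superior occipital
gyrus), so correlation-recovery tests exercise the full pipeline.

`make_worked_fixture()` returns a 10-subject, 5-region cohort with
hand-chosen thickness values (synthetic by construction) whose matrices and
metrics are verifiable by hand and against the brute-force oracles.

## Numerical choices and degenerate inputs

* Kernel weights may underflow to 0 for extreme deviations; such entries
  are treated as absent edges (infinite length, zero efficiency
  contribution).
* Constant thickness vectors, zero-variance reference regions, constant
  outcomes, rank-deficient designs and too-small groups raise typed errors
  (`DegenerateInputError`, `ValidationError`) naming the offending entity.
* Matrix symmetry is exact (the kernel is evaluated on an anti-symmetric
  difference grid), and file round-trips are bit-exact (17-significant-digit
  TSV plus round-trip float parsing).
* Region-name matching is whitespace-trimming and case-folding; thickness
  column order never affects results (tested end-to-end).

## Problem sizes used in the shipped test suite

Oracle-equivalence suites use >=100 random graphs of up to 10 nodes.
Recovery and calibration suites run the full pipeline at the study's sample
sizes (108 subjects x 148 regions): 100 replicates for detection power,
500 for null calibration, 40 for nodal recovery. The acceptance script
uses 30/30/15/5 replicates for its reported rates.

## Known limitations

* The generator's independence of regions (no spatial autocorrelation, no
  shared pathology factor) makes between-subject variance of global indices
  smaller than in real cohorts; planted effect sizes are calibrated to the
  generator, not to biology.
* Characteristic path length is heavy-tailed under strong planted
  heterogeneity (see above); mean path length is reported for inference but
  is outlier-sensitive, as it would be on real data with extreme regional
  deviations.
* The bootstrap interval is the percentile method; no BCa correction.
* The in-sample reference-scoring bias analysed above affects any study
  that scores reference subjects against a reference containing themselves;
  the package's leave-one-out default corrects the comparison but slightly
  changes the control networks relative to the in-sample convention.
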