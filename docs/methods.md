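# Methods

## Model and assumptions

The framework substitutes duration for time: patients with disease duration
in [k, k+L−1] years form overlapping subgroups, and the ordered sequence of
subgroup-vs-control statistical maps is treated as a trajectory. The implicit
assumptions are (i) duration is a usable proxy for progression across
subjects, (ii) duration coverage is reasonably uniform so every window is
populated, and (iii) dysfunction is piecewise-stable: within a stage the
case–control pattern is shared, between stages it differs. Nothing in the
pipeline models within-subject change; it is a cross-sectional construction.

Five functional indicators summarize resting-state activity per voxel or
parcel: fALFF (in-band fraction of square-root spectral power after linear
detrending), ReHo (Kendall's W of a voxel's cubic neighborhood, average-rank
ties), and functional connectivity density at global, local (within a metric
radius) and long-range (the difference) levels. All five are invariant to
per-voxel affine rescaling.

## Parameters

| parameter | default | meaning |
|---|---|---|
| window_length_years | 5 | duration-window length L; windows overlap by L−1 |
| min_subgroup_size | 8 | windows smaller than this are dropped with a warning |
| band | 0.01–0.08 Hz | fALFF band (standard definition) |
| fcd_r_threshold | 0.6 | correlation threshold for FCD counts |
| lfcd_radius_mm | 12 | metric radius defining local FCD |
| n_perm | 5000 | permutations / spins for inference (tests and the
acceptance script use 99–499; see *Problem sizes*) |
| n_boot | 1000 | region bootstrap draws for gene standard errors |
| fdr_q | 0.05 | Benjamini–Hochberg level everywhere |
| z_gene_threshold | 5 | \|Z\| cut for the reported PLS1± gene lists |
| align_alpha | 0.5 | weight of spatial vs temporal similarity in alignment |
| ap_damping / iters | 0.9 / 1000 (50 stable) | affinity propagation schedule |

The FCD threshold, local radius and ReHo neighborhood are field-standard
values; they are stated here as package choices.

## Numerical and procedural choices

**t→z conversion.** Subgroup degrees of freedom differ, so member t-maps are
converted elementwise by the sign-preserving probability transform
z = Φ⁻¹(F_t(t; df)) (computed on |t| with the tail function for numerical
symmetry) before the Liptak–Stouffer combination Z = Σwᵢzᵢ/√(Σwᵢ²),
wᵢ = √nᵢ. The combination applies no correction for the dependence induced
by overlapping windows (adjacent windows share ~(L−1)/L of their patients);
measured on null cohorts this inflates the variance of a stage's combined
z-map to ≈ 2–2.5, yet the average FDR-flagged fraction stays ≈ 0.055 at
q = 0.05 because the step-up threshold adapts. This is a known limitation of
the design, inherited deliberately.

**State selection.** Affinity propagation uses Pearson correlation between
vectorized maps as similarity — map amplitude scales with subgroup size and
is not the scientific object — with the preference swept over the 5th–95th
percentiles (step 10) of the off-diagonal similarities. Among the resulting
partitions, the one maximizing the Calinski–Harabasz index is selected,
excluding partitions that contain a singleton state: a duration-related
state spanning a single window has no temporal extent, and because adjacent
windows are near-duplicates (shared patients), the CH index otherwise
degenerates toward singleton-heavy fragmentations on chain-structured map
sequences. If no candidate survives the restriction the unrestricted argmax
is used. Identical maps short-circuit to one state.

**Alignment.** The reference indicator is the one whose state count equals
the modal count; other indicators are matched by an optimal one-to-one
assignment (Hungarian) on α·corr(exemplars) + (1−α)·Jaccard(member windows),
surplus states attach to their best reference state, windows take the
majority stage across indicators with ties resolved toward the earlier-mean-
duration stage, and stages are renumbered by ascending mean member duration.
Per-indicator stage z-maps are primary; a cross-indicator fused map is also
emitted.

**Spin nulls.** Two rotation nulls are implemented. (1) Label reassignment:
uniform SO(3) rotations move cortical centroids and each cortical region
takes the value of the region nearest its rotated centroid; subcortical
regions, which have no sphere position, are permuted among themselves. This
is the field's standard parcel-level spin and is used in the pipeline.
It is approximate: the observed map is never snapped while every surrogate
is, so for maps much smoother than the parcel spacing the surrogates are
systematically rougher and the explained-variance statistic becomes
anticonservative. (2) Conditional-simulation spin
(`conditional_spin_surrogates`): the map is modeled as an isotropic
squared-exponential process whose length scale is fitted from its empirical
correlogram, and each surrogate is the same realization re-evaluated at
rotated coordinates, drawn from the exact conditional law. This variant is
calibrated (uniform null p-values) even for very smooth maps and is the one
the calibration tests exercise. A control experiment with exactly rotated
realizations confirms the add-one permutation estimator itself is exact.

**Gene bootstrap.** Regions are resampled with replacement (optionally
cortical-only), the PLS1 weights are refitted per draw and sign-aligned to
the original weights (flipping a draw whose weights anti-correlate), and
z = weight / bootstrap SE with two-sided normal p-values and BH-FDR. The
reported short list is the top |z| decile; the |Z| > 5 operating point used
for real-scale gene lists is exposed as `z_gene_threshold`.

**Degenerate inputs.** Constant time series yield ReHo 0 with a warning;
constant templates and zero-variance feature columns are reported missing or
dropped with a warning; a single map passed to the combination is returned
unchanged; the demeaned gradient ratio is reported missing where the
denominator's magnitude is below 1e−6.

## The synthetic generator

`synthetic` plants a known truth: five stages tile 0–30 duration-years with
boundaries at half-years (5.5/11.5/17.5/23.5) — an integer boundary would
split some 5-year windows exactly 50/50 and leave their planted stage
undefined. Stage effect maps are smooth sphere fields, sequentially
decorrelated and sparsified to ~35 % of parcels at amplitude d = 0.8
(pairwise map correlation ≤ ~0.1); indicators share the pattern up to a
fixed per-indicator gain. Patient durations are stratified-uniform (equal
counts per stratum, jittered): marginally uniform, while guaranteeing every
window its expected ~15 patients — the method's own requirement of
relatively uniform duration coverage. Patient parcel values are control
baseline + d·(reference SD) + N(0, noise_sd); PANSS scores are a stage base
profile plus a stage-specific coupling times the subject's centered
pattern-projection score plus noise; morphology carries a planted negative
duration–gray-matter slope; drug equivalents are independent of duration.
Expression matrices plant coupled genes at an exact sample correlation with
the stage-1 map, remaining genes being smooth fields; templates are built
the same way at a requested r. A timeseries mode synthesizes band-limited
voxel series on a toy grid whose mixing weight and band-power gain are
frozen calibrations mapping d to all five indicators with the correct sign.

What the generator does not emulate: hemodynamics, scanner noise and
spatial smoothing; site effects; medication confounds on the indicators;
nested/progressively-expanding stage maps (stages are planted as distinct
patterns, the harder recovery case); donor-level expression structure.
Passing tests therefore demonstrate the machinery recovers planted structure
under idealized noise, not that real cohorts contain such structure. Chance
correlations between independent smooth maps are large at 246 parcels
(|r| ≈ 0.2–0.4 is common) — this is exactly why the spatial nulls exist.

## Problem sizes

The test suite and acceptance script run the full framework at the reference
conditions (246 parcels, 90 patients / 26 windows, 120 controls) with 99–499
permutations or spins per inference, 100–500 bootstrap draws, 10–25 seeded
replicates for recovery rates, and 200 replicates for p-value uniformity
checks; the RunConfig defaults (5000 permutations, 1000 bootstrap draws)
match the real-scale analysis. Calibration statements in the tests are
Monte-Carlo statements at those sizes.

## Known limitations

- Overlapping windows are combined as if independent (inherited design);
  stage z-map variance is inflated accordingly and documented above.
- Parcel-level snap spins are anticonservative for ultra-smooth maps; use
  the conditional spin when the map's autocorrelation length rivals the
  parcel spacing.
- With window length exceeding the true stage duration, every window mixes
  stages and the state count becomes unstable (more, finer states); the
  stage partition remains broadly consistent but not identical across
  window lengths.
- PLS1 on small stages (n ≈ 20) estimates loadings noisily; the permutation
  p is exact but power is limited.
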