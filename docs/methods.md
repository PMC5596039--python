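# Methods

## The WM damage metric

For a tissue compartment occupying voxels `i = 1..n` of a FLAIR (or T2W)
image, the compartment intensity is the plain arithmetic mean
`I = Σ I_i / n`. The damage metric is

```
WM_damage = (I_WMH − I_NAWM)/I_NAWM × WMH_vol/(WMH_vol + NAWM_vol)
```

— the lesion proportion of the white matter (the tissue in which WMH can
appear; the cortex is excluded by construction of the masks), weighted by
the relative lesion contrast. Properties the implementation guarantees and
the test suite asserts:

- **Zero cases.** `WM_damage = 0` when the WMH volume is 0 (by definition,
  no intensity statistics are requested in that case) and when
  `I_WMH = I_NAWM`.
- **Bounds.** With WMH defined operationally as signal at least 3 NAWM
  standard deviations above the NAWM mean, `0 ≤ SD_NAWM ≤ (Imax − Imin)/2`,
  and the NAWM mean in the 50–67% window of the intensity ceiling that is
  conventional for T2-based sequences, the metric lies in [0, 1]. The lower
  end of that window matters: it is what caps the contrast term at 1. Both
  a 10⁴-draw sweep (acceptance) and a Hypothesis property test cover the
  region.
- **Scale invariance, shift sensitivity.** Multiplying all intensities by
  `c > 0` leaves the metric unchanged (the contrast term is a ratio);
  adding a constant does not. Both are asserted.
- **Negative contrast** (`I_WMH < I_NAWM`) almost certainly indicates a
  segmentation error; the raw negative value is reported with
  `valid=False` rather than clamped, so the problem stays visible.
- When intense/less-intense lesion compartments exist, `I_WMH` is computed
  on their union, i.e. the volume-weighted mean.

Volumes are `voxel count × voxel volume (mm³) / 1000` ml, with voxel
dimensions from the FLAIR header; masks are never resampled. Longitudinal
change is available both as the difference of numeric volumes and as mask
subtraction (new = follow-up∖baseline, vanished = baseline∖follow-up); the
net spatial change equals the volume difference of the same two masks
exactly, which the suite asserts.

## Segmentation routes

**Colour fusion + minimum-variance quantisation.** Two sequences (default
T2*W → red, FLAIR → green) are min-max normalised within the brain mask and
treated as points in the RG unit square. The quantiser greedily applies the
axis-aligned binary split with the largest reduction in total within-level
SSE (found exactly per axis by prefix sums over sorted values), then
refines with Lloyd iterations; it is deterministic, achieves zero variance
when the image has exactly k colours, and its within-level variance is
non-increasing in k. Level-to-tissue assignment is a centroid rule: the
most populous level anchors WM; any level within `margin` (default 0.1,
normalised units) of the anchor in both channels is merged into WM (a
variance-minimising quantiser will split a large homogeneous tissue into
near-identical levels); levels whose green centroid exceeds the anchor's by
more than `margin` are WMH, the single highest-green one being the intense
compartment. The original colour-fusion method's level selection is
operator-guided; this rule is a deterministic stand-in and is not claimed
equivalent.

**Gaussian-mixture clustering.** A k-component (default 4: CSF, cortical
grey matter, NAWM, WMH) mixture with diagonal covariances is fitted by EM
(scikit-learn; 10 k-means-seeded restarts, relative tolerance 1e-6, fixed
seed, up to 3 reseeded rounds if a component collapses) to the per-voxel
feature vectors of the min-max normalised sequences. The NAWM component is
the one with the highest T1-weighted mean (white matter is T1-bright), or
the highest-weight component if no T1W channel exists; components whose
mean profiles are within `merge_tol` (default 0.1) of it are absorbed, for
the same over-segmentation reason as above.

**FLAIR thresholding.** WMH are voxels with intensity at least
`mean_NAWM + k_sd·SD_NAWM` (default `k_sd = 3`, the conventional
hyperintensity definition); a second threshold at `k_sd_intense = 5`
separates intense from less-intense lesions. The comparison is inclusive
(≥) except when the margin `k_sd·SD` is exactly zero: there the threshold
degenerates to the NAWM mean and an inclusive rule would label all of NAWM
as lesion, so the comparison becomes strict and a warning is emitted (a
zero SD essentially only occurs on noiseless synthetic input). Raising
`k_sd` never adds voxels. The combined pipeline
(`segment_cluster_threshold`) uses the mixture's NAWM component to supply
the threshold statistics and returns NAWM minus the detected WMH — the
fully automatic configuration; the quantisation route is
`segment_mcmxxxvi`. On real data the user must supply a brain mask with the
cortex already excluded (atlas conventions are out of scope); the phantom
provides one.

## The phantom

A stated world for testing, not a realism dial. Nested-ellipsoid anatomy:
intracranial ellipsoid (semi-axes 0.44 of the grid), cortex as the outer
18% shell, a central ventricular ellipsoid of CSF, white matter in
between. Ellipsoidal lesions (radii 2–5 voxels) are placed fully inside the
white matter without overlap, alternating intense / less-intense so both
compartments are populated. FLAIR means: NAWM 150 ± nominal SD 15, CSF 30,
cortex 170, lesions at `150 + k·15` with `k_intense = 6`, `k_less = 3` (the
definitional floor), ceiling 255 — the NAWM mean sits at 59% of the
ceiling, inside the 50–75% convention. Additive Gaussian noise with SD 7.5
(SNR = mean/SD = 20) is applied to every channel; with `noise_sd = 0` the
image is exactly piecewise constant, so the measured metric equals the
closed-form expectation to machine precision (asserted at 1e-12). T1W, T2W
and T2*W channels use fixed per-tissue lookup tables with plausible
qualitative contrast (CSF T1-dark/T2-bright, lesions T1-hypointense,
T2-hyperintense); they exercise the multispectral routes and are not
claimed physiological.

What a green phantom test does *not* establish: robustness to partial
voluming, Rician noise statistics, bias fields, motion, anatomy-dependent
lesion shape, or registration error — none of which the generator models.
The parameter-recovery checks (full pipeline within 15% of the closed form
at SNR 20 with lesions at the 3-SD floor) are statements about this stated
world only.

## Evaluation statistics

- **Bootstrapped Spearman**: rho and asymptotic p on the full sample (ties
  by average ranks), percentile CI from 2000 paired resamples by default
  (replicate count and CI type are documented choices; the original robust
  correlation tooling does not state its settings). Degenerate resamples
  (constant vector) are dropped from the CI.
- **Bland-Altman**: differences as a percentage of the pair mean by
  default (appropriate when comparing measurements across a wide dynamic
  range), limits of agreement `mean ± 1.96·SD` (sample SD). Absolute mode
  available; zero pair means are an error in relative mode, naming pairs.
- **ANCOVA**: OLS of follow-up on baseline + change score (statsmodels);
  listwise deletion with counts reported; optional log transform of the
  outcome; condition-number warning above 1e6.
- **Paired tests**: two-sided Wilcoxon signed-rank (Pratt handling of zero
  differences) and paired t; an all-zero difference vector returns p = 1
  with a `degenerate` flag. A zero-variance nonzero shift yields t p = 0.
- **Multiple testing**: none by default, `holm_adjust` available.

## Numerical and design choices

- Probabilistic masks binarise at 0.5 (configurable) — the threshold the
  upstream probabilistic segmentations leave unstated.
- Grid congruence: shapes exact, affines within 1e-3 per element
  (co-registration is assumed done upstream).
- Mask invariants (NAWM ∩ WMH = ∅; intense/less-intense partition WMH;
  tissue ⊆ ICV; exclusion disjoint from tissue) are enforced at
  construction with voxel counts in the error; validation is idempotent.
- `IntensityStats.sd` is the population SD (ddof 0); Bland-Altman uses the
  sample SD (ddof 1), following each statistic's convention.
- EM log-likelihood monotonicity is asserted via warm-started
  single-iteration refits (the library does not expose per-iteration
  trajectories).
- Additive Gaussian rather than Rician noise in the phantom: at SNR ≥ 20
  the Rician distribution is within ~0.3% of Gaussian in mean shift, below
  the tolerances tested.

## Known limitations

The metric's value is sequence- and protocol-dependent (it is built from
non-quantitative intensities); only its associations are expected to
transfer. The quantisation level-selection and NAWM-component rules are
deterministic surrogates for operator judgement and may need margin tuning
on real data. No registration, bias-field correction, DICOM support, or
periventricular/deep lesion subtyping.
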