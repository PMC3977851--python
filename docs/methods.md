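# Methods

This note documents the models, estimators, numerical choices and
limitations of `wbdwi`, and what the synthetic phantoms do and do not
establish about behavior on clinical data.

## Signal model and ADC estimation

All volumes are magnitude MR images. The diffusion signal is modeled
as monoexponential, `S(b) = S(0)·exp(−b·ADC)`, with ADC in mm²/s.
With exactly two acquired b-values the two-point log-ratio estimator
is the exact maximum-likelihood fit, so no estimator choice arises.
Voxels with a non-positive signal at either b-value have no defined
log-ratio; they are flagged invalid, excluded from every downstream
histogram, and their computed-DWI value is forced to 0 so they cannot
survive thresholding. Negative ADC estimates (pure noise voxels) are
*retained* and counted, never clamped: clamping would bias the gADC
histogram moments.

## Station harmonization

Gain: the abutting 3-slice boundary slabs of adjacent stations are
assumed to sample the same intensity distribution up to a
multiplicative factor. The gain is the slope of a quantile–quantile
regression through the origin on 64 quantiles of the nonzero voxels —
the least-squares cumulative-histogram match for a pure gain model.
Shift: integer displacement along the phase-encode axis minimizing the
mean-square difference over the overlap, searched in ±5 voxels, ties
broken toward 0 then negative. Sub-voxel registration is deliberately
not attempted. Stations are corrected in turn against their
already-corrected superior neighbor; corrections estimated on the
low-b volume are re-applied to the high-b volume, because a gain
applied to a single b-value would corrupt the ADC map while a joint
scaling leaves it invariant.

Slab thickness 3 is a bias/variance compromise: thicker slabs
stabilize the quantile estimates but sample increasingly different
anatomy on the two sides of the boundary.

## Segmentation

The disease threshold is a *required user parameter* (strict `>`),
mirroring the interactive step of the clinical workflow; no automatic
threshold estimation is attempted. For the default phantom the tests
use τ = 25 on the computed-DWI image at b_c = 1355 s/mm², which sits
between the background (≈7) and lesion (≈34) computed intensities.

**GrowCut.** Two-class cellular automaton on a 26-neighborhood with
synchronous updates computed from the previous iteration's state;
attack force `g(|C_p − C_q|)·θ_q` with `g(x) = 1 − x / max‖C‖`
(`g(0) = 1`), seed strengths 1.0, maximum 500 iterations (convergence
= zero label changes). The feature volume is the computed-DWI image —
the volume a reader scrolls while placing the seed boxes. For region
removal, voxels in an inner box seed the structure, the surface of an
outer box seeds background, and the automaton runs on the outer box's
interior only.

**MRF smoothing.** Two-class model with Gaussian class likelihoods and
a Potts prior:

    E(l) = Σ_p −log N(I_p; μ_{l_p}, σ_{l_p}) + β Σ_{p∼q} [l_p ≠ l_q]

optimized by iterated conditional modes (ICM) from the per-voxel
maximum-likelihood labeling. Sweeps visit, in raster order, the
voxels whose single-site flip lowers the energy under the sweep-start
labeling, re-evaluating each flip sequentially; this active-set
formulation reaches the same class of fixed points as a full raster
sweep while scaling to whole-body volumes, and accepted flips can only
decrease E. β defaults to 1.5 (in log-likelihood units) on a
6-neighborhood — the face neighborhood keeps the exhaustive-MAP test
oracle tractable and is conventional; both are configurable. β = 0
reduces exactly to maximum-likelihood classification. A class whose
estimated σ is 0 is given a configurable floor (default 1e-6) with a
warning.

Two estimation choices deserve emphasis:

* *Likelihood feature.* The MRF runs by default on the measured
  high-b volume, not the computed-DWI image. Extrapolating to a high
  computed b-value raises the noise floor wherever the low-b signal is
  small (the computed intensity is a negative power of S(b_low)), so
  background speckle can reach lesion-like computed intensities; in
  the measured high-b image the same voxels stay near the noise floor
  and the two classes separate cleanly. `mrf_feature="cdwi"` restores
  smoothing on the computed image.
* *Interleaved re-estimation.* When class statistics are estimated
  from the mask (the default: mean/stddev of inside vs outside
  voxels), estimation and ICM are interleaved for two rounds. The
  initial threshold mask is contaminated by exactly the speckle and
  artifact voxels the smoothing is meant to remove, which inflates the
  disease-class variance and lets the boundary creep; statistics
  re-estimated from the first smoothed labeling separate the classes
  far better. With explicitly provided statistics a single round is
  run.

**Components and editing.** Connected components use 26-connectivity;
ids are assigned by decreasing voxel count with ties broken by first
raster occurrence, so runs are bit-reproducible. The superior cutoff
clears every slice strictly superior to (index lower than) the cutoff
slice, which itself survives — the user supplies the slice index of
the chosen cervical landmark; no anatomical detection is attempted.
VOI exclusion is non-destructive bookkeeping and is exactly inverted
by re-inclusion.

## Metrics and statistics

tDV is the included-voxel census times the voxel volume (ml). gADC
statistics are computed on the raw ADC values pooled over all included
components — one global distribution, not per-lesion averages; the
100-bin 0–3.0×10⁻³ mm²/s histogram is for display only. Estimators:
sample median; unbiased variance; adjusted Fisher–Pearson skewness;
bias-corrected *excess* (Fisher) kurtosis. Excess kurtosis is used
throughout because post-treatment disease distributions can plausibly
be platykurtic, which a raw Pearson kurtosis could not express.
Numerically constant distributions report NaN shape moments with an
explicit `moments_defined = False` flag rather than a silent 0.

Rank tests are exact by enumeration at small sample sizes — all
`C(n_a+n_b, n_a)` group assignments for Mann-Whitney at combined
n ≤ 12, all 2^m sign patterns for Wilcoxon at m ≤ 15 nonzero
differences (zero differences dropped, ties mid-ranked) — and fall
back to tie-corrected normal approximations above those sizes; the
switchover points are configurable. The Δ median gADC comparison is
one-sided (responders greater) on the standing assumption that
effective treatment raises ADC; all other metrics use two-sided tests.
α = 0.05.

## Phantoms

The generator emulates the acquisition features the pipeline must
survive, with analytic ground truth:

* ellipsoidal lesions (default ADC 0.82×10⁻³ mm²/s, amplitude 100) in
  an elliptic-cylinder body compartment (amplitude 60, ADC
  1.6×10⁻³ mm²/s — bright at low b, suppressed at high b) surrounded
  by signal-free air;
* optional spleen-like blobs (lesion-bright, low ADC) for the editing
  workflow, a one-slice fat-suppression-failure band (low ADC ≈
  0.3×10⁻³ mm²/s, so it decays little and survives computed-DWI
  extrapolation), and salt voxels planted in the high-b image;
* Rician noise `√((S+ε₁)² + ε₂²)` per b-value with σ set so that the
  mean noiseless lesion signal over σ equals the SNR target (defaults
  22 at b = 50, 15 at b = 900; SNR conventions vary — this one is
  fixed and documented);
* per-station gain and phase-encode-shift corruptions applied *after*
  the noise, as scanner gain differences would be.

Default geometry is 4 stations × 24 slices × 96×96 at 4×4×6 mm.
Lesions are placed well inside stations: the gain estimator assumes
the abutting boundary slabs sample the same distribution, and a lesion
straddling a boundary violates that assumption (on clinical data this
shows up as residual gain error, not failure). Treatment response
scales lesion semi-axes by the cube root of a volume factor and shifts
ADC additively; progression adds lesions.

Cohort simulations default to 7 responders (volume scale lognormal
around 0.5, ADC shift ≈ N(+0.18, 0.05²)×10⁻³ mm²/s) and 4
non-responders (scale around 1.26, shift ≈ N(−0.02, 0.03²)×10⁻³),
with volume scales clamped to [0.1, 2.5] so lesions neither vanish
from the grid nor outgrow the torso. Per-patient phantoms use a
reduced 2-station 64×64 geometry, chosen so a full paired cohort of 22
studies runs in seconds; at these sizes each study still exercises
fusion, extrapolation, MRF smoothing and metric pooling end to end.

**What the phantoms do not show.** Plateau compartments have no
partial-volume gradients, no T2 shine-through, no EPI geometric
distortion, no anatomy change across station boundaries, and lesion
ADC is uniform within a lesion. Passing the recovery tests therefore
demonstrates correctness of the estimators and the pipeline plumbing
under the stated noise model — not segmentation accuracy on clinical
WBDWI, where threshold choice, reader editing and artifact burden
dominate.

## Known limitations

* The MRF neighborhood energy treats volume boundaries by dropping
  out-of-grid pairs, which mildly favors flips at edges.
* ICM is a local optimizer; on small random grids it attains the
  exhaustively enumerated MAP in ≳90% of instances but has no global
  guarantee.
* The GrowCut automaton is synchronous and can need many iterations on
  large uniform regions; editing therefore runs it only inside the
  user's outer box.
* Histogram metrics are estimated on voxels pooled across lesions;
  per-lesion statistics are available but not used in the headline
  comparisons.
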