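# Methods

`tricolo` quantifies the nanoscale association of three molecular species —
the MCM replicative helicase, nascent DNA (EdU), and G-quadruplex (G4) DNA
structures — from three-color single-molecule localization microscopy (SMLM)
coordinates. Because public raw data do not exist for this assay, every stage
is driven and validated by a synthetic-data generator whose ground truth is
known exactly. This note records the models, the parameter choices, and what
the synthetic studies do and do not demonstrate.

## Single-molecule localization

**Camera model.** Frames follow the sCMOS model: for pixel *k*,
`ADU_k = offset_k + gain_k · Poisson(µ_k) + N(0, var_k)`, with per-pixel
calibration maps. After offset/gain correction the read noise has variance
`var_k / gain_k²` in photon units.

**Likelihood.** The exact pixel likelihood is a Poisson–Gaussian convolution.
We use the standard variance-shifted Poisson approximation: adding
`var_k/gain_k²` to both the data and the model rate and treating the result
as Poisson. The approximation is accurate for read-noise variances small
against the signal, is differentiable, and makes the Fisher information
analytic: `I_ij = Σ_k ∂µ_i ∂µ_j / (µ_k + v_k)`.

**Detection.** Each corrected frame is high-pass filtered by subtracting an
inverse-variance-weighted box mean (box side = round(4·FWHM/pixel), forced
odd). Candidates are strict 8-neighborhood maxima above `threshold_sd` (default
4) robust standard deviations (1.4826·MAD) of the filtered frame, deduplicated
within 2 px keeping the brighter.

**Fitting.** 7×7 patches around candidates are fitted with an integrated 2-D
Gaussian PSF (error-function pixel integrals) by maximum likelihood
(L-BFGS-B with analytic gradients; iteration cap 100, likelihood tolerance
1e-8). A two-emitter model is accepted over the single-emitter model when
`2·ΔlogL > 24` (a ~χ²₃ threshold far in the tail; the source method states no
criterion, so it is a configurable default). Fits below `min_photons`
(default 100) are rejected: at typical backgrounds a 100-photon spot sits at
the detection limit, so dimmer fits are almost always noise peaks. Precision
is the Cramér–Rao bound from the same likelihood; the pooled precision
distribution is summarized by a maximum-likelihood skew-Gaussian fit
(moment-based starting values keep the optimizer off the |shape|→∞ ridge;
note the skew-normal shape is weakly identified near 0, where the Fisher
information is singular, so the shape itself should not be over-interpreted).

**Blink merging.** A fluorophore emits over several consecutive frames.
Localizations in consecutive frames (gap ≤ `max_gap_frames`, default 1) are
linked when the Euclidean distance to the running chain centroid is within
`factor` (default 2.5) times the combined precision
`sqrt(cx² + cy²)`, `cx² = crlb_x,new² + crlb_x,chain²`. Chains collapse to
the inverse-variance-weighted mean with merged precision `(Σ 1/crlb²)^(-1/2)`;
photons are summed over the event and `n_merged` preserves the raw count.
Linking against the running centroid rather than the previous member keeps
the per-link false-split probability at `exp(-factor²) ≈ 0.2%` instead of
`exp(-factor²/2) ≈ 4.4%`, which is what makes <5% merged-count error
attainable at mean burst length 3. Rows already carrying `n_merged > 1` pass
through untouched — a collapsed blink event is final — which together with
greedy nearest-first assignment makes merging exactly idempotent.

## Channel registration

Chromatic aberration between the four dye channels is corrected by a full
2-D quadratic map (basis `{1, x, y, x², xy, y²}`, 6 coefficients per axis)
fitted per source channel against the reference channel on a bead field.
Beads are matched by mutual nearest neighbor within a 500 nm gate.
Coordinates are centered and scaled to [−1, 1] for conditioning and the
coefficients are expanded back to nm units exactly. The reported
`rms_residual_nm` is the leave-one-out RMS per axis (hat-matrix form). With
2 nm per-axis localization noise in each channel the floor is 2√2 ≈ 2.8 nm
per axis; the map itself adds ~1e-13 relative coefficient error in the
noise-free case because the problem is linear in the coefficients.

## Triple-correlation function

The TCF

    f(r1, r2) = <δρ1(R) δρ2(R+r1) δρ3(R+r2)>_R / (<ρ1><ρ2><ρ3>)

is estimated by visiting each channel-1 coordinate: channel-2 offsets are
histogrammed into annular sectors over (r1, θ) and channel-3 offsets over
(r2, θ+Δθ); counts become local densities via the sector area; fluctuations
are taken against the ROI-wide mean densities (global CSR reference); and the
product δρ2·δρ3 is averaged over visited coordinates and θ. Because the
average runs over channel-1 *points*, the estimator equals the definition up
to an additive term proportional to the unconditioned channel-2/3 cross
correlation `<δρ2 δρ3>` at the same lag; that term vanishes in expectation
whenever any one channel is independent of the others, so the null behavior
(f ≡ 0) and the location of planted-geometry peaks are unaffected.

Numerical choices:

- **Grids.** r1, r2 ∈ [0, 500] nm in 25 nm bins by default; Δθ is binned as
  circular *shifts* of the θ binning (`ntheta` uniform bins, default 12), so
  Δθ values sit at multiples of 2π/ntheta. This makes the binned estimator an
  exact θ-index shift and puts common geometries (e.g. Δθ = π/3 at ntheta=12)
  at bin centers.
- **Edge correction.** `analytic` mode normalizes every sector bin by its
  in-ROI area fraction, computed by quadrature of the exact square–annulus
  intersection (Gauss–Legendre in radius × a 720-point angular grid); no
  point is discarded. Bins with in-ROI fraction below 5% are excluded from
  the average rather than variance-amplified. `periodic` mode wraps
  coordinates on the ROI torus and exists for oracle testing.
- **θ-averaging.** f is re-indexed from (r1, r2, Δθ) to (r1, r2, r3) using
  the geometric third side r3² = r1² + r2² − 2·r1·r2·cosΔθ of the triangle
  spanned by the two displacement vectors (the `minus` convention, the
  default; a `plus` convention is exposed because the transform is sometimes
  printed with the opposite sign). Bins are averaged weighted by raw triple
  counts; empty target bins are NaN, never zero.

## Conditional local density

    C3(r1, r2) = <δρ1 δρ2 δρ3> / <δρ1(R) δρ2(R+r1)>

estimates the density (per nm²) of the third species at r2−r1 given a
channel-1/2 pair correlating at r1. The denominator is estimated on the same
binning. A conditional density is only meaningful where the pair actually
correlates: r1 bins are masked when the denominator is below an absolute
floor (10⁻³·<ρ1><ρ2>) **or** not significantly positive (below 3× its
standard error over visited points; configurable, 0 disables). Without the
significance clause the ratio in uncorrelated r1 bins is noise divided by
noise and its argmax is meaningless at realistic densities. Masked bins are
reported, never silently zeroed; negative (anticorrelated) denominators are
masked by the same rule.

## Association endpoint

The per-nucleus endpoint is the density of replisome-associated G4
structures. "Structure" = single-linkage cluster (ε = `cluster_eps_nm`,
default 75 nm) of blink-merged localizations with ≥ `min_cluster` (default 3)
members — labeled structures carry multiple fluorophores, so genuine
structures produce several merged localizations while stray single molecules
do not. A G4 structure counts (once) when both an MCM structure and an EdU
structure lie within `r_assoc_nm` (default 150 nm) of its centroid. The
clustering radius is deliberately independent of `r_assoc` so that counts are
monotone in the association radius. The TCF/C3 peak extent can suggest
`r_assoc` (`suggest_r_assoc`); every result row carries the parameters that
produced it. This reduction rule is an explicit operational choice of this
package — the endpoint's definition in terms of thresholds and cluster
parameters is not uniquely determined by correlation functions alone.

## Condition statistics

Per-nucleus densities are summarized as mean ± SD (n−1). The treatment
effect is the PDS/NT ratio of means with first-order (delta-method)
propagated SEM `ratio·sqrt((SEM_P/m_P)² + (SEM_N/m_N)²)`, and a two-sided
unpaired t-test; Welch's variant is the default because nucleus-to-nucleus
variance need not be equal across conditions (the Student variant is a
flag). Cell lines are analyzed independently and absolute densities are not
compared across lines. No multiple-testing correction is applied across cell
lines by default (a Holm option exists in the per-line table consumer's
hands); this mirrors per-line presentation of the endpoint.

## Synthetic-data generator: what it emulates, and what not

A scene plants Poisson-distributed triplet anchors (channel 1) with channel-2
and channel-3 members at polar offsets (r1, θ) and (r2, θ+Δθ), one shared
uniform orientation θ per triplet, isotropic Gaussian jitter on members, and
independent per-channel Poisson background. Defaults: 6×6 µm ROI; triplet
geometry r1=100 nm, r2=150 nm, Δθ=π/3, jitter 5 nm. The geometry values are
operator choices for exercising the estimator — the true MCM–EdU–G4 spacing
is unknown — and are stated with every scene. Members falling outside the ROI
are kept and flagged; the correlation stage decides inclusion.

Blinking is two-state: geometric on-bursts (mean 3 frames), geometric dark
gaps, optional reactivation; every molecule activates at least once. Frames
are rendered with the integrated-Gaussian PSF and the full sCMOS noise model
(2000 frames by default, matching a typical acquisition). For cohort-scale
studies the localization stage is emulated at coordinate level: each
structure carries 1 + Poisson(3) fluorophores with 10 nm linkage jitter, each
on-frame yields a localization displaced by a skew-Gaussian-distributed
precision. This exercises everything downstream of fitting at realistic
sizes; the frame-level path (render → detect → fit) is validated separately
at small scale.

Not emulated: stage drift, 3-D defocus, dye-specific photophysics beyond two
states, variable labeling efficiency between conditions, and chromatic maps
beyond degree 2. Passing the synthetic studies therefore shows the estimators
and the pipeline logic are correct under the stated model; it does not
certify performance on data whose aberrations or photophysics depart from it.

## Problem sizes used in the validation studies

Null calibration uses 100 scenes at 50/µm²/channel on a coarse (≈64-bin)
grid — with many more bins a correct estimator still produces |z|>3
excursions by chance alone (0.27% of bins), so bin count is chosen to keep
the familywise chance below ~1. Planted-geometry recovery uses 100 scenes at
5 triplets/µm² over 10/µm² background with 40 nm radial bins (placing the
planted radii inside, not on, bin edges). Localization efficiency uses 500
single-emitter patches at 1000 photons. Cohort recovery uses 50 replicate
cohorts of 20 nuclei/arm with planted densities 0.5 (NT) and 0.8 (PDS) per
µm², i.e. a true ratio of 1.6, with 500-frame acquisitions; background
structure density is 1/µm²/channel, representative of well-pre-extracted
nuclei. `scripts/acceptance.py` re-measures the same quantities at reduced
replicate counts (30 scenes, 8 cohorts) to stay fast while remaining
diagnostic.

## Known limitations

- The two-emitter fitter handles k ≤ 2; overlapping clusters of ≥3 active
  emitters in one frame bias photometry (rare at SMLM activation densities).
- The TCF estimator's visited-point centering (above) reproduces the
  definition only up to the unconditioned 2–3 correlation term; for analyses
  whose point is the *absolute amplitude* of f in the presence of strong 2–3
  correlation, a CSR-reference subtraction would be needed.
- The skew-Gaussian precision model is a descriptive QC summary; its shape
  parameter is ill-determined near symmetry.
- Association counts depend on (`r_assoc`, `cluster_eps`, `min_cluster`);
  conclusions should be checked for stability across a range of `r_assoc`,
  which the monotonicity property makes cheap.
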