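# Methods

`rimap` estimates the refractive index `n` of a thin sample layer —
prototypically a single collagen fibril — by combining defocused
single-molecule localization microscopy (SMLM/dSTORM) with an
independent height measurement from atomic force microscopy (AFM).
This note describes the models, the estimators, the numerical choices,
and what the synthetic validation does and does not demonstrate.

## Image formation

A fluorophore is modeled as a freely rotating dipole: the incoherent
sum of three orthogonal fixed dipoles.  The emitter sits in the imaging
buffer (index `n_ambient`, default 1.33) at height `z` above the
coverslip; between it and the glass (index `n_immersion`, default 1.52,
matched to the objective immersion) lies a laterally infinite planar
layer of index `n_layer` and thickness `H` — the local planar
approximation of the curved fibril.  The expected camera image is
computed in the pupil:

* the dipole far field is decomposed into s- and p-polarized plane
  waves on a Cartesian back-focal-plane grid limited to
  `sin θ ≤ NA/n_immersion` (default 96 samples across the pupil);
* each component crosses the ambient/layer/glass stack with
  transfer-matrix Fresnel coefficients; evanescent components are kept,
  so supercritical-angle fluorescence (SAF) is included and the
  collected power genuinely decays with emitter height;
* the stationary-phase factor `k_gz/k_az` and the aplanatic
  `1/√cos θ_g` apodization map the far field to the pupil; defocus is
  the pupil phase `exp(−i k_gz δ)` referenced to the coverslip
  (positive δ puts the nominal focal plane inside the sample — this
  sign is pinned by reproducing the published precision numbers);
  aberrations enter as Noll-indexed Zernike phases in radians;
* a partial discrete Fourier transform produces the image on a
  subpixel grid, which is binned into camera pixels (default 3×
  oversampling of a 160 nm back-projected pixel, 15 × 15 px ROI);
* normalization uses Parseval's identity on the pupil so that the
  image integrated over an unbounded detector equals the photon count
  `N`; a uniform background `BG` is added per pixel.

For fitting, `z < H` is handled by analytic continuation of the
ambient propagation phase.  This matters only for flank dyes when the
layer is held at the AFM height; the crest dyes that determine the
height estimate sit at `z ≈ H` where the model is exact.

Camera counts are treated as Poisson (EMCCD excess noise is not
modeled; see Limitations).

Numerical accuracy: halving the pupil step or doubling the pixel
oversampling changes pixel values by well under 1%; the defocused
ring pattern limits subpixel quadrature to ~0.5% at the default 3×
oversampling (geometric convergence beyond).  Because the hard pupil
edge and the critical-angle cusp give ~1/x³ intensity tails, a 15 px
ROI captures ≈ 92% of the photons; photon conservation to 0.5% needs a
≈ 20 µm ROI.

## Precision theory

With `H` known, the best attainable precision of `n` from one image is
the Cramér–Rao bound `Δn_SMLM = 1/√FI` with the Poisson Fisher
information `FI = Σ_px (∂I/∂n)² / I`; the derivative is a central
finite difference in `n` (step 1e-4, verified by a half-step check).
At `H = 0` the image carries no information on `n` and the bound is
reported as infinite, a distinguished value so sweeps complete.

An AFM height error `Δz_AFM` propagates by refitting: noise-free
images computed at `H ± Δz_AFM` are matched in least squares by images
at `H` with a free index; the mean one-sided index shift is
`Δn_AFM`.  The two contributions add in quadrature.  The photon-budget
inversion uses the exact `1/√N` scaling of the bound at fixed
signal-to-background ratio.

The bound versus `H` is U-shaped at fixed defocus: it improves while
the layer-top dye moves away from the glass but degrades again once
the dye approaches the focal plane (within roughly half the defocus),
where the axial shape sensitivity of defocused imaging collapses.  The
monotone-improvement picture therefore applies for `H` up to ~200 nm
at 500 nm defocus.

## Localization

Candidates are detected per frame on a box-summed,
background-subtracted statistic (the defocused PSF is a ring; raw
pixel maxima are multimodal), with an absolute integrated-photon
threshold and a relative-to-median threshold, and a both-members
rejection for candidates closer than one ROI.  Each ROI is fit by
maximum likelihood over `(x, y, z, N, BG)` at fixed `(n, H)` with
analytic pupil-space gradients, L-BFGS-B in rescaled parameters
(positions in units of 50 nm, photons and background relative to their
initial estimates; unscaled photon coordinates stall at large `N`).
Fit quality is the deviance against the saturated Poisson model,
`LLR = 2(LL_sat − LL_fit)`; on clean 15 × 15 ROIs it concentrates near
the pixel count (~225).  The conventional gate `LLR < 600` absorbs
EMCCD excess noise, which roughly doubles the deviance; the pipeline
default for pure-Poisson synthetic data is 300 (the χ²₂₂₀ tail).

Repeated fast re-estimates of `z` alone (for the defocus scan and the
assumed-index grid) use a vectorized golden-section search against
cached pupils.  Axial position and defocus trade off strongly and the
mismatch likelihood develops secondary minima far from the coverslip,
so reference-plane refits are confined to |z| ≤ 250 nm.

## Fibril analysis pipeline

1. **Fiducials and drift.**  Persistently recurring candidates are
   fiducials; their background-subtracted centroids form drift tracks,
   and the per-frame mean displacement (relative to the track mean) is
   subtracted.  All PSF refits run in the raw camera frame; drift
   correction applies to coordinates only afterwards.
2. **Reference plane and defocus.**  The defocus is the value at which
   coverslip-bound dyes refit to mean `z = 0` (root-finding over a
   ±250 nm scan); the residual tilt plane is removed from all heights.
   The prediction uncertainty of the plane at the fibril propagates
   into the final error budget: a reference-level error shifts every
   apparent height together, exactly like an AFM height error.
3. **Axis.**  With an AFM map available, the axis is the height-ridge
   line of the dense topography (per-100 nm bins, height-weighted
   lateral centroid), registered to the localization cloud by the
   median lateral offset — a pure translation, since drift correction
   is defined up to a constant.  Both modalities then share one axis,
   so its residual error smears both cross sections alike and cancels
   in the height comparison.  Without a map, a stiff least-squares
   spline (cubic by default; interior knots sized so each span holds
   ~150 localizations, never closer than 300 nm; 3-pass sigma
   clipping) is fit through the cloud's principal frame.  A flexible
   smoother would chase the transverse labeling noise — at a few
   hundred localizations per micrometer the cloud's local center has
   5–15 nm of irreducible sampling noise.
4. **Cross sections.**  Localizations map to `(s, X, Z)` by
   nearest-point projection onto the axis (dense 10 nm presampling,
   local segment refinement; boundary points flagged).  DBSCAN in
   `(X, Z)` (eps 30 nm, min_samples 10) keeps the main cluster.
5. **Heights.**  The fibril height for an assumed index is the crest
   of the cross-section profile: sliding windows with a fixed count of
   localizations (default 40) ordered by `X`, per-window median `Z`, a
   moving average over one window-length of medians (step-1 windows
   are almost fully correlated; a shorter smoother leaves the maximum
   of profile noise as a bias), maximum plus the AFM-measured debris
   offset.  The error is estimated by the half-sample/√2 resampling
   rule (1000 resamples by default).
6. **Matched AFM crest.**  The AFM crest consumed by the intersection
   is computed from the same axis by emulating the SMLM sampling of
   the measured profile: surface-uniform labels are edge-dense when
   projected to `X` (arc-length weighting of the profile), each
   carries the lateral localization error (five-point Gaussian
   quadrature of the CRLB-plus-drift width) and the axial fit noise.
   Both modalities then estimate the crest of the same smeared
   surface, and the smearing biases cancel in the comparison instead
   of masquerading as a refractive-index shift.
7. **Intersection.**  A line through `(n_assumed, H_SMLM)` — apparent
   height rises with the assumed index, ≈ 2H nm per index unit — is
   intersected with the AFM height; the fit grid is 1.38–1.48 in steps
   of 0.02.  `σ_n` comes from 10,000 Monte Carlo draws of all heights
   (including the AFM and reference-plane terms).
8. **Swelling.**  Cross-sectional areas integrate the raw
   (unsmoothed) window-median profile; the hydrated index, the area
   swelling `ΔA = A_wet/A_dry − 1` and the water index 1.33 invert the
   area-weighted mixing model to the dry-state index,
   `n_dry = n(1 + ΔA) − ΔA·n_water`.
9. **Mapping and variance.**  Sliding windows of 100 localizations
   along `s` (90% overlap) repeat the height-and-intersection estimate
   against the local AFM height; the inner crest window is capped at a
   quarter of the mapping window so half-sample resampling still
   evaluates the same estimator.  Across window sizes, the total map
   variance splits as `σ_n² = σ_n,collagen² + σ_n,exp²` with the
   sample term floored at zero.

## Synthetic data

The generator emulates the full measurement: emitters placed by a
Poisson point process on the upper half-cylinder surface (radius 69 nm
hydrated, 40 nm dry by default; 600 µm⁻² surface density) and on the
surrounding coverslip (60 µm⁻²); two-state Markov blinking (geometric
on-times, mean 1.5 frames); log-normal photons per frame (mean 3000,
CV 0.3) over a 27-count background — the ~3000-photon, SBR ≈ 110
per-localization regime of real defocused dSTORM collagen recordings —
linear stage drift; always-on fiducials; Poisson noise.  Rendering
uses the same vectorial model as fitting, each fibril dye imaged
through a local planar layer of its own height, so recovery tests
isolate pipeline correctness from model misspecification — a
deliberate idealization.  AFM maps sample the true surface on a 39 nm
grid with Gaussian height noise and per-scan-line tilts.

What the synthetic tests do **not** show about real data: antibody
label offsets (exposed as a parameter, default 0), dye orientation
effects, EMCCD excess noise, axial index heterogeneity, AFM tip
convolution, and SMLM/AFM registration errors beyond a translation are
all outside the generator.

Validation problem sizes: the seeded end-to-end recoveries use a
2.5 µm fibril, 7000 frames and ~450 fibril localizations per run
(under a minute each); mapping and variance tests run on
analysis-level synthetic cross sections (20 µm, ~5000 localizations)
that skip image rendering.

## Known limitations

* The half-sample/√2 height-error rule assumes the error scales as
  `1/√n_locs`; with fixed-count crest windows the dominant noise term
  does not shrink with the total count, and the rule under-reports the
  height error by ~25–30% (measured against a fresh-data Monte Carlo
  oracle).  The reported `σ_n` inherits part of this underestimate.
* The end-to-end recovery at reduced synthetic scale carries a
  residual bias of roughly one reported σ (≈ 0.005 in `n`),
  dominated by residual ROI contamination and the finite fidelity of
  the matched AFM-crest emulation.
* Heights of narrow ridges from AFM are tip-convolved upper bounds;
  no deconvolution is applied.
* The precision sweep's U-shape beyond `H ≈ 250 nm` (dye near focus)
  means the defocus should be rechosen for thick samples; the
  `defocus` parameter is free for that purpose.
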