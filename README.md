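# rimap

**Refractive-index mapping below the diffraction limit, from defocused
single-molecule localization microscopy (SMLM) combined with AFM.**

The shape of a defocused single-molecule point spread function depends
on the refractive index `n` of the material between the dye and the
coverslip — but almost the same way it depends on the dye's height, so
`n` is unrecoverable from images alone.  Measuring the sample height
independently with an atomic force microscope (AFM) breaks the
degeneracy: fitting the localizations with a layered vectorial PSF
model while *assuming* different values of `n` yields an apparent
sample height `H_SMLM(n)` that rises linearly with the assumed index
(slope ≈ 2H nm per index unit); the assumed index at which it matches
the AFM height `H_AFM` is the refractive index of the sample,

    n̂ :  H_SMLM(n̂) = H_AFM ,     σ_n² from Monte Carlo over all
                                   height errors,

with the attainable precision bounded by

    Δn² = Δn_SMLM²(N, BG, θ, n, H) + Δn_AFM²(θ, n, H, Δz_AFM),
    Δn_SMLM = 1/√FI,   FI = Σ_px (∂I/∂n)²/I   (Poisson counts).

The package implements the full chain for single collagen fibrils:
the vectorial three-layer image model (supercritical-angle collection,
defocus, Zernike aberrations), the Cramér–Rao precision theory and
photon budget, Poisson maximum-likelihood localization, drift and
reference-plane calibration, fibril-centric cross-section geometry,
crest-height estimation, the `H_SMLM(n)`×`H_AFM` intersection, the
swelling/mixing analysis of dry vs hydrated fibrils, sliding-window
refractive-index maps along the fibril, and their variance
decomposition — plus a synthetic-data generator that emulates the
entire experiment with known ground truth.

Audience: microscopists and method developers working on SMLM-based
refractometry or multimodal SMLM+AFM analysis who want a tested,
self-contained reference implementation with simulation-based
validation.

## Worked example

```bash
python examples/crlb_budget.py
```

```
delta_n (SMLM photon limit)  = 0.0025
delta_n (AFM height, 1 nm)   = 0.0022
delta_n (total, quadrature)  = 0.0033

Photons for delta_n = 0.01 on a 50 nm sample (SBR 100, AFM 1 nm): 76,839
About 1e5 photons, i.e. >100 localizations at ~1000 photons each.
```

That is the error budget for a measured fibril (H = 138 nm, 123,648
photons, signal-to-background 110): the photon-limited bound on `n`,
the contribution of a 1 nm AFM height uncertainty, and their
quadrature total of ≈ 0.0033 — a refractive index to three decimal
places from one fibril.  The second block inverts the budget: a 50 nm
sample needs on the order of 10⁵ photons for Δn = 0.01.

A complete simulated analysis (about a minute):

```bash
python examples/fibril_analysis.py
```

prints the recovered index with its error, the `H_SMLM(n)` line it was
read off from, and the swelling record (`ΔA`, dry-state index from the
area-weighted mixing model).  Further examples: `psf_broadening.py`
(how the PSF widens with `n`), `localize_and_merge.py` (detection,
fitting, blink merging), `ri_map_variance.py` (index maps along a
fibril and the sample-vs-noise variance split).

## Library layout

| module            | contents |
|-------------------|----------|
| `rimap.optics`    | vectorial layered-medium PSF, `MoleculeImageModel` |
| `rimap.precision` | Fisher information, CRLB, AFM error, photon budget |
| `rimap.localize`  | detection, Poisson MLE fitting, blink merging |
| `rimap.fibril`    | drift/tilt/defocus calibration, axis, cross sections, heights, intersection, swelling, maps, errors |
| `rimap.afm`       | AFM map I/O, line flattening, ridge axis, matched crest/area profiles |
| `rimap.synth`     | ground-truth phantoms, blinking stack and AFM rendering |
| `rimap.pipeline`  | `analyze_fibril_stack`: images + map → `n ± σ_n` |
| `rimap.recovery`  | seeded end-to-end validation runs |
| `rimap.cli`       | `rimap simulate | localize | crlb | required-photons | fibril-ri | ri-map` |

A thin command-line interface mirrors the library (`rimap --help`);
configuration is a single validated YAML file and every run writes its
resolved configuration and a JSON run report next to the outputs.

See `docs/methods.md` for the models, estimator choices and known
limitations.

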