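"""Precision budget for refractive-index estimation.

Two independent error sources limit how well the sample refractive index
``n`` can be determined:

* the SMLM photon budget — quantified by the Cramér-Rao lower bound
  (CRLB) from the Poisson Fisher information of the expected image with
  respect to ``n`` at known layer thickness ``H``;
* the AFM height uncertainty — an error ``dz`` in ``H`` is absorbed by
  the fit as a shift in the best-matching refractive index, quantified by
  refitting noise-free model images computed at ``H +/- dz``.

The two variances add, since the measurements are unrelated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from rimap.optics import (
    EmitterState,
    LayeredSample,
    MoleculeImageModel,
    OpticalSystem,
)

__all__ = [
    "AFMUncertainty",
    "PrecisionBudget",
    "UnattainablePrecisionError",
    "fisher_information_n",
    "fisher_information_param",
    "delta_n_smlm",
    "delta_n_afm",
    "total_delta_n",
    "required_photons",
    "crlb_sweep",
]

#: refractive-index bracket used when refitting noise-free images
N_FIT_BOUNDS = (1.30, 1.60)


@dataclass(frozen=True)
class AFMUncertainty:
    """Standard error of the AFM height measurement, in nm."""

    delta_z: float

    def __post_init__(self) -> None:
        if self.delta_z < 0:
            raise ValueError("delta_z must be >= 0")


@dataclass(frozen=True)
class PrecisionBudget:
    """SMLM, AFM and combined refractive-index standard errors."""

    delta_n_smlm: float
    delta_n_afm: float
    delta_n_total: float


class UnattainablePrecisionError(ValueError):
    """Raised when a target precision lies below the AFM error floor."""

    def __init__(self, target: float, afm_floor: float):
        self.target = target
        self.afm_floor = afm_floor
        super().__init__(
            f"target delta_n {target:g} is unattainable: AFM height "
            f"uncertainty alone contributes delta_n_AFM = {afm_floor:g}"
        )


def _replace_sample(sample: LayeredSample, **kw) -> LayeredSample:
    return LayeredSample(
        n_layer=kw.get("n_layer", sample.n_layer),
        thickness=kw.get("thickness", sample.thickness),
    )


def fisher_information_param(system: OpticalSystem, sample: LayeredSample,
                             emitter: EmitterState, param: str = "n",
                             step: float | None = None) -> float:
    """Poisson Fisher information of the expected image w.r.t. one parameter.

    FI = sum over pixels of (dI/dp)^2 / I, with the derivative taken by
    central finite differences at fixed values of all other parameters.
    Supported parameters: ``"n"`` (layer index), ``"z"`` (axial position),
    ``"x"``/``"y"`` (lateral position).
    """
    if param == "n":
        if sample.thickness == 0:
            return 0.0  # no layer: the image does not depend on n
        h = 1e-4 if step is None else step
        lo = MoleculeImageModel(system, _replace_sample(
            sample, n_layer=sample.n_layer - h))
        hi = MoleculeImageModel(system, _replace_sample(
            sample, n_layer=sample.n_layer + h))
        mid = MoleculeImageModel(system, sample)
        i_lo = lo.image(emitter)
        i_hi = hi.image(emitter)
        i_mid = mid.image(emitter)
    elif param in ("z", "x", "y"):
        h = 1.0 if step is None else step
        model = MoleculeImageModel(system, sample)
        x, y = emitter.lateral_offset
        z = emitter.axial_position
        deltas = {"x": ((x - h, y, z), (x + h, y, z)),
                  "y": ((x, y - h, z), (x, y + h, z)),
                  "z": ((x, y, z - h), (x, y, z + h))}[param]
        n_ph, bg = emitter.signal_photons, emitter.background_per_pixel
        i_lo = n_ph * model.psf(*deltas[0]) + bg
        i_hi = n_ph * model.psf(*deltas[1]) + bg
        i_mid = model.image(emitter)
    else:
        raise ValueError(f"unsupported parameter {param!r}")
    deriv = (i_hi - i_lo) / (2.0 * h)
    if np.any((i_mid <= 0) & (deriv != 0)):
        raise FloatingPointError(
            "zero expected intensity with nonzero derivative; add background"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(deriv == 0, 0.0, deriv ** 2 / i_mid)
    return float(terms.sum())


def fisher_information_n(system: OpticalSystem, sample: LayeredSample,
                         emitter: EmitterState,
                         step: float = 1e-4) -> float:
    """Fisher information for the layer refractive index (0 when H = 0)."""
    return fisher_information_param(system, sample, emitter, "n", step)


def delta_n_smlm(system: OpticalSystem, sample: LayeredSample,
                 emitter: EmitterState, step: float = 1e-4) -> float:
    """CRLB for n from the SMLM photon budget: 1/sqrt(FI).

    Returns ``inf`` when the information vanishes (H = 0), a distinguished
    value rather than an exception so parameter sweeps complete.
    """
    fi = fisher_information_n(system, sample, emitter, step)
    if fi == 0:
        return math.inf
    return 1.0 / math.sqrt(fi)


def delta_n_afm(system: OpticalSystem, sample: LayeredSample,
                afm: AFMUncertainty, xatol: float = 1e-6) -> float:
    """Refractive-index error induced by the AFM height uncertainty.

    Noise-free images are computed at thicknesses ``H +/- dz`` (true n);
    the refractive indices whose images at thickness ``H`` match best in
    least squares absorb the height error.  The symmetric error is the
    mean of the two one-sided deviations, which differ only negligibly.
    """
    dz = afm.delta_z
    if dz == 0:
        return 0.0
    h = sample.thickness
    n_true = sample.n_layer
    emitter_at = lambda z: EmitterState(axial_position=z, signal_photons=1.0)

    def mismatch_factory(h_pert: float):
        target = MoleculeImageModel(
            system, _replace_sample(sample, thickness=h_pert)
        ).image(emitter_at(h_pert))

        def mismatch(n_fit: float) -> float:
            img = MoleculeImageModel(
                system, _replace_sample(sample, n_layer=n_fit)
            ).image(emitter_at(h))
            return float(((target - img) ** 2).sum())

        return mismatch

    shifts = []
    for h_pert in (max(h - dz, 0.0), h + dz):
        res = minimize_scalar(mismatch_factory(h_pert), bounds=N_FIT_BOUNDS,
                              method="bounded",
                              options={"xatol": xatol})
        if not res.success:
            raise RuntimeError(
                f"refit of n did not converge for H = {h_pert} nm: {res}")
        shifts.append(abs(n_true - res.x))
    return 0.5 * (shifts[0] + shifts[1])


def total_delta_n(smlm: float, afm: float) -> PrecisionBudget:
    """Combine independent SMLM and AFM errors in quadrature."""
    if smlm < 0 or afm < 0:
        raise ValueError("error contributions must be >= 0")
    return PrecisionBudget(
        delta_n_smlm=smlm,
        delta_n_afm=afm,
        delta_n_total=math.hypot(smlm, afm),
    )


def required_photons(target_delta_n: float, system: OpticalSystem,
                     sample: LayeredSample, sbr: float,
                     afm: AFMUncertainty,
                     reference_photons: float = 1e5) -> int:
    """Smallest photon count N reaching a target total precision.

    Uses the exact 1/sqrt(N) scaling of the CRLB at fixed SBR (background
    scales with signal), anchored at one reference evaluation.
    """
    if target_delta_n <= 0:
        raise ValueError("target_delta_n must be positive")
    afm_floor = delta_n_afm(system, sample, afm)
    if target_delta_n <= afm_floor:
        raise UnattainablePrecisionError(target_delta_n, afm_floor)
    emitter = EmitterState(
        axial_position=sample.thickness,
        signal_photons=reference_photons,
        background_per_pixel=reference_photons / sbr,
    )
    ref = delta_n_smlm(system, sample, emitter)
    if not math.isfinite(ref):
        raise UnattainablePrecisionError(target_delta_n, math.inf)
    needed_smlm = math.sqrt(target_delta_n ** 2 - afm_floor ** 2)
    n_req = reference_photons * (ref / needed_smlm) ** 2
    return int(math.ceil(n_req))


def crlb_sweep(system: OpticalSystem, heights_nm, sbr_values,
               photons: float = 1e5, n_layer: float = 1.43,
               afm: AFMUncertainty | None = None):
    """Precision budget over a (H, SBR) grid at fixed photon count.

    Returns a pandas DataFrame with columns
    ``H_nm, sbr, N, delta_n_smlm, delta_n_afm, delta_n_total``.
    """
    import pandas as pd

    afm = afm or AFMUncertainty(0.0)
    rows = []
    for h in heights_nm:
        sample = LayeredSample(n_layer=n_layer, thickness=float(h))
        afm_err = delta_n_afm(system, sample, afm) if afm.delta_z > 0 else 0.0
        for sbr in sbr_values:
            emitter = EmitterState(axial_position=float(h),
                                   signal_photons=photons,
                                   background_per_pixel=photons / sbr)
            smlm = delta_n_smlm(system, sample, emitter)
            budget = total_delta_n(smlm, afm_err) if math.isfinite(smlm) \
                else PrecisionBudget(smlm, afm_err, math.inf)
            rows.append({"H_nm": float(h), "sbr": float(sbr),
                         "N": float(photons),
                         "delta_n_smlm": budget.delta_n_smlm,
                         "delta_n_afm": budget.delta_n_afm,
                         "delta_n_total": budget.delta_n_total})
    return pd.DataFrame(rows)
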