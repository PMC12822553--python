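"""Vectorial image formation for single emitters above a layered sample.

The forward model computes the expected camera image of a freely rotating
dipole emitter located in the imaging buffer, above a thin sample layer
(refractive index ``n_layer``, thickness ``H``) that rests on a glass
coverslip.  Collection is through the glass with a high-NA oil objective,
so supercritical-angle fluorescence (SAF) is included.  A freely rotating
dipole is modeled as the incoherent sum of three orthogonal fixed dipoles.

The computation follows the standard angular-spectrum recipe: the dipole
far field is decomposed into s- and p-polarized plane waves, each component
is transmitted through the ambient / layer / glass stack with Fresnel
coefficients (transfer-matrix form, evanescent components included),
defocus and Zernike aberrations are applied as pupil phases, and the image
is obtained by a vectorial Fourier transform of the back-focal-plane field,
integrated over camera pixels by oversampling and binning.

Axial conventions: ``z = 0`` at the glass/sample interface, positive into
the sample.  The emitter sits in the ambient medium at height ``z``; for a
layer-top dye ``z = H``.  Positive defocus displaces the nominal focal
plane away from the coverslip into the sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import factorial
from typing import Mapping

import numpy as np

__all__ = [
    "OpticalSystem",
    "LayeredSample",
    "EmitterState",
    "MoleculeImage",
    "MoleculeImageModel",
    "compute_molecule_image",
    "radial_second_moment",
    "zernike_noll",
]


@dataclass(frozen=True)
class OpticalSystem:
    """Instrument parameters governing image formation.

    Lengths are in nanometers.  ``pixel_size_sample`` is the camera pixel
    pitch back-projected into the sample plane.  Zernike coefficients are
    given per Noll index, in radians of pupil phase at the pupil edge.
    """

    numerical_aperture: float = 1.46
    emission_wavelength: float = 670.0
    n_immersion: float = 1.52
    n_ambient: float = 1.33
    pixel_size_sample: float = 160.0
    defocus: float = 500.0
    zernike_terms: Mapping[int, float] = field(default_factory=dict)
    roi_size: int = 15
    oversampling: int = 3
    pupil_samples: int = 96

    def __post_init__(self) -> None:
        if self.numerical_aperture >= self.n_immersion:
            raise ValueError("numerical_aperture must be < n_immersion")
        if self.roi_size % 2 == 0 or self.roi_size < 1:
            raise ValueError("roi_size must be odd and positive")
        if self.oversampling < 1:
            raise ValueError("oversampling must be >= 1")
        for name in ("emission_wavelength", "pixel_size_sample", "n_ambient",
                     "n_immersion", "numerical_aperture"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.pupil_samples < 16:
            raise ValueError("pupil_samples too small for a resolved pupil")


@dataclass(frozen=True)
class LayeredSample:
    """The unknown pair (n, H): sample-layer refractive index and thickness."""

    n_layer: float
    thickness: float

    def __post_init__(self) -> None:
        if not (1.0 <= self.n_layer <= 2.0):
            raise ValueError("n_layer must lie in [1.0, 2.0]")
        if self.thickness < 0:
            raise ValueError("thickness must be >= 0")


@dataclass(frozen=True)
class EmitterState:
    """Emitter position, signal and background.

    ``lateral_offset`` is (dx, dy) in nm relative to the ROI center;
    ``axial_position`` is the height above the coverslip surface.
    """

    lateral_offset: tuple[float, float] = (0.0, 0.0)
    axial_position: float = 0.0
    signal_photons: float = 1000.0
    background_per_pixel: float = 0.0

    def __post_init__(self) -> None:
        if self.signal_photons < 0:
            raise ValueError("signal_photons must be >= 0")
        if self.background_per_pixel < 0:
            raise ValueError("background_per_pixel must be >= 0")

    @property
    def sbr(self) -> float:
        """Signal-to-background ratio N / BG (inf when BG = 0)."""
        if self.background_per_pixel == 0:
            return np.inf
        return self.signal_photons / self.background_per_pixel


@dataclass(frozen=True)
class MoleculeImage:
    """Expected (or observed) photons per pixel with its provenance."""

    pixel_grid: np.ndarray
    system: OpticalSystem | None = None
    sample: LayeredSample | None = None
    emitter: EmitterState | None = None


def _noll_to_nm(j: int) -> tuple[int, int]:
    """Map Noll index j >= 1 to (n, m) with the sign convention folded in."""
    if j < 1:
        raise ValueError("Noll indices start at 1")
    n = 0
    j1 = j - 1
    while j1 > n:
        n += 1
        j1 -= n
    m = (-1) ** j * ((n % 2) + 2 * ((j1 + ((n + 1) % 2)) // 2))
    return n, m


def zernike_noll(j: int, rho: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Zernike polynomial Z_j (Noll indexing, Noll normalization) on rho<=1."""
    n, m = _noll_to_nm(j)
    am = abs(m)
    radial = np.zeros_like(rho)
    for k in range((n - am) // 2 + 1):
        c = ((-1) ** k * factorial(n - k)
             / (factorial(k) * factorial((n + am) // 2 - k)
                * factorial((n - am) // 2 - k)))
        radial = radial + c * rho ** (n - 2 * k)
    if m == 0:
        return np.sqrt(n + 1.0) * radial
    norm = np.sqrt(2.0 * (n + 1.0))
    if m > 0:
        return norm * radial * np.cos(am * theta)
    return norm * radial * np.sin(am * theta)


def _kz(n_medium: float, k0: float, kt2: np.ndarray) -> np.ndarray:
    """Axial wavenumber in a medium; evanescent branch with Im >= 0."""
    arg = (n_medium * k0) ** 2 - kt2
    return np.sqrt(arg.astype(complex))


def _fresnel(n1, kz1, n2, kz2):
    """Interface amplitude coefficients (rs, ts, rp, tp), medium 1 -> 2."""
    rs = (kz1 - kz2) / (kz1 + kz2)
    ts = 2.0 * kz1 / (kz1 + kz2)
    # p-polarization in terms of kz and refractive indices
    a = n2 ** 2 * kz1
    b = n1 ** 2 * kz2
    rp = (a - b) / (a + b)
    tp = 2.0 * n1 * n2 * kz1 / (a + b)
    return rs, ts, rp, tp


class MoleculeImageModel:
    """Cached pupil-field model for one (system, sample) pair.

    Building the model evaluates everything that does not depend on the
    emitter position: Fresnel stack transmission, dipole projections,
    apodization and the static aberration phase.  Individual images are
    then produced by a per-emitter pupil phase and a small partial DFT,
    which makes maximum-likelihood fitting and Fisher-information sweeps
    cheap.
    """

    def __init__(self, system: OpticalSystem, sample: LayeredSample,
                 precision: str = "double"):
        if precision not in ("double", "single"):
            raise ValueError("precision must be 'double' or 'single'")
        self.system = system
        self.sample = sample
        self._cdtype = np.complex128 if precision == "double" else np.complex64
        self._build_pupil()
        self._build_image_grid()

    # -- pupil construction -------------------------------------------------
    def _build_pupil(self) -> None:
        sysm, sample = self.system, self.sample
        k0 = 2.0 * np.pi / sysm.emission_wavelength
        kmax = k0 * sysm.numerical_aperture
        n = sysm.pupil_samples
        # offset grid so no node lands exactly on the critical angle
        k = (np.arange(n) - (n - 1) / 2.0) * (2.0 * kmax / n)
        kx = k[:, None]
        ky = k[None, :]
        kt2 = kx ** 2 + ky ** 2
        mask = kt2 <= kmax ** 2
        kt = np.sqrt(kt2)
        phi = np.arctan2(np.broadcast_to(ky, kt.shape),
                         np.broadcast_to(kx, kt.shape))

        k_g = k0 * sysm.n_immersion
        k_a = k0 * sysm.n_ambient
        kgz = _kz(sysm.n_immersion, k0, kt2)
        klz = _kz(sample.n_layer, k0, kt2)
        kaz = _kz(sysm.n_ambient, k0, kt2)

        # stack transmission ambient -> layer -> glass (transfer matrix for
        # a single film; collapses to the bare interface when H = 0)
        rs_al, ts_al, rp_al, tp_al = _fresnel(sysm.n_ambient, kaz,
                                              sample.n_layer, klz)
        rs_lg, ts_lg, rp_lg, tp_lg = _fresnel(sample.n_layer, klz,
                                              sysm.n_immersion, kgz)
        beta = klz * sample.thickness
        eb = np.exp(1j * beta)
        ts = ts_al * ts_lg * eb / (1.0 + rs_al * rs_lg * eb ** 2)
        tp = tp_al * tp_lg * eb / (1.0 + rp_al * rp_lg * eb ** 2)

        cos_g = kgz / k_g
        # stationary-phase far-field factor kgz/kaz and aplanatic 1/sqrt(cos)
        pref = np.where(mask, kgz / kaz / np.sqrt(cos_g), 0.0)

        # dipole projections in the ambient medium (downward-going wave)
        cphi, sphi = np.cos(phi), np.sin(phi)
        s_x, s_y = -sphi, cphi                     # s-hat . mu for x,y dipoles
        p_x = kaz / k_a * cphi                     # p-hat . mu
        p_y = kaz / k_a * sphi
        p_z = kt / k_a

        # static pupil phase: defocus + aberrations
        phase = -kgz * sysm.defocus
        if sysm.zernike_terms:
            rho = np.where(mask, kt / kmax, 0.0)
            ab = np.zeros_like(rho)
            for j, coeff in sysm.zernike_terms.items():
                if coeff != 0.0:
                    ab = ab + coeff * zernike_noll(int(j), rho, phi)
            static = np.exp(1j * phase) * np.exp(1j * ab)
        else:
            static = np.exp(1j * phase)
        base = pref * static

        # six pupil field components: (dipole in {x,y,z}) x (Ex, Ey)
        # E = As * s_hat + Ap * phi_hat after the objective
        fields = []
        for s_d, p_d in ((s_x, p_x), (s_y, p_y), (np.zeros_like(kt), p_z)):
            As = base * ts * s_d
            Ap = base * tp * p_d
            ex = As * (-sphi) + Ap * cphi
            ey = As * cphi + Ap * sphi
            fields.append(ex)
            fields.append(ey)
        self._fields = np.stack(fields).astype(self._cdtype)  # (6, n, n)
        self._kvec = k                           # 1-D pupil frequency axis
        self._kx = np.where(mask, np.broadcast_to(kx, kt.shape), 0.0)
        self._ky = np.where(mask, np.broadcast_to(ky, kt.shape), 0.0)
        self._kaz = np.where(mask, kaz, 0.0)
        self._kgz = np.where(mask, kgz, 0.0)
        self._mask = mask
        self._dk = 2.0 * kmax / n
        self._w_axial = 1j * np.real(kaz) * mask - np.imag(kaz) * mask
        # value + gradient-weighted pupils, stacked once for the analytic
        # derivative transforms (order: value, d/dx, d/dy, d/dz)
        self._fields_all = np.concatenate([
            self._fields,
            -1j * self._kx[None] * self._fields,
            -1j * self._ky[None] * self._fields,
            1j * (kaz * mask).astype(self._cdtype)[None] * self._fields,
        ]).astype(self._cdtype)
        # |E|^2 summed over components, for the z-dependent normalization
        self._power_sum = (np.abs(self._fields.astype(np.complex128)) ** 2
                           ).sum(axis=0)
        self._im_kaz = np.imag(kaz) * mask

    def _build_image_grid(self) -> None:
        sysm = self.system
        m = sysm.roi_size * sysm.oversampling
        self._dsub = sysm.pixel_size_sample / sysm.oversampling
        half = (m - 1) / 2.0
        self._xg = (np.arange(m) - half) * self._dsub
        # partial DFT matrices pupil -> image; the lateral shift is folded
        # into the pupil phase instead, so these stay fixed
        self._Fx = np.exp(1j * np.outer(self._xg, self._kvec)
                          ).astype(self._cdtype)
        self._Fy = np.exp(1j * np.outer(self._kvec, self._xg)
                          ).astype(self._cdtype)

    # -- evaluation ---------------------------------------------------------
    def _phases(self, x, y, z, defocus_shift=0.0) -> np.ndarray:
        """Per-emitter pupil phase factors; batched over the leading axis.

        The lateral phase is separable in kx and ky, so it is built from
        two 1-D complex exponentials; only the axial factor needs a full
        2-D exponential.  Note the sign: multiplying the pupil by
        exp(-i k.x0) shifts the image-plane pattern to +x0.
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        d = np.atleast_1d(np.asarray(z, dtype=float)) - self.sample.thickness
        ct = self._cdtype
        ex = np.exp(np.outer(x, -1j * self._kvec).astype(ct))   # (b, n)
        ey = np.exp(np.outer(y, -1j * self._kvec).astype(ct))
        axial = np.exp(np.multiply.outer(d, self._w_axial).astype(ct))
        if defocus_shift != 0.0:
            axial = axial * np.exp(
                -1j * self._kgz.real[None] * defocus_shift).astype(ct)
        axial *= ex[:, :, None]
        axial *= ey[:, None, :]
        return axial

    def _bin(self, sub: np.ndarray) -> np.ndarray:
        o = self.system.oversampling
        r = self.system.roi_size
        return sub.reshape(sub.shape[:-2] + (r, o, r, o)).sum(axis=(-3, -1))

    def _total_power(self, z) -> np.ndarray:
        """Collected energy integrated over the infinite image plane."""
        d = np.atleast_1d(np.asarray(z, dtype=float))[:, None, None] \
            - self.sample.thickness
        decay = np.exp(-2.0 * self._im_kaz[None] * d)
        return ((self._power_sum[None] * decay).sum(axis=(-2, -1))
                * (2.0 * np.pi / self._dk) ** 2)

    def psf_batch(self, x, y, z, defocus_shift: float = 0.0,
                  chunk: int = 32) -> np.ndarray:
        """Pixel-integrated PSFs for arrays of emitter positions: (B, r, r)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        z = np.atleast_1d(np.asarray(z, dtype=float))
        out = np.empty((len(x), self.system.roi_size, self.system.roi_size))
        for s in range(0, len(x), chunk):
            sl = slice(s, min(s + chunk, len(x)))
            phases = self._phases(x[sl], y[sl], z[sl], defocus_shift)
            arr = self._fields[None] * phases[:, None]     # (b, 6, n, n)
            e_img = self._Fx @ arr @ self._Fy              # (b, 6, m, m)
            sub = (np.abs(e_img) ** 2).sum(axis=1)
            out[sl] = self._bin(sub) * self._dsub ** 2 \
                / self._total_power(z[sl])[:, None, None]
        return out

    def psf(self, x: float = 0.0, y: float = 0.0, z: float | None = None,
            defocus_shift: float = 0.0) -> np.ndarray:
        """Normalized pixel-integrated PSF (fraction of photons per pixel)."""
        if z is None:
            z = self.sample.thickness
        return self.psf_batch([x], [y], [z], defocus_shift)[0]

    def psf_with_gradients(self, x: float, y: float, z: float,
                           defocus_shift: float = 0.0):
        """PSF and its analytic derivatives w.r.t. x, y and z.

        The spatial derivatives are exact pupil-space derivatives: a shift
        multiplies the pupil by exp(i(kx x + ky y + kaz(z - H))), so each
        derivative is one extra transform with the field weighted by the
        corresponding (complex, for z) wavenumber.  Returns
        (psf, dpsf/dx, dpsf/dy, dpsf/dz), each (r, r), in 1/nm units.
        """
        phase = self._phases([x], [y], [z], defocus_shift)[0]
        trans = self._Fx @ (self._fields_all * phase[None]) @ self._Fy
        e, ex, ey, ez = trans[:6], trans[6:12], trans[12:18], trans[18:]
        sub = (np.abs(e) ** 2).sum(axis=0)
        ec = e.conj()
        dx = 2.0 * np.real(ec * ex).sum(axis=0)
        dy = 2.0 * np.real(ec * ey).sum(axis=0)
        dz = 2.0 * np.real(ec * ez).sum(axis=0)
        total = float(self._total_power([z])[0])
        scale = self._dsub ** 2 / total
        p = self._bin(sub) * scale
        gx = self._bin(dx) * scale
        gy = self._bin(dy) * scale
        gz = self._bin(dz) * scale
        # the normalization itself depends on z through the SAF decay
        dtot = float(
            (self._power_sum * -2.0 * self._im_kaz
             * np.exp(-2.0 * self._im_kaz * (z - self.sample.thickness))
             ).sum() * (2.0 * np.pi / self._dk) ** 2)
        gz = gz - p * (dtot / total)
        return p, gx, gy, gz

    def image(self, emitter: EmitterState,
              defocus_shift: float = 0.0) -> np.ndarray:
        """Expected photons per pixel: N * psf + BG."""
        r = self.system.roi_size
        if emitter.signal_photons == 0:
            return np.full((r, r), float(emitter.background_per_pixel))
        x, y = emitter.lateral_offset
        p = self.psf(x, y, emitter.axial_position, defocus_shift)
        return emitter.signal_photons * p + emitter.background_per_pixel


def compute_molecule_image(system: OpticalSystem, sample: LayeredSample,
                           emitter: EmitterState) -> MoleculeImage:
    """Expected single-molecule image for one emitter above the layer stack."""
    model = MoleculeImageModel(system, sample)
    grid = model.image(emitter)
    return MoleculeImage(pixel_grid=grid, system=system, sample=sample,
                        emitter=emitter)


def radial_second_moment(image: np.ndarray,
                         pixel_size: float = 1.0,
                         background: float = 0.0) -> float:
    """Background-subtracted radial second moment about the centroid.

    A broadening measure of the PSF: larger values mean photons spread
    farther from the center of mass.
    """
    img = np.clip(np.asarray(image, dtype=float) - background, 0.0, None)
    total = img.sum()
    if total <= 0:
        raise ValueError("image has no signal above background")
    n = img.shape[0]
    coords = (np.arange(n) - (n - 1) / 2.0) * pixel_size
    xx, yy = np.meshgrid(coords, coords, indexing="ij")
    cx = (img * xx).sum() / total
    cy = (img * yy).sum() / total
    return float((img * ((xx - cx) ** 2 + (yy - cy) ** 2)).sum() / total)
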