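"""Ground-truth synthetic fibril datasets.

Generates everything the analysis pipeline consumes, with known truth:
surface-labeled half-cylindrical fibril phantoms, blinking dSTORM image
stacks rendered through the same vectorial image model used for fitting,
fiducial markers, lateral drift, and AFM height maps with scan-line
artifacts.  Defaults emulate the experimental regime of the method:
~10^3 photons per localization, SBR around 100, fibril radii of tens of
nm, 500 nm defocus.

Because rendering and fitting share one forward model (each fibril dye is
imaged through a locally planar collagen layer of thickness equal to its
own height), recovery tests isolate pipeline correctness from model
misspecification; this idealization is deliberate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from rimap.fibril import FibrilAxis, transform_to_cross_section
from rimap.optics import (
    EmitterState,
    LayeredSample,
    MoleculeImageModel,
    OpticalSystem,
)
from rimap.afm import AFMMap

__all__ = [
    "PhantomConfig",
    "FibrilPhantom",
    "AcquisitionModel",
    "straight_axis",
    "arc_axis",
    "generate_phantom",
    "render_smlm_stack",
    "render_afm_map",
    "spawn_rngs",
]


def spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Independent child generators derived from one master seed."""
    return [np.random.default_rng(s)
            for s in np.random.SeedSequence(seed).spawn(n)]


def straight_axis(length: float, origin=(1000.0, 1000.0), angle: float = 0.0,
                  step: float = 10.0) -> FibrilAxis:
    """A straight fibril axis of the given length (nm) in the z = 0 plane."""
    s = np.arange(0.0, length + step, step)
    direction = np.array([np.cos(angle), np.sin(angle)])
    pts = np.asarray(origin, dtype=float) + np.outer(s, direction)
    tang = np.tile(direction, (len(s), 1))
    return FibrilAxis(s=s, points=pts, tangents=tang, step=step)


def arc_axis(radius: float, arc_angle: float, center=(0.0, 0.0),
             step: float = 10.0) -> FibrilAxis:
    """A circular-arc axis of the given radius (nm) spanning arc_angle rad."""
    s = np.arange(0.0, radius * arc_angle + step, step)
    theta = s / radius
    pts = np.stack([center[0] + radius * np.cos(theta),
                    center[1] + radius * np.sin(theta)], axis=1)
    tang = np.stack([-np.sin(theta), np.cos(theta)], axis=1)
    return FibrilAxis(s=s, points=pts, tangents=tang, step=step)


@dataclass
class PhantomConfig:
    """Geometry, optics-relevant truth and labeling of a fibril phantom.

    Radii are in nm; ``n_true`` may be a constant or a callable of the
    arclength s.  Label densities are per square micrometer.
    """

    axis_length: float = 3500.0
    radius_wet: float = 69.0
    radius_dry: float = 40.0
    n_true: float | Callable[[np.ndarray], np.ndarray] = 1.43
    surface_label_density: float = 600.0     # um^-2 on the half-cylinder
    glass_label_density: float = 60.0        # um^-2 on surrounding glass
    glass_margin: float = 1500.0             # nm band around the fibril
    label_offset: float = 0.0                # nm, along the surface normal
    axis_origin: tuple[float, float] = (1200.0, 4800.0)
    axis_angle: float = 0.0

    def __post_init__(self) -> None:
        if self.radius_wet <= 0 and self.surface_label_density > 0:
            if self.radius_wet < 0:
                raise ValueError("radius must be >= 0")


@dataclass
class FibrilPhantom:
    """A generated phantom: geometry plus labeled emitter list.

    ``emitters`` columns: x_nm, y_nm, z_nm, s, n_local, on_glass.
    """

    config: PhantomConfig
    axis: FibrilAxis
    emitters: pd.DataFrame

    def n_profile(self, s) -> np.ndarray:
        n_true = self.config.n_true
        s = np.asarray(s, dtype=float)
        if callable(n_true):
            return np.asarray(n_true(s), dtype=float)
        return np.full(s.shape, float(n_true))

    def surface_height(self, x_nm, y_nm, hydration: str = "wet") -> np.ndarray:
        """True surface height above glass at lab positions."""
        r = self.config.radius_wet if hydration == "wet" \
            else self.config.radius_dry
        df = pd.DataFrame({"x_nm": np.atleast_1d(x_nm),
                           "y_nm": np.atleast_1d(y_nm),
                           "z_nm": 0.0})
        cs = transform_to_cross_section(df, self.axis)
        x_off = cs["X"].to_numpy()
        h = np.where(np.abs(x_off) < r, np.sqrt(
            np.clip(r ** 2 - x_off ** 2, 0.0, None)), 0.0)
        h[cs["boundary"].to_numpy()] = 0.0
        return h


def generate_phantom(config: PhantomConfig,
                     rng: np.random.Generator) -> FibrilPhantom:
    """Place labels on the fibril surface and the surrounding glass.

    Emitters follow a Poisson point process: uniform in (s, surface arc)
    on the upper half-cylinder, uniform on the glass band around the
    fibril (the footprint under the fibril is excluded).  Each emitter
    carries its true height and the local true refractive index.
    """
    axis = straight_axis(config.axis_length, origin=config.axis_origin,
                         angle=config.axis_angle)
    r = config.radius_wet
    length = config.axis_length
    rows = []
    # fibril surface labels
    area_um2 = np.pi * r * length / 1e6
    n_fib = rng.poisson(config.surface_label_density * area_um2)
    if n_fib > 0:
        s_pos = rng.uniform(0.0, length, n_fib)
        phi = rng.uniform(0.0, np.pi, n_fib)
        r_eff = r + config.label_offset
        x_off = r_eff * np.cos(phi)
        z = r_eff * np.sin(phi)
        base = axis.point(s_pos)
        nrm = axis.normal(s_pos)
        xy = base + x_off[:, None] * nrm
        n_local = (np.full(n_fib, float(config.n_true))
                   if not callable(config.n_true)
                   else np.asarray(config.n_true(s_pos), dtype=float))
        for i in range(n_fib):
            rows.append((xy[i, 0], xy[i, 1], z[i], s_pos[i],
                         n_local[i], False))
    # glass-bound labels in a band around the fibril, excluding its footprint
    band = config.glass_margin
    area_glass_um2 = 2.0 * band * length / 1e6
    n_gl = rng.poisson(config.glass_label_density * area_glass_um2)
    placed = 0
    while placed < n_gl:
        s_pos = rng.uniform(0.0, length)
        x_off = rng.uniform(-band, band)
        if abs(x_off) <= r:
            continue
        base = axis.point(s_pos)
        nrm = axis.normal(s_pos)
        xy = base + x_off * nrm
        rows.append((xy[0], xy[1], 0.0, s_pos, np.nan, True))
        placed += 1
    emitters = pd.DataFrame(rows, columns=["x_nm", "y_nm", "z_nm", "s",
                                           "n_local", "on_glass"])
    return FibrilPhantom(config=config, axis=axis, emitters=emitters)


@dataclass
class AcquisitionModel:
    """Blinking, photon, drift and fiducial parameters of an acquisition.

    Blinking is a two-state Markov chain per emitter: geometric on-times
    with mean ``mean_on_frames`` and activation probability ``p_on`` per
    dark frame.  Photons per frame are log-normal with the configured
    mean.  ``drift`` is either an (frames, 2) trajectory in nm or a
    per-frame linear rate tuple (nm/frame).
    """

    frames: int = 9000
    mean_photons: float = 3000.0
    photon_cv: float = 0.3              # coefficient of variation
    p_on: float = 0.0001                # off -> on per frame
    mean_on_frames: float = 1.5
    background: float = 27.0            # counts per pixel per frame (SBR ~110)
    drift: tuple[float, float] | np.ndarray = (0.02, -0.015)
    fiducial_positions: tuple = ((1280.0, 1280.0), (4480.0, 1280.0))
    fiducial_photons: float = 20000.0
    field_px: tuple[int, int] = (40, 48)

    def __post_init__(self) -> None:
        if self.frames < 1:
            raise ValueError("frames must be >= 1")
        if self.p_on < 0 or self.mean_on_frames < 1:
            raise ValueError("blinking rates are out of range")

    def drift_trajectory(self) -> np.ndarray:
        d = np.asarray(self.drift, dtype=float)
        if d.ndim == 1:
            f = np.arange(self.frames)[:, None]
            return f * d[None, :]
        if d.shape != (self.frames, 2):
            raise ValueError("drift trajectory must be (frames, 2)")
        return d


def _lognormal_photons(rng, mean, cv, size):
    sigma2 = np.log(1.0 + cv ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size)


def _blink_states(rng, n_emitters: int, frames: int, p_on: float,
                  mean_on: float) -> np.ndarray:
    """(frames, n) boolean activity matrix of the two-state Markov model."""
    p_off = 1.0 / mean_on
    states = np.zeros((frames, n_emitters), dtype=bool)
    current = rng.random(n_emitters) < p_on  # start from the off state
    for f in range(frames):
        states[f] = current
        u = rng.random(n_emitters)
        current = np.where(current, u >= p_off, u < p_on)
    return states


def _stamp(canvas: np.ndarray, stamp: np.ndarray, row: int, col: int) -> None:
    half = stamp.shape[0] // 2
    r0, r1 = row - half, row + half + 1
    c0, c1 = col - half, col + half + 1
    sr0 = max(0, -r0)
    sc0 = max(0, -c0)
    r0, c0 = max(r0, 0), max(c0, 0)
    r1c = min(r1, canvas.shape[0])
    c1c = min(c1, canvas.shape[1])
    if r1c <= r0 or c1c <= c0:
        return
    canvas[r0:r1c, c0:c1c] += stamp[sr0:sr0 + (r1c - r0),
                                    sc0:sc0 + (c1c - c0)]


def render_smlm_stack(phantom: FibrilPhantom, acquisition: AcquisitionModel,
                      system: OpticalSystem, rng: np.random.Generator,
                      overlap_warn_fraction: float = 0.05):
    """Render a blinking image stack with Poisson noise and ground truth.

    Returns ``(stack, truth, fiducial_truth)``: the (frames, ny, nx)
    float array of counts, a ground-truth table with one row per emitter
    appearance (frame, emitter, true undrifted position, drifted
    position, photons, n_local), and the per-frame fiducial positions.
    A warning is emitted when the fraction of appearances with another
    active emitter within one ROI exceeds ``overlap_warn_fraction``.
    """
    import warnings

    px = system.pixel_size_sample
    ny, nx = acquisition.field_px
    frames = acquisition.frames
    emitters = phantom.emitters
    n_em = len(emitters)
    drift = acquisition.drift_trajectory()
    states = _blink_states(rng, n_em, frames, acquisition.p_on,
                           acquisition.mean_on_frames)

    glass_model = MoleculeImageModel(
        system, LayeredSample(n_layer=phantom.emitters["n_local"].dropna().mean()
                              if phantom.emitters["n_local"].notna().any()
                              else 1.45, thickness=0.0))
    # per-emitter models are built lazily and kept in a small LRU cache;
    # consecutive frames of one burst reuse the cached pupil
    from collections import OrderedDict
    cache: OrderedDict[int, MoleculeImageModel] = OrderedDict()

    def model_for(i: int) -> MoleculeImageModel:
        if emitters["on_glass"].iat[i] or emitters["z_nm"].iat[i] <= 0:
            return glass_model
        if i in cache:
            cache.move_to_end(i)
            return cache[i]
        m = MoleculeImageModel(system, LayeredSample(
            n_layer=float(emitters["n_local"].iat[i]),
            thickness=float(emitters["z_nm"].iat[i])))
        cache[i] = m
        if len(cache) > 16:
            cache.popitem(last=False)
        return m

    stack = np.empty((frames, ny, nx), dtype=np.float32)
    truth_rows = []
    fid_rows = []
    fid_cache: dict[tuple[int, int], np.ndarray] = {}
    overlaps = 0
    appearances = 0
    xs = emitters["x_nm"].to_numpy()
    ys = emitters["y_nm"].to_numpy()
    zs = emitters["z_nm"].to_numpy()
    for f in range(frames):
        canvas = np.full((ny, nx), acquisition.background, dtype=float)
        active = np.nonzero(states[f])[0]
        # crude overlap audit in pixel space
        if len(active) > 1:
            pos = np.column_stack([xs[active], ys[active]]) + drift[f]
            d2 = ((pos[:, None, :] - pos[None, :, :]) ** 2).sum(axis=2)
            np.fill_diagonal(d2, np.inf)
            lim = (system.roi_size // 2) * px
            overlaps += int((d2.min(axis=1) < lim ** 2).sum())
        appearances += len(active)
        photons = _lognormal_photons(rng, acquisition.mean_photons,
                                     acquisition.photon_cv, len(active))
        for k, i in enumerate(active):
            x = xs[i] + drift[f, 0]
            y = ys[i] + drift[f, 1]
            row, col = int(round(x / px)), int(round(y / px))
            model = model_for(int(i))
            psf = model.psf(x - row * px, y - col * px, zs[i])
            _stamp(canvas, photons[k] * psf, row, col)
            truth_rows.append((f, int(i), xs[i], ys[i], zs[i], x, y,
                               photons[k],
                               float(emitters["n_local"].iat[i])))
        for fx, fy in acquisition.fiducial_positions:
            x = fx + drift[f, 0]
            y = fy + drift[f, 1]
            row, col = int(round(x / px)), int(round(y / px))
            # fiducials drift slowly; quantize the subpixel offset to 2 nm
            # and reuse stamps instead of recomputing one per frame
            key = (round((x - row * px) / 2.0), round((y - col * px) / 2.0))
            psf = fid_cache.get(key)
            if psf is None:
                psf = glass_model.psf(key[0] * 2.0, key[1] * 2.0, 0.0)
                fid_cache[key] = psf
            _stamp(canvas, acquisition.fiducial_photons * psf, row, col)
            fid_rows.append((f, fx, fy, x, y))
        stack[f] = rng.poisson(canvas)
    if appearances and overlaps / appearances > overlap_warn_fraction:
        warnings.warn(
            f"{overlaps / appearances:.1%} of emitter appearances overlap "
            "within one ROI; consider lowering the label density",
            stacklevel=2)
    truth = pd.DataFrame(truth_rows, columns=[
        "frame", "emitter", "x_true", "y_true", "z_true",
        "x_drifted", "y_drifted", "photons", "n_local"])
    fiducials = pd.DataFrame(fid_rows, columns=[
        "frame", "x_true", "y_true", "x_drifted", "y_drifted"])
    return stack, truth, fiducials


def synthetic_cross_section_table(n_grid, rng: np.random.Generator,
                                  axis_length: float = 8000.0,
                                  radius: float = 69.0,
                                  n_profile=1.43,
                                  slope_nm_per_riu: float = 160.0,
                                  density_per_nm: float = 0.25,
                                  z_noise: float = 6.0,
                                  x_noise: float = 10.0) -> pd.DataFrame:
    """Analysis-ready cross-section table with known truth (no imaging).

    Emulates the *output* of the localization stage for a surface-labeled
    half-cylinder: each localization carries fibril coordinates (s, X)
    and one fitted height column ``z@<n>`` per assumed refractive index,
    built from the linear height-versus-assumed-index mechanism with
    slope ``slope_nm_per_riu`` at the crest (scaled by the dye height
    for flank dyes).  ``n_profile`` is the true index, constant or a
    callable of s.  Used to exercise the mapping and variance
    decomposition at scale without rendering camera frames.
    """
    n_locs = rng.poisson(density_per_nm * axis_length)
    s = np.sort(rng.uniform(0.0, axis_length, n_locs))
    phi = rng.uniform(0.0, np.pi, n_locs)
    x_off = radius * np.cos(phi) + rng.normal(0.0, x_noise, n_locs)
    z_surf = radius * np.sin(phi)
    if callable(n_profile):
        n_local = np.asarray(n_profile(s), dtype=float)
    else:
        n_local = np.full(n_locs, float(n_profile))
    out = pd.DataFrame({"s": s, "x_nm": s, "y_nm": x_off, "X": x_off})
    local_slope = slope_nm_per_riu * z_surf / radius
    for n_val in n_grid:
        z = z_surf + local_slope * (n_val - n_local) \
            + rng.normal(0.0, z_noise, n_locs)
        out[f"z@{n_val:.3f}"] = z
    return out


def render_afm_map(phantom: FibrilPhantom, pixel_size: float = 39.0,
                   noise_sigma: float = 0.3,
                   line_tilt_slope: float | np.ndarray = 0.0,
                   line_offset_sigma: float = 0.0,
                   hydration: str = "wet",
                   field_nm: tuple[float, float] | None = None,
                   rng: np.random.Generator | None = None) -> AFMMap:
    """Sample the phantom's upper surface onto an AFM grid.

    Adds Gaussian height noise and per-scan-line tilt/offset artifacts.
    The returned map carries the true glass mask (pixels off the fibril
    footprint) for tilt correction and debris estimation.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    rng = np.random.default_rng() if rng is None else rng
    # maps start at the lab origin so SMLM/AFM registration is exact
    lo = np.zeros(2)
    if field_nm is None:
        margin = phantom.config.glass_margin
        hi = phantom.axis.points.max(axis=0) + margin
    else:
        hi = np.asarray(field_nm, dtype=float)
    n_rows = int(np.ceil((hi[0] - lo[0]) / pixel_size))
    n_cols = int(np.ceil((hi[1] - lo[1]) / pixel_size))
    xs = lo[0] + np.arange(n_rows) * pixel_size
    ys = lo[1] + np.arange(n_cols) * pixel_size
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    surface = phantom.surface_height(xx.ravel(), yy.ravel(),
                                     hydration=hydration)
    grid = surface.reshape(n_rows, n_cols)
    glass_mask = grid == 0.0
    if noise_sigma > 0:
        grid = grid + rng.normal(0.0, noise_sigma, grid.shape)
    slope = np.broadcast_to(np.asarray(line_tilt_slope, dtype=float),
                            (n_rows,))
    cols = np.arange(n_cols, dtype=float)
    grid = grid + slope[:, None] * cols[None, :]
    if line_offset_sigma > 0:
        grid = grid + rng.normal(0.0, line_offset_sigma, (n_rows, 1))
    return AFMMap(heights=grid, pixel_size=pixel_size, hydration=hydration,
                  glass_mask=glass_mask)
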