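"""AFM height-map conditioning and fibril profiling.

Consumes height maps already produced by instrument software (contact
point fitting is outside this package) and provides the two quantities
the refractive-index pipeline needs from AFM: the ground-truth crest
height of a fibril and its cross-sectional area, both computed with the
same sliding-window rule as the SMLM height estimator so the two
modalities are directly comparable.  Tip-convolution deconvolution is
not applied; heights of narrow ridges are therefore upper bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from rimap.fibril import (
    FibrilAxis,
    cross_sectional_area,
    estimate_height,
    height_profile,
    resample_height_error,
)

__all__ = [
    "AFMMap",
    "read_afm_map",
    "write_afm_map",
    "tilt_correct_lines",
    "sample_to_cross_section",
    "afm_fibril_profile",
]


@dataclass
class AFMMap:
    """A 2D height grid in nm with pixel pitch and hydration state."""

    heights: np.ndarray
    pixel_size: float                 # nm per pixel, both axes
    hydration: str = "wet"            # "dry" | "wet"
    glass_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if not np.all(np.isfinite(self.heights)):
            raise ValueError("height grid contains non-finite values")
        if self.hydration not in ("dry", "wet"):
            raise ValueError("hydration must be 'dry' or 'wet'")


def read_afm_map(path, pixel_size: float | None = None,
                 hydration: str = "wet") -> AFMMap:
    """Read a 32-bit float TIFF or whitespace-delimited ASCII grid.

    ASCII grids may carry a sidecar header ``<path>.hdr`` with lines like
    ``pixel_size_nm 39.0``; an explicit ``pixel_size`` overrides it.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        grid = tifffile.imread(path).astype(float)
    else:
        grid = np.loadtxt(path, dtype=float)
    if pixel_size is None:
        hdr = path.with_suffix(path.suffix + ".hdr")
        if hdr.exists():
            for line in hdr.read_text().splitlines():
                parts = line.split()
                if len(parts) == 2 and parts[0] == "pixel_size_nm":
                    pixel_size = float(parts[1])
        if pixel_size is None:
            raise ValueError("pixel_size not given and no sidecar header")
    return AFMMap(heights=grid, pixel_size=pixel_size, hydration=hydration)


def write_afm_map(path, afm: AFMMap) -> None:
    """Write a map as 32-bit float TIFF (or ASCII grid for other suffixes)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        tifffile.imwrite(path, afm.heights.astype(np.float32))
    else:
        np.savetxt(path, afm.heights)
        path.with_suffix(path.suffix + ".hdr").write_text(
            f"pixel_size_nm {afm.pixel_size}\n")


def tilt_correct_lines(afm: AFMMap,
                       background_mask: np.ndarray | None = None
                       ) -> tuple[AFMMap, np.ndarray]:
    """Per-scan-line linear background removal.

    For every row a line is fit to the background pixels (under the mask)
    and subtracted; afterwards the background median is set to zero.
    Rows with fewer than 3 background pixels inherit the interpolated fit
    coefficients of neighboring rows and are flagged.  Returns the
    corrected map and the boolean per-row flag array.
    """
    if background_mask is None:
        background_mask = afm.glass_mask
    if background_mask is None:
        raise ValueError("a background (glass) mask is required")
    mask = np.asarray(background_mask, dtype=bool)
    if mask.shape != afm.heights.shape:
        raise ValueError("mask shape does not match the height grid")
    n_rows, n_cols = afm.heights.shape
    cols = np.arange(n_cols, dtype=float)
    coeffs = np.full((n_rows, 2), np.nan)
    for r in range(n_rows):
        sel = mask[r]
        if sel.sum() >= 3:
            coeffs[r] = np.polyfit(cols[sel], afm.heights[r, sel], 1)
    flagged = np.isnan(coeffs[:, 0])
    if flagged.all():
        raise ValueError("no scan line has >= 3 background pixels")
    if flagged.any():
        good = np.nonzero(~flagged)[0]
        for k in range(2):
            coeffs[flagged, k] = np.interp(np.nonzero(flagged)[0], good,
                                           coeffs[good, k])
    corrected = afm.heights - (coeffs[:, [0]] * cols[None, :] + coeffs[:, [1]])
    corrected = corrected - np.median(corrected[mask])
    out = replace(afm, heights=corrected)
    return out, flagged


def sample_to_cross_section(afm: AFMMap, axis: FibrilAxis,
                            max_lateral: float = 600.0) -> pd.DataFrame:
    """Sample map pixels near the axis into the (s, X, Z) frame.

    Pixel centers sit at (row * pixel_size, col * pixel_size) in the
    same lab frame as the localizations (registration is assumed done).
    """
    n_rows, n_cols = afm.heights.shape
    xs = np.arange(n_rows) * afm.pixel_size
    ys = np.arange(n_cols) * afm.pixel_size
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    df = pd.DataFrame({
        "x_nm": xx.ravel(), "y_nm": yy.ravel(),
        "z_nm": afm.heights.ravel(),
    })
    # coarse prefilter by bounding box to keep the projection cheap
    lo = axis.points.min(axis=0) - max_lateral
    hi = axis.points.max(axis=0) + max_lateral
    df = df[(df.x_nm >= lo[0]) & (df.x_nm <= hi[0])
            & (df.y_nm >= lo[1]) & (df.y_nm <= hi[1])].reset_index(drop=True)
    from rimap.fibril import transform_to_cross_section
    cs = transform_to_cross_section(df, axis)
    cs = cs[(~cs["boundary"]) & (cs["X"].abs() <= max_lateral)]
    return cs.reset_index(drop=True)


_BLUR_OFFSETS = (-1.2816, -0.5244, 0.0, 0.5244, 1.2816)  # quintile centers


def ridge_axis(afm: AFMMap, hint: FibrilAxis, s_bin: float = 100.0,
               max_lateral: float = 600.0,
               min_height_frac: float = 0.5) -> FibrilAxis:
    """Fibril axis from the AFM height ridge.

    The dense, low-noise AFM topography pins the central axis far better
    than a sparse localization cloud can: per arclength bin along the
    hint axis, the ridge offset is the height-weighted mean lateral
    position of the pixels above ``min_height_frac`` of the local crest.
    Returns a smooth axis through those ridge points.
    """
    from rimap.fibril import axis_from_polyline, transform_to_cross_section

    cs = sample_to_cross_section(afm, hint, max_lateral=max_lateral)
    if cs.empty:
        raise ValueError("hint axis does not overlap the AFM map")
    bins = (cs["s"] // s_bin).astype(int)
    pts = []
    for b, grp in cs.groupby(bins):
        crest = grp["Z"].max()
        top = grp[grp["Z"] >= min_height_frac * crest]
        if len(top) < 3 or crest <= 0:
            continue
        w = top["Z"].to_numpy()
        x_off = float((top["X"] * w).sum() / w.sum())
        s_mid = float(grp["s"].mean())
        base = hint.point(s_mid)
        nrm = hint.normal(s_mid)
        pts.append(base + x_off * nrm)
    if len(pts) < 2:
        raise ValueError("too few ridge points to define an axis")
    return axis_from_polyline(np.asarray(pts))


def afm_fibril_profile(afm: AFMMap, axis: FibrilAxis,
                       window_nlocs: int = 40, baseline: float = 0.0,
                       max_lateral: float = 600.0,
                       n_resamples: int = 0,
                       lateral_blur: float = 0.0,
                       axial_noise: float = 0.0,
                       rng: np.random.Generator | None = None):
    """Fibril height and cross-sectional area from an AFM map.

    Applies the identical sliding-window median / smoothed-crest rule as
    the SMLM height estimator to the pixels projected into the (s, X)
    frame, and integrates the cross-section profile for the area.
    ``lateral_blur`` (nm) convolves the cross-section laterally with the
    SMLM localization error (five-point Gaussian quadrature), so the two
    modalities estimate the crest of the *same* smeared surface and the
    smearing bias cancels in their comparison.  Returns
    (HeightEstimate, area_nm2, profile DataFrame).
    """
    cs = sample_to_cross_section(afm, axis, max_lateral=max_lateral)
    if cs.empty:
        raise ValueError("axis does not overlap the AFM map")
    # the area uses the raw sliding-window median profile (no crest
    # smoothing); grid pixels produce tied window centers - collapse them
    prof_raw = height_profile(cs, window_nlocs, smooth_windows=1)
    prof = prof_raw.groupby("X", as_index=False)["height"].mean()
    area = cross_sectional_area(prof["X"].to_numpy(),
                                prof["height"].to_numpy(), baseline=baseline)
    if lateral_blur > 0:
        # emulate the SMLM sampling of the same surface: labels uniform
        # on the surface are edge-dense when projected to X (arc-length
        # weighting), and each carries the lateral localization error.
        # Applying the identical crest estimator to that pseudo-cloud
        # makes the AFM height directly comparable to H_SMLM.
        grid = np.arange(prof["X"].min(), prof["X"].max(), 2.0)
        z_grid = np.interp(grid, prof["X"], prof["height"])
        slope = np.gradient(z_grid, grid)
        w = np.sqrt(1.0 + slope ** 2)
        reps = np.clip(np.round(w), 1, 8).astype(int)
        x_rep = np.repeat(grid, reps)
        z_rep = np.repeat(z_grid, reps)
        parts = []
        for q in _BLUR_OFFSETS:
            parts.append(pd.DataFrame({"X": x_rep + q * lateral_blur,
                                       "Z": z_rep}))
        pseudo = pd.concat(parts, ignore_index=True)
        if axial_noise > 0:
            noise_rng = np.random.default_rng() if rng is None else rng
            pseudo["Z"] = pseudo["Z"] + noise_rng.normal(
                0.0, axial_noise, len(pseudo))
        est = estimate_height(pseudo, window_nlocs,
                              n_resamples=n_resamples, rng=rng)
    else:
        est = estimate_height(cs, window_nlocs, n_resamples=n_resamples,
                              rng=rng)
    return est, float(area), prof
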