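"""Fibril cross-section analysis: from localizations to refractive index.

The pipeline models a fibril as a tube whose surface is decorated with
fluorophores.  After drift and tilt correction, a planar spline through
the fibril's central axis defines fibril-centric coordinates (s, X, Z):
arclength along the axis, signed lateral offset, and height above the
coverslip.  Collapsing all localizations along s yields a cross-section
profile whose crest height H_SMLM depends on the refractive index
assumed when fitting the PSF model.  Comparing H_SMLM(n) with the
AFM-measured height H_AFM by intersecting a linear fit yields the fibril
refractive index; resampling-based error propagation attaches its
experimental uncertainty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from sklearn.cluster import DBSCAN

__all__ = [
    "ReferencePlane",
    "FibrilAxis",
    "HeightEstimate",
    "RIEstimate",
    "SwellingRecord",
    "correct_drift",
    "fit_reference_plane_and_defocus",
    "apply_reference_plane",
    "fit_fibril_axis",
    "transform_to_cross_section",
    "reconstruct_from_cross_section",
    "filter_outliers",
    "height_profile",
    "estimate_height",
    "resample_height_error",
    "estimate_refractive_index",
    "propagate_ri_error",
    "swelling_and_dry_index",
    "cross_sectional_area",
    "map_ri_along_fibril",
    "variance_decomposition",
    "N_WATER",
]

#: refractive index of water, the reference ambient medium
N_WATER = 1.33


# ---------------------------------------------------------------------------
# drift correction
# ---------------------------------------------------------------------------

def correct_drift(localizations: pd.DataFrame,
                  fiducial_tracks: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Subtract the mean fiducial displacement per frame from all positions.

    ``fiducial_tracks`` needs columns frame, x_nm, y_nm, fiducial_id.  The
    drift at each frame is the average over fiducials of their displacement
    from their own time-mean; frames between fiducial samples are linearly
    interpolated.  Returns the corrected table and the RMS of the fiducial
    residuals after correction.
    """
    if fiducial_tracks.empty:
        raise ValueError("at least one fiducial track is required")
    fmin = int(fiducial_tracks["frame"].min())
    fmax = int(fiducial_tracks["frame"].max())
    lmin = int(localizations["frame"].min())
    lmax = int(localizations["frame"].max())
    if lmin < fmin or lmax > fmax:
        raise ValueError(
            f"fiducials cover frames [{fmin}, {fmax}] but localizations span "
            f"[{lmin}, {lmax}]; no fiducial covers the remainder")

    disp = fiducial_tracks.copy()
    for ax in ("x_nm", "y_nm"):
        disp[ax] = disp[ax] - disp.groupby("fiducial_id")[ax].transform("mean")
    per_frame = disp.groupby("frame")[["x_nm", "y_nm"]].mean()
    frames = per_frame.index.to_numpy(dtype=float)
    fquery = localizations["frame"].to_numpy(dtype=float)
    out = localizations.copy()
    for ax in ("x_nm", "y_nm"):
        drift = np.interp(fquery, frames, per_frame[ax].to_numpy())
        out[ax] = out[ax] - drift
    # fiducial residuals after applying the (averaged) correction to them
    resid = []
    for ax in ("x_nm", "y_nm"):
        corr = np.interp(disp["frame"].to_numpy(dtype=float), frames,
                         per_frame[ax].to_numpy())
        resid.append(disp[ax].to_numpy() - corr)
    rms = float(np.sqrt(np.mean(np.concatenate(resid) ** 2)))
    return out, rms


# ---------------------------------------------------------------------------
# reference plane and defocus
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReferencePlane:
    """Tilt plane and defocus fixed by coverslip-bound fluorophores."""

    slope_x: float       # dimensionless (nm of z per nm of x)
    slope_y: float
    offset: float        # nm
    fitted_defocus: float  # nm, absolute defocus of the acquisition
    resid_var: float = 0.0           # nm^2, residual variance of the fit
    xtx_inv: np.ndarray | None = None  # (3, 3) normal-matrix inverse

    def evaluate(self, x_nm: np.ndarray, y_nm: np.ndarray) -> np.ndarray:
        return self.slope_x * np.asarray(x_nm) \
            + self.slope_y * np.asarray(y_nm) + self.offset

    def prediction_se(self, x_nm: float, y_nm: float) -> float:
        """Standard error of the plane level at one position.

        The reference level is subtracted from every fibril height, so
        its uncertainty propagates one-to-one into H_SMLM; it must enter
        the refractive-index error budget.
        """
        if self.xtx_inv is None:
            return 0.0
        v = np.array([x_nm, y_nm, 1.0])
        return float(np.sqrt(max(self.resid_var * v @ self.xtx_inv @ v, 0.0)))


def fit_reference_plane_and_defocus(glass_rois: pd.DataFrame,
                                    glass_fits: pd.DataFrame,
                                    system, sample_glass,
                                    scan_range: tuple[float, float] = (-250.0, 250.0),
                                    tol: float = 1.0,
                                    z_band: float = 250.0) -> ReferencePlane:
    """Find the defocus at which coverslip dyes average to z = 0.

    The axial positions of the glass-bound fluorophores are refit while
    scanning a defocus offset over ``scan_range`` (relative to the nominal
    system defocus); the zero crossing of their mean z fixes the defocus,
    and the residual tilt plane is fit to the refit positions.  The
    refits are confined to ``|z| <= z_band``: defocus and axial position
    trade off against each other, and far outside the band the mismatch
    likelihood develops secondary minima that would derail the scan.
    """
    from rimap.localize import refit_z

    if len(glass_fits) < 10:
        raise ValueError("need >= 10 coverslip-bound localizations")

    cache: dict[float, np.ndarray] = {}

    def mean_z(shift: float) -> float:
        z = refit_z(glass_rois, glass_fits, system, sample_glass,
                    defocus_shift=shift, z_bounds=(-z_band, z_band))
        cache[shift] = z
        return float(np.mean(z))

    lo, hi = scan_range
    f_lo, f_hi = mean_z(lo), mean_z(hi)
    if f_lo * f_hi > 0:
        raise RuntimeError(
            "no defocus in the scan range brings the reference plane to "
            f"z = 0: mean z({lo:+.0f}) = {f_lo:.1f} nm, "
            f"mean z({hi:+.0f}) = {f_hi:.1f} nm")
    shift = brentq(mean_z, lo, hi, xtol=tol)
    z = cache.get(shift)
    if z is None:
        z = refit_z(glass_rois, glass_fits, system, sample_glass,
                    defocus_shift=shift, z_bounds=(-z_band, z_band))
    x = glass_fits["x_nm"].to_numpy()
    y = glass_fits["y_nm"].to_numpy()
    design = np.column_stack([x, y, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(design, z, rcond=None)
    resid = z - design @ coef
    dof = max(len(z) - 3, 1)
    return ReferencePlane(slope_x=float(coef[0]), slope_y=float(coef[1]),
                          offset=float(coef[2]),
                          fitted_defocus=float(system.defocus + shift),
                          resid_var=float(resid @ resid / dof),
                          xtx_inv=np.linalg.inv(design.T @ design))


def apply_reference_plane(localizations: pd.DataFrame,
                          plane: ReferencePlane) -> pd.DataFrame:
    """Tilt-correct z by subtracting the reference plane."""
    out = localizations.copy()
    out["z_nm"] = out["z_nm"] - plane.evaluate(out["x_nm"], out["y_nm"])
    return out


# ---------------------------------------------------------------------------
# fibril axis and cross-section coordinates
# ---------------------------------------------------------------------------

@dataclass
class FibrilAxis:
    """Planar spline through the fibril's central axis (z = 0).

    The axis is stored as a dense arclength presampling (10 nm default)
    of the fitted spline, expressed in lab coordinates.
    """

    s: np.ndarray          # arclength nodes, nm
    points: np.ndarray     # (m, 2) lab coordinates
    tangents: np.ndarray   # (m, 2) unit tangents
    spline_order: int = 3
    step: float = 10.0

    @property
    def domain(self) -> tuple[float, float]:
        return float(self.s[0]), float(self.s[-1])

    def point(self, s) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        x = np.interp(s, self.s, self.points[:, 0])
        y = np.interp(s, self.s, self.points[:, 1])
        return np.stack([x, y], axis=-1)

    def normal(self, s) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        tx = np.interp(s, self.s, self.tangents[:, 0])
        ty = np.interp(s, self.s, self.tangents[:, 1])
        norm = np.hypot(tx, ty)
        return np.stack([-ty / norm, tx / norm], axis=-1)


def axis_from_polyline(points: np.ndarray, step: float = 10.0) -> FibrilAxis:
    """Build a FibrilAxis from an ordered (m, 2) polyline in lab nm."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
        raise ValueError("polyline must be an (m, 2) array with m >= 2")
    seg = np.hypot(*np.diff(pts, axis=0).T)
    s_raw = np.concatenate([[0.0], np.cumsum(seg)])
    s = np.arange(0.0, s_raw[-1] + step, step)
    x = np.interp(s, s_raw, pts[:, 0])
    y = np.interp(s, s_raw, pts[:, 1])
    dx = np.gradient(x, s)
    dy = np.gradient(y, s)
    norm = np.hypot(dx, dy)
    tang = np.stack([dx / norm, dy / norm], axis=1)
    return FibrilAxis(s=s, points=np.stack([x, y], axis=1), tangents=tang,
                      step=step)


def fit_fibril_axis(localizations: pd.DataFrame, spline_order: int = 3,
                    presample_step: float = 10.0,
                    knot_spacing: float | None = None,
                    min_pts_per_span: int = 150) -> FibrilAxis:
    """Least-squares planar spline through a fibril's point cloud.

    The cloud is rotated into its principal frame and the transverse
    coordinate fit as a least-squares spline of the longitudinal one,
    with interior knots every ``knot_spacing`` nm.  The sparse knots
    keep the curve stiff: fibril axes bend on micrometer scales, whereas
    a flexible smoother would chase the transverse labeling noise and
    corrupt the cross-section coordinates.  By default the spacing is
    adaptive, sized so every knot span holds about ``min_pts_per_span``
    localizations (never below 300 nm), which bounds the lateral noise
    of the fitted curve regardless of the labeling density.
    """
    from scipy.interpolate import LSQUnivariateSpline

    pts = localizations[["x_nm", "y_nm"]].to_numpy(dtype=float)
    if len(pts) < 10:
        raise ValueError("too few localizations to define an axis")
    center = pts.mean(axis=0)
    cov = np.cov((pts - center).T)
    w, v = np.linalg.eigh(cov)
    if w[-1] < 1e-6 or math.sqrt(w[-1]) < 250.0:
        raise ValueError("point cloud is too compact to define a fibril axis")
    e1 = v[:, -1]
    e2 = np.array([-e1[1], e1[0]])
    u = (pts - center) @ e1
    t = (pts - center) @ e2
    order = np.argsort(u)
    u, t = u[order], t[order]
    if knot_spacing is None:
        span = float(u[-1] - u[0])
        knot_spacing = max(300.0, span * min_pts_per_span / len(u))
    # iterative sigma-clipping: stray localizations (failed fits, debris)
    # lie far off the tube and would lever the unweighted spline
    keep = np.ones(len(u), dtype=bool)
    spl = None
    for _ in range(3):
        uk, tk = u[keep], t[keep]
        # collapse duplicate abscissae (spline needs strictly increasing x)
        uu, inv = np.unique(np.round(uk, 6), return_inverse=True)
        tt = np.bincount(inv, weights=tk) / np.bincount(inv)
        interior = np.arange(uu[0] + knot_spacing, uu[-1] - knot_spacing / 2,
                             knot_spacing)
        # each knot span needs enough points to be determined
        interior = np.array([k for k in interior
                             if np.sum((uu > k - knot_spacing)
                                       & (uu < k + knot_spacing))
                             > spline_order + 1])
        spl = LSQUnivariateSpline(uu, tt, interior, k=spline_order)
        resid = t - spl(u)
        med = np.median(resid)
        sigma = 1.4826 * np.median(np.abs(resid - med))
        new_keep = np.abs(resid - med) <= max(3.0 * sigma, 25.0)
        if new_keep.sum() < 10 or np.array_equal(new_keep, keep):
            break
        keep = new_keep
    ug = np.arange(uu[0], uu[-1] + presample_step, presample_step)
    vg = spl(ug)
    dvg = spl.derivative()(ug)
    xy = center + np.outer(ug, e1) + np.outer(vg, e2)
    seg = np.hypot(np.diff(xy[:, 0]), np.diff(xy[:, 1]))
    s = np.concatenate([[0.0], np.cumsum(seg)])
    tang = np.stack([e1[0] + dvg * e2[0], e1[1] + dvg * e2[1]], axis=1)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    return FibrilAxis(s=s, points=xy, tangents=tang,
                      spline_order=spline_order, step=presample_step)


def transform_to_cross_section(localizations: pd.DataFrame,
                               axis: FibrilAxis) -> pd.DataFrame:
    """Map localizations to fibril-centric coordinates (s, X, Z).

    Each point is projected to its nearest point on the axis (dense
    presampling refined by projection onto the local segment); X is
    signed by the axis normal (left of the tangent is positive).  Points
    whose nearest point is an axis endpoint keep the endpoint s and are
    flagged in the ``boundary`` column.
    """
    pts = localizations[["x_nm", "y_nm"]].to_numpy(dtype=float)
    nodes = axis.points
    # nearest dense node (chunked to bound memory)
    idx = np.empty(len(pts), dtype=int)
    for start in range(0, len(pts), 2048):
        d = ((pts[start:start + 2048, None, :] - nodes[None, :, :]) ** 2
             ).sum(axis=2)
        idx[start:start + 2048] = np.argmin(d, axis=1)
    s_out = np.empty(len(pts))
    x_out = np.empty(len(pts))
    boundary = np.zeros(len(pts), dtype=bool)
    for i, (p, j) in enumerate(zip(pts, idx)):
        j0 = max(j - 1, 0)
        j1 = min(j + 1, len(nodes) - 1)
        a, b = nodes[j0], nodes[j1]
        ab = b - a
        denom = float(ab @ ab)
        tpar = 0.0 if denom == 0 else float((p - a) @ ab) / denom
        tpar_cl = min(max(tpar, 0.0), 1.0)
        foot = a + tpar_cl * ab
        s_val = axis.s[j0] + tpar_cl * (axis.s[j1] - axis.s[j0])
        if (j0 == 0 and tpar <= 0.0) or (j1 == len(nodes) - 1 and tpar >= 1.0):
            boundary[i] = True
        tang = axis.tangents[j]
        nrm = np.array([-tang[1], tang[0]])
        x_out[i] = float((p - foot) @ nrm)
        s_out[i] = s_val
    out = localizations.copy()
    out["s"] = s_out
    out["X"] = x_out
    out["Z"] = out["z_nm"].to_numpy(dtype=float)
    out["boundary"] = boundary
    return out


def reconstruct_from_cross_section(cross_sections: pd.DataFrame,
                                   axis: FibrilAxis) -> pd.DataFrame:
    """Inverse of :func:`transform_to_cross_section` for interior points."""
    s = cross_sections["s"].to_numpy(dtype=float)
    x_off = cross_sections["X"].to_numpy(dtype=float)
    base = axis.point(s)
    nrm = axis.normal(s)
    out = cross_sections.copy()
    out["x_nm"] = base[:, 0] + x_off * nrm[:, 0]
    out["y_nm"] = base[:, 1] + x_off * nrm[:, 1]
    out["z_nm"] = cross_sections["Z"].to_numpy(dtype=float)
    return out


# ---------------------------------------------------------------------------
# outlier filtering
# ---------------------------------------------------------------------------

def filter_outliers(cross_sections: pd.DataFrame, eps: float = 30.0,
                    min_samples: int = 10) -> tuple[pd.DataFrame, float]:
    """Remove sparse outliers in the (X, Z) plane with DBSCAN.

    Keeps the most populous cluster; returns the filtered table and the
    fraction of points removed.
    """
    xz = cross_sections[["X", "Z"]].to_numpy(dtype=float)
    labels = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(xz)
    valid = labels >= 0
    if not valid.any():
        raise ValueError(
            "DBSCAN classified every localization as noise; revise eps / "
            "min_samples for this point density")
    main = np.bincount(labels[valid]).argmax()
    keep = labels == main
    removed = 1.0 - keep.sum() / len(keep)
    return cross_sections.loc[keep].reset_index(drop=True), float(removed)


# ---------------------------------------------------------------------------
# height estimation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HeightEstimate:
    """A crest-height estimate with its resampling error."""

    H: float
    sigma_H: float
    n_assumed: float
    window_nlocs: int


def _crest_height(x_sorted_z: np.ndarray, window_nlocs: int,
                  smooth_windows: int | None = None) -> float:
    """Max of the smoothed sliding-window median profile (Z sorted by X).

    The windows slide by one localization, so adjacent medians are
    almost fully correlated; smoothing over one window-length of medians
    (the default) suppresses the upward bias that taking the maximum of
    a noisy profile would otherwise introduce.
    """
    z = x_sorted_z
    if len(z) < window_nlocs:
        raise ValueError("fewer localizations than one window")
    if smooth_windows is None:
        smooth_windows = window_nlocs
    win = np.lib.stride_tricks.sliding_window_view(z, window_nlocs)
    med = np.median(win, axis=1)
    if smooth_windows > 1 and len(med) >= smooth_windows:
        kernel = np.ones(smooth_windows) / smooth_windows
        med = np.convolve(med, kernel, mode="valid")
    return float(med.max())


def height_profile(cross_sections: pd.DataFrame, window_nlocs: int,
                   smooth_windows: int | None = None) -> pd.DataFrame:
    """Sliding-window median height versus lateral offset X.

    Windows contain a fixed number of localizations ordered by X; the
    returned profile is smoothed with a centered moving average.
    """
    df = cross_sections.sort_values("X")
    x = df["X"].to_numpy(dtype=float)
    z = df["Z"].to_numpy(dtype=float)
    if len(z) < window_nlocs:
        raise ValueError("fewer localizations than one window")
    if smooth_windows is None:
        smooth_windows = window_nlocs
    win_z = np.lib.stride_tricks.sliding_window_view(z, window_nlocs)
    win_x = np.lib.stride_tricks.sliding_window_view(x, window_nlocs)
    med = np.median(win_z, axis=1)
    ctr = win_x.mean(axis=1)
    if smooth_windows > 1 and len(med) >= smooth_windows:
        kernel = np.ones(smooth_windows) / smooth_windows
        med = np.convolve(med, kernel, mode="valid")
        off = (smooth_windows - 1) // 2
        ctr = ctr[off:off + len(med)]
    return pd.DataFrame({"X": ctr, "height": med})


def estimate_height(cross_sections: pd.DataFrame, window_nlocs: int,
                    debris_offset: float = 0.0, n_assumed: float = np.nan,
                    smooth_windows: int | None = None, n_resamples: int = 0,
                    rng: np.random.Generator | None = None) -> HeightEstimate:
    """Crest height of the cross-section profile.

    The median Z is computed in sliding windows of fixed localization
    count ordered by X, the profile is smoothed, and the crest (maximum)
    plus the AFM-measured debris offset gives H.  When ``n_resamples`` is
    positive, sigma_H is estimated by half-sample resampling.
    """
    z = cross_sections.sort_values("X")["Z"].to_numpy(dtype=float)
    h = _crest_height(z, window_nlocs, smooth_windows) + debris_offset
    sigma = 0.0
    if n_resamples > 0:
        sigma = resample_height_error(cross_sections, window_nlocs,
                                      n_resamples=n_resamples, rng=rng,
                                      smooth_windows=smooth_windows)
    return HeightEstimate(H=float(h), sigma_H=float(sigma),
                          n_assumed=float(n_assumed),
                          window_nlocs=int(window_nlocs))


def resample_height_error(cross_sections: pd.DataFrame, window_nlocs: int,
                          n_resamples: int = 1000,
                          rng: np.random.Generator | None = None,
                          smooth_windows: int | None = None) -> float:
    """Half-sample resampling error of the crest height.

    Half the localizations are drawn without replacement and the height
    recomputed; the standard deviation over resamples, divided by
    sqrt(2), estimates the standard error of the full-sample height.
    """
    rng = np.random.default_rng() if rng is None else rng
    df = cross_sections.sort_values("X")
    x = df["X"].to_numpy(dtype=float)
    z = df["Z"].to_numpy(dtype=float)
    n = len(z)
    half = n // 2
    if half < window_nlocs:
        raise ValueError("need at least 2 x window_nlocs localizations")
    heights = np.empty(n_resamples)
    for i in range(n_resamples):
        pick = np.sort(rng.choice(n, size=half, replace=False))
        heights[i] = _crest_height(z[pick], window_nlocs, smooth_windows)
    return float(np.std(heights, ddof=1) / np.sqrt(2.0))


# ---------------------------------------------------------------------------
# refractive-index estimation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RIEstimate:
    """Refractive index from intersecting H_SMLM(n) with H_AFM."""

    n: float
    sigma_n: float
    slope: float       # nm per refractive-index unit
    intercept: float   # nm
    in_range: bool     # intersection within the physically plausible band


def estimate_refractive_index(heights: list[HeightEstimate],
                              h_afm: HeightEstimate,
                              n_draws: int = 10000,
                              rng: np.random.Generator | None = None,
                              plausible=(1.30, 1.60)) -> RIEstimate:
    """Intersect the linear H_SMLM(n) trend with the AFM height.

    The apparent SMLM height increases with the refractive index assumed
    in the PSF fit; the assumed index at which it matches the AFM ground
    truth is the sample's refractive index.  sigma_n comes from Monte
    Carlo propagation of all height uncertainties through the fit.
    """
    if len(heights) < 3:
        raise ValueError("need >= 3 grid points for the linear fit")
    n_grid = np.array([h.n_assumed for h in heights])
    h_vals = np.array([h.H for h in heights])
    slope, intercept = np.polyfit(n_grid, h_vals, 1)
    if slope <= 0:
        raise ValueError(
            "H_SMLM(n) has non-positive slope; the fitted heights do not "
            "increase with the assumed refractive index")
    n_est = (h_afm.H - intercept) / slope
    sigma_n = 0.0
    if n_draws > 0:
        sigmas = np.array([h.sigma_H for h in heights])
        sigma_n = propagate_ri_error(n_grid, h_vals, sigmas, h_afm.H,
                                     h_afm.sigma_H, n_draws=n_draws, rng=rng)
    in_range = plausible[0] <= n_est <= plausible[1]
    return RIEstimate(n=float(n_est), sigma_n=float(sigma_n),
                      slope=float(slope), intercept=float(intercept),
                      in_range=bool(in_range))


def propagate_ri_error(n_grid: np.ndarray, heights: np.ndarray,
                       sigma_heights: np.ndarray, h_afm: float,
                       sigma_afm: float, n_draws: int = 10000,
                       rng: np.random.Generator | None = None) -> float:
    """Monte Carlo error of the line-intersection refractive index.

    Heights are perturbed with their Gaussian errors, the linear fit and
    intersection recomputed per draw, and the sample standard deviation
    of the intersections returned.
    """
    rng = np.random.default_rng() if rng is None else rng
    n_grid = np.asarray(n_grid, dtype=float)
    m = len(n_grid)
    draws_h = heights[None, :] + rng.standard_normal((n_draws, m)) \
        * np.asarray(sigma_heights, dtype=float)[None, :]
    draws_afm = h_afm + rng.standard_normal(n_draws) * sigma_afm
    design = np.column_stack([n_grid, np.ones(m)])
    pinv = np.linalg.pinv(design)
    coef = pinv @ draws_h.T                       # (2, n_draws)
    slopes, intercepts = coef[0], coef[1]
    n_vals = (draws_afm - intercepts) / slopes
    return float(np.std(n_vals, ddof=1))


# ---------------------------------------------------------------------------
# swelling and cross-sectional area
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SwellingRecord:
    """Swelling upon rehydration and the implied dry refractive index."""

    A_dry: float
    A_wet: float
    delta_A: float
    n_dry: float
    n_water: float = N_WATER
    shrinkage: bool = False


def swelling_and_dry_index(A_dry: float, A_wet: float,
                           n_collagen: float,
                           n_water: float = N_WATER) -> SwellingRecord:
    """Invert the area-weighted mixing model for the dry-state index.

    The hydrated-fibril index is modeled as the area-weighted average of
    dry collagen and the water taken up by swelling,
    n_collagen = (n_dry + dA * n_water) / (1 + dA), which inverts exactly
    to n_dry = n_collagen * (1 + dA) - dA * n_water.
    """
    if A_dry <= 0 or A_wet <= 0:
        raise ValueError("areas must be positive")
    delta_a = A_wet / A_dry - 1.0
    n_dry = n_collagen * (1.0 + delta_a) - delta_a * n_water
    return SwellingRecord(A_dry=float(A_dry), A_wet=float(A_wet),
                          delta_A=float(delta_a), n_dry=float(n_dry),
                          n_water=float(n_water),
                          shrinkage=bool(A_wet < A_dry))


def cross_sectional_area(x: np.ndarray, height: np.ndarray,
                         baseline: float = 0.0) -> float:
    """Trapezoidal area under a height profile, clipped at the baseline."""
    x = np.asarray(x, dtype=float)
    h = np.asarray(height, dtype=float)
    dx = np.diff(x)
    if not (np.all(dx > 0) or np.all(dx < 0)):
        raise ValueError("profile grid must be monotone in X")
    if dx[0] < 0:
        x, h = x[::-1], h[::-1]
    return float(np.trapezoid(np.clip(h - baseline, 0.0, None), x))


# ---------------------------------------------------------------------------
# RI mapping along the fibril and variance decomposition
# ---------------------------------------------------------------------------

def map_ri_along_fibril(cross_sections: pd.DataFrame, n_grid,
                        z_columns: dict, afm_height, window_nlocs: int = 100,
                        overlap_fraction: float = 0.9,
                        height_window_nlocs: int = 40,
                        afm_sigma: float = 1.0,
                        n_resamples: int = 200, n_draws: int = 2000,
                        max_window_extent: float | None = None,
                        rng: np.random.Generator | None = None,
                        debris_offset: float = 0.0) -> pd.DataFrame:
    """Refractive index in sliding windows along the fibril axis.

    ``cross_sections`` must be a single table with one row per
    localization carrying s, x_nm, y_nm, X and one Z column per assumed
    refractive index (named by ``z_columns[n]``).  ``afm_height`` is a
    callable s -> H_AFM (nm).  Windows hold a fixed localization count
    with the configured overlap; within each window the full
    height-and-intersection estimate is run against the local AFM height.
    Windows stretching over fibril gaps (extent above
    ``max_window_extent``) are skipped.
    """
    rng = np.random.default_rng() if rng is None else rng
    df = cross_sections.sort_values("s").reset_index(drop=True)
    n_total = len(df)
    if n_total < window_nlocs:
        raise ValueError("fewer localizations than one mapping window")
    step = max(1, int(round((1.0 - overlap_fraction) * window_nlocs)))
    # the crest window must stay well below half the mapping window so
    # that half-sample resampling still evaluates the same estimator
    hw = min(height_window_nlocs, window_nlocs // 4)
    rows = []
    for start in range(0, n_total - window_nlocs + 1, step):
        w = df.iloc[start:start + window_nlocs]
        extent = float(w["s"].max() - w["s"].min())
        if max_window_extent is not None and extent > max_window_extent:
            continue
        s_center = float(w["s"].mean())
        heights = []
        for n_val in n_grid:
            sub = w[["X"]].copy()
            sub["Z"] = w[z_columns[n_val]].to_numpy(dtype=float)
            heights.append(estimate_height(
                sub, hw, debris_offset=debris_offset, n_assumed=n_val,
                n_resamples=n_resamples, rng=rng))
        h_afm = HeightEstimate(H=float(afm_height(s_center)),
                               sigma_H=afm_sigma, n_assumed=np.nan,
                               window_nlocs=window_nlocs)
        est = estimate_refractive_index(heights, h_afm, n_draws=n_draws,
                                        rng=rng)
        rows.append({"s_nm": s_center,
                     "x_nm": float(w["x_nm"].mean()),
                     "y_nm": float(w["y_nm"].mean()),
                     "n": est.n, "sigma_n_exp": est.sigma_n,
                     "window_nm": extent})
    return pd.DataFrame(rows, columns=["s_nm", "x_nm", "y_nm", "n",
                                       "sigma_n_exp", "window_nm"])


def variance_decomposition(maps_by_window: dict) -> pd.DataFrame:
    """Split map variance into sample and experimental contributions.

    For each window size (keyed by its RI map as produced by
    :func:`map_ri_along_fibril`), the total variance of the mapped n
    values is decomposed as sigma_n^2 = sigma_n,collagen^2 +
    sigma_n,exp^2, with the sample term floored at zero; reported against
    the mean window extent along the fibril.  Sizes with fewer than 3
    windows are skipped.
    """
    rows = []
    for window_nlocs, ri_map in sorted(maps_by_window.items()):
        if len(ri_map) < 3:
            continue
        var_total = float(np.var(ri_map["n"].to_numpy(), ddof=1))
        var_exp = float(np.mean(ri_map["sigma_n_exp"].to_numpy() ** 2))
        rows.append({
            "window_nlocs": int(window_nlocs),
            "mean_distance_nm": float(np.mean(ri_map["window_nm"])),
            "var_total": var_total,
            "var_exp": var_exp,
            "var_collagen": max(0.0, var_total - var_exp),
        })
    return pd.DataFrame(rows, columns=["window_nlocs", "mean_distance_nm",
                                       "var_total", "var_exp",
                                       "var_collagen"])
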