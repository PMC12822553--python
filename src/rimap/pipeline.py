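"""End-to-end drivers: image stacks + AFM maps -> refractive index.

Chains the building blocks into the standard analysis: detect and fit
emitters, identify fiducials and correct drift, fix defocus and tilt
from coverslip-bound dyes, refit fibril dye heights over a grid of
assumed refractive indices, build fibril-centric cross sections, and
intersect the apparent-height trend with the AFM ground truth.

Fibrils are supplied pre-segmented: an approximate axis (``axis_hint``)
defines which localizations belong to the fibril and which to the
surrounding coverslip; the axis used for the cross-section transform is
refit from the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from rimap import fibril as fb
from rimap import localize as lc
from rimap.afm import AFMMap, afm_fibril_profile, tilt_correct_lines
from rimap.optics import LayeredSample, OpticalSystem

__all__ = [
    "FibrilAnalysisConfig",
    "FibrilReport",
    "identify_fiducials",
    "segment_by_axis",
    "analyze_fibril_stack",
]


@dataclass
class FibrilAnalysisConfig:
    """Tunables of the fibril refractive-index analysis."""

    n_grid: tuple = (1.38, 1.40, 1.42, 1.44, 1.46, 1.48)
    window_nlocs: int = 40
    #: the conventional LLR < 600 gate absorbs EMCCD excess noise, which
    #: roughly doubles the deviance; for plain Poisson counts on a
    #: 15 x 15 ROI the equivalent quality gate is the chi^2_220 tail
    llr_cutoff: float = 300.0
    absolute_threshold: float = 450.0
    relative_threshold: float = 1.5
    dbscan_eps: float = 30.0
    dbscan_min_samples: int = 10
    n_resamples: int = 1000
    n_draws: int = 10000
    defocus_scan: tuple = (-250.0, 250.0)
    fibril_halfwidth: float = 250.0     # nm band around the hint axis
    glass_exclusion: float = 700.0      # nm, min distance of glass dyes
    max_glass_refs: int = 200           # cap for the defocus scan
    debris_offset: float = 0.0


@dataclass
class FibrilReport:
    """Results of one fibril analysis."""

    ri: fb.RIEstimate
    heights: list
    h_afm: fb.HeightEstimate
    axis: fb.FibrilAxis | None
    fitted_defocus: float
    drift_residual_rms: float
    n_fibril_locs: int
    n_glass_locs: int
    cross_sections: pd.DataFrame
    area_wet: float | None = None
    area_dry: float | None = None
    swelling: fb.SwellingRecord | None = None


def identify_fiducials(rois: pd.DataFrame, n_frames: int, px: float,
                       min_presence: float = 0.5,
                       cluster_radius_px: float = 3.0):
    """Split detected ROIs into fiducial and emitter candidates.

    Fiducials are candidates that recur at (nearly) the same position in
    at least ``min_presence`` of all frames.  Their per-frame positions
    (background-subtracted centroids) form drift tracks.  Returns
    ``(emitter_rois, fiducial_tracks)``.
    """
    if rois.empty:
        return rois, pd.DataFrame(columns=["frame", "x_nm", "y_nm",
                                           "fiducial_id"])
    # a fiducial recurs at (nearly) the same pixel in most frames: count
    # candidates on a coarse grid and look for persistently hot cells
    rows = rois["row"].to_numpy()
    cols = rois["col"].to_numpy()
    cell = (rows // int(cluster_radius_px)) * 100000 \
        + cols // int(cluster_radius_px)
    counts = pd.Series(cell).value_counts()
    hot = counts[counts >= 0.5 * min_presence * n_frames].index
    centers = []
    for h in hot:
        sel0 = cell == h
        centers.append((rows[sel0].mean(), cols[sel0].mean()))
    # merge neighboring hot cells into single fiducial centers
    merged_centers: list[tuple[float, float]] = []
    for r, c in sorted(centers):
        if any(abs(r - mr) <= 2 * cluster_radius_px
               and abs(c - mc) <= 2 * cluster_radius_px
               for mr, mc in merged_centers):
            continue
        merged_centers.append((r, c))
    tracks = []
    is_fid = np.zeros(len(rois), dtype=bool)
    fid_id = 0
    for r0, c0 in merged_centers:
        sel = (np.abs(rows - r0) <= cluster_radius_px) \
            & (np.abs(cols - c0) <= cluster_radius_px)
        if rois.loc[sel, "frame"].nunique() < min_presence * n_frames:
            continue
        is_fid |= sel
        for rec in rois.loc[sel].itertuples(index=False):
            roi = rec.roi
            border = np.concatenate([roi[0], roi[-1],
                                     roi[1:-1, 0], roi[1:-1, -1]])
            sig = np.clip(roi - np.median(border), 0.0, None)
            tot = sig.sum()
            n = roi.shape[0]
            idx = np.arange(n) - n // 2
            dx = float((sig.sum(axis=1) * idx).sum() / tot)
            dy = float((sig.sum(axis=0) * idx).sum() / tot)
            tracks.append({"frame": int(rec.frame),
                           "x_nm": (rec.row + dx) * px,
                           "y_nm": (rec.col + dy) * px,
                           "fiducial_id": fid_id})
        fid_id += 1
    emitter_rois = rois.loc[~is_fid].reset_index(drop=True)
    return emitter_rois, pd.DataFrame(
        tracks, columns=["frame", "x_nm", "y_nm", "fiducial_id"])


def segment_by_axis(positions: pd.DataFrame, axis_hint: fb.FibrilAxis,
                    fibril_halfwidth: float, glass_exclusion: float):
    """Classify points as fibril or coverslip by lateral offset.

    ``positions`` needs x_nm / y_nm columns (ROI centers are accurate
    enough: segmentation tolerance is hundreds of nm).
    """
    df = positions[["x_nm", "y_nm"]].copy()
    df["z_nm"] = 0.0
    cs = fb.transform_to_cross_section(df, axis_hint)
    lateral = cs["X"].abs().to_numpy()
    interior = ~cs["boundary"].to_numpy()
    fibril_sel = (lateral <= fibril_halfwidth) & interior
    glass_sel = (lateral >= glass_exclusion) & interior
    return fibril_sel, glass_sel


def analyze_fibril_stack(stack: np.ndarray, system: OpticalSystem,
                         axis_hint: fb.FibrilAxis, h_afm_estimate,
                         config: FibrilAnalysisConfig | None = None,
                         rng: np.random.Generator | None = None,
                         afm_wet: AFMMap | None = None,
                         afm_dry: AFMMap | None = None) -> FibrilReport:
    """Full analysis of one fibril from a blinking stack.

    ``h_afm_estimate`` is the AFM crest height of the fibril (a
    :class:`~rimap.fibril.HeightEstimate`); pass ``afm_wet`` / ``afm_dry``
    maps as well to obtain areas and the swelling record.  All
    stochastic steps (resampling, error propagation) draw from ``rng``.
    """
    config = config or FibrilAnalysisConfig()
    rng = np.random.default_rng() if rng is None else rng
    px = system.pixel_size_sample
    h_fibril = h_afm_estimate.H

    rois = lc.extract_rois(stack, config.absolute_threshold,
                           config.relative_threshold, system.roi_size)
    rois, fiducial_tracks = identify_fiducials(rois, len(stack), px)
    if rois.empty:
        raise ValueError("no emitter candidates detected")

    # segment candidates by ROI center before fitting, so each class is
    # fit with its appropriate layer model
    centers = pd.DataFrame({"x_nm": rois["row"].to_numpy(dtype=float) * px,
                            "y_nm": rois["col"].to_numpy(dtype=float) * px})
    fibril_sel, glass_sel = segment_by_axis(
        centers, axis_hint, config.fibril_halfwidth, config.glass_exclusion)

    glass_sample = LayeredSample(n_layer=system.n_ambient, thickness=0.0)
    n_ref = config.n_grid[len(config.n_grid) // 2]
    mid_sample = LayeredSample(n_layer=float(n_ref), thickness=h_fibril)

    def _fit_class(sel, sample):
        cls_rois = rois.loc[sel].reset_index(drop=True)
        fits = lc.fit_rois(cls_rois, system, sample)
        good = ((fits["llr"] < config.llr_cutoff)
                & fits["converged"]).to_numpy()
        return (cls_rois.loc[good].reset_index(drop=True),
                fits.loc[good].reset_index(drop=True))

    # the defocus scan only needs a bounded number of coverslip dyes;
    # subsample before the (costly) fits
    if glass_sel.sum() > config.max_glass_refs:
        idx = np.nonzero(glass_sel)[0]
        drop = rng.choice(idx, len(idx) - config.max_glass_refs,
                          replace=False)
        glass_sel = glass_sel.copy()
        glass_sel[drop] = False

    glass_rois, glass_fits = _fit_class(glass_sel, glass_sample)
    fib_rois, fib_fits = _fit_class(fibril_sel, mid_sample)

    # NOTE: all PSF refits below must run in the raw (drifted) camera
    # frame the ROIs were cut in; drift correction is applied to the
    # lateral coordinates only afterwards, for the geometry steps.
    plane = fb.fit_reference_plane_and_defocus(
        glass_rois, glass_fits, system, glass_sample,
        scan_range=config.defocus_scan)
    system_cal = replace(system, defocus=plane.fitted_defocus)

    if len(fib_fits) < 2 * config.window_nlocs:
        raise ValueError("too few fibril localizations for the analysis")

    # refit the fibril dye heights for every assumed refractive index,
    # with the layer held at the AFM height of the fibril
    z_cols = {}
    for n_val in config.n_grid:
        sample = LayeredSample(n_layer=float(n_val), thickness=h_fibril)
        z = lc.refit_z(fib_rois, fib_fits, system_cal, sample,
                       z_bounds=(max(h_fibril - 400.0, -50.0),
                                 h_fibril + 600.0))
        col = f"z@{n_val:.3f}"
        fib_fits[col] = z - plane.evaluate(fib_fits["x_nm"],
                                           fib_fits["y_nm"])
        z_cols[n_val] = col

    if not fiducial_tracks.empty:
        fib_fits, drift_rms = fb.correct_drift(fib_fits, fiducial_tracks)
    else:
        drift_rms = float("nan")

    if afm_wet is not None:
        # the dense AFM topography defines the axis far more precisely
        # than the sparse localization cloud; register it to the cloud
        # by the median lateral offset (drift correction leaves a
        # constant translation).  Both modalities then share one axis
        # and its residual error cancels in the height comparison.
        from rimap.afm import ridge_axis

        geom_axis = ridge_axis(afm_wet, axis_hint)
        cs0 = fb.transform_to_cross_section(fib_fits, geom_axis)
        x_med = float(cs0["X"].median())
        mean_nrm = fb.FibrilAxis.normal(geom_axis, geom_axis.s).mean(axis=0)
        axis = fb.FibrilAxis(s=geom_axis.s,
                             points=geom_axis.points + x_med * mean_nrm,
                             tangents=geom_axis.tangents,
                             step=geom_axis.step)
    else:
        axis = fb.fit_fibril_axis(fib_fits)
    n_ref = config.n_grid[len(config.n_grid) // 2]
    fib_fits["z_nm"] = fib_fits[z_cols[n_ref]]
    cs_raw = fb.transform_to_cross_section(fib_fits, axis)
    cs, _removed = fb.filter_outliers(cs_raw, eps=config.dbscan_eps,
                                      min_samples=config.dbscan_min_samples)

    # when the AFM map is available, re-derive its crest height with the
    # same fitted axis used for the SMLM cross sections: lateral errors
    # of the axis then smear both modalities alike and cancel in the
    # intersection (the input estimate still fixed the layer thickness)
    area_wet0 = None
    if afm_wet is not None:
        # lateral localization error smears the SMLM cross section; blur
        # the AFM one to match so the crest comparison is like-for-like
        from rimap.precision import fisher_information_param
        from rimap.optics import EmitterState

        med_emitter = EmitterState(
            axial_position=h_fibril,
            signal_photons=float(fib_fits["photons"].median()),
            background_per_pixel=float(fib_fits["background"].median()))
        fi_x = fisher_information_param(system_cal, mid_sample,
                                        med_emitter, "x")
        sigma_lat = 1.0 / np.sqrt(fi_x) if fi_x > 0 else 0.0
        if np.isfinite(drift_rms):
            sigma_lat = float(np.hypot(sigma_lat, drift_rms))
        fi_z = fisher_information_param(system_cal, mid_sample,
                                        med_emitter, "z")
        sigma_ax = 1.0 / np.sqrt(fi_z) if fi_z > 0 else 0.0
        h_afm_estimate, area_wet0, _ = afm_fibril_profile(
            afm_wet, axis, window_nlocs=config.window_nlocs,
            n_resamples=max(config.n_resamples // 4, 50),
            lateral_blur=sigma_lat, axial_noise=sigma_ax, rng=rng)

    heights = []
    for n_val in config.n_grid:
        sub = cs[["X"]].copy()
        sub["Z"] = cs[z_cols[n_val]].to_numpy(dtype=float)
        heights.append(fb.estimate_height(
            sub, config.window_nlocs, debris_offset=config.debris_offset,
            n_assumed=n_val, n_resamples=config.n_resamples, rng=rng))
    # the reference-plane level shifts every H_SMLM(n) together, exactly
    # like an error on the AFM height: add it to that term of the budget
    plane_se = plane.prediction_se(float(fib_fits["x_nm"].mean()),
                                   float(fib_fits["y_nm"].mean()))
    h_afm_eff = fb.HeightEstimate(
        H=h_afm_estimate.H,
        sigma_H=float(np.hypot(h_afm_estimate.sigma_H, plane_se)),
        n_assumed=h_afm_estimate.n_assumed,
        window_nlocs=h_afm_estimate.window_nlocs)
    ri = fb.estimate_refractive_index(heights, h_afm_eff,
                                      n_draws=config.n_draws, rng=rng)

    area_wet = area_wet0
    area_dry = None
    swelling = None
    if afm_dry is not None:
        _, area_dry, _ = afm_fibril_profile(
            afm_dry, axis, window_nlocs=config.window_nlocs)
    if afm_dry is not None:
        _, area_dry, _ = afm_fibril_profile(afm_dry, axis,
                                            window_nlocs=config.window_nlocs)
    if area_wet is not None and area_dry is not None:
        swelling = fb.swelling_and_dry_index(area_dry, area_wet, ri.n)

    return FibrilReport(
        ri=ri, heights=heights, h_afm=h_afm_estimate, axis=axis,
        fitted_defocus=plane.fitted_defocus, drift_residual_rms=drift_rms,
        n_fibril_locs=int(len(fib_fits)), n_glass_locs=int(len(glass_fits)),
        cross_sections=cs, area_wet=area_wet, area_dry=area_dry,
        swelling=swelling)
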