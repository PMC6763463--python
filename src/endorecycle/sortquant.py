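"""Mask-based quantification of photoactivated cargo sorting and recycling.

The incorporation readout follows the masking recipe of the original assay:
threshold the photoactivated-cargo channel to obtain an "endosomal cargo"
mask, threshold the compartment-marker channel to obtain the Rab-compartment
mask, and report per frame

    percent(t) = 100 * sum(PA intensity in PA-mask ∩ marker-mask)
                     / sum(PA intensity in PA-mask)

so the denominator is the *endosomal* photoactivated signal, not whole-image
signal (a whole-image denominator is available as an option). Background is
subtracted before summing; masks are recomputed per frame by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from skimage.filters import gaussian, threshold_otsu
from skimage.morphology import dilation, disk, remove_small_objects

from .core import AnalysisConfig, BinaryMaskSeries, IntensityTrace, RegionOfInterest, TimeLapseMovie

__all__ = [
    "RegressionFit",
    "segment_endosomes",
    "endosomal_incorporation_trace",
    "exit_slope",
    "half_maximal_time",
    "total_recycling_halftime",
    "format_minutes_seconds",
    "plasma_membrane_recycling_trace",
    "window_mean",
]


@dataclass
class RegressionFit:
    """Ordinary least-squares line fit of an intensity trace segment."""

    slope: float  # units of value per second
    intercept: float
    slope_se: float
    n_points: int
    window: tuple[float, float]

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValueError("regression needs >= 3 points")
        if self.slope_se < 0:
            raise ValueError("slope_se must be >= 0")


def segment_endosomes(
    image: np.ndarray,
    cfg: AnalysisConfig | None = None,
    *,
    smooth_sigma_px: float = 1.0,
    noise_cap_sigma: float | None = None,
    log_domain: bool = True,
) -> np.ndarray:
    """Threshold one frame into an endosome mask.

    Otsu by default (a constant image has no Otsu threshold and raises) or a
    fixed value; the image is lightly smoothed before thresholding and
    objects smaller than ``cfg.min_object_px`` are removed. Otsu is computed
    in the log-intensity domain, which keeps the threshold between background
    and the dimmest structures when bright aggregates stretch the histogram.
    ``noise_cap_sigma`` additionally caps the threshold at the robust
    background level plus that many noise SDs — useful for channels whose
    foreground spans a large dynamic range (dim free vesicles next to bright
    clusters), where even log-domain Otsu drifts above the dimmest spots.
    """
    cfg = cfg or AnalysisConfig()
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("empty image")
    work = gaussian(image, sigma=smooth_sigma_px, preserve_range=True) if smooth_sigma_px > 0 else image
    if cfg.threshold_method == "otsu":
        if np.ptp(work) == 0:
            raise ValueError("constant image: Otsu threshold undefined; use a fixed threshold")
        if log_domain:
            # normalising by the median before the log keeps the threshold
            # equivariant under uniform intensity rescaling
            scale = float(np.median(work))
            scale = scale if scale > 0 else float(work[work > 0].min())
            thr = scale * float(np.expm1(threshold_otsu(np.log1p(np.clip(work, 0, None) / scale))))
        else:
            thr = float(threshold_otsu(work))
        if noise_cap_sigma is not None:
            med = float(np.median(work))
            mad = 1.4826 * float(np.median(np.abs(work - med)))
            thr = min(thr, med + noise_cap_sigma * mad)
        mask = work > thr
    else:
        mask = work >= cfg.fixed_threshold
    if cfg.min_object_px > 1:
        mask = remove_small_objects(mask, max_size=cfg.min_object_px - 1)
    return mask


def endosomal_incorporation_trace(
    movie: TimeLapseMovie,
    pa_channel: str | int,
    marker_channel: str | int,
    cfg: AnalysisConfig | None = None,
    *,
    denominator: str = "endosomal",  # "endosomal" | "whole_image"
    per_frame_threshold: bool = True,
    cell_id: str = "",
    condition: str = "",
) -> IntensityTrace:
    """Per-frame percentage of endosomal photoactivated intensity residing in
    the labelled compartment.

    Frames with an empty cargo mask give NaN, not zero; the percentage is
    invariant under uniform rescaling of the cargo channel and monotone in the
    marker mask.
    """
    cfg = cfg or AnalysisConfig()
    pa = movie.channel(pa_channel)
    mk = movie.channel(marker_channel)
    bg = _background_level(pa)

    # cargo foreground mixes dim free vesicles with bright clusters, so its
    # threshold gets the background-noise cap; the marker channel is cleanly
    # bimodal and plain Otsu holds
    if not per_frame_threshold:
        ref = int(np.argmax(pa.reshape(pa.shape[0], -1).sum(axis=1)))
        pa_mask_fixed = segment_endosomes(pa[ref], cfg, noise_cap_sigma=6.0)
        mk_mask_fixed = segment_endosomes(mk[ref], cfg)

    values = np.full(movie.n_frames, np.nan)
    for t in range(movie.n_frames):
        if per_frame_threshold:
            try:
                pa_mask = segment_endosomes(pa[t], cfg, noise_cap_sigma=6.0)
            except ValueError:
                pa_mask = np.zeros(movie.shape, dtype=bool)
            try:
                mk_mask = segment_endosomes(mk[t], cfg)
            except ValueError:
                mk_mask = np.zeros(movie.shape, dtype=bool)
        else:
            pa_mask, mk_mask = pa_mask_fixed, mk_mask_fixed
        signal = np.clip(pa[t] - bg, 0, None)
        if denominator == "whole_image":
            denom = signal.sum()
        else:
            denom = signal[pa_mask].sum()
        if denom <= 0:
            continue
        num = signal[pa_mask & mk_mask].sum()
        values[t] = 100.0 * num / denom
    if np.all(np.isnan(values)):
        raise ValueError("cargo mask empty at every frame; nothing to quantify")
    return IntensityTrace(
        times_s=movie.frame_times_s,
        values=np.clip(values, 0.0, 100.0),
        units="%",
        normalization="percent_of_endosomal",
        cell_id=cell_id,
        condition=condition,
    )


def _background_level(stack: np.ndarray) -> float:
    """Robust background estimate: median of the first frame (spots are
    sparse, so the median sits on the camera baseline)."""
    return float(np.median(stack[0]))


def exit_slope(trace: IntensityTrace, cfg: AnalysisConfig | None = None) -> RegressionFit:
    """OLS fit of trace value against time from ``cfg.regression_start_s``
    (default 50 s) to the end of the trace; slope in percent per second."""
    cfg = cfg or AnalysisConfig()
    sel = (trace.times_s >= cfg.regression_start_s) & np.isfinite(trace.values)
    t = trace.times_s[sel]
    y = trace.values[sel]
    if len(t) < 3:
        raise ValueError(
            f"need >= 3 timepoints at or after {cfg.regression_start_s} s; have {len(t)}"
        )
    res = stats.linregress(t, y)
    stderr = 0.0 if np.ptp(y - res.slope * t - res.intercept) < 1e-12 else float(res.stderr)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_se=stderr,
        n_points=len(t),
        window=(float(t[0]), float(t[-1])),
    )


def half_maximal_time(trace: IntensityTrace) -> float:
    """First time the trace crosses half of its plateau, linearly
    interpolated between the bracketing frames.

    The plateau is the mean of the final three timepoints; a trace that never
    reaches plateau/2 returns NaN ("not reached").
    """
    t = trace.times_s[np.isfinite(trace.values)]
    y = trace.values[np.isfinite(trace.values)]
    if len(y) < 3:
        raise ValueError("trace too short for a plateau estimate")
    plateau = y[-3:].mean()
    half = plateau / 2.0
    above = y >= half
    if not above.any():
        return float("nan")
    i = int(np.argmax(above))
    if i == 0:
        return float(t[0])
    y0, y1 = y[i - 1], y[i]
    if y1 == y0:
        return float(t[i])
    return float(t[i - 1] + (half - y0) / (y1 - y0) * (t[i] - t[i - 1]))


def total_recycling_halftime(t_sort_s: float, t_recycle_s: float) -> float:
    """Total half-maximal recycling time: sorting half-time into the
    recycling compartment plus compartment-to-membrane half-time."""
    if t_sort_s < 0 or t_recycle_s < 0:
        raise ValueError("half-times must be >= 0")
    return float(t_sort_s + t_recycle_s)


def format_minutes_seconds(t_s: float) -> str:
    """561.6 -> '9 min 21.6 s'."""
    minutes = int(t_s // 60)
    seconds = t_s - 60 * minutes
    sec_str = f"{seconds:.10g}"
    return f"{minutes} min {sec_str} s"


def plasma_membrane_recycling_trace(
    movie: TimeLapseMovie,
    pscfp_channel: str | int,
    cfg: AnalysisConfig | None = None,
    *,
    pm_band: RegionOfInterest | BinaryMaskSeries | np.ndarray | None = None,
    cell_outline: RegionOfInterest | None = None,
    band_width_px: int = 6,
    endosome_dilation_px: int = 2,
    cell_id: str = "",
    condition: str = "",
) -> IntensityTrace:
    """Plasma-membrane recycling readout.

    Per frame: threshold the photoactivated channel to build the
    photoactivated-endosome mask, dilate it and remove it from the channel so
    only plasma-membrane signal remains, sum the remainder within the PM
    band, and express the result as percent increase over the mean of the
    pre-activation baseline frames.
    """
    cfg = cfg or AnalysisConfig()
    ch = movie.channel(pscfp_channel)
    h, w = movie.shape

    if pm_band is None and cell_outline is None:
        raise ValueError("provide a PM band or a cell outline ROI")
    if pm_band is None:
        cell = cell_outline.to_mask((h, w))
        inner = ndimage.binary_erosion(cell, structure=disk(1), iterations=band_width_px)
        band = cell & ~inner
    elif isinstance(pm_band, RegionOfInterest):
        band = pm_band.to_mask((h, w))
    elif isinstance(pm_band, BinaryMaskSeries):
        band = pm_band.frame(0)
    else:
        band = np.asarray(pm_band, dtype=bool)
    if not band.any():
        raise ValueError("PM band mask is empty")

    first_pa = min(movie.pa_frames) if movie.pa_frames else 0
    baseline_frames = [t for t in range(first_pa) if t not in movie.pa_frames]
    if not baseline_frames:
        raise ValueError("no pre-activation baseline frames available")

    bg = _background_level(ch)
    raw = np.zeros(movie.n_frames)
    selem = disk(endosome_dilation_px) if endosome_dilation_px > 0 else None
    for t in range(movie.n_frames):
        # linear-domain Otsu: the compact photoactivated compartment is far
        # brighter per pixel than diffuse membrane signal, so the threshold
        # falls between them and the PM band survives the subtraction
        try:
            endo = segment_endosomes(ch[t], cfg, log_domain=False)
        except ValueError:
            endo = np.zeros((h, w), dtype=bool)
        if endo.any():
            # objects lying mostly within the band ARE membrane signal; only
            # predominantly intracellular objects are subtracted
            lbl, n_obj = ndimage.label(endo)
            if n_obj:
                in_band = ndimage.sum_labels(band.astype(float), lbl, index=range(1, n_obj + 1))
                sizes = ndimage.sum_labels(np.ones_like(band, dtype=float), lbl, index=range(1, n_obj + 1))
                keep_labels = np.flatnonzero(in_band / sizes > 0.5) + 1
                endo[np.isin(lbl, keep_labels)] = False
        if selem is not None and endo.any():
            endo = dilation(endo, selem)
        keep = band & ~endo
        raw[t] = np.clip(ch[t] - bg, 0, None)[keep].sum()

    base = np.mean(raw[baseline_frames])
    scale = base if base > 0 else 1.0
    values = 100.0 * (raw - base) / scale
    values[list(movie.pa_frames)] = np.nan  # photoactivation frames excluded
    return IntensityTrace(
        times_s=movie.frame_times_s,
        values=values,
        units="%",
        normalization="percent_increase_over_baseline",
        cell_id=cell_id,
        condition=condition,
    )


def window_mean(trace: IntensityTrace, t0_s: float, t1_s: float) -> float:
    """Arithmetic mean of trace values with t0 <= t <= t1 (NaNs skipped)."""
    sub = trace.window(t0_s, t1_s)
    vals = sub.values[np.isfinite(sub.values)]
    if vals.size == 0:
        raise ValueError(f"no finite values in [{t0_s}, {t1_s}] s")
    return float(vals.mean())
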