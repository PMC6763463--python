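"""Seeded synthetic time-lapse generators with ground truth.

Every assay the analysis modules quantify has a generator here that emits a
:class:`~endorecycle.core.TimeLapseMovie` together with a
:class:`SimulationTruth` record of the underlying state, so recovery can be
scored exactly:

* ``simulate_sorting_assay`` — photoactivation pulse-chase of cargo entering
  and leaving a labelled endosomal compartment (two-state continuous-time
  kinetics with rates ``k_entry``, ``k_exit``);
* ``simulate_recycling_assay`` — cargo released from a central compartment by
  a Poisson-thinned vesicle stream and deposited in a plasma-membrane band;
* ``simulate_tirf_fusion`` — TIRF-like fusion events (spot appearance,
  simultaneous intensity decay and lateral spread), optionally with a partner
  channel whose intensity drop marks co-fusion;
* ``simulate_group_traces`` — grouped per-cell traces diverging at a known
  time, for calibrating the divergence statistics;
* ``simulate_aggregation`` — optogenetic-style vesicle merging conserving
  total intensity.

The optical model is a 2D isotropic Gaussian PSF; the camera model is Poisson
photon noise followed by additive Gaussian read noise, both optional. All
generators are deterministic given (params, seed).
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import IntensityTrace, RegionOfInterest, TimeLapseMovie

__all__ = [
    "SortingSimParams",
    "RecyclingSimParams",
    "TirfSimParams",
    "AggregationSimParams",
    "SimulationTruth",
    "simulate_sorting_assay",
    "simulate_recycling_assay",
    "simulate_tirf_fusion",
    "simulate_group_traces",
    "simulate_aggregation",
]


# ---------------------------------------------------------------------------
# Rendering and camera model
# ---------------------------------------------------------------------------


def render_spots(
    shape: tuple[int, int],
    x: np.ndarray,
    y: np.ndarray,
    amplitude: np.ndarray | float,
    sigma: np.ndarray | float,
    out: np.ndarray | None = None,
) -> np.ndarray:
    """Additively render isotropic 2D Gaussian spots (subpixel centres).

    Each spot is evaluated on a local ±5σ window, so total rendered intensity
    is conserved to better than 0.5 % away from image edges.
    """
    h, w = shape
    img = out if out is not None else np.zeros(shape, dtype=float)
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    amp = np.broadcast_to(np.asarray(amplitude, dtype=float), x.shape)
    sig = np.broadcast_to(np.asarray(sigma, dtype=float), x.shape)
    for xi, yi, ai, si in zip(x, y, amp, sig):
        r = int(np.ceil(5 * si))
        x0, x1 = int(np.floor(xi)) - r, int(np.floor(xi)) + r + 1
        y0, y1 = int(np.floor(yi)) - r, int(np.floor(yi)) + r + 1
        x0c, x1c = max(x0, 0), min(x1, w)
        y0c, y1c = max(y0, 0), min(y1, h)
        if x0c >= x1c or y0c >= y1c:
            continue
        xs = np.arange(x0c, x1c) - xi
        ys = np.arange(y0c, y1c) - yi
        g = np.exp(-(ys[:, None] ** 2 + xs[None, :] ** 2) / (2 * si**2))
        img[y0c:y1c, x0c:x1c] += ai * g
    return img


def apply_camera_noise(
    frame: np.ndarray, rng: np.random.Generator, read_noise_sd: float, poisson: bool
) -> np.ndarray:
    """Poisson shot noise on expected photons, then Gaussian read noise,
    clipped at zero (camera output is non-negative)."""
    out = rng.poisson(np.clip(frame, 0, None)).astype(float) if poisson else frame.astype(float)
    if read_noise_sd > 0:
        out = out + rng.normal(0.0, read_noise_sd, size=out.shape)
    return np.clip(out, 0.0, None)


def _spot_amplitude(snr: float, background: float, read_noise_sd: float) -> float:
    # SNR defined as peak / sigma_background; background sigma combines shot
    # noise on the background level with read noise.
    sigma_bg = float(np.sqrt(background + read_noise_sd**2))
    return snr * sigma_bg if sigma_bg > 0 else snr


def _disc_mask(shape: tuple[int, int], cx: float, cy: float, r: float) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2


@dataclass
class SimulationTruth:
    """Ground-truth record emitted by a generator (fields filled per assay)."""

    occupancy_fraction: np.ndarray | None = None  # per-frame, in [0, 1]
    membership: np.ndarray | None = None  # (n_vesicles, n_frames) bool
    fusion_events: list[dict] = field(default_factory=list)
    divergence_time_s: float | None = None
    pm_delivered_fraction: np.ndarray | None = None  # per-frame, in [0, 1]
    initial_compartment_intensity: float | None = None
    vesicle_counts: np.ndarray | None = None
    mean_vesicle_intensity: np.ndarray | None = None
    positions: np.ndarray | None = None  # (n_frames, n_vesicles, 2) x,y; NaN = dark
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Sorting assay
# ---------------------------------------------------------------------------


@dataclass
class SortingSimParams:
    """Photoactivation pulse-chase sorting assay.

    Defaults follow the acquisition protocol of the confocal sorting
    experiments: five photoactivation pulses at 2.5 s intervals, then imaging
    every 2.5 s for 150 frames.
    """

    n_vesicles: int = 200
    k_entry_per_s: float = 0.02
    k_exit_per_s: float = 0.005
    pa_pulses: int = 5
    pa_interval_s: float = 2.5
    n_frames: int = 150
    frame_interval_s: float = 2.5
    psf_sigma_px: float = 1.5
    snr: float = 5.0
    diffusion_step_px: float = 0.6
    drift_to_centre_px_per_frame: float = 0.0
    image_size: tuple[int, int] = (160, 160)
    pixel_size_nm: float = 160.0
    n_endosomes: int = 32
    endosome_radius_px: float = 3.0
    pa_radius_px: float = 25.0
    background: float = 10.0
    read_noise_sd: float = 2.0
    noise: bool = True

    def __post_init__(self) -> None:
        if self.k_entry_per_s < 0 or self.k_exit_per_s < 0:
            raise ValueError("rates must be >= 0")
        h, w = self.image_size
        if self.n_vesicles > 0 and h * w < 25 * self.n_vesicles:
            raise ValueError("image too small for requested n_vesicles")


def simulate_sorting_assay(
    params: SortingSimParams, seed: int
) -> tuple[TimeLapseMovie, SimulationTruth]:
    """Simulate cargo photoactivated inside an ROI, then exchanging between a
    free pool and a labelled compartment with first-order rates.

    Channel 0 is the photoactivated cargo, channel 1 the compartment marker
    (a fixed field of disc-shaped endosomes). Truth records the exact
    per-frame fraction of activated vesicles residing in the compartment.
    """
    p = params
    rng = np.random.default_rng(seed)
    h, w = p.image_size
    cx, cy = w / 2.0, h / 2.0
    dt = p.frame_interval_s
    margin = 5 * p.psf_sigma_px + 1

    # static marker endosomes: discs away from the image border
    ec = rng.uniform([margin + p.endosome_radius_px] * 2,
                     [w - margin - p.endosome_radius_px, h - margin - p.endosome_radius_px],
                     size=(p.n_endosomes, 2))
    marker_img = np.zeros((h, w))
    for ex, ey in ec:
        marker_img[_disc_mask((h, w), ex, ey, p.endosome_radius_px)] = 1.0
    amp = _spot_amplitude(p.snr, p.background, p.read_noise_sd if p.noise else 0.0)
    marker_img *= amp

    # vesicle state
    n = p.n_vesicles
    act_frame = rng.integers(0, max(p.pa_pulses, 1), size=n)  # pulse each vesicle activates on
    from scipy.spatial import cKDTree

    # free vesicles are excluded from the marker discs: outside the kinetic
    # entry event a vesicle is by definition not in the compartment, so its
    # rendered spot must not sit on a marker endosome
    ec_tree = cKDTree(ec)
    excl_r = p.endosome_radius_px + 1.5

    def _free_of_endosomes(cand: np.ndarray) -> np.ndarray:
        # project points that landed on an endosome radially to just outside it
        d, which = ec_tree.query(cand, k=1)
        bad = d < excl_r
        if bad.any():
            centres = ec[which[bad]]
            vec = cand[bad] - centres
            norm = np.linalg.norm(vec, axis=1, keepdims=True)
            vec = np.where(norm > 1e-9, vec / np.maximum(norm, 1e-9), np.array([[1.0, 0.0]]))
            cand[bad] = centres + vec * (excl_r + 0.25)
        return cand

    theta = rng.uniform(0, 2 * np.pi, size=n)
    rad = p.pa_radius_px * np.sqrt(rng.uniform(0, 1, size=n))
    pos = np.column_stack([cx + rad * np.cos(theta), cy + rad * np.sin(theta)])
    for _ in range(50):  # resample starts that landed on an endosome
        d, _ = ec_tree.query(pos, k=1)
        bad = d < excl_r
        if not bad.any():
            break
        nb = int(bad.sum())
        th = rng.uniform(0, 2 * np.pi, size=nb)
        rd = p.pa_radius_px * np.sqrt(rng.uniform(0, 1, size=nb))
        pos[bad] = np.column_stack([cx + rd * np.cos(th), cy + rd * np.sin(th)])
    in_comp = np.zeros(n, dtype=bool)
    home = np.full(n, -1)  # endosome index while in compartment
    active = np.zeros(n, dtype=bool)

    p_enter = 1.0 - np.exp(-p.k_entry_per_s * dt)
    p_exit = 1.0 - np.exp(-p.k_exit_per_s * dt)

    frames = np.zeros((p.n_frames, 2, h, w))
    occupancy = np.zeros(p.n_frames)
    membership = np.zeros((n, p.n_frames), dtype=bool)
    positions = np.full((p.n_frames, n, 2), np.nan)

    for t in range(p.n_frames):
        newly = (~active) & (act_frame == t)
        active |= newly
        if t > 0:  # state update between frames (skip at activation instant)
            free = active & ~in_comp
            enter = free & (rng.uniform(size=n) < p_enter)
            if enter.any():
                # join the nearest endosome
                d2 = ((pos[enter, None, :] - ec[None, :, :]) ** 2).sum(-1)
                home[enter] = np.argmin(d2, axis=1)
                jit = rng.normal(0, p.endosome_radius_px / 6, size=(int(enter.sum()), 2))
                pos[enter] = np.clip(ec[home[enter]] + jit,
                                     ec[home[enter]] - p.endosome_radius_px / 3,
                                     ec[home[enter]] + p.endosome_radius_px / 3)
                in_comp[enter] = True
            leave = active & in_comp & ~enter & (rng.uniform(size=n) < p_exit)
            if leave.any():
                # bud out just beyond the endosome before resuming free diffusion
                idx = np.where(leave)[0]
                centres = ec[home[idx]]
                ang_out = rng.uniform(0, 2 * np.pi, size=len(idx))
                pos[idx] = centres + (excl_r + 0.25) * np.column_stack(
                    [np.cos(ang_out), np.sin(ang_out)]
                )
                in_comp[leave] = False
                home[leave] = -1
            free = active & ~in_comp
            if free.any():
                cand = pos[free] + rng.normal(0, p.diffusion_step_px, size=(int(free.sum()), 2))
                if p.drift_to_centre_px_per_frame > 0:
                    vec = np.array([cx, cy]) - cand
                    dist = np.linalg.norm(vec, axis=1, keepdims=True)
                    np.divide(vec, dist, out=vec, where=dist > 1e-9)
                    cand += p.drift_to_centre_px_per_frame * vec
                # stay fully rendered inside a margin
                cand[:, 0] = np.clip(cand[:, 0], margin, w - 1 - margin)
                cand[:, 1] = np.clip(cand[:, 1], margin, h - 1 - margin)
                pos[free] = _free_of_endosomes(cand)  # free spots stay off endosomes

        n_act = int(active.sum())
        occupancy[t] = in_comp[active].mean() if n_act else 0.0
        membership[:, t] = in_comp & active
        positions[t, active] = pos[active]

        cargo = np.full((h, w), float(p.background))
        if n_act:
            render_spots((h, w), pos[active, 0], pos[active, 1], amp, p.psf_sigma_px, out=cargo)
        mk = marker_img + p.background
        if p.noise:
            cargo = apply_camera_noise(cargo, rng, p.read_noise_sd, poisson=True)
            mk = apply_camera_noise(mk, rng, p.read_noise_sd, poisson=True)
        frames[t, 0] = cargo
        frames[t, 1] = mk

    movie = TimeLapseMovie(
        data=frames,
        channel_names=["pa_cargo", "marker"],
        pixel_size_nm=p.pixel_size_nm,
        frame_times_s=np.arange(p.n_frames) * dt,
        pa_frames=list(range(min(p.pa_pulses, p.n_frames))),
        metadata={"assay": "sorting", "seed": int(seed)},
    )
    truth = SimulationTruth(
        occupancy_fraction=occupancy,
        membership=membership,
        positions=positions,
        extras={"endosome_centres": ec, "pa_roi": {"cx": cx, "cy": cy, "r": p.pa_radius_px},
                "spot_amplitude": amp, "activation_frame": act_frame},
    )
    return movie, truth


def occupancy_closed_form(t_s: np.ndarray, k_entry: float, k_exit: float) -> np.ndarray:
    """Analytic two-state occupancy starting from the free state:
    P(in compartment at t) = k_in/(k_in+k_out) * (1 - exp(-(k_in+k_out) t))."""
    t_s = np.asarray(t_s, dtype=float)
    k = k_entry + k_exit
    if k == 0:
        return np.zeros_like(t_s)
    return (k_entry / k) * (1.0 - np.exp(-k * t_s))


# ---------------------------------------------------------------------------
# Recycling assay
# ---------------------------------------------------------------------------


@dataclass
class RecyclingSimParams:
    """Two-photon pulse-chase recycling assay.

    Defaults follow the two-photon protocol (photoactivation every 30 s for
    10 consecutive cycles) with a chase long enough to cover the 900–1200 s
    plateau window.
    """

    recycled_fraction: float = 0.5
    delivery_rate_per_s: float = np.log(2) / 375.0  # half-delivery at ~375 s
    n_quanta: int = 60
    n_baseline_frames: int = 3
    pa_pulses: int = 10
    frame_interval_s: float = 30.0
    n_frames: int = 48
    compartment_radius_px: float = 8.0
    pm_band_inner_px: float = 50.0
    pm_band_outer_px: float = 56.0
    transit_frames: int = 1
    pm_baseline_fraction: float = 0.25  # resident PM signal, as fraction of I0
    aggregated: bool = False
    agg_factor: int = 6
    psf_sigma_px: float = 1.5
    image_size: tuple[int, int] = (128, 128)
    pixel_size_nm: float = 160.0
    total_intensity: float = 2.0e5
    background: float = 10.0
    read_noise_sd: float = 2.0
    noise: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.recycled_fraction <= 1:
            raise ValueError("recycled_fraction must lie in [0, 1]")
        if self.delivery_rate_per_s < 0:
            raise ValueError("delivery rate must be >= 0")


def simulate_recycling_assay(
    params: RecyclingSimParams, seed: int
) -> tuple[TimeLapseMovie, SimulationTruth]:
    """Simulate photoactivated cargo leaving a central compartment and being
    deposited in a plasma-membrane band.

    The recycled portion of the compartment intensity is split into
    ``n_quanta`` vesicle quanta whose departure times are i.i.d. exponential
    with ``delivery_rate_per_s`` (a Poisson-thinned stream); each quantum
    transits as a moving spot and then joins the PM band. In ``aggregated``
    mode quanta are merged in groups of ``agg_factor`` that depart together
    as single bright clusters. Truth records the cumulative PM-delivered
    fraction at every frame.
    """
    p = params
    rng = np.random.default_rng(seed)
    h, w = p.image_size
    cx, cy = w / 2.0, h / 2.0
    times = np.arange(p.n_frames) * p.frame_interval_s
    t_pa0 = times[p.n_baseline_frames] if p.n_baseline_frames < p.n_frames else 0.0
    pa_frames = list(range(p.n_baseline_frames, min(p.n_baseline_frames + p.pa_pulses, p.n_frames)))

    comp_mask = _disc_mask((h, w), cx, cy, p.compartment_radius_px)
    yy, xx = np.mgrid[0:h, 0:w]
    rr = np.sqrt((xx - cx) ** 2 + (yy - cy) ** 2)
    pm_mask = (rr >= p.pm_band_inner_px) & (rr <= p.pm_band_outer_px)

    i0 = p.total_intensity
    q = p.recycled_fraction * i0 / p.n_quanta
    # departure clocks start at the first photoactivation frame
    dep = t_pa0 + rng.exponential(1.0 / p.delivery_rate_per_s, size=p.n_quanta) \
        if p.delivery_rate_per_s > 0 else np.full(p.n_quanta, np.inf)
    if p.aggregated:
        n_groups = max(1, p.n_quanta // p.agg_factor)
        group = rng.integers(0, n_groups, size=p.n_quanta)
        gdep = t_pa0 + rng.exponential(1.0 / p.delivery_rate_per_s, size=n_groups) \
            if p.delivery_rate_per_s > 0 else np.full(n_groups, np.inf)
        dep = gdep[group]
    arr_t = dep + p.transit_frames * p.frame_interval_s  # arrival at the PM
    ang = rng.uniform(0, 2 * np.pi, size=p.n_quanta)

    frames = np.zeros((p.n_frames, 2, h, w))
    delivered = np.zeros(p.n_frames)
    marker_img = np.where(comp_mask, _spot_amplitude(5.0, p.background, p.read_noise_sd if p.noise else 0.0), 0.0)

    comp_px = max(int(comp_mask.sum()), 1)
    pm_px = max(int(pm_mask.sum()), 1)
    pm_base = p.pm_baseline_fraction * i0 / pm_px
    for t, tt in enumerate(times):
        cargo = np.full((h, w), float(p.background))
        cargo[pm_mask] += pm_base  # resident plasma-membrane signal
        if tt >= t_pa0:
            in_comp_int = i0 - q * float((dep <= tt).sum())
            pm_int = q * float((arr_t <= tt).sum())
            delivered[t] = pm_int / i0
            cargo[comp_mask] += in_comp_int / comp_px
            cargo[pm_mask] += pm_int / pm_px
            transiting = (dep <= tt) & (arr_t > tt)
            if transiting.any():
                frac = np.clip((tt - dep[transiting]) / (arr_t[transiting] - dep[transiting]), 0, 1)
                rad = p.compartment_radius_px + frac * (p.pm_band_inner_px - p.compartment_radius_px)
                sx = cx + rad * np.cos(ang[transiting])
                sy = cy + rad * np.sin(ang[transiting])
                norm = 2 * np.pi * p.psf_sigma_px**2
                render_spots((h, w), sx, sy, q / norm, p.psf_sigma_px, out=cargo)
        mk = marker_img + p.background
        if p.noise:
            cargo = apply_camera_noise(cargo, rng, p.read_noise_sd, poisson=True)
            mk = apply_camera_noise(mk, rng, p.read_noise_sd, poisson=True)
        frames[t, 0] = cargo
        frames[t, 1] = mk

    movie = TimeLapseMovie(
        data=frames,
        channel_names=["pa_cargo", "marker"],
        pixel_size_nm=p.pixel_size_nm,
        frame_times_s=times,
        pa_frames=pa_frames,
        metadata={"assay": "recycling", "seed": int(seed)},
    )
    truth = SimulationTruth(
        pm_delivered_fraction=delivered,
        initial_compartment_intensity=i0,
        extras={
            "pm_band": {"inner_px": p.pm_band_inner_px, "outer_px": p.pm_band_outer_px},
            "compartment": {"cx": cx, "cy": cy, "r": p.compartment_radius_px},
            "departure_times_s": dep,
        },
    )
    return movie, truth


# ---------------------------------------------------------------------------
# TIRF fusion assay
# ---------------------------------------------------------------------------


@dataclass
class TirfSimParams:
    """TIRF fusion-event movie: spot appearances with simultaneous intensity
    decay and lateral spread, at a 200 ms frame interval by default."""

    event_rate_per_min: float = 2.0
    duration_s: float = 600.0
    frame_interval_s: float = 0.2
    cofusion_fraction: float = 0.6
    snr: float = 8.0
    decay_tau_s: float = 1.0
    spread_rate_per_s: float = 0.6  # fractional PSF width growth per second
    event_frames: int = 10  # rendered profile length
    partner_drop_fraction: float = 0.5
    psf_sigma_px: float = 1.3
    image_size: tuple[int, int] = (64, 64)
    pixel_size_nm: float = 100.0
    background: float = 10.0
    read_noise_sd: float = 2.0
    noise: bool = True

    def __post_init__(self) -> None:
        if self.event_rate_per_min < 0:
            raise ValueError("event_rate_per_min must be >= 0")
        if not 0 <= self.cofusion_fraction <= 1:
            raise ValueError("cofusion_fraction must lie in [0, 1]")


def simulate_tirf_fusion(
    params: TirfSimParams, seed: int
) -> tuple[TimeLapseMovie, SimulationTruth]:
    """Simulate plasma-membrane fusion events in a two-channel TIRF movie.

    Events arrive as a Poisson process; each renders as a Gaussian spot whose
    peak decays exponentially while its width grows linearly. Every event
    carries a coincident partner-channel spot; for co-fusion events the
    partner peak falls by ``partner_drop_fraction`` over the profile, for the
    rest it stays constant. Truth lists (frame, x, y, partner_present).
    """
    p = params
    rng = np.random.default_rng(seed)
    h, w = p.image_size
    n_frames = int(round(p.duration_s / p.frame_interval_s))
    n_events = rng.poisson(p.event_rate_per_min * p.duration_s / 60.0)
    margin = 6 * p.psf_sigma_px
    usable = max(n_frames - p.event_frames - 1, 1)
    onset = np.sort(rng.integers(0, usable, size=n_events))
    ex = rng.uniform(margin, w - 1 - margin, size=n_events)
    ey = rng.uniform(margin, h - 1 - margin, size=n_events)
    is_co = rng.uniform(size=n_events) < p.cofusion_fraction
    amp = _spot_amplitude(p.snr, p.background, p.read_noise_sd if p.noise else 0.0)

    frames = np.zeros((n_frames, 2, h, w))
    events = [
        {"frame": int(f), "x": float(x), "y": float(y), "partner_present": bool(c)}
        for f, x, y, c in zip(onset, ex, ey, is_co)
    ]
    for t in range(n_frames):
        cargo = np.full((h, w), float(p.background))
        partner = np.full((h, w), float(p.background))
        for ev, co in zip(events, is_co):
            dt_fr = t - ev["frame"]
            if 0 <= dt_fr < p.event_frames:
                dts = dt_fr * p.frame_interval_s
                a = amp * np.exp(-dts / p.decay_tau_s)
                s = p.psf_sigma_px * (1.0 + p.spread_rate_per_s * dts)
                render_spots((h, w), ev["x"], ev["y"], a, s, out=cargo)
                frac = dt_fr / max(p.event_frames - 1, 1)
                drop = p.partner_drop_fraction if co else 0.0
                ap = amp * (1.0 - drop * frac)
                render_spots((h, w), ev["x"], ev["y"], ap, p.psf_sigma_px, out=partner)
        if p.noise:
            cargo = apply_camera_noise(cargo, rng, p.read_noise_sd, poisson=True)
            partner = apply_camera_noise(partner, rng, p.read_noise_sd, poisson=True)
        frames[t, 0] = cargo
        frames[t, 1] = partner

    movie = TimeLapseMovie(
        data=frames,
        channel_names=["cargo", "partner"],
        pixel_size_nm=p.pixel_size_nm,
        frame_times_s=np.arange(n_frames) * p.frame_interval_s,
        metadata={"assay": "tirf_fusion", "seed": int(seed)},
    )
    truth = SimulationTruth(fusion_events=events, extras={"spot_amplitude": amp})
    return movie, truth


# ---------------------------------------------------------------------------
# Grouped traces with a known divergence time
# ---------------------------------------------------------------------------


def simulate_group_traces(
    n_per_group: int,
    divergence_time_s: float,
    effect_size_sd: float,
    noise_sd: float,
    times_s: np.ndarray,
    seed: int,
    baseline: np.ndarray | None = None,
) -> tuple[list[IntensityTrace], list[IntensityTrace], SimulationTruth]:
    """Two groups of per-cell traces on a common time grid.

    Group A follows ``baseline`` plus i.i.d. Gaussian noise; group B is
    identical before ``divergence_time_s`` and shifted by
    ``effect_size_sd * noise_sd`` afterwards. ``divergence_time_s = inf``
    gives exchangeable (null) groups.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    rng = np.random.default_rng(seed)
    times_s = np.asarray(times_s, dtype=float)
    if baseline is None:
        baseline = np.full_like(times_s, 50.0)
    shift = np.where(times_s >= divergence_time_s, effect_size_sd * noise_sd, 0.0)

    def make(group: str, offset: np.ndarray) -> list[IntensityTrace]:
        return [
            IntensityTrace(
                times_s=times_s,
                values=baseline + offset + rng.normal(0, noise_sd, size=times_s.shape),
                units="%",
                cell_id=f"{group}{i}",
                condition=group,
            )
            for i in range(n_per_group)
        ]

    a = make("A", np.zeros_like(times_s))
    b = make("B", shift)
    return a, b, SimulationTruth(divergence_time_s=float(divergence_time_s))


# ---------------------------------------------------------------------------
# Optogenetic-style aggregation
# ---------------------------------------------------------------------------


@dataclass
class AggregationSimParams:
    """Vesicles merging in groups of ``merge_factor`` at ``switch_frame``,
    conserving total intensity."""

    n_vesicles: int = 40
    merge_factor: int = 4
    switch_frame: int = 10
    n_frames: int = 20
    frame_interval_s: float = 30.0
    snr: float = 8.0
    psf_sigma_px: float = 1.5
    image_size: tuple[int, int] = (128, 128)
    pixel_size_nm: float = 160.0
    background: float = 10.0
    read_noise_sd: float = 2.0
    noise: bool = True

    def __post_init__(self) -> None:
        if self.merge_factor < 1:
            raise ValueError("merge_factor must be >= 1")


def simulate_aggregation(
    params: AggregationSimParams, seed: int
) -> tuple[TimeLapseMovie, SimulationTruth]:
    """Simulate blue-light-induced vesicle aggregation: at the switch frame,
    vesicles merge in groups of ``merge_factor`` into single spots whose
    amplitude is the group sum. Remainder vesicles (when ``merge_factor``
    does not divide ``n_vesicles``) stay unmerged with a warning."""
    p = params
    rng = np.random.default_rng(seed)
    h, w = p.image_size
    margin = 6 * p.psf_sigma_px
    rem = p.n_vesicles % p.merge_factor
    if rem:
        warnings.warn(
            f"merge_factor {p.merge_factor} does not divide n_vesicles {p.n_vesicles}; "
            f"{rem} vesicles left unmerged",
            stacklevel=2,
        )
    amp = _spot_amplitude(p.snr, p.background, p.read_noise_sd if p.noise else 0.0)

    # jittered grid keeps spots well separated for unambiguous detection
    side = int(np.ceil(np.sqrt(p.n_vesicles)))
    gx = np.linspace(margin, w - 1 - margin, side)
    gy = np.linspace(margin, h - 1 - margin, side)
    gxx, gyy = np.meshgrid(gx, gy)
    cells = np.column_stack([gxx.ravel(), gyy.ravel()])[: p.n_vesicles]
    pos = cells + rng.uniform(-1.0, 1.0, size=cells.shape)

    # merge spatially adjacent vesicles (grid order) so merged clusters stay
    # well separated
    n_groups = p.n_vesicles // p.merge_factor
    merged_pos = []
    merged_amp = []
    for g in range(n_groups):
        idx = np.arange(g * p.merge_factor, (g + 1) * p.merge_factor)
        merged_pos.append(pos[idx].mean(axis=0))
        merged_amp.append(amp * len(idx))
    for i in range(n_groups * p.merge_factor, p.n_vesicles):
        merged_pos.append(pos[i])
        merged_amp.append(amp)
    merged_pos = np.asarray(merged_pos).reshape(-1, 2)
    merged_amp = np.asarray(merged_amp)

    frames = np.zeros((p.n_frames, 1, h, w))
    counts = np.zeros(p.n_frames, dtype=int)
    mean_int = np.zeros(p.n_frames)
    norm = 2 * np.pi * p.psf_sigma_px**2  # integrated intensity of a unit-amplitude PSF
    for t in range(p.n_frames):
        img = np.full((h, w), float(p.background))
        if t < p.switch_frame:
            render_spots((h, w), pos[:, 0], pos[:, 1], amp, p.psf_sigma_px, out=img)
            counts[t] = p.n_vesicles
            mean_int[t] = amp * norm
        else:
            render_spots((h, w), merged_pos[:, 0], merged_pos[:, 1], merged_amp, p.psf_sigma_px, out=img)
            counts[t] = len(merged_amp)
            mean_int[t] = merged_amp.mean() * norm
        if p.noise:
            img = apply_camera_noise(img, rng, p.read_noise_sd, poisson=True)
        frames[t, 0] = img

    movie = TimeLapseMovie(
        data=frames,
        channel_names=["marker"],
        pixel_size_nm=p.pixel_size_nm,
        frame_times_s=np.arange(p.n_frames) * p.frame_interval_s,
        metadata={"assay": "aggregation", "seed": int(seed)},
    )
    truth = SimulationTruth(
        vesicle_counts=counts,
        mean_vesicle_intensity=mean_int,
        positions=np.broadcast_to(pos[None], (p.n_frames, p.n_vesicles, 2)).copy(),
        extras={"merged_positions": merged_pos, "merged_amplitudes": merged_amp,
                "spot_amplitude": amp},
    )
    return movie, truth
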