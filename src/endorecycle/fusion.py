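"""TIRF fusion-event detection, co-fusion classification and rate summaries.

An event is a spot that (a) appears — no detection within 1 px over the
preceding lookback frames, (b) peaks above ``k`` sigma of the local
background, and (c) behaves like fusion within the confirmation window:
fitted Gaussian width grows by >= 20 % or the peak decays below 50 % of its
maximum. This formalises what is otherwise a blinded visual call, so the
criteria are deliberately simple and every threshold sits in the config.

Co-fusion follows the >15 % rule: an event carried the partner protein if
the mean of the last three frames' maximum partner intensity falls more than
``cofusion_drop_fraction`` below the initial frame's maximum, measured in a
fixed window about the event position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import AnalysisConfig, TimeLapseMovie
from .vesicles import detect_vesicles

__all__ = [
    "FusionEvent",
    "detect_fusion_events",
    "classify_cofusion",
    "fusion_rate",
    "cofusion_fraction",
]


@dataclass
class FusionEvent:
    onset_frame: int
    x: float
    y: float
    intensity_profile: np.ndarray  # per-frame max in a fixed window, event channel
    partner_profile: np.ndarray | None = None
    cofusion: bool | None = None
    widths_px: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.intensity_profile = np.asarray(self.intensity_profile, dtype=float)
        if self.partner_profile is not None:
            self.partner_profile = np.asarray(self.partner_profile, dtype=float)
            if len(self.partner_profile) != len(self.intensity_profile):
                raise ValueError("profiles must be frame-aligned")
        if len(self.intensity_profile) < 4:
            raise ValueError("profile needs the initial frame plus >= 3 more")


def _window_max(frame: np.ndarray, x: float, y: float, r: int, bg: float) -> float:
    h, w = frame.shape
    xi, yi = int(round(x)), int(round(y))
    y0, y1 = max(yi - r, 0), min(yi + r + 1, h)
    x0, x1 = max(xi - r, 0), min(xi + r + 1, w)
    return float(frame[y0:y1, x0:x1].max() - bg)


def _gaussian_width(frame: np.ndarray, x: float, y: float, r: int, bg: float) -> float:
    """Second-moment width estimate of a spot in a window (sigma, px)."""
    h, w = frame.shape
    xi, yi = int(round(x)), int(round(y))
    y0, y1 = max(yi - r, 0), min(yi + r + 1, h)
    x0, x1 = max(xi - r, 0), min(xi + r + 1, w)
    win = np.clip(frame[y0:y1, x0:x1] - bg, 0, None)
    tot = win.sum()
    if tot <= 0:
        return 0.0
    yy, xx = np.mgrid[y0:y1, x0:x1]
    cx = (win * xx).sum() / tot
    cy = (win * yy).sum() / tot
    var = ((win * ((xx - cx) ** 2 + (yy - cy) ** 2)).sum() / tot) / 2.0
    return float(np.sqrt(max(var, 0.0)))


def detect_fusion_events(
    movie: TimeLapseMovie,
    channel: str | int,
    cfg: AnalysisConfig | None = None,
    *,
    partner_channel: str | int | None = None,
    profile_frames: int = 10,
) -> list[FusionEvent]:
    """Detect candidate plasma-membrane fusion events in one channel.

    Frames inside ``cfg.bleach_prefix_s`` are skipped. Each event carries a
    per-frame maximum-intensity profile (fixed window, not re-centred) for
    the event channel and, when given, the partner channel; co-fusion is
    classified immediately when a partner channel is supplied.
    """
    cfg = cfg or AnalysisConfig()
    stack = movie.channel(channel)
    partner = movie.channel(partner_channel) if partner_channel is not None else None
    n = movie.n_frames
    lookback = cfg.fusion_absence_lookback
    confirm = cfg.fusion_confirm_frames
    if n < lookback + confirm:
        raise ValueError("movie shorter than lookback + confirmation window")

    bg = float(np.median(stack[0]))
    bg_p = float(np.median(partner[0])) if partner is not None else 0.0
    # robust intensity noise level for the peak criterion (b)
    sigma_bg = 1.4826 * float(np.median(np.abs(stack[0] - bg))) + 1e-12
    r = cfg.fusion_window_radius_px
    start = int(np.searchsorted(movie.frame_times_s, cfg.bleach_prefix_s, side="left"))
    start = max(start, lookback)

    dets_per_frame = [detect_vesicles(stack[t], cfg, frame=t) for t in range(n)]
    events: list[FusionEvent] = []
    claimed: list[tuple[int, float, float]] = []  # (frame, x, y) of accepted events

    h, w = stack.shape[1:]
    border = r + 2  # the measurement window must fit inside the frame
    for t in range(start, n - confirm):
        for det in dets_per_frame[t]:
            if not (border <= det.x <= w - 1 - border and border <= det.y <= h - 1 - border):
                continue
            # (a) appearance: nothing within 1 px over the lookback frames
            appeared = True
            for tb in range(max(t - lookback, 0), t):
                for prev in dets_per_frame[tb]:
                    if abs(prev.x - det.x) <= 1.0 and abs(prev.y - det.y) <= 1.0:
                        appeared = False
                        break
                if not appeared:
                    break
            if not appeared:
                continue
            # skip re-detections of an already-claimed event
            if any(
                abs(t - cf) <= profile_frames and (det.x - cx) ** 2 + (det.y - cy) ** 2 <= 9.0
                for cf, cx, cy in claimed
            ):
                continue
            # (c) fusion behaviour inside the confirmation window
            w0 = _gaussian_width(stack[t], det.x, det.y, r, bg)
            peak0 = _window_max(stack[t], det.x, det.y, r, bg)
            # (b) peak must clear k sigma of the background noise
            if peak0 < cfg.detection_threshold_sigma * sigma_bg:
                continue
            # single-frame noise spikes vanish immediately; a fusing vesicle
            # is still bright on the next frame
            if _window_max(stack[t + 1], det.x, det.y, r, bg) < 0.4 * peak0:
                continue
            confirmed = False
            for dt in range(1, confirm + 1):
                wdt = _gaussian_width(stack[t + dt], det.x, det.y, r + 2, bg)
                pdt = _window_max(stack[t + dt], det.x, det.y, r, bg)
                if (w0 > 0 and wdt >= 1.2 * w0) or pdt < 0.5 * peak0:
                    confirmed = True
                    break
            if not confirmed:
                continue
            n_prof = min(profile_frames, n - t)
            prof = np.array([_window_max(stack[t + k], det.x, det.y, r, bg) for k in range(n_prof)])
            pprof = (
                np.array([_window_max(partner[t + k], det.x, det.y, r, bg_p) for k in range(n_prof)])
                if partner is not None
                else None
            )
            widths = np.array([_gaussian_width(stack[t + k], det.x, det.y, r + 2, bg) for k in range(n_prof)])
            if n_prof < 4:
                continue
            ev = FusionEvent(
                onset_frame=t, x=det.x, y=det.y,
                intensity_profile=prof, partner_profile=pprof, widths_px=widths,
            )
            if pprof is not None:
                ev.cofusion = classify_cofusion(ev, cfg)
            events.append(ev)
            claimed.append((t, det.x, det.y))
    return events


def classify_cofusion(event: FusionEvent, cfg: AnalysisConfig | None = None) -> bool | None:
    """Apply the >15 % drop rule to the partner profile.

    Returns True when (I_init - mean of last three maxima) / I_init exceeds
    ``cfg.cofusion_drop_fraction`` strictly; None (unclassifiable) when the
    initial maximum is not positive.
    """
    cfg = cfg or AnalysisConfig()
    if event.partner_profile is None:
        raise ValueError("event has no partner profile")
    prof = event.partner_profile
    if len(prof) < 4:
        raise ValueError("partner profile needs the initial frame plus >= 3 more")
    i0 = prof[0]
    if i0 <= 0:
        return None
    drop = (i0 - prof[-3:].mean()) / i0
    return bool(drop > cfg.cofusion_drop_fraction)


def fusion_rate(events: list[FusionEvent], observation_duration_s: float) -> float:
    """Events per minute over the observation duration."""
    if observation_duration_s <= 0:
        raise ValueError("observation duration must be > 0")
    return 60.0 * len(events) / observation_duration_s


def cofusion_fraction(events: list[FusionEvent]) -> float:
    """Percentage of classified events with cofusion=True; unclassifiable
    (None) events are excluded from numerator and denominator."""
    classified = [e for e in events if e.cofusion is not None]
    if not classified:
        raise ValueError("no classified events")
    return 100.0 * sum(e.cofusion for e in classified) / len(classified)
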