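"""Visual stimulus battery for object-motion-sensitivity experiments.

Every stimulus is rendered as a discretized space-time intensity array
(:class:`StimulusClip`) on a square field of view centered on the recorded
cell's soma, together with a machine-readable event table from which all
downstream analysis windows can be reconstructed.

Conventions
-----------
* intensity is unitless in [0, 1] with a mean (background) level of 0.5
* spatial coordinates are in micrometers, origin at the field center
* Michelson contrast ``c`` modulates intensity as ``mean * (1 +/- c)``
* all generators are deterministic; pseudorandom choices take a seed
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "StimulusClip",
    "GratingSpec",
    "make_spot_series",
    "make_split_field",
    "make_counterphase_annulus",
    "make_texture_motion",
    "make_moving_bar",
    "make_drifting_grating",
    "make_white_noise",
    "white_noise_sequence",
]

# Field-of-view defaults (display geometry is not a measured quantity; these
# are generous relative to the widest receptive-field components analyzed).
DEFAULT_FOV_UM = 1200.0
DEFAULT_PIXEL_PITCH_UM = 2.0
DEFAULT_FRAME_RATE_HZ = 60.0
DEFAULT_MEAN_INTENSITY = 0.5
#: static lead-in before stimulus onset; the last 0.5 s serve as baseline
DEFAULT_LEAD_IN_S = 1.5


@dataclass
class StimulusClip:
    """A space-time intensity movie plus its epoch/event table.

    Attributes
    ----------
    frames : ndarray, shape (t, y, x)
        Intensity in [0, 1], float32.
    frame_rate : float
        Frames per second.
    pixel_pitch : float
        Micrometers per pixel (square pixels).
    mean_intensity : float
        Background / time-average intensity level.
    events : list of (label, start_s, end_s)
        Sorted, non-overlapping epochs; instantaneous events have
        ``start_s == end_s``.
    meta : dict
        Free-form generator metadata (e.g. white-noise clip fraction).
    """

    frames: np.ndarray
    frame_rate: float
    pixel_pitch: float
    mean_intensity: float = DEFAULT_MEAN_INTENSITY
    events: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.float32)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (t, y, x) array")
        lo, hi = float(self.frames.min(initial=0.0)), float(self.frames.max(initial=1.0))
        if lo < -1e-6 or hi > 1 + 1e-6:
            raise ValueError(f"intensities outside [0, 1]: min={lo}, max={hi}")
        self.events = sorted((str(l), float(a), float(b)) for l, a, b in self.events)
        for l, a, b in self.events:
            if b < a:
                raise ValueError(f"event {l!r} ends before it starts")

    # ------------------------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate

    def times(self) -> np.ndarray:
        """Frame onset times in seconds."""
        return np.arange(self.n_frames) / self.frame_rate

    def grid(self) -> tuple[np.ndarray, np.ndarray]:
        """(y, x) pixel-center coordinates in micrometers, origin at center."""
        ny, nx = self.frames.shape[1:]
        y = (np.arange(ny) - (ny - 1) / 2.0) * self.pixel_pitch
        x = (np.arange(nx) - (nx - 1) / 2.0) * self.pixel_pitch
        return y, x

    def frame_means(self) -> np.ndarray:
        return self.frames.reshape(self.n_frames, -1).mean(axis=1)

    def event_window(self, label: str) -> tuple[float, float]:
        for l, a, b in self.events:
            if l == label:
                return (a, b)
        raise KeyError(f"no event labeled {label!r}")

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.events, columns=["label", "start_s", "end_s"])

    # ------------------------------------------------------------------
    # on-disk round trip
    def to_npz(self, path) -> None:
        labels = np.array([e[0] for e in self.events], dtype=object)
        starts = np.array([e[1] for e in self.events])
        ends = np.array([e[2] for e in self.events])
        np.savez_compressed(
            path, frames=self.frames, frame_rate=self.frame_rate,
            pixel_pitch=self.pixel_pitch, mean_intensity=self.mean_intensity,
            event_labels=labels, event_starts=starts, event_ends=ends,
        )

    @classmethod
    def from_npz(cls, path) -> "StimulusClip":
        with np.load(path, allow_pickle=True) as z:
            events = list(zip(z["event_labels"].tolist(),
                              z["event_starts"].tolist(), z["event_ends"].tolist()))
            return cls(frames=z["frames"], frame_rate=float(z["frame_rate"]),
                       pixel_pitch=float(z["pixel_pitch"]),
                       mean_intensity=float(z["mean_intensity"]), events=events)

    def to_hdf5(self, group: "h5py.Group | str") -> None:
        own = isinstance(group, str)
        h = h5py.File(group, "w") if own else group
        try:
            h.create_dataset("frames", data=self.frames, compression="gzip")
            h.attrs["frame_rate"] = self.frame_rate
            h.attrs["pixel_pitch"] = self.pixel_pitch
            h.attrs["mean_intensity"] = self.mean_intensity
            ev = h.create_group("events")
            ev.create_dataset("label", data=np.array([e[0] for e in self.events], dtype="S64"))
            ev.create_dataset("start_s", data=[e[1] for e in self.events])
            ev.create_dataset("end_s", data=[e[2] for e in self.events])
        finally:
            if own:
                h.close()

    @classmethod
    def from_hdf5(cls, group: "h5py.Group | str") -> "StimulusClip":
        own = isinstance(group, str)
        h = h5py.File(group, "r") if own else group
        try:
            ev = h["events"]
            events = list(zip([s.decode() for s in ev["label"][()]],
                              ev["start_s"][()].tolist(), ev["end_s"][()].tolist()))
            return cls(frames=h["frames"][()], frame_rate=float(h.attrs["frame_rate"]),
                       pixel_pitch=float(h.attrs["pixel_pitch"]),
                       mean_intensity=float(h.attrs["mean_intensity"]), events=events)
        finally:
            if own:
                h.close()

    def events_to_csv(self, path) -> None:
        self.events_frame().to_csv(path, index=False)


@dataclass
class GratingSpec:
    """Parameters of a contrast-reversing or moving square-wave grating."""

    bar_width: float
    temporal_frequency: float = 2.0
    contrast: float = 0.9
    phase: float = 0.0
    region: str = "full"  # {center, surround, full}
    annulus_gap: float = 25.0

    def __post_init__(self):
        if self.bar_width <= 0:
            raise ValueError("bar_width must be positive")
        if not 0.0 <= self.contrast <= 1.0:
            raise ValueError("contrast must lie in [0, 1]")
        if self.region not in {"center", "surround", "full"}:
            raise ValueError(f"unknown region {self.region!r}")


# ----------------------------------------------------------------------
# helpers


def _geometry(fov_um, pixel_pitch, frame_rate):
    n = int(round(fov_um / pixel_pitch))
    y = (np.arange(n) - (n - 1) / 2.0) * pixel_pitch
    x = y.copy()
    return n, y[:, None], x[None, :], 1.0 / frame_rate


def _square_wave(phase_cycles: np.ndarray) -> np.ndarray:
    """+1 on the first half of each cycle, -1 on the second."""
    return np.where((phase_cycles % 1.0) < 0.5, 1.0, -1.0)


def _lead_in_events(lead_in_s):
    if lead_in_s > 0:
        return [("baseline", max(0.0, lead_in_s - 0.5), lead_in_s)]
    return []


# ----------------------------------------------------------------------
# stimulus classes


def make_spot_series(
    radii,
    period_s: float = 4.0,
    contrast: float = 0.96,
    order_seed: int = 0,
    n_cycles: int = 2,
    *,
    fov_um: float = DEFAULT_FOV_UM,
    pixel_pitch: float = DEFAULT_PIXEL_PITCH_UM,
    frame_rate: float = DEFAULT_FRAME_RATE_HZ,
    mean_intensity: float = DEFAULT_MEAN_INTENSITY,
    lead_in_s: float = DEFAULT_LEAD_IN_S,
):
    """Square-wave modulated spots of varying radius (area-response battery).

    Luminance in a circular area is stepped to ``mean*(1+contrast)`` for the
    first half of each period (ON) and ``mean*(1-contrast)`` for the second
    (OFF); the default 4-s period gives 2 s ON / 2 s OFF.  Spots are returned
    in a pseudorandom order derived from ``order_seed``, and the first spot
    of the sequence is repeated at the end as a recording-stability check.

    Returns a list of :class:`StimulusClip`, one per presentation.
    """
    radii = [float(r) for r in radii]
    if len(set(radii)) != len(radii) or any(r <= 0 for r in radii):
        raise ValueError("radii must be positive and unique")
    for r in radii:
        if 2 * r > fov_um:
            raise ValueError(f"spot radius {r} um exceeds the {fov_um} um field of view")
    rng = np.random.default_rng(order_seed)
    order = [radii[i] for i in rng.permutation(len(radii))]
    order.append(order[0])  # stability check

    n, yy, xx, dt = _geometry(fov_um, pixel_pitch, frame_rate)
    rr2 = yy**2 + xx**2
    clips = []
    n_lead = int(round(lead_in_s * frame_rate))
    n_mod = int(round(n_cycles * period_s * frame_rate))
    t_mod = (np.arange(n_mod)) * dt
    on_level = mean_intensity * (1 + contrast)
    off_level = mean_intensity * (1 - contrast)
    for r in order:
        disc = rr2 <= r * r
        frames = np.full((n_lead + n_mod, n, n), mean_intensity, dtype=np.float32)
        level = np.where((t_mod % period_s) < period_s / 2, on_level, off_level)
        frames[n_lead:, disc] = level[:, None].astype(np.float32)
        events = _lead_in_events(lead_in_s)
        for k in range(n_cycles):
            t0 = lead_in_s + k * period_s
            events.append(("spot_on", t0, t0 + period_s / 2))
            events.append(("spot_off", t0 + period_s / 2, t0 + period_s))
        clip = StimulusClip(frames, frame_rate, pixel_pitch, mean_intensity, events,
                            meta={"radius_um": r, "contrast": contrast, "period_s": period_s})
        clips.append(clip)
    return clips


def _split_offset(bias_fraction: float, radius: float) -> float:
    """x-position of the chord dividing a disc so the left part has the
    given area fraction."""
    if abs(bias_fraction - 0.5) < 1e-12:
        return 0.0

    def seg(a):  # area left of x=a, disc of radius R centered 0
        return (radius**2 * np.arccos(-a / radius)
                + a * np.sqrt(radius**2 - a**2)) - np.pi * radius**2 * (1 - bias_fraction)

    return brentq(seg, -radius * (1 - 1e-9), radius * (1 - 1e-9))


def make_split_field(
    bias_fraction: float = 0.5,
    temporal_frequency: float = 2.0,
    diameter: float = 200.0,
    contrast: float = 0.9,
    duration_s: float = 3.0,
    *,
    fov_um: float = DEFAULT_FOV_UM,
    pixel_pitch: float = DEFAULT_PIXEL_PITCH_UM,
    frame_rate: float = DEFAULT_FRAME_RATE_HZ,
    mean_intensity: float = DEFAULT_MEAN_INTENSITY,
    lead_in_s: float = DEFAULT_LEAD_IN_S,
) -> StimulusClip:
    """Sinusoidal split-field stimulus over the receptive-field center.

    A disc of the given diameter is divided by a vertical chord into two
    regions whose intensities are modulated by anti-phase sinusoids.  With
    ``bias_fraction=0.5`` the areas are equal and the stimulus is
    luminance-neutral; a biased split leaves a net luminance modulation
    proportional to ``2*bias_fraction - 1``.
    """
    if not 0.0 < bias_fraction < 1.0:
        raise ValueError("bias_fraction must lie strictly in (0, 1)")
    radius = diameter / 2.0
    n, yy, xx, dt = _geometry(fov_um, pixel_pitch, frame_rate)
    disc = (yy**2 + xx**2) <= radius**2
    x0 = _split_offset(bias_fraction, radius)
    left = disc & (np.broadcast_to(xx, disc.shape) <= x0)
    right = disc & ~left

    n_lead = int(round(lead_in_s * frame_rate))
    n_mod = int(round(duration_s * frame_rate))
    t = np.arange(n_mod) * dt
    mod = contrast * mean_intensity * np.sin(2 * np.pi * temporal_frequency * t)
    frames = np.full((n_lead + n_mod, n, n), mean_intensity, dtype=np.float32)
    frames[n_lead:, left] = (mean_intensity + mod)[:, None].astype(np.float32)
    frames[n_lead:, right] = (mean_intensity - mod)[:, None].astype(np.float32)
    events = _lead_in_events(lead_in_s) + [("modulation", lead_in_s, lead_in_s + duration_s)]
    return StimulusClip(frames, frame_rate, pixel_pitch, mean_intensity, events,
                        meta={"bias_fraction": bias_fraction, "diameter_um": diameter,
                              "temporal_frequency": temporal_frequency, "contrast": contrast})


def make_counterphase_annulus(
    bar_width: float = 50.0,
    inner_r: float = 100.0,
    outer_r: float = 300.0,
    temporal_frequency: float = 2.0,
    contrast: float = 0.9,
    duration_s: float = 3.0,
    spatial_phase_um: float = 0.0,
    *,
    fov_um: float = DEFAULT_FOV_UM,
    pixel_pitch: float = DEFAULT_PIXEL_PITCH_UM,
    frame_rate: float = DEFAULT_FRAME_RATE_HZ,
    mean_intensity: float = DEFAULT_MEAN_INTENSITY,
    lead_in_s: float = DEFAULT_LEAD_IN_S,
) -> StimulusClip:
    """Counterphase square-wave grating restricted to a surround annulus.

    Adjacent bars (width ``bar_width``) are sinusoidally modulated in
    anti-phase; with the default spatial phase the bar pattern is odd about
    the field center, so the annulus-mean intensity is constant over time.
    """
    if bar_width <= 0:
        raise ValueError("bar_width must be positive")
    if outer_r <= inner_r:
        raise ValueError("outer_r must exceed inner_r")
    if bar_width > 2 * outer_r:
        raise ValueError("bar_width must not exceed the annulus diameter")
    n, yy, xx, dt = _geometry(fov_um, pixel_pitch, frame_rate)
    rr2 = yy**2 + xx**2
    annulus = (rr2 >= inner_r**2) & (rr2 <= outer_r**2)
    # odd square wave: sign(sin(pi x / bar_width)) -> exact +/- area balance
    sq = np.sign(np.sin(np.pi * (np.broadcast_to(xx, annulus.shape) - spatial_phase_um)
                        / bar_width))
    sq = np.where(sq == 0, 1.0, sq)

    n_lead = int(round(lead_in_s * frame_rate))
    n_mod = int(round(duration_s * frame_rate))
    t = np.arange(n_mod) * dt
    mod = contrast * mean_intensity * np.sin(2 * np.pi * temporal_frequency * t)
    frames = np.full((n_lead + n_mod, n, n), mean_intensity, dtype=np.float32)
    pattern = sq[annulus]
    frames[n_lead:, annulus] = (mean_intensity
                                + mod[:, None] * pattern[None, :]).astype(np.float32)
    events = _lead_in_events(lead_in_s) + [("modulation", lead_in_s, lead_in_s + duration_s)]
    return StimulusClip(frames, frame_rate, pixel_pitch, mean_intensity, events,
                        meta={"bar_width_um": bar_width, "inner_r_um": inner_r,
                              "outer_r_um": outer_r, "temporal_frequency": temporal_frequency,
                              "contrast": contrast})


TEXTURE_SEGMENTS = ("global", "diff_center", "diff_surround")


def make_texture_motion(
    segment: str,
    bar_width: float = 50.0,
    gap: float = 25.0,
    speed: float = 400.0,
    center_radius: float = 100.0,
    surround_outer: float | None = None,
    contrast: float = 0.9,
    duration_s: float = 2.0,
    *,
    fov_um: float = DEFAULT_FOV_UM,
    pixel_pitch: float = DEFAULT_PIXEL_PITCH_UM,
    frame_rate: float = DEFAULT_FRAME_RATE_HZ,
    mean_intensity: float = DEFAULT_MEAN_INTENSITY,
    lead_in_s: float = DEFAULT_LEAD_IN_S,
) -> StimulusClip:
    """Differential / global texture-motion stimulus.

    Two square-wave gratings, one over the receptive-field center and one
    over the surround, separated by a gray annulus of width ``gap``, are
    translated horizontally.  ``segment`` selects which gratings move:
    ``global`` (both, in unison), ``diff_center`` (center only) or
    ``diff_surround`` (surround only).  Static gratings are shown during the
    lead-in so motion onset, not pattern onset, drives responses.
    """
    if segment not in TEXTURE_SEGMENTS:
        raise ValueError(f"unknown segment {segment!r}; expected one of {TEXTURE_SEGMENTS}")
    n, yy, xx, dt = _geometry(fov_um, pixel_pitch, frame_rate)
    rr2 = yy**2 + xx**2
    if surround_outer is None:
        surround_outer = fov_um / 2.0
    center = rr2 <= center_radius**2
    surround = (rr2 >= (center_radius + gap) ** 2) & (rr2 <= surround_outer**2)

    n_lead = int(round(lead_in_s * frame_rate))
    n_mod = int(round(duration_s * frame_rate))
    n_tot = n_lead + n_mod
    t = np.arange(n_tot) * dt
    disp = np.zeros(n_tot)
    disp[n_lead:] = (t[n_lead:] - t[n_lead]) * speed
    move_center = segment in ("global", "diff_center")
    move_surround = segment in ("global", "diff_surround")

    x = np.broadcast_to(xx, center.shape)
    frames = np.full((n_tot, n, n), mean_intensity, dtype=np.float32)
    amp = contrast * mean_intensity
    xc, xs = x[center], x[surround]
    def sq(x):  # odd square wave: balances exactly on the centered grid
        s = np.sign(np.sin(np.pi * x / bar_width))
        return np.where(s == 0, 1.0, s)

    for i in range(n_tot):
        dc = disp[i] if move_center else 0.0
        ds = disp[i] if move_surround else 0.0
        frames[i][center] = mean_intensity + amp * sq(xc - dc)
        frames[i][surround] = mean_intensity + amp * sq(xs - ds)
    events = _lead_in_events(lead_in_s) + [(segment, lead_in_s, lead_in_s + duration_s)]
    return StimulusClip(frames, frame_rate, pixel_pitch, mean_intensity, events,
                        meta={"segment": segment, "bar_width_um": bar_width, "gap_um": gap,
                              "speed_um_s": speed, "center_radius_um": center_radius,
                              "contrast": contrast})


def make_moving_bar(
    height: float = 200.0,
    width: float = 800.0,
    speed: float = 400.0,
    polarity: str = "dark",
    contrast: float = 0.96,
    margin_um: float = 50.0,
    *,
    fov_um: float = DEFAULT_FOV_UM,
    pixel_pitch: float = DEFAULT_PIXEL_PITCH_UM,
    frame_rate: float = DEFAULT_FRAME_RATE_HZ,
    mean_intensity: float = DEFAULT_MEAN_INTENSITY,
    lead_in_s: float = 1.0,
) -> StimulusClip:
    """A bar sweeping horizontally across the full field.

    ``height`` is the bar's vertical extent (perpendicular to motion, the
    "edge length" that drives surround suppression); ``width`` its extent
    along the motion axis, long by default so leading- and trailing-edge
    responses separate in time.  The event table records the times at which
    each edge crosses the field center.
    """
    if speed <= 0:
        raise ValueError("speed must be positive")
    if polarity not in ("dark", "light"):
        raise ValueError("polarity must be 'dark' or 'light'")
    n, yy, xx, dt = _geometry(fov_um, pixel_pitch, frame_rate)
    level = mean_intensity * (1 - contrast if polarity == "dark" else 1 + contrast)

    # leading edge starts margin_um left of the field; bar exits on the right
    x_start = -fov_um / 2.0 - margin_um
    travel = fov_um + width + 2 * margin_um
    n_lead = int(round(lead_in_s * frame_rate))
    n_mov = int(np.ceil(travel / speed * frame_rate)) + 1
    n_tot = n_lead + n_mov
    in_band = np.abs(yy[:, 0]) <= height / 2.0
    frames = np.full((n_tot, n, n), mean_intensity, dtype=np.float32)
    x = xx[0]
    for i in range(n_mov):
        lead_x = x_start + speed * i * dt
        inside = (x <= lead_x) & (x >= lead_x - width)
        if inside.any():
            frames[n_lead + i][np.ix_(in_band, inside)] = level
    t0 = lead_in_s
    t_le = t0 + (0.0 - x_start) / speed
    t_te = t_le + width / speed
    events = _lead_in_events(lead_in_s) + [
        ("bar", t0, t0 + travel / speed),
        ("leading_edge", t_le, t_le),
        ("trailing_edge", t_te, t_te),
    ]
    return StimulusClip(frames, frame_rate, pixel_pitch, mean_intensity, events,
                        meta={"height_um": height, "width_um": width, "speed_um_s": speed,
                              "polarity": polarity, "contrast": contrast})


def make_drifting_grating(
    direction_deg: float,
    temporal_frequency: float = 2.0,
    spatial_period: float = 200.0,
    contrast: float = 0.9,
    duration_s: float = 2.0,
    *,
    fov_um: float = DEFAULT_FOV_UM,
    pixel_pitch: float = DEFAULT_PIXEL_PITCH_UM,
    frame_rate: float = DEFAULT_FRAME_RATE_HZ,
    mean_intensity: float = DEFAULT_MEAN_INTENSITY,
    lead_in_s: float = DEFAULT_LEAD_IN_S,
) -> StimulusClip:
    """Full-field sine grating drifting in the given direction."""
    n, yy, xx, dt = _geometry(fov_um, pixel_pitch, frame_rate)
    th = np.deg2rad(direction_deg)
    proj = (xx * np.cos(th) + yy * np.sin(th)) / spatial_period  # cycles
    n_lead = int(round(lead_in_s * frame_rate))
    n_mod = int(round(duration_s * frame_rate))
    n_tot = n_lead + n_mod
    frames = np.empty((n_tot, n, n), dtype=np.float32)
    frames[:n_lead] = mean_intensity
    amp = contrast * mean_intensity
    for i in range(n_mod):
        ph = temporal_frequency * i * dt
        frames[n_lead + i] = mean_intensity + amp * np.sin(2 * np.pi * (proj - ph))
    events = _lead_in_events(lead_in_s) + [("drift", lead_in_s, lead_in_s + duration_s)]
    return StimulusClip(frames, frame_rate, pixel_pitch, mean_intensity, events,
                        meta={"direction_deg": direction_deg,
                              "temporal_frequency": temporal_frequency,
                              "spatial_period_um": spatial_period, "contrast": contrast})


def white_noise_sequence(refresh_hz, rms_contrast, duration_s, seed,
                         mean_intensity=DEFAULT_MEAN_INTENSITY):
    """Gaussian intensity sequence, clipped to [0, 1].

    Returns (sequence, clip_fraction).  RMS contrast is the standard
    deviation of the pre-clipping draw expressed as a fraction of the mean.
    """
    if rms_contrast >= 1.0:
        raise ValueError("rms_contrast must be < 1")
    rng = np.random.default_rng(seed)
    n = int(round(refresh_hz * duration_s))
    seq = rng.normal(mean_intensity, rms_contrast * mean_intensity, size=n)
    clip_fraction = float(np.mean((seq < 0) | (seq > 1)))
    return np.clip(seq, 0.0, 1.0), clip_fraction


def make_white_noise(
    refresh_hz: float = 30.0,
    rms_contrast: float = 0.4,
    duration_s: float = 600.0,
    region: str = "center",
    seed: int = 0,
    center_radius: float = 100.0,
    annulus: tuple = (125.0, 300.0),
    *,
    fov_um: float = DEFAULT_FOV_UM,
    pixel_pitch: float = DEFAULT_PIXEL_PITCH_UM,
    frame_rate: float | None = None,
    mean_intensity: float = DEFAULT_MEAN_INTENSITY,
) -> StimulusClip:
    """Spatially uniform Gaussian white-noise stimulus.

    A single circular (``region='center'``) or annular
    (``region='surround_annulus'``) area is set to a fresh normal draw at
    every refresh.  The frame rate defaults to the refresh rate so each
    frame holds one independent intensity value; if a faster frame rate is
    requested it must be an integer multiple of the refresh rate.
    """
    if region not in ("center", "surround_annulus"):
        raise ValueError(f"unknown region {region!r}")
    if frame_rate is None:
        frame_rate = refresh_hz
    hold = frame_rate / refresh_hz
    if abs(hold - round(hold)) > 1e-9:
        raise ValueError("refresh_hz must divide frame_rate")
    hold = int(round(hold))
    seq, clip_fraction = white_noise_sequence(refresh_hz, rms_contrast, duration_s, seed,
                                              mean_intensity)
    n, yy, xx, _ = _geometry(fov_um, pixel_pitch, frame_rate)
    rr2 = yy**2 + xx**2
    if region == "center":
        mask = rr2 <= center_radius**2
    else:
        mask = (rr2 >= annulus[0] ** 2) & (rr2 <= annulus[1] ** 2)
    frames = np.full((len(seq) * hold, n, n), mean_intensity, dtype=np.float32)
    frames[:, mask] = np.repeat(seq, hold)[:, None].astype(np.float32)
    events = [("noise", 0.0, len(seq) / refresh_hz)]
    return StimulusClip(frames, frame_rate, pixel_pitch, mean_intensity, events,
                        meta={"refresh_hz": refresh_hz, "rms_contrast": rms_contrast,
                              "seed": seed, "region": region,
                              "clip_fraction": clip_fraction, "sequence": seq})
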