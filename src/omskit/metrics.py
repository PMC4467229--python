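"""Response amplitude, harmonic, and tuning statistics for epoched traces.

Amplitudes are baseline-subtracted window means.  Depolarizations,
inward-current increases (after conversion to conductance) and spike-rate
increases are positive; hyperpolarizations and suppression below baseline
are reported as negative values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .traces import EpochedTrace

__all__ = [
    "HarmonicResult",
    "MotionResponseSet",
    "epoch_amplitude",
    "peak_window_amplitude",
    "current_to_conductance",
    "harmonic_amplitudes",
    "dsi",
    "motion_selectivity",
    "edge_amplitude",
    "size_tuning",
    "speed_tuning",
]

#: default analysis window length (s); the measurement convention uses
#: windows in the 100-200 ms range
DEFAULT_WINDOW_S = 0.15
#: interval after an edge center-crossing searched for the response peak
EDGE_SEARCH_S = 0.35


@dataclass
class HarmonicResult:
    """Fourier amplitudes at the fundamental (F1) and second harmonic (F2)."""

    f1_amplitude: float
    f2_amplitude: float
    f1_hz: float

    @property
    def f2_hz(self) -> float:
        return 2.0 * self.f1_hz

    @property
    def f1_power(self) -> float:
        return self.f1_amplitude**2

    @property
    def f2_power(self) -> float:
        return self.f2_amplitude**2

    @property
    def f2_over_f1(self) -> float:
        return self.f2_amplitude / self.f1_amplitude


@dataclass
class MotionResponseSet:
    """Signed response amplitudes to the three texture-motion segments."""

    global_amp: float
    diff_center_amp: float
    diff_surround_amp: float
    modality: str = "voltage_mV"


def epoch_amplitude(trace: EpochedTrace, window, baseline_window=None) -> float:
    """Baseline-subtracted mean of the trace over ``window`` (start_s, end_s).

    The baseline defaults to the trace's own baseline window.
    """
    if baseline_window is None:
        baseline_window = trace.baseline_window
    return trace.window_mean(window) - trace.window_mean(baseline_window)


def peak_window_amplitude(trace: EpochedTrace, segment, width: float = DEFAULT_WINDOW_S,
                          signed: bool = True) -> float:
    """Amplitude of the strongest ``width``-long window within a segment.

    The window is slid across ``segment`` (a (start_s, end_s) tuple or an
    event label) and placed where the absolute baseline-subtracted mean is
    largest; the signed value there is returned, so suppression below
    baseline comes out negative.
    """
    if isinstance(segment, str):
        segment = trace.event_window(segment)
    start, end = segment
    if end - start < width:
        raise ValueError("segment shorter than the analysis window")
    x = trace.slice(start, end)
    w = max(1, int(round(width * trace.rate)))
    kern = np.ones(w) / w
    means = np.convolve(x, kern, mode="valid")
    dev = means - trace.baseline_mean()
    i = int(np.argmax(np.abs(dev)))
    return float(dev[i]) if signed else float(abs(dev[i]))


def current_to_conductance(trace: EpochedTrace, holding_mV: float,
                           reversal_mV: float) -> EpochedTrace:
    """Convert a voltage-clamp current trace (pA) to conductance (nS).

    ``g(t) = I(t) / (holding - reversal)``; with physiological sign
    conventions (inward currents negative at hyperpolarized holding) the
    result is non-negative.  mV and pA give nS directly.
    """
    if holding_mV == reversal_mV:
        raise ValueError("holding and reversal potentials must differ")
    if trace.modality != "current_pA":
        raise ValueError("expected a current_pA trace")
    g = trace.samples / (holding_mV - reversal_mV)
    return trace.with_samples(g, modality="conductance_nS")


def conductance_to_current(trace: EpochedTrace, holding_mV: float,
                           reversal_mV: float) -> EpochedTrace:
    """Inverse of :func:`current_to_conductance` (exact round trip)."""
    if holding_mV == reversal_mV:
        raise ValueError("holding and reversal potentials must differ")
    return trace.with_samples(trace.samples * (holding_mV - reversal_mV),
                              modality="current_pA")


def harmonic_amplitudes(trace, fundamental_hz: float, window=None) -> HarmonicResult:
    """Fourier amplitudes at the stimulus frequency (F1) and its double (F2).

    The analyzed stretch is truncated to the largest whole number of
    fundamental periods.  ``trace`` may be an :class:`EpochedTrace` or a
    plain (samples, rate) pair.  The amplitude convention is that of a real
    sinusoid: ``A*sin(2*pi*f*t)`` yields F1 = A.
    """
    if isinstance(trace, EpochedTrace):
        x = trace.slice(*window) if window is not None else trace.samples
        rate = trace.rate
    else:
        x, rate = np.asarray(trace[0], dtype=float), float(trace[1])
    period = int(round(rate / fundamental_hz))
    n_periods = len(x) // period
    if n_periods < 1:
        raise ValueError("trace shorter than one fundamental period")
    x = x[: n_periods * period]
    t = np.arange(len(x)) / rate

    def amp(f):
        z = np.mean(x * np.exp(-2j * np.pi * f * t))
        return 2.0 * abs(z)

    return HarmonicResult(f1_amplitude=amp(fundamental_hz),
                          f2_amplitude=amp(2 * fundamental_hz), f1_hz=fundamental_hz)


def dsi(f1_by_direction) -> float:
    """Direction selectivity index ``|sum F1(theta) e^{i theta}| / sum F1(theta)``.

    ``f1_by_direction`` holds non-negative F1 amplitudes at equally spaced
    directions starting at 0 deg (8 directions at 45 deg spacing in the
    standard battery).
    """
    a = np.asarray(f1_by_direction, dtype=float)
    if np.any(a < 0):
        raise ValueError("F1 amplitudes must be non-negative")
    total = a.sum()
    if total == 0:
        raise ValueError("DSI undefined for all-zero amplitudes")
    theta = np.arange(len(a)) * 2 * np.pi / len(a)
    return float(np.abs(np.sum(a * np.exp(1j * theta))) / total)


def motion_selectivity(traces_by_segment: dict, width: float = DEFAULT_WINDOW_S
                       ) -> MotionResponseSet:
    """Signed amplitudes for global / differential-center / differential-
    surround texture motion, all measured with the same peak-window rule."""
    required = ("global", "diff_center", "diff_surround")
    missing = [s for s in required if s not in traces_by_segment]
    if missing:
        raise ValueError(f"missing texture-motion segments: {missing}")
    amps = {s: peak_window_amplitude(traces_by_segment[s], s, width=width)
            for s in required}
    modality = traces_by_segment["global"].modality
    return MotionResponseSet(global_amp=amps["global"],
                             diff_center_amp=amps["diff_center"],
                             diff_surround_amp=amps["diff_surround"],
                             modality=modality)


def edge_amplitude(trace: EpochedTrace, edge: str = "leading_edge",
                   width: float = DEFAULT_WINDOW_S, latency: "float | str" = "auto",
                   signed: bool = False) -> float:
    """Response amplitude at a bar-edge center crossing.

    With ``latency='auto'`` the analysis window is placed at the response
    peak within ``EDGE_SEARCH_S`` after the geometric crossing time; a
    float places the window center at crossing + latency.
    """
    t_cross, _ = trace.event_window(edge)
    if latency == "auto":
        return peak_window_amplitude(trace, (t_cross, min(t_cross + EDGE_SEARCH_S,
                                                          trace.duration_s)),
                                     width=width, signed=signed)
    center = t_cross + float(latency)
    return epoch_amplitude(trace, (center - width / 2, center + width / 2))


def size_tuning(traces_by_height: dict, edge: str = "leading_edge",
                width: float = DEFAULT_WINDOW_S,
                ref_heights=(200.0, 600.0)):
    """Edge-response amplitudes vs bar height and the suppression index.

    Returns ``(table, suppression_index)`` where the table has one row per
    (height, edge) and ``suppression_index = 1 - amp(600) / amp(200)`` for
    the requested edge (reference heights configurable).
    """
    rows = []
    for h, tr in sorted(traces_by_height.items()):
        for e in ("leading_edge", "trailing_edge"):
            try:
                amp = edge_amplitude(tr, e, width=width)
            except KeyError:
                raise ValueError(f"trace for height {h} lacks {e} event") from None
            rows.append({"height_um": float(h), "edge": e, "amplitude": amp})
    table = pd.DataFrame(rows)
    small, large = ref_heights
    for h in ref_heights:
        if float(h) not in set(table["height_um"]):
            raise ValueError(f"size tuning requires a {h} um bar")

    def amp_at(h):
        sel = (table["height_um"] == h) & (table["edge"] == edge)
        return float(table.loc[sel, "amplitude"].iloc[0])

    index = 1.0 - amp_at(float(large)) / amp_at(float(small))
    return table, index


def speed_tuning(traces_by_speed: dict, width: float = DEFAULT_WINDOW_S) -> pd.DataFrame:
    """Edge-response amplitudes keyed by (speed, edge)."""
    rows = []
    for v, tr in sorted(traces_by_speed.items()):
        for e in ("leading_edge", "trailing_edge"):
            try:
                amp = edge_amplitude(tr, e, width=width)
            except KeyError:
                raise ValueError(f"trace for speed {v} lacks {e} event") from None
            rows.append({"speed_um_s": float(v), "edge": e, "amplitude": amp})
    return pd.DataFrame(rows)
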