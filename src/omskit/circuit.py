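"""Rectified-subunit circuit model of the object-motion-detection pathway.

The model implements the inferred circuit motif: mosaics of small,
half-wave-rectified bipolar-cell subunits (separate ON and OFF lattices)
drive three downstream elements —

* a spiking wide-field amacrine population that pools subunit output over
  a large Gaussian and fires only above a threshold (silenced by the
  ``ttx`` switch);
* the VG3 amacrine cell, whose excitatory conductance is a center-Gaussian
  pool of subunit output reduced by presynaptic wide-field inhibition, and
  whose inhibitory conductance is postsynaptic wide-field input; its
  membrane potential is a quasi-static conductance mix relaxed by a
  first-order membrane filter;
* the W3 ganglion cell, which receives a configurable share of its
  excitation from delayed, threshold-rectified VG3 release (removed by the
  ``vglut3_ko`` switch) and the rest from a direct bipolar pool, plus
  wide-field inhibition, and emits spikes as an inhomogeneous Poisson
  process with an absolute refractory period.

All pooling widths default to 1-SD radii of the measured receptive-field
components (e.g. ON excitatory center sigma 68.5 um from a 137-um 1-SD
diameter; ON inhibition sigma 129 um from 258 um).  Subunit spacing
defaults to 25 um so that counterphase gratings of 25-um bars average out
within single subunits while 50-um bars do not, reproducing the step-like
rise of frequency-doubled surround inhibition between those bar widths.
"""

from __future__ import annotations

import shutil
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter
from scipy.signal import fftconvolve, lfilter

from .stimulus import StimulusClip
from .traces import EpochedTrace

__all__ = [
    "CircuitParams",
    "BipolarDrive",
    "default_kernel",
    "bipolar_layer",
    "wide_field_ac",
    "simulate_vg3",
    "simulate_w3",
    "generate_experiment",
]


def default_kernel(rate_hz: float = 60.0, duration_s: float = 0.5,
                   tau_peak_s: float = 0.02, tau_trough_s: float = 0.045,
                   order: int = 3) -> np.ndarray:
    """Biphasic, zero-DC temporal kernel (difference of gamma bumps).

    The zero integral makes subunit responses transient: steps evoke a
    response that decays back to zero, matching the transient ON/OFF
    behavior of the bipolar input.  The positive lobe is normalized to
    unit time-integral, so a sustained unit-contrast step produces a peak
    drive of order one.
    """
    t = np.arange(0.0, duration_s, 1.0 / rate_hz)
    bump = lambda tau: (t / tau) ** order * np.exp(-t / tau)  # noqa: E731
    pos, neg = bump(tau_peak_s), bump(tau_trough_s)
    k = pos / pos.sum() - neg / neg.sum()  # zero DC
    k = k / (np.clip(k, 0, None).sum() / rate_hz)  # unit positive-lobe area
    return k


@dataclass
class CircuitParams:
    """Parameters of the rectified-subunit circuit.

    Spatial scales are in micrometers, times in the units stated, and
    synaptic drive in the dimensionless units produced by the unit-area
    temporal kernels (a sustained unit-contrast step gives peak drive ~1).
    """

    # bipolar subunit lattice
    subunit_spacing: float = 25.0
    subunit_sigma: float = 12.5
    kernel_on: np.ndarray | None = None
    kernel_off: np.ndarray | None = None
    kernel_rate_hz: float = 60.0
    gain_off_over_on: float = 1.5
    rectified: bool = True  # diagnostic switch: False = linear subunits

    # VG3 excitatory center pooling (1-SD radii of measured RF components)
    center_sigma_on: float = 68.5
    center_sigma_off: float = 41.55
    # wide-field amacrine pooling: a single collapsed pooling stage must be
    # wider than the composite inhibitory receptive field it mimics, or
    # center stimulation would recruit as much inhibition as surround
    # stimulation does
    wac_sigma_on: float = 150.0
    wac_sigma_off: float = 150.0
    wac_threshold: float = 0.06
    presyn_inhibition_weight: float = 3.0
    postsyn_inhibition_weight: float = 3.0

    # VG3 membrane
    resting_mV: float = -38.0
    tau_membrane_ms: float = 20.0
    g_leak_nS: float = 1.0
    e_exc_mV: float = 0.0
    e_inh_mV: float = -60.0
    exc_gain_nS: float = 6.0
    inh_gain_nS: float = 6.0

    # VG3 -> W3 synapse
    vg3_release_threshold_mV: float = -37.0
    vg3_to_w3_delay_ms: float = 10.0
    w3_vg3_weight: float = 0.5
    w3_direct_weight: float = 0.5
    w3_center_sigma: float = 58.0
    #: gains scaling each pathway to comparable conductance units; the
    #: release gain is calibrated so both pathways contribute equal
    #: differential-center EPSC amplitude at equal weights
    vg3_release_gain: float = 0.032
    w3_direct_gain: float = 1.0
    w3_exc_gain_nS: float = 8.0
    w3_inh_gain_nS: float = 8.0
    w3_spike_gain_hz: float = 60.0
    w3_spont_rate_hz: float = 1.0
    w3_refractory_ms: float = 2.0

    # condition switches
    ttx: bool = False
    vglut3_ko: bool = False

    # noise and rates
    noise_sd: float = 0.01  # nS, additive on conductances
    seed: int = 0
    sim_rate_hz: float = 1000.0
    output_rate_hz: float = 10000.0

    def __post_init__(self):
        if self.subunit_spacing <= 0 or self.subunit_sigma <= 0:
            raise ValueError("subunit spacing and sigma must be positive")
        for name in ("center_sigma_on", "center_sigma_off", "wac_sigma_on",
                     "wac_sigma_off", "w3_center_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.gain_off_over_on <= 0:
            raise ValueError("gain_off_over_on must be positive")
        if self.vg3_to_w3_delay_ms < 0:
            raise ValueError("delay must be non-negative")
        if self.kernel_on is None:
            self.kernel_on = default_kernel(self.kernel_rate_hz)
        if self.kernel_off is None:
            self.kernel_off = default_kernel(self.kernel_rate_hz)
        if self.vglut3_ko:
            self.w3_vg3_weight = 0.0


@dataclass
class BipolarDrive:
    """Rectified subunit outputs on the ON and OFF lattices."""

    on: np.ndarray  # (t, n_subunits)
    off: np.ndarray
    coords: np.ndarray  # (n_subunits, 2) um, shared by both lattices
    frame_rate: float


# ----------------------------------------------------------------------


def _lattice(fov_um: float, spacing: float) -> np.ndarray:
    """Square subunit lattice, symmetric about the field center."""
    m = int(np.floor(fov_um / spacing))
    c = (np.arange(m) - (m - 1) / 2.0) * spacing
    xx, yy = np.meshgrid(c, c)
    return np.column_stack([xx.ravel(), yy.ravel()])


def _resample_kernel(kernel: np.ndarray, from_rate: float, to_rate: float) -> np.ndarray:
    if abs(from_rate - to_rate) < 1e-9:
        return np.asarray(kernel, dtype=float)
    t_old = np.arange(len(kernel)) / from_rate
    t_new = np.arange(0.0, t_old[-1] + 0.5 / to_rate, 1.0 / to_rate)
    return np.interp(t_new, t_old, kernel)


def _bilinear_sample(stack: np.ndarray, iy: np.ndarray, ix: np.ndarray) -> np.ndarray:
    """Sample (t, y, x) stack at fractional pixel positions -> (t, n)."""
    ny, nx = stack.shape[1:]
    x0 = np.clip(np.floor(ix).astype(int), 0, nx - 2)
    y0 = np.clip(np.floor(iy).astype(int), 0, ny - 2)
    fx, fy = ix - x0, iy - y0
    s00 = stack[:, y0, x0]
    s01 = stack[:, y0, x0 + 1]
    s10 = stack[:, y0 + 1, x0]
    s11 = stack[:, y0 + 1, x0 + 1]
    return (s00 * (1 - fy) * (1 - fx) + s01 * (1 - fy) * fx
            + s10 * fy * (1 - fx) + s11 * fy * fx)


def bipolar_layer(clip: StimulusClip, params: CircuitParams) -> BipolarDrive:
    """Spatial Gaussian pooling, temporal filtering, and rectification.

    Each subunit pools stimulus contrast (intensity minus mean) under a
    Gaussian of SD ``subunit_sigma``, convolves with its temporal kernel,
    and half-wave rectifies at zero.  The OFF lattice sees sign-inverted
    contrast and carries the OFF/ON gain ratio.
    """
    if clip.pixel_pitch >= params.subunit_sigma:
        raise ValueError("clip pixel pitch must be finer than the subunit sigma")
    k_on = _resample_kernel(params.kernel_on, params.kernel_rate_hz, clip.frame_rate)
    k_off = _resample_kernel(params.kernel_off, params.kernel_rate_hz, clip.frame_rate)
    if clip.n_frames < max(len(k_on), len(k_off)):
        raise ValueError("clip shorter than the temporal kernel")

    contrast = clip.frames.astype(np.float64) - clip.mean_intensity
    sig_px = params.subunit_sigma / clip.pixel_pitch
    pooled = gaussian_filter(contrast, sigma=(0.0, sig_px, sig_px),
                             mode="constant", cval=0.0)

    ny, nx = pooled.shape[1:]
    fov = min(ny, nx) * clip.pixel_pitch
    coords = _lattice(fov, params.subunit_spacing)
    iy = coords[:, 1] / clip.pixel_pitch + (ny - 1) / 2.0
    ix = coords[:, 0] / clip.pixel_pitch + (nx - 1) / 2.0
    sub = _bilinear_sample(pooled, iy, ix)  # (t, n_sub), linear contrast drive

    dt = 1.0 / clip.frame_rate

    def pathway(signal, kernel, gain):
        lin = fftconvolve(signal, kernel[:, None], mode="full", axes=0)[: len(signal)] * dt
        lin *= gain
        return np.clip(lin, 0.0, None) if params.rectified else 0.5 * lin

    on = pathway(sub, k_on, 1.0)
    off = pathway(-sub, k_off, params.gain_off_over_on)
    return BipolarDrive(on=on, off=off, coords=coords, frame_rate=clip.frame_rate)


def _gauss_weights(coords: np.ndarray, sigma: float) -> np.ndarray:
    r2 = np.sum(coords**2, axis=1)
    w = np.exp(-r2 / (2.0 * sigma**2))
    return w / w.sum()


def wide_field_ac(drive: BipolarDrive, params: CircuitParams) -> np.ndarray:
    """Thresholded wide-field pool of rectified subunit output (per frame).

    Returns zero everywhere when the ``ttx`` switch is set (the population
    signals through sodium spikes).  The output is the pooled drive in
    excess of ``wac_threshold``, zero below it.
    """
    if params.ttx:
        return np.zeros(drive.on.shape[0])
    w_on = _gauss_weights(drive.coords, params.wac_sigma_on)
    w_off = _gauss_weights(drive.coords, params.wac_sigma_off)
    pooled = drive.on @ w_on + drive.off @ w_off
    return np.clip(pooled - params.wac_threshold, 0.0, None)


# ----------------------------------------------------------------------
# trace assembly helpers


def _upsample(x: np.ndarray, from_rate: float, to_rate: float, n_out: int) -> np.ndarray:
    t_out = np.arange(n_out) / to_rate
    t_in = np.arange(len(x)) / from_rate
    return np.interp(t_out, t_in, x)


def _baseline_window(clip: StimulusClip) -> tuple:
    for l, a, b in clip.events:
        if l == "baseline":
            return (a, b)
    return (0.0, min(0.5, clip.duration_s))


def _membrane_filter(v_inf: np.ndarray, tau_s: float, dt: float, v0: float) -> np.ndarray:
    a = np.exp(-dt / tau_s)
    y, _ = lfilter([1.0 - a], [1.0, -a], v_inf, zi=[a * v0])
    return y


def _make_trace(x, rate, modality, clip, n_out):
    return EpochedTrace(samples=x[:n_out], rate=rate, modality=modality,
                        baseline_window=_baseline_window(clip), events=list(clip.events))


def _vg3_conductances(clip: StimulusClip, params: CircuitParams):
    """Frame-rate excitatory/inhibitory conductance drives of the VG3 cell."""
    drive = bipolar_layer(clip, params)
    wac = wide_field_ac(drive, params)
    w_on = _gauss_weights(drive.coords, params.center_sigma_on)
    w_off = _gauss_weights(drive.coords, params.center_sigma_off)
    exc_drive = drive.on @ w_on + drive.off @ w_off
    g_e = params.exc_gain_nS * np.clip(
        exc_drive - params.presyn_inhibition_weight * wac, 0.0, None)
    g_i = params.inh_gain_nS * params.postsyn_inhibition_weight * wac
    return drive, wac, g_e, g_i


def simulate_vg3(clip: StimulusClip, params: CircuitParams | None = None) -> dict:
    """Simulate VG3 voltage, EPSC, and IPSC responses to a stimulus clip.

    Returns a dict of :class:`EpochedTrace`: ``voltage`` (mV), ``epsc`` and
    ``ipsc`` (pA, at the -60 mV / 0 mV holding potentials), and the
    underlying ``g_exc`` / ``g_inh`` conductances (nS).  Noise is additive
    Gaussian on the conductances, seeded from ``params.seed``.
    """
    params = params or CircuitParams()
    _, _, g_e_f, g_i_f = _vg3_conductances(clip, params)

    sr, orate = params.sim_rate_hz, params.output_rate_hz
    n_sim = int(round(clip.duration_s * sr))
    dt = 1.0 / sr
    rng = np.random.default_rng(params.seed)
    g_e = _upsample(g_e_f, clip.frame_rate, sr, n_sim)
    g_i = _upsample(g_i_f, clip.frame_rate, sr, n_sim)
    if params.noise_sd > 0:
        g_e = g_e + rng.normal(0.0, params.noise_sd, n_sim)
        g_i = g_i + rng.normal(0.0, params.noise_sd, n_sim)
    g_e = np.clip(g_e, 0.0, None)
    g_i = np.clip(g_i, 0.0, None)

    g_tot = params.g_leak_nS + g_e + g_i
    v_inf = (params.g_leak_nS * params.resting_mV + g_e * params.e_exc_mV
             + g_i * params.e_inh_mV) / g_tot
    v = _membrane_filter(v_inf, params.tau_membrane_ms / 1000.0, dt, params.resting_mV)

    epsc = g_e * (params.e_inh_mV - params.e_exc_mV)  # held at Cl- reversal
    ipsc = g_i * (params.e_exc_mV - params.e_inh_mV)  # held at cation reversal

    n_out = int(round(clip.duration_s * orate))
    out = {
        "voltage": _upsample(v, sr, orate, n_out),
        "epsc": _upsample(epsc, sr, orate, n_out),
        "ipsc": _upsample(ipsc, sr, orate, n_out),
        "g_exc": _upsample(g_e, sr, orate, n_out),
        "g_inh": _upsample(g_i, sr, orate, n_out),
    }
    modal = {"voltage": "voltage_mV", "epsc": "current_pA", "ipsc": "current_pA",
             "g_exc": "conductance_nS", "g_inh": "conductance_nS"}
    return {k: _make_trace(x, orate, modal[k], clip, n_out) for k, x in out.items()}


def simulate_w3(clip: StimulusClip, params: CircuitParams | None = None) -> dict:
    """Simulate W3 EPSC, IPSC, spike times, and smoothed spike rate.

    Excitation combines threshold-rectified VG3 release (delayed by the
    synaptic delay, weighted by ``w3_vg3_weight``; zero under
    ``vglut3_ko``) with a direct bipolar center pool; inhibition is the
    wide-field drive.  Spikes are drawn as an inhomogeneous Poisson
    process from the rectified net drive with an absolute refractory
    period, seeded for reproducibility.
    """
    params = params or CircuitParams()
    drive, wac, g_e_vg3_f, g_i_vg3_f = _vg3_conductances(clip, params)

    sr, orate = params.sim_rate_hz, params.output_rate_hz
    n_sim = int(round(clip.duration_s * sr))
    dt = 1.0 / sr
    rng = np.random.default_rng(params.seed + 1)

    # --- VG3 voltage (noiseless core) -> release
    g_e = np.clip(_upsample(g_e_vg3_f, clip.frame_rate, sr, n_sim), 0, None)
    g_i = np.clip(_upsample(g_i_vg3_f, clip.frame_rate, sr, n_sim), 0, None)
    g_tot = params.g_leak_nS + g_e + g_i
    v_inf = (params.g_leak_nS * params.resting_mV + g_e * params.e_exc_mV
             + g_i * params.e_inh_mV) / g_tot
    v = _membrane_filter(v_inf, params.tau_membrane_ms / 1000.0, dt, params.resting_mV)
    release = params.vg3_release_gain * np.clip(v - params.vg3_release_threshold_mV, 0, None)
    delay = int(round(params.vg3_to_w3_delay_ms / 1000.0 * sr))
    if delay:
        release = np.concatenate([np.zeros(delay), release[:-delay]])

    # --- direct bipolar pool
    w_c = _gauss_weights(drive.coords, params.w3_center_sigma)
    direct_f = params.w3_direct_gain * (drive.on @ w_c + drive.off @ w_c)
    direct = _upsample(direct_f, clip.frame_rate, sr, n_sim)

    g_e_w3 = params.w3_exc_gain_nS * (params.w3_vg3_weight * release
                                      + params.w3_direct_weight * direct)
    g_i_w3 = params.w3_inh_gain_nS * _upsample(wac, clip.frame_rate, sr, n_sim)
    if params.noise_sd > 0:
        g_e_w3 = g_e_w3 + rng.normal(0.0, params.noise_sd, n_sim)
        g_i_w3 = g_i_w3 + rng.normal(0.0, params.noise_sd, n_sim)
    g_e_w3 = np.clip(g_e_w3, 0.0, None)
    g_i_w3 = np.clip(g_i_w3, 0.0, None)

    epsc = g_e_w3 * (params.e_inh_mV - params.e_exc_mV)
    ipsc = g_i_w3 * (params.e_exc_mV - params.e_inh_mV)

    # --- spikes: rectified net drive -> inhomogeneous Poisson + refractory
    rate = params.w3_spont_rate_hz + params.w3_spike_gain_hz * np.clip(
        g_e_w3 - g_i_w3, 0.0, None)
    refr = int(round(params.w3_refractory_ms / 1000.0 * sr))
    u = rng.random(n_sim)
    spikes = []
    last = -10 * max(refr, 1)
    for i in range(n_sim):
        if i - last > refr and u[i] < rate[i] * dt:
            spikes.append(i * dt)
            last = i
    spike_times = np.asarray(spikes)

    # smoothed rate (50-ms Gaussian) for amplitude analyses
    binned = np.zeros(n_sim)
    if len(spike_times):
        binned[np.minimum((spike_times * sr).astype(int), n_sim - 1)] = sr
    rate_smooth = gaussian_filter(binned, sigma=0.05 * sr)

    n_out = int(round(clip.duration_s * orate))
    result = {
        "epsc": _make_trace(_upsample(epsc, sr, orate, n_out), orate, "current_pA",
                            clip, n_out),
        "ipsc": _make_trace(_upsample(ipsc, sr, orate, n_out), orate, "current_pA",
                            clip, n_out),
        "g_exc": _make_trace(_upsample(g_e_w3, sr, orate, n_out), orate,
                             "conductance_nS", clip, n_out),
        "spike_rate": _make_trace(_upsample(rate_smooth, sr, orate, n_out), orate,
                                  "spike_rate_Hz", clip, n_out),
        "spike_times": EpochedTrace(samples=spike_times, rate=sr,
                                    modality="spike_times_s", events=list(clip.events)),
    }
    return result


# ----------------------------------------------------------------------
# experiment generation (on-disk synthetic dataset)

from . import stimulus as _stim  # noqa: E402

DEFAULT_EXPERIMENT_CONFIG = {
    "seed": 0,
    "geometry": {"fov_um": 800.0, "pixel_pitch": 8.0, "frame_rate": 30.0},
    "cells": [
        {"cell_id": "vg3_0", "cell_type": "vg3", "conditions": ["control", "ttx"]},
        {"cell_id": "w3_0", "cell_type": "w3", "conditions": ["control", "ko"]},
    ],
    "stimuli": {
        "texture": {"segments": ["global", "diff_center", "diff_surround"],
                    "bar_width": 50.0, "speed": 400.0},
        "bars": {"heights": [200.0, 600.0], "speed": 400.0},
        "split_field": {"biases": [0.5, 0.75]},
        "spots": {"radii": [25.0, 50.0, 100.0, 200.0, 290.0]},
    },
}


def _condition_params(base: CircuitParams, condition: str) -> CircuitParams:
    if condition == "control":
        return base
    if condition == "ttx":
        return replace(base, ttx=True)
    if condition == "ko":
        return replace(base, vglut3_ko=True)
    raise ValueError(f"unknown condition {condition!r}")


def generate_experiment(config: dict | None = None, out_dir="synthetic_experiment",
                        params: CircuitParams | None = None) -> pd.DataFrame:
    """Generate an on-disk synthetic dataset across stimuli x cells x conditions.

    Writes ``traces/<cell>/<stimulus>/<condition>.h5`` (one group per
    recorded quantity), per-stimulus event CSVs, a ``manifest.csv``, and
    the fully-resolved config as YAML, so the dataset is reproducible from
    config + seed alone.  Partial output is removed on failure.
    """
    cfg = dict(DEFAULT_EXPERIMENT_CONFIG)
    if config:
        cfg = {**cfg, **config}
    out = Path(out_dir)
    created = not out.exists()
    out.mkdir(parents=True, exist_ok=True)
    try:
        geo = cfg["geometry"]
        geo_kw = {"fov_um": geo["fov_um"], "pixel_pitch": geo["pixel_pitch"],
                  "frame_rate": geo["frame_rate"]}
        base = params or CircuitParams(seed=int(cfg["seed"]))

        clips = {}
        st = cfg["stimuli"]
        if "texture" in st:
            for seg in st["texture"]["segments"]:
                clips[f"texture_{seg}"] = _stim.make_texture_motion(
                    seg, bar_width=st["texture"]["bar_width"],
                    speed=st["texture"]["speed"], **geo_kw)
        if "bars" in st:
            for h in st["bars"]["heights"]:
                clips[f"bar_h{int(h)}"] = _stim.make_moving_bar(
                    height=h, width=geo["fov_um"], speed=st["bars"]["speed"], **geo_kw)
        if "split_field" in st:
            for b in st["split_field"]["biases"]:
                clips[f"split_{b:g}"] = _stim.make_split_field(bias_fraction=b, **geo_kw)
        if "spots" in st:
            for i, clip in enumerate(_stim.make_spot_series(
                    st["spots"]["radii"], order_seed=int(cfg["seed"]), **geo_kw)):
                clips[f"spot_{i}_r{int(clip.meta['radius_um'])}"] = clip

        rows = []
        for name, clip in clips.items():
            clip.events_to_csv(out / f"events_{name}.csv")
        for cell in cfg["cells"]:
            sim = simulate_vg3 if cell["cell_type"] == "vg3" else simulate_w3
            for cond in cell["conditions"]:
                p = _condition_params(base, cond)
                for name, clip in clips.items():
                    traces = sim(clip, p)
                    rel = Path("traces") / cell["cell_id"] / name / f"{cond}.h5"
                    path = out / rel
                    path.parent.mkdir(parents=True, exist_ok=True)
                    import h5py
                    with h5py.File(path, "w") as h:
                        for key, tr in traces.items():
                            tr.to_hdf5(h, name=key)
                    rows.append({"cell_id": cell["cell_id"],
                                 "cell_type": cell["cell_type"], "stimulus": name,
                                 "condition": cond, "seed": p.seed, "path": str(rel)})
        manifest = pd.DataFrame(rows)
        manifest.to_csv(out / "manifest.csv", index=False)
        with open(out / "config.yaml", "w") as f:
            yaml.safe_dump(cfg, f)
        return manifest
    except Exception:
        if created:
            shutil.rmtree(out, ignore_errors=True)
        raise
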