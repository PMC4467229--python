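"""Epoched response traces (voltage, current, conductance, spikes)."""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = ["EpochedTrace", "MODALITIES"]

MODALITIES = ("voltage_mV", "current_pA", "conductance_nS",
              "spike_rate_Hz", "spike_times_s")


@dataclass
class EpochedTrace:
    """A uniformly sampled response trace with its epoch markers.

    For ``modality='spike_times_s'`` the samples are event times in seconds
    (strictly increasing) and ``rate`` refers to the clock they were
    detected on.
    """

    samples: np.ndarray
    rate: float = 10_000.0
    modality: str = "voltage_mV"
    baseline_window: tuple = (0.0, 0.0)
    events: list = field(default_factory=list)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.modality == "spike_times_s":
            if np.any(np.diff(self.samples) <= 0):
                raise ValueError("spike times must be strictly increasing")
        else:
            a, b = self.baseline_window
            if not (0.0 <= a <= b <= self.duration_s + 1e-9):
                raise ValueError("baseline window must lie inside the trace")
        self.events = [(str(l), float(a), float(b)) for l, a, b in self.events]

    @property
    def duration_s(self) -> float:
        if self.modality == "spike_times_s":
            return float(self.samples[-1]) if len(self.samples) else 0.0
        return len(self.samples) / self.rate

    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.rate

    def slice(self, start_s: float, end_s: float) -> np.ndarray:
        """Samples with start_s <= t < end_s."""
        i0 = int(np.ceil(start_s * self.rate - 1e-9))
        i1 = int(np.ceil(end_s * self.rate - 1e-9))
        if i0 < 0 or i1 > len(self.samples) or i1 <= i0:
            raise ValueError(f"window ({start_s}, {end_s}) s outside trace "
                             f"of duration {self.duration_s:.3f} s")
        return self.samples[i0:i1]

    def window_mean(self, window) -> float:
        return float(self.slice(*window).mean())

    def baseline_mean(self) -> float:
        return self.window_mean(self.baseline_window)

    def event_window(self, label: str) -> tuple:
        for l, a, b in self.events:
            if l == label:
                return (a, b)
        raise KeyError(f"no event labeled {label!r}")

    def with_samples(self, samples, modality=None) -> "EpochedTrace":
        return EpochedTrace(samples=samples, rate=self.rate,
                            modality=modality or self.modality,
                            baseline_window=self.baseline_window,
                            events=list(self.events))

    # ------------------------------------------------------------------
    def to_hdf5(self, group: "h5py.Group | str", name: str | None = None) -> None:
        own = isinstance(group, str)
        h = h5py.File(group, "w") if own else group
        try:
            g = h.create_group(name) if name else h
            g.create_dataset("samples", data=self.samples, compression="gzip")
            g.attrs["rate"] = self.rate
            g.attrs["modality"] = self.modality
            g.attrs["baseline_window"] = list(self.baseline_window)
            ev = g.create_group("events")
            ev.create_dataset("label", data=np.array([e[0] for e in self.events], dtype="S64"))
            ev.create_dataset("start_s", data=[e[1] for e in self.events])
            ev.create_dataset("end_s", data=[e[2] for e in self.events])
        finally:
            if own:
                h.close()

    @classmethod
    def from_hdf5(cls, group: "h5py.Group | str", name: str | None = None) -> "EpochedTrace":
        own = isinstance(group, str)
        h = h5py.File(group, "r") if own else group
        try:
            g = h[name] if name else h
            ev = g["events"]
            events = list(zip([s.decode() for s in ev["label"][()]],
                              ev["start_s"][()].tolist(), ev["end_s"][()].tolist()))
            return cls(samples=g["samples"][()], rate=float(g.attrs["rate"]),
                       modality=str(g.attrs["modality"]),
                       baseline_window=tuple(g.attrs["baseline_window"]), events=events)
        finally:
            if own:
                h.close()
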