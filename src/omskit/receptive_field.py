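"""Spatial receptive-field models fit to area-response (spot-size) data.

The response to a spot of radius ``r`` is modeled as the integral of a
center-surround Difference-of-Gaussians sensitivity profile over the spot
disc, which gives the cumulative form

    R(r) = k_c * (1 - exp(-r^2 / (2 sigma_c^2)))
         - k_s * (1 - exp(-r^2 / (2 sigma_s^2)))

with k_c, k_s >= 0 and sigma_s > sigma_c.  Receptive-field sizes are
reported as the diameter of the respective Gaussian at 1 SD (2 * sigma).
Inhibitory inputs, which rise monotonically with spot size, are fit with
the single-Gaussian special case (k_s = 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "AreaResponseCurve",
    "DoGFit",
    "dog_area_response",
    "fit_dog",
    "fit_gaussian",
    "rf_diameter",
    "coverage_factor",
]

# multi-start initialization grid (um)
SIGMA_C_STARTS = (15.0, 30.0, 60.0)
SIGMA_S_STARTS = (75.0, 150.0, 300.0)


@dataclass
class AreaResponseCurve:
    """Signed ON and OFF response amplitudes as a function of spot radius."""

    radii: np.ndarray
    on_amp: np.ndarray
    off_amp: np.ndarray
    modality: str = "voltage_mV"

    def __post_init__(self):
        self.radii = np.asarray(self.radii, dtype=float)
        self.on_amp = np.asarray(self.on_amp, dtype=float)
        self.off_amp = np.asarray(self.off_amp, dtype=float)
        if np.any(np.diff(self.radii) <= 0):
            raise ValueError("radii must be strictly increasing")
        if len(self.radii) < 5:
            raise ValueError("at least 5 radii are required for fitting")
        if len(self.on_amp) != len(self.radii) or len(self.off_amp) != len(self.radii):
            raise ValueError("amplitude arrays must match radii")

    def amplitudes(self, polarity: str) -> np.ndarray:
        if polarity == "on":
            return self.on_amp
        if polarity == "off":
            return self.off_amp
        raise ValueError("polarity must be 'on' or 'off'")


@dataclass
class DoGFit:
    """Fitted amplitudes and SDs of the center and surround Gaussians."""

    k_center: float
    k_surround: float
    sigma_center: float
    sigma_surround: float
    rss: float
    flipped: bool = False  # data were sign-inverted before fitting

    def predict(self, radii) -> np.ndarray:
        y = dog_area_response(np.asarray(radii, float), self.k_center, self.k_surround,
                              self.sigma_center, self.sigma_surround)
        return -y if self.flipped else y


def dog_area_response(r, k_c, k_s, sigma_c, sigma_s):
    """Disc-integrated Difference-of-Gaussians forward model."""
    r = np.asarray(r, dtype=float)
    return (k_c * (1.0 - np.exp(-(r**2) / (2.0 * sigma_c**2)))
            - k_s * (1.0 - np.exp(-(r**2) / (2.0 * sigma_s**2))))


def gaussian_area_response(r, k_c, sigma_c):
    return dog_area_response(r, k_c, 0.0, sigma_c, 10.0 * sigma_c)


def _fit(radii, y, single_gaussian, max_nfev=2000):
    scale = np.max(np.abs(y))
    if scale == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate area-response curve (all values equal)")
    flipped = False
    # fit with positive center amplitude; invert pure-suppression curves
    if y[np.argmax(np.abs(y))] < 0:
        y, flipped = -y, True
    r_max = radii[-1]
    best = None
    for sc in SIGMA_C_STARTS:
        for ss in SIGMA_S_STARTS if not single_gaussian else (None,):
            if ss is not None and ss <= sc:
                continue
            if single_gaussian:
                x0 = [scale, sc]
                lb = [0.0, 1.0]
                ub = [10 * scale, 5 * r_max]

                def resid(p):
                    return gaussian_area_response(radii, p[0], p[1]) - y
            else:
                x0 = [2 * scale, scale, sc, ss]
                lb = [0.0, 0.0, 1.0, 2.0]
                ub = [20 * scale, 20 * scale, 5 * r_max, 10 * r_max]

                def resid(p):
                    return dog_area_response(radii, p[0], p[1], p[2], p[3]) - y
            try:
                sol = least_squares(resid, x0, bounds=(lb, ub), xtol=1e-8, ftol=1e-8,
                                    gtol=1e-8, max_nfev=max_nfev)
            except Exception:
                continue
            rss = float(np.sum(sol.fun**2))
            if not single_gaussian and sol.x[3] <= sol.x[2]:
                continue  # surround must be wider than center
            if best is None or rss < best[0]:
                best = (rss, sol.x)
    if best is None:
        raise RuntimeError("DoG fit failed to converge from every start of the "
                           f"{SIGMA_C_STARTS} x {SIGMA_S_STARTS} grid")
    rss, p = best
    if single_gaussian:
        return DoGFit(k_center=float(p[0]), k_surround=0.0, sigma_center=float(p[1]),
                      sigma_surround=float(10 * p[1]), rss=rss, flipped=flipped)
    return DoGFit(k_center=float(p[0]), k_surround=float(p[1]), sigma_center=float(p[2]),
                  sigma_surround=float(p[3]), rss=rss, flipped=flipped)


def fit_dog(curve: AreaResponseCurve, polarity: str = "on") -> DoGFit:
    """Least-squares Difference-of-Gaussians fit with multi-start optimization.

    Used for voltage and excitatory-input area-response curves, which show
    center-surround antagonism.
    """
    return _fit(curve.radii, curve.amplitudes(polarity).copy(), single_gaussian=False)


def fit_gaussian(curve: AreaResponseCurve, polarity: str = "on") -> DoGFit:
    """Single-Gaussian fit (k_surround fixed at 0) for monotonically rising
    inputs such as surround inhibition."""
    return _fit(curve.radii, curve.amplitudes(polarity).copy(), single_gaussian=True)


def rf_diameter(fit: DoGFit, component: str = "center") -> float:
    """Receptive-field diameter at 1 SD of the requested Gaussian (2*sigma)."""
    if component == "center":
        return 2.0 * fit.sigma_center
    if component == "surround":
        return 2.0 * fit.sigma_surround
    raise ValueError("component must be 'center' or 'surround'")


def coverage_factor(density_per_mm2: float, territory_um2: float) -> float:
    """How many times the population tiles the retina.

    ``density [cells/mm^2] * territory [um^2] * 1e-6 [mm^2/um^2]``.
    """
    if density_per_mm2 <= 0 or territory_um2 <= 0:
        raise ValueError("density and territory must be positive")
    return density_per_mm2 * territory_um2 * 1e-6
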