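"""End-to-end orchestration: generate -> simulate -> analyze -> summarize.

A run is fully described by a :class:`RunConfig` (serializable to YAML);
one global seed fans out deterministically to per-stage child seeds, so
any stage can be rerun in isolation and the whole bundle is
bit-reproducible.  ``validate_run`` re-reads a bundle and checks the
qualitative circuit signatures (sign patterns, harmonic dominance,
suppression, knockout share, scaling contracts) that the run's tables
support.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import anatomy as an
from . import circuit as ck
from . import filters as fl
from . import metrics as mx
from . import receptive_field as rf
from . import stimulus as st

__all__ = ["RunConfig", "run_pipeline", "validate_run", "child_seed"]


def child_seed(seed: int, stage: int) -> int:
    """Deterministic per-stage child seed (< 2**31)."""
    return int(np.random.SeedSequence(entropy=int(seed),
                                      spawn_key=(int(stage),)).generate_state(1)[0]
               % (2**31))


@dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run."""

    seed: int = 0
    fov_um: float = 800.0
    pixel_pitch: float = 8.0
    frame_rate: float = 30.0
    bar_heights: tuple = (50.0, 100.0, 200.0, 400.0, 600.0)
    bar_speed: float = 400.0
    split_biases: tuple = (0.5, 0.75)
    spot_radii: tuple = (25.0, 50.0, 100.0, 200.0, 300.0)
    noise_duration_s: float = 120.0
    mosaic_density_per_mm2: float = 898.0
    mosaic_exclusion_um: float = 18.0
    mosaic_region_um: float = 1000.0
    territory_um2: float = 7662.0
    n_puncta: int = 400
    connected_fraction: float = 0.6
    circuit_overrides: dict = field(default_factory=dict)

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(dataclasses.asdict(self), f)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            d = yaml.safe_load(f) or {}
        for k in ("bar_heights", "split_biases", "spot_radii"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    def geometry(self) -> dict:
        return {"fov_um": self.fov_um, "pixel_pitch": self.pixel_pitch,
                "frame_rate": self.frame_rate}

    def params(self, **over) -> ck.CircuitParams:
        kw = {"seed": child_seed(self.seed, 1), **self.circuit_overrides, **over}
        return ck.CircuitParams(**kw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig | None = None, out_dir="pipeline_run") -> dict:
    """Run the full synthetic battery and write the results bundle.

    Writes tidy metric tables (CSV), receptive-field fit tables, recovered
    temporal filters, anatomy statistics, and a manifest with SHA-256
    checksums of every artifact.  Returns the results as a dict of
    DataFrames / dicts.  Any stage failure aborts with a stage-tagged
    error.
    """
    cfg = config or RunConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    geo = cfg.geometry()
    results: dict = {}
    rows = []

    def stage(name):
        def deco(fn):
            try:
                fn()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return deco

    # ------------------------------------------------------------- motion
    @stage("texture_motion")
    def _():
        p = cfg.params()
        pt = cfg.params(ttx=True)
        pko = cfg.params(vglut3_ko=True)
        clips = {s: st.make_texture_motion(s, **geo) for s in st.TEXTURE_SEGMENTS}
        for cond, pp in (("control", p), ("ttx", pt)):
            vg3 = {s: ck.simulate_vg3(c, pp) for s, c in clips.items()}
            for mod in ("voltage", "epsc", "ipsc"):
                ms = mx.motion_selectivity({s: vg3[s][mod] for s in clips})
                for seg, val in (("global", ms.global_amp),
                                 ("diff_center", ms.diff_center_amp),
                                 ("diff_surround", ms.diff_surround_amp)):
                    rows.append({"cell_id": "vg3_0", "metric": f"motion_{mod}_{seg}",
                                 "condition": cond, "value": val})
        for cond, pp in (("control", p), ("ko", pko)):
            w3 = {s: ck.simulate_w3(c, pp) for s, c in clips.items()}
            for seg in clips:
                amp = mx.peak_window_amplitude(w3[seg]["g_exc"], seg)
                rows.append({"cell_id": "w3_0", "metric": f"motion_gexc_{seg}",
                             "condition": cond, "value": amp})

    # --------------------------------------------------------------- bars
    @stage("size_tuning")
    def _():
        p = cfg.params()
        pt = cfg.params(ttx=True)
        clips = {h: st.make_moving_bar(height=h, width=cfg.fov_um, speed=cfg.bar_speed,
                                       **geo) for h in cfg.bar_heights}
        for cond, pp in (("control", p), ("ttx", pt)):
            sims = {h: ck.simulate_vg3(c, pp) for h, c in clips.items()}
            table, idx = mx.size_tuning({h: s["voltage"] for h, s in sims.items()})
            rows.append({"cell_id": "vg3_0", "metric": "size_suppression_index",
                         "condition": cond, "value": idx})
            for _, r in table.iterrows():
                rows.append({"cell_id": "vg3_0",
                             "metric": f"edge_voltage_h{int(r.height_um)}_{r.edge}",
                             "condition": cond, "value": r.amplitude})
            if cond == "control":
                for h, s in sims.items():
                    amp = mx.edge_amplitude(s["ipsc"], "leading_edge")
                    rows.append({"cell_id": "vg3_0", "metric": f"edge_ipsc_h{int(h)}",
                                 "condition": cond, "value": amp})

    # -------------------------------------------------------- split field
    @stage("split_field")
    def _():
        p = cfg.params()
        plin = cfg.params(rectified=False)
        for bias in cfg.split_biases:
            clip = st.make_split_field(bias, **geo)
            h = mx.harmonic_amplitudes(ck.simulate_vg3(clip, p)["epsc"], 2.0,
                                       window=clip.event_window("modulation"))
            rows.append({"cell_id": "vg3_0", "metric": f"split_{bias:g}_f1",
                         "condition": "control", "value": h.f1_amplitude})
            rows.append({"cell_id": "vg3_0", "metric": f"split_{bias:g}_f2",
                         "condition": "control", "value": h.f2_amplitude})
        clip = st.make_split_field(0.5, **geo)
        h = mx.harmonic_amplitudes(ck.simulate_vg3(clip, plin)["epsc"], 2.0,
                                   window=clip.event_window("modulation"))
        rows.append({"cell_id": "vg3_0", "metric": "split_0.5_f2",
                     "condition": "linear", "value": h.f2_amplitude})

    # -------------------------------------------------------------- spots
    @stage("area_response")
    def _():
        p = cfg.params()
        clips = st.make_spot_series(list(cfg.spot_radii), order_seed=cfg.seed, **geo)
        by_radius = {c.meta["radius_um"]: c for c in clips}  # last repeat overwrites
        on, off = [], []
        radii = sorted(by_radius)
        for r in radii:
            v = ck.simulate_vg3(by_radius[r], p)["voltage"]
            on.append(mx.peak_window_amplitude(v, "spot_on"))
            off.append(mx.peak_window_amplitude(v, "spot_off"))
        curve = rf.AreaResponseCurve(radii=np.array(radii), on_amp=np.array(on),
                                     off_amp=np.array(off))
        fit_rows = []
        for pol in ("on", "off"):
            f = rf.fit_dog(curve, pol)
            fit_rows.append({"cell_id": "vg3_0", "polarity": pol, "k_center": f.k_center,
                             "k_surround": f.k_surround, "sigma_center": f.sigma_center,
                             "sigma_surround": f.sigma_surround,
                             "diameter_center": rf.rf_diameter(f, "center"),
                             "diameter_surround": rf.rf_diameter(f, "surround"),
                             "rss": f.rss})
        results["fits"] = pd.DataFrame(fit_rows)
        results["area_response"] = pd.DataFrame(
            {"radius_um": radii, "on_amp": on, "off_amp": off})

    # ------------------------------------------------------------ filters
    @stage("temporal_filters")
    def _():
        p = cfg.params(noise_sd=0.0)
        wn = st.make_white_noise(duration_s=cfg.noise_duration_s,
                                 seed=child_seed(cfg.seed, 2), fov_um=240.0,
                                 pixel_pitch=cfg.pixel_pitch, center_radius=100.0)
        v = ck.simulate_vg3(wn, p)["voltage"]
        ens = fl.response_weighted_ensemble(wn.meta["sequence"], v, refresh_hz=30.0)
        pair = fl.split_on_off(ens)
        m = fl.filter_metrics(pair)
        truth = ck._resample_kernel(p.kernel_on, p.kernel_rate_hz, 30.0)[: len(pair.on_filter)]
        corr = float(np.corrcoef(pair.on_filter, truth)[0, 1])
        results["filters"] = pd.DataFrame({"lag_s": pair.lags_s(),
                                           "on": pair.on_filter, "off": pair.off_filter})
        rows.append({"cell_id": "vg3_0", "metric": "filter_on_truth_corr",
                     "condition": "control", "value": corr})
        rows.append({"cell_id": "vg3_0", "metric": "filter_scale_residual",
                     "condition": "control",
                     "value": abs(pair.scale_checksum - ens.global_average.sum())})
        for name in ("on", "off"):
            rows.append({"cell_id": "vg3_0", "metric": f"filter_{name}_peak_time_s",
                         "condition": "control", "value": m.peak_time_s[name]})
            rows.append({"cell_id": "vg3_0", "metric": f"filter_{name}_biphasic_index",
                         "condition": "control", "value": m.biphasic_index[name]})

    # ------------------------------------------------------------ anatomy
    @stage("anatomy")
    def _():
        L = cfg.mosaic_region_um
        mosaic = an.simulate_mosaic(cfg.mosaic_density_per_mm2, cfg.mosaic_exclusion_um,
                                    (0, L, 0, L), seed=child_seed(cfg.seed, 3))
        prof = an.drp(mosaic, bin_width=2.0, max_radius=50.0)
        rows.append({"cell_id": "population", "metric": "drp_effective_radius_um",
                     "condition": "control", "value": prof.effective_radius})
        rows.append({"cell_id": "population", "metric": "coverage_factor",
                     "condition": "control",
                     "value": rf.coverage_factor(cfg.mosaic_density_per_mm2,
                                                 cfg.territory_um2)})
        results["drp"] = prof.to_frame()
        scene = an.make_neurite_scene(n_puncta=cfg.n_puncta, n_branches=8, n_steps=30,
                                      tube_radius_um=0.5,
                                      connected_fraction=cfg.connected_fraction,
                                      seed=child_seed(cfg.seed, 4))
        null = an.randomized_null(scene, n_iter=500, seed=child_seed(cfg.seed, 5))
        for name, val in (("apposition_fraction", null.observed),
                          ("apposition_null_mean", null.null_mean),
                          ("apposition_p", null.p_value)):
            rows.append({"cell_id": "w3_0", "metric": name, "condition": "control",
                         "value": val})

    # ------------------------------------------------------------- output
    results["metrics"] = pd.DataFrame(rows)
    written = []
    for name in ("metrics", "fits", "area_response", "filters", "drp"):
        path = out / f"{name}.csv"
        results[name].to_csv(path, index=False)
        written.append(path)
    cfg.to_yaml(out / "config.yaml")
    written.append(out / "config.yaml")
    manifest = {"artifacts": {p.name: _sha256(p) for p in written}}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return results


# ----------------------------------------------------------------------
# validation


def _get(metrics: pd.DataFrame, metric: str, condition: str = "control") -> float:
    sel = (metrics["metric"] == metric) & (metrics["condition"] == condition)
    if not sel.any():
        raise KeyError(f"{metric} [{condition}] missing from bundle")
    return float(metrics.loc[sel, "value"].iloc[0])


def validate_run(out_dir) -> dict:
    """Check a results bundle against the circuit's qualitative signatures.

    Returns ``{"checks": {name: {"passed": bool, "detail": str}},
    "missing": [...], "passed": bool}``.
    """
    out = Path(out_dir)
    checks: dict = {}
    missing: list = []
    try:
        metrics = pd.read_csv(out / "metrics.csv")
    except FileNotFoundError:
        return {"checks": {}, "missing": ["metrics.csv"], "passed": False}

    def check(name, fn):
        try:
            passed, detail = fn()
        except KeyError as exc:
            missing.append(str(exc))
            return
        checks[name] = {"passed": bool(passed), "detail": detail}

    def motion_signs():
        dc = _get(metrics, "motion_voltage_diff_center")
        gl = _get(metrics, "motion_voltage_global")
        ds = _get(metrics, "motion_voltage_diff_surround")
        return (dc > 0 > gl and ds < 0), f"diff_Ce={dc:.2f}, global={gl:.2f}, diff_Su={ds:.2f}"

    def ttx_reversal():
        gl = _get(metrics, "motion_voltage_global", "ttx")
        ds = _get(metrics, "motion_voltage_diff_surround", "ttx")
        return (gl > 0 and ds > -1.0), f"TTX global={gl:.2f}, diff_Su={ds:.2f}"

    def f2_dominance():
        f1 = _get(metrics, "split_0.5_f1")
        f2 = _get(metrics, "split_0.5_f2")
        f1b = _get(metrics, "split_0.75_f1")
        f2b = _get(metrics, "split_0.75_f2")
        f2lin = _get(metrics, "split_0.5_f2", "linear")
        ok = (f2 / f1 >= 3.0) and (f1b > f2b) and (f2 >= 10.0 * f2lin)
        return ok, (f"even F2/F1={f2 / f1:.1f}, biased F1/F2={f1b / f2b:.1f}, "
                    f"linear collapse x{f2 / max(f2lin, 1e-12):.0f}")

    def size_suppression():
        idx = _get(metrics, "size_suppression_index")
        idxt = _get(metrics, "size_suppression_index", "ttx")
        heights = sorted(int(m.split("_h")[1]) for m in metrics["metric"]
                         if m.startswith("edge_ipsc_h"))
        ipsc = [_get(metrics, f"edge_ipsc_h{h}") for h in heights]
        tol = 0.02 * max(ipsc) if ipsc else 0.0
        monotone = all(b >= a - tol for a, b in zip(ipsc, ipsc[1:]))
        ok = idx >= 0.5 and (1 - idxt) >= 0.8 and monotone
        return ok, (f"index={idx:.2f}, TTX ratio={1 - idxt:.2f}, "
                    f"IPSC monotone={monotone}")

    def ko_share():
        wt = _get(metrics, "motion_gexc_diff_center")
        ko = _get(metrics, "motion_gexc_diff_center", "ko")
        wt_g = _get(metrics, "motion_gexc_global")
        ko_g = _get(metrics, "motion_gexc_global", "ko")
        red = 1 - ko / wt
        dg = abs(ko_g - wt_g) / abs(wt_g)
        return (0.35 <= red <= 0.65 and dg < 0.10), \
            f"diff_Ce reduction={red * 100:.0f}%, global change={dg * 100:.1f}%"

    def coverage():
        c = _get(metrics, "coverage_factor")
        return abs(c - 6.88) < 0.005, f"coverage={c:.2f}"

    def filter_recovery():
        corr = _get(metrics, "filter_on_truth_corr")
        resid = _get(metrics, "filter_scale_residual")
        return (corr > 0.9 and resid < 1e-9), f"corr={corr:.3f}, scale residual={resid:.2e}"

    try:
        cfg = RunConfig.from_yaml(out / "config.yaml")
    except FileNotFoundError:
        cfg = RunConfig()

    def drp_radius():
        r = _get(metrics, "drp_effective_radius_um")
        target = cfg.mosaic_exclusion_um
        return abs(r - target) / target <= 0.15, \
            f"effective radius={r:.1f} um (target {target:g})"

    def apposition():
        obs = _get(metrics, "apposition_fraction")
        nm = _get(metrics, "apposition_null_mean")
        p = _get(metrics, "apposition_p")
        return (obs > 2 * nm and p <= 0.01), f"observed={obs:.2f}, null={nm:.2f}, p={p:.3g}"

    for name, fn in [("motion_sign_pattern", motion_signs), ("ttx_reversal", ttx_reversal),
                     ("f2_dominance", f2_dominance), ("size_suppression", size_suppression),
                     ("ko_share", ko_share), ("coverage_factor", coverage),
                     ("filter_recovery", filter_recovery), ("drp_radius", drp_radius),
                     ("apposition_enrichment", apposition)]:
        check(name, fn)
    passed = bool(checks) and all(c["passed"] for c in checks.values()) and not missing
    return {"checks": checks, "missing": missing, "passed": passed}
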