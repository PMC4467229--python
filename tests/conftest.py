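"""Shared fixtures: a compact stimulus geometry and cached circuit runs.

The analysis geometry (800-um field, 8-um pixels, 30 Hz) is a scaled-down
rendering of the display; it keeps the full surround of every stimulus
inside the field while the whole battery simulates in seconds.
"""

import dataclasses

import pytest

from omskit import circuit as ck
from omskit import stimulus as st

GEO = dict(fov_um=800.0, pixel_pitch=8.0, frame_rate=30.0)


@pytest.fixture(scope="session")
def geo():
    return dict(GEO)


@pytest.fixture(scope="session")
def quiet_params():
    """Deterministic circuit parameters (no conductance noise)."""
    return ck.CircuitParams(noise_sd=0.0)


@pytest.fixture(scope="session")
def texture_clips():
    return {seg: st.make_texture_motion(seg, **GEO) for seg in st.TEXTURE_SEGMENTS}


@pytest.fixture(scope="session")
def vg3_texture(texture_clips, quiet_params):
    """VG3 responses to the texture battery, control and TTX."""
    pt = dataclasses.replace(quiet_params, ttx=True)
    return {
        "control": {s: ck.simulate_vg3(c, quiet_params) for s, c in texture_clips.items()},
        "ttx": {s: ck.simulate_vg3(c, pt) for s, c in texture_clips.items()},
    }


@pytest.fixture(scope="session")
def w3_texture(texture_clips, quiet_params):
    """W3 responses to the texture battery, wild-type and knockout."""
    pko = dataclasses.replace(quiet_params, vglut3_ko=True)
    return {
        "wt": {s: ck.simulate_w3(c, quiet_params) for s, c in texture_clips.items()},
        "ko": {s: ck.simulate_w3(c, pko) for s, c in texture_clips.items()},
    }


@pytest.fixture(scope="session")
def bar_sims(quiet_params):
    """VG3 responses to moving bars of varying height, control and TTX."""
    pt = dataclasses.replace(quiet_params, ttx=True)
    out = {"control": {}, "ttx": {}}
    for h in (50.0, 100.0, 200.0, 400.0, 600.0):
        clip = st.make_moving_bar(height=h, width=GEO["fov_um"], speed=400.0, **GEO)
        out["control"][h] = ck.simulate_vg3(clip, quiet_params)
        out["ttx"][h] = ck.simulate_vg3(clip, pt)
    return out
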