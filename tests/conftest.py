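"""Shared fixtures: small synthetic sessions and helpers."""

from __future__ import annotations

import numpy as np
import pytest

import ripplesync as rs


@pytest.fixture(scope="session")
def wt_session():
    """A short MEC-leads session with ground truth (deterministic)."""
    cfg = rs.preset_config("wt", duration_s=200.0, seed=11, ripple_rate_hz=0.3)
    return rs.generate_session(cfg)


@pytest.fixture(scope="session")
def wt_detections(wt_session):
    """Events detected on both regions of the shared session."""
    lfp_ca1, lfp_mec, track, truth = wt_session
    speed = rs.compute_speed(track)
    mask = rs.immobility_mask(speed, lfp_ca1)
    ev_ca1 = rs.detect_events(rs.ripple_envelope_z(lfp_ca1), mask, lfp=lfp_ca1)
    ev_mec = rs.detect_events(rs.ripple_envelope_z(lfp_mec), mask, lfp=lfp_mec)
    return ev_ca1, ev_mec, mask


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
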