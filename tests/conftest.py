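"""Shared fixtures: synthetic trials at the canonical study conditions.

Expensive trials are session-scoped; anything cheap is built inline in
the tests themselves.
"""
from dataclasses import replace

import numpy as np
import pytest

from glottovib.synth import RECIPES, make_trial


@pytest.fixture(scope="session")
def ventricular_trial():
    """Opaque slow-ramp trial: 2 kHz-band oscillation filmed at 20 kfps."""
    return make_trial("ventricular-slow-ramp", seed=101)


@pytest.fixture(scope="session")
def membrane_trial():
    """Translucent fast-pulse trial: ~15 kHz oscillation at 125 kfps."""
    return make_trial("membrane-fast-pulses", seed=202)


@pytest.fixture(scope="session")
def short_opaque_noiseless_trial():
    """Small noiseless opaque trial for pixel-exact segmentation checks."""
    rec = replace(RECIPES["ventricular-slow-ramp"], video_noise_sd=0.0,
                  video_duration=0.012,
                  protocol_params={"start": 3.0, "end": 6.0, "rate": 1.0,
                                   "hold_s": 0.2})
    return make_trial(rec, seed=303)


@pytest.fixture(scope="session")
def disk_trial(tmp_path_factory):
    """A short trial written in the canonical on-disk bundle layout."""
    rec = replace(RECIPES["ventricular-slow-ramp"], video_duration=0.02,
                  protocol_params={"start": 3.0, "end": 6.0, "rate": 1.0,
                                   "hold_s": 0.2})
    out = tmp_path_factory.mktemp("trials") / "trial"
    make_trial(rec, seed=404, out_dir=out)
    return out
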