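"""Shared fixtures: benchmark suites and the image-analysis pipeline helper."""

import numpy as np
import pytest

from caber.imaging import (
    EventIndices,
    calibrate_scale,
    detect_breakup,
    detect_motion_stop,
    extract_trace,
    measure_widths,
    track_gap,
)
from caber.simulate import make_benchmark_suite

SUITE_SEED = 7


@pytest.fixture(scope="session")
def suite():
    """Benchmark fixtures under the default (noisy) study conditions."""
    return make_benchmark_suite(seed=SUITE_SEED)


@pytest.fixture(scope="session")
def suite_noiseless():
    return make_benchmark_suite(seed=SUITE_SEED, noise=False)


def run_image_pipeline(stack, g_f):
    """Calibrate, find events, and extract the trace from a rendered stack.

    Returns (trace, pixel_scale, motion_stop_frame, breakup_frame).
    """
    scale = calibrate_scale(stack.frames[0])
    stack.pixel_scale = scale
    gaps = track_gap(stack)
    stop = detect_motion_stop(gaps, g_f)
    widths = measure_widths(stack)
    rel = detect_breakup(widths[stop:])
    breakup = None if rel is None else stop + rel
    trace = extract_trace(stack, EventIndices(stop, breakup))
    return trace, scale, stop, breakup


@pytest.fixture(scope="session")
def pipeline():
    return run_image_pipeline


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
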