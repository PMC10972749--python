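import numpy as np
import pytest

from reflexkit import (
    BreathSimParams,
    CalciumSimParams,
    gen_breath_trace,
    gen_calcium_session,
    gen_stimulus_protocol,
    segment_breaths,
)


@pytest.fixture
def compression_epochs():
    return gen_stimulus_protocol("compression")


@pytest.fixture
def clean_breath_trace():
    """Noise-free 60-s trace at 150 BPM with no injected events."""
    return gen_breath_trace(BreathSimParams(seed=0))


@pytest.fixture
def clean_breath_table(clean_breath_trace):
    trace, _ = clean_breath_trace
    return segment_breaths(trace)


@pytest.fixture
def calcium_session():
    """100-ROI session: 10 compression-only, 5 inflation-only, 2 dual
    responders, 2 unhealthy ROIs, zero noise."""
    responder_map = {i: ["compression"] for i in range(10)}
    responder_map.update({i: ["inflation"] for i in range(10, 15)})
    responder_map.update({i: ["compression", "inflation"] for i in range(15, 17)})
    params = CalciumSimParams(
        responder_map=responder_map, unhealthy_rois=[98, 99], noise_sd=0.0, seed=1
    )
    traces, truth = gen_calcium_session(params)
    return params, traces, truth


def sine_trace(freq_hz=2.5, duration_s=10.0, fs=1000.0, amplitude=1.0, kind="pressure"):
    from reflexkit import SampledTrace

    t = np.arange(round(duration_s * fs)) / fs
    return SampledTrace(
        values=amplitude * np.sin(2 * np.pi * freq_hz * t),
        sampling_rate_hz=fs,
        kind=kind,
    )
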