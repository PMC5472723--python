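"""Synthetic stimuli, ground-truth neurons, and the recovery metric."""

import math

import numpy as np
import pytest

from qconv.metrics import pooling_decomposition, sparseness
from qconv.model import predict_rate, softplus
from qconv.stimuli import PatchConfig, grid_shape
from qconv.synthetic import (
    generate_stimulus,
    make_third_order_neuron,
    qc_ground_truth,
    response_rates,
    sample_repeats,
    sample_spikes,
    subspace_projection,
    third_order_response,
)


def test_white_stimulus_moments_and_reproducibility():
    m1 = generate_stimulus("white", 200, 10, 10, seed=5)
    m2 = generate_stimulus("white", 200, 10, 10, seed=5)
    np.testing.assert_array_equal(m1.frames, m2.frames)
    assert abs(m1.frames.mean()) < 1e-12
    assert m1.frames.std() == pytest.approx(1.0, abs=1e-9)


def test_different_seeds_uncorrelated():
    a = generate_stimulus("white", 1200, 10, 10, seed=1).frames.ravel()
    b = generate_stimulus("white", 1200, 10, 10, seed=2).frames.ravel()
    assert abs(np.corrcoef(a, b)[0, 1]) < 0.01


def test_pink_spectrum_slope():
    """Log amplitude falls roughly as -1 per log spatial frequency."""
    m = generate_stimulus("pink", 400, 32, 32, seed=3)
    spec = np.abs(np.fft.fft2(m.frames, axes=(1, 2))).mean(axis=0)
    fy = np.fft.fftfreq(32)[:, None]
    fx = np.fft.fftfreq(32)[None, :]
    f = np.hypot(fy, fx).ravel()
    a = spec.ravel()
    keep = (f > 0.05) & (f < 0.4)
    slope = np.polyfit(np.log(f[keep]), np.log(a[keep]), 1)[0]
    assert slope == pytest.approx(-1.0, abs=0.15)


def test_third_order_response_rules():
    shape = (10, 10)
    movie = generate_stimulus("pink", 3000, *shape, seed=4)
    neuron = make_third_order_neuron(shape, movie=movie)
    # orthonormal features
    G = np.stack(neuron.features)
    np.testing.assert_allclose(G @ G.T, np.eye(3), atol=1e-10)
    # a patch orthogonal to u1 gives exactly the baseline rate
    patch = neuron.features[1] * 2.0 + neuron.features[2]
    assert third_order_response(patch, neuron) == pytest.approx(neuron.baseline_rate)
    # u1+u2+u3 drives the rectified triple product of unit projections
    patch = sum(neuron.features)
    expected = neuron.baseline + neuron.gain * softplus(neuron.scale)
    assert third_order_response(patch, neuron) == pytest.approx(float(expected))
    # calibration: mean rate ~ 1 spike/bin on the probe ensemble
    rates = response_rates(neuron, movie)
    assert rates.mean() == pytest.approx(1.0, abs=0.05)
    bad = make_third_order_neuron(shape)
    bad.features = bad.features[:2]
    with pytest.raises(ValueError, match="3 features"):
        third_order_response(patch, bad)


def test_qc_ground_truth_position_invariance():
    """Uniform pooling: rates are unchanged under one-stride stimulus shifts."""
    cfg = PatchConfig(6, 6, stride=3, n_lags=1)
    probe = generate_stimulus("pink", 2000, 12, 12, seed=6)
    neuron = qc_ground_truth(frame_shape=(12, 12), cfg=cfg, exc_thetas=(0.3,),
                             movie=probe, rule="qc", pooling="uniform")
    rng = np.random.default_rng(7)
    # energy confined to an interior one-stride block, so shifting by one
    # stride permutes the patch views without creating new edge overlaps
    inner = np.zeros((40, 12, 12))
    inner[:, 3:6, 3:6] = rng.normal(size=(40, 3, 3))
    from qconv.stimuli import StimulusMovie

    m1 = StimulusMovie(inner, bin_ms=16.0, center=False)
    m2 = StimulusMovie(np.roll(inner, 3, axis=2), bin_ms=16.0, center=False)
    r1 = predict_rate(m1, neuron.params, cfg, neuron.spec)
    r2 = predict_rate(m2, neuron.params, cfg, neuron.spec)
    np.testing.assert_allclose(r1, r2, rtol=1e-8)


def test_cross_orientation_suppression_signature(cross_orientation_neuron):
    """Preferred gratings beat plaids at matched total contrast."""
    neuron = cross_orientation_neuron
    cfg = neuron.cfg
    H, W = neuron.frame_shape
    y, x = np.mgrid[0:H, 0:W].astype(float)
    pref = np.cos(2 * np.pi * x / 8.4)  # vertical bars = 0-degree carrier
    orth = np.cos(2 * np.pi * y / 8.4)
    c = 2.0
    from qconv.stimuli import StimulusMovie

    def rate_of(frame):
        m = StimulusMovie(np.repeat(frame[None], 1, axis=0), bin_ms=16.0, center=False)
        return predict_rate(m, neuron.params, cfg, neuron.spec)[0]

    r_pref = rate_of(c * pref)
    r_plaid = rate_of(c / np.sqrt(2) * (pref + orth))
    assert r_pref > r_plaid


def test_qc_biphasic_pooling_roundtrip():
    cfg = PatchConfig(6, 6, stride=3, n_lags=1)
    neuron = qc_ground_truth(frame_shape=(12, 12), cfg=cfg, exc_thetas=(0.0,),
                             pooling="biphasic", rule="qc")
    gy, gx = grid_shape((12, 12), cfg)
    dec = pooling_decomposition(neuron.params.v2, (gy, gx), 1)
    assert dec.pooling_type == "biphasic"


def test_sample_spikes():
    assert np.all(sample_spikes(np.zeros(500), seed=1) == 0)
    rates = np.full(100_000, 5.0)
    counts = sample_spikes(rates, seed=2)
    assert counts.mean() == pytest.approx(5.0, abs=3 * math.sqrt(5.0 / 100_000))
    np.testing.assert_array_equal(counts, sample_spikes(rates, seed=2))
    reps = sample_repeats(np.full(50, 2.0), 4, seed=3)
    assert reps.shape == (4, 50)


def test_subspace_projection_examples():
    e = np.eye(4)
    assert subspace_projection([e[0], e[1]], [e[0], e[1]]) == pytest.approx(1.0)
    assert subspace_projection([e[2]], [e[0], e[1]]) == pytest.approx(0.0)
    assert subspace_projection([e[0]], [e[0], e[1]]) == pytest.approx(0.5)
    # invariant to the basis chosen for the recovered span
    mixed = [e[0] + e[1], e[0] - e[1]]
    assert subspace_projection(mixed, [e[0], e[1]]) == pytest.approx(1.0)
    with pytest.raises(ValueError, match="zero vectors"):
        subspace_projection([np.zeros(4)], [e[0]])
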