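"""Poisson NLL, analytic gradients, SGD fitting, and evaluation."""

import numpy as np
import pytest

from qconv.fit import (
    FitConfig,
    evaluate,
    fit_qc,
    nll_gradient,
    noise_ceiling,
    poisson_nll,
)
from qconv.model import ModelSpec, QCParams, forward, softplus
from qconv.stimuli import PatchConfig
from qconv.synthetic import generate_stimulus, sample_repeats, sample_spikes
from qconv.gaborfit import GaborParams, gabor_vector


def test_poisson_nll_examples():
    assert poisson_nll([1.0], [0]) == pytest.approx(1.0)
    assert poisson_nll([2.0, 2.0], [2, 2]) == pytest.approx(2 * (2 - 2 * np.log(2.0)))
    assert poisson_nll([2.0, 2.0], [2, 2], mean=True) == pytest.approx(2 - 2 * np.log(2.0))


def test_poisson_nll_minimized_at_counts():
    counts = np.array([1.0, 3.0, 2.0])
    base = poisson_nll(counts, counts)
    for eps in (-0.1, 0.1):
        assert poisson_nll(counts + eps, counts) > base


def test_poisson_nll_rejects_invalid():
    with pytest.raises(ValueError, match="undefined"):
        poisson_nll([0.0], [1])
    with pytest.raises(ValueError, match="nonnegative"):
        poisson_nll([1.0], [-1])


def _random_instance(rng, P=9, K=3, B=16, quadratic=True, fn="softplus"):
    spec = ModelSpec(quadratic=quadratic, convolutional=True, final_nonlinearity=fn)
    X = rng.normal(size=(B, K, P))
    A = rng.normal(size=(P, P)) * 0.1
    params = QCParams(
        a1=rng.normal() * 0.3,
        v1=rng.normal(size=P) * 0.2,
        J=0.5 * (A + A.T) if quadratic else np.zeros((P, P)),
        v2=rng.normal(size=K) * 0.5,
        a2=rng.normal() * 0.2,
        d=1.0 + rng.random(),
    )
    _, _, r = forward(X, params, spec)
    y = rng.poisson(r + 0.1)
    return spec, X, params, y


@pytest.mark.parametrize("fn", ["softplus", "logistic"])
@pytest.mark.parametrize("quadratic", [True, False])
def test_gradient_matches_finite_differences(fn, quadratic):
    """Analytic gradient of each block agrees with central differences."""
    rng = np.random.default_rng(17)
    spec, X, params, y = _random_instance(rng, quadratic=quadratic, fn=fn)
    grad = nll_gradient(params, spec, X, y)
    eps = 1e-5

    def nll_of(p):
        _, _, r = forward(X, p, spec)
        return poisson_nll(r, y)

    for block in ("a1", "a2", "d"):
        p1, p2 = params.copy(), params.copy()
        setattr(p1, block, getattr(p1, block) + eps)
        setattr(p2, block, getattr(p2, block) - eps)
        num = (nll_of(p1) - nll_of(p2)) / (2 * eps)
        assert getattr(grad, block) == pytest.approx(num, rel=1e-5, abs=1e-7)
    for block in ("v1", "v2"):
        vec = getattr(params, block)
        for i in range(vec.size):
            p1, p2 = params.copy(), params.copy()
            getattr(p1, block)[i] += eps
            getattr(p2, block)[i] -= eps
            num = (nll_of(p1) - nll_of(p2)) / (2 * eps)
            assert getattr(grad, block)[i] == pytest.approx(num, rel=1e-5, abs=1e-7)
    if quadratic:
        idx = [(0, 0), (1, 3), (4, 2), (8, 8)]
        for i, j in idx:
            p1, p2 = params.copy(), params.copy()
            p1.J[i, j] += eps
            p2.J[i, j] -= eps
            num = (nll_of(p1) - nll_of(p2)) / (2 * eps)
            assert grad.J[i, j] == pytest.approx(num, rel=1e-5, abs=1e-7)


def test_gradient_additivity():
    """Duplicating the batch doubles the summed-NLL gradient exactly."""
    rng = np.random.default_rng(23)
    spec, X, params, y = _random_instance(rng)
    g1 = nll_gradient(params, spec, X, y)
    g2 = nll_gradient(params, spec, np.concatenate([X, X]), np.concatenate([y, y]))
    np.testing.assert_allclose(g2.J, 2 * g1.J, rtol=1e-12)
    np.testing.assert_allclose(g2.v1, 2 * g1.v1, rtol=1e-12)
    assert g2.a2 == pytest.approx(2 * g1.a2, rel=1e-12)


def test_d_gradient_zero_at_constant_rate_stationary_point():
    """With v2 = 0 and a2 at the 1-parameter optimum, d has no gradient.

    The constant-rate model's NLL over a2 is minimized when
    softplus(a2) equals the mean count; there the remaining d-direction
    is flat because the pooled signal it scales is identically zero.
    """
    rng = np.random.default_rng(29)
    spec = ModelSpec()
    P, K, B = 4, 2, 64
    X = rng.normal(size=(B, K, P))
    y = rng.poisson(1.3, size=B)
    a2 = float(np.log(np.expm1(y.mean())))
    params = QCParams(a1=0.0, v1=np.zeros(P), J=np.zeros((P, P)),
                      v2=np.zeros(K), a2=a2, d=1.0)
    grad = nll_gradient(params, spec, X, y)
    assert grad.d == pytest.approx(0.0, abs=1e-12)
    assert grad.a2 == pytest.approx(0.0, abs=1e-9)


def test_linear_filter_recovery_and_determinism():
    """An LN ground-truth filter is recovered; same seed gives same fit."""
    H = W = 8
    movie = generate_stimulus("white", 24000, H, W, seed=1)
    g = GaborParams(x0=3.5, y0=3.5, theta=0.5, gamma=1.0, sigma=2.0, lam=5.0, phi=0.3)
    v = gabor_vector(g, (H, W))
    drive = movie.frames.reshape(-1, H * W) @ v * 2.0
    y = sample_spikes(softplus(drive - 0.5), seed=2)
    cfg = PatchConfig(H, W)
    spec = ModelSpec(quadratic=False, convolutional=False)
    fitcfg = FitConfig(seed=0, max_epochs=25, patience=4)
    res = fit_qc(movie, y, cfg, fitcfg, spec)
    cos = abs(res.params.v1 @ v) / np.linalg.norm(res.params.v1)
    assert cos >= 0.9
    res2 = fit_qc(movie, y, cfg, fitcfg, spec)
    np.testing.assert_array_equal(res.params.v1, res2.params.v1)
    np.testing.assert_array_equal(res.params.J, res2.params.J)
    # averaged parameters are the element-wise fold mean
    np.testing.assert_allclose(
        res.params.v1, np.mean([p.v1 for p in res.fold_params], axis=0), rtol=1e-12
    )


def test_constant_rate_neuron_degenerate_target():
    """A stimulus-independent neuron yields a near-constant fitted rate."""
    movie = generate_stimulus("white", 6000, 6, 6, seed=3)
    y = sample_spikes(np.full(6000, 1.5), seed=4)
    cfg = PatchConfig(6, 6)
    res = fit_qc(movie, y, cfg, FitConfig(seed=1, max_epochs=10, patience=3, batch_size=256),
                 ModelSpec(quadratic=False, convolutional=False))
    from qconv.model import predict_rate

    rates = predict_rate(movie, res.params, cfg, ModelSpec(quadratic=False, convolutional=False))
    assert rates.std() / rates.mean() < 0.1
    assert rates.mean() == pytest.approx(y.mean(), rel=0.1)


def test_fit_rejects_degenerate_inputs():
    movie = generate_stimulus("white", 5000, 6, 6, seed=5)
    cfg = PatchConfig(6, 6)
    with pytest.raises(ValueError, match="all-zero"):
        fit_qc(movie, np.zeros(5000), cfg, FitConfig(), ModelSpec())
    with pytest.raises(ValueError, match="usable frames"):
        fit_qc(movie, np.ones(5000), cfg, FitConfig(batch_size=1024), ModelSpec())


def test_noise_corrected_correlation_consistency():
    """Prediction equal to the true rate scores ~1 after noise correction."""
    rng = np.random.default_rng(31)
    T = 1500
    rate = np.exp(rng.normal(size=T) * 0.5)
    reps = sample_repeats(rate, 10, seed=6)
    movie = generate_stimulus("white", T, 4, 4, seed=7)
    cfg = PatchConfig(4, 4)
    # package the known rate as a degenerate model via a monkeypatched
    # prediction would couple tests; use the ceiling machinery directly
    from qconv.fit import _pearson

    r_raw = _pearson(rate, reps.mean(axis=0))
    r_max = noise_ceiling(reps, seed=8)
    assert r_raw / r_max == pytest.approx(1.0, abs=0.05)


def test_evaluate_independent_prediction_scores_zero():
    rng = np.random.default_rng(37)
    T = 1200
    rate = np.exp(rng.normal(size=T) * 0.5)
    reps = sample_repeats(rate, 8, seed=9)
    movie = generate_stimulus("white", T, 4, 4, seed=10)
    cfg = PatchConfig(4, 4)
    p = QCParams(a1=0.0, v1=rng.normal(size=16), J=np.zeros((16, 16)),
                 v2=np.ones(1), a2=0.0, d=1.0)
    res = evaluate(p, ModelSpec(quadratic=False, convolutional=False), cfg, movie, reps, seed=11)
    assert abs(res["r_raw"]) < 0.1
    assert res["r_corrected"] <= 0.12


def test_evaluate_requires_repeats(small_movie):
    p = QCParams.zeros(144, 1)
    with pytest.raises(ValueError, match="2 repeat trials"):
        evaluate(p, ModelSpec(quadratic=False, convolutional=False), PatchConfig(12, 12),
                 small_movie, np.ones((1, 60)))
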