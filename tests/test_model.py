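"""Forward model: nonlinearities, subunits, rates, reduced variants."""

import numpy as np
import pytest

from qconv.model import (
    ModelSpec,
    QCParams,
    logistic,
    predict_rate,
    qls_response,
    softplus,
)
from qconv.stimuli import PatchConfig, StimulusMovie
from qconv.synthetic import generate_stimulus, qc_ground_truth, response_rates, response_rates_loop


@pytest.mark.parametrize(
    "x, expected",
    [(0.0, 0.5), (2.0, 1.0 / (1.0 + np.exp(-2.0))), (800.0, 1.0), (-800.0, 0.0)],
)
def test_logistic(x, expected):
    assert logistic(x) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize(
    "x, expected",
    [(0.0, np.log(2.0)), (50.0, 50.0), (-5.0, np.log1p(np.exp(-5.0)))],
)
def test_softplus(x, expected):
    assert softplus(x) == pytest.approx(expected, rel=1e-9)


def test_qls_neutral_parameters_give_half():
    p = QCParams.zeros(9, 1)
    assert qls_response(np.random.default_rng(0).normal(size=9), p) == 0.5


def test_qls_eigenvector_input():
    """On an eigenvector of J the quadratic form is c^2 * eigenvalue."""
    rng = np.random.default_rng(1)
    A = rng.normal(size=(6, 6))
    J = 0.5 * (A + A.T)
    evals, evecs = np.linalg.eigh(J)
    p = QCParams(a1=0.0, v1=np.zeros(6), J=J, v2=np.ones(1), a2=0.0, d=1.0)
    c = 1.7
    got = qls_response(c * evecs[:, 2], p)
    assert got == pytest.approx(float(logistic(c**2 * evals[2])), rel=1e-12)


def test_qls_matches_double_sum():
    rng = np.random.default_rng(2)
    A = rng.normal(size=(4, 4))
    J = 0.5 * (A + A.T)
    v1 = rng.normal(size=4)
    x = rng.normal(size=4)
    p = QCParams(a1=0.3, v1=v1, J=J, v2=np.ones(1), a2=0.0, d=1.0)
    quad = sum(J[i, j] * x[i] * x[j] for i in range(4) for j in range(4))
    expected = 1.0 / (1.0 + np.exp(-(0.3 + v1 @ x + quad)))
    assert qls_response(x, p) == pytest.approx(expected, rel=1e-12)


def test_constant_rate_when_pooling_zero(small_movie):
    cfg = PatchConfig(6, 6, stride=3, n_lags=2)
    p = QCParams.zeros(36, 2 * 9)
    p.a2 = 0.7
    spec = ModelSpec()
    rates = predict_rate(small_movie, p, cfg, spec)
    assert rates.shape == (small_movie.n_frames - 1,)
    np.testing.assert_allclose(rates, softplus(0.7))


def test_one_hot_pooling_equals_single_position(small_movie):
    """v2 selecting one grid slot reproduces that position's subunit alone."""
    cfg = PatchConfig(6, 6, stride=6, n_lags=1)  # 2x2 grid
    rng = np.random.default_rng(3)
    A = rng.normal(size=(36, 36)) * 0.1
    base = dict(a1=0.1, v1=rng.normal(size=36) * 0.2, J=0.5 * (A + A.T), a2=-0.2, d=1.3)
    v2 = np.zeros(4)
    v2[0] = 1.0
    p_conv = QCParams(v2=v2, **base)
    rates_conv = predict_rate(small_movie, p_conv, cfg, ModelSpec())
    # non-convolutional model evaluated at the same (top-left) position
    from qconv.stimuli import design_tensor
    from qconv.model import forward

    X = design_tensor(small_movie, cfg, positions=[(0, 0)])
    p_single = QCParams(v2=np.ones(1), **base)
    _, _, rates_single = forward(X, p_single, ModelSpec(convolutional=False))
    np.testing.assert_allclose(rates_conv, rates_single, rtol=1e-12)


def test_predict_matches_straight_loop_oracle():
    """Vectorized rates equal an independent straight-loop evaluation."""
    movie = generate_stimulus("white", 25, 14, 14, seed=9)
    cfg = PatchConfig(10, 10, stride=4, n_lags=2)
    probe = generate_stimulus("pink", 500, 14, 14, seed=10)
    neuron = qc_ground_truth(
        frame_shape=(14, 14),
        cfg=cfg,
        exc_thetas=(0.3,),
        sup_thetas=(0.3 + np.pi / 2,),
        movie=probe,
        rule="qc",
    )
    fast = response_rates(neuron, movie)
    slow = response_rates_loop(neuron, movie)
    np.testing.assert_allclose(fast, slow, rtol=1e-10)


def test_translation_covariance(small_movie):
    """Shifting the stimulus by one stride and rolling v2 leaves rates fixed."""
    cfg = PatchConfig(6, 6, stride=3, n_lags=1)  # 3x3 grid on 12x12
    rng = np.random.default_rng(4)
    A = rng.normal(size=(36, 36)) * 0.1
    v2 = rng.normal(size=(3, 3))
    v2[:, 2] = 0.0  # only interior positions carry weight, so the roll is exact
    p = QCParams(a1=0.0, v1=rng.normal(size=36) * 0.1, J=0.5 * (A + A.T),
                 v2=v2.ravel(), a2=0.0, d=1.0)
    shifted = StimulusMovie(np.roll(small_movie.frames, 3, axis=2), bin_ms=16.0, center=False)
    v2_rolled = np.roll(v2, 1, axis=1).ravel()
    p_rolled = QCParams(a1=0.0, v1=p.v1, J=p.J, v2=v2_rolled, a2=0.0, d=1.0)
    r1 = predict_rate(small_movie, p, cfg, ModelSpec())
    r2 = predict_rate(shifted, p_rolled, cfg, ModelSpec())
    np.testing.assert_allclose(r1, r2, rtol=1e-10)


def test_reduced_model_contracts(small_movie):
    """quadratic=off with convolutional=off is the single-feature LN model."""
    cfg = PatchConfig(12, 12)
    rng = np.random.default_rng(5)
    v1 = rng.normal(size=144) * 0.1
    p = QCParams(a1=0.2, v1=v1, J=np.zeros((144, 144)), v2=np.ones(1), a2=0.1, d=1.5)
    spec = ModelSpec(quadratic=False, convolutional=False)
    rates = predict_rate(small_movie, p, cfg, spec)
    X = small_movie.frames.reshape(-1, 144)
    expected = softplus(1.5 * logistic(0.2 + X @ v1) + 0.1)
    np.testing.assert_allclose(rates, expected, rtol=1e-12)
    assert np.all(rates > 0)


def test_logistic_output_bounded(small_movie):
    cfg = PatchConfig(6, 6, stride=3, n_lags=1)
    rng = np.random.default_rng(6)
    A = rng.normal(size=(36, 36))
    p = QCParams(a1=0.0, v1=rng.normal(size=36), J=0.5 * (A + A.T),
                 v2=rng.normal(size=9), a2=0.0, d=2.5)
    rates = predict_rate(small_movie, p, cfg, ModelSpec(final_nonlinearity="logistic"))
    assert np.all(rates > 0) and np.all(rates < 2.5)


def test_nan_parameters_rejected(small_movie):
    p = QCParams.zeros(144, 1)
    p.a1 = np.nan
    with pytest.raises(ValueError, match="non-finite"):
        predict_rate(small_movie, p, PatchConfig(12, 12), ModelSpec())


def test_dimension_mismatch_message():
    p = QCParams.zeros(9, 1)
    with pytest.raises(ValueError, match="4 pixels.*expects 9"):
        qls_response(np.zeros(4), p)
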