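"""Ground-truth model neurons and stimulus ensembles.

Every recovery and calibration test in the package runs against data
simulated here: stimulus movies (spatially white or 1/f "naturalistic"
Gaussian noise), model neurons with exactly known parameters, and
Poisson spike generation.  Three response rules are provided:

* ``quadratic`` -- a single quadratic-logistic subunit (complex-cell-like,
  no pooling);
* ``qc`` -- the full convolutional model with a known pooling mask;
* ``third_order`` -- a neuron driven exclusively by the rectified triple
  product of three orthonormal feature projections, which probes whether
  the quadratic analysis can recover features that act only through
  higher-than-second-order interactions.

The quadratic/qc neurons carry exact :class:`~qconv.model.QCParams`, but
their reference responses are evaluated through a deliberately
independent straight-loop implementation (explicit sums over patches,
pixels and kernel entries) so the vectorized forward pass can be checked
against it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .gaborfit import GaborParams, gabor_vector
from .model import ModelSpec, QCParams, softplus
from .stimuli import PatchConfig, StimulusMovie, _grid_positions, design_tensor, extract_patches, grid_shape

__all__ = [
    "GroundTruthNeuron",
    "generate_stimulus",
    "third_order_response",
    "make_third_order_neuron",
    "qc_ground_truth",
    "sample_spikes",
    "sample_repeats",
    "subspace_projection",
    "response_rates",
    "response_rates_loop",
]


def generate_stimulus(
    kind: str,
    T: int,
    H: int,
    W: int,
    seed: int = 0,
    bin_ms: float = 16.0,
) -> StimulusMovie:
    """Gaussian stimulus movie with a white or 1/f spatial spectrum.

    ``white`` draws i.i.d. standard-normal pixels.  ``pink`` filters
    framewise white noise so the spatial amplitude spectrum falls as
    1/f (random phases come from the underlying noise), a stand-in for
    the second-order statistics of natural movies.  Either way the
    movie is standardized to mean 0, variance 1.
    """
    if T < 1 or H < 1 or W < 1:
        raise ValueError("T, H, W must be positive")
    rng = np.random.default_rng(seed)
    if kind == "white":
        frames = rng.standard_normal((T, H, W))
    elif kind == "pink":
        fy = np.fft.fftfreq(H)[:, None]
        fx = np.fft.fftfreq(W)[None, :]
        f = np.hypot(fy, fx)
        amp = np.zeros_like(f)
        amp[f > 0] = 1.0 / f[f > 0]
        white = rng.standard_normal((T, H, W))
        spec = np.fft.fft2(white, axes=(1, 2)) * amp[None]
        frames = np.fft.ifft2(spec, axes=(1, 2)).real
    else:
        raise ValueError(f"kind must be 'white' or 'pink', got {kind!r}")
    frames = frames - frames.mean()
    sd = frames.std()
    if sd > 0:
        frames = frames / sd
    return StimulusMovie(frames=frames, bin_ms=bin_ms, center=True)


@dataclass
class GroundTruthNeuron:
    """A synthetic neuron with exactly known structure.

    ``features`` are mutually orthonormalized unit-norm patch-space
    vectors.  For the quadratic/qc rules ``params`` holds the exact
    model parameters; for the third-order rule the response is
    ``baseline + gain * softplus(scale * prod_i (u_i . x))`` and
    ``baseline_rate`` (the rate whenever the triple product vanishes)
    equals ``baseline + gain * log 2``.
    """

    rule: str
    features: list
    cfg: PatchConfig
    frame_shape: tuple[int, int]
    params: QCParams | None = None
    spec: ModelSpec | None = None
    gain: float = 1.0
    baseline: float = 0.1
    scale: float = 1.0
    exc_gabors: list = field(default_factory=list)
    sup_gabors: list = field(default_factory=list)

    @property
    def baseline_rate(self) -> float:
        return self.baseline + self.gain * math.log(2.0)


def _orthonormalize(vectors: list) -> list:
    """Gram-Schmidt; raises if the vectors are linearly dependent."""
    basis: list[np.ndarray] = []
    for v in vectors:
        u = np.asarray(v, dtype=np.float64).ravel().copy()
        for b in basis:
            u -= (b @ u) * b
        nrm = np.linalg.norm(u)
        if nrm < 1e-10:
            raise ValueError("features are linearly dependent; cannot orthonormalize")
        basis.append(u / nrm)
    return basis


def third_order_response(patch: np.ndarray, neuron: GroundTruthNeuron) -> float:
    """Rate of a third-order neuron for one patch."""
    if neuron.rule != "third_order":
        raise ValueError(f"neuron rule is {neuron.rule!r}, expected 'third_order'")
    if len(neuron.features) != 3:
        raise ValueError("third-order neuron needs exactly 3 features")
    x = np.asarray(patch, dtype=np.float64).ravel()
    t = 1.0
    for u in neuron.features:
        t *= float(u @ x)
    return neuron.baseline + neuron.gain * float(softplus(neuron.scale * t))


def _feature_gabors(shape: tuple[int, int], thetas, phis=None, lam=None, sigma=None):
    H, W = shape
    lam = lam if lam is not None else 0.6 * min(H, W)
    sigma = sigma if sigma is not None else 0.25 * min(H, W)
    phis = phis if phis is not None else [0.0] * len(thetas)
    out = []
    for th, ph in zip(thetas, phis):
        out.append(
            GaborParams(
                x0=(W - 1) / 2.0,
                y0=(H - 1) / 2.0,
                theta=th,
                gamma=1.0,
                sigma=sigma,
                lam=lam,
                phi=ph,
            )
        )
    return out


def make_third_order_neuron(
    patch_shape: tuple[int, int],
    movie: StimulusMovie | None = None,
    target_rate: float = 1.0,
    baseline: float = 0.1,
    bin_ms: float = 16.0,
    seed: int = 0,
) -> GroundTruthNeuron:
    """Third-order neuron with three orthonormalized Gabor-like features.

    The features are centered Gabors at orientations 0, 60 and 120
    degrees (phases 0, 90, 0 so they are close to orthogonal before
    Gram-Schmidt).  If a probe movie is given, ``scale`` is set to the
    reciprocal standard deviation of the triple product over the probe
    and ``gain`` so the mean rate is about ``target_rate`` spikes/bin.
    """
    H, W = patch_shape
    gabors = _feature_gabors(
        patch_shape,
        thetas=[0.0, math.pi / 3.0, 2.0 * math.pi / 3.0],
        phis=[0.0, math.pi / 2.0, 0.0],
    )
    feats = _orthonormalize([gabor_vector(g, patch_shape) for g in gabors])
    cfg = PatchConfig(H, W, stride=1, n_lags=1)
    neuron = GroundTruthNeuron(
        rule="third_order",
        features=feats,
        cfg=cfg,
        frame_shape=patch_shape,
        baseline=baseline,
        gain=1.0,
        scale=1.0,
    )
    if movie is not None:
        X = design_tensor(movie, cfg, positions=[(0, 0)])[:, 0, :]
        proj = np.stack([X @ u for u in feats])
        t = proj.prod(axis=0)
        sd = float(t.std())
        if sd > 0:
            neuron.scale = 1.0 / sd
        mean_sp = float(np.mean(softplus(neuron.scale * t)))
        neuron.gain = max((target_rate - baseline) / mean_sp, 1e-6)
    return neuron


def qc_ground_truth(
    frame_shape: tuple[int, int] = (14, 14),
    cfg: PatchConfig = None,
    exc_thetas=(0.0,),
    sup_thetas=(),
    exc_weight: float = 1.0,
    sup_weight: float = 1.0,
    pooling: str = "uniform",
    movie: StimulusMovie | None = None,
    target_rate: float = 1.0,
    drive_sd: float = 2.0,
    rule: str = "qc",
) -> GroundTruthNeuron:
    """QC model neuron built from quadrature-pair Gabor features.

    Each entry of ``exc_thetas`` contributes an excitatory quadrature
    pair (phases 0 and 90 degrees) at that orientation, each of
    ``sup_thetas`` a suppressive pair with weight ``-sup_weight``; the
    classic cross-orientation-suppression neuron is one excitatory
    orientation plus the orthogonal suppressive one.  The kernel is
    scaled so the subunit drive has standard deviation ``drive_sd``
    over a probe movie (if given), the subunit bias centers the drive,
    and the output stage is calibrated to ``target_rate`` spikes/bin.
    ``pooling`` chooses a uniform or two-lobed (biphasic) spatial mask.
    With ``rule="quadratic"`` the grid is collapsed to the single
    central position (non-convolutional complex cell).
    """
    if cfg is None:
        cfg = PatchConfig(10, 10, stride=4, n_lags=1)
    patch_shape = (cfg.patch_h, cfg.patch_w)
    P = cfg.patch_h * cfg.patch_w
    exc_gabors, sup_gabors = [], []
    J = np.zeros((P, P))
    for th in exc_thetas:
        for phi in (0.0, math.pi / 2.0):
            g = _feature_gabors(patch_shape, [th], [phi])[0]
            g.w = exc_weight
            v = gabor_vector(g, patch_shape)
            J += exc_weight * np.outer(v, v)
            exc_gabors.append(g)
    for th in sup_thetas:
        for phi in (0.0, math.pi / 2.0):
            g = _feature_gabors(patch_shape, [th], [phi])[0]
            g.w = -sup_weight
            v = gabor_vector(g, patch_shape)
            J -= sup_weight * np.outer(v, v)
            sup_gabors.append(g)
    convolutional = rule == "qc"
    spec = ModelSpec(quadratic=True, convolutional=convolutional)
    positions = _grid_positions(frame_shape, cfg, convolutional=convolutional)
    K = cfg.n_lags * len(positions)
    if pooling == "uniform" or K == 1:
        v2 = np.ones(K) / K
    elif pooling == "biphasic":
        v2 = np.ones(K)
        half = K // 2
        v2[half:] = -1.0
        v2 /= K
    else:
        raise ValueError(f"pooling must be 'uniform' or 'biphasic', got {pooling!r}")
    params = QCParams(a1=0.0, v1=np.zeros(P), J=J, v2=v2, a2=0.0, d=1.0)
    if movie is not None:
        X = design_tensor(movie, cfg, positions=positions)
        Xf = X.reshape(-1, P)
        drive = ((Xf @ params.J) * Xf).sum(axis=1)
        sd = float(drive.std())
        if sd > 0:
            scale = drive_sd / sd
            params.J = params.J * scale
            for g in exc_gabors + sup_gabors:
                g.w *= scale
            drive = drive * scale
        params.a1 = -float(drive.mean())
        from scipy.special import expit

        s = expit(params.a1 + drive).reshape(X.shape[0], K)
        pooled = s @ params.v2
        psd = float(pooled.std())
        params.d = 3.0 / psd if psd > 0 else 1.0
        y0 = target_rate
        # softplus(a2 + d*mean(pooled)) ~ target_rate
        params.a2 = _softplus_inv(y0) - params.d * float(pooled.mean())
    feats = []
    for g in exc_gabors + sup_gabors:
        feats.append(gabor_vector(g, patch_shape))
    return GroundTruthNeuron(
        rule=rule,
        features=feats,
        cfg=cfg,
        frame_shape=frame_shape,
        params=params,
        spec=spec,
        exc_gabors=exc_gabors,
        sup_gabors=sup_gabors,
    )


def _softplus_inv(y: float) -> float:
    y = max(float(y), 1e-8)
    return y if y > 30 else float(np.log(np.expm1(y)))


def response_rates(neuron: GroundTruthNeuron, movie: StimulusMovie) -> np.ndarray:
    """Rates of a ground-truth neuron for every frame with full lag history."""
    if neuron.rule == "third_order":
        X = design_tensor(movie, neuron.cfg, positions=[(0, 0)])[:, 0, :]
        proj = np.stack([X @ u for u in neuron.features])
        t = proj.prod(axis=0)
        return neuron.baseline + neuron.gain * softplus(neuron.scale * t)
    from .model import predict_rate

    return predict_rate(movie, neuron.params, neuron.cfg, neuron.spec)


def response_rates_loop(neuron: GroundTruthNeuron, movie: StimulusMovie) -> np.ndarray:
    """Straight-loop reference response, independent of the vectorized path.

    Explicit Python loops over frames, pooling slots, pixels and kernel
    entries.  Slow by design; use on short movies.
    """
    params, cfg, spec = neuron.params, neuron.cfg, neuron.spec
    if params is None:
        raise ValueError("loop oracle is defined for neurons with explicit QCParams")
    positions = _grid_positions(movie.frame_shape, cfg, convolutional=spec.convolutional)
    pos_set = {p: i for i, p in enumerate(positions)}
    gy, gx = grid_shape(movie.frame_shape, cfg)
    P = cfg.patch_pixels
    rates = []
    for t in range(cfg.n_lags - 1, movie.n_frames):
        all_patches = extract_patches(movie, cfg, t)
        pooled = 0.0
        for lag in range(cfg.n_lags):
            for (py, px), slot in pos_set.items():
                x = all_patches[lag * gy * gx + py * gx + px]
                u = params.a1
                for i in range(P):
                    u += params.v1[i] * x[i]
                    for j in range(P):
                        u += x[i] * params.J[i, j] * x[j]
                s = 1.0 / (1.0 + math.exp(-u))
                pooled += params.v2[lag * len(positions) + slot] * s
        if spec.final_nonlinearity == "softplus":
            rates.append(math.log1p(math.exp(min(params.d * pooled + params.a2, 700.0))))
        else:
            rates.append(params.d / (1.0 + math.exp(-(pooled + params.a2))))
    return np.array(rates)


def sample_spikes(rates: np.ndarray, seed: int = 0) -> np.ndarray:
    """Independent Poisson spike counts per bin, reproducible by seed."""
    rates = np.asarray(rates, dtype=np.float64)
    if np.any(rates < 0):
        raise ValueError("rates must be nonnegative")
    rng = np.random.default_rng(seed)
    return rng.poisson(rates)


def sample_repeats(rates: np.ndarray, n_trials: int, seed: int = 0) -> np.ndarray:
    """(n_trials, T) block of independent Poisson repeat trials."""
    rng = np.random.default_rng(seed)
    rates = np.asarray(rates, dtype=np.float64)
    return rng.poisson(rates[None, :].repeat(n_trials, axis=0))


def subspace_projection(recovered: list, true: list) -> float:
    """Mean squared projection of true features onto the recovered span.

    The recovered vectors are orthonormalized (SVD basis); for each
    normalized true feature the squared norm of its projection onto that
    span is computed and the mean over true features returned.  1 means
    the true span is fully contained in the recovered one.
    """
    if not recovered or not true:
        raise ValueError("both vector sets must be non-empty")
    R = np.stack([np.asarray(v, dtype=np.float64).ravel() for v in recovered])
    Tm = np.stack([np.asarray(v, dtype=np.float64).ravel() for v in true])
    if R.shape[1] != Tm.shape[1]:
        raise ValueError("recovered and true vectors live in different dimensions")
    norms = np.linalg.norm(Tm, axis=1)
    if np.any(norms == 0) or np.any(np.linalg.norm(R, axis=1) == 0):
        raise ValueError("zero vectors are not allowed")
    Tm = Tm / norms[:, None]
    U, S, _ = np.linalg.svd(R.T, full_matrices=False)
    rank = int(np.sum(S > S[0] * 1e-10))
    Q = U[:, :rank]
    proj = Q.T @ Tm.T
    return float(np.mean(np.sum(proj**2, axis=0)))
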