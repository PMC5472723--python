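"""Poisson maximum-likelihood fitting of the QC model.

All model parameters (a1, v1, J, v2, a2, d) are fitted by minimizing the
Poisson negative log-likelihood with stochastic gradient descent.  The
training data are divided into four contiguous temporal fourths; four
models are fitted, each holding out a different fourth as the validation
set for early stopping, and the four are averaged element-wise.
Contiguous (rather than shuffled) fourths are used because temporal
correlation in movie stimuli would leak information across shuffled
splits.

Model performance on repeated test trials is summarized by the Pearson
correlation between the prediction and the trial-averaged response,
divided by an estimate of the maximum attainable correlation given
trial-to-trial variability (split-half reliability of the repeat block,
Spearman-Brown extrapolated to the full trial count).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .model import ModelSpec, QCParams, forward
from .stimuli import PatchConfig, StimulusMovie, _grid_positions, design_tensor

__all__ = [
    "FitConfig",
    "FitResult",
    "poisson_nll",
    "nll_gradient",
    "fit_qc",
    "evaluate",
]

logger = logging.getLogger(__name__)

N_FOLDS = 4  # fixed by the fitting protocol


@dataclass(frozen=True)
class FitConfig:
    """Hyperparameters of the SGD fit.

    The optimizer is plain SGD with momentum on the mean-per-frame NLL.
    Learning rate, batch size and momentum are not dictated by the model
    itself; they are surfaced here rather than hard-coded.  ``init_sd``
    scales the Gaussian initialization of v1 and J; ``v2_init_sd`` that
    of the pooling weights (kept larger so gradient flow into the subunit
    parameters, which is proportional to v2, is not throttled at the
    start).
    """

    learning_rate: float = 0.01
    batch_size: int = 512
    max_epochs: int = 80
    patience: int = 10
    momentum: float = 0.9
    seed: int = 0
    init_sd: float = 1e-3
    v2_init_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.learning_rate <= 0 or self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("learning_rate, batch_size, max_epochs must be positive")


@dataclass
class FitResult:
    """Four fold models, their element-wise average, and NLL traces."""

    fold_params: list
    params: QCParams
    train_nll: list
    val_nll: list
    seed: int
    spec: ModelSpec = None
    cfg: PatchConfig = None


def poisson_nll(rates: np.ndarray, counts: np.ndarray, mean: bool = False) -> float:
    """Poisson negative log-likelihood, dropping the count-factorial term.

    ``sum_t rate_t - count_t * log(rate_t)``; with ``mean=True`` the
    per-frame average is returned instead of the sum.
    """
    rates = np.asarray(rates, dtype=np.float64)
    counts = np.asarray(counts, dtype=np.float64)
    if rates.shape != counts.shape:
        raise ValueError(f"rates {rates.shape} and counts {counts.shape} differ in shape")
    if np.any(counts < 0):
        raise ValueError("spike counts must be nonnegative")
    bad = (rates <= 0) & (counts > 0)
    if np.any(bad):
        raise ValueError(
            f"{int(bad.sum())} bins have rate <= 0 with nonzero counts; "
            "the Poisson likelihood is undefined there"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        logr = np.where(rates > 0, np.log(np.maximum(rates, 1e-300)), 0.0)
    terms = rates - counts * logr
    return float(terms.mean()) if mean else float(terms.sum())


def _grad_common(X: np.ndarray, counts: np.ndarray, params: QCParams, spec: ModelSpec):
    """Shared forward pass and chain-rule factors for the NLL gradient."""
    from scipy.special import expit

    s, z, rates = forward(X, params, spec)
    dldr = 1.0 - counts / np.maximum(rates, 1e-300)
    if spec.final_nonlinearity == "softplus":
        sz = expit(z)
        gz = dldr * sz  # d NLL / d z
        gd = float(gz @ (s @ params.v2))
        gv2 = params.d * (s.T @ gz)
        h = gz[:, None] * (params.d * params.v2)[None, :] * s * (1.0 - s)
    else:
        sz = expit(z)
        gz = dldr * params.d * sz * (1.0 - sz)
        gd = float(dldr @ sz)
        gv2 = s.T @ gz
        h = gz[:, None] * params.v2[None, :] * s * (1.0 - s)
    return s, rates, gz, gd, gv2, h


def nll_gradient(
    params: QCParams,
    spec: ModelSpec,
    X: np.ndarray,
    counts: np.ndarray,
) -> QCParams:
    """Analytic gradient of the summed Poisson NLL on a batch.

    ``X`` is a design tensor of shape (B, K, P) and ``counts`` the
    matching spike counts.  The gradient is returned in a QCParams-shaped
    container; the J block is symmetric by construction.  Blocks that the
    spec freezes (J for linear models) are returned as zeros.
    """
    counts = np.asarray(counts, dtype=np.float64)
    if counts.size == 0:
        raise ValueError("empty batch")
    _, _, gz, gd, gv2, h = _grad_common(X, counts, params, spec)
    B, K, P = X.shape
    Xf = X.reshape(B * K, P)
    hf = h.reshape(B * K)
    ga1 = float(hf.sum())
    gv1 = hf @ Xf
    if spec.quadratic:
        gJ = (Xf * hf[:, None]).T @ Xf
    else:
        gJ = np.zeros((P, P))
    ga2 = float(gz.sum())
    grad = QCParams(a1=ga1, v1=gv1, J=gJ, v2=gv2, a2=ga2, d=gd)
    for name in ("a1", "v1", "J", "v2", "a2", "d"):
        if not np.all(np.isfinite(np.asarray(getattr(grad, name)))):
            raise FloatingPointError(f"non-finite gradient in parameter block {name!r}")
    return grad


def _softplus_inv(y: float) -> float:
    y = max(float(y), 1e-8)
    if y > 30:
        return y
    return float(np.log(np.expm1(y)))


def _init_params(
    n_pixels: int,
    n_pool: int,
    mean_count: float,
    spec: ModelSpec,
    fitcfg: FitConfig,
    rng: np.random.Generator,
) -> QCParams:
    v1 = rng.normal(0.0, fitcfg.init_sd, size=n_pixels)
    J = np.zeros((n_pixels, n_pixels))
    if spec.quadratic:
        J = rng.normal(0.0, fitcfg.init_sd, size=(n_pixels, n_pixels))
        J = 0.5 * (J + J.T)
    v2 = rng.normal(0.0, fitcfg.v2_init_sd, size=n_pool)
    if spec.final_nonlinearity == "softplus":
        a2 = _softplus_inv(mean_count)
        d = 1.0
    else:
        # rate = d * sigma(z); start at the mean count with sigma ~ 0.5
        a2 = 0.0
        d = max(2.0 * mean_count, 1e-3)
    return QCParams(a1=0.0, v1=v1, J=J, v2=v2, a2=a2, d=d)


_BLOCKS = ("a1", "v1", "J", "v2", "a2", "d")


def _sgd_fold(
    X: np.ndarray,
    y: np.ndarray,
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    spec: ModelSpec,
    fitcfg: FitConfig,
    rng: np.random.Generator,
):
    """One early-stopped SGD run; returns best-validation parameters."""
    n_pixels = X.shape[2]
    n_pool = X.shape[1]
    params = _init_params(n_pixels, n_pool, float(y[train_idx].mean()), spec, fitcfg, rng)
    vel = {k: np.zeros_like(np.asarray(getattr(params, k), dtype=float)) for k in _BLOCKS}
    best = params.copy()
    _, _, rates = forward(X[val_idx], params, spec)
    best_val = poisson_nll(rates, y[val_idx], mean=True)
    train_trace, val_trace = [], []
    bad_epochs = 0
    n_train = train_idx.size
    for epoch in range(fitcfg.max_epochs):
        order = rng.permutation(n_train)
        for start in range(0, n_train, fitcfg.batch_size):
            b = train_idx[order[start : start + fitcfg.batch_size]]
            grad = nll_gradient(params, spec, X[b], y[b])
            inv_b = 1.0 / b.size
            for k in _BLOCKS:
                g = np.asarray(getattr(grad, k), dtype=float) * inv_b
                vel[k] = fitcfg.momentum * vel[k] - fitcfg.learning_rate * g
                val = getattr(params, k)
                if np.ndim(val) == 0:
                    setattr(params, k, float(val + vel[k]))
                else:
                    val += vel[k]
        # J stays symmetric because its gradient is symmetric; re-symmetrize
        # anyway to stop round-off drift.
        if spec.quadratic:
            params.J = 0.5 * (params.J + params.J.T)
        _, _, tr = forward(X[train_idx], params, spec)
        train_nll = poisson_nll(tr, y[train_idx], mean=True)
        _, _, vr = forward(X[val_idx], params, spec)
        val_nll = poisson_nll(vr, y[val_idx], mean=True)
        train_trace.append(train_nll)
        val_trace.append(val_nll)
        logger.info("epoch %d train NLL %.6f val NLL %.6f", epoch, train_nll, val_nll)
        if not np.isfinite(train_nll) or not np.isfinite(val_nll):
            raise FloatingPointError("NLL diverged during SGD; aborting fold")
        if val_nll < best_val:
            best_val = val_nll
            best = params.copy()
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= fitcfg.patience:
                break
    return best, train_trace, val_trace


def _canonicalize_sign(params: QCParams, spec: ModelSpec) -> QCParams:
    """Resolve the subunit sign symmetry before averaging fold models.

    Because sigma(-u) = 1 - sigma(u), flipping the sign of (a1, v1, J)
    together with v2 and shifting a2 by d * sum(v2) leaves the predicted
    rates identical.  Folds can land on either branch, which would cancel
    structure in the element-wise average, so every fold is flipped onto
    the branch where the largest-magnitude pooling weight is positive.
    """
    k = int(np.argmax(np.abs(params.v2)))
    if params.v2[k] >= 0:
        return params
    out = params.copy()
    shift = float(params.v2.sum())
    if spec.final_nonlinearity == "softplus":
        shift *= params.d
    out.a1 = -out.a1
    out.v1 = -out.v1
    out.J = -out.J
    out.v2 = -out.v2
    out.a2 = out.a2 + shift
    return out


def fit_qc(
    movie: StimulusMovie,
    counts: np.ndarray,
    cfg: PatchConfig,
    fitcfg: FitConfig,
    spec: ModelSpec,
) -> FitResult:
    """Fit the QC model (or a reduced variant) with the 4-fold protocol.

    ``counts`` is the spike count per frame, aligned to ``movie``; the
    first ``n_lags - 1`` frames are dropped from the likelihood.  The
    result contains the four fold models and their element-wise average,
    and is bit-reproducible given ``fitcfg.seed``.
    """
    counts = np.asarray(counts, dtype=np.float64).ravel()
    if counts.size != movie.n_frames:
        raise ValueError(
            f"counts length {counts.size} does not match movie frames {movie.n_frames}"
        )
    y = counts[cfg.n_lags - 1 :]
    if not np.any(y > 0):
        raise ValueError("all-zero spike train: nothing to fit")
    if y.size < 8 * fitcfg.batch_size:
        raise ValueError(
            f"need at least {8 * fitcfg.batch_size} usable frames, got {y.size}"
        )
    positions = _grid_positions(movie.frame_shape, cfg, convolutional=spec.convolutional)
    X = design_tensor(movie, cfg, positions=positions)
    n = y.size
    edges = np.linspace(0, n, N_FOLDS + 1).astype(int)
    fold_params, train_traces, val_traces = [], [], []
    for fold in range(N_FOLDS):
        val_idx = np.arange(edges[fold], edges[fold + 1])
        train_idx = np.concatenate(
            [np.arange(0, edges[fold]), np.arange(edges[fold + 1], n)]
        )
        rng = np.random.default_rng(fitcfg.seed * N_FOLDS + fold)
        best, tr, vl = _sgd_fold(X, y, train_idx, val_idx, spec, fitcfg, rng)
        fold_params.append(_canonicalize_sign(best, spec))
        train_traces.append(tr)
        val_traces.append(vl)
    avg = QCParams(
        a1=float(np.mean([p.a1 for p in fold_params])),
        v1=np.mean([p.v1 for p in fold_params], axis=0),
        J=np.mean([p.J for p in fold_params], axis=0),
        v2=np.mean([p.v2 for p in fold_params], axis=0),
        a2=float(np.mean([p.a2 for p in fold_params])),
        d=float(np.mean([p.d for p in fold_params])),
    )
    return FitResult(
        fold_params=fold_params,
        params=avg,
        train_nll=train_traces,
        val_nll=val_traces,
        seed=fitcfg.seed,
        spec=spec,
        cfg=cfg,
    )


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def noise_ceiling(repeats: np.ndarray, n_splits: int = 20, seed: int = 0) -> float:
    """Maximum attainable correlation with the trial-averaged response.

    Estimated from the split-half reliability of the repeat block: trials
    are split into random halves, the correlation between the two
    half-mean responses is averaged over splits, Spearman-Brown doubled
    to the reliability of the full-trial mean, and the square root taken.
    """
    repeats = np.asarray(repeats, dtype=np.float64)
    n_trials = repeats.shape[0]
    if n_trials < 2:
        raise ValueError("need at least 2 repeat trials")
    rng = np.random.default_rng(seed)
    rs = []
    for _ in range(n_splits):
        perm = rng.permutation(n_trials)
        half = n_trials // 2
        a = repeats[perm[:half]].mean(axis=0)
        b = repeats[perm[half:]].mean(axis=0)
        rs.append(_pearson(a, b))
    r_half = float(np.mean(rs))
    if r_half <= 0:
        return 0.0
    r_full = 2.0 * r_half / (1.0 + r_half)
    return float(np.sqrt(r_full))


def evaluate(
    params: QCParams,
    spec: ModelSpec,
    cfg: PatchConfig,
    movie_test: StimulusMovie,
    repeats: np.ndarray,
    seed: int = 0,
) -> dict:
    """Noise-corrected correlation between prediction and repeat averages.

    ``repeats`` is an (n_trials, T) block of spike counts to the test
    movie.  Returns raw correlation, the estimated ceiling, and the
    corrected correlation clipped to [0, 1].
    """
    from .model import predict_rate

    repeats = np.asarray(repeats, dtype=np.float64)
    if repeats.ndim != 2:
        raise ValueError(f"repeats must be n_trials x T, got shape {repeats.shape}")
    if repeats.shape[0] < 2:
        raise ValueError("need at least 2 repeat trials to evaluate")
    if repeats.shape[1] != movie_test.n_frames:
        raise ValueError(
            f"repeats have {repeats.shape[1]} frames but movie has {movie_test.n_frames}"
        )
    pred = predict_rate(movie_test, params, cfg, spec)
    rep = repeats[:, cfg.n_lags - 1 :]
    mean_resp = rep.mean(axis=0)
    if np.allclose(pred.std(), 0.0):
        warnings.warn("zero-variance prediction; corrected correlation set to 0")
        return {"r_raw": 0.0, "r_max": 0.0, "r_corrected": 0.0,
                "method": "split-half Spearman-Brown"}
    r_raw = _pearson(pred, mean_resp)
    r_max = noise_ceiling(rep, seed=seed)
    r_corr = 0.0 if r_max == 0 else float(np.clip(r_raw / r_max, 0.0, 1.0))
    return {
        "r_raw": r_raw,
        "r_max": r_max,
        "r_corrected": r_corr,
        "method": "split-half Spearman-Brown",
    }
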