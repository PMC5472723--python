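"""Forward evaluation of the quadratic convolutional (QC) model.

The QC model predicts a spike rate from a stimulus movie in three stages:

1. every lagged patch ``x`` is passed through an identical quadratic
   logistic subunit ``s = sigma(a1 + v1.x + x'Jx)``;
2. subunit outputs are pooled across grid positions and lags with
   weights ``v2``;
3. the pooled signal is rectified, ``rate = softplus(d * (v2.s) + a2)``,
   or, in the saturating variant, ``rate = d * sigma(v2.s + a2)``.

Reduced models are expressed through :class:`ModelSpec`: switching the
quadratic term off fixes ``J`` at zero (linear convolutional /
linear non-convolutional models), and switching convolution off collapses
the pooling grid to the single central patch position per lag.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import expit

from .stimuli import (
    PatchConfig,
    StimulusMovie,
    _grid_positions,
    design_tensor,
    patch_vector_length,
)

__all__ = ["QCParams", "ModelSpec", "logistic", "softplus", "qls_response", "predict_rate"]


def logistic(x):
    """Logistic sigmoid ``1 / (1 + exp(-x))``, numerically stable."""
    return expit(x)


def softplus(x):
    """Soft-plus rectifier ``log(1 + exp(x))``, numerically stable."""
    return np.logaddexp(0.0, x)


@dataclass
class QCParams:
    """Full parameter set of one QC model.

    ``J`` is stored as its symmetric part (the quadratic form only sees
    it), which keeps the eigen-analysis of the fitted kernel valid.
    """

    a1: float
    v1: np.ndarray
    J: np.ndarray
    v2: np.ndarray
    a2: float
    d: float

    def __post_init__(self) -> None:
        self.v1 = np.asarray(self.v1, dtype=np.float64).ravel()
        self.v2 = np.asarray(self.v2, dtype=np.float64).ravel()
        J = np.asarray(self.J, dtype=np.float64)
        P = self.v1.size
        if J.shape != (P, P):
            raise ValueError(f"J must be {P}x{P} to match v1, got {J.shape}")
        self.J = 0.5 * (J + J.T)
        self.a1 = float(self.a1)
        self.a2 = float(self.a2)
        self.d = float(self.d)

    @classmethod
    def zeros(cls, n_pixels: int, n_pool: int, d: float = 1.0) -> "QCParams":
        return cls(
            a1=0.0,
            v1=np.zeros(n_pixels),
            J=np.zeros((n_pixels, n_pixels)),
            v2=np.zeros(n_pool),
            a2=0.0,
            d=d,
        )

    def copy(self) -> "QCParams":
        return QCParams(self.a1, self.v1.copy(), self.J.copy(), self.v2.copy(), self.a2, self.d)

    @property
    def n_pixels(self) -> int:
        return self.v1.size

    @property
    def n_pool(self) -> int:
        return self.v2.size

    def is_finite(self) -> bool:
        return bool(
            np.isfinite(self.a1)
            and np.isfinite(self.a2)
            and np.isfinite(self.d)
            and np.all(np.isfinite(self.v1))
            and np.all(np.isfinite(self.J))
            and np.all(np.isfinite(self.v2))
        )


@dataclass(frozen=True)
class ModelSpec:
    """Which terms of the QC model are active.

    quadratic=False fixes J at zero; convolutional=False restricts the
    pooling grid to the single central position per lag.  The final
    nonlinearity is the soft-plus rectifier by default; the "logistic"
    variant uses a saturating output ``d * sigma(pooled + a2)`` with
    ``d`` acting as an amplitude so spike counts can be matched.
    """

    quadratic: bool = True
    convolutional: bool = True
    final_nonlinearity: str = "softplus"

    def __post_init__(self) -> None:
        if self.final_nonlinearity not in ("softplus", "logistic"):
            raise ValueError(
                f"final_nonlinearity must be 'softplus' or 'logistic', "
                f"got {self.final_nonlinearity!r}"
            )

    @property
    def short_name(self) -> str:
        return {
            (True, True): "qc",
            (True, False): "qnc",
            (False, True): "lc",
            (False, False): "lnc",
        }[(self.quadratic, self.convolutional)]

    @classmethod
    def from_short_name(cls, name: str, final_nonlinearity: str = "softplus") -> "ModelSpec":
        table = {
            "qc": (True, True),
            "qnc": (True, False),
            "lc": (False, True),
            "lnc": (False, False),
        }
        if name not in table:
            raise ValueError(f"unknown model spec {name!r}; expected one of {sorted(table)}")
        q, c = table[name]
        return cls(quadratic=q, convolutional=c, final_nonlinearity=final_nonlinearity)


def qls_response(patch: np.ndarray, params: QCParams) -> float:
    """Response of one quadratic logistic subunit to one patch."""
    x = np.asarray(patch, dtype=np.float64).ravel()
    if x.size != params.n_pixels:
        raise ValueError(
            f"patch has {x.size} pixels but the subunit expects {params.n_pixels}"
        )
    return float(expit(params.a1 + params.v1 @ x + x @ params.J @ x))


def subunit_drive(X: np.ndarray, params: QCParams, quadratic: bool = True) -> np.ndarray:
    """Pre-sigmoid subunit input for a stack of patch vectors.

    ``X`` has shape (..., P); returns the same leading shape.
    """
    u = params.a1 + X @ params.v1
    if quadratic:
        u = u + np.einsum("...p,pq,...q->...", X, params.J, X, optimize=True)
    return u


def forward(X: np.ndarray, params: QCParams, spec: ModelSpec):
    """Evaluate the model on a design tensor ``X`` of shape (T, K, P).

    Returns ``(s, z, rates)`` where ``s`` are the subunit outputs (T, K),
    ``z`` is the input to the final nonlinearity and ``rates`` the
    predicted spikes/bin.
    """
    if X.shape[1] != params.n_pool:
        raise ValueError(
            f"design tensor has {X.shape[1]} pooling slots but v2 has {params.n_pool}"
        )
    T, K, P = X.shape
    Xf = X.reshape(T * K, P)
    u = params.a1 + Xf @ params.v1
    if spec.quadratic:
        u = u + ((Xf @ params.J) * Xf).sum(axis=1)
    s = expit(u).reshape(T, K)
    pooled = s @ params.v2
    if spec.final_nonlinearity == "softplus":
        z = params.d * pooled + params.a2
        rates = softplus(z)
    else:
        z = pooled + params.a2
        rates = params.d * expit(z)
    return s, z, rates


def predict_rate(
    movie: StimulusMovie,
    params: QCParams,
    cfg: PatchConfig,
    spec: ModelSpec,
) -> np.ndarray:
    """Predicted rate per frame (spikes/bin) for frames with full lag history.

    The output has length ``T - (n_lags - 1)``; entry ``i`` is the rate at
    frame ``i + n_lags - 1``.  Frames without full lag history are dropped
    rather than zero-padded.
    """
    if not params.is_finite():
        raise ValueError("QCParams contain non-finite values")
    positions = _grid_positions(movie.frame_shape, cfg, convolutional=spec.convolutional)
    expected_pool = cfg.n_lags * len(positions)
    if params.n_pool != expected_pool:
        raise ValueError(
            f"v2 has length {params.n_pool} but the geometry implies {expected_pool}"
        )
    if params.n_pixels != patch_vector_length(cfg):
        raise ValueError(
            f"v1 has length {params.n_pixels} but patches have "
            f"{patch_vector_length(cfg)} pixels"
        )
    X = design_tensor(movie, cfg, positions=positions)
    _, _, rates = forward(X, params, spec)
    return rates


def strip_quadratic(params: QCParams) -> QCParams:
    """Return a copy with J forced to zero (linear model parameters)."""
    return replace(params.copy(), J=np.zeros_like(params.J))
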