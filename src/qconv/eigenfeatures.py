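"""Significant excitatory/suppressive eigenfeatures of the quadratic kernel.

Eigenvectors of the fitted quadratic kernel J with positive eigenvalues
act as excitatory stimulus features, those with negative eigenvalues as
suppressive ones.  Significance is assessed against a shuffle null: the
scalar mean of J is subtracted first (a nonzero mean alone produces a
spurious outlying eigenvalue), then the diagonal entries and the
off-diagonal entries are permuted separately -- within their own slots,
keeping the matrix symmetric -- and the extreme eigenvalues of each
shuffled matrix form the null distributions.  Eigenvalues of the
centered J are checked in order of decreasing magnitude against the
matching tail (maxima for positive values, minima for negative); testing
stops at the first non-significant eigenvalue.  No deflation of already
accepted components is performed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["EigenFeature", "center_J", "shuffle_null", "significant_features"]


@dataclass
class EigenFeature:
    """A unit-norm eigenvector of (centered) J with its test outcome."""

    vector: np.ndarray
    eigenvalue: float
    p_value: float

    @property
    def label(self) -> str:
        return "excitatory" if self.eigenvalue > 0 else "suppressive"


def _check_symmetric(J: np.ndarray, warn: bool = True) -> np.ndarray:
    J = np.asarray(J, dtype=np.float64)
    if J.ndim != 2 or J.shape[0] != J.shape[1]:
        raise ValueError(f"J must be square, got shape {J.shape}")
    if not np.allclose(J, J.T, rtol=1e-10, atol=1e-12):
        if warn:
            warnings.warn("asymmetric J; using its symmetric part")
        J = 0.5 * (J + J.T)
    return J


def center_J(J: np.ndarray) -> np.ndarray:
    """Subtract the scalar mean of all entries of J."""
    J = _check_symmetric(J)
    return J - J.mean()


def shuffle_null(
    J_centered: np.ndarray,
    n_shuffles: int = 1000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Null distributions of (max, min) eigenvalues under entry shuffling.

    Each shuffle permutes the diagonal entries among diagonal slots and
    the upper-triangle entries among off-diagonal slots (mirrored into the
    lower triangle), so the diagonal and off-diagonal multisets -- and the
    trace -- of every shuffled matrix equal those of the input.
    """
    if n_shuffles < 100:
        raise ValueError("n_shuffles must be >= 100 to resolve the tails")
    J = np.asarray(J_centered, dtype=np.float64)
    n = J.shape[0]
    rng = np.random.default_rng(seed)
    diag = np.diag(J).copy()
    iu = np.triu_indices(n, k=1)
    off = J[iu].copy()
    maxima = np.empty(n_shuffles)
    minima = np.empty(n_shuffles)
    M = np.empty_like(J)
    for k in range(n_shuffles):
        M[:] = 0.0
        M[iu] = rng.permutation(off)
        M += M.T
        M[np.diag_indices(n)] = rng.permutation(diag)
        ev = np.linalg.eigvalsh(M)
        minima[k] = ev[0]
        maxima[k] = ev[-1]
    return maxima, minima


def significant_features(
    J: np.ndarray,
    alpha: float = 0.05,
    n_shuffles: int = 1000,
    seed: int = 0,
) -> list[EigenFeature]:
    """Extract significant eigenfeatures of J via the shuffle test.

    Returns features sorted by decreasing eigenvalue magnitude.  An empty
    list is a valid outcome.  The default of 1000 shuffles resolves a
    p-value of 0.05 with a standard error of about 0.7 percentage points.
    """
    Jc = center_J(J)
    evals, evecs = np.linalg.eigh(Jc)
    order = np.argsort(-np.abs(evals))
    maxima, minima = shuffle_null(Jc, n_shuffles=n_shuffles, seed=seed)
    features: list[EigenFeature] = []
    for idx in order:
        lam = evals[idx]
        if lam > 0:
            p = (1 + int(np.sum(maxima >= lam))) / (n_shuffles + 1)
        elif lam < 0:
            p = (1 + int(np.sum(minima <= lam))) / (n_shuffles + 1)
        else:
            break
        if p >= alpha:
            break
        features.append(EigenFeature(vector=evecs[:, idx].copy(), eigenvalue=float(lam), p_value=float(p)))
    return features


def reconstruct(features: list[EigenFeature], n: int | None = None,
                label: str | None = None) -> np.ndarray:
    """Rebuild a kernel from eigenfeatures, optionally one sign class only.

    ``sum_i lambda_i v_i v_i^T`` over the selected features; ``label``
    restricts to "excitatory" or "suppressive" components.
    """
    chosen = [f for f in features if label is None or f.label == label]
    if n is None:
        if not chosen:
            raise ValueError("cannot infer kernel size from an empty feature list")
        n = chosen[0].vector.size
    out = np.zeros((n, n))
    for f in chosen:
        out += f.eigenvalue * np.outer(f.vector, f.vector)
    return out
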