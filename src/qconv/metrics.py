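"""Population-level analytics for fitted QC models.

Covers the summary statistics used to characterize a population of
fitted neurons: lifetime sparseness of predicted responses with and
without the suppressive part of the quadratic kernel, the angular spread
of excitatory Gabor orientations and the resulting uniform/non-uniform
classification, orientation differences between excitatory and
suppressive Gabors (with a chi-squared test against uniformity),
space-time separation of the pooling mask by SVD with a
uniform/biphasic classification, and the Hartigan dip test for
bimodality of population distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats as sps

from ._dip import dip, dip_test, null_dip_table
from .eigenfeatures import reconstruct, significant_features
from .gaborfit import gabor_sum_J
from .model import ModelSpec, QCParams, predict_rate
from .stimuli import PatchConfig, StimulusMovie

__all__ = [
    "NeuronSummary",
    "sparseness",
    "suppression_sparseness_ratio",
    "angular_std",
    "classify_neurons",
    "ex_supp_orientation_differences",
    "pooling_decomposition",
    "dip_statistic",
    "dip",
    "dip_test",
    "null_dip_table",
]


@dataclass
class NeuronSummary:
    """Per-neuron feature counts, orientation spread, and sparseness."""

    n_excitatory: int
    n_suppressive: int
    angular_std_deg: float
    class_label: str  # "uniform" | "nonuniform"
    pooling_type: str  # "uniform" | "biphasic"
    sparseness_full: float
    sparseness_no_suppression: float

    @property
    def n_total(self) -> int:
        return self.n_excitatory + self.n_suppressive


def sparseness(rates: np.ndarray) -> float:
    """Lifetime sparseness (Treves-Rolls / Vinje-Gallant form).

    S = (1 - (mean r)^2 / mean(r^2)) / (1 - 1/n); 0 for constant rates,
    approaching 1 when activity concentrates in very few bins.  Scale
    invariant.
    """
    r = np.asarray(rates, dtype=np.float64).ravel()
    if r.size < 2:
        raise ValueError("sparseness requires at least 2 bins")
    if np.any(r < 0):
        raise ValueError("rates must be nonnegative")
    m2 = float(np.mean(r**2))
    if m2 == 0.0:
        raise ValueError("all-zero rates: sparseness undefined")
    n = r.size
    return float((1.0 - np.mean(r) ** 2 / m2) / (1.0 - 1.0 / n))


@dataclass
class SparsenessComparison:
    s_full: float
    s_no_suppression: float
    ratio: float
    note: str = ""


def suppression_sparseness_ratio(
    params: QCParams,
    cfg: PatchConfig,
    spec: ModelSpec,
    movie: StimulusMovie,
    features: list | None = None,
    alpha: float = 0.05,
    n_shuffles: int = 1000,
    seed: int = 0,
) -> SparsenessComparison:
    """Sparseness of predicted rates with the full J versus excitatory-only J.

    "Without suppressive features" means rebuilding J from the significant
    excitatory eigencomponents only, with all other parameters fixed; the
    returned ratio is S_no_suppression / S_full.  A ratio below 1 means
    suppression makes the response sparser.
    """
    if features is None:
        features = significant_features(params.J, alpha=alpha, n_shuffles=n_shuffles, seed=seed)
    s_full = sparseness(predict_rate(movie, params, cfg, spec))
    supp = [f for f in features if f.label == "suppressive"]
    exc = [f for f in features if f.label == "excitatory"]
    if not supp:
        return SparsenessComparison(s_full, s_full, 1.0, note="no suppressive features")
    J_exc = (
        reconstruct(exc, n=params.n_pixels)
        if exc
        else np.zeros_like(params.J)
    )
    params_no = replace(params.copy(), J=J_exc)
    s_no = sparseness(predict_rate(movie, params_no, cfg, spec))
    return SparsenessComparison(s_full, s_no, s_no / s_full)


def randomized_suppressive_sparseness(
    params: QCParams,
    cfg: PatchConfig,
    spec: ModelSpec,
    movie: StimulusMovie,
    exc_gabors: list,
    sup_gabors: list,
    shape: tuple[int, int],
    n_draws: int = 10,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Sparseness with fitted versus orientation-randomized suppressive Gabors.

    J is rebuilt from the Gabor sets (excitatory plus suppressive); the
    fitted arrangement is compared against draws in which every
    suppressive Gabor's orientation is resampled uniformly, all else
    fixed.  Returns (sparseness_fitted, array of per-draw sparseness).
    """
    import copy

    rng = np.random.default_rng(seed)
    J_fit = gabor_sum_J(exc_gabors + sup_gabors, shape)
    s_fit = sparseness(predict_rate(movie, replace(params.copy(), J=J_fit), cfg, spec))
    s_rand = np.empty(n_draws)
    for k in range(n_draws):
        randomized = []
        for g in sup_gabors:
            g2 = copy.deepcopy(g)
            g2.theta = float(rng.uniform(-math.pi, math.pi))
            randomized.append(g2)
        J_r = gabor_sum_J(exc_gabors + randomized, shape)
        s_rand[k] = sparseness(
            predict_rate(movie, replace(params.copy(), J=J_r), cfg, spec)
        )
    return s_fit, s_rand


def angular_std(orientations: np.ndarray) -> float:
    """Circular standard deviation of axial orientations, in degrees.

    Orientations are given in radians and treated modulo 180 degrees:
    the angles are doubled, the circular standard deviation
    sqrt(-2 ln R) of the doubled angles is computed, and the result is
    halved back to orientation units.  Returns inf when the doubled
    resultant vanishes (maximal spread, e.g. two orthogonal angles).
    """
    th = np.asarray(orientations, dtype=np.float64).ravel()
    if th.size < 2:
        raise ValueError("need at least 2 orientations")
    z = np.exp(2j * th)
    R = float(np.abs(z.mean()))
    if R <= 1e-12:
        return float("inf")
    if R >= 1.0:
        return 0.0
    return math.degrees(0.5 * math.sqrt(-2.0 * math.log(R)))


def classify_neurons(
    angular_stds: np.ndarray,
    threshold: float | None = None,
) -> tuple[np.ndarray, float]:
    """Split neurons into orientation-uniform and non-uniform classes.

    Below the threshold a neuron is "uniform" (orientations clustered),
    above it "nonuniform".  If no threshold is given it is placed at the
    midpoint of the largest gap in the sorted finite spread values; with
    fewer than two distinct values all neurons fall in one class.
    """
    stds = np.asarray(angular_stds, dtype=np.float64).ravel()
    if threshold is None:
        finite = np.sort(stds[np.isfinite(stds)])
        uniq = np.unique(finite)
        if uniq.size < 2:
            threshold = float(stds.max() + 1.0) if stds.size else 0.0
        else:
            gaps = np.diff(uniq)
            k = int(np.argmax(gaps))
            threshold = float(0.5 * (uniq[k] + uniq[k + 1]))
    labels = np.where(stds < threshold, "uniform", "nonuniform")
    return labels, float(threshold)


@dataclass
class OrientationDifferenceResult:
    differences_deg: np.ndarray
    hist: np.ndarray
    bin_edges: np.ndarray
    chi2: float
    p_value: float


def ex_supp_orientation_differences(
    exc_gabors: list,
    sup_gabors: list,
    scope: str = "nearest",
    n_bins: int = 8,
) -> OrientationDifferenceResult:
    """Axial orientation differences between suppressive and excitatory Gabors.

    For each suppressive Gabor, either the difference to its nearest
    excitatory Gabor in space (scope="nearest") or to every excitatory
    Gabor (scope="all").  Differences are axial, in [0, 90] degrees,
    histogrammed into ``n_bins`` equal bins and tested against the
    uniform distribution by chi-squared (n_bins - 1 degrees of freedom).
    """
    if not exc_gabors or not sup_gabors:
        raise ValueError("need at least one excitatory and one suppressive Gabor")
    if scope not in ("nearest", "all"):
        raise ValueError(f"scope must be 'nearest' or 'all', got {scope!r}")
    diffs = []
    for s in sup_gabors:
        pair_diffs = []
        for e in exc_gabors:
            d = abs(s.theta - e.theta) % math.pi
            d = min(d, math.pi - d)
            pair_diffs.append((math.hypot(s.x0 - e.x0, s.y0 - e.y0), math.degrees(d)))
        if scope == "nearest":
            diffs.append(min(pair_diffs)[1])
        else:
            diffs.extend(d for _, d in pair_diffs)
    diffs = np.asarray(diffs)
    edges = np.linspace(0.0, 90.0, n_bins + 1)
    hist, _ = np.histogram(np.clip(diffs, 0.0, 90.0 - 1e-12), bins=edges)
    chi2, p = sps.chisquare(hist)
    return OrientationDifferenceResult(diffs, hist, edges, float(chi2), float(p))


@dataclass
class PoolingDecomposition:
    spatial_map: np.ndarray  # (Gy, Gx)
    temporal: np.ndarray  # (n_lags,)
    pooling_type: str  # "uniform" | "biphasic"
    temporal_type: str  # "unimodal" | "biphasic"
    singular_values: np.ndarray


def _opposed_lobes(v: np.ndarray, lobe_frac: float) -> bool:
    pos = float(np.sum(np.clip(v, 0.0, None)))
    neg = float(np.sum(np.clip(-v, 0.0, None)))
    tot = pos + neg
    return tot > 0 and min(pos, neg) / tot > lobe_frac


def pooling_decomposition(
    v2: np.ndarray,
    grid_shape: tuple[int, int],
    n_lags: int,
    lobe_frac: float = 0.2,
) -> PoolingDecomposition:
    """Rank-1 space-time factorization of the pooling weights by SVD.

    ``v2`` is in the canonical lag-major order; it is reshaped to
    (n_lags, Gy*Gx) and factored.  The sign convention makes the peak of
    the temporal kernel positive.  The spatial map (or temporal kernel)
    is called biphasic when its opposed-sign lobes each carry more than
    ``lobe_frac`` of the total absolute mass; the 20% default is a
    package choice, exposed here.
    """
    gy, gx = grid_shape
    v2 = np.asarray(v2, dtype=np.float64).ravel()
    if v2.size != gy * gx * n_lags:
        raise ValueError(
            f"v2 has length {v2.size}, expected {gy * gx * n_lags} for "
            f"grid {grid_shape} x {n_lags} lags"
        )
    if np.allclose(v2, 0.0):
        raise ValueError("zero pooling vector cannot be decomposed")
    M = v2.reshape(n_lags, gy * gx)
    U, S, Vt = np.linalg.svd(M, full_matrices=False)
    temporal = U[:, 0] * S[0]
    spatial = Vt[0]
    if temporal[int(np.argmax(np.abs(temporal)))] < 0:
        temporal = -temporal
        spatial = -spatial
    pooling_type = "biphasic" if _opposed_lobes(spatial, lobe_frac) else "uniform"
    temporal_type = "biphasic" if _opposed_lobes(temporal, lobe_frac) else "unimodal"
    return PoolingDecomposition(
        spatial_map=spatial.reshape(gy, gx),
        temporal=temporal,
        pooling_type=pooling_type,
        temporal_type=temporal_type,
        singular_values=S,
    )


def dip_statistic(values: np.ndarray, n_boot: int = 500, seed: int = 0) -> tuple[float, float]:
    """Hartigan dip statistic with a Monte-Carlo p-value (uniform null)."""
    return dip_test(values, n_boot=n_boot, seed=seed)
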