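"""Gabor decomposition of the quadratic kernel by differential evolution.

The excitatory (or suppressive) part of the quadratic kernel J --
reconstructed from its significant eigencomponents of one sign -- is
approximated as a weighted sum of outer products of Gabor wavelets,

    J_part  ~  sum_i  w_i  g_i g_i^T ,

with the w_i positive for the excitatory part and negative for the
suppressive part.  The Gabor parameters (and weights) are found by
minimizing the mean squared error of this reconstruction with the
'rand/2/bin' variant of differential evolution, with jDE-style
self-adaptation of the crossover rate CR and differential weight F
(each regenerated with probability tau = 0.1 before mutation).
Multiplicative parameters (sigma, gamma, lambda, |w|) evolve as their
logarithms so mutation steps are changes of scale; proposals outside
the initialization bounds receive infinite error.

A quadrature-constrained mode fits pairs of Gabors that share every
parameter except the spatial phase, fixed at 0 and pi/2 -- the
sine/cosine pairing that makes the pair's energy invariant to small
shifts perpendicular to the carrier.  Each pair member keeps its own
nonnegative weight (a shared-weight mode is available).

Fitted Gabors can then be paired across the full set by proximity of
position and (axial) orientation, and the spatial-phase difference of a
pair is measured after correcting for the phase advance implied by the
displacement of the two centers along the carrier direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GaborParams",
    "DEConfig",
    "GaborPair",
    "GaborFitResult",
    "gabor_image",
    "gabor_vector",
    "gabor_sum_J",
    "fit_gabors",
    "pair_gabors",
    "phase_difference",
]


def _wrap_angle(theta: float) -> float:
    """Reduce an angle to (-pi, pi]."""
    t = math.fmod(theta, 2 * math.pi)
    if t <= -math.pi:
        t += 2 * math.pi
    elif t > math.pi:
        t -= 2 * math.pi
    return t


@dataclass
class GaborParams:
    """One Gabor wavelet plus its signed weight in the kernel sum.

    Positions are in pixels ((x0, y0) = (column, row)), theta is the
    carrier orientation in radians reduced to (-pi, pi], gamma the aspect
    ratio of the Gaussian envelope, sigma its size in pixels, lam the
    spatial wavelength in pixels, phi the spatial phase, A the
    normalization that gives the discrete image unit L2 norm, and w the
    signed weight (positive = excitatory, negative = suppressive).
    """

    x0: float
    y0: float
    theta: float
    gamma: float
    sigma: float
    lam: float
    phi: float
    A: float = 1.0
    w: float = 1.0

    def __post_init__(self) -> None:
        for name in ("gamma", "sigma", "lam"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        self.theta = _wrap_angle(float(self.theta))

    @property
    def orientation_axial(self) -> float:
        """Orientation reduced modulo pi to [0, pi)."""
        return self.theta % math.pi


@dataclass(frozen=True)
class DEConfig:
    """Differential-evolution settings (rand/2/bin, jDE adaptation)."""

    tau: float = 0.1
    restarts: int = 4
    seed: int = 0
    pop_factor: int = 10  # population = pop_factor * n_free_parameters
    max_gens: int = 2000
    shared_pair_weight: bool = False

    def population(self, n_params: int) -> int:
        # rand/2/bin draws 5 distinct partners excluding self
        return max(self.pop_factor * n_params, 7)


@dataclass
class GaborPair:
    """Two paired Gabors with their geometry-corrected phase difference."""

    i: int
    j: int
    delta_phase: float  # degrees in [0, 180)
    delta_x: np.ndarray  # (dx, dy) pixel displacement
    lambda_bar: float  # wavelength of the mean spatial frequency


@dataclass
class GaborFitResult:
    gabors: list
    mse: float
    norm_mse: float
    correlation: float
    n_generations: int
    restart_errors: list = field(default_factory=list)


def gabor_image(g: GaborParams, shape: tuple[int, int]) -> np.ndarray:
    """Render a Gabor on an H x W pixel grid with unit L2 norm.

    Rotated coordinates: xr = (x-x0) cos(theta) + (y-y0) sin(theta),
    yr = -(x-x0) sin(theta) + (y-y0) cos(theta); the image is
    A * exp(-(xr^2 + gamma^2 yr^2) / (2 sigma^2)) * cos(2 pi xr / lam + phi).
    """
    H, W = shape
    y, x = np.mgrid[0:H, 0:W].astype(np.float64)
    dx = x - g.x0
    dy = y - g.y0
    ct, st = math.cos(g.theta), math.sin(g.theta)
    xr = dx * ct + dy * st
    yr = -dx * st + dy * ct
    env = np.exp(-(xr**2 + (g.gamma**2) * yr**2) / (2.0 * g.sigma**2))
    img = env * np.cos(2.0 * math.pi * xr / g.lam + g.phi)
    nrm = np.linalg.norm(img)
    if nrm > 0:
        g.A = 1.0 / nrm
        img = img * g.A
    return img


def gabor_vector(g: GaborParams, shape: tuple[int, int]) -> np.ndarray:
    """Flattened (row-major) unit-norm Gabor image."""
    return gabor_image(g, shape).ravel()


def gabor_sum_J(gabors: list, shape: tuple[int, int]) -> np.ndarray:
    """Weighted sum of Gabor outer products: sum_i w_i g_i g_i^T."""
    if not gabors:
        raise ValueError("need at least one Gabor")
    P = shape[0] * shape[1]
    out = np.zeros((P, P))
    for g in gabors:
        v = gabor_vector(g, shape)
        out += g.w * np.outer(v, v)
    return out


# ---------------------------------------------------------------------------
# differential evolution engine


def _de_rand2bin(objective, lower, upper, cfg: DEConfig, rng: np.random.Generator):
    """Minimize a box-bounded objective with self-adaptive rand/2/bin DE.

    Proposals are u' = x_r1 + F (x_r2 - x_r3) + F (x_r4 - x_r5) with five
    distinct partners excluding the target, binomial crossover with a
    forced coordinate j_rand, per-member CR ~ U[0,1) and
    F ~ 0.1 + 0.9 U[0,1) each regenerated with probability tau before
    mutation.  Out-of-bounds trials get infinite error; replacement is
    greedy on the objective.  Terminates when a full generation passes
    with no replacement (or at max_gens).
    """
    n_par = lower.size
    NP = cfg.population(n_par)
    pop = rng.uniform(lower, upper, size=(NP, n_par))
    CR = rng.uniform(0.0, 1.0, size=NP)
    F = 0.1 + 0.9 * rng.uniform(0.0, 1.0, size=NP)
    err = np.array([objective(x) for x in pop])
    gen = 0
    for gen in range(1, cfg.max_gens + 1):
        changed = False
        for i in range(NP):
            if rng.random() < cfg.tau:
                CR[i] = rng.random()
            if rng.random() < cfg.tau:
                F[i] = 0.1 + 0.9 * rng.random()
            choices = rng.choice(NP - 1, size=5, replace=False)
            choices[choices >= i] += 1
            r1, r2, r3, r4, r5 = choices
            mutant = pop[r1] + F[i] * (pop[r2] - pop[r3]) + F[i] * (pop[r4] - pop[r5])
            cross = rng.random(n_par) < CR[i]
            cross[rng.integers(n_par)] = True
            trial = np.where(cross, mutant, pop[i])
            if np.any(trial < lower) or np.any(trial > upper):
                continue  # infinite error: never replaces
            f_trial = objective(trial)
            if f_trial < err[i]:
                pop[i] = trial
                err[i] = f_trial
                changed = True
        if not changed:
            break
    best = int(np.argmin(err))
    return pop[best], float(err[best]), gen


# ---------------------------------------------------------------------------
# genome encoding

_LOG = True
_LIN = False


def _genome_spec(shape, n_gabors, quadrature, w_hi, shared_weight):
    """Bounds and scale flags for the DE genome.

    Independent mode: per Gabor [x0, y0, theta, log gamma, log sigma,
    log lambda, phi, log w].  Quadrature mode: per pair [x0, y0, theta,
    log gamma, log sigma, log lambda, log w0, log w90] (or a single
    log w if the pair shares one weight).
    """
    H, W = shape
    smax = max(H, W)
    lo_common = [0.0, 0.0, -math.pi, math.log(0.2), math.log(0.7), math.log(2.0)]
    hi_common = [W - 1.0, H - 1.0, math.pi, math.log(5.0), math.log(smax / 1.5),
                 math.log(4.0 * smax)]
    w_lo = math.log(w_hi * 1e-3)
    w_hi_log = math.log(w_hi * 3.0)
    if not quadrature:
        lo = lo_common + [-math.pi, w_lo]
        hi = hi_common + [math.pi, w_hi_log]
    elif shared_weight:
        lo = lo_common + [w_lo]
        hi = hi_common + [w_hi_log]
    else:
        lo = lo_common + [w_lo, w_lo]
        hi = hi_common + [w_hi_log, w_hi_log]
    lower = np.tile(lo, n_gabors)
    upper = np.tile(hi, n_gabors)
    return lower, upper, len(lo)


def _decode(genome, shape, n_units, block, quadrature, shared_weight):
    """Genome -> list of GaborParams (weights positive; sign applied later)."""
    gabors = []
    for k in range(n_units):
        seg = genome[k * block : (k + 1) * block]
        x0, y0, theta = seg[0], seg[1], seg[2]
        gamma, sigma, lam = math.exp(seg[3]), math.exp(seg[4]), math.exp(seg[5])
        if not quadrature:
            phi, w = seg[6], math.exp(seg[7])
            gabors.append(GaborParams(x0, y0, theta, gamma, sigma, lam, phi, w=w))
        else:
            if shared_weight:
                w0 = w90 = math.exp(seg[6])
            else:
                w0, w90 = math.exp(seg[6]), math.exp(seg[7])
            gabors.append(GaborParams(x0, y0, theta, gamma, sigma, lam, 0.0, w=w0))
            gabors.append(
                GaborParams(x0, y0, theta, gamma, sigma, lam, math.pi / 2.0, w=w90)
            )
    return gabors


def _reconstruction_stats(gabors, J_target, shape):
    """(mse, norm_mse, correlation) of sum_i w_i g_i g_i^T against J_target."""
    G = np.stack([gabor_vector(g, shape) for g in gabors])
    w = np.array([g.w for g in gabors])
    GJ = G @ J_target
    quad = np.einsum("ip,ip->i", GJ, G)
    gram = G @ G.T
    P2 = J_target.size
    jj = float(np.sum(J_target * J_target))
    mm = float(w @ (gram**2) @ w)
    mj = float(w @ quad)
    mse = max((mm - 2.0 * mj + jj) / P2, 0.0)  # guard round-off at exact fits
    norm_mse = mse / (jj / P2) if jj > 0 else np.inf
    # Pearson correlation between the flattened matrices
    jsum = float(J_target.sum())
    msum = float(w @ (G.sum(axis=1) ** 2))
    cov = mj - msum * jsum / P2
    var_j = jj - jsum**2 / P2
    var_m = mm - msum**2 / P2
    corr = cov / math.sqrt(var_j * var_m) if var_j > 0 and var_m > 0 else 0.0
    return mse, norm_mse, corr


def fit_gabors(
    J_part: np.ndarray,
    shape: tuple[int, int],
    n_gabors: int,
    quadrature: bool = False,
    de: DEConfig | None = None,
) -> GaborFitResult:
    """Fit a sign-definite part of J as a weighted sum of Gabor outer products.

    ``J_part`` is the kernel rebuilt from significant eigencomponents of
    one sign; its dominant sign is detected and the fit is carried out on
    the positive version, with weight signs restored on output.  In
    quadrature mode ``n_gabors`` counts pairs.  The best of
    ``de.restarts`` independent DE runs is returned.
    """
    if n_gabors < 1:
        raise ValueError("n_gabors must be >= 1")
    de = de or DEConfig()
    J_part = np.asarray(J_part, dtype=np.float64)
    if J_part.ndim != 2 or J_part.shape[0] != J_part.shape[1]:
        raise ValueError(f"J_part must be square, got {J_part.shape}")
    if not np.allclose(J_part, J_part.T, rtol=1e-8, atol=1e-10):
        raise ValueError("J_part must be symmetric")
    P = shape[0] * shape[1]
    if J_part.shape[0] != P:
        raise ValueError(f"J_part is {J_part.shape[0]}x{J_part.shape[0]} but shape implies {P}")
    evals = np.linalg.eigvalsh(J_part)
    pos_energy = float(np.sum(evals[evals > 0] ** 2))
    neg_energy = float(np.sum(evals[evals < 0] ** 2))
    sign = 1.0 if pos_energy >= neg_energy else -1.0
    J_fit = sign * J_part
    w_hi = float(np.max(np.abs(evals)))
    if w_hi == 0:
        raise ValueError("J_part is identically zero")

    lower, upper, block = _genome_spec(shape, n_gabors, quadrature, w_hi,
                                       de.shared_pair_weight)

    def objective(genome: np.ndarray) -> float:
        gabors = _decode(genome, shape, n_gabors, block, quadrature,
                         de.shared_pair_weight)
        mse, _, _ = _reconstruction_stats(gabors, J_fit, shape)
        return mse

    best_genome, best_err, best_gens = None, np.inf, 0
    restart_errors = []
    for r in range(de.restarts):
        rng = np.random.default_rng(de.seed * max(de.restarts, 1) + r)
        genome, errv, gens = _de_rand2bin(objective, lower, upper, de, rng)
        restart_errors.append(errv)
        if errv < best_err:
            best_genome, best_err, best_gens = genome, errv, gens
    gabors = _decode(best_genome, shape, n_gabors, block, quadrature,
                     de.shared_pair_weight)
    mse, norm_mse, corr = _reconstruction_stats(gabors, J_fit, shape)
    for g in gabors:
        gabor_image(g, shape)  # sets the normalization constant A
        g.w *= sign
    return GaborFitResult(
        gabors=gabors,
        mse=mse,
        norm_mse=norm_mse,
        correlation=corr,
        n_generations=best_gens,
        restart_errors=restart_errors,
    )


# ---------------------------------------------------------------------------
# pairing and phase differences


def _axial_diff_rad(a: float, b: float) -> float:
    """Axial (mod pi) angular difference in [0, pi/2]."""
    d = abs(a - b) % math.pi
    return min(d, math.pi - d)


def _harmonic_mean_wavelength(la: float, lb: float) -> float:
    """Wavelength of the mean spatial frequency of two Gabors."""
    return 2.0 / (1.0 / la + 1.0 / lb)


def pair_gabors(
    gabors: list,
    max_dist_lambda: float = 1.0,
    max_angle_deg: float = 30.0,
) -> list[GaborPair]:
    """Greedy nearest-neighbour pairing by position and axial orientation.

    A candidate pair qualifies when the center distance is below
    ``max_dist_lambda`` mean wavelengths and the axial orientation
    difference is below ``max_angle_deg``.  Pairs are accepted in order
    of a combined normalized similarity score, ties broken in favour of
    larger combined |w|; each Gabor joins at most one pair.
    """
    if len(gabors) < 2:
        raise ValueError("need at least 2 Gabors to pair")
    cands = []
    for i in range(len(gabors)):
        for j in range(i + 1, len(gabors)):
            a, b = gabors[i], gabors[j]
            lam_bar = _harmonic_mean_wavelength(a.lam, b.lam)
            dist = math.hypot(a.x0 - b.x0, a.y0 - b.y0)
            ang = math.degrees(_axial_diff_rad(a.theta, b.theta))
            if dist < max_dist_lambda * lam_bar and ang < max_angle_deg:
                score = dist / (max_dist_lambda * lam_bar) + ang / max_angle_deg
                cands.append((score, -(abs(a.w) + abs(b.w)), i, j, lam_bar))
    cands.sort()
    used: set[int] = set()
    pairs: list[GaborPair] = []
    for _, _, i, j, lam_bar in cands:
        if i in used or j in used:
            continue
        used.update((i, j))
        dx = np.array([gabors[i].x0 - gabors[j].x0, gabors[i].y0 - gabors[j].y0])
        pair = GaborPair(i=i, j=j, delta_phase=0.0, delta_x=dx, lambda_bar=lam_bar)
        pair.delta_phase = phase_difference(pair, gabors)
        pairs.append(pair)
    return pairs


def phase_difference(pair: GaborPair, gabors: list) -> float:
    """Displacement-corrected spatial phase difference of a pair, in degrees.

    The raw difference phi_i - phi_j is corrected by the phase advance
    (2 pi / lambda_bar) * (delta_x . n_hat) implied by the displacement of
    the centers along the carrier direction n_hat, where lambda_bar is the
    wavelength of the pair's mean spatial frequency; the result is folded
    into [0, 180) degrees.
    """
    a, b = gabors[pair.i], gabors[pair.j]
    # mean carrier direction from the axial circular mean of 2*theta
    s = math.sin(2 * a.theta) + math.sin(2 * b.theta)
    c = math.cos(2 * a.theta) + math.cos(2 * b.theta)
    theta_bar = 0.5 * math.atan2(s, c)
    n_hat = np.array([math.cos(theta_bar), math.sin(theta_bar)])
    lam_bar = pair.lambda_bar
    raw = a.phi - b.phi - (2.0 * math.pi / lam_bar) * float(pair.delta_x @ n_hat)
    deg = math.degrees(raw) % 360.0
    return min(deg, 360.0 - deg)
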