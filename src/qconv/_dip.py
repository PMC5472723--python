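"""Hartigan-Hartigan dip statistic for unimodality.

The dip of an empirical CDF F_n is the smallest sup-norm distance
between F_n and any unimodal distribution function.  It is computed
here from the variational characterization: a unimodal CDF is convex to
the left of the mode and concave to the right, with an arbitrary upward
jump at the mode.  For every placement of the mode between adjacent
order statistics the minimal sup-distance is a small linear program
(band constraints from the ECDF steps, convexity/concavity of the two
chains, monotone continuation across the jump); the dip is the minimum
over mode placements.

Solving one LP per split would be wasteful, so a fast lower bound is
computed first: ignoring the monotone coupling across the jump, the
minimal sup-distance of a convex (concave) chain to the band centers
c_i = (i - 1/2)/n equals half the largest gap between the centers and
their greatest convex minorant (least concave majorant), accumulated
with incremental hulls in O(n^2).  Only splits whose bound undercuts
the best exact value found so far are handed to the LP, which makes the
result exact at a few LP solves per sample.

Tied observations follow the convention of the classical algorithm:
every observation is its own ECDF step, and a chain passing through a
tied location must satisfy the intersected band of the whole tie block.
A constant sample has dip 0.  The p-value is estimated by Monte Carlo
against uniform null samples of the same size, the standard calibration
for the dip test.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog

__all__ = ["dip", "dip_test", "null_dip_table"]


def _prefix_convex_violations(x: np.ndarray, c: np.ndarray) -> np.ndarray:
    """V[a] = max_i<=a (c_i - GCM(x_i)) for each prefix, via incremental hulls.

    The greatest convex minorant is anchored at (x_0 - B, 0) with B large,
    encoding that a unimodal CDF rises from 0 far to the left.
    """
    n = x.size
    B = 1e6 * (x[-1] - x[0] + 1.0)
    hx = [x[0] - B]
    hy = [0.0]
    V = np.empty(n)
    for a in range(n):
        while len(hx) >= 2:
            (x1, y1), (x2, y2) = (hx[-2], hy[-2]), (hx[-1], hy[-1])
            if (c[a] - y2) * (x2 - x1) < (y2 - y1) * (x[a] - x2):
                hx.pop()
                hy.pop()
            else:
                break
        if x[a] > hx[-1]:
            hx.append(x[a])
            hy.append(c[a])
        # tied x: the earlier (lower) point already carries the minorant
        gcm = np.interp(x[: a + 1], hx, hy)
        V[a] = float(np.max(c[: a + 1] - gcm))
    return V


def _split_min_t(x: np.ndarray, a: int) -> float:
    """Exact minimal sup-distance for the mode between x[a] and x[a+1].

    Linear program over one G value per distinct location within each
    chain plus the distance t.  Band constraints come from the ECDF step
    limits at each observation; the left chain is convex and anchored at
    0 far to the left, the right chain concave and anchored at 1 far to
    the right, and the two must join monotonically across the jump.
    """
    n = x.size
    B = 1e6 * (x[-1] - x[0] + 1.0)
    lmap: dict[float, int] = {}
    lxs: list[float] = []
    for i in range(a + 1):
        if x[i] not in lmap:
            lmap[x[i]] = len(lxs)
            lxs.append(x[i])
    rmap: dict[float, int] = {}
    rxs: list[float] = []
    for i in range(a + 1, n):
        if x[i] not in rmap:
            rmap[x[i]] = len(lxs) + len(rxs)
            rxs.append(x[i])
    nv = len(lxs) + len(rxs) + 1
    T = nv - 1
    cobj = np.zeros(nv)
    cobj[T] = 1.0
    rows, rhs = [], []

    def add(row, b):
        rows.append(row)
        rhs.append(b)

    for i in range(n):
        v = lmap[x[i]] if i <= a else rmap[x[i]]
        r = np.zeros(nv)
        r[v] = -1.0
        r[T] = -1.0
        add(r, -(i + 1) / n)  # g >= (i+1)/n - t
        r = np.zeros(nv)
        r[v] = 1.0
        r[T] = -1.0
        add(r, i / n)  # g <= i/n + t

    def chain(points, convex):
        # slope(k,k+1) <= slope(k+1,k+2) for convex; reversed for concave
        sgn = 1.0 if convex else -1.0
        for k in range(len(points) - 2):
            (x1, i1, y1), (x2, i2, y2), (x3, i3, y3) = points[k : k + 3]
            r = np.zeros(nv)
            b = 0.0
            for idx, yv, coef in (
                (i1, y1, -(x3 - x2)),
                (i2, y2, (x3 - x2) + (x2 - x1)),
                (i3, y3, -(x2 - x1)),
            ):
                if idx is None:
                    b -= sgn * coef * yv
                else:
                    r[idx] += sgn * coef
            add(r, b)

    if lxs:
        chain([(x[0] - B, None, 0.0)] + [(xx, lmap[xx], 0.0) for xx in lxs], convex=True)
        r = np.zeros(nv)
        r[lmap[lxs[0]]] = -1.0
        add(r, 0.0)  # g_first >= 0
    if rxs:
        chain([(xx, rmap[xx], 0.0) for xx in rxs] + [(x[-1] + B, None, 1.0)], convex=False)
        r = np.zeros(nv)
        r[rmap[rxs[-1]]] = 1.0
        add(r, 1.0)  # g_last <= 1
    if lxs and rxs:
        r = np.zeros(nv)
        r[lmap[lxs[-1]]] = 1.0
        r[rmap[rxs[0]]] = -1.0
        add(r, 0.0)  # monotone across the jump
    res = linprog(
        cobj,
        A_ub=np.array(rows),
        b_ub=np.array(rhs),
        bounds=[(0.0, 1.0)] * nv,
        method="highs",
    )
    if not res.success:  # pragma: no cover - the LP is always feasible
        raise RuntimeError(f"dip split LP failed: {res.message}")
    return float(res.fun)


def dip(values: np.ndarray) -> float:
    """Dip statistic of a sample (n >= 4)."""
    x = np.sort(np.asarray(values, dtype=np.float64))
    n = x.size
    if n < 4:
        raise ValueError(f"dip requires at least 4 values, got {n}")
    if x[0] == x[-1]:
        return 0.0
    c = (np.arange(n) + 0.5) / n
    V_left = _prefix_convex_violations(x, c)
    # concave suffix violations via the reflection x -> -x, F -> 1 - F
    W_rev = _prefix_convex_violations(-x[::-1], (1.0 - c)[::-1])
    W_right = W_rev[::-1]
    # lower bound per mode placement: between x[a] and x[a+1]
    # (a = -1 and a = n-1 put the mode outside the data range)
    bounds = np.empty(n + 1)
    bounds[0] = W_right[0]
    bounds[n] = V_left[n - 1]
    bounds[1:n] = np.maximum(V_left[: n - 1], W_right[1:])
    bounds = 1.0 / (2.0 * n) + 0.5 * bounds
    order = np.argsort(bounds)
    best = np.inf
    for k in order:
        if bounds[k] >= best:
            break
        best = min(best, _split_min_t(x, k - 1))
    return float(best)


def dip_test(
    values: np.ndarray,
    n_boot: int = 200,
    seed: int = 0,
    null_dips: np.ndarray | None = None,
) -> tuple[float, float]:
    """Dip statistic and Monte-Carlo p-value against the uniform null.

    ``null_dips`` may carry a precomputed table of null dip values for
    this sample size (useful when testing many samples of equal n).
    """
    x = np.asarray(values, dtype=np.float64)
    d = dip(x)
    if null_dips is None:
        null_dips = null_dip_table(x.size, n_boot=n_boot, seed=seed)
    null_dips = np.asarray(null_dips, dtype=np.float64)
    p = (1 + int(np.sum(null_dips >= d))) / (null_dips.size + 1)
    return d, float(p)


def null_dip_table(n: int, n_boot: int = 200, seed: int = 0) -> np.ndarray:
    """Monte-Carlo table of dip values for uniform samples of size n."""
    rng = np.random.default_rng(seed)
    return np.array([dip(rng.random(n)) for _ in range(n_boot)])
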