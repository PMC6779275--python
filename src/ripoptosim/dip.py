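"""Hartigan's dip statistic and bootstrap test of unimodality.

The dip of an empirical CDF ``F_n`` is the smallest ``d`` such that some
unimodal CDF (convex up to a mode, concave after it) fits inside the uniform
band ``[F_n - d, F_n + d]``.  We compute it directly from this definition by
bisection on ``d`` with an exact band-feasibility check:

* a convex function fits the band over points ``x_1..x_k`` iff the greatest
  convex minorant of the upper band stays above the lower band there;
* a concave function fits over ``x_k..x_n`` iff the least concave majorant of
  the lower band stays below the upper band;
* the two pieces can be joined at some ``x_k`` iff the minorant value is not
  below the majorant value at the junction (the mode may carry a jump).

Step-function geometry: on ``[x_j, x_{j+1})`` the empirical CDF equals
``j/n``, so the binding constraints at the sample points are
``L_j = j/n - d`` (from the left limit of the band's floor) and
``U_j = (j-1)/n + d`` (the band's ceiling just left of the jump).

The p-value is a Monte-Carlo calibration against the uniform null — the
least-favourable unimodal distribution — at the observed sample size.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["dip_statistic", "dip_test"]


@njit(cache=True)
def _feasible(x, n, d):
    """Can a unimodal CDF fit within +-d of the empirical CDF of x (sorted)?"""
    L = np.empty(n)
    U = np.empty(n)
    for j in range(n):
        Lj = (j + 1) / n - d
        if Lj < 0.0:
            Lj = 0.0
        Uj = j / n + d
        if Uj > 1.0:
            Uj = 1.0
        L[j] = Lj
        U[j] = Uj
    # left_ok[k]: convex piece fits on 0..k  (computed by one incremental scan)
    # right_ok[k]: concave piece fits on k..n-1 (mirror scan)
    left_ok = np.zeros(n, dtype=np.bool_)
    # incremental convex scan
    stack = np.empty(n, dtype=np.int64)
    top = 0
    stack[0] = 0
    ok = L[0] <= U[0]
    left_ok[0] = ok
    for j in range(1, n):
        if not ok:
            left_ok[j] = False
            continue
        if L[j] > U[j]:
            ok = False
            left_ok[j] = False
            continue
        while top >= 1:
            a = stack[top - 1]
            b = stack[top]
            if ((U[b] - U[a]) * (x[j] - x[b]) >= (U[j] - U[b]) * (x[b] - x[a])):
                top -= 1
            else:
                break
        a = stack[top]
        if x[j] > x[a]:
            slope = (U[j] - U[a]) / (x[j] - x[a])
            for i in range(a + 1, j):
                if U[a] + slope * (x[i] - x[a]) < L[i] - 1e-12:
                    ok = False
                    break
        else:
            mn = U[a] if U[a] < U[j] else U[j]
            for i in range(a + 1, j):
                if mn < L[i] - 1e-12:
                    ok = False
                    break
        if not ok:
            left_ok[j] = False
            continue
        top += 1
        stack[top] = j
        left_ok[j] = True

    if not left_ok[n - 1]:
        pass  # may still be feasible with an earlier mode

    # mirror: concave piece from the right == convex piece of the reflected,
    # flipped problem; track feasibility and junction values
    right_ok = np.zeros(n, dtype=np.bool_)
    top = 0
    stack[0] = n - 1
    ok = L[n - 1] <= U[n - 1]
    right_ok[n - 1] = ok
    for jj in range(1, n):
        j = n - 1 - jj
        if not ok:
            right_ok[j] = False
            continue
        if L[j] > U[j]:
            ok = False
            right_ok[j] = False
            continue
        while top >= 1:
            a = stack[top - 1]
            b = stack[top]
            # LCM of lower bounds, scanning right-to-left
            if ((L[b] - L[a]) * (x[j] - x[b]) >= (L[j] - L[b]) * (x[b] - x[a])):
                top -= 1
            else:
                break
        a = stack[top]
        if x[j] < x[a]:
            slope = (L[j] - L[a]) / (x[j] - x[a])
            for i in range(j + 1, a):
                if L[a] + slope * (x[i] - x[a]) > U[i] + 1e-12:
                    ok = False
                    break
        else:
            mx = L[a] if L[a] > L[j] else L[j]
            for i in range(j + 1, a):
                if mx > U[i] + 1e-12:
                    ok = False
                    break
        if not ok:
            right_ok[j] = False
            continue
        top += 1
        stack[top] = j
        right_ok[j] = True

    # junction: mode between x_k and x_{k+1} (or at a sample point).  The
    # convex piece can reach up to U[k] and the concave piece down to L[k+1];
    # since U[k] = k/n + d and L[k+1] = (k+2)/n - d, U[k] >= L[k+1] holds
    # whenever d >= 1/n, so the pieces join whenever both halves fit.
    for k in range(n):
        lo = left_ok[k]
        hi = right_ok[k + 1] if k + 1 < n else True
        if lo and hi:
            return True
    if right_ok[0]:
        return True  # mode at/left of the first point: purely concave fit
    return False


@njit(cache=True)
def _dip_sorted(x, n, tol):
    if n < 4 or x[0] == x[n - 1]:
        return 0.0
    lo = 0.0
    hi = 0.5
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _feasible(x, n, mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def dip_statistic(data, tol: float = 1e-6) -> float:
    """Hartigan's dip of a 1-D sample (bisection to absolute ``tol``)."""
    x = np.sort(np.asarray(data, dtype=float))
    return float(_dip_sorted(x, x.size, tol))


@njit(cache=True)
def _null_dips(n, n_boot, seed, tol):
    np.random.seed(seed)
    out = np.empty(n_boot)
    for b in range(n_boot):
        u = np.sort(np.random.random(n))
        out[b] = _dip_sorted(u, n, tol)
    return out


_NULL_CACHE: dict = {}


def dip_test(data, n_boot: int = 500, seed: int = 12345,
             tol: float = 1e-5) -> tuple[float, float]:
    """Dip statistic and Monte-Carlo p-value against the uniform null.

    Returns ``(dip, p_value)``; small p indicates departure from unimodality.
    The null distribution is cached per (n, n_boot, seed).
    """
    x = np.asarray(data, dtype=float)
    n = x.size
    if n < 4:
        return 0.0, 1.0
    d = dip_statistic(x, tol)
    key = (n, n_boot, seed)
    if key not in _NULL_CACHE:
        _NULL_CACHE[key] = _null_dips(n, n_boot, seed, tol)
    null = _NULL_CACHE[key]
    p = float((np.sum(null >= d - tol) + 1) / (n_boot + 1))
    return d, p
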