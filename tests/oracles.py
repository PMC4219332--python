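"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's solver paths: vertices of small
polyhedra are enumerated from tight-constraint subsets with plain numpy
linear algebra, so LP results can be cross-checked against an
implementation that shares no code with scipy's simplex/IPM machinery.
"""

from __future__ import annotations

import itertools

import numpy as np


def lp_vertex_min(c, A_eq, b_eq, lo, hi, A_ub=None, b_ub=None, tol=1e-7):
    """Minimize ``c @ x`` over a bounded polyhedron by vertex enumeration.

    Returns ``(value, x)`` at the best vertex, or ``(None, None)`` when the
    feasible set is empty.  Exponential in the number of constraints; only
    for tiny instances.
    """
    c = np.asarray(c, dtype=float)
    n = len(c)
    E = np.atleast_2d(np.asarray(A_eq, dtype=float)) if A_eq is not None else np.zeros((0, n))
    e = np.asarray(b_eq, dtype=float) if b_eq is not None else np.zeros(0)
    G_rows: list[np.ndarray] = []
    g_vals: list[float] = []
    if A_ub is not None:
        for row, bv in zip(np.atleast_2d(A_ub), np.asarray(b_ub, dtype=float)):
            G_rows.append(np.asarray(row, dtype=float))
            g_vals.append(float(bv))
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    for i in range(n):
        if np.isfinite(lo[i]):
            row = np.zeros(n)
            row[i] = -1.0
            G_rows.append(row)
            g_vals.append(-lo[i])
        if np.isfinite(hi[i]):
            row = np.zeros(n)
            row[i] = 1.0
            G_rows.append(row)
            g_vals.append(hi[i])
    G = np.array(G_rows)
    g = np.array(g_vals)

    rank_E = np.linalg.matrix_rank(E) if E.size else 0
    need = n - rank_E
    best_val, best_x = None, None
    for combo in itertools.combinations(range(len(G)), need):
        M = np.vstack([E, G[list(combo)]])
        rhs = np.concatenate([e, g[list(combo)]])
        x, _, rank, _ = np.linalg.lstsq(M, rhs, rcond=None)
        if rank < n:
            continue
        if np.max(np.abs(M @ x - rhs), initial=0.0) > tol:
            continue
        if E.size and np.max(np.abs(E @ x - e), initial=0.0) > tol:
            continue
        if np.any(G @ x > g + tol):
            continue
        val = float(c @ x)
        if best_val is None or val < best_val - 1e-12:
            best_val, best_x = val, x
    return best_val, best_x


def l1_adjust_vertex(stoich, v_ut, upper, tol=1e-7):
    """Independent L1 minimal-adjustment optimum by vertex enumeration.

    The minimum of the piecewise-linear convex distance over the flux
    polytope is attained at a vertex of the polytope refined by the
    breakpoint hyperplanes ``v_i = v_ut_i``; those hyperplanes are offered
    to the enumerator as candidate tight rows (as opposing inequality
    pairs), so the search stays in flux space instead of the lifted
    ``(v, a)`` space.
    """
    stoich = np.atleast_2d(np.asarray(stoich, dtype=float))
    v_ut = np.asarray(v_ut, dtype=float)
    upper = np.asarray(upper, dtype=float)
    m, r = stoich.shape
    G_rows: list[np.ndarray] = []
    g_vals: list[float] = []
    eye = np.eye(r)
    for i in range(r):
        G_rows += [-eye[i], eye[i], eye[i], -eye[i]]
        g_vals += [0.0, float(upper[i]), float(v_ut[i]), float(-v_ut[i])]
    G = np.array(G_rows)
    g = np.array(g_vals)
    # feasibility rows only (breakpoints excluded from the feasibility check)
    feas_rows = np.array([row for i in range(r) for row in (-eye[i], eye[i])])
    feas_vals = np.array([val for i in range(r) for val in (0.0, float(upper[i]))])

    need = r - (np.linalg.matrix_rank(stoich) if stoich.size else 0)
    best_val, best_x = None, None
    for combo in itertools.combinations(range(len(G)), need):
        M = np.vstack([stoich, G[list(combo)]])
        rhs = np.concatenate([np.zeros(m), g[list(combo)]])
        x, _, rank, _ = np.linalg.lstsq(M, rhs, rcond=None)
        if rank < r:
            continue
        if np.max(np.abs(M @ x - rhs), initial=0.0) > tol:
            continue
        if stoich.size and np.max(np.abs(stoich @ x), initial=0.0) > tol:
            continue
        if np.any(feas_rows @ x > feas_vals + tol):
            continue
        val = float(np.abs(x - v_ut).sum())
        if best_val is None or val < best_val - 1e-12:
            best_val, best_x = val, x
    return best_val, best_x


def fba_vertex(stoich, lower, upper, j_obj):
    """Independent two-stage FBA by vertex enumeration.

    Returns ``(objective, min_total_flux_among_optima)``.
    """
    stoich = np.atleast_2d(np.asarray(stoich, dtype=float))
    m, r = stoich.shape
    c = np.zeros(r)
    c[j_obj] = -1.0
    val, _ = lp_vertex_min(c, stoich, np.zeros(m), lower, upper, None, None)
    assert val is not None
    opt = -val
    # second stage: pin the objective, minimize total flux
    A_eq = np.vstack([stoich, np.eye(r)[j_obj][None, :]])
    b_eq = np.concatenate([np.zeros(m), [opt]])
    total, _ = lp_vertex_min(np.ones(r), A_eq, b_eq, lower, upper, None, None)
    return opt, total
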