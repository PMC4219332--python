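"""Forward evaluation of treated fluxes: L1/L2 minimal-adjustment solvers.

Given a restricted bound set ``W(h)`` (from
:func:`fluxdose.inhibition.apply_inhibition`), the treated flux vector is
the point of ``W(h)`` closest to the reference fluxes.  The L1 variant is
the linear program used inside the bilevel machinery; the L2 variant is a
strictly convex quadratic cross-check with a unique minimizer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, linprog, minimize

from .errors import SolverError, ValidationError
from .netio import FEASIBILITY_TOL, MetabolicNetwork, ReferenceFluxes


@dataclass
class TreatedFluxes:
    """Result of a minimal-adjustment solve."""

    v_tr: np.ndarray
    abs_devs: np.ndarray
    side_effect: float
    norm_tag: str


def side_effect(v_tr, v_ut) -> float:
    """Total flux perturbation ``sum_i |v_tr_i - v_ut_i|``."""
    v_tr = np.asarray(v_tr, dtype=float)
    v_ut = np.asarray(v_ut, dtype=float)
    if v_tr.shape != v_ut.shape:
        raise ValidationError(f"flux vectors differ in shape: {v_tr.shape} vs {v_ut.shape}")
    return float(np.abs(v_tr - v_ut).sum())


def _as_upper(net: MetabolicNetwork, restricted_bounds) -> np.ndarray:
    upper = net.upper_bounds if restricted_bounds is None else np.asarray(restricted_bounds, dtype=float)
    if upper.shape != (net.n_reactions,):
        raise ValidationError(f"restricted bounds have shape {upper.shape}, expected ({net.n_reactions},)")
    return upper


def moma_l1(
    net: MetabolicNetwork,
    v_ut: ReferenceFluxes | np.ndarray,
    restricted_bounds=None,
) -> TreatedFluxes:
    """L1 minimal adjustment: ``min sum_i a_i`` over ``W(h)``.

    Variables are fluxes ``v`` and deviations ``a`` with the absolute value
    split ``v - a <= v_ut`` and ``-v - a <= -v_ut``.  The optimal value is
    unique even when the minimizer is not; the solver's vertex solution is
    returned.
    """
    ref = v_ut.v_ut if isinstance(v_ut, ReferenceFluxes) else np.asarray(v_ut, dtype=float)
    upper = _as_upper(net, restricted_bounds)
    r = net.n_reactions
    m = net.n_metabolites

    # columns: [v (r), a (r)]
    c = np.concatenate([np.zeros(r), np.ones(r)])
    A_eq = np.hstack([net.stoich, np.zeros((m, r))])
    b_eq = np.zeros(m)
    eye = np.eye(r)
    A_ub = np.vstack(
        [
            np.hstack([eye, -eye]),  # v - a <= v_ut
            np.hstack([-eye, -eye]),  # -v - a <= -v_ut
        ]
    )
    b_ub = np.concatenate([ref, -ref])
    bounds = [(0.0, float(u)) for u in upper] + [(0.0, None)] * r
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
    if not res.success:
        raise SolverError(f"L1 adjustment LP failed: {res.message}", status=res.status)
    v = np.asarray(res.x[:r], dtype=float)
    a = np.abs(v - ref)
    return TreatedFluxes(v_tr=v, abs_devs=a, side_effect=float(a.sum()), norm_tag="L1")


def moma_l2(
    net: MetabolicNetwork,
    v_ut: ReferenceFluxes | np.ndarray,
    restricted_bounds=None,
    tol: float = 1e-12,
) -> TreatedFluxes:
    """L2 minimal adjustment: unique projection of the reference onto ``W(h)``."""
    ref = v_ut.v_ut if isinstance(v_ut, ReferenceFluxes) else np.asarray(v_ut, dtype=float)
    upper = _as_upper(net, restricted_bounds)
    r = net.n_reactions

    def fun(v):
        d = v - ref
        return float(d @ d)

    def jac(v):
        return 2.0 * (v - ref)

    x0 = np.clip(ref, 0.0, upper)
    res = minimize(
        fun,
        x0,
        jac=jac,
        hess=lambda v: 2.0 * np.eye(r),
        method="trust-constr",
        constraints=[LinearConstraint(net.stoich, 0.0, 0.0)],
        bounds=Bounds(np.zeros(r), upper),
        options={"gtol": tol, "xtol": tol, "maxiter": 2000, "verbose": 0},
    )
    v = np.asarray(res.x, dtype=float)
    v = _polish_projection(net, ref, upper, v)
    if np.max(np.abs(net.stoich @ v)) > 1e-6 or np.any(v < -1e-6) or np.any(v > upper + 1e-6):
        raise SolverError(f"L2 adjustment QP failed to satisfy constraints: {res.message}", status=res.status)
    a = np.abs(v - ref)
    return TreatedFluxes(v_tr=v, abs_devs=a, side_effect=float(a.sum()), norm_tag="L2")


def _polish_projection(net: MetabolicNetwork, ref: np.ndarray, upper: np.ndarray, v: np.ndarray,
                       active_tol: float = 1e-5) -> np.ndarray:
    """Snap an approximate projection to the exact minimizer on its active set.

    Fixes the bounds the iterative solve ended (nearly) active on and solves
    the remaining equality-constrained least-squares problem in closed form
    via its KKT system; the polished point is used only when it stays
    feasible and does not worsen the objective.
    """
    r = net.n_reactions
    rows = [net.stoich]
    rhs = [np.zeros(net.n_metabolites)]
    eye = np.eye(r)
    for i in range(r):
        if v[i] < active_tol:
            rows.append(eye[i][None, :])
            rhs.append([0.0])
        elif upper[i] - v[i] < active_tol:
            rows.append(eye[i][None, :])
            rhs.append([float(upper[i])])
    E = np.vstack(rows)
    e = np.concatenate(rhs)
    # projection onto {E v = e}: v* = ref - E^T nu with (E E^T) nu = E ref - e
    nu = np.linalg.lstsq(E @ E.T, E @ ref - e, rcond=None)[0]
    cand = ref - E.T @ nu
    feasible = (
        np.max(np.abs(net.stoich @ cand), initial=0.0) <= 1e-9
        and np.all(cand >= -1e-9)
        and np.all(cand <= upper + 1e-9)
    )
    if feasible and (cand - ref) @ (cand - ref) <= (v - ref) @ (v - ref) + 1e-9:
        return np.clip(cand, 0.0, upper)
    return v


def check_within(net: MetabolicNetwork, v, restricted_bounds=None, tol: float = 1e-6) -> bool:
    """Feasibility check of a flux vector against ``W(h)``."""
    upper = _as_upper(net, restricted_bounds)
    v = np.asarray(v, dtype=float)
    return bool(
        np.max(np.abs(net.stoich @ v), initial=0.0) <= tol
        and np.all(v >= -tol)
        and np.all(v <= upper + tol)
    )


__all__ = [
    "TreatedFluxes",
    "side_effect",
    "moma_l1",
    "moma_l2",
    "check_within",
    "FEASIBILITY_TOL",
]
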