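"""Downstream computations: oracle, nonlinearity index, surfaces, screening.

The exhaustive oracle enumerates every achievable dosage vector and solves
the inner adjustment LP for each; it serves as the independent reference
against which the single-level MILP is checked.  The screening protocol
runs the MILP for every reaction as modulation objective over a list of
thresholds and deduplicates identical dosage vectors across thresholds.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from .bilevel import DEFAULT_B, TreatmentSolution, solve_bilevel
from .errors import FluxdoseError, SolverError, ValidationError
from .inhibition import DrugCatalog, InhibitionEncoding, apply_inhibition
from .moma import moma_l1, moma_l2
from .netio import MetabolicNetwork, ReferenceFluxes

#: Enumeration cap for the oracle (grid points).
DEFAULT_ORACLE_CAP = 200_000

_ZERO_FLUX_TOL = 1e-9


# ---------------------------------------------------------------------------
# exhaustive oracle
# ---------------------------------------------------------------------------


def _extreme_mod_flux(
    net: MetabolicNetwork,
    ref: ReferenceFluxes,
    upper: np.ndarray,
    inner_opt: float,
    j_mod: int,
    sense: str,
) -> float:
    """Min (or max) of ``v_mod`` over the inner-optimal face of ``W(h)``.

    The inner L1 optimum can be degenerate; feasibility of a dosage vector
    means *some* inner-optimal flux vector satisfies the modulation
    constraint, so we optimize ``v_mod`` subject to
    ``sum |v - v_ut| <= inner_opt``.
    """
    r, m = net.n_reactions, net.n_metabolites
    c = np.zeros(2 * r)
    c[j_mod] = 1.0 if sense == "min" else -1.0
    eye = np.eye(r)
    A_ub = np.vstack(
        [
            np.hstack([eye, -eye]),
            np.hstack([-eye, -eye]),
            np.concatenate([np.zeros(r), np.ones(r)])[None, :],
        ]
    )
    b_ub = np.concatenate([ref.v_ut, -ref.v_ut, [inner_opt + 1e-9]])
    A_eq = np.hstack([net.stoich, np.zeros((m, r))])
    bounds = [(0.0, float(u)) for u in upper] + [(0.0, None)] * r
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=np.zeros(m), bounds=bounds, method="highs")
    if not res.success:
        raise SolverError(f"mod-flux extremization failed: {res.message}", status=res.status)
    return float(res.x[j_mod])


def exhaustive_oracle(
    net: MetabolicNetwork,
    ref: ReferenceFluxes,
    catalog: DrugCatalog,
    mod_id: str,
    tau: float,
    mode: str = "inhibit",
    precision: int = 1,
    scheme: str = "binary-expansion",
    b: float = DEFAULT_B,
    cap: int = DEFAULT_ORACLE_CAP,
) -> TreatmentSolution:
    """Brute-force search over the full dosage grid.

    For every achievable ``h`` the inner L1 optimum is computed; ``h`` is
    feasible when some inner-optimal flux vector satisfies the modulation
    constraint.  Returns the minimizer of ``side_effect + b * sum(h)`` or an
    infeasible-marker solution (``status='infeasible'``).
    """
    if mode not in ("inhibit", "activate"):
        raise ValidationError(f"mode must be 'inhibit' or 'activate', got {mode!r}")
    encoding = InhibitionEncoding.for_catalog(catalog, precision, scheme)
    grids = [encoding.achievable_levels(did) for did in catalog.drug_ids]
    n_points = int(np.prod([len(g) for g in grids]))
    if n_points > cap:
        raise ValidationError(
            f"oracle grid has {n_points} points (> cap {cap}); reduce precision or drug count"
        )
    j_mod = net.reaction_index(mod_id)
    target = tau * float(ref.v_ut[j_mod])

    best: tuple[float, np.ndarray, float] | None = None  # (objective, h, side effect)
    for combo in itertools.product(*grids):
        h = np.asarray(combo, dtype=float)
        upper = apply_inhibition(net, catalog, h)
        inner = moma_l1(net, ref, upper)
        if mode == "inhibit":
            extreme = _extreme_mod_flux(net, ref, upper, inner.side_effect, j_mod, "min")
            feasible = extreme <= target + 1e-7
        else:
            extreme = _extreme_mod_flux(net, ref, upper, inner.side_effect, j_mod, "max")
            feasible = extreme >= target - 1e-7
        if not feasible:
            continue
        objective = inner.side_effect + b * float(h.sum())
        if best is None or objective < best[0] - 1e-12:
            best = (objective, h, inner.side_effect)

    if best is None:
        return TreatmentSolution(
            h=np.zeros(catalog.n_drugs),
            booleans={},
            v_tr=ref.v_ut.copy(),
            side_effect=float("nan"),
            objective=float("nan"),
            duality_residual=float("nan"),
            status="infeasible",
            mode=mode,
            tau=tau,
            precision=precision,
            scheme=scheme,
            drug_ids=list(catalog.drug_ids),
        )
    objective, h, se = best
    v_tr = moma_l1(net, ref, apply_inhibition(net, catalog, h)).v_tr
    return TreatmentSolution(
        h=h,
        booleans={},
        v_tr=v_tr,
        side_effect=se,
        objective=objective,
        duality_residual=0.0,
        status="optimal",
        mode=mode,
        tau=tau,
        precision=precision,
        scheme=scheme,
        drug_ids=list(catalog.drug_ids),
    )


# ---------------------------------------------------------------------------
# nonlinearity index
# ---------------------------------------------------------------------------


def nonlinearity_index(v_ut_mod: float, single_effects, combined: float) -> float | None:
    """Scaled deviation of the combined effect from linear superposition.

    ``(sum_k single_k - (d - 1) * v_ut_mod - combined) / (v_ut_mod - combined)``;
    returns ``None`` when the treatment leaves the objective flux unchanged
    (zero denominator: the index is undefined, not a number).
    """
    singles = np.asarray(list(single_effects), dtype=float)
    d = len(singles)
    denom = v_ut_mod - combined
    if abs(denom) < 1e-12:
        return None
    return float((singles.sum() - (d - 1) * v_ut_mod - combined) / denom)


def eta_for_treatment(
    net: MetabolicNetwork,
    ref: ReferenceFluxes,
    catalog: DrugCatalog,
    mod_id: str,
    h,
    norm: str = "L1",
    _cache: dict | None = None,
) -> float | None:
    """Nonlinearity index of a dosage vector, measured on ``mod_id``."""
    h = np.asarray(h, dtype=float)
    j_mod = net.reaction_index(mod_id)
    solver = moma_l1 if norm == "L1" else moma_l2

    def mod_flux(hvec) -> float:
        key = (j_mod, tuple(np.round(hvec, 12)))
        if _cache is not None and key in _cache:
            return _cache[key]
        val = float(solver(net, ref, apply_inhibition(net, catalog, hvec)).v_tr[j_mod])
        if _cache is not None:
            _cache[key] = val
        return val

    singles = []
    for k in range(catalog.n_drugs):
        e = np.zeros(catalog.n_drugs)
        e[k] = h[k]
        singles.append(mod_flux(e) if h[k] > 0 else float(ref.v_ut[j_mod]))
    combined = mod_flux(h)
    return nonlinearity_index(float(ref.v_ut[j_mod]), singles, combined)


# ---------------------------------------------------------------------------
# interaction surfaces
# ---------------------------------------------------------------------------


@dataclass
class InteractionSurface:
    """A 2-drug dosage scan at fixed background.

    ``flux_pct[i, j]`` is ``100 * v_mod_tr / v_ut_mod`` at
    ``(grid_a[i], grid_b[j])``; ``eta_matrix`` holds the nonlinearity index
    with ``nan`` marking undefined or failed cells.
    """

    drug_pair: tuple[str, str]
    fixed_background: np.ndarray
    grid_a: np.ndarray
    grid_b: np.ndarray
    flux_pct: np.ndarray
    eta_matrix: np.ndarray
    norm_tag: str


def interaction_surface(
    net: MetabolicNetwork,
    ref: ReferenceFluxes,
    catalog: DrugCatalog,
    mod_id: str,
    drug_a: str,
    drug_b: str,
    background_h=None,
    precision: int = 4,
    norm: str = "L1",
) -> InteractionSurface:
    """Scan the dosage plane of two drugs, holding the others fixed."""
    if drug_a == drug_b:
        raise ValidationError("interaction surface needs two distinct drugs")
    if norm not in ("L1", "L2"):
        raise ValidationError(f"norm must be 'L1' or 'L2', got {norm!r}")
    ka = catalog.drug_ids.index(drug_a) if drug_a in catalog.drug_ids else None
    kb = catalog.drug_ids.index(drug_b) if drug_b in catalog.drug_ids else None
    if ka is None or kb is None:
        missing = drug_a if ka is None else drug_b
        raise ValidationError(f"unknown drug id {missing!r}; catalog has {catalog.drug_ids}")
    background = (
        np.zeros(catalog.n_drugs) if background_h is None else np.asarray(background_h, dtype=float)
    )
    j_mod = net.reaction_index(mod_id)
    vut_mod = float(ref.v_ut[j_mod])
    if abs(vut_mod) < _ZERO_FLUX_TOL:
        raise ValidationError(f"objective reaction {mod_id!r} carries no reference flux")

    encoding = InhibitionEncoding.for_catalog(catalog, precision, "binary-expansion")
    grid_a = encoding.achievable_levels(drug_a)
    grid_b = encoding.achievable_levels(drug_b)
    solver = moma_l1 if norm == "L1" else moma_l2
    cache: dict = {}

    flux_pct = np.full((len(grid_a), len(grid_b)), np.nan)
    eta = np.full((len(grid_a), len(grid_b)), np.nan)
    for ia, ha in enumerate(grid_a):
        for ib, hb in enumerate(grid_b):
            h = background.copy()
            h[ka] = ha
            h[kb] = hb
            try:
                tr = solver(net, ref, apply_inhibition(net, catalog, h))
                flux_pct[ia, ib] = 100.0 * tr.v_tr[j_mod] / vut_mod
                val = eta_for_treatment(net, ref, catalog, mod_id, h, norm=norm, _cache=cache)
                eta[ia, ib] = np.nan if val is None else val
            except FluxdoseError:
                # masked cell: leave nan, keep scanning
                continue
    return InteractionSurface(
        drug_pair=(drug_a, drug_b),
        fixed_background=background,
        grid_a=grid_a,
        grid_b=grid_b,
        flux_pct=flux_pct,
        eta_matrix=eta,
        norm_tag=norm,
    )


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------


@dataclass
class ScreeningRecord:
    mod_id: str
    tau: float
    precision: int
    mode: str
    solution: TreatmentSolution | None
    status: str  # optimal | infeasible | skipped-zero-flux | error
    cardinality: int | None = None
    eta: float | None = None
    kept: bool = True
    message: str = ""


def _mode_for_tau(tau: float) -> str:
    if 0.0 <= tau < 1.0:
        return "inhibit"
    if tau > 1.0:
        return "activate"
    raise ValidationError(f"tau={tau} is neither an inhibition (<1) nor an activation (>1) threshold")


def screen_reactions(
    net: MetabolicNetwork,
    ref: ReferenceFluxes,
    catalog: DrugCatalog,
    tau_list,
    precision: int = 1,
    scheme: str = "binary-expansion",
    b: float = DEFAULT_B,
    mod_ids=None,
    compute_eta: bool = True,
) -> list[ScreeningRecord]:
    """Run the MILP for every reaction as modulation objective.

    Reactions with zero reference flux are skipped with a marker record.
    For each (reaction, precision) group, identical dosage vectors found at
    several thresholds of the same mode are kept only at the most stringent
    one (smallest inhibition threshold, largest activation threshold).
    Per-cell solver failures are recorded, never raised.
    """
    tau_list = list(tau_list)
    if not tau_list:
        raise ValidationError("tau_list must not be empty")
    for tau in tau_list:
        _mode_for_tau(tau)  # validate ranges early
    mod_ids = list(net.reaction_ids) if mod_ids is None else list(mod_ids)

    records: list[ScreeningRecord] = []
    eta_cache: dict = {}
    for mod_id in mod_ids:
        j = net.reaction_index(mod_id)
        if abs(ref.v_ut[j]) < _ZERO_FLUX_TOL:
            for tau in tau_list:
                records.append(
                    ScreeningRecord(
                        mod_id=mod_id,
                        tau=tau,
                        precision=precision,
                        mode=_mode_for_tau(tau),
                        solution=None,
                        status="skipped-zero-flux",
                        kept=False,
                        message="reference flux is zero; fractional modulation undefined",
                    )
                )
            continue
        for tau in tau_list:
            mode = _mode_for_tau(tau)
            try:
                sol = solve_bilevel(
                    net, ref, catalog, mod_id, tau,
                    mode=mode, precision=precision, scheme=scheme, b=b,
                )
                eta = (
                    eta_for_treatment(net, ref, catalog, mod_id, sol.h, _cache=eta_cache)
                    if compute_eta
                    else None
                )
                records.append(
                    ScreeningRecord(
                        mod_id=mod_id,
                        tau=tau,
                        precision=precision,
                        mode=mode,
                        solution=sol,
                        status="optimal",
                        cardinality=sol.cardinality,
                        eta=eta,
                    )
                )
            except FluxdoseError as exc:
                status = "infeasible" if "no drug combination" in str(exc) else "error"
                records.append(
                    ScreeningRecord(
                        mod_id=mod_id,
                        tau=tau,
                        precision=precision,
                        mode=mode,
                        solution=None,
                        status=status,
                        kept=False,
                        message=str(exc),
                    )
                )
    deduplicate_records(records)
    return records


def deduplicate_records(records: list[ScreeningRecord]) -> None:
    """Apply the most-stringent-threshold rule in place.

    Duplicates are exact dosage-vector matches within a (mod_id, precision,
    mode) group; the survivor has the smallest tau among inhibition records
    and the largest tau among activation records.
    """
    groups: dict[tuple, list[ScreeningRecord]] = {}
    for rec in records:
        if rec.status != "optimal" or rec.solution is None:
            continue
        groups.setdefault((rec.mod_id, rec.precision, rec.mode), []).append(rec)
    for (_, _, mode), group in groups.items():
        by_h: dict[tuple, list[ScreeningRecord]] = {}
        for rec in group:
            key = tuple(np.round(rec.solution.h, 9))
            by_h.setdefault(key, []).append(rec)
        for dupes in by_h.values():
            if len(dupes) < 2:
                continue
            keep = min(dupes, key=lambda r: r.tau) if mode == "inhibit" else max(dupes, key=lambda r: r.tau)
            for rec in dupes:
                rec.kept = rec is keep


def screening_summary(records: list[ScreeningRecord]):
    """The four summary tables behind a dosage-precision screen.

    Returns a dict of tidy DataFrames: ``counts`` (kept solutions per
    (precision, tau)), ``cardinality`` (drug count per kept solution),
    ``side_effect`` and ``eta`` (per kept solution, pooled over tau).
    """
    import pandas as pd

    kept = [r for r in records if r.status == "optimal" and r.kept]
    counts = (
        pd.DataFrame(
            [(r.precision, r.tau) for r in kept], columns=["precision", "tau"]
        )
        .groupby(["precision", "tau"])
        .size()
        .rename("n_solutions")
        .reset_index()
        if kept
        else pd.DataFrame(columns=["precision", "tau", "n_solutions"])
    )
    detail = pd.DataFrame(
        [
            {
                "mod_id": r.mod_id,
                "precision": r.precision,
                "tau": r.tau,
                "mode": r.mode,
                "cardinality": r.cardinality,
                "side_effect": r.solution.side_effect,
                "eta": r.eta,
            }
            for r in kept
        ]
    )
    return {
        "counts": counts,
        "cardinality": detail[["precision", "mod_id", "tau", "cardinality"]] if len(detail) else detail,
        "side_effect": detail[["precision", "mod_id", "tau", "side_effect"]] if len(detail) else detail,
        "eta": detail[["precision", "mod_id", "tau", "eta"]] if len(detail) else detail,
    }
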