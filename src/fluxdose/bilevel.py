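"""Single-level MILP reformulation of the dosage bilevel program.

The inner L1 minimal-adjustment problem is folded into one mixed-integer
linear program via LP strong duality.  Writing the inner problem in the
standard form ``max c.x  s.t.  A x <= b, x >= 0`` (with the equalities kept
as free-dual rows), its dual is ``min b.theta  s.t.  A^T theta >= c`` and
at any inner optimum the two objective values coincide.  The derivation is
spelled out in ``docs/duality.md``; the resulting coupling equality is

    sum_i a_i + sum_j U_j lam_j + sum_p U_{i(p)} (1 - h_{k(p)}) delta_p
        + sum_j v_ut_j (alpha_j - beta_j)  =  0,

where ``p`` ranges over (drug, target) pairs.  The bilinear products
``delta_p * h_k`` are expanded over the Boolean dosage variables and each
``delta_p * x_{k,n}`` is replaced by an auxiliary ``z`` variable with the
standard four big-M rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

from .errors import InfeasibleTreatmentError, SolverError, ValidationError
from .inhibition import DrugCatalog, InhibitionEncoding, apply_inhibition
from .moma import moma_l1
from .netio import MetabolicNetwork, ReferenceFluxes

#: Default anti-overselection weight on ``sum_k h_k`` in the outer objective.
DEFAULT_B = 1e-3

#: Default scale factor for the uniform dual bound ``delta_max``.
DEFAULT_KAPPA = 10.0

_INF = float("inf")


# ---------------------------------------------------------------------------
# variable layout
# ---------------------------------------------------------------------------


@dataclass
class VariableLayout:
    """Column layout of the assembled MILP.

    Order: fluxes ``v`` (r), deviations ``a`` (r), metabolite duals ``mu``
    (m, free), bound duals ``lam`` (r), inhibition duals ``delta`` (one per
    (drug, target) pair), abs-value duals ``alpha``/``beta`` (r each),
    products ``z`` (one per (pair, Boolean)), dosage Booleans ``x``.
    """

    net: MetabolicNetwork
    catalog: DrugCatalog
    encoding: InhibitionEncoding
    pairs: list[tuple[int, int]] = field(init=False)  # (drug index, reaction column)

    def __post_init__(self) -> None:
        targets = self.catalog.resolve_targets(self.net)
        self.pairs = [
            (k, j)
            for k, did in enumerate(self.catalog.drug_ids)
            for j in targets[did]
        ]
        r, m = self.net.n_reactions, self.net.n_metabolites
        enc = self.encoding
        self.n_bits = [enc.n_booleans(d) for d in self.catalog.drug_ids]
        self.off_v = 0
        self.off_a = r
        self.off_mu = 2 * r
        self.off_lam = 2 * r + m
        self.off_delta = self.off_lam + r
        self.off_alpha = self.off_delta + len(self.pairs)
        self.off_beta = self.off_alpha + r
        self.off_z = self.off_beta + r
        self._z_start = np.concatenate(
            [[0], np.cumsum([self.n_bits[k] for k, _ in self.pairs])]
        ).astype(int)
        self.off_x = self.off_z + int(self._z_start[-1])
        self._x_start = np.concatenate([[0], np.cumsum(self.n_bits)]).astype(int)
        self.n_vars = self.off_x + int(self._x_start[-1])

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def n_booleans(self) -> int:
        return int(self._x_start[-1])

    @property
    def n_products(self) -> int:
        return int(self._z_start[-1])

    def v(self, j: int) -> int:
        return self.off_v + j

    def a(self, j: int) -> int:
        return self.off_a + j

    def mu(self, i: int) -> int:
        return self.off_mu + i

    def lam(self, j: int) -> int:
        return self.off_lam + j

    def delta(self, p: int) -> int:
        return self.off_delta + p

    def alpha(self, j: int) -> int:
        return self.off_alpha + j

    def beta(self, j: int) -> int:
        return self.off_beta + j

    def z(self, p: int, n: int) -> int:
        return self.off_z + int(self._z_start[p]) + n

    def x(self, k: int, n: int) -> int:
        return self.off_x + int(self._x_start[k]) + n

    def drug_weight(self, k: int) -> np.ndarray:
        return self.encoding.weights[self.catalog.drug_ids[k]]

    def variable_names(self) -> list[str]:
        names = [""] * self.n_vars
        rids = self.net.reaction_ids
        for j in range(self.net.n_reactions):
            names[self.v(j)] = f"v_{rids[j]}"
            names[self.a(j)] = f"a_{rids[j]}"
            names[self.lam(j)] = f"lam_{rids[j]}"
            names[self.alpha(j)] = f"alpha_{rids[j]}"
            names[self.beta(j)] = f"beta_{rids[j]}"
        for i, mid in enumerate(self.net.metabolite_ids):
            names[self.mu(i)] = f"mu_{mid}"
        for p, (k, j) in enumerate(self.pairs):
            names[self.delta(p)] = f"delta_{self.catalog.drug_ids[k]}_{rids[j]}"
            for n in range(self.n_bits[k]):
                names[self.z(p, n)] = f"z_{self.catalog.drug_ids[k]}_{rids[j]}_{n}"
        for k, did in enumerate(self.catalog.drug_ids):
            for n in range(self.n_bits[k]):
                names[self.x(k, n)] = f"x_{did}_{n}"
        return names


#: A constraint row: (name, {column: coefficient}, lower, upper).
Row = tuple[str, dict[int, float], float, float]


@dataclass
class ConstraintBlock:
    label: str
    rows: list[Row]

    def __len__(self) -> int:
        return len(self.rows)


# ---------------------------------------------------------------------------
# constraint blocks
# ---------------------------------------------------------------------------


def build_primal_block(
    layout: VariableLayout,
    ref: ReferenceFluxes,
) -> ConstraintBlock:
    """Inner-problem primal rows: steady state, bounds, inhibition bounds
    with the dosage expansion, and the absolute-value split.

    Emits exactly ``m + r + t + 2r`` rows for ``t`` (drug, target) pairs.
    """
    net = layout.net
    r, m = net.n_reactions, net.n_metabolites
    vut = ref.v_ut
    rows: list[Row] = []
    for i in range(m):
        coefs = {
            layout.v(j): float(net.stoich[i, j])
            for j in range(r)
            if net.stoich[i, j] != 0.0
        }
        rows.append((f"steady_{net.metabolite_ids[i]}", coefs, 0.0, 0.0))
    for j in range(r):
        rows.append((f"ub_{net.reaction_ids[j]}", {layout.v(j): 1.0}, -_INF, float(net.upper_bounds[j])))
    for p, (k, j) in enumerate(layout.pairs):
        U = float(net.upper_bounds[j])
        w = layout.drug_weight(k)
        coefs = {layout.v(j): 1.0}
        for n, wn in enumerate(w):
            coefs[layout.x(k, n)] = U * float(wn)
        rows.append((f"inhib_{p}", coefs, -_INF, U))
    for j in range(r):
        rows.append(
            (f"absp_{net.reaction_ids[j]}", {layout.v(j): 1.0, layout.a(j): -1.0}, -_INF, float(vut[j]))
        )
    for j in range(r):
        rows.append(
            (f"absm_{net.reaction_ids[j]}", {layout.v(j): -1.0, layout.a(j): -1.0}, -_INF, float(-vut[j]))
        )
    return ConstraintBlock("primal", rows)


def build_dual_block(layout: VariableLayout) -> ConstraintBlock:
    """Dual-feasibility rows of the inner LP: one per reaction for the flux
    column, one per reaction for the deviation column (``2r`` rows)."""
    net = layout.net
    r = net.n_reactions
    rows: list[Row] = []
    pairs_by_target: dict[int, list[int]] = {}
    for p, (_, j) in enumerate(layout.pairs):
        pairs_by_target.setdefault(j, []).append(p)
    for j in range(r):
        coefs: dict[int, float] = {}
        for i in range(net.n_metabolites):
            if net.stoich[i, j] != 0.0:
                coefs[layout.mu(i)] = float(net.stoich[i, j])
        coefs[layout.lam(j)] = 1.0
        for p in pairs_by_target.get(j, ()):
            coefs[layout.delta(p)] = 1.0
        coefs[layout.alpha(j)] = 1.0
        coefs[layout.beta(j)] = -1.0
        rows.append((f"dual_v_{net.reaction_ids[j]}", coefs, 0.0, _INF))
    for j in range(r):
        rows.append(
            (f"dual_a_{net.reaction_ids[j]}", {layout.alpha(j): 1.0, layout.beta(j): 1.0}, -_INF, 1.0)
        )
    return ConstraintBlock("dual", rows)


def build_duality_coupling(
    layout: VariableLayout,
    ref: ReferenceFluxes,
    delta_max: np.ndarray,
) -> ConstraintBlock:
    """Strong-duality equality plus big-M product linearization rows.

    One ``z`` variable exists per (pair, Boolean); its four relations are
    ``z >= 0`` (variable bound), ``z <= delta_max * x``, ``z <= delta`` and
    ``z >= delta - delta_max * (1 - x)``.
    """
    net = layout.net
    delta_max = np.asarray(delta_max, dtype=float)
    if delta_max.shape != (layout.n_pairs,):
        raise ValidationError(f"delta_max must have one entry per pair; got shape {delta_max.shape}")
    if np.any(delta_max <= 0) or not np.all(np.isfinite(delta_max)):
        raise ValidationError("delta_max entries must be positive and finite")
    rows: list[Row] = []

    # coupling equality: sum a + sum U lam + sum_p U delta_p
    #   - sum_p U sum_n w_n z_{p,n} + vut.(alpha - beta) = 0
    coefs: dict[int, float] = {}
    for j in range(net.n_reactions):
        coefs[layout.a(j)] = 1.0
        U = float(net.upper_bounds[j])
        if U != 0.0:
            coefs[layout.lam(j)] = U
        vut_j = float(ref.v_ut[j])
        if vut_j != 0.0:
            coefs[layout.alpha(j)] = vut_j
            coefs[layout.beta(j)] = -vut_j
    for p, (k, j) in enumerate(layout.pairs):
        U = float(net.upper_bounds[j])
        coefs[layout.delta(p)] = coefs.get(layout.delta(p), 0.0) + U
        for n, wn in enumerate(layout.drug_weight(k)):
            coefs[layout.z(p, n)] = coefs.get(layout.z(p, n), 0.0) - U * float(wn)
    rows.append(("strong_duality", coefs, 0.0, 0.0))

    for p, (k, _) in enumerate(layout.pairs):
        M = float(delta_max[p])
        for n in range(layout.n_bits[k]):
            zi, di, xi = layout.z(p, n), layout.delta(p), layout.x(k, n)
            rows.append((f"bigm_zx_{p}_{n}", {zi: 1.0, xi: -M}, -_INF, 0.0))
            rows.append((f"bigm_zd_{p}_{n}", {zi: 1.0, di: -1.0}, -_INF, 0.0))
            rows.append((f"bigm_dz_{p}_{n}", {di: 1.0, zi: -1.0, xi: M}, -_INF, M))
    return ConstraintBlock("coupling", rows)


def build_encoding_block(layout: VariableLayout) -> ConstraintBlock:
    """Dosage-variable structure rows.

    Binary expansion (P >= 1): the anti-redundancy rule
    ``P * x_{k,0} <= sum_{n=1..P} x_{k,n}`` (x_{k,0} may be one only when
    all other bits are).  Dose-response chains: ``x_{k,n+1} <= x_{k,n}``.
    At P = 0 a binary drug has a single Boolean and no extra row.
    """
    rows: list[Row] = []
    for k, did in enumerate(layout.catalog.drug_ids):
        nb = layout.n_bits[k]
        if layout.encoding.uses_chain(did):
            for n in range(nb - 1):
                rows.append(
                    (f"chain_{did}_{n}", {layout.x(k, n + 1): 1.0, layout.x(k, n): -1.0}, -_INF, 0.0)
                )
        elif nb > 1:
            P = nb - 1
            coefs = {layout.x(k, 0): float(P)}
            for n in range(1, nb):
                coefs[layout.x(k, n)] = -1.0
            rows.append((f"redund_{did}", coefs, -_INF, 0.0))
    return ConstraintBlock("encoding", rows)


def build_outer_block(
    layout: VariableLayout, ref: ReferenceFluxes, mod_id: str, tau: float, mode: str
) -> ConstraintBlock:
    """The outer modulation row on the objective reaction."""
    j = layout.net.reaction_index(mod_id)
    target = tau * float(ref.v_ut[j])
    if mode == "inhibit":
        row: Row = ("modulation", {layout.v(j): 1.0}, -_INF, target)
    else:
        row = ("modulation", {layout.v(j): 1.0}, target, _INF)
    return ConstraintBlock("outer", [row])


# ---------------------------------------------------------------------------
# dual bound estimation and fixed-h dual solve
# ---------------------------------------------------------------------------


def solve_inner_dual(
    net: MetabolicNetwork,
    ref: ReferenceFluxes,
    catalog: DrugCatalog,
    h,
):
    """Solve the dual of the fixed-h inner L1 adjustment LP.

    Returns ``(objective, duals)`` where duals is a dict with keys
    ``mu, lam, delta, alpha, beta``.  By strong duality the objective equals
    minus the inner L1 optimum.
    """
    h = np.asarray(h, dtype=float)
    targets = catalog.resolve_targets(net)
    pairs = [(k, j) for k, did in enumerate(catalog.drug_ids) for j in targets[did]]
    r, m, t = net.n_reactions, net.n_metabolites, len(pairs)
    # columns: mu (m, free) | lam (r) | delta (t) | alpha (r) | beta (r)
    n = m + r + t + 2 * r
    c = np.zeros(n)
    c[m : m + r] = net.upper_bounds
    for p, (k, j) in enumerate(pairs):
        c[m + r + p] = net.upper_bounds[j] * (1.0 - h[k])
    c[m + r + t : m + r + t + r] = ref.v_ut
    c[m + r + t + r :] = -ref.v_ut

    rows = []
    rhs = []
    # -(7g): -(S^T mu + lam_j + sum delta + alpha_j - beta_j) <= 0
    for j in range(r):
        row = np.zeros(n)
        row[:m] = -net.stoich[:, j]
        row[m + j] = -1.0
        for p, (_, jj) in enumerate(pairs):
            if jj == j:
                row[m + r + p] = -1.0
        row[m + r + t + j] = -1.0
        row[m + r + t + r + j] = 1.0
        rows.append(row)
        rhs.append(0.0)
    # (7h): alpha_j + beta_j <= 1
    for j in range(r):
        row = np.zeros(n)
        row[m + r + t + j] = 1.0
        row[m + r + t + r + j] = 1.0
        rows.append(row)
        rhs.append(1.0)
    bounds = [(None, None)] * m + [(0.0, None)] * (r + t + 2 * r)
    res = linprog(c, A_ub=np.array(rows), b_ub=np.array(rhs), bounds=bounds, method="highs")
    if not res.success:
        raise SolverError(f"inner dual LP failed: {res.message}", status=res.status)
    x = res.x
    duals = {
        "mu": x[:m],
        "lam": x[m : m + r],
        "delta": x[m + r : m + r + t],
        "alpha": x[m + r + t : m + r + t + r],
        "beta": x[m + r + t + r :],
    }
    return float(res.fun), duals


def estimate_delta_max(
    net: MetabolicNetwork,
    ref: ReferenceFluxes,
    catalog: DrugCatalog,
    kappa: float = DEFAULT_KAPPA,
    tighten: bool = False,
    max_samples: int = 32,
) -> np.ndarray:
    """Per-pair upper bounds for the inhibition duals.

    Default is the conservative uniform bound ``max(1, kappa * max_i U_i)``.
    With ``tighten=True`` the dual LP is solved over a sample of extreme
    dosage vectors and the observed maxima (with a 10x safety margin) cap
    the default.  Correctness is independently guarded by the post-solve
    re-validation in :func:`solve_bilevel`.
    """
    targets = catalog.resolve_targets(net)
    t = sum(len(targets[d]) for d in catalog.drug_ids)
    base = max(1.0, kappa * float(net.upper_bounds.max(initial=0.0)))
    bound = np.full(t, base)
    if not tighten:
        return bound
    d = catalog.n_drugs
    samples = [np.zeros(d), np.ones(d), np.full(d, 0.5)]
    for k in range(min(d, max_samples)):
        e = np.zeros(d)
        e[k] = 1.0
        samples.append(e)
        samples.append(1.0 - e)
    observed = np.zeros(t)
    for h in samples:
        _, duals = solve_inner_dual(net, ref, catalog, h)
        observed = np.maximum(observed, duals["delta"])
    tightened = np.maximum(1.0, 10.0 * observed)
    return np.minimum(bound, tightened)


# ---------------------------------------------------------------------------
# model assembly and solve
# ---------------------------------------------------------------------------


@dataclass
class BilevelModel:
    """The assembled MILP, exportable and solvable."""

    layout: VariableLayout
    blocks: list[ConstraintBlock]
    objective: np.ndarray
    integrality: np.ndarray
    var_lb: np.ndarray
    var_ub: np.ndarray
    delta_max: np.ndarray
    tau: float
    mode: str
    overselect_b: float
    mod_id: str

    @property
    def n_boolean_variables(self) -> int:
        return self.layout.n_booleans

    def rows(self) -> list[Row]:
        return [row for blk in self.blocks for row in blk.rows]

    def as_linear_constraints(self) -> list[LinearConstraint]:
        rows = self.rows()
        data, ri, ci = [], [], []
        lb = np.empty(len(rows))
        ub = np.empty(len(rows))
        for idx, (_, coefs, lo, up) in enumerate(rows):
            lb[idx] = lo
            ub[idx] = up
            for col, val in coefs.items():
                ri.append(idx)
                ci.append(col)
                data.append(val)
        A = sparse.csr_matrix((data, (ri, ci)), shape=(len(rows), self.layout.n_vars))
        return [LinearConstraint(A, lb, ub)]

    # -- text export --------------------------------------------------------

    def write_lp(self, path: str) -> None:
        """Write the model in CPLEX LP text format for external audit."""
        names = self.layout.variable_names()

        def term(coef, name):
            return f"{'+' if coef >= 0 else '-'} {abs(coef):.12g} {name}"

        with open(path, "w") as fh:
            fh.write("Minimize\n obj: ")
            fh.write(
                " ".join(
                    term(c, names[i]) for i, c in enumerate(self.objective) if c != 0.0
                )
            )
            fh.write("\nSubject To\n")
            for name, coefs, lo, up in self.rows():
                expr = " ".join(term(v, names[i]) for i, v in coefs.items())
                if lo == up:
                    fh.write(f" {name}: {expr} = {lo:.12g}\n")
                else:
                    if up != _INF:
                        fh.write(f" {name}: {expr} <= {up:.12g}\n")
                    if lo != -_INF:
                        fh.write(f" {name}_lo: {expr} >= {lo:.12g}\n")
            fh.write("Bounds\n")
            for i, name in enumerate(names):
                lo, up = self.var_lb[i], self.var_ub[i]
                lo_s = "-inf" if lo == -_INF else f"{lo:.12g}"
                up_s = "+inf" if up == _INF else f"{up:.12g}"
                fh.write(f" {lo_s} <= {name} <= {up_s}\n")
            binaries = [names[i] for i in range(len(names)) if self.integrality[i]]
            if binaries:
                fh.write("Binary\n " + " ".join(binaries) + "\n")
            fh.write("End\n")

    def write_mps(self, path: str) -> None:
        """Write the model in free MPS format for external audit."""
        names = self.layout.variable_names()
        rows = self.rows()
        with open(path, "w") as fh:
            fh.write("NAME fluxdose_bilevel\nROWS\n N obj\n")
            row_kind = []
            for name, _, lo, up in rows:
                if lo == up:
                    kind = "E"
                elif up != _INF and lo == -_INF:
                    kind = "L"
                elif lo != -_INF and up == _INF:
                    kind = "G"
                else:
                    kind = "L"  # ranged rows emitted with RANGES below
                row_kind.append(kind)
                fh.write(f" {kind} {name}\n")
            fh.write("COLUMNS\n")
            by_col: dict[int, list[tuple[str, float]]] = {}
            for ridx, (name, coefs, _, _) in enumerate(rows):
                for col, val in coefs.items():
                    by_col.setdefault(col, []).append((name, val))
            in_int = False
            for col in range(self.layout.n_vars):
                is_int = bool(self.integrality[col])
                if is_int and not in_int:
                    fh.write(" MARKER 'MARKER' 'INTORG'\n")
                    in_int = True
                if not is_int and in_int:
                    fh.write(" MARKER 'MARKER' 'INTEND'\n")
                    in_int = False
                if self.objective[col] != 0.0:
                    fh.write(f" {names[col]} obj {self.objective[col]:.12g}\n")
                for rname, val in by_col.get(col, ()):
                    fh.write(f" {names[col]} {rname} {val:.12g}\n")
            if in_int:
                fh.write(" MARKER 'MARKER' 'INTEND'\n")
            fh.write("RHS\n")
            for (name, _, lo, up), kind in zip(rows, row_kind):
                rhs = up if kind in ("E", "L") else lo
                if rhs != 0.0:
                    fh.write(f" rhs {name} {rhs:.12g}\n")
            fh.write("BOUNDS\n")
            for i, name in enumerate(names):
                lo, up = self.var_lb[i], self.var_ub[i]
                if lo == -_INF:
                    fh.write(f" MI bnd {name}\n")
                elif lo != 0.0:
                    fh.write(f" LO bnd {name} {lo:.12g}\n")
                if up != _INF:
                    fh.write(f" UP bnd {name} {up:.12g}\n")
            fh.write("ENDATA\n")


@dataclass
class TreatmentSolution:
    """Optimal treatment returned by the single-level MILP."""

    h: np.ndarray
    booleans: dict[str, np.ndarray]
    v_tr: np.ndarray
    side_effect: float
    objective: float
    duality_residual: float
    status: str
    mode: str
    tau: float
    precision: int
    scheme: str
    drug_ids: list[str]
    delta_max_ok: bool = True
    feasibility_tol: float = 1e-9

    @property
    def h_by_drug(self) -> dict[str, float]:
        return dict(zip(self.drug_ids, self.h.tolist()))

    @property
    def cardinality(self) -> int:
        return int(np.sum(self.h > 1e-9))


def build_bilevel_model(
    net: MetabolicNetwork,
    ref: ReferenceFluxes,
    catalog: DrugCatalog,
    mod_id: str,
    tau: float,
    mode: str = "inhibit",
    precision: int = 1,
    scheme: str = "binary-expansion",
    b: float = DEFAULT_B,
    delta_max: np.ndarray | float | None = None,
) -> BilevelModel:
    """Assemble (but do not solve) the single-level MILP."""
    if mode not in ("inhibit", "activate"):
        raise ValidationError(f"mode must be 'inhibit' or 'activate', got {mode!r}")
    if mode == "inhibit" and not (0.0 <= tau < 1.0):
        raise ValidationError(f"inhibit mode requires 0 <= tau < 1, got {tau}")
    if mode == "activate" and not tau > 1.0:
        raise ValidationError(f"activate mode requires tau > 1, got {tau}")
    if not net.is_canonical:
        raise ValidationError("bilevel model requires a canonical network")
    catalog.validate_against(net)
    net.reaction_index(mod_id)

    encoding = InhibitionEncoding.for_catalog(catalog, precision, scheme)
    layout = VariableLayout(net, catalog, encoding)
    if delta_max is None:
        dmax = estimate_delta_max(net, ref, catalog)
    else:
        dmax = np.broadcast_to(np.asarray(delta_max, dtype=float), (layout.n_pairs,)).copy()

    blocks = [
        build_primal_block(layout, ref),
        build_dual_block(layout),
        build_duality_coupling(layout, ref, dmax),
        build_encoding_block(layout),
        build_outer_block(layout, ref, mod_id, tau, mode),
    ]

    n = layout.n_vars
    c = np.zeros(n)
    for j in range(net.n_reactions):
        c[layout.a(j)] = 1.0
    for k in range(catalog.n_drugs):
        for nbit, w in enumerate(layout.drug_weight(k)):
            c[layout.x(k, nbit)] = b * float(w)

    lb = np.zeros(n)
    ub = np.full(n, _INF)
    for j in range(net.n_reactions):
        ub[layout.v(j)] = net.upper_bounds[j]
    for i in range(net.n_metabolites):
        lb[layout.mu(i)] = -_INF
    for j in range(net.n_reactions):
        ub[layout.alpha(j)] = 1.0
        ub[layout.beta(j)] = 1.0
    for p in range(layout.n_pairs):
        ub[layout.delta(p)] = dmax[p]
        for nbit in range(layout.n_bits[layout.pairs[p][0]]):
            ub[layout.z(p, nbit)] = dmax[p]
    integrality = np.zeros(n)
    for k in range(catalog.n_drugs):
        for nbit in range(layout.n_bits[k]):
            idx = layout.x(k, nbit)
            integrality[idx] = 1
            ub[idx] = 1.0

    return BilevelModel(
        layout=layout,
        blocks=blocks,
        objective=c,
        integrality=integrality,
        var_lb=lb,
        var_ub=ub,
        delta_max=dmax,
        tau=tau,
        mode=mode,
        overselect_b=b,
        mod_id=mod_id,
    )


def solve_bilevel(
    net: MetabolicNetwork,
    ref: ReferenceFluxes,
    catalog: DrugCatalog,
    mod_id: str,
    tau: float,
    mode: str = "inhibit",
    precision: int = 1,
    scheme: str = "binary-expansion",
    b: float = DEFAULT_B,
    delta_max: np.ndarray | float | None = None,
    mip_rel_gap: float = 0.0,
    time_limit: float | None = None,
    validate: bool = True,
) -> TreatmentSolution:
    """Solve the single-level MILP and return the optimal treatment.

    The returned dosage vector is decoded from the Boolean variables and
    re-validated by an independent inner L1 solve at the returned ``h``; a
    mismatch (symptom of a too-small ``delta_max``) raises
    :class:`SolverError`.
    """
    model = build_bilevel_model(
        net, ref, catalog, mod_id, tau, mode, precision, scheme, b, delta_max
    )
    layout = model.layout
    options = {"mip_rel_gap": mip_rel_gap}
    if time_limit is not None:
        options["time_limit"] = time_limit
    res = milp(
        c=model.objective,
        constraints=model.as_linear_constraints(),
        integrality=model.integrality,
        bounds=Bounds(model.var_lb, model.var_ub),
        options=options,
    )
    if res.status == 2 or (not res.success and res.x is None):
        raise InfeasibleTreatmentError(
            f"no drug combination achieves the modulation target "
            f"(mod={mod_id!r}, tau={tau}, mode={mode}): {res.message}",
            status=res.status,
        )
    if not res.success:
        raise SolverError(f"MILP solve failed: {res.message}", status=res.status)

    sol = np.asarray(res.x, dtype=float)
    booleans: dict[str, np.ndarray] = {}
    h = np.zeros(catalog.n_drugs)
    for k, did in enumerate(catalog.drug_ids):
        bits = np.array([sol[layout.x(k, nb)] for nb in range(layout.n_bits[k])])
        bits = np.round(bits).clip(0, 1)
        booleans[did] = bits
        h[k] = layout.encoding.decode(did, bits)

    v_tr = sol[: net.n_reactions]
    se = float(np.abs(v_tr - ref.v_ut).sum())

    # strong-duality residual from the returned variable values
    lam = np.array([sol[layout.lam(j)] for j in range(net.n_reactions)])
    alpha = np.array([sol[layout.alpha(j)] for j in range(net.n_reactions)])
    beta = np.array([sol[layout.beta(j)] for j in range(net.n_reactions)])
    dual_obj = float(net.upper_bounds @ lam + ref.v_ut @ (alpha - beta))
    for p, (k, j) in enumerate(layout.pairs):
        dual_obj += float(net.upper_bounds[j] * (1.0 - h[k]) * sol[layout.delta(p)])
    residual = abs(se + dual_obj)

    delta_vals = np.array([sol[layout.delta(p)] for p in range(layout.n_pairs)])
    at_bound = bool(np.any(delta_vals > 0.99 * model.delta_max)) if layout.n_pairs else False

    if validate:
        check = moma_l1(net, ref, apply_inhibition(net, catalog, h))
        if abs(check.side_effect - se) > 1e-6 * max(1.0, abs(se)) + 1e-6:
            raise SolverError(
                f"bilevel optimum failed re-validation: MILP side effect {se} vs "
                f"independent inner solve {check.side_effect}; consider raising delta_max"
            )

    objective = se + b * float(h.sum())
    return TreatmentSolution(
        h=h,
        booleans=booleans,
        v_tr=v_tr,
        side_effect=se,
        objective=objective,
        duality_residual=residual,
        status="optimal",
        mode=mode,
        tau=tau,
        precision=precision,
        scheme=scheme,
        drug_ids=list(catalog.drug_ids),
        delta_max_ok=not at_bound,
    )
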