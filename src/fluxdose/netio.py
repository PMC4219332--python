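"""Metabolic model I/O, canonicalization and reference fluxes.

A :class:`MetabolicNetwork` holds the stoichiometric matrix together with
flux bounds and reversibility flags.  The downstream optimization machinery
assumes the *canonical* form in which every reaction is irreversible with a
zero lower bound; :func:`make_irreversible` produces it by splitting each
reversible reaction into a forward/backward pair.

Supported on-disk dialects:

``structured-model``
    The repo's native line-based text format (see :data:`MODEL_SCHEMA`).
``tsv-triplet``
    A sparse triplet table (metabolite, reaction, coefficient) next to a
    bounds table; see :func:`_load_tsv_triplet`.
``sbml``
    SBML via cobrapy (optional dependency).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import linprog

from .errors import FormatError, SolverError, ValidationError

#: Feasibility tolerance used throughout (reported in solution metadata).
FEASIBILITY_TOL = 1e-9

#: Default flux upper bound for fluxes without an explicit one.
DEFAULT_UPPER_BOUND = 1e3

#: Schema of the ``structured-model`` dialect, kept here so the format is
#: documented next to its parser.
MODEL_SCHEMA = """\
# structured-model dialect (tab- or whitespace-separated)
#
#   [metabolites]        one metabolite id per line
#   [biomass]            single line: id of the biomass reaction
#   [reactions]          one reaction per line:
#       <id> <reversible:0|1> <lower> <upper> <met>:<coef> [<met>:<coef> ...]
#
# Lines starting with '#' and blank lines are ignored.  Coefficients are
# negative for substrates, positive for products.
"""


@dataclass
class MetabolicNetwork:
    """A stoichiometric model with flux bounds.

    Attributes
    ----------
    stoich:
        Dense ``(m, r)`` array of stoichiometric coefficients; column ``j``
        describes reaction ``reaction_ids[j]``.
    lower_bounds, upper_bounds:
        Per-reaction flux bounds, ``lower_bounds[i] <= upper_bounds[i]``.
    reversible_flags:
        Boolean per reaction.  In canonical form all entries are False.
    split_map:
        Maps an original reversible reaction id to its ``(forward, backward)``
        pair of canonical ids; empty for networks that were never split.
    ref_lower_bounds:
        Lower bounds enforced only in the reference-flux LP stage.  The
        canonical form requires ``lower_bounds == 0``; strictly positive
        original lower bounds are preserved here (see
        :func:`make_irreversible`).
    """

    stoich: np.ndarray
    lower_bounds: np.ndarray
    upper_bounds: np.ndarray
    reversible_flags: np.ndarray
    reaction_ids: list[str]
    metabolite_ids: list[str]
    biomass_id: str | None = None
    split_map: dict[str, tuple[str, str]] = field(default_factory=dict)
    ref_lower_bounds: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.stoich = np.asarray(self.stoich, dtype=float)
        self.lower_bounds = np.asarray(self.lower_bounds, dtype=float)
        self.upper_bounds = np.asarray(self.upper_bounds, dtype=float)
        self.reversible_flags = np.asarray(self.reversible_flags, dtype=bool)
        m, r = self.stoich.shape
        if len(self.reaction_ids) != r:
            raise ValidationError(
                f"stoich has {r} columns but {len(self.reaction_ids)} reaction ids"
            )
        if len(self.metabolite_ids) != m:
            raise ValidationError(
                f"stoich has {m} rows but {len(self.metabolite_ids)} metabolite ids"
            )
        for name, ids in (("reaction", self.reaction_ids), ("metabolite", self.metabolite_ids)):
            seen: set[str] = set()
            for rid in ids:
                if rid in seen:
                    raise ValidationError(f"duplicate {name} id: {rid!r}")
                seen.add(rid)
        if np.any(self.lower_bounds > self.upper_bounds + FEASIBILITY_TOL):
            bad = int(np.argmax(self.lower_bounds > self.upper_bounds))
            raise ValidationError(
                f"lower bound exceeds upper bound for reaction {self.reaction_ids[bad]!r}"
            )
        if self.biomass_id is not None and self.biomass_id not in self.reaction_ids:
            raise ValidationError(f"biomass id {self.biomass_id!r} not among reactions")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_metabolites(self) -> int:
        return self.stoich.shape[0]

    @property
    def n_reactions(self) -> int:
        return self.stoich.shape[1]

    @property
    def is_canonical(self) -> bool:
        """True when all reactions are irreversible with zero lower bounds."""
        return not self.reversible_flags.any() and np.all(self.lower_bounds == 0.0)

    def reaction_index(self, rid: str) -> int:
        try:
            return self.reaction_ids.index(rid)
        except ValueError:
            raise ValidationError(f"unknown reaction id: {rid!r}") from None

    def copy(self) -> "MetabolicNetwork":
        return replace(
            self,
            stoich=self.stoich.copy(),
            lower_bounds=self.lower_bounds.copy(),
            upper_bounds=self.upper_bounds.copy(),
            reversible_flags=self.reversible_flags.copy(),
            reaction_ids=list(self.reaction_ids),
            metabolite_ids=list(self.metabolite_ids),
            split_map=dict(self.split_map),
            ref_lower_bounds=None
            if self.ref_lower_bounds is None
            else self.ref_lower_bounds.copy(),
        )


@dataclass
class ReferenceFluxes:
    """Unperturbed fluxes from the two-stage reference LP."""

    v_ut: np.ndarray
    objective_value: float
    tie_break_tag: str = "lexicographic-min-total-flux"


# ---------------------------------------------------------------------------
# canonicalization
# ---------------------------------------------------------------------------

_FWD_SUFFIX = "__fwd"
_BWD_SUFFIX = "__bwd"


def make_irreversible(net: MetabolicNetwork) -> MetabolicNetwork:
    """Return the canonical all-irreversible form of *net*.

    Every reaction with a negative lower bound is replaced by a forward copy
    (bounds ``[0, U]``) and a backward copy (negated column, bounds
    ``[0, -L]``); the pairing is recorded in ``split_map``.  A reaction
    flagged reversible whose lower bound is already nonnegative is passed
    through unchanged with a warning.  Strictly positive lower bounds are
    relaxed to zero in the canonical bounds and kept in
    ``ref_lower_bounds`` for the reference-LP stage only.
    """
    cols: list[np.ndarray] = []
    lowers: list[float] = []
    uppers: list[float] = []
    ref_lowers: list[float] = []
    ids: list[str] = []
    split_map: dict[str, tuple[str, str]] = {}

    for j, rid in enumerate(net.reaction_ids):
        lo = float(net.lower_bounds[j])
        up = float(net.upper_bounds[j])
        col = net.stoich[:, j]
        if lo < 0.0:
            fwd, bwd = rid + _FWD_SUFFIX, rid + _BWD_SUFFIX
            if fwd in net.reaction_ids or bwd in net.reaction_ids:
                raise ValidationError(f"split id collision for reaction {rid!r}")
            cols.append(col)
            ids.append(fwd)
            lowers.append(0.0)
            uppers.append(max(up, 0.0))
            ref_lowers.append(0.0)
            cols.append(-col)
            ids.append(bwd)
            lowers.append(0.0)
            uppers.append(-lo)
            ref_lowers.append(0.0)
            split_map[rid] = (fwd, bwd)
        else:
            if net.reversible_flags[j] and lo >= 0.0:
                warnings.warn(
                    f"reaction {rid!r} flagged reversible but has lower bound "
                    f"{lo} >= 0; treating as irreversible",
                    stacklevel=2,
                )
            cols.append(col)
            ids.append(rid)
            lowers.append(0.0)
            uppers.append(up)
            ref_lowers.append(lo)

    return MetabolicNetwork(
        stoich=np.column_stack(cols) if cols else np.zeros((net.n_metabolites, 0)),
        lower_bounds=np.array(lowers),
        upper_bounds=np.array(uppers),
        reversible_flags=np.zeros(len(ids), dtype=bool),
        reaction_ids=ids,
        metabolite_ids=list(net.metabolite_ids),
        biomass_id=net.biomass_id,
        split_map=split_map,
        ref_lower_bounds=np.array(ref_lowers),
    )


def canonical_ids_for(net: MetabolicNetwork, rid: str) -> list[str]:
    """Canonical reaction ids corresponding to an original id.

    For a split reversible reaction both halves are returned (a drug on the
    enzyme inhibits the catalyzed reaction in both directions).
    """
    if rid in net.split_map:
        return list(net.split_map[rid])
    if rid in net.reaction_ids:
        return [rid]
    raise ValidationError(f"unknown reaction id: {rid!r}")


# ---------------------------------------------------------------------------
# reference fluxes
# ---------------------------------------------------------------------------


def _solve_lp(c, A_ub=None, b_ub=None, A_eq=None, b_eq=None, bounds=None):
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
    if not res.success:
        raise SolverError(f"LP failed: {res.message}", status=res.status)
    return res


def fba_reference(net: MetabolicNetwork, objective_id: str | None = None) -> ReferenceFluxes:
    """Compute the unperturbed reference fluxes by two-stage FBA.

    Stage 1 maximizes the objective flux subject to steady state and bounds;
    stage 2 fixes the objective at its optimum and minimizes total flux,
    which removes degenerate-optimum dependence so the reference vector is
    reproducible.  Requires the canonical (all-irreversible) network.
    """
    if not net.is_canonical:
        raise ValidationError("fba_reference requires a canonical network; call make_irreversible first")
    if objective_id is None:
        objective_id = net.biomass_id
    if objective_id is None:
        raise ValidationError("no objective reaction: network has no biomass id and none was given")
    j_obj = net.reaction_index(objective_id)
    r = net.n_reactions

    lo = net.ref_lower_bounds if net.ref_lower_bounds is not None else net.lower_bounds
    bounds = list(zip(lo, net.upper_bounds))
    c1 = np.zeros(r)
    c1[j_obj] = -1.0
    res1 = _solve_lp(c1, A_eq=net.stoich, b_eq=np.zeros(net.n_metabolites), bounds=bounds)
    opt = -res1.fun

    # stage 2: pin the objective, minimize total flux
    c2 = np.ones(r)
    A_eq = np.vstack([net.stoich, np.zeros((1, r))])
    A_eq[-1, j_obj] = 1.0
    b_eq = np.concatenate([np.zeros(net.n_metabolites), [opt]])
    try:
        res2 = _solve_lp(c2, A_eq=A_eq, b_eq=b_eq, bounds=bounds)
    except SolverError:
        # numerical fallback: allow a feasibility-tolerance slack on the pin
        A_ub = np.zeros((1, r))
        A_ub[0, j_obj] = -1.0
        b_ub = np.array([-(opt - FEASIBILITY_TOL)])
        res2 = _solve_lp(
            c2, A_ub=A_ub, b_ub=b_ub, A_eq=net.stoich, b_eq=np.zeros(net.n_metabolites), bounds=bounds
        )
    v = np.asarray(res2.x, dtype=float)
    v[np.abs(v) < FEASIBILITY_TOL] = 0.0
    return ReferenceFluxes(v_ut=v, objective_value=float(opt))


# ---------------------------------------------------------------------------
# synthetic generator
# ---------------------------------------------------------------------------


def generate_synthetic(
    n_metabolites: int,
    n_reactions: int,
    n_drugs: int,
    targets_per_drug: int,
    seed: int,
    reversible_fraction: float = 0.25,
):
    """Generate a random feasible toy network plus a random drug catalog.

    The network is an uptake reaction feeding a chain through every
    metabolite into a biomass sink, plus random extra internal edges (some
    reversible), so the biomass optimum is always strictly positive.  Fully
    determined by *seed*.

    Returns ``(MetabolicNetwork, DrugCatalog)`` with the network in its
    original (possibly reversible) form.
    """
    from .inhibition import DrugCatalog  # local import to avoid a cycle

    if min(n_metabolites, n_reactions, n_drugs, targets_per_drug) < 1:
        raise ValidationError("all counts must be positive")
    base = n_metabolites + 1  # uptake + chain + biomass
    if n_reactions < base:
        raise ValidationError(
            f"need at least n_metabolites+1={base} reactions; got {n_reactions} "
            "(increase n_reactions)"
        )
    rng = np.random.default_rng(seed)
    mets = [f"M{i}" for i in range(n_metabolites)]
    m = n_metabolites

    cols: list[np.ndarray] = []
    ids: list[str] = []
    lowers: list[float] = []
    uppers: list[float] = []
    revs: list[bool] = []

    def add(rid, stoich_pairs, lo, up, rev):
        col = np.zeros(m)
        for idx, coef in stoich_pairs:
            col[idx] = coef
        cols.append(col)
        ids.append(rid)
        lowers.append(lo)
        uppers.append(up)
        revs.append(rev)

    add("uptake", [(0, 1.0)], 0.0, 10.0, False)
    for i in range(m - 1):
        u = float(np.round(rng.uniform(5.0, 15.0), 3))
        add(f"chain_{i}", [(i, -1.0), (i + 1, 1.0)], 0.0, u, False)
    add("biomass", [(m - 1, -1.0)], 0.0, 20.0, False)

    n_extra = n_reactions - len(ids)
    for e in range(n_extra):
        if m >= 2:
            i, j = sorted(rng.choice(m, size=2, replace=False).tolist())
        else:
            i, j = 0, 0
        u = float(np.round(rng.uniform(1.0, 10.0), 3))
        rev = bool(rng.random() < reversible_fraction) and i != j
        lo = -u if rev else 0.0
        pairs = [(i, -1.0), (j, 1.0)] if i != j else [(i, 0.0)]
        add(f"extra_{e}", pairs, lo, u, rev)

    net = MetabolicNetwork(
        stoich=np.column_stack(cols),
        lower_bounds=np.array(lowers),
        upper_bounds=np.array(uppers),
        reversible_flags=np.array(revs, dtype=bool),
        reaction_ids=ids,
        metabolite_ids=mets,
        biomass_id="biomass",
    )

    druggable = [rid for rid in ids if rid != "biomass"]
    k_targets = min(targets_per_drug, len(druggable))
    drug_ids = [f"drug_{k}" for k in range(n_drugs)]
    target_sets = {
        did: tuple(sorted(rng.choice(druggable, size=k_targets, replace=False).tolist()))
        for did in drug_ids
    }
    catalog = DrugCatalog(drug_ids=drug_ids, target_sets=target_sets)
    return net, catalog


# ---------------------------------------------------------------------------
# structured-model dialect
# ---------------------------------------------------------------------------


def _parse_structured(text: str, source: str) -> MetabolicNetwork:
    section = None
    mets: list[str] = []
    biomass: str | None = None
    rxn_rows: list[tuple[str, bool, float, float, dict[str, float]]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("[") and line.endswith("]"):
            section = line[1:-1].strip().lower()
            if section not in ("metabolites", "biomass", "reactions"):
                raise FormatError(f"{source}:{lineno}: unknown section {section!r}")
            continue
        if section == "metabolites":
            mets.append(line)
        elif section == "biomass":
            if biomass is not None:
                raise FormatError(f"{source}:{lineno}: duplicate biomass declaration")
            biomass = line
        elif section == "reactions":
            parts = line.split()
            if len(parts) < 5:
                raise FormatError(
                    f"{source}:{lineno}: reaction record needs "
                    f"'id rev lower upper met:coef ...', got {line!r}"
                )
            rid = parts[0]
            try:
                rev = bool(int(parts[1]))
                lo, up = float(parts[2]), float(parts[3])
            except ValueError as exc:
                raise FormatError(f"{source}:{lineno}: bad numeric field in {rid!r}: {exc}") from None
            coefs: dict[str, float] = {}
            for tok in parts[4:]:
                if ":" not in tok:
                    raise FormatError(f"{source}:{lineno}: expected met:coef, got {tok!r}")
                met, _, val = tok.rpartition(":")
                try:
                    coefs[met] = coefs.get(met, 0.0) + float(val)
                except ValueError:
                    raise FormatError(f"{source}:{lineno}: bad coefficient {tok!r}") from None
            rxn_rows.append((rid, rev, lo, up, coefs))
        else:
            raise FormatError(f"{source}:{lineno}: content outside any section: {line!r}")

    if not rxn_rows:
        raise FormatError(f"{source}: no reactions found")
    met_index = {mid: i for i, mid in enumerate(mets)}
    if len(met_index) != len(mets):
        dup = next(mid for i, mid in enumerate(mets) if mid in mets[:i])
        raise FormatError(f"{source}: duplicate metabolite id {dup!r}")
    S = np.zeros((len(mets), len(rxn_rows)))
    seen: set[str] = set()
    for j, (rid, rev, lo, up, coefs) in enumerate(rxn_rows):
        if rid in seen:
            raise FormatError(f"{source}: duplicate reaction id {rid!r}")
        seen.add(rid)
        for met, coef in coefs.items():
            if met not in met_index:
                raise FormatError(f"{source}: reaction {rid!r} references unknown metabolite {met!r}")
            S[met_index[met], j] = coef
    return MetabolicNetwork(
        stoich=S,
        lower_bounds=np.array([row[2] for row in rxn_rows]),
        upper_bounds=np.array([row[3] for row in rxn_rows]),
        reversible_flags=np.array([row[1] for row in rxn_rows], dtype=bool),
        reaction_ids=[row[0] for row in rxn_rows],
        metabolite_ids=mets,
        biomass_id=biomass,
    )


def _format_number(x: float) -> str:
    return repr(float(x))


def _write_structured(net: MetabolicNetwork) -> str:
    buf = io.StringIO()
    buf.write("# structured-model\n[metabolites]\n")
    for mid in net.metabolite_ids:
        buf.write(mid + "\n")
    if net.biomass_id is not None:
        buf.write("[biomass]\n" + net.biomass_id + "\n")
    buf.write("[reactions]\n")
    for j, rid in enumerate(net.reaction_ids):
        pairs = [
            f"{net.metabolite_ids[i]}:{_format_number(net.stoich[i, j])}"
            for i in range(net.n_metabolites)
            if net.stoich[i, j] != 0.0
        ]
        buf.write(
            "\t".join(
                [
                    rid,
                    str(int(net.reversible_flags[j])),
                    _format_number(net.lower_bounds[j]),
                    _format_number(net.upper_bounds[j]),
                ]
                + pairs
            )
            + "\n"
        )
    return buf.getvalue()


# ---------------------------------------------------------------------------
# tsv-triplet dialect
# ---------------------------------------------------------------------------

_TRIPLET_SUFFIX = ".stoich.tsv"
_BOUNDS_SUFFIX = ".bounds.tsv"


def _triplet_paths(path: str) -> tuple[str, str]:
    if path.endswith(_TRIPLET_SUFFIX):
        base = path[: -len(_TRIPLET_SUFFIX)]
    elif path.endswith(_BOUNDS_SUFFIX):
        base = path[: -len(_BOUNDS_SUFFIX)]
    else:
        base = path
    return base + _TRIPLET_SUFFIX, base + _BOUNDS_SUFFIX


def _load_tsv_triplet(path: str) -> MetabolicNetwork:
    import pandas as pd

    stoich_path, bounds_path = _triplet_paths(path)
    try:
        trip = pd.read_csv(stoich_path, sep="\t", dtype={"metabolite": str, "reaction": str})
        bnd = pd.read_csv(bounds_path, sep="\t", dtype={"reaction": str})
    except (FileNotFoundError, ValueError) as exc:
        raise FormatError(f"tsv-triplet load failed: {exc}") from exc
    for col in ("metabolite", "reaction", "coefficient"):
        if col not in trip.columns:
            raise FormatError(f"{stoich_path}: missing column {col!r}")
    for col in ("reaction", "reversible", "lower", "upper"):
        if col not in bnd.columns:
            raise FormatError(f"{bounds_path}: missing column {col!r}")
    if bnd["reaction"].duplicated().any():
        dup = bnd.loc[bnd["reaction"].duplicated(), "reaction"].iloc[0]
        raise FormatError(f"{bounds_path}: duplicate reaction id {dup!r}")
    rids = bnd["reaction"].tolist()
    mids = sorted(trip["metabolite"].unique().tolist())
    met_index = {mid: i for i, mid in enumerate(mids)}
    rxn_index = {rid: j for j, rid in enumerate(rids)}
    S = np.zeros((len(mids), len(rids)))
    for rec in trip.itertuples(index=False):
        if rec.reaction not in rxn_index:
            raise FormatError(f"{stoich_path}: reaction {rec.reaction!r} missing from bounds table")
        S[met_index[rec.metabolite], rxn_index[rec.reaction]] = float(rec.coefficient)
    biomass = None
    if "biomass" in bnd.columns:
        flagged = bnd.loc[bnd["biomass"].astype(int) == 1, "reaction"].tolist()
        if len(flagged) > 1:
            raise FormatError(f"{bounds_path}: more than one biomass reaction flagged")
        biomass = flagged[0] if flagged else None
    return MetabolicNetwork(
        stoich=S,
        lower_bounds=bnd["lower"].to_numpy(dtype=float),
        upper_bounds=bnd["upper"].to_numpy(dtype=float),
        reversible_flags=bnd["reversible"].to_numpy(dtype=int).astype(bool),
        reaction_ids=rids,
        metabolite_ids=mids,
        biomass_id=biomass,
    )


def _write_tsv_triplet(net: MetabolicNetwork, path: str) -> None:
    stoich_path, bounds_path = _triplet_paths(path)
    with open(stoich_path, "w") as fh:
        fh.write("metabolite\treaction\tcoefficient\n")
        for j, rid in enumerate(net.reaction_ids):
            for i, mid in enumerate(net.metabolite_ids):
                if net.stoich[i, j] != 0.0:
                    fh.write(f"{mid}\t{rid}\t{_format_number(net.stoich[i, j])}\n")
    with open(bounds_path, "w") as fh:
        fh.write("reaction\treversible\tlower\tupper\tbiomass\n")
        for j, rid in enumerate(net.reaction_ids):
            fh.write(
                f"{rid}\t{int(net.reversible_flags[j])}\t"
                f"{_format_number(net.lower_bounds[j])}\t"
                f"{_format_number(net.upper_bounds[j])}\t"
                f"{int(rid == net.biomass_id)}\n"
            )


# ---------------------------------------------------------------------------
# sbml dialect (optional)
# ---------------------------------------------------------------------------


def _load_sbml(path: str, biomass_id: str | None) -> MetabolicNetwork:
    try:
        import cobra.io
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise FormatError("SBML support requires the optional 'cobra' dependency") from exc
    try:
        model = cobra.io.read_sbml_model(path)
    except Exception as exc:
        raise FormatError(f"SBML parse failed for {path}: {exc}") from exc
    mets = [m.id for m in model.metabolites]
    met_index = {mid: i for i, mid in enumerate(mets)}
    rids = [r.id for r in model.reactions]
    S = np.zeros((len(mets), len(rids)))
    lowers, uppers, revs = [], [], []
    for j, rxn in enumerate(model.reactions):
        for met, coef in rxn.metabolites.items():
            S[met_index[met.id], j] = float(coef)
        lowers.append(float(rxn.lower_bound))
        uppers.append(float(rxn.upper_bound))
        revs.append(rxn.lower_bound < 0)
    if biomass_id is None:
        objective = [r.id for r in model.reactions if r.objective_coefficient]
        biomass_id = objective[0] if objective else None
    return MetabolicNetwork(
        stoich=S,
        lower_bounds=np.array(lowers),
        upper_bounds=np.array(uppers),
        reversible_flags=np.array(revs, dtype=bool),
        reaction_ids=rids,
        metabolite_ids=mets,
        biomass_id=biomass_id,
    )


# ---------------------------------------------------------------------------
# public load/write entry points
# ---------------------------------------------------------------------------

FORMATS = ("structured-model", "tsv-triplet", "sbml")


def load_network(path: str, format: str = "structured-model", biomass_id: str | None = None) -> MetabolicNetwork:
    """Load a model file in one of the supported dialects.

    ``biomass_id`` overrides (or supplies, where the dialect cannot express
    it) the biomass reaction id.
    """
    if format not in FORMATS:
        raise FormatError(f"unknown model format {format!r}; expected one of {FORMATS}")
    if format == "structured-model":
        with open(path) as fh:
            net = _parse_structured(fh.read(), source=str(path))
    elif format == "tsv-triplet":
        net = _load_tsv_triplet(str(path))
    else:
        net = _load_sbml(str(path), biomass_id)
    if biomass_id is not None:
        if biomass_id not in net.reaction_ids:
            raise ValidationError(f"biomass id {biomass_id!r} not among reactions")
        net = replace(net, biomass_id=biomass_id)
    return net


def write_network(net: MetabolicNetwork, path: str, format: str = "structured-model") -> None:
    """Write *net* in a text dialect; output is byte-stable for fixed input."""
    if format == "structured-model":
        with open(path, "w") as fh:
            fh.write(_write_structured(net))
    elif format == "tsv-triplet":
        _write_tsv_triplet(net, str(path))
    else:
        raise FormatError(f"unsupported write format {format!r}")


def parse_structured_model(text: str, source: str = "<string>") -> MetabolicNetwork:
    """Parse the structured-model dialect from a string (mostly for tests)."""
    return _parse_structured(text, source)
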