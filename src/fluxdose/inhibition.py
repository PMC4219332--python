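"""Drug catalogs and partial-inhibition encodings.

A drug ``k`` with inhibition level ``h_k`` tightens the upper bound of each
of its target reactions ``i`` to ``U_i * (1 - h_k)``.  Inhibition levels are
not continuous decision variables: they are decoded from Boolean dosage
variables under one of two schemes,

``binary-expansion``
    ``h = x_0 / 2**P + sum_n x_n / 2**n`` on the grid ``{m / 2**P}``;
    ``P = 0`` reduces to a plain ON/OFF switch.
``dose-response``
    prefix-of-ones chains whose achievable values are exactly
    ``{0} | levels | {1}`` for experimentally measured levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError, ValidationError
from .netio import MetabolicNetwork, canonical_ids_for

SCHEMES = ("binary-expansion", "dose-response")


@dataclass
class DrugCatalog:
    """A set of drugs with target reactions and optional dose-response levels.

    ``target_sets`` maps drug id to a tuple of reaction ids, interpreted in
    the network the catalog is applied to; a drug targeting a reversible
    reaction that was split targets both canonical halves.  ``dose_levels``
    optionally maps drug id to a strictly increasing tuple of levels in
    (0, 1).
    """

    drug_ids: list[str]
    target_sets: dict[str, tuple[str, ...]]
    dose_levels: dict[str, tuple[float, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.drug_ids)) != len(self.drug_ids):
            dup = next(d for i, d in enumerate(self.drug_ids) if d in self.drug_ids[:i])
            raise ValidationError(f"duplicate drug id {dup!r}")
        for did in self.drug_ids:
            if did not in self.target_sets or not self.target_sets[did]:
                raise ValidationError(f"drug {did!r} has no target set")
            self.target_sets[did] = tuple(self.target_sets[did])
        for did, levels in self.dose_levels.items():
            arr = tuple(float(x) for x in levels)
            if any(not (0.0 < x < 1.0) for x in arr):
                raise ValidationError(f"dose levels for {did!r} must lie strictly inside (0,1)")
            if any(a >= b for a, b in zip(arr, arr[1:])):
                raise ValidationError(f"dose levels for {did!r} must be strictly increasing")
            self.dose_levels[did] = arr

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    def validate_against(self, net: MetabolicNetwork) -> None:
        """Check that every target id resolves in *net* (or its split map)."""
        for did in self.drug_ids:
            for rid in self.target_sets[did]:
                canonical_ids_for(net, rid)

    def resolve_targets(self, net: MetabolicNetwork) -> dict[str, list[int]]:
        """Per-drug canonical column indices of the targets in *net*."""
        out: dict[str, list[int]] = {}
        for did in self.drug_ids:
            idx: list[int] = []
            for rid in self.target_sets[did]:
                for cid in canonical_ids_for(net, rid):
                    j = net.reaction_index(cid)
                    if j not in idx:
                        idx.append(j)
            out[did] = idx
        return out


# ---------------------------------------------------------------------------
# encodings
# ---------------------------------------------------------------------------


def _binary_weights(precision: int) -> np.ndarray:
    # coefficient of x_0 duplicates the finest bit so that all-ones decodes
    # exactly to 1 (convex combination)
    if precision < 0:
        raise ValidationError("precision must be >= 0")
    if precision == 0:
        return np.array([1.0])
    w = np.empty(precision + 1)
    w[0] = 2.0**-precision
    for n in range(1, precision + 1):
        w[n] = 2.0**-n
    return w


def _dose_increments(levels: tuple[float, ...]) -> np.ndarray:
    # increments of the prefix-of-ones chain: 0 -> l1 -> ... -> lP -> 1
    ext = (0.0, *levels, 1.0)
    return np.diff(np.asarray(ext))


@dataclass
class InhibitionEncoding:
    """Boolean dosage layout for a whole catalog.

    ``weights[k]`` are the decoding coefficients of drug *k*'s Boolean
    vector; under binary expansion every drug has ``precision + 1``
    Booleans, under dose-response a drug with measured levels gets
    ``len(levels) + 1`` (drugs without levels fall back to binary
    expansion).
    """

    precision: int
    scheme: str
    drug_ids: list[str]
    weights: dict[str, np.ndarray]
    chains: dict[str, bool]  # True -> prefix-of-ones chain applies

    @classmethod
    def for_catalog(cls, catalog: DrugCatalog, precision: int, scheme: str = "binary-expansion"):
        if scheme not in SCHEMES:
            raise ValidationError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
        weights: dict[str, np.ndarray] = {}
        chains: dict[str, bool] = {}
        for did in catalog.drug_ids:
            if scheme == "dose-response" and did in catalog.dose_levels:
                weights[did] = _dose_increments(catalog.dose_levels[did])
                chains[did] = True
            else:
                # drugs without measured levels fall back to binary expansion
                weights[did] = _binary_weights(precision)
                chains[did] = False
        return cls(
            precision=precision,
            scheme=scheme,
            drug_ids=list(catalog.drug_ids),
            weights=weights,
            chains=chains,
        )

    def n_booleans(self, drug_id: str) -> int:
        return len(self.weights[drug_id])

    @property
    def total_booleans(self) -> int:
        return sum(self.n_booleans(d) for d in self.drug_ids)

    def uses_chain(self, drug_id: str) -> bool:
        """True when the drug's Booleans carry the prefix-of-ones chain rule."""
        return self.chains[drug_id]

    def decode(self, drug_id: str, booleans) -> float:
        if self.chains[drug_id]:
            return _decode_with_increments(booleans, self.weights[drug_id])
        return decode_binary(booleans, self.precision)

    def achievable_levels(self, drug_id: str) -> np.ndarray:
        """Sorted array of inhibition values this drug can take."""
        if self.chains[drug_id]:
            return np.concatenate([[0.0], np.cumsum(self.weights[drug_id])])
        return np.arange(2**self.precision + 1) / 2.0**self.precision


def _check_boolean_vector(booleans) -> np.ndarray:
    arr = np.asarray(booleans, dtype=float)
    if arr.ndim != 1:
        raise ValidationError("Boolean vector must be one-dimensional")
    if not np.all((arr == 0.0) | (arr == 1.0)):
        raise ValidationError(f"non-Boolean entry in dosage vector: {booleans!r}")
    return arr


def decode_binary(booleans, precision: int) -> float:
    """Decode a binary-expansion dosage vector into an inhibition fraction.

    ``h = x_0 / 2**P + sum_{n=1..P} x_n / 2**n``; the vector must have
    ``P + 1`` entries.  The result lies on the grid ``{m / 2**P}``.
    """
    arr = _check_boolean_vector(booleans)
    if len(arr) != precision + 1:
        raise ValidationError(f"expected {precision + 1} Booleans for precision {precision}, got {len(arr)}")
    return float(np.dot(_binary_weights(precision), arr))


def _decode_with_increments(booleans, increments: np.ndarray) -> float:
    arr = _check_boolean_vector(booleans)
    if len(arr) != len(increments):
        raise ValidationError(f"expected {len(increments)} Booleans, got {len(arr)}")
    for j in range(len(arr) - 1):
        if arr[j + 1] > arr[j]:
            raise ValidationError(
                f"dose-response chain violated: x[{j + 1}]={int(arr[j + 1])} > x[{j}]={int(arr[j])}"
            )
    return float(np.dot(increments, arr))


def decode_dose_response(booleans, levels) -> float:
    """Decode a prefix-of-ones dosage chain against measured levels.

    The ``len(levels) + 1`` Booleans must satisfy ``x[j+1] <= x[j]``; a
    prefix of ``j`` ones decodes to the ``j``-th measured level, all ones to
    1, so the achievable set is exactly ``{0} | levels | {1}``.
    """
    levels = tuple(float(x) for x in levels)
    return _decode_with_increments(booleans, _dose_increments(levels))


# ---------------------------------------------------------------------------
# applying a treatment
# ---------------------------------------------------------------------------


def apply_inhibition(net: MetabolicNetwork, catalog: DrugCatalog, h) -> np.ndarray:
    """Upper-bound vector of the restricted flux set ``W(h)``.

    Emits one tightened bound per (drug, target) pair,
    ``v_i <= U_i * (1 - h_k)``; taking the componentwise minimum over pairs
    realizes the max-over-drugs rule for shared targets.
    """
    h = np.asarray(h, dtype=float)
    if h.shape != (catalog.n_drugs,):
        raise ValidationError(f"expected {catalog.n_drugs} inhibition levels, got shape {h.shape}")
    if np.any((h < 0.0) | (h > 1.0)):
        raise ValidationError(f"inhibition levels must lie in [0,1]: {h}")
    upper = net.upper_bounds.copy()
    targets = catalog.resolve_targets(net)
    for k, did in enumerate(catalog.drug_ids):
        for j in targets[did]:
            upper[j] = min(upper[j], net.upper_bounds[j] * (1.0 - h[k]))
    return upper


# ---------------------------------------------------------------------------
# catalog file format
# ---------------------------------------------------------------------------

CATALOG_SCHEMA = """\
# drug-catalog dialect (one drug per line)
#
#   <drug-id> targets=<rid>[,<rid>...] [levels=<f>[,<f>...]]
#
# Lines starting with '#' and blank lines are ignored.
"""


def load_catalog(path: str) -> DrugCatalog:
    """Parse a drug catalog text file (see :data:`CATALOG_SCHEMA`)."""
    drug_ids: list[str] = []
    target_sets: dict[str, tuple[str, ...]] = {}
    dose_levels: dict[str, tuple[float, ...]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            did = parts[0]
            if did in target_sets:
                raise FormatError(f"{path}:{lineno}: duplicate drug id {did!r}")
            fields = {}
            for tok in parts[1:]:
                if "=" not in tok:
                    raise FormatError(f"{path}:{lineno}: expected key=value, got {tok!r}")
                key, _, val = tok.partition("=")
                fields[key] = val
            if "targets" not in fields:
                raise FormatError(f"{path}:{lineno}: drug {did!r} missing targets=")
            drug_ids.append(did)
            target_sets[did] = tuple(t for t in fields["targets"].split(",") if t)
            if "levels" in fields:
                try:
                    dose_levels[did] = tuple(float(x) for x in fields["levels"].split(",") if x)
                except ValueError:
                    raise FormatError(f"{path}:{lineno}: bad levels for {did!r}") from None
    if not drug_ids:
        raise FormatError(f"{path}: no drugs found")
    return DrugCatalog(drug_ids=drug_ids, target_sets=target_sets, dose_levels=dose_levels)


def write_catalog(catalog: DrugCatalog, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# drug-catalog\n")
        for did in catalog.drug_ids:
            line = f"{did}\ttargets=" + ",".join(catalog.target_sets[did])
            if did in catalog.dose_levels:
                line += "\tlevels=" + ",".join(repr(x) for x in catalog.dose_levels[did])
            fh.write(line + "\n")
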