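"""Curated hand-checkable worked-example instances.

Each fixture bundles a tiny network and drug catalog (stored as data files
in the structured-model / drug-catalog dialects, so they double as format
documentation) together with certified expected values.  Certification
re-runs the exhaustive oracle; any drift fails loudly.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .errors import ValidationError
from .inhibition import DrugCatalog, load_catalog
from .netio import MetabolicNetwork, ReferenceFluxes, fba_reference, load_network, make_irreversible


@dataclass
class ExpectedCase:
    """One certified optimum: run parameters plus the oracle-verified answer."""

    precision: int
    tau: float
    mode: str
    h: dict[str, float]
    side_effect: float
    note: str


@dataclass
class FixtureInstance:
    name: str
    network: MetabolicNetwork  # canonical form
    catalog: DrugCatalog
    reference: ReferenceFluxes
    mod_id: str
    expected: list[ExpectedCase]


# name -> (mod_id, expected cases)
# side effects certified by running the exhaustive oracle on the data files;
# hand derivations in each note.
_REGISTRY: dict[str, tuple[str, list[ExpectedCase]]] = {
    "chain": (
        "consume",
        [
            ExpectedCase(
                precision=1,
                tau=0.5,
                mode="inhibit",
                h={"d1": 0.5},
                side_effect=10.0,
                note="uptake bound 10 -> 5 halves both fluxes: |5-10|+|5-10| = 10",
            ),
            ExpectedCase(
                precision=0,
                tau=0.5,
                mode="inhibit",
                h={"d1": 1.0},
                side_effect=20.0,
                note="ON/OFF can only shut uptake entirely: |0-10|+|0-10| = 20",
            ),
        ],
    ),
    "diamond": (
        "direct",
        [
            ExpectedCase(
                precision=1,
                tau=0.5,
                mode="inhibit",
                h={"d1": 0.5},
                side_effect=6.3,
                note=(
                    "direct bound 6 -> 3; adjustment reroutes 3 units through the "
                    "leaky path: |3-6| + |7-4| + |9.3-9.6| = 6.3"
                ),
            ),
        ],
    ),
    "superfluous": (
        "consume",
        [
            ExpectedCase(
                precision=1,
                tau=0.5,
                mode="inhibit",
                h={"narrow": 0.0, "broad": 0.5},
                side_effect=10.0,
                note=(
                    "broad at 0.5 caps uptake at 5; narrow alone cannot reach the "
                    "threshold below full dose, and adding it to broad is penalized "
                    "by the overselection term, so it returns with zero dosage"
                ),
            ),
        ],
    ),
    "activation": (
        "alt",
        [
            ExpectedCase(
                precision=1,
                tau=2.0,
                mode="activate",
                h={"d1": 0.5},
                side_effect=7.0,
                note=(
                    "main bound 7 -> 3.5 reroutes 3.5 units of A through alt "
                    "(alt: 1.5 -> 3.25 >= 2*1.5): |3.5-7| + |3.25-1.5| + |6.75-8.5| = 7"
                ),
            ),
        ],
    ),
}


def fixture_names() -> list[str]:
    return sorted(_REGISTRY)


def _data_path(filename: str):
    return resources.files("fluxdose").joinpath("data", "fixtures", filename)


def fixture(name: str) -> FixtureInstance:
    """Load a registered fixture (canonical network + reference fluxes)."""
    if name not in _REGISTRY:
        raise ValidationError(f"unknown fixture {name!r}; registry: {fixture_names()}")
    mod_id, expected = _REGISTRY[name]
    with resources.as_file(_data_path(f"{name}.model")) as p:
        net = load_network(str(p), "structured-model")
    with resources.as_file(_data_path(f"{name}.drugs")) as p:
        catalog = load_catalog(str(p))
    canon = make_irreversible(net)
    ref = fba_reference(canon)
    catalog.validate_against(canon)
    return FixtureInstance(
        name=name,
        network=canon,
        catalog=catalog,
        reference=ref,
        mod_id=mod_id,
        expected=list(expected),
    )


def certify(inst: FixtureInstance, tol: float = 1e-6) -> None:
    """Re-derive every expected value with the exhaustive oracle.

    Raises :class:`ValidationError` on any drift between the registry and
    the oracle's answer.
    """
    from .analysis import exhaustive_oracle

    for case in inst.expected:
        sol = exhaustive_oracle(
            inst.network,
            inst.reference,
            inst.catalog,
            inst.mod_id,
            case.tau,
            mode=case.mode,
            precision=case.precision,
        )
        if sol.status != "optimal":
            raise ValidationError(
                f"fixture {inst.name!r} case {case.tau}/{case.precision}: oracle found no solution"
            )
        if abs(sol.side_effect - case.side_effect) > tol:
            raise ValidationError(
                f"fixture {inst.name!r} drifted: expected side effect {case.side_effect}, "
                f"oracle found {sol.side_effect}"
            )
        got_h = dict(zip(inst.catalog.drug_ids, sol.h))
        for did, expected_h in case.h.items():
            if abs(got_h[did] - expected_h) > tol:
                raise ValidationError(
                    f"fixture {inst.name!r} drifted: expected h[{did}]={expected_h}, "
                    f"oracle found {got_h[did]}"
                )
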