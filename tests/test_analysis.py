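import numpy as np
import pytest

import fluxdose as fd
import fluxdose.analysis as analysis
from fluxdose.analysis import eta_for_treatment
from fluxdose.netio import parse_structured_model

from conftest import make_synthetic_case


class TestExhaustiveOracle:
    def test_evaluation_count_d2_p1(self, superfluous, monkeypatch):
        calls = {"n": 0}
        real = analysis.moma_l1

        def counting(*args, **kwargs):
            calls["n"] += 1
            return real(*args, **kwargs)

        monkeypatch.setattr(analysis, "moma_l1", counting)
        fd.exhaustive_oracle(
            superfluous.network, superfluous.reference, superfluous.catalog,
            "consume", 0.5, precision=1,
        )
        # one inner solve per grid point, plus one re-solve for the winner
        assert calls["n"] == (2**1 + 1) ** 2 + 1

    def test_matches_bilevel_on_chain(self, chain):
        o = fd.exhaustive_oracle(chain.network, chain.reference, chain.catalog, "consume", 0.5, precision=1)
        s = fd.solve_bilevel(chain.network, chain.reference, chain.catalog, "consume", 0.5, precision=1)
        assert o.objective == pytest.approx(s.objective, rel=1e-6)

    def test_tau_zero_requires_full_dose(self, chain):
        sol = fd.exhaustive_oracle(chain.network, chain.reference, chain.catalog, "consume", 0.0, precision=1)
        assert sol.h[0] == pytest.approx(1.0)

    def test_cap_exceeded(self, chain):
        with pytest.raises(fd.ValidationError, match="cap"):
            fd.exhaustive_oracle(
                chain.network, chain.reference, chain.catalog, "consume", 0.5,
                precision=10, cap=100,
            )

    def test_infeasible_marker(self):
        text = """
        [metabolites]
        A
        B
        [biomass]
        consume
        [reactions]
        uptake 0 0 10 A:1
        consume 0 0 20 A:-1
        side_in 0 0 5 B:1
        side_out 0 0 5 B:-1
        """
        net = fd.make_irreversible(parse_structured_model(text))
        ref = fd.fba_reference(net)
        cat = fd.DrugCatalog(drug_ids=["d"], target_sets={"d": ("side_in",)})
        sol = fd.exhaustive_oracle(net, ref, cat, "consume", 0.1, precision=1)
        assert sol.status == "infeasible"


class TestNonlinearityIndex:
    def test_single_drug_is_linear(self):
        assert fd.nonlinearity_index(10.0, [7.0], 7.0) == pytest.approx(0.0)

    def test_worked_example(self):
        assert fd.nonlinearity_index(10.0, [8.0, 7.0], 2.0) == pytest.approx(0.375)

    def test_exact_superposition_is_zero(self):
        combined = 8.0 + 6.0 - (2 - 1) * 10.0
        assert fd.nonlinearity_index(10.0, [8.0, 6.0], combined) == pytest.approx(0.0)

    def test_zero_denominator_undefined(self):
        assert fd.nonlinearity_index(10.0, [10.0, 10.0], 10.0) is None

    def test_inactive_components_do_not_change_eta(self):
        with_zero = fd.nonlinearity_index(10.0, [8.0, 6.0, 10.0], 3.0)
        without = fd.nonlinearity_index(10.0, [8.0, 6.0], 3.0)
        assert with_zero == pytest.approx(without)


@pytest.fixture(scope="module")
def two_drug_chain():
    text = """
    [metabolites]
    A
    [biomass]
    consume
    [reactions]
    uptake 0 0 10 A:1
    consume 0 0 20 A:-1
    """
    net = fd.make_irreversible(parse_structured_model(text))
    ref = fd.fba_reference(net)
    cat = fd.DrugCatalog(
        drug_ids=["a", "b"], target_sets={"a": ("uptake",), "b": ("uptake",)}
    )
    return net, ref, cat


class TestInteractionSurface:
    def test_corner_and_shape(self, two_drug_chain):
        net, ref, cat = two_drug_chain
        surf = fd.interaction_surface(net, ref, cat, "consume", "a", "b", precision=4)
        assert surf.flux_pct.shape == (17, 17)
        assert surf.flux_pct[0, 0] == pytest.approx(100.0)
        assert np.isnan(surf.eta_matrix[0, 0])

    def test_shared_target_depends_on_max(self, two_drug_chain):
        net, ref, cat = two_drug_chain
        surf = fd.interaction_surface(net, ref, cat, "consume", "a", "b", precision=2)
        for ia, ha in enumerate(surf.grid_a):
            for ib, hb in enumerate(surf.grid_b):
                expected = 100.0 * (1.0 - max(ha, hb))
                assert surf.flux_pct[ia, ib] == pytest.approx(expected, abs=1e-6)

    def test_eta_matches_pointwise_index(self, diamond):
        cat = fd.DrugCatalog(
            drug_ids=["d1", "d2"], target_sets={"d1": ("direct",), "d2": ("uptake",)}
        )
        surf = fd.interaction_surface(
            diamond.network, diamond.reference, cat, "consume", "d1", "d2", precision=1
        )
        for ia, ha in enumerate(surf.grid_a):
            for ib, hb in enumerate(surf.grid_b):
                direct = eta_for_treatment(
                    diamond.network, diamond.reference, cat, "consume", [ha, hb]
                )
                if direct is None:
                    assert np.isnan(surf.eta_matrix[ia, ib])
                else:
                    assert surf.eta_matrix[ia, ib] == pytest.approx(direct, abs=1e-6)

    def test_same_drug_twice_rejected(self, two_drug_chain):
        net, ref, cat = two_drug_chain
        with pytest.raises(fd.ValidationError, match="distinct"):
            fd.interaction_surface(net, ref, cat, "consume", "a", "a")

    def test_unknown_drug_rejected(self, two_drug_chain):
        net, ref, cat = two_drug_chain
        with pytest.raises(fd.ValidationError, match="'zzz'"):
            fd.interaction_surface(net, ref, cat, "consume", "a", "zzz")

    def test_l2_surface_smoke(self, two_drug_chain):
        net, ref, cat = two_drug_chain
        surf = fd.interaction_surface(net, ref, cat, "consume", "a", "b", precision=1, norm="L2")
        assert surf.norm_tag == "L2"
        assert surf.flux_pct[0, 0] == pytest.approx(100.0, abs=1e-4)


class TestScreening:
    def test_dedup_inhibition_keeps_most_stringent(self, chain):
        records = fd.screen_reactions(
            chain.network, chain.reference, chain.catalog, [0.1, 0.5],
            precision=0, mod_ids=["consume"],
        )
        # ON/OFF finds h=1 at both thresholds; only tau=0.1 survives
        by_tau = {r.tau: r for r in records if r.status == "optimal"}
        assert by_tau[0.1].kept and not by_tau[0.5].kept

    def test_dedup_activation_keeps_most_stringent(self, activation):
        records = fd.screen_reactions(
            activation.network, activation.reference, activation.catalog, [1.5, 2.0],
            precision=1, mod_ids=["alt"],
        )
        by_tau = {r.tau: r for r in records if r.status == "optimal"}
        assert by_tau[2.0].kept and not by_tau[1.5].kept

    def test_zero_flux_reactions_skipped(self):
        text = """
        [metabolites]
        A
        B
        [biomass]
        consume
        [reactions]
        uptake 0 0 10 A:1
        consume 0 0 20 A:-1
        dead 0 0 5 A:-1 B:1
        dead_out 0 0 0 B:-1
        """
        net = fd.make_irreversible(parse_structured_model(text))
        ref = fd.fba_reference(net)
        cat = fd.DrugCatalog(drug_ids=["d"], target_sets={"d": ("uptake",)})
        records = fd.screen_reactions(net, ref, cat, [0.5], precision=0)
        dead = [r for r in records if r.mod_id in ("dead", "dead_out")]
        assert dead and all(r.status == "skipped-zero-flux" for r in dead)

    def test_failures_recorded_not_raised(self):
        text = """
        [metabolites]
        A
        B
        [biomass]
        consume
        [reactions]
        uptake 0 0 10 A:1
        consume 0 0 20 A:-1
        side_in 0 0 5 B:1
        side_out 0 0 5 B:-1
        """
        net = fd.make_irreversible(parse_structured_model(text))
        ref = fd.fba_reference(net)
        cat = fd.DrugCatalog(drug_ids=["d"], target_sets={"d": ("side_in",)})
        records = fd.screen_reactions(net, ref, cat, [0.1], precision=0, mod_ids=["consume"])
        assert records[0].status == "infeasible"

    def test_feasible_count_monotone_in_precision(self):
        net, ref, cat = make_synthetic_case(17, 5, 10, 3, 2)
        counts = {}
        for precision in (0, 1):
            records = fd.screen_reactions(
                net, ref, cat, [0.5], precision=precision, compute_eta=False
            )
            counts[precision] = sum(1 for r in records if r.status == "optimal")
        assert counts[1] >= counts[0]

    def test_empty_tau_list_rejected(self, chain):
        with pytest.raises(fd.ValidationError, match="tau_list"):
            fd.screen_reactions(chain.network, chain.reference, chain.catalog, [])

    def test_tau_one_rejected(self, chain):
        with pytest.raises(fd.ValidationError, match="neither"):
            fd.screen_reactions(chain.network, chain.reference, chain.catalog, [1.0])

    def test_summary_tables(self, chain):
        records = fd.screen_reactions(
            chain.network, chain.reference, chain.catalog, [0.5], precision=1
        )
        tables = fd.screening_summary(records)
        assert set(tables) == {"counts", "cardinality", "side_effect", "eta"}
        assert tables["counts"]["n_solutions"].sum() == sum(
            1 for r in records if r.status == "optimal" and r.kept
        )


class TestOracleEquivalenceSample:
    @pytest.mark.parametrize("seed", [3, 7, 11, 19, 23])
    def test_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        net, ref, cat = make_synthetic_case(seed, 4, int(rng.integers(6, 9)), 2, 2)
        precision = int(rng.integers(0, 3))
        tau = float(rng.choice([0.0, 0.3, 0.5]))
        oracle = fd.exhaustive_oracle(net, ref, cat, "biomass", tau, precision=precision)
        if oracle.status == "infeasible":
            with pytest.raises(fd.InfeasibleTreatmentError):
                fd.solve_bilevel(net, ref, cat, "biomass", tau, precision=precision)
        else:
            sol = fd.solve_bilevel(net, ref, cat, "biomass", tau, precision=precision)
            assert sol.objective == pytest.approx(oracle.objective, rel=1e-6, abs=1e-6)
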