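import numpy as np
import pytest

import fluxdose as fd
from fluxdose.bilevel import (
    VariableLayout,
    build_bilevel_model,
    build_dual_block,
    build_duality_coupling,
    build_encoding_block,
    build_primal_block,
)
from fluxdose.inhibition import InhibitionEncoding
from fluxdose.netio import parse_structured_model

from conftest import make_synthetic_case, random_grid_h


def layout_for(inst, precision=1, scheme="binary-expansion"):
    enc = InhibitionEncoding.for_catalog(inst.catalog, precision, scheme)
    return VariableLayout(inst.network, inst.catalog, enc)


class TestBlockShapes:
    def test_primal_row_count(self, superfluous):
        lay = layout_for(superfluous, precision=2)
        m, r = superfluous.network.n_metabolites, superfluous.network.n_reactions
        t = lay.n_pairs
        assert t == 3  # narrow: 1 target, broad: 2 targets
        block = build_primal_block(lay, superfluous.reference)
        assert len(block) == m + r + t + 2 * r

    def test_dual_row_count(self, superfluous):
        lay = layout_for(superfluous)
        assert len(build_dual_block(lay)) == 2 * superfluous.network.n_reactions

    def test_z_variable_count(self, superfluous):
        for precision in (0, 1, 3):
            lay = layout_for(superfluous, precision)
            assert lay.n_products == lay.n_pairs * (precision + 1)

    def test_p0_inhibition_rows_have_single_boolean(self, chain):
        lay = layout_for(chain, precision=0)
        block = build_primal_block(lay, chain.reference)
        inhib_rows = [row for row in block.rows if row[0].startswith("inhib_")]
        assert len(inhib_rows) == 1
        _, coefs, _, _ = inhib_rows[0]
        x_cols = [c for c in coefs if c >= lay.off_x]
        assert len(x_cols) == 1

    def test_untargeted_reaction_dual_row_has_no_delta(self, chain):
        lay = layout_for(chain)
        block = build_dual_block(lay)
        j = chain.network.reaction_index("consume")  # drug targets uptake only
        name, coefs, _, _ = block.rows[j]
        assert name == "dual_v_consume"
        delta_cols = [c for c in coefs if lay.off_delta <= c < lay.off_alpha]
        assert delta_cols == []

    def test_eight_drugs_p5_gives_48_booleans(self):
        net, _ = fd.generate_synthetic(5, 12, 8, 2, seed=5)
        canon = fd.make_irreversible(net)
        ref = fd.fba_reference(canon)
        _, catalog = fd.generate_synthetic(5, 12, 8, 2, seed=5)
        model = build_bilevel_model(canon, ref, catalog, "biomass", 0.5, precision=5)
        assert model.n_boolean_variables == 48


class TestBigM:
    def test_rows_force_z_equal_delta_when_x_one(self, chain):
        lay = layout_for(chain, precision=0)
        block = build_duality_coupling(lay, chain.reference, np.full(lay.n_pairs, 5.0))
        p, n = 0, 0
        zi, di, xi = lay.z(p, n), lay.delta(p), lay.x(0, n)
        rows = {name: (coefs, lo, up) for name, coefs, lo, up in block.rows}
        # substitute x = 1 into the three big-M rows
        coefs, _, up = rows[f"bigm_zx_{p}_{n}"]
        assert up - coefs[xi] * 1.0 == pytest.approx(5.0)  # z <= 5
        coefs, _, up = rows[f"bigm_zd_{p}_{n}"]
        assert coefs == {zi: 1.0, di: -1.0} and up == 0.0  # z <= delta
        coefs, _, up = rows[f"bigm_dz_{p}_{n}"]
        assert up - coefs[xi] * 1.0 == pytest.approx(0.0)  # delta - z <= 0

    def test_rows_force_z_zero_when_x_zero(self, chain):
        lay = layout_for(chain, precision=0)
        block = build_duality_coupling(lay, chain.reference, np.full(lay.n_pairs, 5.0))
        rows = {name: (coefs, lo, up) for name, coefs, lo, up in block.rows}
        coefs, _, up = rows["bigm_zx_0_0"]
        # with x = 0: z <= 0, and z >= 0 by variable bound
        assert up == 0.0 and coefs[lay.z(0, 0)] == 1.0

    def test_nonpositive_delta_max_rejected(self, chain):
        lay = layout_for(chain)
        with pytest.raises(fd.ValidationError, match="positive"):
            build_duality_coupling(lay, chain.reference, np.zeros(lay.n_pairs))


class TestEncodingBlock:
    def test_redundancy_row_binary(self, chain):
        lay = layout_for(chain, precision=3)
        block = build_encoding_block(lay)
        assert len(block) == 1
        _, coefs, _, up = block.rows[0]
        assert coefs[lay.x(0, 0)] == 3.0
        assert up == 0.0

    def test_no_redundancy_row_at_p0(self, chain):
        lay = layout_for(chain, precision=0)
        assert len(build_encoding_block(lay)) == 0

    def test_chain_rows_dose_response(self):
        cat = fd.DrugCatalog(
            drug_ids=["a"], target_sets={"a": ("uptake",)}, dose_levels={"a": (0.2, 0.6)}
        )
        inst = fd.fixture("chain")
        enc = InhibitionEncoding.for_catalog(cat, 1, "dose-response")
        lay = VariableLayout(inst.network, cat, enc)
        block = build_encoding_block(lay)
        assert [name for name, *_ in block.rows] == ["chain_a_0", "chain_a_1"]


class TestStrongDualityFixedH:
    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5, 6])
    def test_primal_equals_dual(self, seed):
        net, ref, cat = make_synthetic_case(seed)
        rng = np.random.default_rng(seed + 50)
        h = random_grid_h(rng, cat, 2)
        primal = fd.moma_l1(net, ref, fd.apply_inhibition(net, cat, h)).side_effect
        dual, duals = fd.solve_inner_dual(net, ref, cat, h)
        assert dual == pytest.approx(-primal, abs=1e-9)
        assert np.all(duals["lam"] >= -1e-12)
        assert np.all(duals["alpha"] + duals["beta"] <= 1 + 1e-9)


class TestEstimateDeltaMax:
    def test_grid_duals_never_exceed_bound(self, chain):
        bound = fd.estimate_delta_max(chain.network, chain.reference, chain.catalog)
        enc = InhibitionEncoding.for_catalog(chain.catalog, 2)
        for h in enc.achievable_levels("d1"):
            _, duals = fd.solve_inner_dual(chain.network, chain.reference, chain.catalog, [h])
            assert np.all(duals["delta"] <= bound + 1e-9)

    def test_rescaled_bounds_still_valid(self, chain):
        net = chain.network.copy()
        net.upper_bounds = net.upper_bounds * 2.0
        ref = fd.fba_reference(net)
        bound = fd.estimate_delta_max(net, ref, chain.catalog)
        for h in (0.0, 0.5, 1.0):
            _, duals = fd.solve_inner_dual(net, ref, chain.catalog, [h])
            assert np.all(duals["delta"] <= bound + 1e-9)

    def test_tighten_mode_returns_valid_bound(self, diamond):
        loose = fd.estimate_delta_max(diamond.network, diamond.reference, diamond.catalog)
        tight = fd.estimate_delta_max(
            diamond.network, diamond.reference, diamond.catalog, tighten=True
        )
        assert np.all(tight <= loose + 1e-12)
        sol = fd.solve_bilevel(
            diamond.network, diamond.reference, diamond.catalog, "direct", 0.5,
            precision=1, delta_max=tight,
        )
        assert sol.side_effect == pytest.approx(6.3, abs=1e-6)

    def test_artificially_tiny_delta_max_is_flagged_or_fails(self, chain):
        try:
            sol = fd.solve_bilevel(
                chain.network, chain.reference, chain.catalog, "consume", 0.5,
                precision=1, delta_max=1e-6, validate=False,
            )
            assert not sol.delta_max_ok or sol.side_effect != pytest.approx(10.0, abs=1e-6)
        except fd.SolverError:
            pass  # infeasible coupling is an acceptable symptom


class TestSolveBilevel:
    def test_chain_partial_beats_on_off(self, chain):
        p1 = fd.solve_bilevel(chain.network, chain.reference, chain.catalog, "consume", 0.5, precision=1)
        p0 = fd.solve_bilevel(chain.network, chain.reference, chain.catalog, "consume", 0.5, precision=0)
        assert p1.h[0] == pytest.approx(0.5)
        assert p1.side_effect == pytest.approx(10.0, abs=1e-6)
        assert p0.h[0] == pytest.approx(1.0)
        assert p0.side_effect == pytest.approx(20.0, abs=1e-6)

    def test_superfluous_drug_unused(self, superfluous):
        sol = fd.solve_bilevel(
            superfluous.network, superfluous.reference, superfluous.catalog, "consume", 0.5, precision=1
        )
        assert sol.h_by_drug["narrow"] == pytest.approx(0.0)
        assert sol.h_by_drug["broad"] == pytest.approx(0.5)

    def test_activation_mode(self, activation):
        sol = fd.solve_bilevel(
            activation.network, activation.reference, activation.catalog, "alt", 2.0,
            mode="activate", precision=1,
        )
        j = activation.network.reaction_index("alt")
        assert sol.v_tr[j] >= 2.0 * activation.reference.v_ut[j] - 1e-6
        assert sol.side_effect == pytest.approx(7.0, abs=1e-6)

    def test_irrelevant_target_infeasible(self):
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
        with pytest.raises(fd.InfeasibleTreatmentError, match="no drug combination"):
            fd.solve_bilevel(net, ref, cat, "consume", 0.1, precision=1)

    def test_duality_residual_small(self, all_fixtures):
        for inst in all_fixtures:
            case = inst.expected[0]
            sol = fd.solve_bilevel(
                inst.network, inst.reference, inst.catalog, inst.mod_id, case.tau,
                mode=case.mode, precision=case.precision,
            )
            assert sol.duality_residual <= 1e-6 * max(1.0, sol.side_effect)

    def test_h_on_achievable_grid(self, diamond):
        sol = fd.solve_bilevel(diamond.network, diamond.reference, diamond.catalog, "direct", 0.5, precision=2)
        grid = np.arange(5) / 4.0
        for hk in sol.h:
            assert np.min(np.abs(grid - hk)) < 1e-9

    def test_tau_monotonicity_inhibit(self, diamond):
        values = []
        for tau in (0.0, 0.25, 0.5, 0.75):
            sol = fd.solve_bilevel(
                diamond.network, diamond.reference, diamond.catalog, "direct", tau, precision=2
            )
            values.append(sol.side_effect)
        assert all(a >= b - 1e-9 for a, b in zip(values, values[1:]))

    def test_invalid_tau_mode_combinations(self, chain):
        with pytest.raises(fd.ValidationError, match="inhibit"):
            fd.solve_bilevel(chain.network, chain.reference, chain.catalog, "consume", 1.5)
        with pytest.raises(fd.ValidationError, match="activate"):
            fd.solve_bilevel(
                chain.network, chain.reference, chain.catalog, "consume", 0.5, mode="activate"
            )

    def test_b_term_never_reorders(self, chain):
        # objective gap between the two distinct-side-effect candidates (10 vs
        # 20) dwarfs the largest possible b-term contribution b * d
        gap = 20.0 - 10.0
        assert gap > fd.bilevel.DEFAULT_B * chain.catalog.n_drugs


class TestExport:
    def test_lp_and_mps_export(self, tmp_path, chain):
        model = build_bilevel_model(
            chain.network, chain.reference, chain.catalog, "consume", 0.5, precision=1
        )
        lp = tmp_path / "model.lp"
        mps = tmp_path / "model.mps"
        model.write_lp(str(lp))
        model.write_mps(str(mps))
        lp_text = lp.read_text()
        assert "Minimize" in lp_text and "x_d1_0" in lp_text and "strong_duality" in lp_text
        mps_text = mps.read_text()
        assert mps_text.startswith("NAME") and "INTORG" in mps_text and "ENDATA" in mps_text
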