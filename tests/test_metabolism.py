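"""Transport/metabolism: FBA, convenience kinetics, dFBA mass accounting."""

import numpy as np
import pytest

from colisim.metabolism import (
    COUNT_MMOL,
    KineticReaction,
    LacYExpressionState,
    MetabolicNetwork,
    PoolError,
    TOY_INITIAL_POOLS,
    TOY_PROTEINS,
    biomass_from_pools,
    convenience_rate,
    dfba_step,
    lacY_expression_step,
    solve_fba,
    toy_network,
    toy_transport_reactions,
    transport_step,
)


class TestSolveFBA:
    def chain(self):
        """EX_A (<=10) -> A -> biomass; optimum solvable by hand."""
        return MetabolicNetwork(
            reactions={"EX_A": {"A": 1.0}},
            bounds={"EX_A": (0.0, 10.0)},
            objective={"A": 1.0},
            exchange_reactions={"EX_A": "A"},
            molecular_weights={"A": 1.0},
        )

    def test_toy_chain_optimum_is_uptake_bound(self):
        result = solve_fba(self.chain())
        assert result.feasible
        assert result.objective_value == pytest.approx(10.0)

    def test_closed_exchanges_give_zero_objective(self):
        result = solve_fba(self.chain(), {"EX_A": (0.0, 0.0)})
        assert result.objective_value == pytest.approx(0.0)

    def test_tightening_binding_bound_never_increases_optimum(self):
        net = toy_network()
        values = [
            solve_fba(net, {"EX_glc": (0.0, ub), "EX_lac": (0.0, 0.0)}).objective_value
            for ub in [10.0, 5.0, 2.0, 0.5, 0.0]
        ]
        assert all(a >= b - 1e-9 for a, b in zip(values, values[1:]))

    @pytest.mark.parametrize(
        "glc_cap, lac_cap", [(10.0, 0.0), (0.0, 10.0), (3.0, 7.0), (1.5, 2.5)]
    )
    def test_toy_optimum_matches_cobra_oracle(self, glc_cap, lac_cap):
        """Independent LP oracle: the same network solved through cobra/GLPK."""
        cobra = pytest.importorskip("cobra")
        net = toy_network()
        model = cobra.Model("toy")
        mets = {m: cobra.Metabolite(m) for m in net.metabolites}
        for rid, stoich in net.reactions.items():
            rxn = cobra.Reaction(rid)
            rxn.add_metabolites({mets[m]: c for m, c in stoich.items()})
            rxn.bounds = net.bounds[rid]
            model.add_reactions([rxn])
        biomass = cobra.Reaction("BIOMASS_drain")
        biomass.add_metabolites({mets[m]: -c for m, c in net.objective.items()})
        biomass.bounds = (0.0, 1000.0)
        model.add_reactions([biomass])
        model.reactions.EX_glc.bounds = (0.0, glc_cap)
        model.reactions.EX_lac.bounds = (0.0, lac_cap)
        model.objective = "BIOMASS_drain"
        expected = model.optimize().objective_value

        result = solve_fba(
            net, {"EX_glc": (0.0, glc_cap), "EX_lac": (0.0, lac_cap)}
        )
        assert result.objective_value == pytest.approx(expected, rel=1e-6)


class TestConvenienceKinetics:
    def test_half_saturation(self):
        rxn = KineticReaction(id="r", substrates={"S": 2.0}, enzyme="E", kcat=3.0)
        assert convenience_rate(rxn, {"S": 2.0}, 10.0) == pytest.approx(15.0)

    def test_zero_substrate_zero_rate(self):
        rxn = KineticReaction(id="r", substrates={"S": 2.0}, enzyme="E", kcat=3.0)
        assert convenience_rate(rxn, {"S": 0.0}, 10.0) == 0.0

    @pytest.mark.parametrize("s", [0.01, 0.5, 1.0, 7.3, 100.0])
    def test_reduces_to_michaelis_menten_single_substrate(self, s):
        km, kcat, e = 1.3, 2.0, 5.0
        rxn = KineticReaction(id="r", substrates={"S": km}, enzyme="E", kcat=kcat)
        assert convenience_rate(rxn, {"S": s}, e) == pytest.approx(
            kcat * e * s / (km + s)
        )

    def test_competitive_inhibition_matches_hand_evaluation(self):
        # S >> Km with I = Ki: rate = kcat*E*(s/Km)/(1 + s/Km + 1)
        km, ki, kcat, e, s, i = 0.5, 2.0, 4.0, 3.0, 50.0, 2.0
        rxn = KineticReaction(
            id="r", substrates={"S": km}, competitors={"I": ki},
            enzyme="E", kcat=kcat,
        )
        x = s / km
        expected = kcat * e * x / (1 + x + i / ki)
        assert convenience_rate(rxn, {"S": s, "I": i}, e) == pytest.approx(expected)
        # approaches kcat*E as s -> infinity at fixed inhibitor
        assert expected == pytest.approx(kcat * e, rel=0.05)

    def test_rate_linear_in_enzyme_count(self):
        rxn = KineticReaction(id="r", substrates={"S": 1.0}, enzyme="E", kcat=2.0)
        r1 = convenience_rate(rxn, {"S": 3.0}, 10.0)
        r2 = convenience_rate(rxn, {"S": 3.0}, 20.0)
        assert r2 == pytest.approx(2 * r1)


class TestTransportStep:
    def test_no_transporter_no_uptake(self):
        constraints = transport_step(
            toy_transport_reactions(), {"GalP": 100.0, "LacY": 0.0},
            {"glc": 1.0, "lac": 5.0},
        )
        assert constraints["EX_lac"] == (0.0, 0.0)
        assert constraints["EX_glc"][0] > 0

    def test_no_substrate_no_uptake(self):
        constraints = transport_step(
            toy_transport_reactions(), {"GalP": 100.0, "LacY": 50.0},
            {"glc": 0.0, "lac": 5.0},
        )
        assert constraints["EX_glc"] == (0.0, 0.0)

    def test_missing_transporter_is_config_error(self):
        with pytest.raises(KeyError):
            transport_step(toy_transport_reactions(), {"GalP": 1.0}, {})


class TestDfbaStep:
    def test_rich_environment_grows_pool_mass(self):
        net = toy_network()
        pools = dict(TOY_INITIAL_POOLS)
        deltas, env_deltas, mass_delta, result = dfba_step(
            net, pools, {"glc": 1.0, "lac": 0.0},
            {"EX_glc": (0.005, 0.005), "EX_lac": (0.0, 0.0)},
            dt=1.0, bin_volume_l=2e-12,
        )
        assert result.feasible
        assert mass_delta > 0
        assert deltas["pre"] > 0

    def test_empty_environment_zero_growth(self):
        net = toy_network()
        deltas, env_deltas, mass_delta, _ = dfba_step(
            net, dict(TOY_INITIAL_POOLS), {"glc": 0.0, "lac": 0.0},
            {"EX_glc": (0.01, 0.01), "EX_lac": (0.0, 0.0)},
            dt=1.0, bin_volume_l=2e-12,
        )
        assert mass_delta == 0.0
        assert env_deltas == {}

    def test_mass_conservation_environment_to_cell(self):
        """Mass removed from the environment equals pool mass gained."""
        net = toy_network()
        env = {"glc": 1.0, "lac": 2.0}
        deltas, env_deltas, mass_delta, _ = dfba_step(
            net, dict(TOY_INITIAL_POOLS), env,
            {"EX_glc": (0.004, 0.004), "EX_lac": (0.002, 0.002)},
            dt=1.0, bin_volume_l=2e-12,
        )
        env_mass_loss = -sum(
            mmol / COUNT_MMOL * net.molecular_weights[sp]
            for sp, mmol in env_deltas.items()
        )
        assert env_mass_loss == pytest.approx(mass_delta, rel=1e-9)

    def test_uptake_capped_by_local_availability(self):
        net = toy_network()
        vol = 2e-12
        env = {"glc": 0.001, "lac": 0.0}  # nearly empty bin
        available_counts = env["glc"] * vol / COUNT_MMOL
        deltas, env_deltas, mass_delta, result = dfba_step(
            net, dict(TOY_INITIAL_POOLS), env,
            {"EX_glc": (1000.0, 1000.0), "EX_lac": (0.0, 0.0)},
            dt=1.0, bin_volume_l=vol,
        )
        assert result.fluxes["EX_glc"] <= available_counts + 1e-12

    def test_step_halving_consistency(self):
        """Two dt/2 steps match one dt step under static constraints."""
        net = toy_network()
        constraints = {"EX_glc": (0.003, 0.003), "EX_lac": (0.001, 0.001)}
        env = {"glc": 5.0, "lac": 5.0}

        def run(dts):
            pools = dict(TOY_INITIAL_POOLS)
            total = 0.0
            for dt in dts:
                deltas, _, dm, _ = dfba_step(
                    net, pools, env, constraints, dt, bin_volume_l=2e-12
                )
                for k, v in deltas.items():
                    pools[k] = pools.get(k, 0.0) + v
                total += dm
            return total

        assert run([1.0]) == pytest.approx(run([0.5, 0.5]), rel=1e-9)


class TestLacYExpression:
    def test_high_glucose_represses_to_near_basal(self):
        state = LacYExpressionState()
        dm, _ = lacY_expression_step(state, glucose_signal=1.0, dt=1.0, rng=None)
        assert dm < 2 * state.transcription_basal

    def test_zero_glucose_reaches_positive_steady_state(self):
        state = LacYExpressionState()
        for _ in range(2000):
            dm, dp = lacY_expression_step(state, 0.0, 1.0, rng=None)
            state.lacY_mRNA += dm
            state.LacY_protein += dp
        expected_mrna = (
            state.transcription_max + state.transcription_basal
        ) / state.mrna_decay
        assert state.lacY_mRNA == pytest.approx(expected_mrna, rel=0.01)
        assert state.LacY_protein > 50

    def test_zero_synthesis_decays_to_zero(self):
        state = LacYExpressionState(
            lacY_mRNA=10.0, LacY_protein=100.0,
            transcription_max=0.0, transcription_basal=0.0,
            translation_per_mrna=0.0, dilution=0.01,
        )
        for _ in range(5000):
            dm, dp = lacY_expression_step(state, 0.0, 1.0, rng=None)
            state.lacY_mRNA += dm
            state.LacY_protein += dp
        assert state.lacY_mRNA == pytest.approx(0.0, abs=1e-6)
        assert state.LacY_protein == pytest.approx(0.0, abs=0.1)


class TestBiomassFromPools:
    def test_empty_pools_zero_mass(self):
        assert biomass_from_pools({}, {}) == 0.0

    def test_counts_times_weight_and_linearity(self):
        weights = {"x": 90.0, "y": 10.0}
        m1 = biomass_from_pools({"x": 2.0, "y": 1.0}, weights)
        m2 = biomass_from_pools({"x": 4.0, "y": 2.0}, weights)
        assert m1 == pytest.approx(190.0)
        assert m2 == pytest.approx(2 * m1)

    def test_missing_weight_is_an_error(self):
        with pytest.raises(PoolError):
            biomass_from_pools({"mystery": 1.0}, {})
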