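import numpy as np
import pytest

from coextnet import (
    CascadeState,
    InteractionNetwork,
    SimulationConfig,
    apply_variant,
    exhaustive_expected_survival,
    remove_pollinator,
    run_replicate,
    run_simulation,
    scenario_order,
    survival_probability,
)
from coextnet.errors import CascadeError, ConfigError, DependenceError
from coextnet.scm import _scenario_orders


class TestSurvivalProbability:
    @pytest.mark.parametrize(
        "ipd, d, expected",
        [(1.0, 1.0, 0.0), (0.0, 0.7, 1.0), (0.5, 0.5, 0.75)],
    )
    def test_formula(self, ipd, d, expected):
        assert survival_probability(ipd, d) == pytest.approx(expected)

    @pytest.mark.parametrize("ipd, d", [(-0.1, 0.5), (1.1, 0.5), (0.5, 2.0)])
    def test_domain_errors(self, ipd, d):
        with pytest.raises(DependenceError):
            survival_probability(ipd, d)


class TestApplyVariant:
    def test_variant_d_forces_full_dependence(self, toy22, toy22_dep):
        _, dep = apply_variant(toy22, toy22_dep, "D")
        assert dep == {"A": 1.0, "B": 1.0}

    def test_variant_h_homogenises_shares(self, toy22, toy22_dep):
        net, dep = apply_variant(toy22, toy22_dep, "H")
        row = net.visits[0]
        shares = row[row > 0] / row[row > 0].sum()
        np.testing.assert_allclose(shares, [0.5, 0.5])
        assert dep == toy22_dep

    def test_variant_f_is_identity(self, toy22, toy22_dep):
        net, dep = apply_variant(toy22, toy22_dep, "F")
        assert net is toy22
        assert dep == toy22_dep

    def test_inputs_never_mutated(self, toy22, toy22_dep):
        before = toy22.visits.copy()
        apply_variant(toy22, toy22_dep, "DH")
        np.testing.assert_array_equal(toy22.visits, before)
        assert toy22_dep == {"A": 0.5, "B": 1.0}

    def test_unknown_tag(self, toy22, toy22_dep):
        with pytest.raises(ConfigError):
            apply_variant(toy22, toy22_dep, "X")


class TestScenarioOrder:
    @pytest.fixture
    def degree_net(self):
        # degrees: x=3, y=2, z=1
        visits = np.array([[1.0, 1.0, 1.0], [1.0, 1.0, 0.0], [1.0, 0.0, 0.0]])
        return InteractionNetwork(("A", "B", "C"), ("x", "y", "z"), visits)

    def test_generalist_descending(self, degree_net):
        order = scenario_order(degree_net, "generalist", np.random.default_rng(0))
        assert order == ["x", "y", "z"]

    def test_specialist_ascending(self, degree_net):
        order = scenario_order(degree_net, "specialist", np.random.default_rng(0))
        assert order == ["z", "y", "x"]

    def test_random_is_permutation(self, degree_net):
        order = scenario_order(degree_net, "random", np.random.default_rng(3))
        assert sorted(order) == ["x", "y", "z"]

    def test_ties_broken_uniformly(self):
        net = InteractionNetwork(
            ("A", "B"), ("x", "y"), np.array([[1.0, 1.0], [1.0, 1.0]])
        )
        rng = np.random.default_rng(5)
        orders = _scenario_orders(net, "generalist", rng, 4000)
        first_is_x = (orders[:, 0] == 0).mean()
        assert abs(first_is_x - 0.5) < 3 * np.sqrt(0.25 / 4000)


class TestRemovePollinator:
    def test_forced_coextinction_of_fully_dependent_plant(self):
        net = InteractionNetwork(("A",), ("x",), np.array([[2.0]]))
        state, log = remove_pollinator(
            CascadeState.initial(net), "x", {"A": 1.0}, np.random.default_rng(0)
        )
        assert state.extant_plants == set()
        assert state.extant_pollinators == set()
        kinds = {(e["species"], e["kind"]) for e in log}
        assert ("x", "primary") in kinds and ("A", "secondary") in kinds

    def test_unconnected_plant_untouched(self, toy22, toy22_dep):
        # B only visits y: removing x can never kill B
        for seed in range(20):
            state, _ = remove_pollinator(
                CascadeState.initial(toy22), "x", toy22_dep,
                np.random.default_rng(seed),
            )
            assert "B" in state.extant_plants

    def test_secondary_pollinator_pruned_without_new_draws(self):
        # y's only partner is A; A fully depends on x, so removing x
        # cascades to A and strands y
        net = InteractionNetwork(("A",), ("x", "y"), np.array([[9.0, 1e-9]]))
        state, log = remove_pollinator(
            CascadeState.initial(net), "x", {"A": 1.0}, np.random.default_rng(0)
        )
        # d_Ax ~ 1 so A dies almost surely with this seed; y goes topologically
        if "A" not in state.extant_plants:
            assert "y" not in state.extant_pollinators
            assert any(
                e["species"] == "y" and e["kind"] == "secondary" for e in log
            )

    def test_removing_extinct_pollinator_is_sequencing_error(self, toy22, toy22_dep):
        state = CascadeState(toy22, {"A", "B"}, {"y"})
        with pytest.raises(CascadeError):
            remove_pollinator(state, "x", toy22_dep, np.random.default_rng(0))


class TestRunReplicate:
    def test_zero_dependence_plants_survive_everything(self, sb_community):
        net, _ = sb_community
        dep = {p: 0.0 for p in net.plant_ids}
        order = list(net.pollinator_ids)
        outcome = run_replicate(net, dep, order, np.random.default_rng(1))
        assert outcome.plants_extant.all()
        assert not outcome.pollinators_extant[-1].any()

    def test_full_dependence_plants_all_die_by_the_end(self, pm_community):
        net, _ = pm_community
        dep = {p: 1.0 for p in net.plant_ids}
        order = list(net.pollinator_ids)
        outcome = run_replicate(net, dep, order, np.random.default_rng(2))
        assert not outcome.plants_extant[-1].any()

    def test_extant_sets_shrink_monotonically(self, toy22, toy22_dep):
        order = ["x", "y"]
        outcome = run_replicate(toy22, toy22_dep, order, np.random.default_rng(3))
        assert not np.any(np.diff(outcome.plants_extant.astype(int), axis=0) > 0)
        assert not np.any(np.diff(outcome.pollinators_extant.astype(int), axis=0) > 0)

    def test_order_must_be_permutation(self, toy22, toy22_dep):
        with pytest.raises(CascadeError):
            run_replicate(toy22, toy22_dep, ["x"], np.random.default_rng(0))


class TestRunSimulation:
    def test_event_zero_survival_is_one(self, toy22, toy22_dep):
        surf = run_simulation(toy22, toy22_dep, SimulationConfig(replicates=50, seed=0))
        np.testing.assert_array_equal(surf.survival[:, 0], 1.0)

    def test_single_bernoulli_draw(self):
        net = InteractionNetwork(("A",), ("x",), np.array([[1.0]]))
        surf = run_simulation(
            net, {"A": 0.5}, SimulationConfig(replicates=10_000, seed=1)
        )
        assert abs(surf.survival[0, 1] - 0.5) < 3 * np.sqrt(0.25 / 10_000)

    def test_curves_non_increasing(self, pm_community):
        net, dep = pm_community
        surf = run_simulation(net, dep, SimulationConfig(replicates=300, seed=4))
        assert np.all(np.diff(surf.survival, axis=1) <= 1e-12)

    def test_seed_reproducibility_bit_identical(self, toy22, toy22_dep):
        cfg = SimulationConfig(replicates=500, seed=42)
        a = run_simulation(toy22, toy22_dep, cfg)
        b = run_simulation(toy22, toy22_dep, cfg)
        np.testing.assert_array_equal(a.survival, b.survival)
        np.testing.assert_array_equal(a.frac_species, b.frac_species)

    def test_missing_plant_dependence_rejected(self, toy22):
        with pytest.raises(DependenceError, match="missing"):
            run_simulation(toy22, {"A": 0.5}, SimulationConfig(replicates=10))

    def test_engines_agree_with_enumeration(self, toy_equal):
        """Vectorised and per-replicate engines both match the exact tree."""
        net, dep = toy_equal
        exact = exhaustive_expected_survival(net, dep)
        for engine, reps in (("vectorized", 10_000), ("loop", 4000)):
            cfg = SimulationConfig(replicates=reps, seed=6, engine=engine)
            surf = run_simulation(net, dep, cfg)
            se = np.sqrt(np.clip(exact * (1 - exact), 0, None) / reps)
            assert np.all(np.abs(surf.survival - exact) <= 3 * se + 1e-9), engine

    def test_two_event_toy_probability(self, toy_equal):
        """P(surviving both removals) = (1 - 0.25) * (1 - 0.5) = 0.375."""
        net, dep = toy_equal
        surf = run_simulation(net, dep, SimulationConfig(replicates=20_000, seed=7))
        se = np.sqrt(0.375 * 0.625 / 20_000)
        assert abs(surf.survival[0, 2] - 0.375) <= 3 * se

    def test_dynamic_ranking_targets_current_generalists(self):
        # x supports A,B; y supports A only; z supports B only.  Dynamic
        # generalist removal must take x first in every replicate.
        visits = np.array([[1.0, 1.0, 0.0], [1.0, 0.0, 1.0]])
        net = InteractionNetwork(("A", "B"), ("x", "y", "z"), visits)
        dep = {"A": 1.0, "B": 1.0}
        cfg = SimulationConfig(
            replicates=200, seed=8, scenario="generalist", order_mode="dynamic"
        )
        surf = run_simulation(net, dep, cfg)
        # after event 1 (x removed), both plants faced a 1/2 draw
        assert 0.3 < surf.survival[0, 1] < 0.7

    def test_richness_fractions_consistent(self, pm_community):
        net, dep = pm_community
        surf = run_simulation(net, dep, SimulationConfig(replicates=200, seed=9))
        n_a, n_p = net.n_plants, net.n_pollinators
        expected = (surf.frac_plants * n_a + surf.frac_pollinators * n_p) / (n_a + n_p)
        np.testing.assert_allclose(surf.frac_species, expected, atol=1e-12)
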