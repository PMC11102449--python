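import numpy as np
import pytest

from tmesim import (AgentKind, Lattice, OxygenField, dc_activation_step,
                    dc_inactivation_step, effector_kill_step,
                    t_activation_step, tumor_division_step)
from tmesim.motility import MotilityMode, motility_state


@pytest.fixture
def forced(literal_params):
    """Parameters with deterministic (probability-1) interaction rules and
    no hypoxia/adenosine modulation."""
    return literal_params.replace(P_tumor=1.0, D_act=1.0, C_act=1.0,
                                  D_inact=1.0, mu=1.0, r_At=0.0, r_Ht=0.0,
                                  r_Ar=0.0, r_Hr=0.0, r_Ae=0.0, r_He=0.0)


class TestTumorDivision:
    def test_enclosed_cells_never_divide(self, forced, rng):
        """On a fully occupied lattice no cell has an empty neighbor, so
        even probability-1 division produces no daughters."""
        lat = Lattice(9)
        for i in range(9):
            for j in range(9):
                lat.add_tumor((i, j))
        field = OxygenField(9, 0.8)
        for _ in range(5):
            assert tumor_division_step(lat, field, 0.0, forced, rng) == 0
        assert lat.n_tumor == 81
        lat.audit()

    def test_single_cell_produces_exactly_one_daughter(self, forced, rng):
        lat = Lattice(15)
        lat.add_tumor((7, 7))
        field = OxygenField(15, 0.8)
        tumor_division_step(lat, field, 0.0, forced, rng)
        assert lat.n_tumor == 2
        lat.audit()

    def test_division_frequency_matches_modulated_rate(self, literal_params):
        """Empirical division frequency of a free rim cell at U = 0.8,
        Ad = 0 approximates P_tumor + r_Ht/(U+c) = 0.003593."""
        p_expected = 0.001 + 0.0021 / 0.81
        rng = np.random.default_rng(42)
        field = OxygenField(9, 0.8)
        trials, divisions = 20_000, 0
        lat = Lattice(9)
        lat.add_tumor((4, 4))
        for _ in range(trials):
            tumor_division_step(lat, field, 0.0, literal_params, rng)
            if lat.n_tumor == 2:
                divisions += 1
                daughters = [s for s in lat.iter_tumor_sites() if s != (4, 4)]
                lat.remove_tumor(daughters[0])
        se = np.sqrt(p_expected * (1 - p_expected) / trials)
        assert divisions / trials == pytest.approx(p_expected, abs=4 * se)


class TestDCActivation:
    def test_requires_tumor_contact(self, forced, rng):
        lat = Lattice(15)
        lat.add_immune(AgentKind.DC_INACTIVE, (3, 3))
        for _ in range(20):
            dc_activation_step(lat, forced, rng)
        assert lat.kind[0] == AgentKind.DC_INACTIVE

    def test_certain_activation_switches_to_brownian(self, forced, rng):
        lat = Lattice(15)
        lat.add_immune(AgentKind.DC_INACTIVE, (3, 3))
        lat.add_tumor((3, 4))
        assert dc_activation_step(lat, forced, rng) == 1
        assert lat.kind[0] == AgentKind.DC_ACTIVE
        assert motility_state(lat, 0).mode is MotilityMode.BROWNIAN

    def test_activation_frequency(self, literal_params):
        rng = np.random.default_rng(1)
        lat = Lattice(9)
        lat.add_immune(AgentKind.DC_INACTIVE, (3, 3))
        lat.add_tumor((3, 4))
        trials, hits = 30_000, 0
        for _ in range(trials):
            lat.kind[0] = AgentKind.DC_INACTIVE
            lat.grid[3, 3] = AgentKind.DC_INACTIVE
            hits += dc_activation_step(lat, literal_params, rng)
        se = np.sqrt(0.003 * 0.997 / trials)
        assert hits / trials == pytest.approx(0.003, abs=4 * se)


class TestTActivation:
    def test_requires_active_dc_contact(self, forced, rng):
        lat = Lattice(15)
        lat.add_immune(AgentKind.T_INACTIVE, (3, 3))
        lat.add_immune(AgentKind.DC_INACTIVE, (3, 4))
        field = OxygenField(15, 0.8)
        for _ in range(20):
            t_activation_step(lat, field, 0.0, forced, rng)
        assert lat.kind[0] == AgentKind.T_INACTIVE

    def test_forced_treg_fate(self, forced, rng):
        p = forced.replace(P_Treg=1.0)
        lat = Lattice(15)
        lat.add_immune(AgentKind.T_INACTIVE, (3, 3))
        lat.add_immune(AgentKind.DC_ACTIVE, (3, 4))
        field = OxygenField(15, 0.8)
        assert t_activation_step(lat, field, 0.0, p, rng) == 1
        assert lat.kind[0] == AgentKind.TREG

    def test_treg_fraction_matches_polarization_rate(self, literal_params):
        """At U = 0.8, Ad = 0 the Treg fraction of activations approximates
        P_Treg + r_Hr/(U+c) = 0.30580."""
        p = literal_params.replace(C_act=1.0)  # always activate on contact
        p_treg = 0.3 + 0.0047 / 0.81
        rng = np.random.default_rng(2)
        lat = Lattice(9)
        lat.add_immune(AgentKind.T_INACTIVE, (3, 3))
        lat.add_immune(AgentKind.DC_ACTIVE, (3, 4))
        field = OxygenField(9, 0.8)
        trials, tregs = 30_000, 0
        for _ in range(trials):
            lat.kind[0] = AgentKind.T_INACTIVE
            lat.grid[3, 3] = AgentKind.T_INACTIVE
            t_activation_step(lat, field, 0.0, p, rng)
            tregs += lat.kind[0] == AgentKind.TREG
        se = np.sqrt(p_treg * (1 - p_treg) / trials)
        assert tregs / trials == pytest.approx(p_treg, abs=4 * se)


class TestEffectorKilling:
    def test_no_tumor_neighbor_no_kill(self, forced, rng):
        lat = Lattice(15)
        lat.add_immune(AgentKind.EFFECTOR, (3, 3))
        field = OxygenField(15, 0.8)
        assert effector_kill_step(lat, field, 0.0, forced, rng) == 0

    def test_certain_kill_vacates_the_site_and_keeps_the_effector(self, forced, rng):
        lat = Lattice(15)
        lat.add_immune(AgentKind.EFFECTOR, (3, 3))
        lat.add_tumor((3, 4))
        field = OxygenField(15, 0.8)
        assert effector_kill_step(lat, field, 0.0, forced, rng) == 1
        assert lat.n_tumor == 0
        assert lat.is_empty((3, 4))
        assert lat.kind[0] == AgentKind.EFFECTOR  # serial killer survives
        lat.audit()

    def test_at_most_one_kill_per_effector_per_step(self, forced, rng):
        lat = Lattice(15)
        lat.add_immune(AgentKind.EFFECTOR, (3, 3))
        for s in [(2, 2), (2, 3), (3, 4), (4, 4)]:
            lat.add_tumor(s)
        field = OxygenField(15, 0.8)
        assert effector_kill_step(lat, field, 0.0, forced, rng) == 1
        assert lat.n_tumor == 3

    def test_kill_frequency_matches_cytotoxicity(self, literal_params):
        mu_bar = 0.45 - 0.014 / 0.81
        rng = np.random.default_rng(3)
        lat = Lattice(9)
        lat.add_immune(AgentKind.EFFECTOR, (3, 3))
        field = OxygenField(9, 0.8)
        trials, kills = 20_000, 0
        for _ in range(trials):
            if lat.n_tumor == 0:
                lat.add_tumor((3, 4))
            kills += effector_kill_step(lat, field, 0.0, literal_params, rng)
        se = np.sqrt(mu_bar * (1 - mu_bar) / trials)
        assert kills / trials == pytest.approx(mu_bar, abs=4 * se)


class TestDCInactivation:
    def test_requires_treg_contact(self, forced, rng):
        lat = Lattice(15)
        lat.add_immune(AgentKind.DC_ACTIVE, (3, 3))
        for _ in range(20):
            dc_inactivation_step(lat, forced, rng)
        assert lat.kind[0] == AgentKind.DC_ACTIVE

    def test_certain_deactivation_restores_levy_motion(self, forced, rng):
        lat = Lattice(15)
        lat.add_immune(AgentKind.DC_ACTIVE, (3, 3))
        lat.add_immune(AgentKind.TREG, (3, 4))
        assert dc_inactivation_step(lat, forced, rng) == 1
        st = motility_state(lat, 0)
        assert st.mode is MotilityMode.LEVY and st.steps_remaining == 0

    def test_deactivation_frequency(self, literal_params):
        rng = np.random.default_rng(4)
        lat = Lattice(9)
        lat.add_immune(AgentKind.DC_ACTIVE, (3, 3))
        lat.add_immune(AgentKind.TREG, (3, 4))
        trials, hits = 30_000, 0
        for _ in range(trials):
            lat.kind[0] = AgentKind.DC_ACTIVE
            lat.grid[3, 3] = AgentKind.DC_ACTIVE
            hits += dc_inactivation_step(lat, literal_params, rng)
        se = np.sqrt(0.01 * 0.99 / trials)
        assert hits / trials == pytest.approx(0.01, abs=4 * se)


class TestConservation:
    def test_interaction_rules_conserve_lineage_counts(self, rng, literal_params):
        """T-lineage and DC totals are invariant under every rule; tumor
        count changes only via divisions (+1) and kills (-1)."""
        lat = Lattice(21)
        field = OxygenField(21, 0.8)
        occupied = set()
        def place(kind):
            while True:
                s = (int(rng.integers(21)), int(rng.integers(21)))
                if s not in occupied:
                    occupied.add(s)
                    return lat.add_immune(kind, s) if kind != AgentKind.TUMOR \
                        else lat.add_tumor(s)
        for _ in range(30):
            place(AgentKind.TUMOR)
        for kind, n in [(AgentKind.DC_INACTIVE, 10), (AgentKind.DC_ACTIVE, 10),
                        (AgentKind.T_INACTIVE, 20), (AgentKind.TREG, 10),
                        (AgentKind.EFFECTOR, 10)]:
            for _ in range(n):
                place(kind)
        p = literal_params.replace(P_tumor=0.3, D_act=0.3, C_act=0.5,
                                   D_inact=0.3)
        for _ in range(30):
            c0 = lat.counts()
            n0 = lat.n_tumor
            births = tumor_division_step(lat, field, 100.0, p, rng)
            dc_activation_step(lat, p, rng)
            t_activation_step(lat, field, 100.0, p, rng)
            kills = effector_kill_step(lat, field, 100.0, p, rng)
            dc_inactivation_step(lat, p, rng)
            c1 = lat.counts()
            t0 = c0[AgentKind.T_INACTIVE] + c0[AgentKind.TREG] + c0[AgentKind.EFFECTOR]
            t1 = c1[AgentKind.T_INACTIVE] + c1[AgentKind.TREG] + c1[AgentKind.EFFECTOR]
            assert t1 == t0
            assert c1[AgentKind.DC_INACTIVE] + c1[AgentKind.DC_ACTIVE] == \
                c0[AgentKind.DC_INACTIVE] + c0[AgentKind.DC_ACTIVE]
            assert lat.n_tumor == n0 + births - kills
            lat.audit()
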