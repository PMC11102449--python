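import numpy as np
import pytest

from tmesim import (AgentKind, ParameterSet, group_protocol, initialize, run,
                    run_replicates, tumor_volume_mm3)
from tmesim.humoral import HumoralState, step_adenosine
from tmesim.protocols import ProtocolSpec
from tmesim.rates import tumor_rate


class TestInitialize:
    def test_default_inventory(self, params):
        lat, field, hum, _ = initialize(params, seed=0)
        counts = lat.counts()
        assert counts[AgentKind.TUMOR] == 1
        assert counts[AgentKind.DC_INACTIVE] == 100
        assert counts[AgentKind.T_INACTIVE] == 750
        assert lat.grid[105, 105] == AgentKind.TUMOR
        assert hum.Ad == hum.px == hum.s_raw == 0.0
        lat.audit()

    def test_same_seed_gives_identical_placement(self, small_params):
        a, *_ = initialize(small_params, seed=9)
        b, *_ = initialize(small_params, seed=9)
        assert np.array_equal(a.grid, b.grid)
        assert np.array_equal(a.row, b.row) and np.array_equal(a.col, b.col)

    def test_over_capacity_rejected(self):
        p = ParameterSet(N=9, N_D=100, N_T=100)
        with pytest.raises(ValueError, match="capacity"):
            initialize(p, seed=0)


class TestVolumeConversion:
    @pytest.mark.parametrize("sites,volume", [(0, 0.0), (1, 0.22), (500, 110.0)])
    def test_site_count_to_mm3(self, sites, volume, params):
        assert tumor_volume_mm3(sites, params) == pytest.approx(volume)


class TestRun:
    def test_replays_are_bit_identical(self, small_params):
        a = run(small_params, group_protocol("siRNA+Px-478+DC"), seed=5,
                horizon_days=1)
        b = run(small_params, group_protocol("siRNA+Px-478+DC"), seed=5,
                horizon_days=1)
        for name in a.series:
            assert np.array_equal(a[name], b[name]), name

    def test_untreated_equals_run_without_protocol_object(self, small_params):
        a = run(small_params, None, seed=3, horizon_days=1)
        b = run(small_params, ProtocolSpec("Untreated"), seed=3, horizon_days=1)
        for name in a.series:
            assert np.array_equal(a[name], b[name]), name

    def test_frozen_dynamics_keep_a_single_tumor_cell(self):
        p = ParameterSet(N=30, N_D=0, N_T=0, P_tumor=0.0, r_At=0.0, r_Ht=0.0,
                         hypoxia_ref=0.0, adenosine_ref=0.0)
        traj = run(p, None, seed=1, horizon_days=1)
        assert np.all(traj["tumor_sites"] == 1)

    def test_tumor_count_non_decreasing_without_effectors(self):
        p = ParameterSet(N=30, N_D=0, N_T=0)
        traj = run(p, None, seed=2, horizon_days=1)
        assert np.all(np.diff(traj["tumor_sites"]) >= 0)
        assert np.all(traj["cum_kills"] == 0)

    def test_birth_death_ledger_explains_tumor_count(self, small_params):
        traj = run(small_params, group_protocol("DC"), seed=4, horizon_days=2)
        assert np.all(traj["tumor_sites"] ==
                      1 + traj["cum_births"] - traj["cum_kills"])

    def test_bookkeeping_audits_pass_during_a_run(self, small_params):
        run(small_params, group_protocol("siRNA+Px-478+DC"), seed=6,
            horizon_days=1, audit_every=120)

    def test_dc_injection_day_adds_active_dcs(self, small_params):
        traj = run(small_params, group_protocol("DC"), seed=7, horizon_days=8)
        day = traj.day
        # the injection lands on the first step of day 7, so it is visible
        # from the first recording strictly after day 7.0
        before = traj["n_dc_active"][day <= 7].max()
        total_after = (traj["n_dc_active"] + traj["n_dc_inactive"])[day > 7]
        assert np.all(total_after == small_params.N_D + 70)
        assert before <= small_params.N_D

    def test_trajectory_csv_round_trip(self, small_params, tmp_path):
        import pandas as pd
        traj = run(small_params, None, seed=8, horizon_days=1)
        out = tmp_path / "traj.csv"
        traj.to_csv(out)
        back = pd.read_csv(out)
        assert len(back) == traj.step.size
        assert np.allclose(back["tumor_volume"], traj["tumor_volume"])


class TestRimGrowthOracle:
    def test_pure_rim_growth_matches_independent_oracle(self):
        """With no immune cells and a flat oxygen field, the engine's tumor
        growth must replay an independent pure-Python rim-division oracle
        that consumes the same random stream."""
        p = ParameterSet(N=30, N_D=0, N_T=0, f_bar=0.0, k=0.0)
        traj = run(p, None, seed=11, horizon_days=1, record_every=1)

        # oracle: dict-of-sites grid, same RNG consumption order
        rng = np.random.default_rng(11)
        offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1),
                   (1, -1), (1, 0), (1, 1)]
        n = p.N
        tumor = [(n // 2, n // 2)]
        occupied = {tumor[0]}
        hum = HumoralState(p.M)
        counts = [1]
        for step in range(720):
            u_eff = p.U_boundary  # flat field: every summary equals 0.8
            step_adenosine(hum, u_eff, p)
            # rim list in slot order, then one shuffled pass
            rim = [j for j, s in enumerate(tumor)
                   if any((s[0] + dr, s[1] + dc) not in occupied
                          and 0 <= s[0] + dr < n and 0 <= s[1] + dc < n
                          for dr, dc in offsets)]
            perm = rng.permutation(len(rim))
            for idx in perm:
                r, c = tumor[rim[idx]]
                cand = [(r + dr, c + dc) for dr, dc in offsets
                        if 0 <= r + dr < n and 0 <= c + dc < n
                        and (r + dr, c + dc) not in occupied]
                if not cand:
                    continue
                if rng.random() < tumor_rate(p.U_boundary, hum.Ad, p):
                    site = cand[int(rng.integers(len(cand)))]
                    tumor.append(site)
                    occupied.add(site)
            counts.append(len(tumor))
        assert np.array_equal(traj["tumor_sites"], np.array(counts))


class TestReplicates:
    def test_single_replicate_has_zero_ci(self, small_params):
        s = run_replicates(small_params, None, [3], horizon_days=1)
        assert s.n_replicates == 1
        assert all(np.all(v == 0) for v in s.ci_halfwidth.values())
        assert s.ci_of("final_tumor_volume") == 0.0

    def test_identical_seeds_give_zero_spread(self, small_params):
        s = run_replicates(small_params, None, [5, 5, 5], horizon_days=1)
        assert s.ci_of("final_tumor_volume") == 0.0
        assert np.all(s.ci_halfwidth["tumor_volume"] == 0)

    def test_summary_aggregates_per_replicate_scalars(self, small_params):
        s = run_replicates(small_params, None, [1, 2], horizon_days=1,
                           keep_trajectories=True)
        manual = np.mean([t.mean_tumor_volume for t in s.replicates])
        assert s.mean_tumor_volume == pytest.approx(manual)
        assert len(s.days) == 2  # day 0 and day 1
        d = s.to_json_dict()
        assert d["n_replicates"] == 2 and "tumor_volume" in d["mean"]

    def test_replicate_count_shorthand(self, small_params):
        s = run_replicates(small_params, None, 2, horizon_days=1)
        assert list(s.per_replicate["seed"]) == [0, 1]

    def test_empty_seed_list_rejected(self, small_params):
        with pytest.raises(ValueError):
            run_replicates(small_params, None, [], horizon_days=1)
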