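import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import steppesim as ss
from steppesim.demography import (
    FARMER,
    PASTORALIST,
    ScenarioConfig,
    admix_exchange,
    draw_ldd_distances,
    effective_K,
    logistic_step,
    migrate_ldd,
    migrate_short,
    run_forward,
    _displacement_table,
    LDD_SHAPE,
    LDD_RATE,
)
from steppesim.geography import DemeIndex, build_grid


class TestLogisticStep:
    def test_carrying_capacity_is_fixed_point(self):
        assert logistic_step(1000.0, 0.6, 1000.0) == pytest.approx(1000.0)

    def test_extinction_absorbing(self):
        assert logistic_step(0.0, 0.6, 1000.0) == 0.0

    def test_growth_value(self):
        # independently: 100 * (1 + 0.6 * (1 - 100/1000)) = 154
        assert logistic_step(100.0, 0.6, 1000.0) == pytest.approx(154.0)

    def test_competition_shares_density(self):
        # D = N + N_other = K -> no growth
        assert logistic_step(400.0, 0.6, 1000.0, N_other=600.0, competition_on=True) \
            == pytest.approx(400.0)

    def test_nonpositive_K_rejected(self):
        with pytest.raises(ValueError):
            logistic_step(10.0, 0.6, 0.0)


class TestAdmixExchange:
    @pytest.mark.parametrize("nf,np_,g,expect", [
        (1000.0, 1000.0, 0.0, 0.0),
        (1000.0, 0.0, 0.01, 0.0),
        (1000.0, 1000.0, 0.01, 5.0),  # 0.01 * 1e6 / 2000
    ])
    def test_transfer_values(self, nf, np_, g, expect):
        t_fp, t_pf = admix_exchange(nf, np_, g)
        assert float(t_fp) == pytest.approx(expect)
        assert float(t_pf) == pytest.approx(expect)

    def test_rate_bounds(self):
        with pytest.raises(ValueError):
            admix_exchange(1.0, 1.0, 1.5)

    @settings(max_examples=50, deadline=None)
    @given(st.floats(0, 1e5), st.floats(0, 1e5), st.floats(0, 1))
    def test_symmetric_and_bounded(self, nf, np_, g):
        t_fp, t_pf = admix_exchange(nf, np_, g)
        assert float(t_fp) == float(t_pf)
        assert 0 <= float(t_fp) <= min(nf, np_) + 1e-9


class TestEffectiveK:
    def test_control_scenario_unchanged(self):
        sc = ScenarioConfig(decline_targets=frozenset())
        assert effective_K(1000.0, 250, sc, FARMER) == 1000.0

    def test_decline_strength_applied(self):
        sc = ScenarioConfig(decline_targets={"farmer"}, decline_strength=0.654,
                            decline_end_gen=300)
        assert effective_K(1000.0, 250, sc, FARMER) == pytest.approx(346.0)

    def test_window_boundaries(self):
        sc = ScenarioConfig(decline_targets={"farmer"}, decline_strength=0.6,
                            decline_end_gen=300)
        assert effective_K(1000.0, 221, sc, FARMER) == 1000.0       # before onset
        assert effective_K(1000.0, 222, sc, FARMER) == pytest.approx(400.0)
        assert effective_K(1000.0, 300, sc, FARMER) == 1000.0       # restored
        assert effective_K(1000.0, 250, sc, PASTORALIST) == 1000.0  # untargeted


class TestMigrateShort:
    def test_zero_rate_identity(self):
        grid = build_grid(np.ones((5, 5), dtype=bool))
        occ = np.full(grid.n_land, 100.0)
        new, out = migrate_short(occ, 0.0, grid, np.random.default_rng(0))
        assert np.array_equal(new, occ)
        assert out.sum() == 0

    def test_equal_split_interior(self):
        grid = build_grid(np.ones((5, 5), dtype=bool))
        occ = np.zeros(grid.n_land)
        centre = grid.land_id_of(DemeIndex(2, 2))
        occ[centre] = 1000.0
        new, out = migrate_short(occ, 0.5, grid, np.random.default_rng(0))
        # 1000 * 0.5 / 4 = 125 to each of the four neighbours
        assert sorted(out[:, centre]) == [125, 125, 125, 125]
        assert new.sum() == pytest.approx(1000.0)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.floats(0.0, 1.0))
    def test_conservation(self, seed, m):
        rng = np.random.default_rng(seed)
        grid = build_grid(rng.random((6, 6)) > 0.3)
        occ = rng.uniform(0, 5000, grid.n_land)
        new, _ = migrate_short(occ, m, grid, rng)
        assert new.sum() == pytest.approx(occ.sum())
        assert (new >= 0).all()


class TestMigrateLdd:
    def test_zero_rate_identity(self):
        grid = build_grid(np.ones((6, 6), dtype=bool))
        occ = np.full(grid.n_land, 500.0)
        new, (src, dst, cnt) = migrate_ldd(occ, 0.0, LDD_SHAPE, LDD_RATE, grid,
                                           np.random.default_rng(0))
        assert np.array_equal(new, occ)
        assert src.size == 0

    def test_kernel_mean_800_km(self):
        """Mean jump ~8.03 demes, i.e. 800 km to the nearest 100 km."""
        d = draw_ldd_distances(np.random.default_rng(1), 100_000)
        mean_km = d.mean() * 100.0  # 100-km demes
        assert round(mean_km / 100.0) * 100 == 800

    def test_seeded_determinism(self):
        grid = build_grid(np.ones((20, 20), dtype=bool))
        occ = np.full(grid.n_land, 1000.0)
        outs = []
        for _ in range(2):
            new, ev = migrate_ldd(occ.copy(), 0.05, LDD_SHAPE, LDD_RATE, grid,
                                  np.random.default_rng(42), emigration_rate=0.5)
            outs.append((new.copy(), ev))
        assert np.array_equal(outs[0][0], outs[1][0])
        for a, b in zip(outs[0][1], outs[1][1]):
            assert np.array_equal(a, b)

    def test_conservation_and_land_only(self):
        rng = np.random.default_rng(5)
        grid = build_grid(rng.random((12, 12)) > 0.3)
        occ = rng.uniform(0, 3000, grid.n_land)
        new, (src, dst, cnt) = migrate_ldd(occ, 0.05, LDD_SHAPE, LDD_RATE, grid,
                                           rng, emigration_rate=0.6)
        assert new.sum() == pytest.approx(occ.sum())
        assert (dst >= 0).all() and (dst < grid.n_land).all()

    def test_displacement_table_matches_direct_draws(self):
        """The tabulated offset law equals (uniform direction, gamma distance,
        nearest-deme rounding), checked against direct Monte Carlo draws."""
        dc, dr, cum = _displacement_table(LDD_SHAPE, LDD_RATE)
        prob = np.diff(np.concatenate([[0.0], cum]))
        rng = np.random.default_rng(2)
        n = 400_000
        theta = rng.uniform(0, 2 * np.pi, n)
        dist = draw_ldd_distances(rng, n)
        oc = np.rint(dist * np.cos(theta)).astype(int)
        orr = np.rint(dist * np.sin(theta)).astype(int)
        keep = ~((oc == 0) & (orr == 0))
        oc, orr = oc[keep], orr[keep]
        # compare total mass in a few coarse rings
        rad_tab = np.hypot(dc, dr)
        rad_mc = np.hypot(oc, orr)
        for lo, hi in [(0, 2), (2, 5), (5, 10), (10, 20), (20, 100)]:
            p_tab = prob[(rad_tab >= lo) & (rad_tab < hi)].sum()
            p_mc = ((rad_mc >= lo) & (rad_mc < hi)).mean()
            assert p_tab == pytest.approx(p_mc, abs=0.005)


class TestScenarioConfig:
    def test_prior_bounds_enforced(self):
        with pytest.raises(ValueError):
            ScenarioConfig(gamma_admix=0.5)
        with pytest.raises(ValueError):
            ScenarioConfig(ldd_rate=0.2)
        with pytest.raises(ValueError):
            ScenarioConfig(decline_end_gen=200)  # before the fixed onset 222

    def test_draw_within_priors(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            # construction re-validates every drawn rate against the priors
            sc = ScenarioConfig.draw(rng, decline_targets={"farmer"})
            assert 230 <= sc.decline_end_gen <= 315


class TestRunForward:
    def test_pastoralists_absent_before_onset(self, toy_record):
        onset = toy_record.scenario.pastoralist_onset_gen
        assert toy_record.N[:onset, PASTORALIST].sum() == 0.0
        assert toy_record.N[onset, PASTORALIST].sum() > 0

    def test_water_source_rejected(self):
        mask = np.ones((4, 4), dtype=bool)
        mask[0, 0] = False
        grid = build_grid(mask)
        sc = ScenarioConfig(farmer_source=DemeIndex(0, 0),
                            pastoralist_source=DemeIndex(3, 3),
                            pastoralist_onset_gen=5, n_generations=10)
        with pytest.raises(ValueError, match="source"):
            run_forward(sc, grid)

    def test_one_deme_world_matches_scalar_recursion(self):
        """On a single deme the full engine reduces to the scalar logistic
        recursion, checked exactly over all 400 generations."""
        grid = build_grid(np.ones((1, 1), dtype=bool))
        sc = ScenarioConfig(
            K_F=1000, r_F=0.62, K_P=1500, r_P=0.55, gamma_admix=0.0, ldd_rate=0.0,
            farmer_source=DemeIndex(0, 0), pastoralist_source=DemeIndex(0, 0),
            n_generations=400, seed=0,
        )
        rec = run_forward(sc, grid, rng=np.random.default_rng(0))
        N = 1000.0
        for t in range(1, 401):
            N = max(N * (1 + 0.62 * (1 - N / 1000)), 0.0)
            assert rec.N[t, FARMER, 0] == pytest.approx(N, rel=1e-6)
        N = 1500.0
        for t in range(177, 401):
            N = max(N * (1 + 0.55 * (1 - N / 1500)), 0.0)
            assert rec.N[t, PASTORALIST, 0] == pytest.approx(N, rel=1e-6)

    def test_front_advances_at_most_one_deme_per_generation(self):
        grid = build_grid(np.ones((9, 9), dtype=bool))
        sc = ScenarioConfig(ldd_rate=0.0, gamma_admix=0.001,
                            farmer_source=DemeIndex(0, 0),
                            pastoralist_source=DemeIndex(4, 4),
                            pastoralist_onset_gen=5, n_generations=20, seed=1)
        rec = run_forward(sc, grid, rng=np.random.default_rng(1))
        for t in range(5, 21):
            occ = np.nonzero(rec.N[t, PASTORALIST] >= 1)[0]
            d = np.abs(grid.land_cols[occ] - 4) + np.abs(grid.land_rows[occ] - 4)
            # the onset generation's own update already moves migrants once
            assert d.max(initial=0) <= t - 5 + 1

    def test_layer_exchangeability_under_relabel(self):
        """With competition on and identical (r, K, m), swapping the layer
        roles and sources leaves the ensemble dynamics unchanged."""
        grid = build_grid(np.ones((6, 6), dtype=bool))
        common = dict(r_F=0.6, r_P=0.6, K_F=3000, K_P=3000, m_F=0.5, m_P=0.5,
                      gamma_admix=0.0, ldd_rate=0.0, competition_on=True,
                      pastoralist_onset_gen=0, n_generations=40)
        a = ScenarioConfig(farmer_source=DemeIndex(0, 0),
                           pastoralist_source=DemeIndex(5, 5), **common)
        b = ScenarioConfig(farmer_source=DemeIndex(5, 5),
                           pastoralist_source=DemeIndex(0, 0), **common)
        tot_a = np.mean([run_forward(a, grid, rng=np.random.default_rng(s),
                                     record_flows=False).N[40, FARMER].sum()
                         for s in range(10)])
        tot_b = np.mean([run_forward(b, grid, rng=np.random.default_rng(s),
                                     record_flows=False).N[40, PASTORALIST].sum()
                         for s in range(10)])
        assert tot_a == pytest.approx(tot_b, rel=0.05)

    def test_wavefront_speed_increases_with_migration(self):
        grid = build_grid(np.ones((15, 15), dtype=bool))
        reach = {}
        for m in (0.4, 0.8):
            occs = []
            for s in range(10):
                sc = ScenarioConfig(m_F=m, m_P=m, ldd_rate=0.0, gamma_admix=0.0,
                                    K_F=3000, K_P=3000,
                                    farmer_source=DemeIndex(0, 0),
                                    pastoralist_source=DemeIndex(14, 14),
                                    pastoralist_onset_gen=24, n_generations=25)
                rec = run_forward(sc, grid, rng=np.random.default_rng(s),
                                  record_flows=False)
                occs.append((rec.N[25, FARMER] >= 1).sum())
            reach[m] = np.mean(occs)
        assert reach[0.8] > reach[0.4]
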