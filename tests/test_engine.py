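"""Brownian engine: increments, collisions, binding, turnover, conservation."""

import numpy as np
import pytest

from morphograd import engine, synthetic
from morphograd.config import ConfigError, SimulationConfig
from morphograd.engine import (BounceCapError, brownian_step,
                               move_with_collisions, run, seed_ligands)
from morphograd.geometry import build_geometry, open_box_geometry, CAVITY


class TestBrownianStep:
    def test_second_moment_is_cDh(self):
        # <|Gamma|^2> = c*D*h = 4 * 20 * 0.003 = 0.24 um^2 in 2D
        rng = np.random.default_rng(0)
        g = brownian_step(rng, dim=2, D=20.0, h=0.003, n=1_000_000)
        sq = (g ** 2).sum(axis=1)
        se = sq.std(ddof=1) / np.sqrt(len(sq))
        assert abs(sq.mean() - 0.24) < 4 * se

    def test_zero_mean_and_no_lag_correlation(self):
        rng = np.random.default_rng(1)
        g = brownian_step(rng, dim=2, D=20.0, h=0.003, n=1_000_000)
        se = g.std(ddof=1) / np.sqrt(len(g))
        assert np.all(np.abs(g.mean(axis=0)) < 4 * se)
        # successive draws are independent (delta_tt' constraint)
        r = np.corrcoef(g[:-1, 0], g[1:, 0])[0, 1]
        assert abs(r) < 4 / np.sqrt(len(g))

    def test_3d_moment(self):
        rng = np.random.default_rng(2)
        g = brownian_step(rng, dim=3, D=20.0, h=0.003, n=200_000)
        sq = (g ** 2).sum(axis=1)
        se = sq.std(ddof=1) / np.sqrt(len(sq))
        assert abs(sq.mean() - 6 * 20 * 0.003) < 4 * se

    def test_rejects_bad_parameters(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            brownian_step(rng, dim=2, D=-1.0, h=0.003)
        with pytest.raises(ValueError):
            brownian_step(rng, dim=4, D=20.0, h=0.003)


class TestSeeding:
    def test_apical_seeding_starts_in_cavity(self):
        geom = build_geometry(SimulationConfig())
        pos, t_ent, in_cav, origin = seed_ligands(
            geom, "apical", 1000, np.random.default_rng(0))
        assert np.all(geom.classify_points(pos[:, :2]) == CAVITY)
        assert np.all(t_ent == -1.0)
        assert np.all(in_cav == 1)
        # ligands originate from ExE cells only
        assert set(origin) <= {c.index for c in geom.exe_cells()}

    def test_basolateral_seeding_stamps_entry(self):
        geom = build_geometry(SimulationConfig())
        pos, t_ent, in_cav, _ = seed_ligands(
            geom, "basolateral", 500, np.random.default_rng(0))
        assert np.all(t_ent == 0.0)
        assert np.all(in_cav == 0)
        assert np.all(pos[:, 1] < geom.basal_y)

    def test_uniform_cavity_mean_is_centroid(self):
        geom = build_geometry(SimulationConfig())
        pos, _, _, _ = seed_ligands(
            geom, "uniform_cavity", 10_000, np.random.default_rng(0))
        cx, cy = geom.width / 2, (geom.apical_y + geom.height) / 2
        se_x = geom.width / np.sqrt(12 * 10_000)
        se_y = (geom.height - geom.apical_y) / np.sqrt(12 * 10_000)
        assert abs(pos[:, 0].mean() - cx) < 4 * se_x
        assert abs(pos[:, 1].mean() - cy) < 4 * se_y

    def test_zero_ligands_rejected(self):
        geom = build_geometry(SimulationConfig())
        with pytest.raises(ValueError):
            seed_ligands(geom, "apical", 0, np.random.default_rng(0))

    def test_secretion_needs_exe(self):
        from morphograd.presets import get_preset
        geom = build_geometry(get_preset("hesc_colony").with_(n_arrays=1))
        with pytest.raises(ConfigError):
            seed_ligands(geom, "apical", 10, np.random.default_rng(0))


class TestMoveWithCollisions:
    def test_free_move_without_surfaces(self):
        box = open_box_geometry(100.0, 100.0)
        out, new, pool = move_with_collisions(box, (50.0, 50.0), (1.0, -2.0))
        assert out == "free"
        assert new == pytest.approx([51.0, 48.0])
        assert pool == -1

    def test_reflection_at_wall(self):
        box = open_box_geometry(100.0, 100.0)
        out, new, _ = move_with_collisions(box, (99.0, 50.0), (2.0, 0.0))
        assert out == "free"
        assert new[0] == pytest.approx(99.0, abs=1e-5)

    def test_certain_binding_on_first_contact(self):
        geom = build_geometry(SimulationConfig())
        # aim at the basal membrane of the first epiblast column
        epi = geom.epiblast_cells()[0]
        x = (epi.x_lo + epi.x_hi) / 2
        out, new, pool = move_with_collisions(
            geom, (x, 1.0), (0.0, 2.0), P_binding=1.0)
        assert out == "bound"
        assert geom.pool_face[pool] == "basal"
        assert int(geom.pool_cell[pool]) == epi.index

    def test_zero_binding_reflects_like_barrier(self):
        geom = build_geometry(SimulationConfig())
        epi = geom.epiblast_cells()[0]
        x = (epi.x_lo + epi.x_hi) / 2
        out, new, _ = move_with_collisions(
            geom, (x, 1.0), (0.0, 2.0), P_binding=0.0)
        assert out == "free"
        assert new[1] < geom.basal_y  # reflected back into the interstitium


class TestRunContracts:
    def test_same_seed_bitwise_identical(self):
        cfg = SimulationConfig(n_ligands=50, duration=60.0,
                               snapshot_interval=30.0, n_replicates=2, seed=3)
        a = run(cfg)
        b = run(cfg)
        for ra, rb in zip(a.replicates, b.replicates):
            assert np.array_equal(ra.positions, rb.positions)
            assert ra.events.equals(rb.events)

    def test_replicates_use_distinct_seeds(self):
        cfg = SimulationConfig(n_ligands=50, duration=30.0,
                               snapshot_interval=15.0, n_replicates=3, seed=3)
        res = run(cfg)
        assert [r.seed for r in res.replicates] == [3, 4, 5]
        assert not np.array_equal(res.replicates[0].positions,
                                  res.replicates[1].positions)

    def test_default_snapshot_schedule_has_twelve_frames(self):
        cfg = SimulationConfig(n_ligands=10, duration=5400.0, h=0.05,
                               snapshot_interval=450.0, P_binding=0.0)
        res = run(cfg, n_replicates=1)
        assert len(res.times) == 12
        assert res.times[0] == pytest.approx(450.0)
        assert res.times[-1] == pytest.approx(5400.0)

    def test_containment_every_snapshot(self, gradient_result):
        geom = gradient_result.geometry
        for rep in gradient_result.replicates:
            for k in range(len(rep.times)):
                pos = rep.free_positions(k, geom.dim)
                lab = geom.classify_points(pos)
                assert not np.any(np.isin(lab, (4, 5)))  # inside_cell/outside

    def test_bound_ligands_match_pool_counters(self, gradient_result):
        for rep in gradient_result.replicates:
            for k in range(len(rep.times)):
                assert (rep.status[k] == 1).sum() == rep.pool_bound[k].sum()


class TestTurnover:
    def _quick_bind_config(self, variant):
        # P_binding=1 with basolateral seeding binds essentially at t=0,
        # making turnover times observable
        return SimulationConfig(n_ligands=40, duration=30.0, T_t=10.0,
                                P_binding=1.0, snapshot_interval=5.0,
                                turnover_variant=variant, seed=11)

    def test_pairs_dissolve_exactly_at_Tt(self):
        cfg = self._quick_bind_config("constant_total")
        res = run(cfg, n_replicates=1)
        ev = res.replicates[0].events
        binds = ev[ev["event"] == "bind"]
        unbinds = ev[ev["event"] == "unbind"]
        assert len(unbinds) > 0
        for _, u in unbinds.iterrows():
            # a ligand can bind repeatedly; each release pairs with the
            # latest preceding bind of that ligand
            mine = binds[(binds["ligand_id"] == u["ligand_id"])
                         & (binds["t"] <= u["t"])]
            t_bind = mine["t"].max()
            # dissolved at the first step whose clock reaches t_bind + T_t
            assert u["t"] - t_bind >= cfg.T_t
            assert u["t"] - t_bind < cfg.T_t + 2 * cfg.h

    def test_constant_total_conserves_ligand_count(self):
        cfg = self._quick_bind_config("constant_total")
        res = run(cfg, n_replicates=1)
        assert np.all(res.replicates[0].n_active == cfg.n_ligands)

    def test_decreasing_is_monotone_nonincreasing(self):
        cfg = self._quick_bind_config("decreasing")
        res = run(cfg, n_replicates=1)
        n = res.replicates[0].n_active
        assert np.all(np.diff(n) <= 0)
        assert n[-1] < cfg.n_ligands  # some ligands were cleared

    def test_increasing_adds_at_rate_n_over_Tt(self):
        cfg = self._quick_bind_config("increasing")
        res = run(cfg, n_replicates=1)
        n = res.replicates[0].n_active
        assert np.all(np.diff(n) >= 0)
        # influx rate n_ligands / T_t = 4 ligands/s over 30 s
        expected = cfg.n_ligands + cfg.n_ligands / cfg.T_t * cfg.duration
        assert n[-1] == pytest.approx(expected, abs=2)

    def test_resecretion_returns_to_origin_face(self):
        cfg = self._quick_bind_config("constant_total")
        res = run(cfg, n_replicates=1)
        geom = res.geometry
        # after release the ligand re-enters from the ExE basal side and is
        # free again somewhere in the basolateral compartments
        rep = res.replicates[0]
        assert (rep.events["event"] == "unbind").sum() > 0
        final_free = rep.free_positions(-1, geom.dim)
        assert len(final_free) > 0


class TestDiffusionLaw:
    def test_msd_matches_cDt(self, msd_run):
        res, start, times = msd_run
        cfg = res.config
        rep = res.replicates[0]
        disp = rep.positions[:, :, :2] - start[None, :, :]
        sq = (disp ** 2).sum(axis=2)
        # per-ligand slope estimate at the final time; ensemble mean must
        # agree with c*D within 3 standard errors
        slopes = sq[-1] / times[-1]
        se = slopes.std(ddof=1) / np.sqrt(len(slopes))
        assert abs(slopes.mean() - cfg.c * cfg.D) < 3 * se
        # and the MSD curve is linear through the origin: early-time slope
        # agrees too
        early = sq[0] / times[0]
        se0 = early.std(ddof=1) / np.sqrt(len(early))
        assert abs(early.mean() - cfg.c * cfg.D) < 3 * se0

    def test_open_box_reaches_uniform_density(self):
        # small box mixes fast; chi-square test on a 10-bin histogram
        from scipy import stats
        cfg, geom = synthetic.open_box_config(size=20.0, n_ligands=100_000,
                                              duration=5.0, h=0.010)
        start = np.full((100_000, 2), 10.0)
        res = engine.run(cfg, geometry=geom, snapshot_times=[5.0],
                         initial_positions=start, n_replicates=1)
        x = res.replicates[0].positions[-1, :, 0]
        counts, _ = np.histogram(x, bins=10, range=(0.0, 20.0))
        p = stats.chisquare(counts).pvalue
        assert p > 0.01

    def test_zero_ligand_run_is_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(n_ligands=0)


class TestInsulation:
    def test_sealed_channel_keeps_apical_ligands_out(self):
        cfg = SimulationConfig(n_ligands=100, duration=300.0, P_binding=0.0,
                               secretion_mode="apical",
                               snapshot_interval=150.0, seed=5)
        geom = build_geometry(cfg).seal_channels()
        res = run(cfg, geometry=geom, n_replicates=2)
        for rep in res.replicates:
            assert (rep.events["event"] == "cross").sum() == 0
            # every ligand still strictly above the apical plane region
            for k in range(len(rep.times)):
                assert np.all(rep.positions[k, :, 1] > geom.apical_y - 1e-9)


class TestGradient:
    def test_bound_fraction_decreases_with_distance_bins(self, gradient_result):
        from morphograd.observables import occupancy_profile
        prof = occupancy_profile(gradient_result, 1800.0)
        near = np.mean([prof.by_d_edge[k] for k in (1, 2)])
        mid = np.mean([prof.by_d_edge[k] for k in range(3, 7)])
        far = np.mean([prof.by_d_edge[k] for k in range(7, 21)])
        assert near > mid > far


class TestEctopicAccess:
    @pytest.mark.parametrize("condition", ["tenfold_apical_receptors",
                                           "tenfold_no_junctions"])
    def test_mislocalization_gives_interior_cells_ectopic_occupancy(
            self, robustness_results, condition):
        """With basolateral receptors and junctions intact, tissue-interior
        cells (d_edge 7-20) stay nearly unoccupied even at a tenfold
        source; mis-localizing receptors apically or removing junctions
        exposes those same cells to the cavity ligand pool and their
        occupancy jumps by an order of magnitude (ectopic signaling)."""
        from morphograd.observables import occupancy_profile
        interior = lambda prof: np.mean(
            [prof.by_d_edge[k] for k in range(7, 21)])
        buffered = interior(occupancy_profile(
            robustness_results["tenfold"], 5400.0))
        exposed = interior(occupancy_profile(
            robustness_results[condition], 5400.0))
        assert exposed > 0.4
        assert exposed > 5 * buffered
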