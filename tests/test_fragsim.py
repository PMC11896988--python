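import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ivimon.fragsim import (SimConfig, arm_acceptance,
                            carbon_pbc, emit_fragments, highland_sigma,
                            highland_sigma_path, propagate_to_trackers,
                            proton_energy_from_range, proton_pbc, read_run,
                            sample_fragmentation_vertices, simulate_delivery,
                            simulate_spot, write_run)
from ivimon.motion import LujanParams, position
from ivimon.phantom import AIR, Material, PhantomGeometry
from ivimon.plan import BeamSpot, delivery_timeline

VACUUM = Material("vacuum", 1e-12, 0.0, 1e12)


def vacuum_geometry() -> PhantomGeometry:
    return PhantomGeometry().with_materials(
        wall_material=VACUUM, foam_material=VACUUM, insert_material=VACUUM,
        outside_material=AIR)


def uniform_geometry(density: float) -> PhantomGeometry:
    mat = Material("uniform", density, density, 1e9)
    return PhantomGeometry().with_materials(
        wall_material=mat, foam_material=mat, insert_material=mat)


def central_spot(range_model, wepl=57.8, n=10_000, x=0.0, y=0.0):
    e = float(range_model.range_to_energy(wepl))
    return BeamSpot(0, 0, e, x, y, 0.0, n)


class TestHighland:
    def test_unit_point(self):
        # 13.6/13.6 * 1 * sqrt(1) * (1 + 0) = 1 rad
        assert highland_sigma(13.6, 1, 1.0) == pytest.approx(1.0, abs=1e-12)

    def test_limit_zero(self):
        assert highland_sigma(100.0, 1, 0.0) == 0.0
        assert highland_sigma(100.0, 1, 1e-12) < 1e-4

    def test_150mev_proton(self):
        # independent kinematics oracle
        t, m = 150.0, 938.272
        pc = np.sqrt(t * t + 2 * t * m)
        beta = pc / (t + m)
        pbc = pc * beta
        x = 0.01
        expect = 13.6 / pbc * np.sqrt(x) * (1 + 0.038 * np.log(x))
        got = highland_sigma(proton_pbc(150.0), 1, x)
        assert got == pytest.approx(expect, rel=1e-12)
        assert got == pytest.approx(4.0e-3, rel=0.02)

    def test_path_split_invariance(self):
        # quadrature additivity over split layers (total-log convention)
        whole = highland_sigma_path(200.0, 1, [0.05])
        split = highland_sigma_path(200.0, 1, [0.02, 0.02, 0.01])
        assert abs(whole - split) < 1e-9

    def test_path_quadrature_sum(self):
        xs = [0.01, 0.03]
        total = sum(xs)
        br = 1 + 0.038 * np.log(total)
        expect = np.sqrt(sum((13.6 / 200.0) ** 2 * x * br ** 2 for x in xs))
        assert highland_sigma_path(200.0, 1, xs) == pytest.approx(expect,
                                                                  rel=1e-12)

    def test_invalid(self):
        with pytest.raises(ValueError):
            highland_sigma(200.0, 1, -0.1)
        with pytest.raises(ValueError):
            highland_sigma(0.0, 1, 0.1)

    def test_carbon_pbc_scales(self):
        assert carbon_pbc(200.0) > carbon_pbc(100.0)

    def test_proton_range_energy(self):
        # 150 MeV proton has ~15-16 cm water range
        assert proton_energy_from_range(155.0) == pytest.approx(150.0,
                                                                rel=0.05)


class TestVertexSampling:
    def test_zero_density_no_vertices(self, scanner, range_model):
        geom = vacuum_geometry()
        spot = central_spot(range_model)
        df = sample_fragmentation_vertices(geom, range_model, spot, scanner,
                                           seed=0)
        assert len(df) == 0

    def test_density_scaling(self, scanner, range_model):
        # Poisson-expectation oracle: in a thin front slab the expected
        # vertex count is n * rho * L / lambda; doubling rho doubles it.
        cfg = SimConfig(beam_sigma_mm=0.0)
        spot = central_spot(range_model, wepl=80.0, n=100_000)
        counts = {}
        for rho in (0.1, 0.2):
            geom = uniform_geometry(rho)
            df = sample_fragmentation_vertices(geom, range_model, spot,
                                               scanner, seed=1, cfg=cfg)
            counts[rho] = np.sum(df["z_mm"] < -110.0)  # first 20 mm
        n, lam = 100_000, cfg.lambda_w_mm
        for rho in (0.1, 0.2):
            expect = n * rho * 20.0 / lam
            assert counts[rho] == pytest.approx(expect,
                                                abs=3 * np.sqrt(expect))

    def test_no_vertices_beyond_stopping_depth(self, geom, scanner,
                                               range_model):
        spot = central_spot(range_model, n=20_000)
        df = sample_fragmentation_vertices(geom, range_model, spot, scanner,
                                           seed=2,
                                           cfg=SimConfig(beam_sigma_mm=0.0))
        # central ray stops at z = 0 (57.8 mm WEPL)
        assert df["z_mm"].max() <= 0.5

    def test_offset_shifts_vertices_downstream(self, geom, scanner,
                                               range_model):
        # foam corridor at 20 mm offset -> fragments produced at larger z
        spot = central_spot(range_model, n=30_000, y=-22.0)
        cfg = SimConfig(beam_sigma_mm=0.0)
        z90 = {}
        for off in (0.0, 20.0):
            df = sample_fragmentation_vertices(geom, range_model, spot,
                                               scanner, offset=off, seed=3,
                                               cfg=cfg)
            z90[off] = np.percentile(df["z_mm"], 90)
        assert z90[20.0] > z90[0.0] + 5.0

    def test_reproducible(self, geom, scanner, range_model):
        spot = central_spot(range_model, n=5_000)
        a = sample_fragmentation_vertices(geom, range_model, spot, scanner,
                                          seed=7)
        b = sample_fragmentation_vertices(geom, range_model, spot, scanner,
                                          seed=7)
        pd.testing.assert_frame_equal(a, b)


class TestEmitFragments:
    def test_zero_sigma_collinear(self, rng):
        cfg = SimConfig(frag_angle_sigma=0.0, fragments_per_vertex=4)
        vid, sx, sy, fr = emit_fragments(np.zeros((10, 3)), (0.01, -0.02),
                                         np.full(10, 30.0), cfg, rng)
        assert np.all(sx == 0.01) and np.all(sy == -0.02)
        assert np.all(fr == 30.0 * cfg.frag_range_multiplier)
        assert vid.tolist() == np.repeat(np.arange(10), 4).tolist()

    def test_polar_angle_distribution(self, rng):
        # distributional oracle: transverse-slope Gaussian => polar angle
        # Rayleigh(sigma); KS test at n = 10^4
        sigma = 0.08
        cfg = SimConfig(frag_angle_sigma=sigma, fragments_per_vertex=1)
        vid, sx, sy, _ = emit_fragments(np.zeros((10_000, 3)), (0.0, 0.0),
                                        np.ones(10_000), cfg, rng)
        polar = np.hypot(sx, sy)
        ks = stats.kstest(polar, stats.rayleigh(scale=sigma).cdf)
        assert ks.pvalue > 0.01

    def test_mean_polar_exceeds_beam_divergence(self, rng):
        cfg = SimConfig()
        vid, sx, sy, _ = emit_fragments(np.zeros((5_000, 3)), (0.0, 0.0),
                                        np.ones(5_000), cfg, rng)
        beam_divergence = 25.0 / 7534.0  # max planned slope
        assert np.hypot(sx, sy).mean() > beam_divergence

    def test_range_exceeds_residual(self, rng):
        cfg = SimConfig()
        _, _, _, fr = emit_fragments(np.zeros((100, 3)), (0, 0),
                                     np.full(100, 10.0), cfg, rng)
        assert np.all(fr >= 10.0)


class TestPropagate:
    def test_noiseless_collinear_clusters(self, tracker):
        geom = vacuum_geometry()
        cfg = SimConfig(scattering=False, smearing=False,
                        prefilter_margin_mm=None)
        a = np.deg2rad(10.5)
        sx = np.tan(a)
        start = np.zeros((1, 3))
        det, us, vs, arms = propagate_to_trackers(
            geom, tracker, start, np.array([sx]), np.array([0.0]),
            np.array([1e4]), np.zeros(1), cfg, np.random.default_rng(0))
        assert det.tolist() == [0]
        assert arms[0] == 2  # the +10.5 deg arm
        np.testing.assert_allclose(us[0], 0.0, atol=1e-9)
        np.testing.assert_allclose(vs[0], 0.0, atol=1e-9)

    def test_stopped_fragment_not_detected(self, geom, tracker):
        cfg = SimConfig(scattering=False, smearing=False,
                        prefilter_margin_mm=None)
        a = np.deg2rad(10.5)
        det, *_ = propagate_to_trackers(
            geom, tracker, np.zeros((1, 3)), np.array([np.tan(a)]),
            np.array([0.0]), np.array([5.0]), np.zeros(1), cfg,
            np.random.default_rng(0))
        assert det.size == 0

    def test_solid_angle_matches_analytic(self, tracker):
        # MC isotropic source at the isocenter vs the rectangle solid angle
        # of the limiting (farthest) sensor of each of the 4 arms
        rng = np.random.default_rng(42)
        n = 2_000_000
        u = rng.uniform(-1, 1, n)
        phi = rng.uniform(0, 2 * np.pi, n)
        s = np.sqrt(1 - u * u)
        dirs = np.stack([s * np.cos(phi), s * np.sin(phi), u], axis=1)
        aid, _, _ = arm_acceptance(tracker, np.zeros((n, 3)), dirs)
        frac = np.mean(aid >= 0)
        d = tracker.sensor_distance(tracker.sensors_per_arm - 1)
        hu, hv = tracker.half_u, tracker.half_v
        omega = 4 * np.arctan(hu * hv / (d * np.sqrt(d * d + hu * hu
                                                     + hv * hv)))
        expect = tracker.n_arms * omega / (4 * np.pi)
        sigma = np.sqrt(expect * (1 - expect) / n)
        assert frac == pytest.approx(expect, abs=3 * sigma)

    def test_prefilter_preserves_noiseless_detections(self, geom, tracker,
                                                      rng):
        cfg_all = SimConfig(scattering=False, smearing=False,
                            prefilter_margin_mm=None)
        cfg_pre = SimConfig(scattering=False, smearing=False,
                            prefilter_margin_mm=10.0)
        m = 20_000
        sx = rng.normal(0, 0.15, m)
        sy = rng.normal(0, 0.15, m)
        start = np.tile(np.array([0.0, 0.0, -30.0]), (m, 1))
        franges = np.full(m, 500.0)
        det_a, *_ = propagate_to_trackers(geom, tracker, start, sx, sy,
                                          franges, np.zeros(m), cfg_all,
                                          np.random.default_rng(1))
        det_b, *_ = propagate_to_trackers(geom, tracker, start, sx, sy,
                                          franges, np.zeros(m), cfg_pre,
                                          np.random.default_rng(1))
        assert det_a.tolist() == det_b.tolist()


class TestSimulateSpot:
    def test_seed_determinism(self, geom, tracker, scanner, range_model):
        spot = central_spot(range_model, n=5_000)
        cfg = SimConfig()
        out = []
        for _ in range(2):
            rng = np.random.default_rng(99)
            cl, tv, summ = simulate_spot(geom, tracker, scanner, range_model,
                                         spot, 0.0, 0.005,
                                         lambda t: np.zeros_like(t), cfg, rng)
            out.append((cl, tv, summ))
        pd.testing.assert_frame_equal(out[0][0], out[1][0])
        pd.testing.assert_frame_equal(out[0][1], out[1][1])
        assert out[0][2] == out[1][2]

    def test_detected_fraction_rises_with_energy(self, geom, tracker, scanner,
                                                 range_model,
                                                 study_sim_config):
        fracs = []
        for wepl in (35.0, 80.0):
            spot = central_spot(range_model, wepl=wepl, n=20_000)
            rng = np.random.default_rng(5)
            _, _, summ = simulate_spot(geom, tracker, scanner, range_model,
                                       spot, 0.0, 0.02,
                                       lambda t: np.zeros_like(t),
                                       study_sim_config, rng)
            fracs.append(summ["n_detected"] / summ["n_ions"])
        assert fracs[1] > fracs[0]

    def test_overshoot_excess_beyond_static_edge(self, geom, tracker, scanner,
                                                 range_model,
                                                 study_sim_config):
        # static_out vertex z distribution extends beyond the static_in
        # distal edge for central spots (overshoot property)
        spot = central_spot(range_model, n=20_000)
        qs = {}
        for off in (0.0, 20.0):
            rng = np.random.default_rng(17)
            _, tv, _ = simulate_spot(geom, tracker, scanner, range_model,
                                     spot, 0.0, 0.02,
                                     lambda t: np.full_like(t, off),
                                     study_sim_config, rng)
            qs[off] = np.percentile(tv["z_mm"], 99)
        assert qs[20.0] > qs[0.0] + 3.0

    def test_max_ions_cap(self, geom, tracker, scanner, range_model):
        spot = central_spot(range_model, n=50_000)
        cfg = SimConfig(max_ions_per_spot=1_000)
        rng = np.random.default_rng(0)
        _, _, summ = simulate_spot(geom, tracker, scanner, range_model, spot,
                                   0.0, 0.05, lambda t: np.zeros_like(t), cfg,
                                   rng)
        assert summ["n_ions"] == 1_000
        assert summ["ion_scale"] == pytest.approx(50.0)


@pytest.fixture(scope="module")
def small_setup():
    spots = [BeamSpot(i, 0, 160.0, 4.0 * (i - 1), 0.0, 0.0, 2_000)
             for i in range(3)]
    tl = delivery_timeline(spots, 1e6, inter_spot_gap=0.4)
    cfg = SimConfig()
    lujan = LujanParams()
    return spots, tl, cfg, lujan


class TestSimulateDelivery:
    def test_static_truth_offsets(self, geom, tracker, scanner, range_model,
                                  small_setup):
        spots, tl, cfg, lujan = small_setup
        b_in = simulate_delivery(geom, tracker, scanner, range_model, spots,
                                 tl, "static_in", lujan, cfg, seed=1)
        assert np.all(b_in.truth_spots["offset_mid"] == 0.0)
        b_out = simulate_delivery(geom, tracker, scanner, range_model, spots,
                                  tl, "static_out", lujan, cfg, seed=1)
        assert np.all(b_out.truth_spots["offset_mid"] == 20.0)

    def test_moving_offsets_match_motor_log(self, geom, tracker, scanner,
                                            range_model, small_setup):
        spots, tl, cfg, lujan = small_setup
        b = simulate_delivery(geom, tracker, scanner, range_model, spots, tl,
                              "moving", lujan, cfg, seed=2)
        for _, row in b.truth_spots.iterrows():
            interp = b.motor.interp(row["t_mid"])
            assert row["offset_mid"] == pytest.approx(interp, abs=1e-4)
            assert row["offset_mid"] == pytest.approx(
                position(row["t_mid"], lujan), abs=1e-12)

    def test_fpga_next_spot_count(self, geom, tracker, scanner, range_model,
                                  small_setup):
        spots, tl, cfg, lujan = small_setup
        b = simulate_delivery(geom, tracker, scanner, range_model, spots, tl,
                              "static_in", lujan, cfg, seed=3)
        assert b.fpga.count("next_spot") == len(b.spot_log)

    def test_bit_identical_rerun_and_io_round_trip(self, geom, tracker,
                                                   scanner, range_model,
                                                   small_setup, tmp_path):
        spots, tl, cfg, lujan = small_setup
        b1 = simulate_delivery(geom, tracker, scanner, range_model, spots, tl,
                               "moving", lujan, cfg, seed=4)
        b2 = simulate_delivery(geom, tracker, scanner, range_model, spots, tl,
                               "moving", lujan, cfg, seed=4)
        pd.testing.assert_frame_equal(b1.clusters, b2.clusters)
        pd.testing.assert_frame_equal(b1.spot_log, b2.spot_log)
        pd.testing.assert_frame_equal(b1.truth_vertices, b2.truth_vertices)
        assert np.array_equal(b1.motor.positions, b2.motor.positions)
        write_run(b1, tmp_path / "run")
        back = read_run(tmp_path / "run")
        assert back.case == "moving" and back.seed == 4
        assert len(back.clusters) == len(b1.clusters)
        assert back.motor == b1.motor
        np.testing.assert_allclose(back.spot_log["x_i"], b1.spot_log["x_i"])

    def test_unknown_case(self, geom, tracker, scanner, range_model,
                          small_setup):
        spots, tl, cfg, lujan = small_setup
        with pytest.raises(ValueError):
            simulate_delivery(geom, tracker, scanner, range_model, spots, tl,
                              "wiggling", lujan, cfg, seed=0)
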