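"""Wake-plane operators: vorticity, masking, reconstruction, integrals."""

import numpy as np
import pytest

from flightpower.exceptions import InsufficientDataError, InvalidInputError, ShapeError
from flightpower.synth import gen_vortex_wake
from flightpower.wake import (
    SequenceResult,
    WakePlaneSeries,
    drag_corrected_power,
    homogenize_background,
    kinetic_power,
    mask_wake,
    mirror_half_wake,
    net_drag,
    process_sequence,
    reconstruct_flow,
    select_sequences,
    streamwise_vorticity,
    vertical_force,
)

RHO = 1.2


def make_series(u=None, v=None, w=None, n=41, extent=0.2, n_frames=4,
                u_inf=6.0, f_wb=10.0, frame_rate=40.0):
    """Small hand-built series; velocity arguments are (y, z) field callables."""
    y = np.linspace(-extent, extent, n)
    z = np.linspace(-extent, extent, n)
    yy, zz = np.meshgrid(y, z, indexing="ij")
    zero = np.zeros_like(yy)
    fields = []
    for fld in (u, v, w):
        grid = zero if fld is None else fld(yy, zz)
        fields.append(np.broadcast_to(grid, (n_frames, n, n)).copy())
    return WakePlaneSeries(
        y_coords=y, z_coords=z, timestamps=np.arange(n_frames) / frame_rate,
        u=fields[0], v=fields[1], w=fields[2],
        freestream=np.full_like(yy, u_inf), wingbeat_freq=f_wb)


class TestVorticity:
    def test_solid_body_rotation_is_twice_omega(self):
        om = 3.0
        s = make_series(v=lambda y, z: -om * z, w=lambda y, z: om * y)
        wx = streamwise_vorticity(s, 0)
        assert np.allclose(wx[1:-1, 1:-1], 2 * om, atol=1e-10)

    def test_zero_flow_gives_zero_field(self):
        s = make_series()
        assert np.all(streamwise_vorticity(s, 0) == 0)

    def test_gaussian_vortex_circulation_recovered(self):
        series, truth = gen_vortex_wake(gamma=0.05, noise_sd=0.0, n_frames=2, seed=0)
        wx = streamwise_vorticity(series, 0)
        # positive-circulation core only (y > 0 half)
        half = wx[series.y_coords > 0, :]
        circ = half.sum() * series.dy * series.dz
        assert circ == pytest.approx(truth.params["circulation"], rel=0.005)

    def test_too_coarse_grid_rejected(self):
        y = np.array([0.0, 0.1])
        s = WakePlaneSeries(y_coords=y, z_coords=y, timestamps=np.array([0.0]),
                            u=np.zeros((1, 2, 2)), v=np.zeros((1, 2, 2)),
                            w=np.zeros((1, 2, 2)), freestream=np.ones((2, 2)),
                            wingbeat_freq=10.0)
        with pytest.raises(Exception):
            streamwise_vorticity(s, 0)


class TestHomogenize:
    def test_uniform_background_is_untouched(self):
        s = make_series(u=lambda y, z: np.zeros_like(y))
        out = homogenize_background([s])[0]
        assert np.allclose(out.u, s.u, atol=1e-12)

    def test_imposed_shear_removed(self):
        shear = lambda y, z: 0.5 * y  # linear background distortion
        s = make_series(u=shear)
        out = homogenize_background([s])[0]
        residual = out.u[0] - out.u[0].mean()
        imposed = shear(*np.meshgrid(s.y_coords, s.z_coords, indexing="ij"))
        assert np.abs(residual).max() < 0.01 * np.abs(imposed).max()

    def test_mean_freestream_preserved(self):
        s = make_series(u=lambda y, z: 0.3 * y + 0.1)
        out = homogenize_background([s])[0]
        assert out.u.mean() == pytest.approx(s.u.mean(), abs=1e-12)

    def test_idempotent(self):
        s = make_series(u=lambda y, z: 0.5 * y + 0.2 * z**2)
        once = homogenize_background([s])[0]
        twice = homogenize_background([once])[0]
        assert np.allclose(twice.u, once.u, atol=1e-9)

    def test_mismatched_grids_rejected(self):
        a = make_series(n=41)
        b = make_series(n=31)
        with pytest.raises(ShapeError):
            homogenize_background([a, b])


class TestMask:
    def test_zero_threshold_masks_everything(self):
        s = make_series()
        assert mask_wake(s, threshold=0.0).mask.all()

    def test_threshold_above_max_gives_empty_mask_and_zero_power(self):
        series, _ = gen_vortex_wake(n_frames=20, seed=0)
        masks = mask_wake(series, threshold=1e9)
        assert not masks.mask.any()
        assert kinetic_power(series, masks, air_density=RHO) == 0.0

    def test_mask_keeps_circulation_and_rejects_noise(self):
        clean, truth = gen_vortex_wake(n_frames=2, wingbeat_freq=100.0,
                                       noise_sd=0.0, seed=3)
        peak = np.abs(clean.v).max()
        noisy, _ = gen_vortex_wake(n_frames=2, wingbeat_freq=100.0,
                                   noise_sd=0.01 * peak, seed=3)
        masks = mask_wake(noisy)
        wx = streamwise_vorticity(noisy, 0)
        masked_half = np.where(masks.mask[0], wx, 0.0)[noisy.y_coords > 0, :]
        circ = masked_half.sum() * noisy.dy * noisy.dz
        assert circ == pytest.approx(truth.params["circulation"], rel=0.02)
        # the unmasked background noise carries essentially no net circulation
        unmasked_half = np.where(masks.mask[0], 0.0, wx)[noisy.y_coords > 0, :]
        noise_circ = unmasked_half.sum() * noisy.dy * noisy.dz
        assert abs(noise_circ) < 0.05 * truth.params["circulation"]

    def test_mask_purpose_noise_robustness(self):
        """Masked power is noise-robust; unmasked power is swamped by noise.

        The noise-adapted mask is applied to both the clean and the noisy
        fields, isolating the effect of the noise itself.
        """
        geom = dict(n_frames=2, wingbeat_freq=100.0, extent=0.7,
                    n_grid=401, seed=4)
        clean, _ = gen_vortex_wake(noise_sd=0.0, **geom)
        peak = np.abs(clean.v).max()
        noisy, _ = gen_vortex_wake(noise_sd=0.05 * peak, **geom)
        masks = mask_wake(noisy)
        p_clean = kinetic_power(clean, masks, air_density=RHO)
        p_masked = kinetic_power(noisy, masks, air_density=RHO)
        open_mask = mask_wake(clean, threshold=0.0)
        p_clean_open = kinetic_power(clean, open_mask, air_density=RHO)
        p_open = kinetic_power(noisy, open_mask, air_density=RHO)
        assert abs(p_masked / p_clean - 1) < 0.05
        assert abs(p_open / p_clean_open - 1) > 0.20


class TestReconstruction:
    def test_zero_vorticity_gives_zero_velocity(self):
        y = np.linspace(-0.2, 0.2, 41)
        v, w = reconstruct_flow(np.zeros((41, 41)), y, y)
        assert np.allclose(v, 0) and np.allclose(w, 0)

    def test_lamb_oseen_tangential_profile(self):
        """Reconstructed swirl matches the analytic vortex profile off-boundary."""
        gamma, rc = 0.05, 0.02
        y = np.linspace(-0.3, 0.3, 201)
        yy, zz = np.meshgrid(y, y, indexing="ij")
        r2 = yy**2 + zz**2
        omega = gamma / (np.pi * rc**2) * np.exp(-r2 / rc**2)
        v, w = reconstruct_flow(omega, y, y)
        speed = np.sqrt(v**2 + w**2)
        r = np.sqrt(r2)
        analytic = gamma / (2 * np.pi * np.where(r > 0, r, 1.0)) * (1 - np.exp(-r2 / rc**2))
        sel = (r > 1.5 * rc) & (r < 0.15)  # off-core, off-boundary annulus
        assert np.abs(speed[sel] / analytic[sel] - 1).max() < 0.02

    def test_vorticity_round_trip(self):
        series, _ = gen_vortex_wake(n_frames=2, wingbeat_freq=100.0,
                                    n_grid=301, seed=5)
        wx = streamwise_vorticity(series, 0)
        v, w = reconstruct_flow(wx, series.y_coords, series.z_coords)
        rebuilt = WakePlaneSeries(
            y_coords=series.y_coords, z_coords=series.z_coords,
            timestamps=series.timestamps[:1],
            u=series.u[:1], v=v[None], w=w[None],
            freestream=series.freestream, wingbeat_freq=series.wingbeat_freq)
        wx2 = streamwise_vorticity(rebuilt, 0)
        rms = np.sqrt(np.mean((wx2 - wx)**2)) / np.sqrt(np.mean(wx**2))
        assert rms < 0.01


class TestIntegrals:
    def test_still_wake_has_zero_power_and_drag(self):
        s = make_series()
        masks = mask_wake(s, threshold=0.0)
        assert kinetic_power(s, masks, air_density=RHO) == 0.0
        assert net_drag(s, masks, air_density=RHO) == 0.0

    def test_energy_flux_of_vortex_pair_recovered(self):
        series, truth = gen_vortex_wake(n_frames=20, seed=1)
        p = kinetic_power(series, mask_wake(series, threshold=0.0), air_density=RHO)
        assert p == pytest.approx(truth.params["kinetic_power"], rel=0.03)

    def test_energy_flux_quadratic_in_perturbation(self):
        """With zero streamwise perturbation the flux scales exactly as the
        square of the in-plane velocities."""
        series, _ = gen_vortex_wake(gamma=0.02, n_frames=20, seed=2)
        doubled, _ = gen_vortex_wake(gamma=0.04, n_frames=20, seed=2)
        m = mask_wake(series, threshold=0.0)
        p1 = kinetic_power(series, m, air_density=RHO)
        p2 = kinetic_power(doubled, m, air_density=RHO)
        assert p2 == pytest.approx(4 * p1, rel=0.01)

    def test_uniform_deficit_net_drag_exact(self):
        d, u_inf = 0.4, 6.0
        s = make_series(u=lambda y, z: np.full_like(y, -d), u_inf=u_inf)
        masks = mask_wake(s, threshold=0.0)
        area = (s.y_coords[-1] - s.y_coords[0] + s.dy) * \
               (s.z_coords[-1] - s.z_coords[0] + s.dz)
        # trapezoid-free cell sum: n*n cells of dy*dz
        area = s.y_coords.size * s.z_coords.size * s.dy * s.dz
        expected = -RHO * d * (u_inf - d) * area
        assert net_drag(s, masks, air_density=RHO) == pytest.approx(expected, rel=1e-12)

    def test_momentum_balanced_wake_has_negligible_drag(self):
        deficit = (-0.5, 0.04, 0.0, -0.08)
        surplus = (+0.5, 0.04, 0.0, +0.08)
        series, _ = gen_vortex_wake(deficits=(deficit, surplus), n_frames=20, seed=6)
        dnet = net_drag(series, mask_wake(series, threshold=0.0), air_density=RHO)
        area = 0.6 * 0.6
        assert abs(dnet) < 1e-3 * RHO * 6.0**2 * area

    def test_drag_correction_arithmetic_and_sign(self):
        assert drag_corrected_power(0.08, 0.002, 6.0) == pytest.approx(0.092)
        assert drag_corrected_power(0.08, 0.0, 6.0) == 0.08
        surplus, _ = gen_vortex_wake(deficits=((+0.3, 0.04, 0.0, 0.0),),
                                     n_frames=20, seed=7)
        m = mask_wake(surplus, threshold=0.0)
        d = net_drag(surplus, m, air_density=RHO)
        assert d > 0  # momentum surplus raises the corrected power
        p = kinetic_power(surplus, m, air_density=RHO)
        assert drag_corrected_power(p, d, 6.0) > p


class TestVerticalForce:
    def test_counter_rotating_pair_closed_form(self):
        series, truth = gen_vortex_wake(gamma=0.05, separation=0.1, u_inf=6.0,
                                        n_frames=20, seed=1)
        fv = vertical_force(series, mask_wake(series, threshold=0.0),
                            air_density=RHO)
        assert truth.params["vertical_force"] == pytest.approx(0.036)
        assert fv == pytest.approx(truth.params["vertical_force"], rel=0.01)

    def test_zero_vorticity_zero_force(self):
        s = make_series(u=lambda y, z: 0.1 * np.ones_like(y))
        assert vertical_force(s, mask_wake(s, threshold=0.0), y0=0.0,
                              air_density=RHO) == pytest.approx(0.0, abs=1e-12)

    def test_linearity_in_circulation(self):
        gammas = np.array([0.01, 0.02, 0.03, 0.04, 0.05])
        forces = []
        for g in gammas:
            series, _ = gen_vortex_wake(gamma=float(g), n_frames=2,
                                        wingbeat_freq=100.0, seed=8)
            forces.append(vertical_force(series, mask_wake(series, threshold=0.0),
                                         air_density=RHO))
        r = np.corrcoef(gammas, forces)[0, 1]
        assert r**2 > 0.9999

    def test_mirrored_half_wake_matches_full_wake(self):
        full, _ = gen_vortex_wake(n_frames=20, seed=9)
        half, _ = gen_vortex_wake(n_frames=20, half_wake=True, seed=9)
        mirrored = mirror_half_wake(half)
        mf = mask_wake(full, threshold=0.0)
        mm = mask_wake(mirrored, threshold=0.0)
        fv_full = vertical_force(full, mf, y0=0.0, air_density=RHO)
        fv_mir = vertical_force(mirrored, mm, y0=float(mirrored.y_coords.mean()),
                                air_density=RHO)
        assert fv_mir == pytest.approx(fv_full, rel=0.01)
        p_full = kinetic_power(full, mf, air_density=RHO)
        p_mir = kinetic_power(mirrored, mm, air_density=RHO)
        assert p_mir == pytest.approx(p_full, rel=0.01)

    def test_grid_convergence(self):
        """Halving the grid spacing moves the smooth-wake integrals < 1%."""
        coarse, truth = gen_vortex_wake(core_radius=0.04, n_frames=2,
                                        wingbeat_freq=100.0, n_grid=101, seed=10)
        fine, _ = gen_vortex_wake(core_radius=0.04, n_frames=2,
                                  wingbeat_freq=100.0, n_grid=201, seed=10)
        res = {}
        for name, s in (("coarse", coarse), ("fine", fine)):
            m = mask_wake(s, threshold=0.0)
            res[name] = (vertical_force(s, m, air_density=RHO),
                         kinetic_power(s, m, air_density=RHO))
        assert res["fine"][0] == pytest.approx(res["coarse"][0], rel=0.01)
        assert res["fine"][1] == pytest.approx(res["coarse"][1], rel=0.01)

    def test_y0_outside_grid_rejected(self):
        s = make_series()
        with pytest.raises(InvalidInputError):
            vertical_force(s, mask_wake(s, threshold=0.0), y0=5.0)


class TestSelection:
    @staticmethod
    def result(fv, n_wb):
        return SequenceResult(power_raw=0.1, net_drag=0.0, power_corrected=0.1,
                              vertical_force=fv, n_wingbeats=n_wb)

    def test_weight_supporting_sequence_retained(self):
        res = [self.result(1.0, 3)]
        assert select_sequences(res, weight=1.0) == res

    def test_thirty_percent_deviation_rejected(self):
        assert select_sequences([self.result(0.7, 3)], weight=1.0) == []

    def test_single_wingbeat_rejected(self):
        assert select_sequences([self.result(1.0, 1)], weight=1.0) == []

    def test_matches_brute_force_filter(self, rng):
        results = [self.result(float(rng.uniform(0.5, 1.5)), int(rng.integers(1, 5)))
                   for _ in range(10)]
        kept = select_sequences(results, weight=1.0)
        brute = [r for r in results
                 if r.n_wingbeats > 1 and abs(r.vertical_force - 1.0) <= 0.2]
        assert kept == brute

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(InvalidInputError):
            select_sequences([], weight=0.0)


class TestProcessSequence:
    def test_full_pipeline_recovers_truth(self):
        series, truth = gen_vortex_wake(n_frames=40, seed=11)
        res = process_sequence(series, air_density=RHO, threshold=0.0)
        assert res.vertical_force == pytest.approx(
            truth.params["vertical_force"], rel=0.01)
        assert res.n_wingbeats == 2
        assert res.power_corrected == pytest.approx(
            res.power_raw + res.net_drag * 6.0, rel=1e-9)

    def test_half_wake_is_mirrored_before_integration(self):
        half, truth = gen_vortex_wake(n_frames=40, half_wake=True, seed=12)
        res = process_sequence(half, air_density=RHO, threshold=0.0)
        assert res.vertical_force == pytest.approx(
            truth.params["vertical_force"], rel=0.02)

    def test_too_few_frames_rejected(self):
        series, _ = gen_vortex_wake(n_frames=4, seed=13)
        with pytest.raises(InsufficientDataError):
            process_sequence(series, air_density=RHO, threshold=0.0)
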