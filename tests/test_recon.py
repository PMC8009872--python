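import math

import numpy as np
import pytest

from tiltkit.ctf import CtfParams, TiltGeometry
from tiltkit.phantom import (
    make_phantom_map,
    render_point_source_tilt_series,
    simulate_particle_dataset,
)
from tiltkit.recon import (
    ParticleRecord,
    ReconError,
    assign_particle_defocus,
    compute_fsc,
    constrained_refine,
    derive_exposure_weights,
    euler_to_matrix,
    extract_particle_projections,
    project_map,
    project_position,
    rotation_angle_between,
    score_projections,
    tilt_matrix,
    weighted_reconstruct,
)
from tiltkit.recon import _band_mask, _cfft2, _freq_grid_2d
from tiltkit.scheme import generate_grouped_dose_symmetric

PX = 2.0


def _particle(pos=(0.0, 0.0, 0.0), eulers=(0.0, 0.0, 0.0), pid=0):
    return ParticleRecord(
        particle_id=pid, tilt_series_id="t", position_um=pos, eulers_deg=eulers
    )


class TestRotations:
    def test_euler_identity(self):
        assert np.allclose(euler_to_matrix(0, 0, 0), np.eye(3))

    def test_tilt_matrix_matches_axis_rotation_model(self):
        m = tilt_matrix(30.0)
        y, z = 2.0, 0.1
        v = m @ np.array([0.0, y, z])
        t = math.radians(30.0)
        assert v[1] == pytest.approx(y * math.cos(t) + z * math.sin(t), abs=1e-12)
        assert v[2] == pytest.approx(-y * math.sin(t) + z * math.cos(t), abs=1e-12)

    def test_rotation_distance(self):
        a = euler_to_matrix(10, 20, 30)
        assert rotation_angle_between(a, a) == pytest.approx(0.0, abs=1e-6)
        b = euler_to_matrix(10, 20, 31)
        assert rotation_angle_between(a, b) == pytest.approx(1.0, abs=0.05)


class TestAssignDefocus:
    def _setup(self, n_tilts=3):
        geoms = [TiltGeometry(tilt_angle=a) for a in (0.0, 36.0, -36.0)[:n_tilts]]
        ctfs = [CtfParams(15000, 15000) for _ in geoms]
        return geoms, ctfs

    def test_origin_particle_keeps_base_defocus(self):
        geoms, ctfs = self._setup()
        out = assign_particle_defocus(_particle(), geoms, ctfs)
        for i in range(len(geoms)):
            assert out[i] == (15000.0, 15000.0)

    def test_known_offset_at_36deg(self):
        # oracle: height -y sin(36) + z cos(36) for (y, z) = (0.5, 0.2) um
        geoms, ctfs = self._setup(2)
        out = assign_particle_defocus(_particle(pos=(0.0, 0.5, 0.2)), geoms, ctfs)
        assert out[1][0] - 15000.0 == pytest.approx(-1320.8922727124706, abs=1e-6)
        assert out[1][1] - 15000.0 == pytest.approx(-1320.8922727124706, abs=1e-6)

    def test_mirror_symmetry_in_y(self):
        geoms, ctfs = self._setup()
        a = assign_particle_defocus(_particle(pos=(0.0, 0.5, 0.0)), geoms, ctfs)
        b = assign_particle_defocus(_particle(pos=(0.0, -0.5, 0.0)), geoms, ctfs)
        for i in range(len(geoms)):
            assert a[i][0] - 15000.0 == pytest.approx(-(b[i][0] - 15000.0), abs=1e-9)

    def test_theta_derivative_is_minus_y(self):
        # d(height)/d(theta) at 0 = -y (in um per radian), checked numerically
        y = 0.7
        eps = 1e-4
        geoms = [TiltGeometry(tilt_angle=a) for a in (-eps, eps)]
        ctfs = [CtfParams(0, 0)] * 2
        out = assign_particle_defocus(_particle(pos=(0.0, y, 0.0)), geoms, ctfs)
        deriv_um = (out[1][0] - out[0][0]) * 1e-4 / (2 * math.radians(eps))
        assert deriv_um == pytest.approx(-y, rel=1e-5)

    def test_missing_ctf_rejected(self):
        geoms, ctfs = self._setup()
        with pytest.raises(ReconError):
            assign_particle_defocus(_particle(), geoms, [ctfs[0], None, ctfs[2]])


class TestExtraction:
    def _series(self, positions):
        geoms = [TiltGeometry(tilt_angle=a) for a in (0.0, 30.0, -30.0, 60.0)]
        series = render_point_source_tilt_series(positions, geoms, (96, 96), PX)
        return series, geoms

    def test_centered_particle_identity_transforms(self):
        series, geoms = self._series([(0.0, 0.0, 0.0)])
        p = _particle()
        stack, meta = extract_particle_projections(series, geoms, [p], 16, PX)
        assert len(stack) == 4
        for m in meta:
            assert m["center_col"] == pytest.approx(47.5)
            assert m["center_row"] == pytest.approx(47.5)

    def test_point_source_maxima_near_predicted_centers(self):
        positions = [(0.004, 0.003, 0.001), (-0.005, -0.002, 0.0)]
        series, geoms = self._series(positions)
        for pos in positions:
            p = _particle(pos=pos)
            stack, meta = extract_particle_projections(series, geoms, [p], 16, PX)
            for box, m in zip(stack, meta):
                r, c = np.unravel_index(np.argmax(box), box.shape)
                # box centre carries the sub-pixel remainder of the predicted
                # centre; maxima must sit within 1 px of it
                pred_r = m["center_row"] - (round(m["center_row"]) - 8)
                pred_c = m["center_col"] - (round(m["center_col"]) - 8)
                assert abs(r - pred_r) <= 1.0
                assert abs(c - pred_c) <= 1.0

    def test_edge_particle_dropped_at_high_tilt(self):
        # tall particle: the height term pushes its 60 deg projection off
        # the field while the 0 deg projection stays inside
        pos = (0.0, 0.0, 0.0095)
        series, geoms = self._series([pos])
        p = _particle(pos=pos)
        stack, meta = extract_particle_projections(series, geoms, [p], 24, PX)
        tilt_ids = {m["tilt_index"] for m in meta}
        assert 0 in tilt_ids
        assert 3 not in tilt_ids  # the 60 deg tilt is not visible

    def test_all_invisible_raises_on_empty_result(self):
        series, geoms = self._series([(0.0, 0.0, 0.0)])
        p = _particle(pos=(1.0, 1.0, 0.0))  # far outside the field
        with pytest.raises(ReconError):
            extract_particle_projections(series, geoms, [p], 16, PX)


@pytest.fixture(scope="module")
def tiny():
    scheme = generate_grouped_dose_symmetric(12, 6)
    return simulate_particle_dataset(
        scheme, n_particles=3, box=32, damage_rate=0.0, noise_sigma=0.0,
        with_ctf=False, seed=2,
    )


class TestScoring:
    def test_perfect_projection_scores_one(self, tiny):
        s = score_projections(tiny.stack, tiny.phantom, tiny.rotations,
                              band=(20.0, 8.0), pixel_size=PX)
        assert np.all(s > 0.999)

    def test_contrast_inversion_invariant(self, tiny):
        a = score_projections(tiny.stack, tiny.phantom, tiny.rotations,
                              band=(20.0, 8.0), pixel_size=PX)
        b = score_projections(-tiny.stack, tiny.phantom, tiny.rotations,
                              band=(20.0, 8.0), pixel_size=PX)
        assert np.allclose(a, b, atol=1e-12)

    def test_noise_scores_match_null_resampling(self, tiny, rng):
        # permutation oracle: |NCC| of independent noise pairs in the band
        n_proj = len(tiny.rotations)
        noise_stack = rng.normal(size=(n_proj, 32, 32))
        s = score_projections(noise_stack, tiny.phantom,
                              tiny.rotations, band=(20.0, 8.0), pixel_size=PX)
        mask = _band_mask(32, PX, (20.0, 8.0))
        null = []
        for _ in range(200):
            a = _cfft2(rng.normal(size=(32, 32)))[mask]
            b = _cfft2(rng.normal(size=(32, 32)))[mask]
            num = abs(float(np.sum((a * np.conj(b)).real)))
            den = math.sqrt(float(np.sum(np.abs(a) ** 2)) * float(np.sum(np.abs(b) ** 2)))
            null.append(num / den)
        se = np.std(null) / math.sqrt(n_proj) + np.std(null) / math.sqrt(200)
        assert abs(s.mean() - np.mean(null)) < 4 * se + 0.01

    def test_empty_band_rejected(self, tiny):
        with pytest.raises(ReconError):
            score_projections(tiny.stack, tiny.phantom, tiny.rotations,
                              band=(8.0, 20.0), pixel_size=PX)


class TestWeights:
    def test_equal_scores_give_unit_weights(self):
        ew = derive_exposure_weights([[0.5, 0.5], [0.5], [0.5, 0.5, 0.5]])
        assert np.all(ew.b_factors == 0.0)
        f = np.linspace(0, 0.25, 10)
        for i in range(3):
            assert np.allclose(ew.weight(i, f), 1.0)

    def test_decaying_scores_give_increasing_b(self):
        scores = [[0.5 - 0.02 * i] for i in range(10)]
        ew = derive_exposure_weights(scores, conversion=100.0)
        assert np.all(np.diff(ew.b_factors) > 0)
        assert ew.b_factors[0] == 0.0

    def test_weight_at_zero_frequency_is_one(self):
        ew = derive_exposure_weights([[0.9], [0.1]], conversion=500.0)
        for i in range(2):
            assert ew.weight(i, 0.0) == 1.0

    def test_weights_never_amplify(self):
        ew = derive_exposure_weights([[0.9], [0.4], [0.1]], conversion=300.0)
        f = np.linspace(0.0, 0.5, 50)
        for i in range(3):
            w = ew.weight(i, f)
            assert np.all(w <= 1.0) and np.all(w > 0.0)

    def test_spectral_contribution_shifts_to_early_tilts(self):
        ew = derive_exposure_weights([[0.9], [0.5], [0.2]], conversion=500.0)
        contrib = ew.spectral_contribution(np.array([0.0, 0.25]))
        assert contrib[0, 1] > contrib[0, 0]  # best tilt gains share at high f
        assert np.allclose(contrib.sum(axis=0), 1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ReconError):
            derive_exposure_weights([[0.5], []])


class TestReconstruct:
    def test_single_noiseless_particle_high_fidelity(self):
        # insertion oracle: near-complete angular coverage reproduces the
        # analytic phantom to > 0.99 per-shell correlation up to half-Nyquist
        scheme = generate_grouped_dose_symmetric(88, 2)
        ds = simulate_particle_dataset(
            scheme, n_particles=1, box=32, damage_rate=0.0, noise_sigma=0.0,
            with_ctf=False, seed=1,
        )
        full, _, _ = weighted_reconstruct(
            ds.stack, ds.rotations, particle_ids=ds.particle_of_projection,
            pixel_size=PX,
        )
        fsc = compute_fsc(full, ds.phantom, pixel_size=PX)
        assert np.all(fsc.fsc[1:9] > 0.99)

    def test_identical_halves_fsc_one(self):
        scheme = generate_grouped_dose_symmetric(12, 6)
        ds = simulate_particle_dataset(scheme, n_particles=2, box=32,
                                       damage_rate=0.0, noise_sigma=0.0,
                                       with_ctf=False, seed=3)
        full, _, _ = weighted_reconstruct(ds.stack, ds.rotations, pixel_size=PX)
        fsc = compute_fsc(full, full.copy(), pixel_size=PX)
        assert np.allclose(fsc.fsc[:10], 1.0, atol=1e-9)

    def test_unit_weights_match_unweighted_path(self):
        scheme = generate_grouped_dose_symmetric(12, 6)
        ds = simulate_particle_dataset(scheme, n_particles=2, box=32,
                                       damage_rate=0.0, noise_sigma=0.2,
                                       with_ctf=False, seed=4)
        ones = [np.ones((32, 32))] * len(ds.stack)
        a, _, _ = weighted_reconstruct(ds.stack, ds.rotations, weights=ones,
                                       pixel_size=PX)
        b, _, _ = weighted_reconstruct(ds.stack, ds.rotations, pixel_size=PX)
        assert np.allclose(a, b, atol=1e-10)

    def test_empty_stack_rejected(self):
        with pytest.raises(ReconError):
            weighted_reconstruct(np.zeros((0, 8, 8)), [])


class TestFsc:
    def test_self_correlation_is_one(self, rng):
        vol = rng.normal(size=(24, 24, 24))
        fsc = compute_fsc(vol, vol, pixel_size=PX)
        assert np.allclose(fsc.fsc[1:], 1.0, atol=1e-9)

    def test_zero_map_rejected(self, rng):
        with pytest.raises(ReconError):
            compute_fsc(np.zeros((16, 16, 16)), rng.normal(size=(16, 16, 16)))

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ReconError):
            compute_fsc(rng.normal(size=(16,) * 3), rng.normal(size=(24,) * 3))

    def test_noise_null_matches_resampling_oracle(self):
        # 95th percentile of |FSC| across independent noise pairs agrees
        # with a direct resampling estimate
        n = 24
        vals = []
        for seed in range(30):
            r = np.random.default_rng(seed)
            fsc = compute_fsc(r.normal(size=(n,) * 3), r.normal(size=(n,) * 3),
                              pixel_size=PX)
            vals.append(np.abs(fsc.fsc[5:]))
        emp95 = np.percentile(np.concatenate(vals), 95)
        # oracle: |correlation of k iid complex pairs| scales as 2/sqrt(n_k);
        # estimate by resampling plain Gaussian vectors of the shell sizes
        r = np.random.default_rng(99)
        shell_sizes = []
        grids = np.meshgrid(*[np.arange(n) - n // 2] * 3, indexing="ij")
        rad = np.sqrt(sum(g * g for g in grids)).astype(int)
        for k in range(5, n // 2):
            shell_sizes.append(int((rad == k).sum()))
        null = []
        for _ in range(300):
            m = shell_sizes[int(r.integers(len(shell_sizes)))]
            a = r.normal(size=m)
            b = r.normal(size=m)
            null.append(abs(np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))))
        orc95 = np.percentile(null, 95)
        assert emp95 == pytest.approx(orc95, rel=0.35)

    def test_resolution_interpolation(self):
        curve_f = np.arange(8) / 16.0
        from tiltkit.recon import FscCurve
        fsc = FscCurve(freq=curve_f, fsc=np.array([1, 1, 1, 0.8, 0.4, 0.1, 0, 0]))
        res = fsc.resolution_at(0.143)
        # crossing between shells 4 (0.4) and 5 (0.1): f = 0.25 + (0.257/0.3)/16
        f_cross = curve_f[4] + (0.4 - 0.143) / 0.3 * (1 / 16.0)
        assert res == pytest.approx(1.0 / f_cross, rel=1e-6)


class TestRefine:
    def test_zero_perturbation_fixed_point(self):
        scheme = generate_grouped_dose_symmetric(24, 12)
        ds = simulate_particle_dataset(scheme, n_particles=2, box=32,
                                       damage_rate=0.0, noise_sigma=0.0,
                                       with_ctf=False, seed=5)
        refined, _ = constrained_refine(
            ds.stack, ds.phantom, ds.particles, ds.proj_meta, ds.geoms,
            pixel_size=PX,
        )
        for p, q in zip(ds.particles, refined):
            d = rotation_angle_between(
                euler_to_matrix(*p.eulers_deg), euler_to_matrix(*q.eulers_deg)
            )
            assert d < 0.2
            assert np.allclose(q.position_um, p.position_um, atol=0.2 * PX * 1e-4)

    def test_perturb_and_recover(self):
        scheme = generate_grouped_dose_symmetric(36, 12)
        ds = simulate_particle_dataset(
            scheme, n_particles=3, box=32, damage_rate=0.0, noise_sigma=0.0,
            with_ctf=False, perturb_angles=2.0, perturb_shift_px=2.0, seed=6,
        )
        refined, _ = constrained_refine(
            ds.stack, ds.phantom, ds.particles, ds.proj_meta, ds.geoms,
            pixel_size=PX,
        )
        meta_by_pid = {m["particle_id"]: m for m in ds.proj_meta}
        for q in refined:
            m = meta_by_pid[q.particle_id]
            d_rot = rotation_angle_between(
                euler_to_matrix(*q.eulers_deg), euler_to_matrix(*m["true_eulers"])
            )
            d_shift = np.abs(
                np.array(q.position_um[:2]) / (PX * 1e-4)
                - np.array(m["stored_shift_px"])
            ).max()
            assert d_rot < 0.5
            assert d_shift < 0.5

    def test_axis_angle_recovery(self):
        # data generated at axis 1.0 deg; geometry handed in claims 0
        scheme = generate_grouped_dose_symmetric(36, 12)
        ds = simulate_particle_dataset(
            scheme, n_particles=8, box=32, damage_rate=0.0, noise_sigma=0.0,
            with_ctf=False, tilt_axis_angle=1.0, seed=7,
        )
        geoms = [TiltGeometry(tilt_axis_angle=0.0, tilt_angle=g.tilt_angle)
                 for g in ds.geoms]
        _, axis_off = constrained_refine(
            ds.stack, ds.phantom, ds.particles, ds.proj_meta, geoms,
            pixel_size=PX, refine_geometry=True,
        )
        assert axis_off == pytest.approx(1.0, abs=0.2)
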