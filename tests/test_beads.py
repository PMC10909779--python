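"""Forward-model tests: Debye intensities, Rg, scale/background fitting."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from ntdsplay.beads import (
    BeadConformation,
    ConformationalEnsemble,
    debye_intensity,
    ensemble_average_intensity,
    fit_scale_background,
    guinier_rg,
    radius_of_gyration,
    weighted_rg_distribution,
)
from ntdsplay.curves import ScatteringCurve
from ntdsplay.synthetic import ToyTetramerSpec, gen_toy_tetramer


def brute_force_debye(coords, b, q):
    """Independent O(n^2) double-loop reference for the Debye sum."""
    I = np.zeros_like(q)
    n = len(b)
    for i in range(n):
        for j in range(n):
            r = np.linalg.norm(coords[i] - coords[j])
            qr = q * r
            with np.errstate(invalid="ignore"):
                s = np.where(qr == 0, 1.0, np.sin(qr) / np.where(qr == 0, 1.0, qr))
            I += b[i] * b[j] * s
    return I


class TestDebye:
    def test_forward_limit_is_total_scattering_length_squared(self):
        conf = BeadConformation([[0, 0, 0], [10, 0, 0]], [1.0, 1.0])
        # q=0 anchor allowed in computed curves
        curve = debye_intensity(conf, [0.0, 1e-6])
        assert curve.I[0] == pytest.approx(4.0)
        assert curve.I[1] == pytest.approx(4.0, rel=1e-9)

    def test_two_beads_at_qd_pi_leaves_self_terms(self):
        d = 25.0
        conf = BeadConformation([[0, 0, 0], [d, 0, 0]], [1.0, 1.0])
        curve = debye_intensity(conf, [np.pi / d])
        assert curve.I[0] == pytest.approx(2.0, abs=1e-12)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(11)
        q = np.linspace(0.001, 0.5, 30)
        coords = rng.normal(size=(50, 3)) * 20
        b = rng.uniform(0.5, 1.5, 50)
        conf = BeadConformation(coords, b)
        I = debye_intensity(conf, q).I
        ref = brute_force_debye(coords, b, q)
        assert np.max(np.abs(I - ref) / ref) < 1e-10

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_rotation_translation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        coords = rng.normal(size=(40, 3)) * 15
        b = rng.uniform(0.5, 2.0, 40)
        q = np.linspace(0.005, 0.4, 25)
        base = debye_intensity(BeadConformation(coords, b), q).I
        R = Rotation.random(random_state=seed).as_matrix()
        moved = coords @ R.T + np.array([123.0, -45.0, 6.0])
        rotated = debye_intensity(BeadConformation(moved, b), q).I
        assert np.max(np.abs(rotated - base) / base) < 1e-10

    def test_intensity_bounded_by_forward_scattering(self):
        conf = gen_toy_tetramer(ToyTetramerSpec(seed=4, splay=20.0))
        q = np.linspace(0.0, 0.5, 120)
        I = debye_intensity(conf, q).I
        assert np.all(I <= I[0] + 1e-9)

    def test_histogram_method_agrees_to_half_percent(self):
        conf = gen_toy_tetramer(ToyTetramerSpec(seed=2, splay=15.0))
        q = np.linspace(0.005, 0.5, 60)
        exact = debye_intensity(conf, q, method="exact").I
        approx = debye_intensity(conf, q, method="histogram", bin_width=1.0).I
        assert np.max(np.abs(approx - exact) / exact) < 0.005

    def test_empty_q_grid_rejected(self):
        conf = BeadConformation([[0, 0, 0], [1, 0, 0]])
        with pytest.raises(ValueError):
            debye_intensity(conf, [])


class TestRg:
    def test_two_equal_beads_half_separation(self):
        conf = BeadConformation([[-3.0, 0, 0], [3.0, 0, 0]])
        assert radius_of_gyration(conf) == pytest.approx(3.0)

    def test_single_bead_zero(self):
        assert radius_of_gyration(BeadConformation([[5.0, 5.0, 5.0]])) == 0.0

    def test_spherical_shell_rg_approaches_radius(self):
        rng = np.random.default_rng(7)
        R = 30.0
        v = rng.standard_normal((4000, 3))
        v /= np.linalg.norm(v, axis=1)[:, None]
        conf = BeadConformation(R * v)
        assert radius_of_gyration(conf) == pytest.approx(R, rel=0.01)

    def test_all_zero_weights_rejected(self):
        conf = BeadConformation([[0, 0, 0], [1, 0, 0]], [0.0, 0.0])
        with pytest.raises(ValueError):
            radius_of_gyration(conf)

    def test_guinier_slope_consistent_with_direct_rg(self):
        conf = gen_toy_tetramer(ToyTetramerSpec(seed=1))
        rg = radius_of_gyration(conf)
        q = np.linspace(1e-3, 1.2 / rg, 80)
        curve = debye_intensity(conf, q)
        assert guinier_rg(curve) == pytest.approx(rg, rel=0.03)


class TestEnsembleAverage:
    def test_single_frame_identity(self):
        q = np.linspace(0.01, 0.3, 20)
        f = ScatteringCurve(q, np.exp(-q))
        avg = ensemble_average_intensity([f], [1.0])
        assert np.array_equal(avg.I, f.I)

    def test_weighted_sum_matches_direct(self):
        q = np.linspace(0.01, 0.3, 20)
        f1 = ScatteringCurve(q, np.exp(-q))
        f2 = ScatteringCurve(q, 1.0 / (1 + q**2))
        avg = ensemble_average_intensity([f1, f2], [0.25, 0.75])
        assert np.allclose(avg.I, 0.25 * f1.I + 0.75 * f2.I)

    def test_grid_mismatch_rejected(self):
        f1 = ScatteringCurve(np.linspace(0.01, 0.3, 20), np.ones(20))
        f2 = ScatteringCurve(np.linspace(0.01, 0.4, 20), np.ones(20))
        with pytest.raises(ValueError):
            ensemble_average_intensity([f1, f2], [0.5, 0.5])

    def test_negative_weights_rejected(self):
        q = np.linspace(0.01, 0.3, 5)
        f = ScatteringCurve(q, np.ones(5))
        with pytest.raises(ValueError):
            ensemble_average_intensity([f, f], [1.5, -0.5])


class TestScaleBackground:
    def test_exact_linear_case(self):
        q = np.linspace(0.01, 0.3, 30)
        model = ScatteringCurve(q, np.exp(-10 * q**2))
        data = ScatteringCurve(q, 3.0 * model.I + 5.0, np.ones(30))
        s, b, chi2r = fit_scale_background(model, data)
        assert s == pytest.approx(3.0)
        assert b == pytest.approx(5.0)
        assert chi2r == pytest.approx(0.0, abs=1e-20)

    def test_chi2r_near_one_for_matched_noise(self):
        rng = np.random.default_rng(0)
        q = np.linspace(0.01, 0.3, 200)
        model = ScatteringCurve(q, 100 * np.exp(-50 * q**2))
        data = ScatteringCurve(
            q, model.I + rng.standard_normal(200), np.ones(200)
        )
        _, _, chi2r = fit_scale_background(model, data)
        assert abs(chi2r - 1.0) < 0.3

    def test_constant_model_degenerate(self):
        q = np.linspace(0.01, 0.3, 30)
        model = ScatteringCurve(q, np.zeros(30))
        data = ScatteringCurve(q, np.ones(30), np.ones(30))
        with pytest.raises(ValueError):
            fit_scale_background(model, data)


class TestRgDistribution:
    def _ensemble(self, splays, seed=0):
        frames = [
            gen_toy_tetramer(ToyTetramerSpec(seed=seed, splay=s)) for s in splays
        ]
        return ConformationalEnsemble(frames)

    def test_identical_frames_single_bin(self):
        ens = self._ensemble([10.0, 10.0, 10.0])
        dist = weighted_rg_distribution(ens, np.full(3, 1 / 3), bin_width=1.0)
        assert np.sum(dist.density > 0) == 1
        rg = radius_of_gyration(ens.frames[0])
        assert dist.weighted_mean == pytest.approx(rg)

    def test_density_integrates_to_one(self):
        ens = self._ensemble([0.0, 10.0, 25.0, 40.0])
        dist = weighted_rg_distribution(ens, np.full(4, 0.25), bin_width=0.5)
        widths = np.diff(dist.bin_edges)
        assert np.sum(dist.density * widths) == pytest.approx(1.0, abs=1e-6)

    def test_mean_moves_toward_splayed_state_with_weight(self):
        ens = self._ensemble([0.0, 30.0])
        shifted = weighted_rg_distribution(ens, [0.5, 0.5]).weighted_mean
        prior = weighted_rg_distribution(ens, [0.9, 0.1]).weighted_mean
        rg_splayed = radius_of_gyration(ens.frames[1])
        assert prior < shifted < rg_splayed

    def test_uniform_weights_match_unweighted_histogram(self):
        ens = self._ensemble([0.0, 12.0, 24.0])
        dist = weighted_rg_distribution(ens, np.full(3, 1 / 3), bin_width=1.0)
        rgs = [radius_of_gyration(f) for f in ens.frames]
        ref, _ = np.histogram(
            rgs, bins=dist.bin_edges, density=True
        )
        assert np.allclose(dist.density, ref)
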