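"""Aggregate modelling, composite fitting, subtraction, and the IFT floor."""

import numpy as np
import pytest

from ntdsplay.beads import ensemble_average_intensity, guinier_rg
from ntdsplay.curves import ScatteringCurve
from ntdsplay.purification import (
    AggregateParams,
    _ift_solve,
    fit_composite,
    fractal_structure_factor,
    ift_chi2_floor,
    subtract_aggregate,
)
from ntdsplay.synthetic import (
    NoiseModel,
    ToyTetramerSpec,
    ensemble_frame_curves,
    gen_sans_dataset,
    gen_two_state_ensemble,
)


class TestFractalStructureFactor:
    def test_d2_matches_closed_form(self):
        q = np.logspace(-3, 0, 400)
        xi, r0 = 100.0, 40.0
        S = fractal_structure_factor(q, 2.0, xi, r0)
        closed = 1.0 + 2.0 * (xi / r0) ** 2 / (1.0 + q**2 * xi**2)
        assert np.max(np.abs(S - closed) / closed) < 1e-12

    def test_zero_q_limit_equal_sizes(self):
        assert fractal_structure_factor([0.0], 2.0, 50.0, 50.0)[0] == pytest.approx(3.0)

    def test_value_at_q_xi_one(self):
        # q*xi = 1 with xi=100, r0=40: 1 + 2*(2.5)^2/2 = 7.25
        S = fractal_structure_factor([1.0 / 100.0], 2.0, 100.0, 40.0)
        assert S[0] == pytest.approx(7.25, rel=1e-12)

    def test_high_q_limit_is_one(self):
        S = fractal_structure_factor([50.0], 2.0, 300.0, 40.0)
        assert S[0] == pytest.approx(1.0, abs=1e-3)

    def test_monotone_decreasing_and_at_least_one_for_d2(self):
        q = np.logspace(-4, 1, 500)
        S = fractal_structure_factor(q, 2.0, 200.0, 40.0)
        assert np.all(np.diff(S) <= 0)
        assert np.all(S >= 1.0)

    def test_dimension_at_or_below_one_rejected(self):
        with pytest.raises(ValueError):
            fractal_structure_factor([0.01], 1.0, 100.0, 40.0)


def _contaminated(seed, c_a=0.03, xi=150.0, bkg=10.0):
    """Shared synthetic contamination setup (flat 1% noise, log-q grid)."""
    spec = ToyTetramerSpec(n_beads_per_subunit=12, subunit_radius=15.0, seed=0)
    ens, _ = gen_two_state_ensemble(spec, 60, splayed_fraction=0.5, seed=0)
    q = np.logspace(np.log10(0.003), np.log10(0.30), 100)
    fc = ensemble_frame_curves(ens, q)
    w = np.full(len(ens), 1.0 / len(ens))
    form = ensemble_average_intensity(fc, w)
    r0 = np.sqrt(5.0 / 3.0) * guinier_rg(form)
    agg = AggregateParams(c_a, 2.0, xi, r0) if c_a > 0 else None
    data, truth = gen_sans_dataset(
        ens, w, agg, bkg, NoiseModel(0.01, 0.0, seed=seed), q, frame_curves=fc
    )
    return data, truth, form, r0


class TestCompositeFit:
    def test_null_aggregate_recovers_clean_curve(self):
        data, truth, form, r0 = _contaminated(seed=0, c_a=0.0)
        fit = fit_composite(data, form, AggregateParams(1e-3, 2.0, 100.0, r0))
        assert fit.aggregate.fraction_scale <= 1e-6 * fit.c_tet + 1e-12
        filtered = subtract_aggregate(data, fit)
        assert np.allclose(filtered.I, data.I, rtol=1e-6, atol=1e-9)

    def test_known_parameters_recovered(self):
        c_a, xi, bkg = 0.03, 150.0, 10.0
        data, truth, form, r0 = _contaminated(seed=1, c_a=c_a, xi=xi, bkg=bkg)
        fit = fit_composite(data, form, AggregateParams(1e-3, 2.0, 100.0, r0))
        assert fit.c_tet == pytest.approx(1.0, rel=0.10)
        assert fit.aggregate.fraction_scale == pytest.approx(c_a, rel=0.10)
        assert fit.aggregate.correlation_length == pytest.approx(xi, rel=0.20)
        assert fit.background == pytest.approx(bkg, rel=0.10)

    def test_pure_background_data(self):
        q = np.linspace(0.01, 0.3, 50)
        form = ScatteringCurve(q, 100.0 * np.exp(-500.0 * q**2))
        data = ScatteringCurve(q, np.full(50, 7.0), np.full(50, 0.07))
        fit = fit_composite(data, form, AggregateParams(1e-3, 2.0, 100.0, 40.0))
        assert fit.background == pytest.approx(7.0, rel=0.02)
        assert abs(fit.c_tet) < 1e-3
        assert fit.aggregate.fraction_scale < 1e-3


class TestSubtraction:
    def test_filtered_matches_truth_at_noise_level(self):
        data, truth, form, r0 = _contaminated(seed=2)
        fit = fit_composite(data, form, AggregateParams(1e-3, 2.0, 100.0, r0))
        filtered = subtract_aggregate(data, fit)
        # background is not subtracted: compare against truth + background
        chi2r = float(np.mean(((filtered.I - truth.I - 10.0) / data.sigma) ** 2))
        assert 0.7 < chi2r < 1.3

    def test_refit_after_subtraction_finds_no_aggregate(self):
        data, truth, form, r0 = _contaminated(seed=3)
        fit = fit_composite(data, form, AggregateParams(1e-3, 2.0, 100.0, r0))
        filtered = subtract_aggregate(data, fit)
        refit = fit_composite(filtered, form, AggregateParams(1e-3, 2.0, 100.0, r0))
        assert refit.aggregate.fraction_scale < 0.1 * fit.aggregate.fraction_scale

    def test_grid_and_sigma_preserved_exactly(self):
        data, truth, form, r0 = _contaminated(seed=4)
        fit = fit_composite(data, form, AggregateParams(1e-3, 2.0, 100.0, r0))
        filtered = subtract_aggregate(data, fit)
        assert np.array_equal(filtered.q, data.q)
        assert np.array_equal(filtered.sigma, data.sigma)
        assert len(filtered) == len(data)

    def test_mismatched_grid_rejected(self):
        data, truth, form, r0 = _contaminated(seed=5)
        fit = fit_composite(data, form, AggregateParams(1e-3, 2.0, 100.0, r0))
        other = ScatteringCurve(data.q * 1.01, data.I, data.sigma)
        with pytest.raises(ValueError):
            subtract_aggregate(other, fit)


def _sphere_curve(R=40.0, n_q=100, rel_noise=0.01, seed=5):
    q = np.linspace(0.008, 0.35, n_q)
    qR = q * R
    I = (3.0 * (np.sin(qR) - qR * np.cos(qR)) / qR**3) ** 2
    rng = np.random.default_rng(seed)
    sigma = rel_noise * I + 1e-6
    return ScatteringCurve(q, I + sigma * rng.standard_normal(n_q), sigma), R


class TestIFT:
    def test_sphere_support_ends_near_diameter(self):
        data, R = _sphere_curve()
        chi2r, pr = ift_chi2_floor(data, d_max_init=100.0)
        support_end = pr.r[np.where(pr.p > 0.05 * pr.p.max())[0][-1]]
        assert support_end == pytest.approx(2 * R, rel=0.10)

    def test_floor_near_one_for_matched_noise(self):
        data, _ = _sphere_curve(seed=6)
        chi2r, _ = ift_chi2_floor(data, d_max_init=100.0)
        assert 0.7 < chi2r < 1.3

    def test_oversmoothing_raises_chi2(self):
        data, _ = _sphere_curve(seed=7)
        _, pr = ift_chi2_floor(data, d_max_init=100.0, refine_dmax=False)
        opt = _ift_solve(data.q, data.I, data.sigma, 100.0, pr.alpha, 60)
        over = _ift_solve(data.q, data.I, data.sigma, 100.0, 1e18, 60)
        assert over[3] > opt[3]  # chi2 strictly increases

    def test_too_small_dmax_reported(self):
        data, R = _sphere_curve()
        with pytest.warns(UserWarning, match="piles up"):
            ift_chi2_floor(data, d_max_init=0.9 * R, refine_dmax=False)
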