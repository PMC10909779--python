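"""Generator tests: geometry exactness, sampler statistics, determinism."""

import numpy as np
import pytest
from scipy import stats

from ntdsplay.beads import radius_of_gyration
from ntdsplay.purification import AggregateParams
from ntdsplay.synthetic import (
    KT_300K,
    NoiseModel,
    PMFSpec,
    ToyTetramerSpec,
    ensemble_frame_curves,
    gen_current_trace,
    gen_ensemble,
    gen_recovery_series,
    gen_sans_dataset,
    gen_toy_tetramer,
    gen_umbrella_windows,
    ntd_distance,
)


class TestToyTetramer:
    def test_same_seed_identical_coordinates(self):
        a = gen_toy_tetramer(ToyTetramerSpec(seed=5))
        b = gen_toy_tetramer(ToyTetramerSpec(seed=5))
        assert np.array_equal(a.coordinates, b.coordinates)

    def test_splay_shifts_ntd_com_distance_exactly(self):
        base = gen_toy_tetramer(ToyTetramerSpec(seed=5, splay=0.0))
        splayed = gen_toy_tetramer(ToyTetramerSpec(seed=5, splay=20.0))
        assert ntd_distance(splayed) - ntd_distance(base) == pytest.approx(
            20.0, abs=1e-9
        )

    def test_com_distance_equals_base_plus_splay(self):
        spec = ToyTetramerSpec(seed=1, splay=13.5)
        conf = gen_toy_tetramer(spec)
        assert ntd_distance(conf) == pytest.approx(
            spec.base_ntd_distance + 13.5, abs=1e-9
        )

    def test_splaying_increases_rg(self):
        compact = gen_toy_tetramer(ToyTetramerSpec(seed=7, splay=0.0))
        splayed = gen_toy_tetramer(ToyTetramerSpec(seed=7, splay=30.0))
        assert radius_of_gyration(splayed) > radius_of_gyration(compact)

    @pytest.mark.parametrize(
        "kw", [{"n_beads_per_subunit": 0}, {"subunit_radius": -1.0}, {"splay": -5.0}]
    )
    def test_invalid_spec_rejected(self, kw):
        with pytest.raises(ValueError):
            ToyTetramerSpec(**kw)


class TestEnsembleSampler:
    def test_unbiased_harmonic_variance_matches_kT_over_kappa(self):
        kappa = 200.0
        pmf = PMFSpec("harmonic", {"kappa": kappa, "x0": 2.0}, kT=KT_300K)
        _, trace = gen_ensemble(
            ToyTetramerSpec(n_beads_per_subunit=1, seed=0), 50_000, pmf, seed=42,
            build_frames=False,
        )
        splay = trace.cv - ToyTetramerSpec(n_beads_per_subunit=1, seed=0).base_ntd_distance / 10
        assert np.var(splay) == pytest.approx(KT_300K / kappa, rel=0.10)

    def test_unbiased_sampling_matches_boltzmann_ks(self):
        # detailed balance: long-run splay histogram matches exp(-G/kT)
        kappa = 200.0
        pmf = PMFSpec("harmonic", {"kappa": kappa, "x0": 2.0}, kT=KT_300K)
        spec = ToyTetramerSpec(n_beads_per_subunit=1, seed=0)
        _, trace = gen_ensemble(spec, 100_000, pmf, seed=9, build_frames=False)
        splay = trace.cv - spec.base_ntd_distance / 10
        d, _ = stats.kstest(
            splay, stats.norm(loc=2.0, scale=np.sqrt(KT_300K / kappa)).cdf
        )
        assert d < 0.02

    def test_flattening_bias_gives_uniform_histogram(self):
        # V_bias = -G inside a confining box: sampling is flat there
        pmf = PMFSpec("double_well", {"height": 12.0, "x0": 2.0, "w": 1.0}, kT=KT_300K)

        def bias(x):
            x = np.asarray(x, dtype=float)
            wall = np.where((x < 1.0) | (x > 3.0), 1e6, 0.0)
            return -pmf.energy(x) + wall

        spec = ToyTetramerSpec(n_beads_per_subunit=1, seed=0)
        _, trace = gen_ensemble(
            spec, 40_000, pmf, seed=21, bias=bias, step=0.3, build_frames=False
        )
        splay = trace.cv - spec.base_ntd_distance / 10
        inside = splay[(splay > 1.0) & (splay < 3.0)]
        counts, _ = np.histogram(inside, bins=10, range=(1.0, 3.0))
        # chi-square uniformity test at alpha = 0.01
        chi2 = np.sum((counts - counts.mean()) ** 2 / counts.mean())
        assert chi2 < stats.chi2(df=9).ppf(0.99)

    def test_minimal_two_frame_ensemble(self):
        pmf = PMFSpec("harmonic", {"kappa": 100.0, "x0": 1.0})
        ens, trace = gen_ensemble(ToyTetramerSpec(seed=0), 2, pmf, seed=0)
        assert len(ens) == 2
        assert ens.weights is None
        assert trace.bias_energy.shape == (2,)

    def test_too_few_frames_rejected(self):
        pmf = PMFSpec("harmonic", {"kappa": 100.0, "x0": 1.0})
        with pytest.raises(ValueError):
            gen_ensemble(ToyTetramerSpec(seed=0), 1, pmf, seed=0)


class TestSansGenerator:
    def _setup(self, seed=0, n=8):
        spec = ToyTetramerSpec(n_beads_per_subunit=6, seed=0)
        pmf = PMFSpec("harmonic", {"kappa": 100.0, "x0": 1.0})
        ens, _ = gen_ensemble(spec, n, pmf, seed=seed)
        q = np.linspace(0.01, 0.3, 40)
        return ens, q, np.full(n, 1.0 / n)

    def test_clean_curve_equals_weighted_debye_average(self):
        ens, q, w = self._setup()
        curves = ensemble_frame_curves(ens, q)
        data, truth = gen_sans_dataset(
            ens, w, None, 0.0, NoiseModel(relative_sigma=1e-12, seed=0), q
        )
        ref = np.einsum("f,fq->q", w, np.vstack([c.I for c in curves]))
        assert np.allclose(truth.I, ref)
        assert np.allclose(data.I, ref, rtol=1e-9)

    def test_same_seed_identical_noise(self):
        ens, q, w = self._setup()
        d1, _ = gen_sans_dataset(ens, w, None, 1.0, NoiseModel(seed=3), q)
        d2, _ = gen_sans_dataset(ens, w, None, 1.0, NoiseModel(seed=3), q)
        assert np.array_equal(d1.I, d2.I)

    def test_aggregate_lifts_low_q(self):
        ens, q, w = self._setup()
        agg = AggregateParams(0.01, 2.0, 300.0, 40.0)
        noise = NoiseModel(relative_sigma=1e-12, seed=0)
        with_agg, _ = gen_sans_dataset(ens, w, agg, 0.0, noise, q)
        without, _ = gen_sans_dataset(ens, w, None, 0.0, noise, q)
        assert with_agg.I[0] > without.I[0]

    def test_noise_z_scores_standardized(self):
        ens, q, w = self._setup()
        data, truth = gen_sans_dataset(
            ens, w, None, 2.0, NoiseModel(0.02, 1.0, seed=11), q
        )
        z = (data.I - (truth.I + 2.0)) / data.sigma
        n_q = len(q)
        assert abs(z.mean()) < 3.0 / np.sqrt(n_q)
        assert abs(z.var() - 1.0) < 3.0 * np.sqrt(2.0 / n_q)


class TestUmbrellaGenerator:
    def test_flat_pmf_windows_are_gaussian(self):
        pmf = PMFSpec("square_well", {"depth": 0.0, "x_lo": 0.0, "x_hi": 1.0})
        k = 1000.0
        windows = gen_umbrella_windows(pmf, [1.0, 2.0, 3.0], k, 4000, seed=2)
        for w in windows:
            assert w.samples.size == 4000
            assert abs(w.samples.mean() - w.center) < 0.01
            assert w.samples.var() == pytest.approx(pmf.kT / k, rel=0.15)

    def test_single_sample_windows_valid(self):
        pmf = PMFSpec("harmonic", {"kappa": 10.0, "x0": 1.0})
        windows = gen_umbrella_windows(pmf, [0.5, 1.5], 500.0, 1, seed=0)
        assert all(w.samples.size == 1 for w in windows)

    def test_barrier_window_wider_than_well_window(self):
        pmf = PMFSpec("double_well", {"height": 8.0, "x0": 2.0, "w": 0.3})
        k = 1000.0
        # barrier at x0, well at x0 + w; negative curvature at the barrier
        # partially cancels the restraint
        windows = gen_umbrella_windows(pmf, [2.0, 2.3], k, 20_000, seed=4)
        barrier, well = windows[0], windows[1]
        assert barrier.samples.var() > well.samples.var()

    def test_centers_outside_support_rejected(self):
        pmf = PMFSpec("harmonic", {"kappa": 10.0, "x0": 1.0})

        with pytest.raises(ValueError):
            gen_umbrella_windows(pmf, [2.0, 1.0], 100.0, 10, seed=0)  # not ascending


class TestEphysGenerators:
    def test_single_exponential_closed_form(self):
        trace = gen_current_trace([(1.0, 10.0)], 50.0, 0.5, 0.0, seed=0)
        k = int(round(10.0 / 0.5))
        assert trace.i[k] == pytest.approx(np.exp(-1.0))

    def test_sum_of_amplitudes_at_onset(self):
        trace = gen_current_trace([(2.0, 3.0), (1.0, 9.0)], 50.0, 0.1, 0.0, seed=0)
        assert trace.i[0] == pytest.approx(3.0)

    def test_recovery_ratio_closed_form(self):
        series = gen_recovery_series(17.0, [17.0, 34.0, 51.0, 68.0], 0.0, seed=0)
        assert series.peak_ratios[0] == pytest.approx(1 - np.exp(-1.0))

    def test_ratios_clipped_to_ceiling(self):
        series = gen_recovery_series(5.0, [200.0, 300.0, 400.0, 500.0], 0.5, seed=1)
        assert np.all(series.peak_ratios <= 1.05)
        assert np.all(series.peak_ratios >= 0.0)

    def test_invalid_dt_rejected(self):
        with pytest.raises(ValueError):
            gen_current_trace([(1.0, 5.0)], 10.0, 0.0, 0.0, seed=0)
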