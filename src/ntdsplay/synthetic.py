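"""Seeded synthetic-data generators for every input the pipeline consumes.

The generators emulate the statistical structure of the study inputs —
a tetramer ensemble in equilibrium between a compact and an NTD-splayed
state, SANS curves contaminated by a fractal-aggregate term and constant
background, biased conformational sampling along the NTD-distance
collective variable, umbrella-sampling windows, and patch-clamp
desensitization/recovery recordings — without running any molecular
dynamics or touching external data. Everything is bit-reproducible
under a fixed seed.

Units: bead geometry in Angstrom, the NTD-distance collective variable
and free-energy profiles in nm, energies in kJ/mol, currents in pA,
time in ms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._sampling import metropolis
from .beads import (
    BeadConformation,
    ConformationalEnsemble,
    debye_intensity,
    ensemble_average_intensity,
)
from .curves import ScatteringCurve
from .ephys import CurrentTrace, RecoverySeries
from .purification import AggregateParams, fractal_structure_factor
from .reweight import BiasTrace
from .wham import UmbrellaWindow

__all__ = [
    "KT_300K",
    "KT_323K",
    "ToyTetramerSpec",
    "PMFSpec",
    "NoiseModel",
    "gen_toy_tetramer",
    "gen_ensemble",
    "gen_two_state_ensemble",
    "ensemble_frame_curves",
    "gen_sans_dataset",
    "gen_umbrella_windows",
    "gen_current_trace",
    "gen_recovery_series",
]

#: kT in kJ/mol at the two thermostat settings used by the two analysis
#: tiers: 300 K for the atomistic-analog stages (umbrella sampling / PMF)
#: and 323 K for the coarse-grained-analog stages (biased ensembles).
KT_300K = 2.494
KT_323K = 2.686


@dataclass
class ToyTetramerSpec:
    """Geometry of the toy tetramer bead model.

    Four bead clusters stand in for the tetramer: two "NTD dimer"
    clusters whose center-of-mass separation is ``base_ntd_distance +
    splay``, and two anchor clusters (the LBD/TMD-like body). Only the
    NTD-pair axis is modulated by ``splay``; that isolates the one
    coordinate the analysis uses.
    """

    n_beads_per_subunit: int = 25
    subunit_radius: float = 15.0  # A
    splay: float = 0.0  # A, added separation between the NTD clusters
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_beads_per_subunit < 1:
            raise ValueError("n_beads_per_subunit must be >= 1")
        if self.subunit_radius <= 0:
            raise ValueError("subunit_radius must be positive")
        if self.splay < 0:
            raise ValueError("splay must be >= 0")

    @property
    def base_ntd_distance(self) -> float:
        """NTD-cluster COM separation at splay = 0 (A)."""
        return 2.0 * self.subunit_radius + 10.0


@dataclass
class PMFSpec:
    """Analytic free-energy profile G(x) over a 1-D coordinate x (nm).

    Forms
    -----
    harmonic : 0.5*kappa*(x-x0)^2 — params ``kappa`` (kJ/mol/nm^2), ``x0``.
    double_well : barrier ``height`` at ``x0`` with minima at x0 +- ``w``
        (quartic; wells at G = 0).
    morse_like : depth ``depth`` at ``x0``, range parameter ``alpha``
        (1/nm); G -> 0 at large separation — the generic shape of an
        NTD-binding profile.
    square_well : G = -``depth`` on [``x_lo``, ``x_hi``], 0 outside.
    """

    form: str
    parameters: dict
    kT: float = KT_300K

    def __post_init__(self) -> None:
        if self.kT <= 0:
            raise ValueError("kT must be positive")
        if self.form not in ("harmonic", "double_well", "morse_like", "square_well"):
            raise ValueError(f"unknown PMF form {self.form!r}")
        for v in self.parameters.values():
            if not np.isfinite(v):
                raise ValueError("PMF parameters must be finite")

    def energy(self, x):
        """G(x) in kJ/mol, vectorized over x (nm)."""
        x = np.asarray(x, dtype=float)
        p = self.parameters
        if self.form == "harmonic":
            return 0.5 * p["kappa"] * (x - p["x0"]) ** 2
        if self.form == "double_well":
            w = p["w"]
            return p["height"] * ((x - p["x0"]) ** 2 - w**2) ** 2 / w**4
        if self.form == "morse_like":
            e = 1.0 - np.exp(-p["alpha"] * (x - p["x0"]))
            return p["depth"] * (e**2 - 1.0)
        # square_well
        inside = (x >= p["x_lo"]) & (x <= p["x_hi"])
        return np.where(inside, -p["depth"], 0.0)

    def suggest_start(self) -> float:
        """A point of low free energy, used to seed Metropolis chains."""
        p = self.parameters
        if self.form == "harmonic":
            return float(p["x0"])
        if self.form == "double_well":
            return float(p["x0"] + p["w"])
        if self.form == "morse_like":
            return float(p["x0"])
        return 0.5 * (p["x_lo"] + p["x_hi"])


@dataclass
class NoiseModel:
    """Heteroscedastic SANS noise: sigma(q) = rel*I(q)*(1 + c*q_scale/q).

    ``relative_sigma`` sets the relative error at high q; the
    ``low_q_inflation`` coefficient ``c`` inflates errors as 1/q below
    the reference momentum transfer ``q_scale`` (0.01 1/A), which gives
    SANS-like low-q error bars. This emulates an instrument error model;
    it reproduces no particular beamline.
    """

    relative_sigma: float = 0.01
    low_q_inflation: float = 0.0
    seed: int = 0
    q_scale: float = 0.01  # 1/A

    def __post_init__(self) -> None:
        if self.relative_sigma <= 0:
            raise ValueError("relative_sigma must be positive")
        if self.low_q_inflation < 0:
            raise ValueError("low_q_inflation must be >= 0")

    def sigma(self, q, I):
        q = np.asarray(q, dtype=float)
        return self.relative_sigma * np.abs(I) * (
            1.0 + self.low_q_inflation * self.q_scale / q
        )


# ---------------------------------------------------------------------------
# structural generators


def _cluster_beads(center, n, radius, rng):
    """n beads uniform in a sphere, recentred so their mean is exactly center."""
    pts = np.empty((n, 3))
    got = 0
    while got < n:
        cand = rng.uniform(-radius, radius, size=(n - got, 3))
        ok = (cand**2).sum(1) <= radius**2
        k = int(ok.sum())
        pts[got : got + k] = cand[ok]
        got += k
    pts -= pts.mean(0)  # exact COM placement (unit scattering lengths)
    return pts + np.asarray(center, dtype=float)


def gen_toy_tetramer(spec: ToyTetramerSpec) -> BeadConformation:
    """Build the four-cluster toy tetramer for a given splay.

    The distance between the centers of mass of the two NTD clusters is
    exactly ``spec.base_ntd_distance + spec.splay``. For a fixed seed the
    intra-cluster bead layout is identical across splay values, so two
    conformations differing only in ``splay`` differ only along the
    NTD-pair axis.
    """
    rng = np.random.default_rng(spec.seed)
    r = spec.subunit_radius
    d = spec.base_ntd_distance + spec.splay
    h = 1.5 * r
    centers = {
        "NTD_AB": (-d / 2.0, 0.0, h),
        "NTD_CD": (+d / 2.0, 0.0, h),
        "anchor_1": (0.0, -r, -h),
        "anchor_2": (0.0, +r, -h),
    }
    coords, labels = [], []
    for name, c in centers.items():
        coords.append(_cluster_beads(c, spec.n_beads_per_subunit, r, rng))
        labels.extend([name] * spec.n_beads_per_subunit)
    return BeadConformation(
        np.vstack(coords), cluster_labels=np.array(labels, dtype=object)
    )


def ntd_distance(conf: BeadConformation) -> float:
    """NTD-distance collective variable of a toy conformation (A)."""
    d = conf.cluster_com("NTD_CD") - conf.cluster_com("NTD_AB")
    return float(np.linalg.norm(d))


def gen_ensemble(
    spec: ToyTetramerSpec,
    n_frames: int,
    splay_sampler: PMFSpec,
    seed: int,
    bias=None,
    step: float = 0.1,
    build_frames: bool = True,
):
    """Draw an ensemble by Metropolis sampling of the splay coordinate.

    Frames are sampled from exp(-(G(x) + V_bias(x))/kT) where G is the
    ``splay_sampler`` profile over splay x (nm) and ``bias`` is an
    optional callable V_bias(x) in kJ/mol (zero when omitted) — the
    synthetic analog of a biased (metadynamics-like) trajectory. The
    per-frame bias energies are recorded in the returned
    :class:`~ntdsplay.reweight.BiasTrace`; the collective variable is
    the NTD-cluster COM distance in nm.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    v_bias = bias if bias is not None else (lambda x: np.zeros_like(np.asarray(x, float)))

    def total(x):
        x = np.asarray(x, dtype=float)
        g = splay_sampler.energy(x) + np.asarray(v_bias(x), dtype=float)
        return np.where(x >= 0, g, np.inf)  # splay cannot be negative

    x0 = max(splay_sampler.suggest_start(), 0.0)
    if not np.isfinite(total(np.atleast_1d(x0))[0]):
        raise ValueError("PMF is not finite at the sampling start point")
    rng = np.random.default_rng(seed)
    splay_nm, _ = metropolis(total, x0, n_frames, splay_sampler.kT, rng, step=step)

    cv = (spec.base_ntd_distance + 10.0 * splay_nm) / 10.0  # nm
    if build_frames:
        frames = [
            gen_toy_tetramer(
                ToyTetramerSpec(
                    spec.n_beads_per_subunit, spec.subunit_radius, 10.0 * s, spec.seed
                )
            )
            for s in splay_nm
        ]
        ensemble = ConformationalEnsemble(frames, cv=cv)
    else:
        # statistical checks of the sampler need only the trace
        ensemble = None
    trace = BiasTrace(
        cv=cv,
        bias_energy=np.asarray(v_bias(splay_nm), dtype=float),
        kT=splay_sampler.kT,
    )
    return ensemble, trace


def gen_two_state_ensemble(
    spec: ToyTetramerSpec,
    n_frames: int,
    splay_compact: float = 0.0,
    splay_splayed: float = 3.0,
    splayed_fraction: float = 0.5,
    jitter: float = 0.05,
    seed: int = 0,
):
    """Two-state (compact/splayed) ensemble with an exact state split.

    ``splay_compact``/``splay_splayed`` are in nm; ``splayed_fraction``
    of the frames (rounded) are splayed. Small Gaussian jitter on the
    splay keeps frames within a state non-identical. Returns
    ``(ensemble, is_splayed)`` where the boolean array is the generator
    truth downstream recovery experiments are scored against.
    """
    rng = np.random.default_rng(seed)
    n_splayed = int(round(splayed_fraction * n_frames))
    is_splayed = np.zeros(n_frames, dtype=bool)
    is_splayed[n_frames - n_splayed :] = True
    splay_nm = np.where(is_splayed, splay_splayed, splay_compact)
    splay_nm = np.maximum(splay_nm + jitter * rng.standard_normal(n_frames), 0.0)
    frames = [
        gen_toy_tetramer(
            ToyTetramerSpec(
                spec.n_beads_per_subunit, spec.subunit_radius, 10.0 * s, spec.seed
            )
        )
        for s in splay_nm
    ]
    cv = (spec.base_ntd_distance + 10.0 * splay_nm) / 10.0
    return ConformationalEnsemble(frames, cv=cv), is_splayed


# ---------------------------------------------------------------------------
# scattering generator


def ensemble_frame_curves(ensemble: ConformationalEnsemble, q_grid) -> list:
    """Per-frame Debye intensities on a shared q grid."""
    return [debye_intensity(f, q_grid) for f in ensemble.frames]


def gen_sans_dataset(
    ensemble: ConformationalEnsemble,
    true_weights,
    aggregate: AggregateParams | None,
    background: float,
    noise: NoiseModel,
    q_grid,
    frame_curves=None,
):
    """Synthetic SANS measurement of a weighted ensemble.

    I(q) = sum_f w_f I_f(q) + I_agg(q) + background, with Gaussian noise
    whose per-point sigma comes from the :class:`NoiseModel`. The
    aggregate term follows the aggregates-of-tetramers model,
    I_agg(q) = c_a * P_tet(q) * S(q), with P_tet the weighted ensemble
    form factor and S the fractal structure factor.

    Returns ``(data, truth)``: the noisy contaminated curve (with the
    sigma column) and the aggregate-free, background-free, noise-free
    ensemble average used to build it.
    """
    w = np.asarray(true_weights, dtype=float)
    if len(w) != len(ensemble):
        raise ValueError("one weight per frame required")
    if frame_curves is None:
        frame_curves = ensemble_frame_curves(ensemble, q_grid)
    truth = ensemble_average_intensity(frame_curves, w)
    I = truth.I.copy()
    if aggregate is not None and aggregate.fraction_scale > 0:
        S = fractal_structure_factor(
            truth.q,
            aggregate.fractal_dimension,
            aggregate.correlation_length,
            aggregate.building_block_radius,
        )
        I = I + aggregate.fraction_scale * truth.I * S
    I = I + background
    sigma = noise.sigma(truth.q, I)
    rng = np.random.default_rng(noise.seed)
    data = ScatteringCurve(
        truth.q.copy(), I + sigma * rng.standard_normal(I.shape), sigma
    )
    return data, truth


# ---------------------------------------------------------------------------
# umbrella windows


def gen_umbrella_windows(
    pmf: PMFSpec,
    centers,
    k: float,
    n_per_window: int,
    seed: int,
    step: float = 0.05,
    thin: int = 5,
):
    """Metropolis samples from each harmonically restrained window.

    Each window holds ``n_per_window`` samples of
    exp(-(G(x) + 0.5*k*(x-c)^2)/kT); the post-burn-in acceptance rate is
    recorded on the window. Chains are thinned (default: keep every 5th
    step) so the retained samples are close to decorrelated — the
    downstream histogram analysis assumes that. Defaults mirror umbrella
    runs restrained at 0.1-nm-spaced centers with k = 1000 kJ/mol/nm^2.
    """
    centers = np.asarray(centers, dtype=float)
    if k <= 0:
        raise ValueError("force constant must be positive")
    if centers.size == 0 or np.any(np.diff(centers) <= 0):
        raise ValueError("centers must be ascending and non-empty")
    g0 = pmf.energy(centers)
    if not np.all(np.isfinite(g0)):
        raise ValueError("PMF not finite at some window centers")

    def u(x):
        return pmf.energy(x) + 0.5 * k * (x - centers) ** 2

    rng = np.random.default_rng(seed)
    samples, acc = metropolis(
        u, centers, n_per_window, pmf.kT, rng, step=step, thin=thin
    )
    samples = np.atleast_2d(samples)
    acc = np.atleast_1d(acc)
    return [
        UmbrellaWindow(
            center=float(c),
            force_constant=float(k),
            samples=samples[:, j].copy(),
            acceptance_rate=float(acc[j]),
        )
        for j, c in enumerate(centers)
    ]


# ---------------------------------------------------------------------------
# electrophysiology generators


def gen_current_trace(
    tau_entries,
    duration: float,
    dt: float,
    noise_sd: float,
    seed: int,
    onset: float = 0.0,
) -> CurrentTrace:
    """Multi-exponential current decay y(t) = sum_i A_i exp(-t/tau_i) + noise.

    ``tau_entries`` is a list of (amplitude pA, tau ms) pairs; the decay
    starts at ``onset`` (trace is zero before). Negative amplitudes give
    the physiological negative-going currents.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    for _, tau in tau_entries:
        if tau <= 0:
            raise ValueError("tau must be positive")
    t = np.arange(0.0, duration + 0.5 * dt, dt)
    i = np.zeros_like(t)
    after = t >= onset
    for A, tau in tau_entries:
        i[after] += A * np.exp(-(t[after] - onset) / tau)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        i = i + noise_sd * rng.standard_normal(i.shape)
    return CurrentTrace(t=t, i=i, stimulus_onset=onset)


def gen_recovery_series(
    tau_recov: float, intervals, noise_sd: float, seed: int
) -> RecoverySeries:
    """Two-pulse recovery ratios 1 - exp(-dt/tau_recov) plus noise.

    Ratios are clipped to [0, 1.05] (a peak ratio slightly above 1 can
    occur through noise; larger values are unphysical).
    """
    if tau_recov <= 0:
        raise ValueError("tau_recov must be positive")
    intervals = np.asarray(intervals, dtype=float)
    if np.any(intervals <= 0):
        raise ValueError("intervals must be positive")
    order = np.argsort(intervals)
    intervals = intervals[order]
    ratios = 1.0 - np.exp(-intervals / tau_recov)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        ratios = ratios + noise_sd * rng.standard_normal(ratios.shape)
    return RecoverySeries(
        interpulse_intervals=intervals, peak_ratios=np.clip(ratios, 0.0, 1.05)
    )
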