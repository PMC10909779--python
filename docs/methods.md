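# Methods

`ntdsplay` is a desk-scale re-implementation of the analysis chain that
connects AMPA-receptor N-terminal-domain (NTD) splaying to
desensitization kinetics: forward scattering from coarse bead models,
subtraction of a fractal-aggregate contribution from small-angle
neutron scattering (SANS) curves, Bayesian/maximum-entropy (BME)
reweighting of a biased conformational ensemble against the cleaned
curve, umbrella-sampling/WHAM estimation of the NTD binding free
energy, and exponential kinetics fits of desensitization entry and
recovery. No molecular dynamics is run anywhere; a seeded
synthetic-data module generates every input with the statistical
structure the analysis assumes, so each stage can be calibrated
against known truth.

## The toy tetramer and its ensemble

The structural object is a four-cluster bead model: two "NTD dimer"
clusters and two anchor clusters standing in for the rest of the
receptor. Beads are uniform in a sphere of the subunit radius
(default 15 Å, 12–25 beads per cluster, unit scattering lengths), and
each cluster is recentred so its center of mass sits exactly on its
target site. The single structural coordinate is the *splay*: the
extra separation added along the NTD-pair axis, so the NTD
center-of-mass distance is exactly `base + splay` (base = 2·radius +
10 Å). For a fixed seed the intra-cluster bead layout is identical
across splay values — two frames differ only along the coordinate the
analysis uses. This isolates the collective variable on purpose; the
toy model makes no attempt to reproduce the real receptor's Rg (real
values run ~49–67 Å; the toy compact/splayed states sit near 31/37 Å
with the default geometry).

Ensembles are drawn by a 1-D Metropolis walk on the splay coordinate
under an analytic free-energy profile G(x) plus an optional bias
V_bias(x) (the synthetic analog of a converged metadynamics bias).
The sampler auto-tunes its step to 30–50% acceptance during a 10%
burn-in that is discarded; retained samples therefore obey detailed
balance for the final step size. Ensemble chains are not thinned
(serial correlation inflates statistical error but not bias, and the
calibration experiments size their sampling accordingly); the
umbrella-window generator thins by 5 — see the WHAM section.
Profile forms available: harmonic, quartic double-well, Morse-like
(generic binding profile: minimum −depth at contact, zero at large
separation), and square well. kT defaults: 2.494 kJ/mol (300 K) for
the umbrella/PMF stages, 2.686 kJ/mol (323 K) for the
coarse-grained-style ensemble stages; both configurable.

## Forward scattering

`debye_intensity` evaluates the exact pairwise Debye sum
I(q) = Σᵢⱼ bᵢbⱼ sin(q rᵢⱼ)/(q rᵢⱼ); self terms contribute Σbᵢ², and
I(0) = (Σb)². An optional distance-histogram path (1 Å bins) uses the
per-bin first moment as the representative distance and a
second-moment curvature correction, which keeps it within ~10⁻⁴
relative of the exact sum for q ≤ 0.5 Å⁻¹ — far inside its 0.5%
contract. Scattering code works in Å and Å⁻¹; the collective-variable
and PMF code in nm, with one explicit conversion (1 nm = 10 Å).

No hydration layer or solvent contrast is modelled: the scalar
scale/background fitted against data absorbs contrast, and absolute
comparison to profiles from hydration-aware external calculators is
not attempted.

## SANS noise model

σ(q) = relative_sigma · I(q) · (1 + c·q_scale/q), with q_scale = 0.01
Å⁻¹. The 1/q term emulates the low-q error-bar inflation of SANS
instruments (the inflation equals c at q = q_scale); it reproduces no
particular beamline. Purification calibration uses c = 0 (flat 1%
noise) because the criterion it certifies is phrased at a flat noise
level and the aggregate parameters are identified exactly by the
low-q points the inflation would drown.

## In-silico purification

Aggregates are modelled as mass fractals *of the tetramer itself*:
I_agg(q) = c_a · P_tet(q) · S(q), with S the Teixeira fractal
structure factor parameterized by dimension D (fixed to 2 during
fits, configurable), correlation length ξ and building-block radius
r0. r0 is fixed to the tetramer form factor's sphere-equivalent
Guinier radius √(5/3)·Rg. The composite fit (c_tet, c_a, ξ,
background) is a trust-region weighted least squares (bounds c ≥ 0,
ξ > r0; tolerances 1e-12, max ~500 iterations); a c_a that lands on
its zero bound is reported as 0 with a warning. Subtraction removes
*only* the fitted aggregate term; the constant background stays in
the curve (it belongs to any later fit), and σ is copied unchanged —
the subtracted term is a smooth fitted model treated as noise-free.

The model-free χ²_r floor comes from a Bayesian indirect Fourier
transform: a 60-bin p(r) on [0, D_max] with a second-difference
smoothness prior (implicit zero boundaries) and a free constant
background; α is selected by a Laplace-approximation evidence over a
41-point log grid (10⁻²…10¹⁸) and D_max by golden-section around the
initial guess. χ²_r uses n_q minus the effective number of determined
parameters (trace of the resolution matrix). A p(r) piling up near
D_max triggers a warning that the assumed extent is too small.

## Bias-to-weight conversion and BME reweighting

Final-bias reweighting assigns prior weights w0ᵢ ∝ exp(+V_bias,ᵢ/kT)
(max-shifted exponents; invariant to constant offsets). "Inverse of
the bias" means this exponential inversion, not 1/V.

BME minimizes Q(w) = χ²_r(w) − θ·S_REL(w) over the weight simplex,
with S_REL = −Σ wᵢ ln(wᵢ/w0ᵢ) ≤ 0 (zero iff w = w0), χ²_r on n_q − 2
degrees of freedom. The optimum has the Gibbs form
wᵢ ∝ w0ᵢ·exp(−Σ_q λ_q Iᵢ(q)), and the convex dual over λ is solved by
damped Newton with the analytic Hessian on residual-scaled
multipliers (gradient tolerance 10⁻⁸, λ = 0 start, deterministic). A
generic quasi-Newton solver was not reliable at small θ, where the
dual is badly conditioned; the exact Newton step is.

The global scale and background entering χ² are profile-refitted in
closed form against the current weighted average, alternating with
the weight update (block coordinate descent, monotone in Q). Freezing
them at the prior-average fit — the literal "fit once, freeze"
reading — biases χ²_r by several units at the generating weights and
was rejected; the freeze remains available through arguments for
scans that need strictly shared globals.

θ is scanned over 10⁻³…10³ (25 log-spaced points by default; θ = 1 is
the replication preset) and selected at the knee of the χ²_r-vs-φ_eff
trade-off, computed as the maximum chord distance on normalized
(φ_eff, ln χ²_r) axes. The log on χ²_r matters: the scan spans two
orders of magnitude in misfit and a linear axis pushes the apparent
knee deep into the underfit regime. φ_eff = exp(S_REL) is the Kish
effective sample fraction. When an IFT floor is supplied, the largest
θ whose χ²_r reaches the floor is reported alongside (the least
perturbation consistent with the data).

Calibration: with a 50/50 compact/splayed truth measured at 1% noise
and a 90/10 prior, the knee-selected posterior splayed fraction is
0.50 ± 0.05 across seeds, with χ²_r ≈ 1 at selection.

## WHAM and binding free energy

Standard self-consistent WHAM over window offsets f_k (log-sum-exp
throughout; tolerance 10⁻⁶ kT on max|Δf|, max 10⁵ iterations, 0.02 nm
bins). Windows must form a connected chain through shared occupied
bins; a gap raises an error naming the disconnected centers. A single
k = 0 window degenerates to −kT·ln(histogram). The profile is
anchored to min G = 0; ΔG = G(bound minimum) − mean G over the
plateau interval (by default the far tail of the sampled range), and
is anchoring-independent. The bound minimum is read from a 5-bin
moving average of the profile: the raw minimum over ~10² noisy bins
is extreme-value-biased deep — enough to misread a −1.6 kJ/mol well
as −2.1 — while the boxcar's own parabolic bias is ~0.2 kJ/mol at
the default bin width and typical well curvatures.

The umbrella generator thins its Metropolis chains by a factor 5, so
the retained samples are close to decorrelated — which is exactly
the premise the WHAM estimator and the bootstrap are built on.
Unthinned chains at the tuned acceptance carry an integrated
autocorrelation time of ~5–10 steps and inflate the per-run ΔG
scatter to ~0.6 kJ/mol, comparable to the separation of the two
weakest calibration wells.

Bins outside every window's restrained support (|x − c| > 3·√(kT/k))
are dropped by default. Such bins hold a handful of correlated
excursions, and their noisy G estimates can otherwise capture the
global minimum (observed: a −3.6 kJ/mol well misread as −10 kJ/mol
through one junk tail bin). Per-bin errors and the ΔG standard error
come from a within-window bootstrap (resampling assumes decorrelated
samples; with correlated chains it underestimates somewhat).

Calibration depths follow the four construct binding strengths
(−40, −26, −3.6, −1.6 kJ/mol) through Morse-like profiles, windows
0.6–3.5 nm at 0.1 nm spacing, k = 1000 kJ/mol/nm², 5000
samples/window: all depths return within ±2 kJ/mol and the strength
ordering is reproduced in ≥95% of seeds. The harmonic-truth RMSD
check (< 0.3 kJ/mol over the restrained range) is run at 30,000
samples/window, where Metropolis autocorrelation noise (~0.4–0.5
kJ/mol at 5000) no longer dominates the quantity being certified.

## Kinetics

Decay fits: the segment from the detected peak (3-point-median
smoothed extremum after stimulus onset) to the stimulus end is
normalized to peak = 1 (baseline fixed to the pre-stimulus mean) and
fitted with y = Σ Aᵢ·exp(−t/τᵢ), order 1 or 2, log-linear initial
guesses, τ bounded in [10⁻³, 10⁴] ms (bound hits are flagged). With
order unspecified, the biexponential must beat the monoexponential by
more than 10 AIC units; exponential components are heavily nested and
plain AIC accepts a noise component in ~12% of monoexponential traces
at SNR 20, while the strong-evidence margin keeps both error
directions below 5%. Weighted time constant: Σ Aᵢτᵢ/Σ Aᵢ
(amplitude-fraction weighting, the field convention for weighted
means).

Recovery: ratios of test- to initial-pulse peaks, fitted with
r(Δt) = 1 − (1 − r0)·exp(−Δt/τ). r0 (the zero-interval ratio) is free
with lower bound 0 by default; the calibration experiments fix
r0 = 0 because the synthetic protocol desensitizes fully at Δt → 0
and freeing a boundary-constrained nuisance parameter adds a ~+7%
bias to τ. With the matched model, bias < 3% and SD < 10% of truth at
5% noise over 100 replicates, for τ ∈ {17, 30, 75} ms. The low-pH
peak ratio is |peak_low|/|peak_ref| from independently detected
peaks.

## Titration arithmetic

Protonated fraction f = 1/(1 + 10^(pH−pKa)); pKa and burial fractions
are inputs from external predictors, never computed here. f = 0.5 at
pH = pKa and the occupancy odds change 10-fold per pH unit.

## What the synthetic data does and does not show

The generators emulate: two-state structural heterogeneity with a
low-q-visible size change, aggregate-contaminated heteroscedastic
SANS curves, biased/bimodal sampling along one collective variable,
harmonic-window sampling of analytic binding profiles, and mono/
bi-exponential currents with first-order recovery. They do not
emulate: real instrument resolution/smearing, hydration-layer
contrast, force-field error, multi-dimensional conformational
coupling, channel rundown, or series-resistance artifacts. Passing
calibrations therefore certify the *estimators* (they recover known
truth under the assumed statistics), not the field accuracy of any
particular published number.

## Problem sizes and numerical defaults

Calibration experiments use: 160-frame ensembles on 60-point q grids
(reweighting), 100-point log q grids (purification), 30 windows ×
5000 samples (ΔG recovery; 30,000 for the harmonic RMSD
certification), 100 replicates for kinetics. These sizes were chosen
so each experiment resolves its tolerance with margin while the whole
calibration suite completes in a few minutes on one core. Defaults
exposed in config: WHAM bin 0.02 nm, tol 10⁻⁶ kT; BME gradient tol
10⁻⁸; IFT α grid 10⁻²…10¹⁸ (41 points), 60 p(r) bins; Metropolis
burn-in 10%, acceptance target 30–50%.

## Known limitations

- Single-chain Metropolis sampling is serially correlated; error bars
  derived from sample counts (bootstrap, SEM arguments) are mildly
  optimistic.
- The aggregate model assumes the aggregating unit is the tetramer
  itself and a fixed fractal dimension; misspecified aggregates leave
  a biased ξ/c_a, though the filtered curve remains fit-table (the
  pipeline demo shows this regime deliberately).
- The IFT evidence is a Laplace approximation on a fixed grid; the
  χ²_r floor inherits its α/D_max discretization.
- Degenerate inputs are rejected loudly rather than repaired: zero-σ
  data points, constant model curves, disconnected window chains,
  all-recovered recovery series.
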