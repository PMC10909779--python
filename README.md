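# ntdsplay

Desk-scale analysis of AMPA-receptor **N-terminal-domain (NTD)
splaying** and its link to channel desensitization. AMPA-type
glutamate receptors are tetramers whose two NTD dimers can separate
("splay") while the channel is desensitized; how much they splay, how
strongly the NTD interface binds, and how fast the channel enters and
leaves desensitization are measured by three very different
experiments — small-angle neutron scattering (SANS), free-energy
simulations, and patch-clamp recordings. `ntdsplay` implements the
full analysis chain for all three, together with seeded synthetic-data
generators that emulate each input, so every estimator in the chain
can be calibrated against known truth without any molecular-dynamics
engine or external dataset.

The four analysis stages, each usable on its own:

1. **Forward scattering** (`ntdsplay.beads`) — exact Debye sums
   I(q) = Σᵢⱼ bᵢbⱼ sin(qrᵢⱼ)/(qrᵢⱼ) and radii of gyration from bead
   models; closed-form scale/background fits.
2. **In-silico purification** (`ntdsplay.purification`) — SANS curves
   of aggregate-prone samples are fitted as
   I(q) = c_tet·P_tet(q) + c_a·P_tet(q)·S(q) + b, where S is the
   Teixeira mass-fractal structure factor (for D = 2,
   S(q) = 1 + 2(ξ/r₀)²/(1 + q²ξ²)); the fitted aggregate term is then
   subtracted. A Bayesian indirect Fourier transform supplies the
   model-free χ²ᵣ floor a structural model can aim for.
3. **Ensemble reweighting** (`ntdsplay.reweight`) — frame weights from
   a biased simulation (w₀ᵢ ∝ exp(+V_bias,ᵢ/kT)) are refined against
   the cleaned SANS curve by Bayesian/maximum-entropy reweighting:
   minimize Q = χ²ᵣ − θ·S_REL with S_REL = −Σ wᵢ ln(wᵢ/w₀ᵢ), solved in
   its convex dual; θ is chosen at the knee of the χ²ᵣ-vs-φ_eff scan.
   The headline readout is the posterior **splayed fraction** of the
   ensemble and the weighted Rg distribution.
4. **Free energies and kinetics** (`ntdsplay.wham`, `ntdsplay.ephys`)
   — WHAM over umbrella windows gives the NTD-distance potential of
   mean force and the binding free energy ΔG (bound minimum vs.
   far-separation plateau); exponential fits of current decays
   (y = Σ Aᵢ e^(−t/τᵢ), amplitude-weighted τ) and two-pulse recovery
   series (r(Δt) = 1 − (1−r₀)e^(−Δt/τ)) give the desensitization
   entry/recovery time constants and the low-pH peak ratio.
   `ntdsplay.protonation` adds Henderson–Hasselbalch occupancies
   f = 1/(1 + 10^(pH−pKa)) for titratable interface residues.

`ntdsplay.synthetic` generates every input (two-state tetramer
ensembles, contaminated SANS curves, umbrella windows, current
traces), and `ntdsplay.pipeline` ties the stages into a seeded,
reproducible run with a JSON report. A thin CLI (`ntd`) exposes the
same operations from the shell.

## Worked example

Recover a 50/50 compact/splayed population from a simulation prior
that badly underweights the splayed state (`examples/03_reweighting.py`):

```text
theta      chi2_r   phi_eff   splayed fraction
    0.001     0.65     0.381      0.493
     0.01     0.66     0.495      0.493
      0.1     0.66     0.603      0.490
        1     0.67     0.617      0.487
       10     0.91     0.645      0.466
      100    13.01     0.834      0.320
    1e+03    54.90     0.995      0.130

knee of the scan: theta = 3.16, chi2_r = 0.69, phi_eff = 0.62
posterior splayed fraction = 0.482  (truth 0.500, prior 0.100)
```

Reading the scan: at large θ the weights stay near the 90/10 prior
(φ_eff → 1) and the fit is poor (χ²ᵣ ≈ 55); at small θ the data are
overfitted at the cost of effective sample size. The knee selects
θ ≈ 3, where χ²ᵣ has reached the noise floor while 62% of the frames
still contribute — and the posterior splayed mass lands on the true
50%.

The other examples are equally short: forward scattering
(`01_forward_scattering.py`), aggregate subtraction with the IFT
floor (`02_purification.py`; recovers c_a = 0.028 vs truth 0.030,
ξ = 156 Å vs 150 Å), WHAM binding energy (`04_wham_binding.py`;
ΔG = −25.99 ± 0.31 kJ/mol for a −26 kJ/mol well), kinetics fits
(`05_kinetics.py`), titration (`06_protonation.py`), and the full
pipeline (`07_full_pipeline.py`, equivalently
`ntd run --seed 1 --out report.json`).

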