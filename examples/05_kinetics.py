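"""Desensitization kinetics: decay fits, recovery fits, pH peak ratio.

Generates noisy current traces (entry into desensitization), a
two-pulse recovery series, and a low-pH/reference peak pair, then fits
the standard kinetic quantities: the (weighted) entry time constant,
the first-order recovery time constant, and the peak-current ratio.
"""

from ntdsplay.ephys import fit_decay, fit_recovery, peak_ratio_ph
from ntdsplay.synthetic import gen_current_trace, gen_recovery_series

# entry into desensitization: tau = 8.9 ms at SNR 20
trace = gen_current_trace([(-1.0, 8.9)], 250.0, 0.04, 0.05, seed=2)
decay = fit_decay(trace)
print(f"entry: fitted order {decay.order}, "
      f"tau_weighted = {decay.tau_weighted:.2f} ms (truth 8.9)")

# recovery from desensitization at two time scales
for tau in (17.0, 75.0):
    series = gen_recovery_series(tau, [5, 10, 20, 40, 80, 160], 0.05, seed=4)
    fit = fit_recovery(series, r0_free=False)
    print(f"recovery: tau_recov = {fit:6.2f} ms (truth {tau:.0f})")

# proton block of the peak current
ref = gen_current_trace([(-1.0, 8.9)], 100.0, 0.04, 0.05, seed=5)
low = gen_current_trace([(-0.12, 4.5)], 100.0, 0.04, 0.006, seed=6)
print(f"peak ratio (low pH / reference) = {peak_ratio_ph(low, ref):.3f} "
      "(truth 0.120)")
print("\nA >4-fold slowing of recovery plus a ~12% peak ratio is the "
      "kinetic fingerprint of strong proton modulation.")
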