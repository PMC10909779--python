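"""Forward scattering of a compact vs an NTD-splayed toy tetramer.

Builds the two bead-model states, computes their Debye scattering
curves and radii of gyration, and checks the Guinier region against
the direct Rg. Splaying the NTD pair makes the particle larger, which
shows up as a bigger Rg and a steeper low-q falloff — the signal the
ensemble reweighting stage feeds on.
"""

import numpy as np

from ntdsplay.beads import debye_intensity, guinier_rg, radius_of_gyration
from ntdsplay.synthetic import ToyTetramerSpec, gen_toy_tetramer

q = np.linspace(0.002, 0.3, 80)
for label, splay in [("compact", 0.0), ("splayed (+30 A)", 30.0)]:
    conf = gen_toy_tetramer(ToyTetramerSpec(splay=splay, seed=1))
    curve = debye_intensity(conf, q)
    rg = radius_of_gyration(conf)
    rg_guinier = guinier_rg(curve)
    print(
        f"{label:16s}  Rg = {rg:5.2f} A   Guinier Rg = {rg_guinier:5.2f} A   "
        f"I(q_min)/I(q_max) = {curve.I[0] / curve.I[-1]:8.1f}"
    )
print(
    "\nRg grows with splay and the Guinier estimate tracks the direct value "
    "to a few percent; the intensity contrast shows the shape change the "
    "SANS data can detect."
)
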