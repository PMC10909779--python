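import numpy as np
import pytest

from ntdsplay.beads import ensemble_average_intensity
from ntdsplay.synthetic import (
    ToyTetramerSpec,
    ensemble_frame_curves,
    gen_two_state_ensemble,
)


@pytest.fixture
def toy_spec():
    return ToyTetramerSpec(n_beads_per_subunit=12, subunit_radius=15.0, seed=0)


def state_weights(is_splayed, splayed_mass):
    """Frame weights putting `splayed_mass` on the splayed state."""
    n_s = int(is_splayed.sum())
    n_c = is_splayed.size - n_s
    w = np.empty(is_splayed.size)
    w[~is_splayed] = (1.0 - splayed_mass) / max(n_c, 1)
    w[is_splayed] = splayed_mass / max(n_s, 1)
    return w / w.sum()


def make_two_state(seed, n_frames=160, n_q=60, spec=None):
    """Two-state ensemble + frame curves on a shared q grid."""
    spec = spec or ToyTetramerSpec(n_beads_per_subunit=12, subunit_radius=15.0, seed=0)
    ens, is_spl = gen_two_state_ensemble(spec, n_frames, splayed_fraction=0.5, seed=seed)
    q = np.linspace(0.005, 0.3, n_q)
    fc = ensemble_frame_curves(ens, q)
    return spec, ens, is_spl, q, fc


@pytest.fixture
def two_state():
    return make_two_state(seed=3)
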