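import numpy as np
import pytest

from kqfod.dictionary import build_dictionary, sample_hemisphere
from kqfod.forward_model import TissueMaps
from kqfod.phantom import make_phantom, make_phase_maps, simulate_coils
from kqfod.sampling import masks_for_scheme, qspace_single_shell


@pytest.fixture(scope="session")
def dirs48():
    return sample_hemisphere(48, seed=0)


@pytest.fixture(scope="session")
def small_setup(dirs48):
    """12x12x8 phantom with a 15-gradient single-shell scheme, full k-space,
    4 coils — the workhorse for solver and calibration tests."""
    phantom = make_phantom((12, 12, 8), dirs=dirs48, seed=1)
    scheme = qspace_single_shell(15, seed=0)
    dictionary = build_dictionary(scheme, dirs48)
    masks = masks_for_scheme(scheme, phantom.shape, factor=1.0)
    coils = simulate_coils(phantom.shape, C=4, seed=0)
    phases = make_phase_maps(phantom.shape, scheme.M, 4, seed=0)
    tissues = TissueMaps.from_dict(phantom.tissue_maps)
    return {
        "phantom": phantom,
        "scheme": scheme,
        "dictionary": dictionary,
        "masks": masks,
        "coils": coils,
        "phases": phases,
        "tissues": tissues,
        "dirs": dirs48,
    }
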