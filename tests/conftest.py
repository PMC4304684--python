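import numpy as np
import pytest

from meltshift.melt_core import AnalysisConfig
from meltshift.synthgen import SynthParams, two_state_curve

#: 1% of the default folded->unfolded fluorescence amplitude.
NOISE_1PCT = 0.01 * (SynthParams().f_unfolded - SynthParams().f_native)


@pytest.fixture
def config():
    return AnalysisConfig()


@pytest.fixture
def clean_curve():
    """Noiseless default two-state curve (Tm 60, dHvH 400 kJ/mol)."""
    curve, _ = two_state_curve(SynthParams(tm=60.0, dh_vh=400.0))
    return curve


def make_curve(tm=60.0, dh_vh=400.0, noise_sd=0.0, seed=0, **kw):
    curve, _ = two_state_curve(
        SynthParams(tm=tm, dh_vh=dh_vh, noise_sd=noise_sd, seed=seed, **kw))
    return curve
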