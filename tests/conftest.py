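import numpy as np
import pytest

from sfgsim.cohort import (AUDIOMETRY_FREQS, ObserverModel,
                           ParticipantProfile, young_template)
from sfgsim.quest import PsychometricParams
from sfgsim.stimulus import build_frequency_grid


@pytest.fixture(scope="session")
def grid():
    return build_frequency_grid()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_observer(threshold=12.0, **kw):
    return ObserverModel(psychometric=PsychometricParams(threshold=threshold),
                         **kw)


def flat_audiogram(level=10.0):
    return {ear: {f: level for f in AUDIOMETRY_FREQS}
            for ear in ("left", "right")}


def make_profile(age_group="young", template=None, audiogram=None):
    return ParticipantProfile(
        id="test", age_group=age_group,
        audiogram=audiogram or flat_audiogram(),
        digit_span_forward=6, digit_span_backward=5,
        observer=make_observer(),
        erp_template=template or young_template())
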