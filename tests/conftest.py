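import numpy as np
import pytest

from anthroagree import AnthroProfile
from anthroagree.synthetic import SYNTHETIC_MOMENTS, TABLE_MOMENTS

SKINFOLDS = ("BI", "TR", "SS", "SI", "SSP", "AB", "TH", "C")
GIRTHS = ("Ac", "FAc", "THc", "Cc", "CHc", "WC", "HC")


def make_profile(sex="male", *, subject_id="S1", race="hispanic", age=None, bw=None, h=None, **overrides):
    """A fully measured profile at the study's sample means, overridable per site."""
    skinfolds = {k: TABLE_MOMENTS[k][0] for k in SKINFOLDS}
    circumferences = {k: (TABLE_MOMENTS.get(k) or SYNTHETIC_MOMENTS[k])[0] for k in GIRTHS}
    diameters = {k: SYNTHETIC_MOMENTS[k][0] for k in ("WD", "FD")}
    for key, value in overrides.items():
        if key in skinfolds:
            skinfolds[key] = value
        elif key in circumferences:
            circumferences[key] = value
        elif key in diameters:
            diameters[key] = value
        else:
            raise KeyError(key)
    return AnthroProfile(
        subject_id=subject_id,
        sex=sex,
        age=TABLE_MOMENTS["age"][0] if age is None else age,
        race=race,
        body_weight_kg=TABLE_MOMENTS["body_weight_kg"][0] if bw is None else bw,
        height_cm=TABLE_MOMENTS["height_cm"][0] if h is None else h,
        skinfolds_mm=skinfolds,
        circumferences_cm=circumferences,
        diameters_cm=diameters,
    )


@pytest.fixture
def mean_profile():
    """The 'mean subject': sample means with the 22/27 male fraction."""
    return make_profile(sex=22.0 / 27.0)


@pytest.fixture
def male_profile():
    return make_profile(sex="male")


@pytest.fixture
def female_profile():
    return make_profile(sex="female")


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
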