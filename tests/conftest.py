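import numpy as np
import pytest
from hypothesis import settings

import calcmorph as cm

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def male_means() -> cm.ParameterVector:
    return cm.ParameterVector(
        **{p: cm.NORMATIVE_PARAMS["male"][p].mean for p in cm.PARAMETERS})


@pytest.fixture(scope="session")
def mean_landmarks(male_means) -> cm.LandmarkSet:
    return cm.realize_landmarks(male_means)


def random_vectors(n: int, seed: int = 0):
    """Random feasible parameter vectors drawn from the normative per-gender
    distributions (half male, half female)."""
    spec = cm.study_cohort_spec(seed=seed,
                                sizes={"male": (n + 1) // 2, "female": n // 2})
    df = cm.sample_cohort(spec)
    return [cm.ParameterVector(**{p: row[p] for p in cm.PARAMETERS})
            for _, row in df.iterrows()]


@pytest.fixture(scope="session")
def sphere_phantom() -> cm.Phantom:
    """R = 10 mm sphere at 0.5 mm spacing with a h = 2 mm apex cap."""
    return cm.build_phantom(cm.sphere_phantom_spec(radius=10.0, spacing=0.5,
                                                   cap_height=2.0))


@pytest.fixture(scope="session")
def sphere_mesh(sphere_phantom):
    vol = sphere_phantom.volume
    mask = cm.threshold_bone(vol, 150.0)
    labels = cm.label_components(mask, spacing=vol.spacing, origin=vol.origin)
    return cm.extract_mesh(vol, labels, 1)


@pytest.fixture(scope="session")
def calc_phantom(male_means) -> cm.Phantom:
    """Calcaneus-like phantom at the male normative means, 1 mm spacing."""
    return cm.build_phantom(cm.calcaneus_phantom_spec(male_means, spacing=1.0))


@pytest.fixture(scope="session")
def calc_mesh(calc_phantom):
    vol = calc_phantom.volume
    mask = cm.threshold_bone(vol, 150.0)
    labels = cm.label_components(mask, spacing=vol.spacing, origin=vol.origin)
    return cm.extract_mesh(vol, labels, 1)
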