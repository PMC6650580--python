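import numpy as np
import pytest

from capgap.fixtures import (
    default_rom_assessment,
    generate_synthetic_trial,
    make_reference_template,
    make_toy_model,
    true_motor_control,
)
from capgap.model import (
    JointCoordinate,
    MusculoskeletalModel,
    MuscleTendonActuator,
    PathPoint,
    Segment,
)
from capgap.trial import make_reference_trial
from capgap.tuning import tune_muscle_parameters


@pytest.fixture(scope="session")
def model0():
    return make_toy_model(seed=0)


@pytest.fixture(scope="session")
def trial0(model0):
    return generate_synthetic_trial(model0, seed=0)


@pytest.fixture(scope="session")
def rom0():
    return default_rom_assessment()


@pytest.fixture(scope="session")
def template0(model0):
    return make_reference_template(model0, mass=35.0)


@pytest.fixture(scope="session")
def desired0(template0, model0):
    return make_reference_trial(template0, model0, mass=35.0)


@pytest.fixture(scope="session")
def mc_true0(model0, trial0):
    _, gt = trial0
    return true_motor_control(model0, gt)


@pytest.fixture(scope="session")
def tuned_default(model0, trial0, rom0):
    """Default-config tuning run on the seed-0 fixture (shared: it is slow)."""
    bundle, _ = trial0
    return tune_muscle_parameters(model0, bundle, rom0)


def make_hinge_toy(f_ext: float = 500.0, f_flex: float = 400.0,
                   subset: str = "N") -> MusculoskeletalModel:
    """Minimal 1-DOF, 2-muscle model (agonist/antagonist pair on one hinge)."""
    segments = [
        Segment("base", None),
        Segment("arm", "base", joint_axis=[0, 0, 1], joint_center=[0, 0, 0]),
    ]
    coords = [JointCoordinate("hinge", "arm", range=(-1.5, 1.5))]
    muscles = [
        MuscleTendonActuator(
            name="extensor",
            path=[PathPoint("base", [-0.05, 0.03, 0], "origin"),
                  PathPoint("arm", [-0.05, -0.25, 0], "insertion")],
            F_max=f_ext, l_mo=0.1, l_ts=0.15, subset=subset),
        MuscleTendonActuator(
            name="flexor",
            path=[PathPoint("base", [0.05, 0.03, 0], "origin"),
                  PathPoint("arm", [0.05, -0.25, 0], "insertion")],
            F_max=f_flex, l_mo=0.1, l_ts=0.15, subset=subset),
    ]
    return MusculoskeletalModel(segments=segments, coordinates=coords,
                                muscles=muscles, name="hinge-toy")


@pytest.fixture()
def hinge_toy():
    return make_hinge_toy()


def rel_err(est: dict, truth: dict) -> list[float]:
    return [abs(est[k] - truth[k]) / abs(truth[k]) for k in est]


def perturbed_copy(model, rel_mo=0.2, rel_ts=0.05, seed=100):
    """Model copy with tuned-muscle parameters perturbed (recovery harness)."""
    rng = np.random.default_rng(seed)
    out = model.copy()
    for mu in out.muscles:
        if mu.subset == "M":
            mu.l_mo *= 1 + rel_mo * rng.uniform(-1, 1)
            mu.l_ts *= 1 + rel_ts * rng.uniform(-1, 1)
    return out
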