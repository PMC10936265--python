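import logging

import numpy as np
import pytest

from liftrisk import default_config
from liftrisk.assembly import build_from_config
from liftrisk.reduced import ReducedMap
from liftrisk.synthetic import LiftScenario, ReferenceMotion

logging.getLogger("liftrisk.exoskeleton").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture(scope="session")
def ho_model(cfg):
    return build_from_config(cfg, with_exo=False)


@pytest.fixture(scope="session")
def hwe_model(cfg):
    return build_from_config(cfg, with_exo=True)


@pytest.fixture(scope="session")
def scenario(cfg):
    return LiftScenario.from_config(cfg)


@pytest.fixture(scope="session")
def ho_motion(ho_model, scenario):
    return ReferenceMotion(ho_model, scenario)


@pytest.fixture(scope="session")
def hwe_motion(hwe_model, scenario):
    return ReferenceMotion(hwe_model, scenario)


@pytest.fixture(scope="session")
def ho_rmap(ho_model):
    return ReducedMap(ho_model)


@pytest.fixture(scope="session")
def study_result(cfg):
    """The full 2x4 study at the default settings (shared, expensive)."""
    from liftrisk.study import run_study

    return run_study(cfg, seed=1)


def consistent_state(rmap, zeta, zeta_dot, phase=1):
    """Full (q, qd) on the constraint manifold from reduced coordinates.

    qd is the exact pushforward of zeta_dot through the reduced map
    (central differences on the map with a tiny step).
    """
    h = 1e-6
    q = rmap.q(zeta, phase)
    qd = (rmap.q(zeta + h * zeta_dot, phase) - rmap.q(zeta - h * zeta_dot, phase)) / (
        2 * h
    )
    return q, qd
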