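"""Shared fixtures.

Expensive simulation runs are session-scoped so that property tests and the
result-level checks can share them. Iteration counts here are the package's
reduced desk-scale defaults; they trade Monte-Carlo precision for runtime
and every comparison below accounts for that with explicit error bands.
"""

import numpy as np
import pytest

import sparsecrowd as sc

SEED = 20260921  # fixed suite-wide base seed


@pytest.fixture(scope="session")
def peripheral_cfg():
    return sc.default_config("peripheral")


@pytest.fixture(scope="session")
def foveal_cfg():
    return sc.default_config("foveal")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(SEED)


# ---------------------------------------------------------------------------
# Heavy shared runs


@pytest.fixture(scope="session")
def peripheral_full(peripheral_cfg):
    """Full peripheral model accuracy, 100 iterations."""
    return sc.run_accuracy(peripheral_cfg, SEED, n_iterations=100)


@pytest.fixture(scope="session")
def peripheral_retrain_curve(peripheral_cfg):
    """Peripheral sampling curve, units removed + retrained, 50 iterations."""
    return sc.run_sampling_curve(
        peripheral_cfg, SEED + 1, n_iterations=50, mode="drop_units_retrain"
    )


@pytest.fixture(scope="session")
def peripheral_noretrain_curve(peripheral_cfg):
    """Peripheral sampling curve, units silenced without retraining."""
    return sc.run_sampling_curve(
        peripheral_cfg, SEED + 2, n_iterations=100, mode="drop_units_no_retrain"
    )


@pytest.fixture(scope="session")
def flanker_probe(peripheral_cfg):
    """50%-ablated model on the 12-image single-flanker battery.

    This probe is cheap, so it runs at the full 1000 iterations used for
    the original asymmetry/substitution analyses.
    """
    return sc.run_flanker_probe(peripheral_cfg, SEED + 3, n_iterations=1000)


@pytest.fixture(scope="session")
def radial_bias(peripheral_cfg):
    return sc.run_radial_bias(peripheral_cfg, SEED + 4, n_iterations=100)


@pytest.fixture(scope="session")
def foveal_full(foveal_cfg):
    return sc.run_accuracy(foveal_cfg, SEED + 5, n_iterations=100)


@pytest.fixture(scope="session")
def foveal_retrain_curve(foveal_cfg):
    return sc.run_sampling_curve(
        foveal_cfg, SEED + 6, n_iterations=50, mode="drop_units_retrain"
    )


@pytest.fixture(scope="session")
def feature_object():
    return sc.run_feature_object(seed=SEED + 7, n_iterations=100)


@pytest.fixture(scope="session")
def permutation_null(peripheral_cfg):
    return sc.run_permutation_null(peripheral_cfg, SEED + 8, n_perm=200)


@pytest.fixture(scope="session")
def zone_map():
    cfg = sc.default_config("zone")
    return sc.run_zone_map(cfg, SEED + 9, n_iterations=12, stride=5)
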