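import numpy as np
import pytest

import sloppyscan as ss


@pytest.fixture(scope="session")
def lti_model():
    return ss.make_benchmark("lti_diag")


@pytest.fixture(scope="session")
def biexp_model():
    return ss.make_benchmark("biexp")


@pytest.fixture(scope="session")
def toy_experiment():
    # the standard 0-20 s grid at 0.5 s sampling, x0 = (1, 1)
    return ss.default_experiment("lti_diag")


def _scenario_scan(theta, seed=1):
    model = ss.make_benchmark("lti_diag")
    experiment = ss.default_experiment("lti_diag")
    cfg = ss.ShellScanConfig(
        theta_ref=np.asarray(theta, dtype=float),
        delta_total=0.3,
        n_shells=30,
        N0=20000,
        alpha=1000.0,
        seed=seed,
    )
    return ss.scan(model, experiment, cfg)


@pytest.fixture(scope="session")
def scan_nonsloppy():
    """Scenario: well-separated rates (0.4, 1) — identifiable, not sloppy."""
    return _scenario_scan([0.4, 1.0])


@pytest.fixture(scope="session")
def scan_sloppy():
    """Scenario: rates (1, 10) — identifiable but sloppy."""
    return _scenario_scan([1.0, 10.0])


@pytest.fixture(scope="session")
def scan_unidentifiable():
    """Scenario: rates (0.4, 0.5) — swap image inside the ball at sqrt(0.02)."""
    return _scenario_scan([0.4, 0.5])
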