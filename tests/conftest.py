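import logging

import pytest

import pcstates as pc


@pytest.fixture(scope="session", autouse=True)
def _quiet_curve_cross_warnings():
    # The shipped survival table legitimately has PFS/OS curve crossings
    # (independently sourced curves); the clamp warning is expected.
    logging.getLogger("pcstates.hazards").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_cfg():
    return pc.default_config()


@pytest.fixture(scope="session")
def hazard_profile(default_cfg):
    return default_cfg.hazard_profile()


@pytest.fixture(scope="session")
def baseline_run(default_cfg, hazard_profile):
    cfg = default_cfg
    return pc.run_simulation(
        hazard_profile, cfg.topology, cfg.routing, cfg.incidence,
        start=cfg.start, horizon=cfg.horizon,
    )


@pytest.fixture(scope="session")
def scenario_runs(default_cfg, hazard_profile):
    cfg = default_cfg
    return {
        name: pc.run_simulation(
            hazard_profile, cfg.topology, cfg.routing, cfg.incidence,
            start=cfg.start, horizon=cfg.horizon,
            scenarios=pc.load_scenarios(name),
        )
        for name in ("nmcrpc", "mcrpc", "combined")
    }
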