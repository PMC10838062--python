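import pytest

from gvhdcea import ArmParameters, RunSettings, base_case_spec


@pytest.fixture(scope="session")
def base_spec():
    return base_case_spec()


@pytest.fixture(scope="session")
def table_params():
    """Arm parameters built directly from the published per-cycle values."""
    shared = dict(
        p_progress_per_cycle=0.041,
        p_death_responder_per_cycle=0.013,
        p_death_progressed_per_cycle=0.042,
        p_discontinue_per_cycle=0.201,
        frac_death_respiratory=0.55,
    )
    ecp = ArmParameters(
        arm_name="ECP", p_response_week12=0.802, p_progression_week12=0.198, **shared
    )
    soc = ArmParameters(
        arm_name="SoC", p_response_week12=0.203, p_progression_week12=0.797, **shared
    )
    return ecp, soc


@pytest.fixture()
def default_settings():
    return RunSettings()


@pytest.fixture()
def frozen_params():
    """Induction split only; no transitions after cycle 1."""
    return ArmParameters(
        arm_name="frozen",
        p_response_week12=0.7,
        p_progression_week12=0.3,
        p_progress_per_cycle=0.0,
        p_death_responder_per_cycle=0.0,
        p_death_progressed_per_cycle=0.0,
        p_discontinue_per_cycle=0.0,
    )
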