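import pytest

from throughfall import nitrification_endmember, scenario_templates


@pytest.fixture
def analysis_endmember():
    """Default end-member interval from the 2/3-water + 1/3-O2 rule with
    ambient water delta-18O in [-10, -5] per mil."""
    return nitrification_endmember()


@pytest.fixture
def cj1_case():
    """Printed worked example of the actively nitrifying incubation."""
    return {
        "delta18O_initial": 74.1,
        "delta18O_final": 49.8,
        "delta15N_initial": 6.1,
        "delta15N_final": -1.7,
        "no3_initial_uM": 219.0,
        "no3_final_uM": 332.0,
    }


@pytest.fixture
def cj1_config():
    return scenario_templates(seed=0)["cj1_like"]
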