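import numpy as np
import pytest

from erythrosim.calibration import calibrate_reference
from erythrosim.vpop import VpopSpec, build_nd_vpop


@pytest.fixture(scope="session")
def model():
    """Fully calibrated model (physiology, drugs, reference VPs)."""
    return calibrate_reference()


@pytest.fixture(scope="session")
def healthy(model):
    return model.vp("healthy")


@pytest.fixture(scope="session")
def small_nd_vpop(model):
    spec = VpopSpec(label="test-nd", dialysis="ND",
                    stage_fractions={"ckd3": 0.5, "ckd4": 0.5},
                    baseline_hb_range=(7.5, 12.0), n_patients=6, seed=42)
    return build_nd_vpop(spec, model.reference_vps)


@pytest.fixture(scope="session")
def study_cache(model):
    """Run each published study at most once per session."""
    from erythrosim import studies

    cache = {}

    def get(name, n=50, seed=2024):
        key = (name, n, seed)
        if key not in cache:
            makers = {
                "nd-rhuepo": studies.nd_rhuepo_study,
                "nd-darbepoetin": studies.nd_darbepoetin_study,
                "nd-vadadustat": studies.nd_vadadustat_study,
                "hd-vadadustat": studies.hd_vadadustat_study,
                "validation-TIW": lambda n, s: studies.validation_arm_study("TIW", n, s),
                "validation-QW": lambda n, s: studies.validation_arm_study("QW", n, s),
                "validation-Q2W": lambda n, s: studies.validation_arm_study("Q2W", n, s),
            }
            cfg = makers[name](n, seed)
            cache[key] = studies.run_study(cfg, model)
        return cache[key]

    return get
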