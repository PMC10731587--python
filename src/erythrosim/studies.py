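"""Pre-configured trial cohorts and protocols for the published studies.

Each study bundles the Vpop entry criteria (CKD-stage mixture and baseline
Hb band, taken as the reported cohort mean +/- 2 SD), the drug, the dosing
pattern and the titration protocol.  These are the simulation set-ups used
for calibration endpoints and validation; n and seed stay caller-chosen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .calibration import CalibratedModel
from .core import SolverOptions
from .trials import (ArmSwitch, TitrationProtocol, TrialResult,
                     protocol_epoetin_validation, protocol_generic_esa,
                     protocol_vadadustat_hd_phase3, protocol_vadadustat_nd,
                     run_trial, summarize_trial)
from .vpop import HdRunIn, Vpop, VpopSpec, build_hd_vpop, build_nd_vpop

#: weekly rHuEPO dose ladder (IU) for the generic ND epoetin trial; real ND
#: trials escalate from 10,000 IU QW up to 40,000-60,000 IU weekly
RHUEPO_ND_LADDER = (2500.0, 5000.0, 7500.0, 10000.0, 15000.0, 20000.0,
                    30000.0, 40000.0, 60000.0)

#: darbepoetin Q2W ladder (ug) as listed for the ND trial
DARBEPOETIN_LADDER = (10.0, 15.0, 20.0, 30.0, 40.0, 50.0, 60.0, 80.0, 100.0)


@dataclass
class StudyConfig:
    name: str
    vpop_spec: VpopSpec
    drug: str
    pattern: str
    protocol: TitrationProtocol
    duration_weeks: float
    switches: tuple[ArmSwitch, ...] = ()


def _band(mean: float, sd: float) -> tuple[float, float]:
    return (mean - 2.0 * sd, mean + 2.0 * sd)


def nd_rhuepo_study(n: int, seed: int) -> StudyConfig:
    """Treatment-naive ND cohort (CKD 3/4/5 = 9.8/60.3/29.9 %), baseline Hb
    9.1 +/- 0.7, 10,000 IU QW epoetin with generic titration, 16 weeks."""
    spec = VpopSpec(label="nd-rhuepo", dialysis="ND",
                    stage_fractions={"ckd3": 0.098, "ckd4": 0.603,
                                     "ckd5": 0.299},
                    baseline_hb_range=_band(9.1, 0.7), n_patients=n,
                    seed=seed)
    prot = protocol_generic_esa(10000.0, RHUEPO_ND_LADDER)
    return StudyConfig("nd-rhuepo", spec, "rhuepo", "QW", prot, 16.0)


def nd_darbepoetin_study(n: int, seed: int) -> StudyConfig:
    """Treatment-naive ND cohort, baseline 9.9 +/- 0.9, darbepoetin Q2W
    (start 30 ug ~ 0.45 ug/kg) with generic titration, 24 weeks.  The trial
    does not report its stage mixture; the vadadustat ND mixture is used."""
    spec = VpopSpec(label="nd-darbepoetin", dialysis="ND",
                    stage_fractions={"ckd3": 0.261, "ckd4": 0.616,
                                     "ckd5": 0.123},
                    baseline_hb_range=_band(9.9, 0.9), n_patients=n,
                    seed=seed)
    prot = protocol_generic_esa(30.0, DARBEPOETIN_LADDER,
                                name="nd-darbepoetin")
    return StudyConfig("nd-darbepoetin", spec, "darbepoetin", "Q2W", prot,
                       24.0)


def nd_vadadustat_study(n: int, seed: int,
                        published_protocol: bool = False) -> StudyConfig:
    """Phase-2 vadadustat ND cohort (CKD 3/4/5 = 26.1/61.6/12.3 %),
    baseline 9.9 +/- 0.86, 450 mg QD, modified titration, 20 weeks."""
    spec = VpopSpec(label="nd-vadadustat", dialysis="ND",
                    stage_fractions={"ckd3": 0.261, "ckd4": 0.616,
                                     "ckd5": 0.123},
                    baseline_hb_range=_band(9.9, 0.86), n_patients=n,
                    seed=seed)
    prot = protocol_vadadustat_nd(published_protocol)
    return StudyConfig("nd-vadadustat", spec, "vadadustat", "QD", prot, 20.0)


def hd_vadadustat_study(n: int, seed: int) -> StudyConfig:
    """HD cohort (CKD 5, prior rHuEPO run-in to baseline 10.4 +/- 0.7),
    switched to vadadustat 300 mg QD with the phase-3 HD rules, 18 weeks."""
    spec = VpopSpec(label="hd-vadadustat", dialysis="HD",
                    stage_fractions={"ckd5": 1.0},
                    baseline_hb_range=_band(10.4, 0.7), n_patients=n,
                    seed=seed, hd_run_in=HdRunIn())
    prot = protocol_vadadustat_hd_phase3()
    return StudyConfig("hd-vadadustat", spec, "vadadustat", "QD", prot, 18.0)


#: epoetin validation arms: (pattern, per-dose IU, baseline mean, sd)
VALIDATION_ARMS = {
    "TIW": ("TIW", 3500.0, 9.63, 0.86),     # 50 IU/kg x 70 kg
    "QW": ("QW", 10000.0, 9.71, 0.74),
    "Q2W": ("Q2W", 20000.0, 9.91, 0.75),
}

def _geometric_ladder(start: float, step: float = 1.25,
                      n_down: int = 6, n_up: int = 6) -> tuple[float, ...]:
    """~25%-step dose ladder around the starting dose (real epoetin
    titration adjusts in 25% increments)."""
    return tuple(start * step ** k for k in range(-n_down, n_up + 1))


_VALIDATION_LADDERS = {
    "TIW": _geometric_ladder(3500.0),
    "QW": _geometric_ladder(10000.0),
    "Q2W": _geometric_ladder(20000.0),
}


def validation_arm_study(arm: str, n: int, seed: int) -> StudyConfig:
    """One arm of the 44-week epoetin validation trial in CKD 3/4 ND VPs,
    titrated to 11-11.9 g/dL; the TIW arm switches to 10,000 IU QW at
    week 23."""
    pattern, start, mean, sd = VALIDATION_ARMS[arm]
    spec = VpopSpec(label=f"validation-{arm.lower()}", dialysis="ND",
                    stage_fractions={"ckd3": 0.5, "ckd4": 0.5},
                    baseline_hb_range=_band(mean, sd), n_patients=n,
                    seed=seed)
    down = 11.9 if arm == "Q2W" else 11.6
    prot = protocol_epoetin_validation(start, _VALIDATION_LADDERS[arm],
                                       down_threshold=down)
    switches: tuple[ArmSwitch, ...] = ()
    if arm == "TIW":
        qw_prot = protocol_epoetin_validation(10000.0,
                                              _VALIDATION_LADDERS["QW"])
        switches = (ArmSwitch(23.0, "QW", 10000.0, protocol=qw_prot),)
    return StudyConfig(f"validation-{arm.lower()}", spec, "rhuepo", pattern,
                       prot, 44.0, switches=switches)


def build_study_vpop(cfg: StudyConfig, model: CalibratedModel) -> Vpop:
    if cfg.vpop_spec.dialysis == "ND":
        return build_nd_vpop(cfg.vpop_spec, model.reference_vps)
    return build_hd_vpop(cfg.vpop_spec, model.reference_vps,
                         model.drugs["rhuepo"])


def run_study(cfg: StudyConfig, model: CalibratedModel,
              solver: SolverOptions | None = None
              ) -> tuple[Vpop, TrialResult, dict]:
    """Build the cohort, run the adaptive trial, and summarize."""
    vpop = build_study_vpop(cfg, model)
    result = run_trial(vpop, cfg.protocol, model.drugs[cfg.drug],
                       cfg.pattern, cfg.duration_weeks,
                       seed=cfg.vpop_spec.seed, switches=cfg.switches,
                       solver=solver)
    return vpop, result, summarize_trial(result)
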