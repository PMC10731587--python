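"""Virtual populations matched to trial entry criteria.

A Vpop is an ensemble of virtual patients sampled around the reference VPs:
disease-relevant parameters receive lognormal variability (median at the
reference value), each candidate is re-solved to its own steady state, and
candidates are accepted when their baseline Hb falls inside the trial's
entry band.  Non-dialysis (ND) cohorts mix CKD stages 3/4/5 in the trial's
reported proportions and are ESA-naive; hemodialysis (HD) cohorts are CKD 5
only and reach their baseline *on therapy*, via a simulated rHuEPO run-in.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import units
from .core import SolverOptions, compute_hb, simulate
from .dosing import Regimen, expand_regimen
from .drugs import DrugSpec
from .params import PhysioParams
from .patients import ReferenceVP, SteadyStateError, solve_steady_state
from .state import ErythroState

#: parameters receiving inter-patient variability, with default lognormal CVs.
#: The set covers the four disease axes plus the EPO-production midpoint and
#: the per-cell Hb content; CVs are chosen to reproduce the ~0.7-1.0 g/dL
#: baseline-Hb spread reported for trial cohorts.
DEFAULT_PARAMETER_CV: dict[str, float] = {
    "k_production_epo": 0.30,
    "k_prod_progenitors": 0.20,
    "k_baseline_deg": 0.20,
    "k_deg_rbcm": 0.20,
    "km_prod_epo": 0.20,
    "mch_rbcm": 0.05,
    "mch_reti": 0.05,
}

HD_RUN_IN_TIW_RANGE = (3500.0, 4800.0)   # IU per dose
HD_RUN_IN_QW_DOSE = 4650.0               # IU per dose
HD_RUN_IN_WEEKS_RANGE = (17, 21)         # ~4-5 months


class VpopError(RuntimeError):
    pass


@dataclass
class HdRunIn:
    pattern: str = "TIW"                  # TIW or QW
    dose_range_iu: tuple[float, float] = HD_RUN_IN_TIW_RANGE
    qw_dose_iu: float = HD_RUN_IN_QW_DOSE
    weeks_range: tuple[int, int] = HD_RUN_IN_WEEKS_RANGE


@dataclass
class VpopSpec:
    label: str
    dialysis: str                          # "ND" or "HD"
    stage_fractions: dict[str, float]
    baseline_hb_range: tuple[float, float]
    n_patients: int
    parameter_cv: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PARAMETER_CV))
    seed: int = 0
    hd_run_in: HdRunIn | None = None

    def validate(self) -> None:
        if self.dialysis not in ("ND", "HD"):
            raise ValueError("dialysis must be 'ND' or 'HD'")
        tot = sum(self.stage_fractions.values())
        if abs(tot - 1.0) > 1e-9:
            raise ValueError(f"stage fractions must sum to 1, got {tot}")
        lo, hi = self.baseline_hb_range
        if not lo < hi:
            raise ValueError("baseline_hb_range must satisfy lo < hi")
        if self.dialysis == "HD":
            if set(self.stage_fractions) != {"ckd5"}:
                raise ValueError("HD Vpops contain only CKD stage 5")
            if self.hd_run_in is None:
                raise ValueError("HD Vpops require an hd_run_in block")


@dataclass
class VirtualPatient:
    id: str
    stage: str
    params: PhysioParams
    baseline_state: ErythroState
    baseline_hb: float
    body_weight_kg: float = 70.0
    reference_stage: str = ""
    seed: int = 0
    run_in: dict | None = None            # HD only: pattern/dose/weeks

    def weekly_esa_iu(self) -> float | None:
        """Weekly-equivalent prior rHuEPO dose (HD VPs), for trials that
        convert the entry dose from prior ESA exposure."""
        if self.run_in is None:
            return None
        per_dose = self.run_in["dose_iu"]
        return per_dose * (3.0 if self.run_in["pattern"] == "TIW" else 1.0)


@dataclass
class Vpop:
    spec: VpopSpec
    patients: list[VirtualPatient]
    acceptance_stats: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.patients)

    def baseline_hbs(self) -> np.ndarray:
        return np.array([vp.baseline_hb for vp in self.patients])


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def sample_vp(reference: ReferenceVP, cv: dict[str, float],
              rng: np.random.Generator, vp_id: str = "vp",
              seed: int = 0) -> VirtualPatient:
    """Draw one candidate around a reference VP.

    Each varied parameter is lognormal with median at the reference value
    and the stated coefficient of variation; the candidate's drug-free
    steady state is re-solved.  Raises SteadyStateError if the candidate
    physiology has no steady state (caller discards it).
    """
    p = reference.params
    for name, c in cv.items():
        if c < 0:
            raise ValueError(f"CV for {name} must be non-negative")
        if c == 0:
            continue
        sigma = math.sqrt(math.log(1.0 + c * c))
        p = p.replace(**{name: getattr(p, name)
                         * math.exp(sigma * rng.standard_normal())})
    ss = solve_steady_state(p)
    hb = compute_hb(ss.retics_plasma, ss.rbc_m, p)
    return VirtualPatient(id=vp_id, stage=reference.stage, params=p,
                          baseline_state=ss, baseline_hb=hb,
                          reference_stage=reference.stage, seed=seed)


def _stage_counts(fractions: dict[str, float], n: int) -> dict[str, int]:
    """Largest-remainder apportionment of n patients across stages."""
    raw = {s: f * n for s, f in fractions.items()}
    counts = {s: int(math.floor(v)) for s, v in raw.items()}
    short = n - sum(counts.values())
    for s in sorted(raw, key=lambda s: raw[s] - counts[s], reverse=True)[:short]:
        counts[s] += 1
    return counts


def build_nd_vpop(spec: VpopSpec,
                  references: dict[str, ReferenceVP]) -> Vpop:
    """Accept/reject sampling of an ESA-naive non-dialysis cohort."""
    spec.validate()
    if spec.dialysis != "ND":
        raise ValueError("build_nd_vpop requires an ND spec")
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.baseline_hb_range
    counts = _stage_counts(spec.stage_fractions, spec.n_patients)
    patients: list[VirtualPatient] = []
    attempts = 0
    accepted = 0
    for stage, n_stage in counts.items():
        ref = references[stage]
        got = 0
        while got < n_stage:
            attempts += 1
            if attempts > 10000 and accepted / attempts < 0.01:
                raise VpopError(
                    f"acceptance rate {accepted}/{attempts} below 1%; "
                    f"baseline Hb band [{lo}, {hi}] is the binding constraint "
                    f"for stage {stage}")
            try:
                vp = sample_vp(ref, spec.parameter_cv, rng,
                               vp_id=f"{spec.label}-{stage}-{got:03d}",
                               seed=spec.seed)
            except SteadyStateError:
                continue
            if lo <= vp.baseline_hb <= hi:
                patients.append(vp)
                got += 1
                accepted += 1
    return Vpop(spec=spec, patients=patients,
                acceptance_stats={"attempts": attempts, "accepted": accepted,
                                  "rate": accepted / max(attempts, 1)})


def build_hd_vpop(spec: VpopSpec, references: dict[str, ReferenceVP],
                  rhuepo: DrugSpec,
                  solver: SolverOptions | None = None) -> Vpop:
    """Hemodialysis cohort: CKD 5 VPs carried to baseline by an rHuEPO
    run-in (3,500-4,800 IU TIW or 4,650 IU QW for ~4-5 months); a candidate
    is accepted when its end-of-run-in Hb lies in the entry band."""
    spec.validate()
    if spec.dialysis != "HD":
        raise ValueError("build_hd_vpop requires an HD spec")
    run_cfg = spec.hd_run_in
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.baseline_hb_range
    ref = references["ckd5"]
    solver = solver or SolverOptions(rtol=1e-6, atol_scale=1e-8)
    patients: list[VirtualPatient] = []
    attempts = 0
    while len(patients) < spec.n_patients:
        attempts += 1
        if attempts > 10000 and len(patients) / attempts < 0.01:
            raise VpopError(
                f"HD acceptance rate {len(patients)}/{attempts} below 1%; "
                f"run-in cannot reach baseline band [{lo}, {hi}]")
        try:
            vp = sample_vp(ref, spec.parameter_cv, rng, seed=spec.seed)
        except SteadyStateError:
            continue
        if rng.random() < 0.5:
            pattern, dose = "TIW", float(rng.uniform(*run_cfg.dose_range_iu))
        else:
            pattern, dose = "QW", run_cfg.qw_dose_iu
        weeks = int(rng.integers(run_cfg.weeks_range[0],
                                 run_cfg.weeks_range[1] + 1))
        reg = Regimen(drug=rhuepo, pattern=pattern, dose=dose,
                      duration_weeks=weeks)
        tr = simulate(vp.baseline_state, vp.params,
                      doses=expand_regimen(reg), drugs=(rhuepo,),
                      t_span=(0.0, weeks * units.HOURS_PER_WEEK),
                      options=solver)
        end_hb = float(tr.hb()[-1])
        if lo <= end_hb <= hi:
            i = len(patients)
            patients.append(VirtualPatient(
                id=f"{spec.label}-ckd5-{i:03d}", stage="ckd5",
                params=vp.params, baseline_state=tr.final_physio(),
                baseline_hb=end_hb, reference_stage="ckd5", seed=spec.seed,
                run_in={"pattern": pattern, "dose_iu": dose, "weeks": weeks}))
    return Vpop(spec=spec, patients=patients,
                acceptance_stats={"attempts": attempts,
                                  "accepted": len(patients),
                                  "rate": len(patients) / max(attempts, 1)})


def build_vpop(spec: VpopSpec, references: dict[str, ReferenceVP],
               rhuepo: DrugSpec | None = None) -> Vpop:
    if spec.dialysis == "ND":
        return build_nd_vpop(spec, references)
    if rhuepo is None:
        raise ValueError("HD Vpops need the rHuEPO DrugSpec for the run-in")
    return build_hd_vpop(spec, references, rhuepo)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_vpop(vpop: Vpop, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    spec_d = dataclasses.asdict(vpop.spec)
    if spec_d.get("hd_run_in"):
        spec_d["hd_run_in"] = dataclasses.asdict(vpop.spec.hd_run_in)
    with open(d / "manifest.json", "w") as fh:
        json.dump({"spec": spec_d, "acceptance": vpop.acceptance_stats,
                   "n": len(vpop)}, fh, indent=2, default=list)
    rows = []
    states = []
    for vp in vpop.patients:
        row = {"id": vp.id, "stage": vp.stage, "baseline_hb": vp.baseline_hb,
               "body_weight_kg": vp.body_weight_kg,
               "run_in": json.dumps(vp.run_in) if vp.run_in else ""}
        row.update(vp.params.to_dict())
        rows.append(row)
        st = {"id": vp.id}
        st.update(vp.baseline_state.to_dict())
        states.append(st)
    pd.DataFrame(rows).to_csv(d / "patients.csv", index=False)
    pd.DataFrame(states).to_csv(d / "baseline_states.csv", index=False)


def load_vpop(directory) -> Vpop:
    d = Path(directory)
    with open(d / "manifest.json") as fh:
        manifest = json.load(fh)
    sd = manifest["spec"]
    if sd.get("hd_run_in"):
        ri = sd["hd_run_in"]
        for k in ("dose_range_iu", "weeks_range"):
            ri[k] = tuple(ri[k])
        sd["hd_run_in"] = HdRunIn(**ri)
    sd["baseline_hb_range"] = tuple(sd["baseline_hb_range"])
    spec = VpopSpec(**sd)
    pats = pd.read_csv(d / "patients.csv", keep_default_na=False)
    states = pd.read_csv(d / "baseline_states.csv").set_index("id")
    param_names = set(PhysioParams().to_dict())
    patients = []
    for _, row in pats.iterrows():
        params = PhysioParams.from_dict(
            {k: row[k] for k in param_names})
        st = ErythroState.from_dict(states.loc[row["id"]].to_dict())
        patients.append(VirtualPatient(
            id=row["id"], stage=row["stage"], params=params,
            baseline_state=st, baseline_hb=float(row["baseline_hb"]),
            body_weight_kg=float(row["body_weight_kg"]),
            reference_stage=row["stage"], seed=spec.seed,
            run_in=json.loads(row["run_in"]) if row["run_in"] else None))
    return Vpop(spec=spec, patients=patients,
                acceptance_stats=manifest.get("acceptance", {}))
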