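"""Synthetic fixture generator: everything the test-suite and calibration
examples need, with no external downloads.

Three fixture kinds:

* ``pk_table`` — simulated single-dose drug concentrations at clinical
  sampling times with multiplicative lognormal noise;
* ``hb_trace`` — a scripted assessment-time Hb series engineered to trigger
  each titration action (maintain, step_up, step_down, hold, resume) at
  known assessments;
* ``vpop_small`` — a small serialized virtual population for fast tests.

All randomness flows from the given seed.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import phi_concentration
from .drugs import get_drug
from .vpop import VpopSpec, build_nd_vpop, save_vpop

#: Table-1-like sampling grid (h) for a single oral dose (first sample
#: placed after the absorption lag so log-scale fitting is well defined)
PK_SAMPLING_TIMES_H = (1.0, 2.0, 4.0, 6.0, 8.0, 12.0, 16.0, 24.0,
                       36.0, 48.0, 72.0)


def make_pk_table(drug: str = "vadadustat", dose: float = 450.0,
                  noise_cv: float = 0.0, seed: int = 0,
                  times_h=PK_SAMPLING_TIMES_H) -> pd.DataFrame:
    """Single-dose concentration table (columns time_h, conc, sd, drug,
    dose_label) from the built-in PK model, optionally noised."""
    spec = get_drug(drug)
    if spec.kind != "phi":
        raise ValueError("pk_table fixtures are generated for oral PHIs")
    t = np.asarray(times_h, float)
    conc = phi_concentration(spec, dose, t)
    rng = np.random.default_rng(seed)
    if noise_cv > 0:
        sigma = np.sqrt(np.log(1.0 + noise_cv ** 2))
        conc = conc * np.exp(sigma * rng.standard_normal(len(t)))
    return pd.DataFrame({
        "time_h": t, "conc": conc, "sd": conc * max(noise_cv, 0.05),
        "drug": drug, "dose_label": f"{dose:g} {spec.dose_unit} single dose",
    })


def make_hb_trace() -> pd.DataFrame:
    """Scripted (week, hb) series for the generic ESA rules (band 12-12.9,
    hold 13, fixed phase 4 wk, biweekly assessments) triggering, in order:
    maintain (fixed phase), step_up, step_down, hold, hold, resume.

    Hand walk: wk2 fixed phase; wk4 Hb 10.2 with rise 0.2 < 1 over 4 wk
    -> step_up; wk6 12.0 (rise 1.8 > 1.2 in 2 wk) -> step_down; wk8 13.2
    > 13 -> hold; wk10 12.4 (still >= 12, held) -> hold; wk12 11.8 < 12
    -> resume one step down.
    """
    return pd.DataFrame({
        "week": [0.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0],
        "hb": [10.0, 10.1, 10.2, 12.0, 13.2, 12.4, 11.8],
        "expected_action": ["baseline", "maintain", "step_up", "step_down",
                            "hold", "hold", "resume"],
    })


def make_vpop_small(references, n: int = 10, seed: int = 0,
                    directory=None):
    """10-VP ND cohort around the CKD 3/4 references, optionally saved."""
    spec = VpopSpec(label="vpop-small", dialysis="ND",
                    stage_fractions={"ckd3": 0.5, "ckd4": 0.5},
                    baseline_hb_range=(7.5, 12.0), n_patients=n, seed=seed)
    vpop = build_nd_vpop(spec, references)
    if directory is not None:
        save_vpop(vpop, directory)
    return vpop


def generate_fixtures(kind: str, out_dir, seed: int = 0,
                      references=None, **kw) -> list[Path]:
    """Write fixture files of the requested kind; returns written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if kind == "pk_table":
        df = make_pk_table(seed=seed, **kw)
        p = out / f"pk_table_{df['drug'].iloc[0]}_seed{seed}.csv"
        df.to_csv(p, index=False)
        return [p]
    if kind == "hb_trace":
        p = out / "hb_trace.csv"
        make_hb_trace().to_csv(p, index=False)
        return [p]
    if kind == "vpop_small":
        if references is None:
            from .calibration import calibrate_reference
            references = calibrate_reference().reference_vps
        d = out / f"vpop_small_seed{seed}"
        make_vpop_small(references, seed=seed, directory=d, **kw)
        return sorted(d.iterdir())
    raise ValueError(f"unknown fixture kind {kind!r}")
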