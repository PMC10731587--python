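"""Drug definitions: ESA and PHI pharmacokinetic/pharmacodynamic parameters.

Two drug classes are modelled:

* **ESAs** (rHuEPO / epoetin alfa, darbepoetin alfa) — injectable EPO
  analogues.  A subcutaneous dose enters a depot drained by first-order
  absorption ``ka`` into plasma; the plasma drug shares the endogenous EPO
  disposition (non-specific elimination, peripheral distribution) and binds
  EPOR with drug-specific on/off rates, giving target-mediated disposition.
* **PHIs** (vadadustat, daprodustat) — oral small molecules with delayed
  first-order absorption, two-compartment disposition and (daprodustat only)
  an additional saturable clearance.  Their pharmacodynamic effect is a Hill
  function of the plasma concentration that deactivates PHD.

The numeric values for absorption/elimination are calibrated against the
printed anchors (Tmax ~16 h for SC rHuEPO; darbepoetin terminal half-life
3-4x rHuEPO's) by :mod:`erythrosim.calibration`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Literal

from . import units

DrugKind = Literal["esa", "phi"]


@dataclass
class DrugSpec:
    name: str
    kind: DrugKind
    ka: float                       # 1/h, SC or oral absorption
    mw: float                       # g/mol
    dose_unit: str                  # "IU", "ug" or "mg"
    ng_per_unit: float = 1.0        # dose unit -> ng (ESAs)
    tlag: float = 0.0               # h, PHI absorption lag
    kel: float = 0.0                # 1/h, PHI linear clearance (CL/V)
    k_cp: float = 0.0               # 1/h, PHI central -> peripheral
    k_pc: float = 0.0               # 1/h, PHI peripheral -> central
    vmax_nl: float = 0.0            # mg/L/h, PHI saturable clearance Vmax
    km_nl: float = 1.0              # mg/L, PHI saturable clearance Km
    kon: float = 0.0                # mL/molecule/h, ESA EPOR binding
    koff: float = 0.0               # 1/h, ESA EPOR unbinding
    v_dist_l: float = 15.0          # L, PHI dose -> plasma conc
    f_bioavail: float = 1.0         # SC/oral bioavailability fraction
    emax_phd: float = 0.0           # PHI effect ceiling (dimensionless)
    ec50_phd: float = 1.0           # mg/L
    n_phd: float = 1.0              # Hill exponent

    def validate(self) -> None:
        if self.kind == "esa" and self.emax_phd != 0.0:
            raise ValueError("ESA drugs must have emax_phd = 0")
        if self.kind == "phi" and (self.kon != 0.0 or self.koff != 0.0):
            raise ValueError("PHI drugs must have kon = koff = 0")
        if self.ka <= 0:
            raise ValueError("ka must be positive")
        if self.tlag < 0:
            raise ValueError("tlag must be non-negative")

    def replace(self, **kw) -> "DrugSpec":
        return dataclasses.replace(self, **kw)

    def dose_to_ng(self, amount: float) -> float:
        """ESA dose in its labelled unit -> ng of protein."""
        return amount * self.ng_per_unit


def phi_effect(central_conc: float, spec: DrugSpec) -> float:
    """Dimensionless PHD-deactivation effect of a PHI plasma concentration."""
    if central_conc < 0:
        raise ValueError("concentration must be non-negative")
    if spec.emax_phd == 0.0 or central_conc == 0.0:
        return 0.0
    cn = central_conc ** spec.n_phd
    return spec.emax_phd * cn / (spec.ec50_phd ** spec.n_phd + cn)


def darbepoetin_dose_from_rhuepo(weekly_iu: float) -> float:
    """Convert a weekly rHuEPO dose (IU) to darbepoetin alfa (ug).

    Uses the clinical peptide-mass conversion 200 IU rHuEPO = 1 ug.
    """
    if weekly_iu < 0:
        raise ValueError("dose must be non-negative")
    return weekly_iu / units.IU_RHUEPO_PER_UG_DARBEPOETIN


def rhuepo_dose_from_darbepoetin(ug: float) -> float:
    if ug < 0:
        raise ValueError("dose must be non-negative")
    return ug * units.IU_RHUEPO_PER_UG_DARBEPOETIN


# ---------------------------------------------------------------------------
# Built-in drug library (pre-calibration values; see calibration module)
# ---------------------------------------------------------------------------

def builtin_drugs() -> dict[str, DrugSpec]:
    """Fresh copies of the four built-in drug parameterizations."""
    return {
        "rhuepo": DrugSpec(
            name="rhuepo", kind="esa",
            ka=0.036, mw=30400.0, dose_unit="IU",
            ng_per_unit=units.NG_PER_IU_RHUEPO, f_bioavail=0.45,
            kon=2.5e-13, koff=0.5,
        ),
        "darbepoetin": DrugSpec(
            name="darbepoetin", kind="esa",
            ka=0.012, mw=37100.0, dose_unit="ug", ng_per_unit=1000.0,
            # lumped effective bioavailability; absorbs darbepoetin's higher
            # in-vivo activity per ug of protein
            f_bioavail=0.80,
            # reduced EPOR affinity relative to rHuEPO
            kon=6.0e-14, koff=0.5,
        ),
        "vadadustat": DrugSpec(
            name="vadadustat", kind="phi",
            ka=0.8, tlag=0.5, mw=306.7, dose_unit="mg",
            kel=0.154, k_cp=0.05, k_pc=0.10, v_dist_l=17.0,
            emax_phd=3.0, ec50_phd=10.0, n_phd=1.0,
        ),
        "daprodustat": DrugSpec(
            name="daprodustat", kind="phi",
            ka=1.0, tlag=0.3, mw=393.4, dose_unit="mg",
            kel=0.30, k_cp=0.08, k_pc=0.06, v_dist_l=15.0,
            vmax_nl=0.5, km_nl=0.10,
            emax_phd=3.0, ec50_phd=0.15, n_phd=1.0,
        ),
    }


def get_drug(name: str) -> DrugSpec:
    lib = builtin_drugs()
    if name not in lib:
        raise KeyError(f"unknown drug {name!r}; known: {sorted(lib)}")
    return lib[name]
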