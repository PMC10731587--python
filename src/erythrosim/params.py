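"""Physiological parameters of the erythropoiesis model.

All rates are per hour; concentrations follow the conventions in
:mod:`erythrosim.units`.  The defaults below are the *pre-calibration*
baseline for a healthy adult; :func:`erythrosim.calibration.calibrate_reference`
refines the handful of parameters that the printed clinical anchors pin down
(HIF half-life window, reticulocyte peak timing, baseline and on-treatment Hb).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Literal

import yaml

from . import units


@dataclass
class PhysioParams:
    """Rate constants and Hill parameters of the erythropoiesis ODE system.

    Attributes
    ----------
    phd_basal:
        Active PHD concentration (a.u.) at the reference Hb with no PHI.
    hb_effect_emax, hb_effect_km, hb_effect_n:
        Hill parameters of the Hb effect on active PHD.  ``hb_effect_emax``
        is chosen so the effect equals 1 at ``hb_reference``.
    phd_form:
        ``"ratio"`` (default): PHD = phd_basal/(1+PHI_effect) * Hbeffect(Hb).
        ``"additive"``: PHD = phd_basal/(1+PHI_effect+ (1-Hbeffect(Hb))),
        kept as the alternative reading of the published equation.
    """

    # --- HIF / PHD axis ---
    phd_basal: float = 1.0                    # a.u.
    hb_effect_emax: float = 2.0               # dimensionless (normalisation)
    hb_effect_km: float = 13.5                # g/dL
    hb_effect_n: float = 1.85                 # -
    hb_reference: float = 13.5                # g/dL, healthy reference Hb
    k_modulate_phd_on_hif: float = 8.055        # 1/h per PHD a.u.
    k_prod_hif: float = 8.055                   # a.u./h
    phd_form: Literal["ratio", "additive"] = "ratio"

    # --- EPO production / disposition ---
    k_production_epo: float = 1.93            # ng/mL/h, maximal rate
    km_prod_epo: float = 2.0                  # HIF a.u.
    n2: float = 8.0                           # Hill exponent
    k_el_epo_plasma: float = 0.08             # 1/h
    k_epo_cp: float = 0.02                    # 1/h plasma -> periphery
    k_epo_pc: float = 0.12                    # 1/h periphery -> plasma

    # --- EPO-EPOR binding (TMDD) ---
    kon_epo_lr: float = 2.5e-13               # mL/molecule/h
    koff_epo_lr: float = 0.5                  # 1/h
    k_deg_epo_lr: float = 0.2                 # 1/h, complex internalisation
    epor_per_progenitor: float = 1000.0       # molecules/cell

    # --- erythroid cascade ---
    k_prod_progenitors: float = 3.0e7         # cells/mL/h
    k_prog_to_prec: float = 0.006            # 1/h
    k_baseline_deg: float = 0.15              # 1/h progenitor apoptosis ceiling
    f_complex_emax: float = 0.95               # dimensionless, < 1
    f_complex_km: float = 1.0e9               # molecules/mL
    f_complex_n: float = 1.0                  # -
    k_deg_precursors: float = 0.002           # 1/h
    k_prec_to_retics: float = 0.12           # 1/h
    k_retics_to_rbcm: float = 0.028           # 1/h (ln2/k ~ 1 d maturation)
    k_deg_retics: float = 0.02               # 1/h
    k_deg_rbcm: float = 1.0 / (110.0 * 24.0)  # 1/h (~110 d RBC lifespan)

    # --- observables / units ---
    mch_reti: float = 30.0                    # pg Hb per reticulocyte
    mch_rbcm: float = 30.0                    # pg Hb per RBC
    epo_molecular_weight: float = 30400.0     # g/mol (endogenous / rHuEPO)
    v_dist_esa_ml: float = 5000.0             # mL, ESA dose -> plasma conc

    def validate(self) -> None:
        for f_ in dataclasses.fields(self):
            v = getattr(self, f_.name)
            if isinstance(v, (int, float)) and f_.name not in ("hb_reference",):
                if v < 0:
                    raise ValueError(f"{f_.name} must be non-negative, got {v}")
        rate_fields = [
            "phd_basal", "hb_effect_km", "hb_effect_n", "k_modulate_phd_on_hif",
            "k_prod_hif", "k_production_epo", "km_prod_epo", "n2",
            "k_el_epo_plasma", "kon_epo_lr", "koff_epo_lr", "k_deg_epo_lr",
            "k_prod_progenitors", "k_prog_to_prec", "k_baseline_deg",
            "f_complex_km", "f_complex_n", "k_prec_to_retics",
            "k_retics_to_rbcm", "k_deg_rbcm", "mch_reti", "mch_rbcm",
            "epo_molecular_weight",
        ]
        for name in rate_fields:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not (0.0 <= self.f_complex_emax < 1.0):
            raise ValueError("f_complex_emax must lie in [0, 1)")

    def replace(self, **kw) -> "PhysioParams":
        return dataclasses.replace(self, **kw)

    # --- serialization ------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhysioParams":
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PhysioParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def transit_time_days(params: PhysioParams) -> float:
    """Implied progenitor -> circulating-RBC transit time in days.

    Sum of the pure maturation timescales (1/k) of the three pre-RBC
    compartments; ~8-10 days for the human erythroid lineage.
    """
    h = (1.0 / params.k_prog_to_prec + 1.0 / params.k_prec_to_retics
         + 1.0 / params.k_retics_to_rbcm)
    return h / units.HOURS_PER_DAY
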