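"""Unit conversions used throughout the model.

Internal time unit is hours; cell densities are cells/mL; plasma EPO is
ng/mL; receptor and ligand-receptor complex densities are molecules/mL;
hemoglobin is g/dL. The conversions below are deliberately explicit so no
factor of 10 hides inside a rate constant.
"""

from __future__ import annotations

AVOGADRO = 6.02214076e23

#: 1 IU of epoetin ~ 8.3 ng protein (specific activity ~120,000 IU/mg).
NG_PER_IU_RHUEPO = 8.3

# pg/mL -> g/dL.  1 pg = 1e-12 g and 1 dL = 100 mL, so
# 1 pg/mL = 1e-12 g/mL = 1e-10 g/dL.  Sanity: 4.5e9 cells/mL * 30 pg/cell
# = 1.35e11 pg/mL = 0.135 g/mL = 13.5 g/dL.
PG_PER_ML_TO_G_PER_DL = 1e-10

HOURS_PER_DAY = 24.0
HOURS_PER_WEEK = 168.0

#: rHuEPO IU per ug of darbepoetin alfa (clinical conversion 200 IU : 1 ug).
IU_RHUEPO_PER_UG_DARBEPOETIN = 200.0


def epo_to_molecules(epo_ng_per_ml: float, mw: float) -> float:
    """Convert an EPO-like ligand concentration from ng/mL to molecules/mL.

    molecules/mL = (ng/mL * 1e-9 g/ng / mw [g/mol]) * N_A.
    """
    if mw <= 0:
        raise ValueError(f"molecular weight must be positive, got {mw}")
    if epo_ng_per_ml < 0:
        raise ValueError(f"concentration must be non-negative, got {epo_ng_per_ml}")
    return epo_ng_per_ml * 1e-9 / mw * AVOGADRO


def molecules_to_epo(molecules_per_ml: float, mw: float) -> float:
    """Inverse of :func:`epo_to_molecules`."""
    if mw <= 0:
        raise ValueError(f"molecular weight must be positive, got {mw}")
    return molecules_per_ml * mw / AVOGADRO * 1e9


def iu_to_ng(iu: float, ng_per_iu: float = NG_PER_IU_RHUEPO) -> float:
    return iu * ng_per_iu


def hb_g_dl(retics_pg_ml: float) -> float:
    """pg Hb per mL of blood -> g/dL."""
    return retics_pg_ml * PG_PER_ML_TO_G_PER_DL
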