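"""Reference virtual patients: healthy and CKD stages 1.5/3/4/5.

Disease severity acts through four axes: reduced HIF-mediated EPO
production, reduced progenitor production, increased progenitor apoptosis,
and increased RBC degradation.  A reference VP is the base physiology with
those multiplicative scalings applied, solved to a self-consistent drug-free
steady state.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.optimize import brentq, root

from . import units
from .core import (Simulator, StateLayout, _build_rhs, compute_active_phd,
                   compute_hb, f_complex)
from .params import PhysioParams
from .state import PHYSIO_FIELDS, ErythroState

STAGES = ("healthy", "ckd1_5", "ckd3", "ckd4", "ckd5")


class SteadyStateError(RuntimeError):
    pass


@dataclass(frozen=True)
class SeverityAxes:
    """Multiplicative disease scalings; all 1.0 for the healthy VP."""

    epo_production_scale: float = 1.0     # on k_production_epo, in (0, 1]
    progenitor_production_scale: float = 1.0   # on k_prod_progenitors, (0, 1]
    progenitor_deg_scale: float = 1.0     # on k_baseline_deg, >= 1
    rbc_deg_scale: float = 1.0            # on k_deg_rbcm, >= 1

    def validate(self) -> None:
        if not (0.0 < self.epo_production_scale <= 1.0):
            raise ValueError("epo_production_scale must be in (0, 1]")
        if not (0.0 < self.progenitor_production_scale <= 1.0):
            raise ValueError("progenitor_production_scale must be in (0, 1]")
        if self.progenitor_deg_scale < 1.0:
            raise ValueError("progenitor_deg_scale must be >= 1")
        if self.rbc_deg_scale < 1.0:
            raise ValueError("rbc_deg_scale must be >= 1")

    def is_healthy(self) -> bool:
        return all(getattr(self, f.name) == 1.0
                   for f in dataclasses.fields(self))


def apply_axes(base: PhysioParams, axes: SeverityAxes) -> PhysioParams:
    axes.validate()
    return base.replace(
        k_production_epo=base.k_production_epo * axes.epo_production_scale,
        k_prod_progenitors=(base.k_prod_progenitors
                            * axes.progenitor_production_scale),
        k_baseline_deg=base.k_baseline_deg * axes.progenitor_deg_scale,
        k_deg_rbcm=base.k_deg_rbcm * axes.rbc_deg_scale,
    )


# ---------------------------------------------------------------------------
# steady state
# ---------------------------------------------------------------------------

def _cascade_given_hb(params: PhysioParams, hb: float, epor_total: float):
    """Solve the downstream chain for a fixed Hb (one fixed-point sweep)."""
    p = params
    phd = compute_active_phd(hb, 0.0, p)
    hif = p.k_prod_hif / (phd * p.k_modulate_phd_on_hif)
    production = (p.k_production_epo * hif ** p.n2
                  / (p.km_prod_epo ** p.n2 + hif ** p.n2))
    conv = p.epo_molecular_weight / units.AVOGADRO * 1e9
    km_bind = (p.koff_epo_lr + p.k_deg_epo_lr) / p.kon_epo_lr  # molecules/mL

    def clearance(epo):
        e_mol = epo / conv
        c = epor_total * e_mol / (km_bind + e_mol)
        return p.k_el_epo_plasma * epo + p.k_deg_epo_lr * c * conv

    # bracket the EPO balance
    hi = production / p.k_el_epo_plasma
    epo = brentq(lambda e: production - clearance(e), 0.0, hi * 1.0000001,
                 xtol=1e-18, rtol=1e-14)
    e_mol = epo / conv
    cplx = epor_total * e_mol / (km_bind + e_mol)
    r_free = epor_total - cplx
    eper = p.k_epo_cp / p.k_epo_pc * epo
    fval = f_complex(cplx, p)
    deg_eff = p.k_baseline_deg * (1.0 - fval)
    prog = p.k_prod_progenitors / (p.k_prog_to_prec + deg_eff)
    prec = p.k_prog_to_prec * prog / (p.k_deg_precursors + p.k_prec_to_retics)
    ret = p.k_prec_to_retics * prec / (p.k_retics_to_rbcm + p.k_deg_retics)
    rbc = p.k_retics_to_rbcm * ret / p.k_deg_rbcm
    return ErythroState(hif_alpha=hif, epo_plasma=epo, epo_periphery=eper,
                        epor_free=r_free, epo_lr_complex=cplx,
                        progenitors=prog, precursors=prec,
                        retics_plasma=ret, rbc_m=rbc)


def solve_steady_state(params: PhysioParams,
                       epor_total: float | None = None,
                       tol: float = 1e-8) -> ErythroState:
    """Drug-free steady state of the full feedback loop.

    The Eq-12/13 receptor recycling conserves free receptor + complex, so the
    receptor total is an input, not an outcome.  When ``epor_total`` is None
    it is chosen self-consistently as epor_per_progenitor times the VP's own
    steady-state progenitor density (iterated to convergence).

    Returns a state whose RHS residual is below ``tol`` relative,
    componentwise.
    """
    params.validate()
    self_consistent = epor_total is None
    rt = epor_total if epor_total is not None else 1e11

    def hb_residual(hb, rt_):
        st = _cascade_given_hb(params, hb, rt_)
        return compute_hb(st.retics_plasma, st.rbc_m, params) - hb

    # outer loop: receptor total; inner: bracketed scalar solve on Hb
    # (the open-loop Hb map is decreasing in Hb, so the residual has a
    # unique bracketed root)
    hb = params.hb_reference
    for _ in range(80):
        hi = 1.0
        while hb_residual(hi, rt) > 0 and hi < 1e7:
            hi *= 2.0
        hb = brentq(lambda h: hb_residual(h, rt), 1e-6, hi,
                    xtol=1e-13, rtol=1e-15)
        state = _cascade_given_hb(params, hb, rt)
        rt_new = (params.epor_per_progenitor * state.progenitors
                  if self_consistent else rt)
        if abs(rt_new - rt) < 1e-12 * max(rt, 1.0):
            rt = rt_new
            break
        rt = rt_new
    state = _cascade_given_hb(params, hb, rt)

    # polish with a root solve on the full RHS; the receptor conservation
    # replaces the (linearly dependent) free-receptor equation
    layout = StateLayout(())
    rhs = _build_rhs(params, layout)
    y0 = state.to_array()
    scale = np.maximum(np.abs(y0), 1e-6)

    def fun(z):
        y = z * scale
        dy = rhs(0.0, y)
        dy = dy / scale
        dy[3] = (y[3] + y[4] - rt) / scale[3]
        return dy

    sol = root(fun, y0 / scale, method="hybr", tol=1e-12)
    y = sol.x * scale
    resid = rhs(0.0, y) / scale
    resid[3] = (y[3] + y[4] - rt) / scale[3]
    rnorm = float(np.max(np.abs(resid)))
    if rnorm > tol or np.any(y < -tol * scale):
        raise SteadyStateError(
            f"steady-state solve did not converge (residual {rnorm:.2e})")
    y = np.clip(y, 0.0, None)
    return ErythroState.from_array(y)


# ---------------------------------------------------------------------------
# reference VPs
# ---------------------------------------------------------------------------

@dataclass
class ReferenceVP:
    stage: str
    axes: SeverityAxes
    params: PhysioParams
    steady_state: ErythroState
    baseline_hb: float            # g/dL
    baseline_epo: float           # ng/mL

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "axes": dataclasses.asdict(self.axes),
            "params": self.params.to_dict(),
            "steady_state": self.steady_state.to_dict(),
            "baseline_hb": self.baseline_hb,
            "baseline_epo": self.baseline_epo,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReferenceVP":
        return cls(stage=d["stage"], axes=SeverityAxes(**d["axes"]),
                   params=PhysioParams.from_dict(d["params"]),
                   steady_state=ErythroState.from_dict(d["steady_state"]),
                   baseline_hb=float(d["baseline_hb"]),
                   baseline_epo=float(d["baseline_epo"]))


def make_reference_vp(stage: str, axes: SeverityAxes,
                      base: PhysioParams) -> ReferenceVP:
    """Scale the base physiology by the severity axes and solve steady state."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}")
    params = apply_axes(base, axes)
    try:
        ss = solve_steady_state(params)
    except SteadyStateError as exc:
        raise SteadyStateError(f"steady-state failure for stage {stage}: {exc}")
    hb = compute_hb(ss.retics_plasma, ss.rbc_m, params)
    return ReferenceVP(stage=stage, axes=axes, params=params, steady_state=ss,
                       baseline_hb=hb, baseline_epo=ss.epo_plasma)


def classify_anemia(hb: float, sex: str) -> bool:
    """WHO definition: Hb < 12.0 g/dL in women, < 13.0 g/dL in men."""
    if hb < 0:
        raise ValueError("hb must be non-negative")
    thresholds = {"female": 12.0, "male": 13.0}
    if sex not in thresholds:
        raise ValueError(f"unknown sex label {sex!r}")
    return hb < thresholds[sex]


def save_registry(vps: dict[str, ReferenceVP], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({k: v.to_dict() for k, v in vps.items()}, fh,
                       sort_keys=True)


def load_registry(path) -> dict[str, ReferenceVP]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {k: ReferenceVP.from_dict(v) for k, v in raw.items()}
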