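"""Right-hand side and simulator of the erythropoiesis ODE system.

The physiology is a single feedback loop: hemoglobin sets the active
prolyl-hydroxylase (PHD) level, PHD degrades HIF-alpha, HIF-alpha drives
renal EPO production, plasma EPO binds EPOR on bone-marrow progenitors
(CFU-E) and the ligand-receptor complex rescues progenitors from apoptosis;
surviving progenitors mature through precursors (marrow reticulocytes) and
circulating reticulocytes into RBCs, which carry the hemoglobin that closes
the loop.  ESAs add to the EPO pool seen by the receptor; PHIs deactivate
PHD upstream.

Time unit is hours throughout.  Dose events hard-restart the integrator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import units
from .drugs import DrugSpec, phi_effect
from .dosing import DoseEvent
from .params import PhysioParams
from .state import PHYSIO_FIELDS, ErythroState

N_PHYSIO = len(PHYSIO_FIELDS)
ESA_STATES = ("depot", "central", "peripheral", "complex")
PHI_STATES = ("depot", "central", "peripheral")


class SimulationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# scalar observables
# ---------------------------------------------------------------------------

def hb_effect(hb: float, params: PhysioParams) -> float:
    """Increasing, saturating Hill effect of Hb on active PHD (1 at reference)."""
    if hb < 0:
        raise ValueError("hb must be non-negative")
    n = params.hb_effect_n
    hn = hb ** n
    return params.hb_effect_emax * hn / (params.hb_effect_km ** n + hn)


def compute_active_phd(hb: float, phi_effect_value: float,
                       params: PhysioParams) -> float:
    """Active PHD concentration as a function of Hb and total PHI effect.

    Default ("ratio") form: PHD = phd_basal / (1 + PHI_effect) * Hbeffect(Hb),
    strictly increasing in Hb and strictly decreasing in the PHI effect.
    The "additive" form folds the (inverted) Hb effect into the denominator
    instead; it is the alternative reading of the published equation.
    """
    if hb < 0 or phi_effect_value < 0:
        raise ValueError("hb and phi_effect must be non-negative")
    e = hb_effect(hb, params)
    if params.phd_form == "ratio":
        return params.phd_basal / (1.0 + phi_effect_value) * e
    # additive: deficit of the Hb effect below its reference value of 1
    # raises the denominator the same way a PHI does
    return params.phd_basal / (1.0 + phi_effect_value + max(0.0, 2.0 - e) - 1.0)


def hif_half_life(hb: float, phi_effect_value: float,
                  params: PhysioParams) -> float:
    """HIF-alpha half-life in minutes at a given Hb and PHI effect."""
    phd = compute_active_phd(hb, phi_effect_value, params)
    return math.log(2.0) / (phd * params.k_modulate_phd_on_hif) * 60.0


def compute_hb(retics_plasma: float, rbc_m: float,
               params: PhysioParams) -> float:
    """Hemoglobin (g/dL) from circulating reticulocyte and RBC densities."""
    if retics_plasma < 0 or rbc_m < 0:
        raise ValueError("cell densities must be non-negative")
    pg_per_ml = params.mch_reti * retics_plasma + params.mch_rbcm * rbc_m
    return pg_per_ml * units.PG_PER_ML_TO_G_PER_DL


def f_complex(total_complex: float, params: PhysioParams) -> float:
    """EPO-signal survival fraction: Hill of the total EPO-EPOR complex."""
    c = max(total_complex, 0.0)
    if c == 0.0:
        return 0.0
    cn = c ** params.f_complex_n
    return params.f_complex_emax * cn / (params.f_complex_km ** params.f_complex_n + cn)


# ---------------------------------------------------------------------------
# state layout with drugs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StateLayout:
    """Index map for the packed state vector: physiology first, then drugs."""

    drugs: tuple[DrugSpec, ...]

    @property
    def n_states(self) -> int:
        n = N_PHYSIO
        for d in self.drugs:
            n += 4 if d.kind == "esa" else 3
        return n

    def drug_slice(self, name: str) -> slice:
        i = N_PHYSIO
        for d in self.drugs:
            w = 4 if d.kind == "esa" else 3
            if d.name == name:
                return slice(i, i + w)
            i += w
        raise KeyError(f"drug {name!r} not in layout")

    def names(self) -> list[str]:
        out = list(PHYSIO_FIELDS)
        for d in self.drugs:
            block = ESA_STATES if d.kind == "esa" else PHI_STATES
            out += [f"{d.name}_{s}" for s in block]
        return out

    def pack(self, state: ErythroState) -> np.ndarray:
        y = np.zeros(self.n_states)
        y[:N_PHYSIO] = state.to_array()
        return y


def model_rhs(t: float, y: np.ndarray, params: PhysioParams,
              layout: StateLayout) -> np.ndarray:
    """Time derivative of the full (physiology + drug PK) state vector."""
    if not np.all(np.isfinite(y)):
        raise SimulationError(f"non-finite state at t={t:.3f} h: {y!r}")
    return _build_rhs(params, layout)(t, y)


def _build_rhs(params: PhysioParams, layout: StateLayout):
    """Compile a fast closure for the RHS (parameters hoisted to locals)."""
    p = params
    # hoisted physiological constants
    kmod = p.k_modulate_phd_on_hif
    kprodhif = p.k_prod_hif
    kprod_epo = p.k_production_epo
    km_epo = p.km_prod_epo
    n2 = p.n2
    kel = p.k_el_epo_plasma
    kcp, kpc = p.k_epo_cp, p.k_epo_pc
    kon0, koff0, kdeg_lr = p.kon_epo_lr, p.koff_epo_lr, p.k_deg_epo_lr
    kprodprog = p.k_prod_progenitors
    kmat = p.k_prog_to_prec
    kbdeg = p.k_baseline_deg
    kdegprec, kprec = p.k_deg_precursors, p.k_prec_to_retics
    kret, kdegret = p.k_retics_to_rbcm, p.k_deg_retics
    kdegrbc = p.k_deg_rbcm
    mchr, mchm = p.mch_reti, p.mch_rbcm
    conv0 = p.epo_molecular_weight / units.AVOGADRO * 1e9  # molecules -> ng
    mol0 = 1.0 / conv0                                      # ng -> molecules
    femax, fkm, fn = p.f_complex_emax, p.f_complex_km, p.f_complex_n
    fkm_n = fkm ** fn
    km_epo_n = km_epo ** n2
    hbconv = units.PG_PER_ML_TO_G_PER_DL
    hb_n = p.hb_effect_n
    hb_km_n = p.hb_effect_km ** hb_n
    hb_emax = p.hb_effect_emax
    phd_basal = p.phd_basal
    ratio_form = p.phd_form == "ratio"

    esa = [(layout.drug_slice(d.name).start, d.kon, d.koff,
            d.mw / units.AVOGADRO * 1e9)
           for d in layout.drugs if d.kind == "esa"]
    phi = [(layout.drug_slice(d.name).start, d) for d in layout.drugs
           if d.kind == "phi"]

    def rhs(t, y):
        dy = np.zeros_like(y)
        hif = y[0] if y[0] > 0.0 else 0.0
        epo = y[1] if y[1] > 0.0 else 0.0
        eper = y[2]
        r_free = y[3] if y[3] > 0.0 else 0.0
        c0 = y[4] if y[4] > 0.0 else 0.0
        prog = y[5] if y[5] > 0.0 else 0.0
        prec = y[6] if y[6] > 0.0 else 0.0
        ret = y[7] if y[7] > 0.0 else 0.0
        rbc = y[8] if y[8] > 0.0 else 0.0

        hbv = (mchr * ret + mchm * rbc) * hbconv

        # PHI effect on PHD
        pe = 0.0
        for i0, d in phi:
            c = y[i0 + 1]
            if c > 0.0:
                cn = c ** d.n_phd
                pe += d.emax_phd * cn / (d.ec50_phd ** d.n_phd + cn)

        hn = hbv ** hb_n
        he = hb_emax * hn / (hb_km_n + hn)
        if ratio_form:
            phd = phd_basal / (1.0 + pe) * he
        else:
            phd = phd_basal / (pe + max(0.0, 2.0 - he))

        # HIF-alpha
        dy[0] = kprodhif - hif * phd * kmod

        # endogenous EPO production (Hill in HIF) and disposition
        hifn = hif ** n2
        production = kprod_epo * hifn / (km_epo_n + hifn)
        net0 = kon0 * r_free * (epo * mol0) - koff0 * c0  # molecules/mL/h
        dy[1] = production - kel * epo - (kcp * epo - kpc * eper) - net0 * conv0
        dy[2] = kcp * epo - kpc * eper
        dy[4] = net0 - kdeg_lr * c0

        # receptor recycling: internalised complexes return as free receptor
        dr = kdeg_lr * c0 - net0
        ctot = c0

        # ESA PK blocks
        for i0, kon_d, koff_d, conv_d in esa:
            dep = y[i0]
            ce = y[i0 + 1] if y[i0 + 1] > 0.0 else 0.0
            pe_ = y[i0 + 2]
            cc = y[i0 + 3] if y[i0 + 3] > 0.0 else 0.0
            ka_d = _ka_of[i0]
            net_d = kon_d * r_free * (ce / conv_d) - koff_d * cc
            dy[i0] = -ka_d * dep
            dy[i0 + 1] = (ka_d * dep - kel * ce - (kcp * ce - kpc * pe_)
                          - net_d * conv_d)
            dy[i0 + 2] = kcp * ce - kpc * pe_
            dy[i0 + 3] = net_d - kdeg_lr * cc
            dr += kdeg_lr * cc - net_d
            ctot += cc
        dy[3] = dr

        # PHI PK blocks
        for i0, d in phi:
            dep = y[i0]
            c = y[i0 + 1] if y[i0 + 1] > 0.0 else 0.0
            per = y[i0 + 2]
            nl = d.vmax_nl * c / (d.km_nl + c) if d.vmax_nl else 0.0
            dy[i0] = -d.ka * dep
            dy[i0 + 1] = (d.ka * dep - d.kel * c - nl
                          - (d.k_cp * c - d.k_pc * per))
            dy[i0 + 2] = d.k_cp * c - d.k_pc * per

        # erythroid cascade
        if ctot > 0.0:
            cn = ctot ** fn
            fval = femax * cn / (fkm_n + cn)
        else:
            fval = 0.0
        dy[5] = kprodprog - kmat * prog - kbdeg * prog * (1.0 - fval)
        dy[6] = kmat * prog - kdegprec * prec - kprec * prec
        dy[7] = kprec * prec - kret * ret - kdegret * ret
        dy[8] = kret * ret - kdegrbc * rbc
        return dy

    _ka_of = {layout.drug_slice(d.name).start: d.ka
              for d in layout.drugs if d.kind == "esa"}
    return rhs


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Dense result of a simulation on a regular time grid."""

    t: np.ndarray                  # h
    y: np.ndarray                  # (n_t, n_states)
    layout: StateLayout
    params: PhysioParams

    def __post_init__(self):
        self._idx = {n: i for i, n in enumerate(self.layout.names())}

    def column(self, name: str) -> np.ndarray:
        return self.y[:, self._idx[name]]

    def hb(self) -> np.ndarray:
        ret = np.clip(self.column("retics_plasma"), 0.0, None)
        rbc = np.clip(self.column("rbc_m"), 0.0, None)
        return ((self.params.mch_reti * ret + self.params.mch_rbcm * rbc)
                * units.PG_PER_ML_TO_G_PER_DL)

    def total_plasma_epo(self) -> np.ndarray:
        """Endogenous plus ESA plasma EPO-like concentration (ng/mL)."""
        tot = np.clip(self.column("epo_plasma"), 0.0, None).copy()
        for d in self.layout.drugs:
            if d.kind == "esa":
                tot += np.clip(self.column(f"{d.name}_central"), 0.0, None)
        return tot

    def hb_at(self, t_h: float) -> float:
        return float(np.interp(t_h, self.t, self.hb()))

    def final_state(self) -> np.ndarray:
        return self.y[-1].copy()

    def final_physio(self) -> ErythroState:
        return ErythroState.from_array(self.y[-1, :N_PHYSIO])

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table: time_h, variable, value, units."""
        unit_of = {"hif_alpha": "a.u.", "epo_plasma": "ng/mL",
                   "epo_periphery": "ng/mL", "epor_free": "molecules/mL",
                   "epo_lr_complex": "molecules/mL"}
        rows = []
        for name in self.layout.names():
            if name in unit_of:
                u = unit_of[name]
            elif name.endswith(("_depot", "_central", "_peripheral")):
                u = "ng/mL" if any(d.kind == "esa" and name.startswith(d.name)
                                   for d in self.layout.drugs) else "mg/L"
            elif name.endswith("_complex"):
                u = "molecules/mL"
            else:
                u = "cells/mL"
            rows.append(pd.DataFrame({"time_h": self.t, "variable": name,
                                      "value": self.column(name), "units": u}))
        rows.append(pd.DataFrame({"time_h": self.t, "variable": "hb",
                                  "value": self.hb(), "units": "g/dL"}))
        return pd.concat(rows, ignore_index=True)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_trajectory_csv(path) -> pd.DataFrame:
    """Round-trip reader for :meth:`Trajectory.write_csv` output."""
    df = pd.read_csv(path)
    expected = {"time_h", "variable", "value", "units"}
    if set(df.columns) != expected:
        raise ValueError(f"not a trajectory table; columns {list(df.columns)}")
    return df


# ---------------------------------------------------------------------------
# simulator
# ---------------------------------------------------------------------------

@dataclass
class SolverOptions:
    rtol: float = 1e-8
    atol_scale: float = 1e-10   # atol_i = atol_scale * typical_i
    method: str = "LSODA"
    grid_h: float = 1.0         # output sampling step


class Simulator:
    """Stiff-capable integrator with hard restarts at dose events."""

    def __init__(self, params: PhysioParams, drugs: tuple[DrugSpec, ...] = (),
                 options: SolverOptions | None = None):
        self.params = params
        self.layout = StateLayout(tuple(drugs))
        self.options = options or SolverOptions()
        self._rhs = _build_rhs(params, self.layout)
        self._spec_of = {d.name: d for d in drugs}

    def _typical(self, y0: np.ndarray) -> np.ndarray:
        typ = np.ones_like(y0)
        typ[:N_PHYSIO] = np.maximum(np.abs(y0[:N_PHYSIO]), 1e-3)
        # drug states scale with what has been dosed so far; use a generous
        # floor so fresh (zero) drug states are still resolved
        for d in self.layout.drugs:
            s = self.layout.drug_slice(d.name)
            typ[s] = max(np.max(np.abs(y0[s]), initial=0.0), 1.0)
        return typ

    def _atol(self, y0: np.ndarray) -> np.ndarray:
        return np.maximum(self._typical(y0) * self.options.atol_scale, 1e-16)

    def _apply_dose(self, y: np.ndarray, ev: DoseEvent) -> None:
        spec = self._spec_of[ev.drug]
        s = self.layout.drug_slice(ev.drug)
        if spec.kind == "esa":
            conc = spec.dose_to_ng(ev.amount) / self.params.v_dist_esa_ml
            if ev.route == "IV":
                y[s.start + 1] += conc
            else:
                y[s.start] += conc * spec.f_bioavail
        else:
            y[s.start] += ev.amount * spec.f_bioavail / spec.v_dist_l  # mg/L

    def run(self, y0: np.ndarray, t0: float, tf: float,
            doses: list[DoseEvent] | None = None) -> Trajectory:
        """Integrate from t0 to tf applying dose events (times in hours).

        PHI oral doses reach the absorption depot after the drug's lag time;
        the lag is applied here by shifting the event time.
        """
        if not np.isfinite([t0, tf]).all() or tf < t0:
            raise ValueError("invalid time span")
        doses = sorted(doses or [], key=lambda e: e.time)
        events: list[DoseEvent] = []
        for ev in doses:
            spec = self._spec_of.get(ev.drug)
            if spec is None:
                raise ValueError(f"dose for drug {ev.drug!r} not in simulator")
            t = ev.time + (spec.tlag if spec.kind == "phi" else 0.0)
            events.append(DoseEvent(time=t, drug=ev.drug, amount=ev.amount,
                                    route=ev.route))
        events.sort(key=lambda e: e.time)

        y = np.asarray(y0, dtype=float).copy()
        if y.shape != (self.layout.n_states,):
            raise ValueError(f"state vector must have length "
                             f"{self.layout.n_states}, got {y.shape}")
        # segment boundaries: t0, dose times within (t0, tf), tf
        cuts = [t0]
        for ev in events:
            if t0 - 1e-9 <= ev.time < tf - 1e-9:
                if abs(ev.time - cuts[-1]) > 1e-9:
                    cuts.append(ev.time)
        if abs(cuts[-1] - tf) > 1e-9:
            cuts.append(tf)

        grid = self.options.grid_h
        ts_out: list[np.ndarray] = []
        ys_out: list[np.ndarray] = []
        ev_i = 0
        t_cur = t0
        # apply doses scheduled exactly at t0
        while ev_i < len(events) and events[ev_i].time <= t0 + 1e-9:
            self._apply_dose(y, events[ev_i])
            ev_i += 1
        for a, b in zip(cuts[:-1], cuts[1:]):
            n = max(int(math.ceil((b - a) / grid)), 1)
            t_eval = np.linspace(a, b, n + 1)
            sol = solve_ivp(self._rhs, (a, b), y, method=self.options.method,
                            t_eval=t_eval, rtol=self.options.rtol,
                            atol=self._atol(y), dense_output=False)
            if not sol.success:
                raise SimulationError(
                    f"integration failed at t={sol.t[-1] if len(sol.t) else a:.2f} h: "
                    f"{sol.message}")
            keep = slice(0, -1) if b < tf - 1e-9 else slice(None)
            ts_out.append(sol.t[keep])
            ys_out.append(sol.y.T[keep])
            y = sol.y[:, -1].copy()
            t_cur = b
            while ev_i < len(events) and events[ev_i].time <= t_cur + 1e-9:
                self._apply_dose(y, events[ev_i])
                ev_i += 1

        t_all = np.concatenate(ts_out)
        y_all = np.vstack(ys_out)
        # integration-quality guard: no state may be meaningfully negative
        # (relative to its typical scale, so drug washout to ~0 is fine)
        typ = np.maximum(np.abs(y_all).max(axis=0),
                         self._typical(y_all[0]))
        worst = (y_all / typ).min()
        if worst < -1e-6:
            raise SimulationError(
                f"state went negative beyond tolerance (min scaled value {worst:.2e})")
        return Trajectory(t=t_all, y=y_all, layout=self.layout,
                          params=self.params)


def simulate(state0: ErythroState, params: PhysioParams,
             doses: list[DoseEvent] | None = None,
             drugs: tuple[DrugSpec, ...] | None = None,
             t_span: tuple[float, float] = (0.0, 168.0),
             options: SolverOptions | None = None) -> Trajectory:
    """Convenience one-shot simulation from a drug-free physiological state."""
    doses = doses or []
    if drugs is None:
        from .drugs import get_drug
        names = sorted({ev.drug for ev in doses})
        drugs = tuple(get_drug(n) for n in names)
    sim = Simulator(params, drugs, options)
    y0 = sim.layout.pack(state0)
    return sim.run(y0, t_span[0], t_span[1], doses)
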