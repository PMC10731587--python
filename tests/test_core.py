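import math

import numpy as np
import pytest

from erythrosim import units
from erythrosim.core import (Simulator, SolverOptions, StateLayout,
                             _build_rhs, compute_active_phd, compute_hb,
                             f_complex, hif_half_life, read_trajectory_csv,
                             simulate)
from erythrosim.dosing import DoseEvent, Regimen, expand_regimen
from erythrosim.params import PhysioParams, transit_time_days
from erythrosim.patients import solve_steady_state
from erythrosim.state import ErythroState


class TestActivePhd:
    def test_normalisation_at_reference(self, model):
        p = model.params
        assert compute_active_phd(p.hb_reference, 0.0, p) == pytest.approx(
            p.phd_basal, rel=1e-12)

    def test_monotone_in_hb(self, model):
        p = model.params
        hbs = np.linspace(4.0, 18.0, 40)
        vals = [compute_active_phd(h, 0.0, p) for h in hbs]
        assert np.all(np.diff(vals) > 0)

    def test_decreasing_in_phi_effect(self, model):
        p = model.params
        vals = [compute_active_phd(11.0, e, p) for e in (0.0, 0.5, 2.0, 10.0)]
        assert np.all(np.diff(vals) < 0)
        assert all(v > 0 for v in vals)

    def test_hand_evaluated_hill(self, model):
        # direct scalar evaluation of the Hill expression at Hb 11.5
        p = model.params
        n, km, emax = p.hb_effect_n, p.hb_effect_km, p.hb_effect_emax
        expected = p.phd_basal * emax * 11.5 ** n / (km ** n + 11.5 ** n)
        assert compute_active_phd(11.5, 0.0, p) == pytest.approx(
            expected, rel=1e-14)

    def test_input_domain(self, model):
        with pytest.raises(ValueError):
            compute_active_phd(-1.0, 0.0, model.params)
        with pytest.raises(ValueError):
            compute_active_phd(10.0, -0.1, model.params)


class TestHifHalfLife:
    def test_calibrated_window(self, model):
        """HIF-alpha half-life spans 5 -> 8 min as Hb falls 14 -> 9 g/dL."""
        assert hif_half_life(14.0, 0.0, model.params) == pytest.approx(5.0,
                                                                       abs=0.01)
        assert hif_half_life(9.0, 0.0, model.params) == pytest.approx(8.0,
                                                                      abs=0.01)

    def test_doubling_phd_halves_half_life(self, model):
        p = model.params
        doubled = p.replace(phd_basal=2 * p.phd_basal)
        assert hif_half_life(12.0, 0.0, doubled) == pytest.approx(
            hif_half_life(12.0, 0.0, p) / 2.0, rel=1e-12)


class TestComputeHb:
    def test_empty_blood(self, model):
        assert compute_hb(0.0, 0.0, model.params) == 0.0

    def test_hand_arithmetic(self):
        p = PhysioParams(mch_rbcm=30.0)
        assert compute_hb(0.0, 4.5e9, p) == pytest.approx(13.5)

    def test_healthy_steady_state(self, healthy):
        got = compute_hb(healthy.steady_state.retics_plasma,
                         healthy.steady_state.rbc_m, healthy.params)
        assert got == pytest.approx(13.5, abs=1e-6)

    def test_negative_rejected(self, model):
        with pytest.raises(ValueError):
            compute_hb(-1.0, 1e9, model.params)


def _reference_rhs(y, p):
    """Independent transcription of the drug-free model equations, written
    directly from the model description (kept separate from the package
    implementation on purpose)."""
    hif, epo, eper, r_free, cplx, prog, prec, ret, rbc = y
    hb = (p.mch_reti * ret + p.mch_rbcm * rbc) * 1e-10
    hbeff = p.hb_effect_emax * hb ** p.hb_effect_n / (
        p.hb_effect_km ** p.hb_effect_n + hb ** p.hb_effect_n)
    phd = p.phd_basal * hbeff
    d_hif = p.k_prod_hif - hif * phd * p.k_modulate_phd_on_hif
    production = p.k_production_epo * hif ** p.n2 / (
        p.km_prod_epo ** p.n2 + hif ** p.n2)
    conv = p.epo_molecular_weight / 6.02214076e23 * 1e9
    net_mol = p.kon_epo_lr * r_free * (epo / conv) - p.koff_epo_lr * cplx
    d_epo = (production - p.k_el_epo_plasma * epo
             - (p.k_epo_cp * epo - p.k_epo_pc * eper) - net_mol * conv)
    d_eper = p.k_epo_cp * epo - p.k_epo_pc * eper
    d_r = p.k_deg_epo_lr * cplx - net_mol
    d_cplx = net_mol - p.k_deg_epo_lr * cplx
    f = p.f_complex_emax * cplx ** p.f_complex_n / (
        p.f_complex_km ** p.f_complex_n + cplx ** p.f_complex_n)
    d_prog = (p.k_prod_progenitors - p.k_prog_to_prec * prog
              - p.k_baseline_deg * prog * (1.0 - f))
    d_prec = (p.k_prog_to_prec * prog - p.k_deg_precursors * prec
              - p.k_prec_to_retics * prec)
    d_ret = (p.k_prec_to_retics * prec - p.k_retics_to_rbcm * ret
             - p.k_deg_retics * ret)
    d_rbc = p.k_retics_to_rbcm * ret - p.k_deg_rbcm * rbc
    return np.array([d_hif, d_epo, d_eper, d_r, d_cplx, d_prog, d_prec,
                     d_ret, d_rbc])


class TestModelRhs:
    def test_steady_state_residual(self, healthy):
        layout = StateLayout(())
        rhs = _build_rhs(healthy.params, layout)
        y = healthy.steady_state.to_array()
        dy = rhs(0.0, y)
        scale = np.maximum(np.abs(y), 1e-6)
        assert np.max(np.abs(dy) / scale) < 1e-8

    def test_production_ceiling_at_high_hif(self, healthy):
        """The EPO production term saturates at its maximal rate."""
        p = healthy.params
        layout = StateLayout(())
        rhs = _build_rhs(p, layout)
        y = healthy.steady_state.to_array().copy()
        y[0] = 1e9                      # HIF -> infinity
        dy = rhs(0.0, y)
        epo = y[1]
        eper = y[2]
        conv = p.epo_molecular_weight / units.AVOGADRO * 1e9
        clearance = (p.k_el_epo_plasma * epo
                     + (p.k_epo_cp * epo - p.k_epo_pc * eper)
                     + (p.kon_epo_lr * y[3] * epo / conv
                        - p.koff_epo_lr * y[4]) * conv)
        assert dy[1] + clearance == pytest.approx(p.k_production_epo,
                                                  rel=1e-9)

    def test_matches_independent_transcription(self, model):
        """One explicit-Euler step agrees with an independently coded
        duplicate of the drug-free equations to 1e-12 relative."""
        p = model.params
        rng = np.random.default_rng(5)
        layout = StateLayout(())
        rhs = _build_rhs(p, layout)
        base = model.vp("healthy").steady_state.to_array()
        for _ in range(5):
            y = base * rng.uniform(0.3, 3.0, size=base.size)
            got = rhs(0.0, y)
            want = _reference_rhs(y, p)
            scale = np.maximum(np.abs(want), 1e-12 * np.abs(base))
            assert np.max(np.abs(got - want) / scale) < 1e-12

    def test_feedback_sign(self, healthy):
        """Raising Hb raises PHD, lowers steady HIF and EPO production."""
        p = healthy.params
        lo, hi = 12.0, 15.0
        phd_lo, phd_hi = (compute_active_phd(h, 0.0, p) for h in (lo, hi))
        assert phd_hi > phd_lo
        hif_lo = p.k_prod_hif / (phd_lo * p.k_modulate_phd_on_hif)
        hif_hi = p.k_prod_hif / (phd_hi * p.k_modulate_phd_on_hif)
        assert hif_hi < hif_lo
        prod = lambda hif: hif ** p.n2 / (p.km_prod_epo ** p.n2 + hif ** p.n2)
        assert prod(hif_hi) < prod(hif_lo)


class TestSimulate:
    def test_fixed_point_is_constant(self, healthy):
        tr = simulate(healthy.steady_state, healthy.params,
                      t_span=(0.0, 52 * units.HOURS_PER_WEEK))
        hb = tr.hb()
        assert np.max(np.abs(hb - hb[0])) < 1e-6

    def test_solver_tolerance_convergence(self, model, healthy):
        """Halving rtol/atol changes the week-4 Hb by < 1e-4 g/dL."""
        rh = model.drugs["rhuepo"]
        doses = expand_regimen(Regimen(drug=rh, pattern="QW", dose=40000.0,
                                       duration_weeks=4))
        ends = []
        for rtol in (1e-8, 5e-9):
            tr = simulate(healthy.steady_state, healthy.params, doses=doses,
                          drugs=(rh,), t_span=(0.0, 4 * 168.0),
                          options=SolverOptions(rtol=rtol,
                                                atol_scale=rtol * 1e-2))
            ends.append(tr.hb()[-1])
        assert abs(ends[0] - ends[1]) < 1e-4

    def test_rk4_oracle(self, healthy):
        """LSODA trajectory matches a fixed-step RK4 reference."""
        p = healthy.params
        layout = StateLayout(())
        rhs = _build_rhs(p, layout)
        y0 = healthy.steady_state.to_array() * np.linspace(0.8, 1.2, 9)
        weeks = 2
        tr = simulate(ErythroState.from_array(y0), p,
                      t_span=(0.0, weeks * 168.0))
        h = 0.01
        y = y0.copy()
        t = 0.0
        n = int(weeks * 168.0 / h)
        checkpoints = {}
        for i in range(n):
            k1 = rhs(t, y)
            k2 = rhs(t + h / 2, y + h / 2 * k1)
            k3 = rhs(t + h / 2, y + h / 2 * k2)
            k4 = rhs(t + h, y + h * k3)
            y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t = (i + 1) * h
            if abs(t / 24.0 - round(t / 24.0)) < 1e-9:
                checkpoints[round(t)] = y.copy()
        for t_h, y_ref in checkpoints.items():
            i = int(np.searchsorted(tr.t, t_h))
            rel = np.abs(tr.y[i] - y_ref) / np.maximum(np.abs(y_ref), 1e-12)
            assert np.max(rel) < 1e-3

    def test_non_negativity_under_dosing(self, model, healthy):
        rh = model.drugs["rhuepo"]
        doses = expand_regimen(Regimen(drug=rh, pattern="QW", dose=40000.0,
                                       duration_weeks=4))
        tr = simulate(healthy.steady_state, healthy.params, doses=doses,
                      drugs=(rh,), t_span=(0.0, 6 * 168.0))
        typ = np.maximum(np.abs(tr.y).max(axis=0), 1e-12)
        assert (tr.y / typ).min() > -1e-6

    def test_epo_mass_balance_at_steady_state(self, healthy):
        """Production equals total clearance at the drug-free fixed point."""
        p = healthy.params
        ss = healthy.steady_state
        production = p.k_production_epo * ss.hif_alpha ** p.n2 / (
            p.km_prod_epo ** p.n2 + ss.hif_alpha ** p.n2)
        conv = p.epo_molecular_weight / units.AVOGADRO * 1e9
        clearance = (p.k_el_epo_plasma * ss.epo_plasma
                     + (p.k_epo_cp * ss.epo_plasma
                        - p.k_epo_pc * ss.epo_periphery)
                     + (p.kon_epo_lr * ss.epor_free * ss.epo_plasma / conv
                        - p.koff_epo_lr * ss.epo_lr_complex) * conv)
        assert clearance == pytest.approx(production, rel=1e-6)

    def test_sustained_epo_monotone_hb(self, model):
        """A sweep of constant EPO production levels gives monotone
        non-decreasing steady-state Hb."""
        p = model.params
        hbs = []
        for scale in (0.5, 1.0, 2.0, 4.0):
            q = p.replace(k_production_epo=p.k_production_epo * scale)
            ss = solve_steady_state(q)
            hbs.append(compute_hb(ss.retics_plasma, ss.rbc_m, q))
        assert np.all(np.diff(hbs) >= 0)


class TestTrajectoryIO:
    def test_round_trip(self, model, healthy, tmp_path):
        rh = model.drugs["rhuepo"]
        tr = simulate(healthy.steady_state, healthy.params,
                      doses=[DoseEvent(0.0, "rhuepo", 10000.0)],
                      drugs=(rh,), t_span=(0.0, 48.0))
        path = tmp_path / "traj.csv"
        tr.write_csv(path)
        df = read_trajectory_csv(path)
        hb = df[df.variable == "hb"].sort_values("time_h")
        np.testing.assert_allclose(hb["value"].to_numpy(), tr.hb(),
                                   rtol=1e-12)
        assert set(df.units) >= {"g/dL", "ng/mL", "cells/mL"}


class TestTransitTimes:
    def test_invariant_windows(self, model):
        p = model.params
        assert 8.0 <= transit_time_days(p) <= 10.0
        assert 1.0 <= math.log(2.0) / p.k_retics_to_rbcm / 24.0 <= 2.0
        assert 100.0 <= 1.0 / p.k_deg_rbcm / 24.0 <= 120.0
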