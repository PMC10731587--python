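import math

import numpy as np
import pytest

from erythrosim import units
from erythrosim.calibration import (measure_epo_tmax,
                                    measure_terminal_halflife,
                                    phi_concentration)
from erythrosim.core import SolverOptions, simulate
from erythrosim.dosing import DoseEvent, Regimen, expand_regimen
from erythrosim.drugs import get_drug, phi_effect


class TestExpandRegimen:
    def test_zero_duration(self, model):
        reg = Regimen(drug=model.drugs["rhuepo"], pattern="QW", dose=1000.0,
                      duration_weeks=0.0)
        assert expand_regimen(reg) == []

    def test_q2w_count(self, model):
        reg = Regimen(drug=model.drugs["darbepoetin"], pattern="Q2W",
                      dose=40.0, duration_weeks=44.0)
        events = expand_regimen(reg)
        assert len(events) == 22
        assert events[0].time == 0.0
        assert events[-1].time == 42 * 168.0

    def test_tiw_per_kg(self, model):
        reg = Regimen(drug=model.drugs["rhuepo"], pattern="TIW", dose=50.0,
                      per_kg=True, body_weight_kg=70.0, duration_weeks=2.0)
        events = expand_regimen(reg)
        assert [e.time for e in events] == [0.0, 48.0, 96.0,
                                            168.0, 216.0, 264.0]
        assert all(e.amount == 3500.0 for e in events)

    def test_unknown_pattern(self, model):
        reg = Regimen(drug=model.drugs["rhuepo"], pattern="Q3W", dose=1.0,
                      duration_weeks=4.0)
        with pytest.raises(ValueError):
            expand_regimen(reg)

    def test_route_consistency(self, model):
        reg = Regimen(drug=model.drugs["vadadustat"], pattern="QD",
                      dose=450.0, duration_weeks=1.0, route="SC")
        with pytest.raises(ValueError):
            expand_regimen(reg)


class TestEsaPk:
    def test_iv_depot_stays_empty(self, model, healthy):
        rh = model.drugs["rhuepo"]
        tr = simulate(healthy.steady_state, healthy.params,
                      doses=[DoseEvent(0.0, "rhuepo", 10000.0, route="IV")],
                      drugs=(rh,), t_span=(0.0, 48.0))
        assert np.max(np.abs(tr.column("rhuepo_depot"))) == 0.0

    def test_sc_tmax_16h(self, model, healthy):
        tmax = measure_epo_tmax(healthy.params, model.drugs["rhuepo"],
                                healthy.steady_state)
        assert tmax == pytest.approx(16.0, abs=0.5)

    def test_monoexponential_without_binding_or_distribution(self, model,
                                                             healthy):
        """With binding and peripheral exchange off, the post-absorption
        decay is a single exponential at the plasma elimination rate."""
        p = healthy.params.replace(k_epo_cp=0.0, k_epo_pc=1e-9)
        rh = model.drugs["rhuepo"].replace(kon=0.0, koff=0.0)
        tr = simulate(healthy.steady_state, p,
                      doses=[DoseEvent(0.0, "rhuepo", 40000.0)], drugs=(rh,),
                      t_span=(0.0, 400.0))
        conc = tr.column("rhuepo_central")
        # terminal window well past absorption; flip-flop -> slope = min(ka, kel)
        mask = (tr.t > 250.0) & (conc > 0.0)
        slope = np.polyfit(tr.t[mask], np.log(conc[mask]), 1)[0]
        assert -slope == pytest.approx(min(rh.ka, p.k_el_epo_plasma),
                                       rel=1e-4)

    def test_dose_conservation(self, model, healthy):
        """Total absorbed drug equals bioavailable dose / volume."""
        rh = model.drugs["rhuepo"]
        dose = 40000.0
        tr = simulate(healthy.steady_state, healthy.params,
                      doses=[DoseEvent(0.0, "rhuepo", dose)], drugs=(rh,),
                      t_span=(0.0, 500.0),
                      options=SolverOptions(grid_h=0.25))
        depot = tr.column("rhuepo_depot")
        absorbed = np.trapezoid(rh.ka * depot, tr.t)
        expected = rh.dose_to_ng(dose) * rh.f_bioavail / healthy.params.v_dist_esa_ml
        assert absorbed == pytest.approx(expected, rel=1e-4)

    def test_darbepoetin_halflife_ratio(self, model, healthy):
        t_rh = measure_terminal_halflife(healthy.params, model.drugs["rhuepo"],
                                         healthy.steady_state, 40000.0, 336.0)
        t_da = measure_terminal_halflife(healthy.params,
                                         model.drugs["darbepoetin"],
                                         healthy.steady_state, 60.0, 1000.0)
        assert 3.0 <= t_da / t_rh <= 4.0


class TestPhiPk:
    def test_lag_blocks_early_exposure(self, model):
        vada = model.drugs["vadadustat"]
        t = np.array([0.1, 0.25, vada.tlag + 1.0])
        conc = phi_concentration(vada, 450.0, t)
        assert conc[0] == 0.0 and conc[1] == 0.0 and conc[2] > 0.0

    def test_vadadustat_superposition(self, model):
        """Linear PK: doubling the dose doubles the concentration at all
        times (to tight numerical tolerance)."""
        vada = model.drugs["vadadustat"]
        t = np.linspace(1.0, 48.0, 30)
        c1 = phi_concentration(vada, 450.0, t)
        c2 = phi_concentration(vada, 900.0, t)
        np.testing.assert_allclose(c2, 2.0 * c1, rtol=1e-6)

    def test_daprodustat_saturable_clearance_auc(self, model):
        """With saturable elimination, AUC grows superlinearly in dose
        (checked against a dense quadrature oracle)."""
        dap = model.drugs["daprodustat"]
        t = np.linspace(0.0, 96.0, 2000)
        auc1 = np.trapezoid(phi_concentration(dap, 4.0, t), t)
        auc2 = np.trapezoid(phi_concentration(dap, 8.0, t), t)
        assert auc2 > 2.0 * auc1 * (1.0 + 1e-6)


class TestPhiEffect:
    def test_zero_at_zero(self, model):
        assert phi_effect(0.0, model.drugs["vadadustat"]) == 0.0

    def test_half_max_at_ec50(self, model):
        vada = model.drugs["vadadustat"]
        assert phi_effect(vada.ec50_phd, vada) == pytest.approx(
            vada.emax_phd / 2.0, rel=1e-12)

    def test_monotone_and_bounded(self, model):
        vada = model.drugs["vadadustat"]
        cs = np.logspace(-3, 3, 40)
        vals = [phi_effect(c, vada) for c in cs]
        assert np.all(np.diff(vals) >= 0)
        assert vals[-1] <= vada.emax_phd

    def test_negative_conc(self, model):
        with pytest.raises(ValueError):
            phi_effect(-1.0, model.drugs["vadadustat"])
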