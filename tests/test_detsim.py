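import math

import numpy as np
import pytest
from scipy.optimize import curve_fit
from scipy.stats import norm

from cldend import (
    CableParams,
    IonParams,
    PumpParams,
    SolverError,
    SynapseParams,
    StimulusTrain,
    attach_spines,
    build_cylinder,
    cl_from_current,
    egaba,
    gaba_conductance,
    make_stimulus,
    nernst,
    pump_step,
    run_simulation,
    synaptic_currents,
    trajectory_metrics,
)


class TestNernst:
    def test_chloride_rest(self):
        # RT/F at 308.15 K is 26.55 mV; ln(133.5/5) = 3.285
        assert nernst(-1, 5.0, 133.5, 308.15) == pytest.approx(-87.22, abs=0.05)

    def test_bicarbonate_rest(self):
        assert nernst(-1, 16.0, 26.0, 308.15) == pytest.approx(-12.89, abs=0.05)

    @pytest.mark.parametrize("c", [0.1, 5.0, 133.5])
    def test_equal_concentrations_zero(self, c):
        assert nernst(-1, c, c, 310.0) == 0.0

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            nernst(-1, 0.0, 133.5)
        with pytest.raises(ValueError):
            nernst(-1, 5.0, -1.0)


class TestEgaba:
    def test_printed_resting_value(self):
        p = IonParams()
        assert egaba(p.e_cl, p.e_hco3, 0.25) == pytest.approx(-68.63, abs=0.1)

    def test_pure_chloride_and_pure_bicarbonate(self):
        assert egaba(-87.2, -12.9, 0.0) == -87.2
        assert egaba(-87.2, -12.9, 1.0) == -12.9

    def test_fraction_out_of_range(self):
        with pytest.raises(ValueError):
            egaba(-87.2, -12.9, 1.5)


class TestSynapseKinetics:
    def test_conductance_zero_at_onset_and_infinity(self):
        s = SynapseParams(target=0, train=make_stimulus("periodic", 10, 1))
        assert gaba_conductance(0.0, s) == pytest.approx(0.0)
        assert gaba_conductance(1e5, s) == pytest.approx(0.0, abs=1e-12)

    def test_peak_time_and_amplitude(self):
        s = SynapseParams(target=0, train=make_stimulus("periodic", 10, 1), g_max=1.5)
        # closed-form extremum of the double exponential
        t_peak = 0.5 * 6 / (6 - 0.5) * math.log(6 / 0.5)
        assert s.t_peak == pytest.approx(1.355, abs=1e-3)
        assert gaba_conductance(t_peak, s) == pytest.approx(1.5, rel=1e-12)
        # strictly below peak elsewhere
        t = np.linspace(0.01, 50, 500)
        assert gaba_conductance(t, s).max() <= 1.5 + 1e-12

    def test_invalid_time_constants(self):
        with pytest.raises(ValueError):
            SynapseParams(target=0, train=make_stimulus("periodic", 10, 1),
                          tau1=6.0, tau2=0.5)

    def test_current_split_and_conservation(self):
        i_cl, i_hco3 = synaptic_currents(-87.2, 1.0, -87.2, -12.9, 0.0)
        assert i_cl == 0.0 and i_hco3 == 0.0
        i_cl, _ = synaptic_currents(-67.2, 1.0, -87.2, -12.9, 0.0)
        assert i_cl == pytest.approx(20.0)
        v, g, p = -60.0, 0.8, 0.25
        i_cl, i_hco3 = synaptic_currents(v, g, -87.2, -12.9, p)
        assert i_cl + i_hco3 == pytest.approx(g * (v - (1 - p) * -87.2 - p * -12.9))


class TestClFromCurrent:
    def test_worked_unit_check(self):
        # 20 pA into 1 μm³ for 1 ms: 2e-14 C / F / 1e-15 L ≈ 0.207 mM
        assert cl_from_current(20.0, 1.0, 1.0) == pytest.approx(0.207, abs=5e-4)

    def test_zero_current_and_volume_scaling(self):
        assert cl_from_current(0.0, 1.0, 1.0) == 0.0
        assert cl_from_current(20.0, 2.0, 1.0) == pytest.approx(
            cl_from_current(20.0, 1.0, 1.0) / 2
        )

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError):
            cl_from_current(1.0, 0.0, 1.0)


class TestPump:
    def test_fixed_point_and_mask(self):
        p = PumpParams(tau_cl=3000.0, cl_rest=5.0)
        assert pump_step(5.0, p, 10.0) == pytest.approx(5.0)
        masked = PumpParams(mask=np.array([True, False]))
        out = pump_step(np.array([10.0, 10.0]), masked, 500.0)
        assert out[0] < 10.0 and out[1] == 10.0

    def test_closed_form_one_time_constant(self):
        p = PumpParams(tau_cl=3000.0, cl_rest=5.0)
        cl = 10.0
        for _ in range(30):
            cl = pump_step(cl, p, 100.0)
        assert cl == pytest.approx(5 + 5 / math.e, rel=1e-12)


class TestRunSimulation:
    def test_mass_conservation_without_pump(self, small_cylinder):
        init = np.full(small_cylinder.n, 5.0)
        init[150] = 10.0
        traj = run_simulation(small_cylinder, t_end=500.0, dt=0.5,
                              record_dt=100.0, initial_cl=init)
        vols = small_cylinder.volumes()
        m0 = (traj.cl[0] * vols).sum()
        m1 = (traj.cl[-1] * vols).sum()
        assert abs(m1 - m0) / m0 < 1e-9

    def test_uniform_pump_relaxation_time_constant(self):
        morph = build_cylinder(20.0, 1.0, 1.0)
        traj = run_simulation(
            morph, pump=PumpParams(tau_cl=3000.0, cl_rest=5.0),
            t_end=12000.0, dt=5.0, record_dt=50.0, initial_cl=10.0,
        )
        y = traj.cl[:, 0]

        def mono_exp(t, amp, tau):
            return 5.0 + amp * np.exp(-t / tau)

        (amp, tau), _ = curve_fit(mono_exp, traj.times, y, p0=(4.0, 2000.0))
        assert tau == pytest.approx(3000.0, rel=0.01)

    def test_focal_release_matches_gaussian_green_function(self):
        morph = build_cylinder(300.0, 1.0, 1.0)
        init = np.full(morph.n, 5.0)
        center = morph.nearest_shaft(150.0)
        init[center] = 10.0
        t_end = 100.0
        traj = run_simulation(morph, t_end=t_end, dt=0.25, record_dt=t_end,
                              initial_cl=init)
        x = morph.positions()
        excess = traj.cl[-1] - 5.0
        excess /= excess.sum()
        sigma = math.sqrt(2 * 2.0 * t_end)
        ref = norm.pdf(x, loc=x[center], scale=sigma)
        ref /= ref.sum()
        l2 = np.linalg.norm(excess - ref) / np.linalg.norm(ref)
        assert l2 < 0.02

    def test_variance_growth_slope_is_2D(self, small_cylinder):
        init = np.full(small_cylinder.n, 5.0)
        init[150] = 10.0
        traj = run_simulation(small_cylinder, t_end=200.0, dt=0.5,
                              record_dt=20.0, initial_cl=init)
        m = trajectory_metrics(traj, small_cylinder)
        # before boundary influence D_app ≈ D_Cl at every time point
        assert np.allclose(m.d_app, 2.0, rtol=0.02)

    def test_refinement_convergence_of_d_app(self):
        def d_app(dx, dt):
            morph = build_cylinder(200.0, 1.0, dx)
            init = np.full(morph.n, 5.0)
            init[morph.nearest_shaft(100.0)] = 5.0 + 5.0 / dx  # fixed released mass
            traj = run_simulation(morph, t_end=500.0, dt=dt,
                                  record_dt=500.0, initial_cl=init)
            return trajectory_metrics(traj, morph).d_app_end

        coarse = d_app(1.0, 0.5)
        fine = d_app(0.5, 0.1)
        assert abs(fine - coarse) / coarse < 0.01

    def test_resting_egaba_everywhere(self, small_cylinder):
        traj = run_simulation(small_cylinder, t_end=10.0, dt=1.0)
        assert np.allclose(traj.e_gaba(), -68.63, atol=0.1)

    def test_synaptic_chloride_loading_raises_local_cl(self):
        morph = build_cylinder(50.0, 1.0, 1.0)
        syn = SynapseParams(target=25, train=make_stimulus("periodic", 10.0, 5))
        traj = run_simulation(morph, synapses=[syn], t_end=600.0, dt=0.05,
                              record_dt=50.0)
        assert traj.cl[-1, 25] > 5.0
        assert traj.cl[-1, 25] > traj.cl[-1, 0]
        assert len(traj.events) == 5

    def test_instability_reported_as_solver_error(self):
        # strong efflux (E_Cl above clamped V) from a tiny compartment
        morph = attach_spines(build_cylinder(5.0, 1.0, 1.0), 0.2, seed=0)
        head = morph.spines[0][2]
        syn = SynapseParams(target=head, train=make_stimulus("periodic", 100.0, 50),
                            g_max=200.0)
        with pytest.raises(SolverError, match="dt"):
            run_simulation(morph, ions=IonParams(cl_in_rest=200.0),
                           synapses=[syn], t_end=400.0, dt=0.5)

    def test_radial_shells_do_not_change_axial_metrics(self):
        morph = build_cylinder(200.0, 1.0, 1.0)
        init = np.full(morph.n, 5.0)
        init[morph.nearest_shaft(100.0)] = 10.0
        kw = dict(t_end=500.0, dt=0.5, record_dt=100.0, initial_cl=init)
        flat = trajectory_metrics(run_simulation(morph, **kw), morph)
        shelled = trajectory_metrics(
            run_simulation(morph, radial_shells=4, **kw), morph
        )
        assert shelled.d_app_end == pytest.approx(flat.d_app_end, rel=0.01)

    def test_cable_with_shells_unsupported(self, small_cylinder):
        with pytest.raises(SolverError):
            run_simulation(small_cylinder, cable=CableParams(),
                           radial_shells=4, t_end=1.0, dt=0.5)


class TestPassiveCable:
    def test_rest_is_stationary(self):
        morph = build_cylinder(50.0, 1.0, 1.0)
        traj = run_simulation(morph, cable=CableParams(), t_end=50.0, dt=0.1,
                              record_dt=10.0)
        assert np.allclose(traj.v, -70.0, atol=1e-9)

    def test_gaba_hyperpolarizes_below_rest(self):
        # E_GABA (−68.6) is above rest here, so GABA depolarizes slightly
        # toward E_GABA; with a low-Cl cell (E_GABA < −70) it hyperpolarizes.
        morph = build_cylinder(50.0, 1.0, 1.0)
        syn = SynapseParams(target=25, train=make_stimulus("periodic", 10.0, 3),
                            g_max=1.0)
        low_cl = IonParams(cl_in_rest=3.0)
        traj = run_simulation(morph, ions=low_cl, synapses=[syn], cable=CableParams(),
                              t_end=250.0, dt=0.05, record_dt=1.0)
        assert traj.v.min() < -70.0
        # and the standard ionic conditions depolarize toward E_GABA
        traj2 = run_simulation(morph, synapses=[syn], cable=CableParams(),
                               t_end=250.0, dt=0.05, record_dt=1.0)
        assert traj2.v.max() > -70.0
        assert traj2.v.max() < egaba(IonParams().e_cl, IonParams().e_hco3, 0.25) + 0.5
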