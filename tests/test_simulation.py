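"""Integrator correctness: closed forms, superposition, events, resampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import expm

from pbrpk import (
    InjectionSchedule,
    SolverSettings,
    ValidationError,
    assemble_rhs,
    build_toy_model,
    resample,
    simulate,
)
from pbrpk.graph import LIGAND_KINDS, RECEPTOR_KINDS


class TestAssembleRhs:
    def test_decay_only_derivative(self):
        g = build_toy_model("decay_only")
        model = assemble_rhs(g)
        dy = model.rhs(0.0, np.array([10.0, 0.0]))
        lam = g.parameters["lambda_phys"]
        assert dy == pytest.approx([-10 * lam, 10 * lam])

    def test_zero_state_zero_derivative(self):
        for kind in ("decay_only", "two_compartment_exchange", "minimal_binding"):
            model = assemble_rhs(build_toy_model(kind))
            assert np.all(model.rhs(0.0, np.zeros(model.n)) == 0)

    def test_jacobian_matches_finite_differences(self):
        g = build_toy_model("minimal_binding")
        model = assemble_rhs(g)
        rng = np.random.default_rng(0)
        y = rng.uniform(0.1, 2.0, model.n)
        J = model.jac(0.0, y)
        eps = 1e-7
        for j in range(model.n):
            yp = y.copy()
            yp[j] += eps
            fd = (model.rhs(0.0, yp) - model.rhs(0.0, y)) / eps
            assert np.allclose(J[:, j], fd, rtol=1e-5, atol=1e-6)


class TestClosedForms:
    def test_decay_closed_form(self):
        g = build_toy_model("decay_only")
        res = simulate(g, InjectionSchedule(1.0, 0.0), SolverSettings(t_end=100.0, n_grid=50))
        lam = g.parameters["lambda_phys"]
        expected = np.exp(-lam * res.times)
        assert np.max(np.abs(res.species_amount("hot") - expected) / expected) < 1e-7

    def test_two_compartment_matches_matrix_exponential(self):
        """Hot-ligand subsystem equals expm of the independent 2x2 rate matrix."""
        g = build_toy_model("two_compartment_exchange")
        lam, k12, k21 = (g.parameters[k] for k in ("lambda_phys", "k12", "k21"))
        res = simulate(
            g,
            InjectionSchedule(1.0, 0.0),
            SolverSettings(t_end=100.0, times=(1.0, 10.0, 100.0)),
        )
        M = np.array([[-k12 - lam, k21], [k12, -k21 - lam]])
        for t in (1.0, 10.0, 100.0):
            i = int(np.flatnonzero(res.times == t)[0])
            num = np.array(
                [res.species_amount("hot_vein")[i], res.species_amount("hot_tis")[i]]
            )
            exact = expm(M * t) @ np.array([1.0, 0.0])
            assert np.max(np.abs(num - exact) / exact) < 1e-6

    def test_minimal_binding_equilibrium_satisfies_kd(self):
        g = build_toy_model("minimal_binding")
        res = simulate(g, InjectionSchedule(0.0, 0.0), SolverSettings(t_end=5000.0, n_grid=40))
        free = res.species_amount("hot")[-1]
        rec = res.species_amount("receptor")[-1]
        bound = res.species_amount("hot_bound")[-1]
        # amounts in a 1 L compartment double as concentrations
        assert free * rec / bound == pytest.approx(g.parameters["K_D"], rel=1e-4)


class TestEvents:
    def test_linear_superposition_of_boluses(self):
        """For a linear model, a 2-bolus run equals the sum of shifted 1-bolus runs."""
        g = build_toy_model("two_compartment_exchange")
        tau = 100.0
        times = tuple(np.linspace(0.0, 400.0, 21))
        s2 = simulate(
            g,
            InjectionSchedule(1.0, 0.0, n_injections=2, interval=tau),
            SolverSettings(t_end=400.0, times=times),
        )
        s1 = simulate(
            g, InjectionSchedule(0.5, 0.0), SolverSettings(t_end=400.0, times=times)
        )
        h2 = s2.species_amount("hot_vein")
        h1 = s1.species_amount("hot_vein")
        shifted = np.where(
            s1.times >= tau, np.interp(s1.times - tau, s1.times, h1), 0.0
        )
        ref = h1 + shifted
        mask = ref > 1e-12
        assert np.max(np.abs(h2[mask] - ref[mask]) / ref[mask]) < 1e-6

    def test_total_injected_equals_schedule_totals(self):
        sched = InjectionSchedule(10.0, 100.0, n_injections=7, interval=50.0)
        boluses = sched.bolus_amounts()
        assert sum(b[1] for b in boluses) == pytest.approx(10.0)
        assert sum(b[2] for b in boluses) == pytest.approx(100.0)

    def test_unequal_split_fractions(self):
        sched = InjectionSchedule(
            10.0, 0.0, n_injections=2, interval=10.0, hot_fractions=(0.8, 0.2)
        )
        assert [b[1] for b in sched.bolus_amounts()] == pytest.approx([8.0, 2.0])

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValidationError):
            InjectionSchedule(1.0, 0.0, n_injections=2, hot_fractions=(0.9, 0.2))


class TestResample:
    def test_identity_on_original_grid(self):
        g = build_toy_model("decay_only")
        res = simulate(g, InjectionSchedule(1.0, 0.0), SolverSettings(t_end=50.0, n_grid=30))
        r2 = resample(res, res.times)
        assert np.array_equal(r2.amounts, res.amounts)

    def test_midpoint_accuracy(self):
        g = build_toy_model("decay_only")
        res = simulate(g, InjectionSchedule(1.0, 0.0), SolverSettings(t_end=50.0, times=tuple(np.linspace(0, 50, 101))))
        mid = (res.times[:-1] + res.times[1:]) / 2
        r2 = resample(res, mid)
        lam = g.parameters["lambda_phys"]
        exact = np.exp(-lam * mid)
        assert np.max(np.abs(r2.species_amount("hot") - exact) / exact) < 1e-5

    def test_out_of_range_grid_rejected(self):
        g = build_toy_model("decay_only")
        res = simulate(g, InjectionSchedule(1.0, 0.0), SolverSettings(t_end=50.0, n_grid=30))
        with pytest.raises(ValidationError):
            resample(res, [60.0])


@given(
    n=st.integers(min_value=1, max_value=6),
    tau=st.floats(min_value=10.0, max_value=500.0),
    hot=st.floats(min_value=0.1, max_value=50.0),
    cold=st.floats(min_value=0.0, max_value=400.0),
)
@settings(max_examples=15, deadline=None, derandomize=True)
def test_minimal_binding_conserves_moieties_under_random_schedules(n, tau, hot, cold):
    g = build_toy_model("minimal_binding")
    t_end = (n - 1) * tau + 500.0
    res = simulate(
        g,
        InjectionSchedule(hot, cold, n_injections=n, interval=tau),
        SolverSettings(t_end=t_end, n_grid=40),
    )
    lig = res.total_amount(LIGAND_KINDS)
    rec = res.total_amount(RECEPTOR_KINDS)
    total = hot + cold + 1.0  # toy starts with 1 nmol free hot
    assert abs(lig[-1] - total) / total < 1e-6
    assert np.max(np.abs(rec - 5.0)) / 5.0 < 1e-6
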