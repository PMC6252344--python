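"""Compartmental simulation: oracles, conservation, steady state."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from superchild.kinetics import (ModelSpec, ModelValidationError,
                                 SingularSteadyStateError, TracerCurve,
                                 _augmented_system, conservation_residual,
                                 mst_rbp, simulate_tracer,
                                 simulate_tracer_all_compartments,
                                 steady_state)
from superchild.protocols import REDUCED11


def _ivp_fdp(spec, times):
    """Independent adaptive-integrator solution of the delayed system."""
    B, z0, idx = _augmented_system(spec)
    taus = np.asarray(times, dtype=float) - spec.dt3
    out = np.zeros(len(taus))
    pos = taus > 0
    if np.any(pos):
        sol = solve_ivp(lambda t, z: B @ z, (0.0, taus[pos].max() * 1.0001),
                        z0, t_eval=taus[pos], rtol=1e-13, atol=1e-18,
                        method="DOP853")
        out[pos] = sol.y[idx[5]]
    return out


def _random_spec(rng):
    two = rng.random() < 0.5
    full = rng.random() < 0.5
    lo, hi = {"L54": (1, 20), "L65": (20, 40), "L56": (0.015, 0.12),
              "L106": (0.002, 0.05), "L75": (5, 60), "L57": (0.4, 3.7),
              "L21": (20, 100)}, None
    u = lambda a, b: float(np.exp(rng.uniform(np.log(a), np.log(b))))
    L = {(5, 4): u(1, 20), (6, 5): u(20, 40), (5, 6): u(0.015, 0.12),
         (10, 6): u(0.002, 0.05)}
    if two:
        L[(7, 5)] = u(5, 60)
        L[(5, 7)] = u(0.4, 3.7)
    if full:
        L[(2, 1)] = u(20, 100)
        L[(3, 2)] = u(20, 100)
    return ModelSpec("full" if full else "simplified", 2 if two else 1, L,
                     dt3=float(rng.uniform(0.08, 0.4)),
                     absorption=float(rng.uniform(0.7, 0.9)))


class TestSimulateTracer:
    def test_zero_before_delay(self, gm_spec_simplified, gm_spec_full):
        for spec in (gm_spec_simplified, gm_spec_full):
            t = np.array([spec.dt3 * 0.1, spec.dt3 * 0.5, spec.dt3 * 0.99])
            assert np.all(simulate_tracer(spec, t).fdp == 0.0)

    def test_dual_oracle_gm_spec(self, gm_spec_simplified):
        """Matrix-exponential and adaptive-integrator FD_p agree to 1e-8 at
        the 11 reduced times for the geometric-mean simplified model."""
        got = simulate_tracer(gm_spec_simplified, REDUCED11.times).fdp
        ref = _ivp_fdp(gm_spec_simplified, REDUCED11.times)
        mask = ref > 0
        assert np.max(np.abs(got[mask] - ref[mask]) / ref[mask]) < 1e-8

    def test_dual_oracle_random_specs(self):
        """expm and integrator agree to 1e-8 on a grid of 20 random specs."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            spec = _random_spec(rng)
            got = simulate_tracer(spec, REDUCED11.times).fdp
            ref = _ivp_fdp(spec, REDUCED11.times)
            mask = ref > 1e-10  # measurable tracer levels
            assert np.max(np.abs(got[mask] - ref[mask]) / ref[mask]) < 1e-8

    def test_no_recycling_terminal_slope(self):
        """Without return from the extravascular pools, log FD_p declines
        with the plasma exit rate once the faster cascade stages die out
        (closed form of the delay -> 4 -> 5 cascade)."""
        L65, L75 = 3.0, 2.0  # plasma exit 5/d, slower than L(5,4)
        spec = ModelSpec(
            "simplified", 2,
            {(5, 4): 50.0, (6, 5): L65, (5, 6): 1e-12, (10, 6): 0.005,
             (7, 5): L75, (5, 7): 1e-12},
            dt3=0.2,
        )
        # after the fast L(5,4)=50/d stage has died out but before the
        # vanishing return flux floor is reached
        t = np.array([1.5, 2.0, 2.5, 3.0])
        fdp = simulate_tracer(spec, t).fdp
        slopes = np.diff(np.log(fdp)) / np.diff(t)
        assert slopes == pytest.approx(-(L65 + L75), rel=1e-6)

    def test_terminal_slope_is_smallest_eigenvalue(self, gm_spec_full):
        """Far out, log FD_p decays at the smallest system eigenvalue, which
        for slow recycling approximates the storage catabolic rate L(10,6)."""
        B, _, _ = _augmented_system(gm_spec_full)
        lam = -np.max(np.linalg.eigvals(B).real)
        t = np.array([300.0, 320.0])
        fdp = simulate_tracer(gm_spec_full, t).fdp
        slope = (np.log(fdp[1]) - np.log(fdp[0])) / 20.0
        assert slope == pytest.approx(-lam, rel=1e-6)
        assert lam == pytest.approx(gm_spec_full.l(10, 6), rel=0.12)

    def test_validation_errors(self, gm_spec_simplified):
        with pytest.raises(ValueError, match="increasing"):
            simulate_tracer(gm_spec_simplified, [2.0, 1.0])
        with pytest.raises(ModelValidationError, match=r"L\(6,5\)"):
            ModelSpec("simplified", 1, {(5, 4): 5, (5, 6): 0.05, (10, 6): 0.006},
                      dt3=0.3)
        with pytest.raises(ModelValidationError):
            ModelSpec("simplified", 1, {(5, 4): 5, (6, 5): 30, (5, 6): 0.05,
                                        (10, 6): 0.006}, dt3=-0.1)


class TestAllCompartments:
    def test_dose_conservation(self, gm_spec_simplified, gm_spec_full):
        """Compartments + cumulative disposal + unabsorbed loss account for
        the whole dose at every time (residual < 1e-6)."""
        for spec in (gm_spec_simplified, gm_spec_full):
            comps = simulate_tracer_all_compartments(spec, REDUCED11.times)
            assert conservation_residual(comps).max() < 1e-6

    def test_plasma_matches_simulate_tracer(self, gm_spec_full):
        t = REDUCED11.times
        comps = simulate_tracer_all_compartments(gm_spec_full, t)
        assert comps[5] == pytest.approx(simulate_tracer(gm_spec_full, t).fdp,
                                         abs=1e-14)

    def test_open_system_drains(self, gm_spec_simplified):
        comps = simulate_tracer_all_compartments(gm_spec_simplified, [2000.0])
        in_body = sum(comps[k][0] for k in comps if isinstance(k, int))
        assert in_body < 1e-4


class TestSteadyState:
    def test_fast_pool_balance(self):
        """M(7) from flux balance: 31.9 x 1.02 / 1.67 = 19.5 µmol."""
        spec = ModelSpec(
            "simplified", 2,
            {(5, 4): 5, (6, 5): 30.1, (5, 6): 0.0502, (10, 6): 0.00597,
             (7, 5): 31.9, (5, 7): 1.67}, dt3=0.3)
        ss = steady_state(spec, 1.02)
        assert ss.masses[7] == pytest.approx(19.485, rel=1e-3)

    def test_disposal_rate_table_value(self):
        """With M(6) = 538 µmol and L(10,6) = 0.00597/d the disposal rate is
        3.21 µmol/d."""
        l_out = 30.1 * 1.02 / 538.0          # L(5,6) + L(10,6) giving M6=538
        spec = ModelSpec(
            "simplified", 1,
            {(5, 4): 5, (6, 5): 30.1, (5, 6): l_out - 0.00597,
             (10, 6): 0.00597}, dt3=0.3)
        ss = steady_state(spec, 1.02)
        assert ss.masses[6] == pytest.approx(538.0, rel=1e-12)
        assert ss.disposal_rate == pytest.approx(3.21, abs=0.005)

    def test_one_pool_has_empty_fast_pool(self, gm_spec_simplified):
        ss = steady_state(gm_spec_simplified, 1.02)
        assert ss.masses[7] == 0.0
        assert ss.fluxes[(7, 5)] == 0.0 and ss.fluxes[(5, 7)] == 0.0

    def test_balance_and_fixed_point(self, gm_spec_full):
        """Absorbed input equals disposal, and every compartment's in-flux
        equals its out-flux (the steady state is a fixed point)."""
        ss = steady_state(gm_spec_full, 1.02)
        spec = gm_spec_full
        a, U = spec.absorption, ss.dietary_input
        assert a * U == pytest.approx(ss.disposal_rate, rel=1e-9)
        assert ss.disposal_rate == pytest.approx(
            spec.l(10, 6) * ss.masses[6], rel=1e-9)
        m = ss.masses
        # compartment balances (full model): 1, 2, 4, 5, 6, 7
        assert U == pytest.approx(spec.l(2, 1) * m[1], rel=1e-9)
        assert spec.l(2, 1) * m[1] == pytest.approx(spec.l(3, 2) * m[2], rel=1e-9)
        assert a * U == pytest.approx(spec.l(5, 4) * m[4], rel=1e-9)
        in5 = spec.l(5, 4) * m[4] + spec.l(5, 6) * m[6] + spec.l(5, 7) * m[7]
        out5 = (spec.l(6, 5) + spec.l(7, 5)) * m[5]
        assert in5 == pytest.approx(out5, rel=1e-9)
        assert spec.l(6, 5) * m[5] == pytest.approx(
            (spec.l(5, 6) + spec.l(10, 6)) * m[6], rel=1e-9)
        assert spec.l(7, 5) * m[5] == pytest.approx(spec.l(5, 7) * m[7], rel=1e-9)

    def test_singular_system(self):
        spec = ModelSpec("simplified", 1,
                         {(5, 4): 5, (6, 5): 30, (5, 6): 1e-3, (10, 6): 1e-3},
                         dt3=0.3)
        object.__setattr__(spec, "L", {**spec.L, (5, 6): 0.0, (10, 6): 0.0})
        with pytest.raises(SingularSteadyStateError):
            steady_state(spec, 1.0)


class TestMstRbp:
    @pytest.mark.parametrize("variant,expected", [("simplified", 0.5), ("full", 0.54)])
    def test_arithmetic(self, variant, expected):
        L = {(5, 4): 5.0, (6, 5): 30.1, (5, 6): 0.05, (10, 6): 0.006}
        if variant == "full":
            L.update({(2, 1): 50.0, (3, 2): 50.0})
        spec = ModelSpec(variant, 1, L, dt3=0.3)
        assert mst_rbp(spec) == pytest.approx(expected, rel=1e-12)


class TestSerialization:
    def test_modelspec_round_trip(self, gm_spec_full):
        assert ModelSpec.from_text(gm_spec_full.to_text()) == gm_spec_full

    def test_tracer_curve_round_trip(self, tmp_path, gm_spec_full):
        curve = simulate_tracer(gm_spec_full, REDUCED11.times)
        path = tmp_path / "curve.tsv"
        curve.write_tsv(path)
        back = TracerCurve.read_tsv(path)
        assert np.allclose(back.times, curve.times)
        assert np.allclose(back.fdp, curve.fdp)

    def test_tracer_curve_invariants(self):
        with pytest.raises(ValueError):
            TracerCurve(np.array([1.0, 1.0]), np.array([0.1, 0.1]))
        with pytest.raises(ValueError):
            TracerCurve(np.array([1.0, 2.0]), np.array([0.1, 1.5]))
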