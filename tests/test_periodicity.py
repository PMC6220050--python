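"""Coincidence equation, BMF tuning, and the response-matrix experiment."""

import numpy as np
import pytest

from chopnet.periodicity import (
    PeriodicityUnit,
    bmf_of_unit,
    response_matrix,
    solve_coincidence,
    unit_response,
)
from chopnet.stimulus import AMSpec


def brute_force_solutions(tau_c, tau_k, max_int, tol, tau_m=None):
    """Independent enumeration oracle (set-of-triples semantics)."""
    out = set()
    for m in range(1, max_int + 1):
        for n in range(1, max_int + 1):
            for k in range(0, max_int + 1):
                rhs = n * tau_c - k * tau_k
                if rhs <= 0:
                    continue
                cand = rhs / m if tau_m is None else tau_m
                res = 0.0 if tau_m is None else abs(m * tau_m - rhs)
                if cand > tau_c and res <= tol:
                    out.add((m, n, k))
    return out


class TestSolver:
    def test_k_zero_solutions_are_integer_carrier_multiples(self):
        sols = solve_coincidence(0.25, 0.4, max_int=6)
        for s in sols:
            if s.k == 0 and s.m == 1:
                assert s.tau_m == pytest.approx(s.n * 0.25)
        assert {s.n for s in sols if s.k == 0 and s.m == 1} == {2, 3, 4, 5, 6}

    def test_documented_example(self):
        """tau_c 0.25, tau_k 0.4: (m=1, n=8, k=2) gives tau_m = 1.2 ms."""
        sols = solve_coincidence(0.25, 0.4, max_int=8)
        match = [s for s in sols if (s.m, s.n, s.k) == (1, 8, 2)]
        assert match and match[0].tau_m == pytest.approx(1.2)

    def test_harmonic_m2_halves_tau_m(self):
        sols = solve_coincidence(0.3, 0.45, max_int=8)
        by_mnk = {(s.m, s.n, s.k): s.tau_m for s in sols}
        for (m, n, k), tm in by_mnk.items():
            if m == 1 and (2, n, k) in by_mnk:
                assert by_mnk[(2, n, k)] == pytest.approx(tm / 2)

    def test_matches_brute_force_on_random_instances(self):
        """100 random (tau_c, tau_k): identical solution sets, and every
        emitted solution satisfies the equation by substitution."""
        rng = np.random.default_rng(0)
        for _ in range(100):
            tau_c = rng.uniform(0.1, 1.0)
            tau_k = rng.uniform(0.1, 1.0)
            tau_m = rng.uniform(tau_c, 8 * tau_c) if rng.random() < 0.5 else None
            sols = solve_coincidence(tau_c, tau_k, max_int=6, tol=0.05, tau_m=tau_m)
            got = {(s.m, s.n, s.k) for s in sols}
            assert got == brute_force_solutions(tau_c, tau_k, 6, 0.05, tau_m)
            for s in sols:
                assert abs(s.m * s.tau_m - (s.n * tau_c - s.k * tau_k)) <= 0.05 + 1e-12

    def test_sorted_by_m_then_residual(self):
        sols = solve_coincidence(0.25, 0.4, max_int=5)
        ms = [s.m for s in sols]
        assert ms == sorted(ms)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            solve_coincidence(0.0, 0.4)
        with pytest.raises(ValueError):
            solve_coincidence(0.25, 0.4, max_int=0)


class TestBMF:
    def test_documented_unit(self):
        u = PeriodicityUnit(cf=4000.0, tau_k=0.4, integrator_n=8, oscillator_k=2)
        assert bmf_of_unit(u) == pytest.approx(1e3 / 1.2)  # ~833 Hz

    def test_tuned_constructor_hits_ratio(self):
        for cf in (1000.0, 2890.0, 8000.0):
            u = PeriodicityUnit.tuned(cf, cf_bmf_ratio=6.0)
            assert bmf_of_unit(u) == pytest.approx(cf / 6.0, rel=1e-9)

    def test_k_zero_limit(self):
        u = PeriodicityUnit(cf=1000.0, tau_k=0.4, integrator_n=6, oscillator_k=0)
        assert bmf_of_unit(u) == pytest.approx(1000.0 / 6.0)

    def test_untuned_unit_flagged(self):
        # n tau_c - k tau_k <= tau_c: no modulation slower than the carrier
        u = PeriodicityUnit(cf=1000.0, tau_k=3.0, integrator_n=2, oscillator_k=2)
        assert bmf_of_unit(u) is None


@pytest.fixture(scope="module")
def unit():
    return PeriodicityUnit.tuned(4000.0, 6.0, inhibition=True)


@pytest.fixture(scope="module")
def matrices():
    return (
        response_matrix(inhibition=False, seed=3),
        response_matrix(inhibition=True, seed=3),
    )


class TestUnitResponse:

    def test_response_peaks_at_bmf(self, unit):
        bmf = bmf_of_unit(unit)
        tau_c = unit.tau_c
        best = None
        counts = {}
        for fm in np.array([0.5, 0.75, 1.0, 1.5, 2.0, 3.0]) * bmf:
            stim = AMSpec(tau_c=tau_c, tau_m=1e3 / fm, depth=1.0, duration=100.0)
            counts[fm] = unit_response(stim, unit, duration=100.0)
        assert max(counts, key=counts.get) == pytest.approx(bmf)

    def test_inhibition_suppresses_harmonic(self):
        """At twice the BMF the response drops strictly when the inhibitor
        vetoes non-fundamental coincidences."""
        u_no = PeriodicityUnit.tuned(4000.0, 6.0, inhibition=False)
        u_in = PeriodicityUnit.tuned(4000.0, 6.0, inhibition=True)
        bmf = bmf_of_unit(u_no)
        stim = AMSpec(tau_c=u_no.tau_c, tau_m=1e3 / (2 * bmf), depth=1.0, duration=100.0)
        r_no = unit_response(stim, u_no, duration=100.0)
        r_in = unit_response(stim, u_in, duration=100.0)
        assert r_no > 0
        assert r_in < r_no

    def test_zero_depth_no_triggers_no_response(self, unit):
        stim = AMSpec(tau_c=unit.tau_c, tau_m=1.5, depth=0.0, duration=50.0)
        assert unit_response(stim, unit, duration=50.0) == 0

    def test_short_duration_rejected(self, unit):
        stim = AMSpec(tau_c=unit.tau_c, tau_m=10.0, depth=1.0, duration=50.0)
        with pytest.raises(ValueError):
            unit_response(stim, unit, duration=5.0)


class TestResponseMatrix:
    def test_shape_256_cells(self, matrices):
        R0, _ = matrices
        assert R0.response.shape == (16, 16)
        assert R0.carrier_freqs.size == R0.mod_freqs.size == 16

    def test_with_inhibition_rows_peak_at_cf_over_six(self, matrices):
        _, R1 = matrices
        for i, cf in enumerate(R1.carrier_freqs):
            target = np.argmin(np.abs(R1.mod_freqs - cf / 6.0))
            assert np.argmax(R1.response[i]) == target

    def test_inhibition_never_increases_any_cell(self, matrices):
        R0, R1 = matrices
        assert np.all(R1.response <= R0.response)

    def test_harmonic_sidebands_without_inhibition(self, matrices):
        R0, _ = matrices
        strong_secondary = 0
        for i in range(16):
            row = R0.response[i]
            peak = row[i]
            if peak == 0:
                continue
            off = row.copy()
            off[max(0, i - 1): i + 2] = 0
            if off.max() > 0.25 * peak:
                strong_secondary += 1
        assert strong_secondary >= 1

    def test_jittered_triggers_keep_tuning(self):
        R = response_matrix(inhibition=True, seed=5, trigger_jitter_sd=0.002)
        assert np.array_equal(np.argmax(R.response, axis=1), np.arange(16))
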