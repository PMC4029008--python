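"""Statevector Grover search, Bell/superdense operations, monomer register."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from calwave import grover


def _uniform(n):
    return grover.hadamard_all(grover.QuantumState.zero(n))


class TestHadamard:
    def test_zero_state_to_uniform(self):
        s = _uniform(2)
        assert np.allclose(s.amplitudes, 0.5)

    def test_involution(self):
        s = grover.QuantumState.basis(3, 5)
        back = grover.hadamard_all(grover.hadamard_all(s))
        assert np.allclose(back.amplitudes, s.amplitudes, atol=1e-12)

    def test_single_qubit_one(self):
        s = grover.hadamard_all(grover.QuantumState.basis(1, 1))
        assert np.allclose(s.amplitudes, [1 / math.sqrt(2), -1 / math.sqrt(2)])

    @given(st.integers(1, 6), st.integers(0, 63))
    @settings(max_examples=40, derandomize=True)
    def test_norm_preserved(self, n, idx):
        s = grover.QuantumState.basis(n, idx % 2**n)
        out = grover.hadamard_all(s)
        assert abs(out.norm() - 1.0) < 1e-12


class TestOracle:
    def test_phase_flip_on_solutions_only(self):
        s = _uniform(2)
        out = grover.apply_oracle(s, grover.OracleSpec(2, frozenset({2})))
        assert np.allclose(out.amplitudes, [0.5, 0.5, -0.5, 0.5])

    def test_involution(self):
        s = _uniform(3)
        o = grover.OracleSpec(3, frozenset({1, 6}))
        back = grover.apply_oracle(grover.apply_oracle(s, o), o)
        assert np.allclose(back.amplitudes, s.amplitudes)

    def test_empty_solution_set_is_identity(self):
        s = _uniform(2)
        out = grover.apply_oracle(s, grover.OracleSpec(2, frozenset()))
        assert np.allclose(out.amplitudes, s.amplitudes)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            grover.apply_oracle(_uniform(2), grover.OracleSpec(3, frozenset({1})))

    @pytest.mark.parametrize("n", [1, 2, 3, 4])
    def test_equivalent_to_ancilla_construction(self, n):
        rng = np.random.default_rng(7)
        amps = rng.normal(size=2**n) + 1j * rng.normal(size=2**n)
        amps /= np.linalg.norm(amps)
        s = grover.QuantumState(n, amps)
        o = grover.OracleSpec(n, frozenset({0, 2**n - 1}))
        direct = grover.apply_oracle(s, o)
        ancilla = grover.apply_oracle_with_ancilla(s, o)
        assert np.allclose(direct.amplitudes, ancilla.amplitudes, atol=1e-12)


class TestDiffusion:
    def test_uniform_is_fixed_point(self):
        s = _uniform(3)
        out = grover.grover_diffusion(s)
        assert np.allclose(out.amplitudes, s.amplitudes)

    @pytest.mark.parametrize("n", [1, 2, 3, 4, 5, 6])
    def test_matches_dense_matrix_and_is_unitary(self, n):
        N = 2**n
        psi = np.full(N, 1.0 / math.sqrt(N))
        G = 2.0 * np.outer(psi, psi) - np.eye(N)
        assert np.allclose(G @ G.conj().T, np.eye(N), atol=1e-12)
        rng = np.random.default_rng(n)
        amps = rng.normal(size=N) + 1j * rng.normal(size=N)
        amps /= np.linalg.norm(amps)
        s = grover.QuantumState(n, amps)
        out = grover.grover_diffusion(s)
        assert np.allclose(out.amplitudes, G @ amps, atol=1e-12)
        assert abs(out.norm() - 1.0) < 1e-12


class TestGroverSearch:
    def test_four_items_single_target_is_exact(self):
        o = grover.OracleSpec(2, frozenset({3}))
        r = grover.grover_search(2, o, seed=0)
        assert r.iterations == 1
        assert r.success_probability == pytest.approx(1.0, abs=1e-12)
        assert r.measured == 3

    def test_eight_items_single_target(self):
        o = grover.OracleSpec(3, frozenset({5}))
        r = grover.grover_search(3, o, seed=0)
        assert r.iterations == 2
        assert r.success_probability == pytest.approx(0.9453, abs=1e-4)

    def test_all_items_solutions_needs_no_iterations(self):
        o = grover.OracleSpec(2, frozenset({0, 1, 2, 3}))
        r = grover.grover_search(2, o, seed=0)
        assert r.iterations == 0
        assert r.success_probability == pytest.approx(1.0)

    def test_no_solution_rejected(self):
        with pytest.raises(ValueError, match="no solutions"):
            grover.grover_search(2, grover.OracleSpec(2, frozenset()), seed=0)

    def test_closed_form_exhaustive_small_registers(self):
        # success probability equals sin^2((2k+1) asin sqrt(M/N)) for every
        # (n <= 5, 1 <= M <= N)
        for n in range(1, 6):
            N = 2**n
            for M in range(1, N + 1):
                o = grover.OracleSpec(n, frozenset(range(M)))
                r = grover.grover_search(n, o, seed=0)
                theta = math.asin(math.sqrt(M / N))
                expected = math.sin((2 * r.iterations + 1) * theta) ** 2
                assert abs(r.success_probability - expected) < 1e-10

    def test_measurement_reproducible_with_seed(self):
        o = grover.OracleSpec(4, frozenset({3, 9}))
        a = grover.grover_search(4, o, seed=123)
        b = grover.grover_search(4, o, seed=123)
        assert a.measured == b.measured
        assert np.array_equal(a.state.amplitudes, b.state.amplitudes)


class TestQueryCounts:
    def test_four_items_classical_expectation(self):
        classical, k = grover.query_count_comparison(2, 1)
        assert classical == pytest.approx(2.5)
        assert k == 1

    def test_enumeration_matches_closed_form(self):
        # E[T] = (N+1)/(M+1) under uniform random placement
        for n in range(1, 8):
            N = 2**n
            for M in (1, 2, N // 2, N):
                got = grover.classical_expected_queries(n, M)
                assert got == pytest.approx((N + 1) / (M + 1), rel=1e-12)

    def test_bound_formula(self):
        assert grover.query_bound(10, 1) == 26  # ceil((pi/4) sqrt(1024))

    def test_speedup_ratio_scales_as_sqrt_N(self):
        Ns, ratios = [], []
        for n in range(2, 11):
            classical = grover.classical_expected_queries(n, 1)
            Ns.append(2**n)
            ratios.append(classical / grover.query_bound(n, 1))
        slope = np.polyfit(np.log(Ns), np.log(ratios), 1)[0]
        assert slope == pytest.approx(0.5, abs=0.05)


class TestBellAndSuperdense:
    def test_bell_00_amplitudes(self):
        s = grover.bell_state("00")
        assert np.allclose(
            s.amplitudes, [1 / math.sqrt(2), 0, 0, 1 / math.sqrt(2)]
        )

    def test_bell_states_mutually_orthogonal(self):
        labels = ["00", "01", "10", "11"]
        for a, b in itertools.combinations(labels, 2):
            inner = np.vdot(
                grover.bell_state(a).amplitudes, grover.bell_state(b).amplitudes
            )
            assert abs(inner) < 1e-12

    @pytest.mark.parametrize("bits", ["00", "01", "10", "11"])
    def test_superdense_roundtrip(self, bits):
        decoded = grover.superdense_decode(grover.superdense_encode(bits))
        assert decoded.bits == bits
        assert decoded.deterministic
        assert decoded.probability == pytest.approx(1.0, abs=1e-12)

    def test_non_bell_input_flagged_nondeterministic(self):
        s = grover.QuantumState.basis(2, 0)  # |00> overlaps two Bell states
        decoded = grover.superdense_decode(s)
        assert not decoded.deterministic
        assert decoded.probability == pytest.approx(0.5)


class TestMonomerRegister:
    def test_open_configuration(self):
        assert grover.theta_conformation(grover.MonomerRegister("110")) == 1

    def test_all_other_configurations_closed(self):
        for bits in map("".join, itertools.product("01", repeat=3)):
            expected = 1 if bits == "110" else 0
            assert grover.theta_conformation(grover.MonomerRegister(bits)) == expected

    def test_primed_configuration_count(self):
        # Mn!/(Mn-1)! = Mn superposed combinations; 4 for the tetramer
        assert grover.count_primed_configurations(4) == 4
        assert grover.count_primed_configurations(7) == 7
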