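"""Dense statevector implementation of Grover's search, Bell states,
superdense coding, and the IP3R monomer conformational register.

Everything here is an exact linear-algebra simulation over 2^n complex
amplitudes (n up to ~20); there is no gate decomposition or hardware
backend. The oracle is applied as a direct conditional phase flip,
amplitude(x) -> (-1)^theta(x) * amplitude(x); the textbook ancilla-based
construction (an extra qubit prepared in (|0> - |1>)/sqrt(2) and flipped
conditionally on theta) is provided as well, and the two are unitarily
equivalent -- see :func:`apply_oracle_with_ancilla`.

The 3-bit monomer register encodes the conformational state of one IP3R
monomer as (IP3 site, high-affinity Ca2+ site, low-affinity Ca2+ site),
1 = bound; |110> is the open, conducting configuration (theta = 1) and
|100> the activation-primed closed one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np

__all__ = [
    "QuantumState",
    "OracleSpec",
    "MonomerRegister",
    "GroverResult",
    "hadamard_all",
    "apply_oracle",
    "apply_oracle_with_ancilla",
    "grover_diffusion",
    "optimal_iterations",
    "grover_search",
    "classical_expected_queries",
    "query_count_comparison",
    "query_bound",
    "bell_state",
    "superdense_encode",
    "superdense_decode",
    "theta_conformation",
    "count_primed_configurations",
]

@dataclass(frozen=True)
class QuantumState:
    """Pure state of n qubits as a dense complex amplitude vector.

    The basis index is read as a bit string with qubit 0 the most
    significant bit. Construction guards unit norm (1e-9 on the squared
    norm); the gate operations themselves preserve it to 1e-12.
    """

    n_qubits: int
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        if self.n_qubits < 1:
            raise ValueError("n_qubits must be >= 1")
        amps = np.asarray(self.amplitudes, dtype=complex)
        if amps.shape != (2**self.n_qubits,):
            raise ValueError(
                f"amplitude vector must have length 2^{self.n_qubits}"
            )
        norm2 = float(np.sum(np.abs(amps) ** 2))
        if abs(norm2 - 1.0) > 1e-9:
            raise ValueError(f"state norm^2 = {norm2} is not 1")
        object.__setattr__(self, "amplitudes", amps)

    @classmethod
    def zero(cls, n_qubits: int) -> "QuantumState":
        """|0...0>."""
        amps = np.zeros(2**n_qubits, dtype=complex)
        amps[0] = 1.0
        return cls(n_qubits, amps)

    @classmethod
    def basis(cls, n_qubits: int, index: int) -> "QuantumState":
        amps = np.zeros(2**n_qubits, dtype=complex)
        amps[index] = 1.0
        return cls(n_qubits, amps)

    @classmethod
    def uniform(cls, n_qubits: int) -> "QuantumState":
        n = 2**n_qubits
        return cls(n_qubits, np.full(n, 1.0 / math.sqrt(n), dtype=complex))

    def probabilities(self) -> np.ndarray:
        return np.abs(self.amplitudes) ** 2

    def norm(self) -> float:
        return float(np.linalg.norm(self.amplitudes))


@dataclass(frozen=True)
class OracleSpec:
    """Marked (solution) subset of the search register.

    theta(x) = 1 iff x is in ``solution_set``; M = |solution_set|. An empty
    set is representable (the identity oracle) but :func:`grover_search`
    rejects it since there is nothing to find.
    """

    n_qubits: int
    solution_set: frozenset[int]

    def __post_init__(self) -> None:
        sols = frozenset(int(s) for s in self.solution_set)
        n = 2**self.n_qubits
        if any(not (0 <= s < n) for s in sols):
            raise ValueError(f"solution indices must lie in [0, {n})")
        object.__setattr__(self, "solution_set", sols)

    @property
    def M(self) -> int:
        return len(self.solution_set)

    def theta(self, x: int) -> int:
        return 1 if x in self.solution_set else 0


def hadamard_all(state: QuantumState) -> QuantumState:
    """Apply H^(tensor n) via the fast Walsh-Hadamard butterfly.

    On |0...0> this yields the uniform superposition with amplitudes
    1/sqrt(N); applied twice it is the identity.
    """
    a = state.amplitudes.copy()
    n = state.n_qubits
    h = 1
    while h < a.size:
        a = a.reshape(-1, 2 * h)
        top = a[:, :h].copy()
        bot = a[:, h:].copy()
        a[:, :h] = top + bot
        a[:, h:] = top - bot
        a = a.reshape(-1)
        h *= 2
    a /= 2 ** (n / 2)
    return QuantumState(n, a)


def apply_oracle(state: QuantumState, oracle: OracleSpec) -> QuantumState:
    """Conditional phase flip: amplitude(x) -> (-1)^theta(x) amplitude(x)."""
    if oracle.n_qubits != state.n_qubits:
        raise ValueError(
            f"oracle on {oracle.n_qubits} qubits does not match state on "
            f"{state.n_qubits}"
        )
    a = state.amplitudes.copy()
    idx = sorted(oracle.solution_set)
    a[idx] *= -1.0
    return QuantumState(state.n_qubits, a)


def apply_oracle_with_ancilla(state: QuantumState, oracle: OracleSpec) -> QuantumState:
    """Ancilla-based oracle: |x>(|0>-|1>)/sqrt(2) -> (-1)^theta(x)|x>(|0>-|1>)/sqrt(2).

    Adjoins an ancilla qubit prepared in (|0> - |1>)/sqrt(2), applies the
    classical-reversible X on the ancilla controlled on theta(x) (phase
    kickback), then strips the unchanged ancilla. Used to demonstrate the
    equivalence with :func:`apply_oracle`.
    """
    if oracle.n_qubits != state.n_qubits:
        raise ValueError("oracle dimension mismatch")
    minus = np.array([1.0, -1.0], dtype=complex) / math.sqrt(2)
    full = np.kron(state.amplitudes, minus)  # index = 2*x + ancilla_bit
    for x in oracle.solution_set:
        full[2 * x], full[2 * x + 1] = full[2 * x + 1], full[2 * x]
    # factor the ancilla back out: register amplitude = <0|anc part> * sqrt(2)
    reg = full[0::2] * math.sqrt(2)
    return QuantumState(state.n_qubits, reg)


def grover_diffusion(state: QuantumState) -> QuantumState:
    """Inversion about the mean: H^n (2|0><0| - I) H^n = 2|psi><psi| - I."""
    a = state.amplitudes
    mean = a.mean()
    return QuantumState(state.n_qubits, 2.0 * mean - a)


def optimal_iterations(n_qubits: int, M: int) -> int:
    """Optimal Grover iteration count k = round(pi/(4 asin(sqrt(M/N))) - 1/2).

    Rounding is half-up and k is clamped to >= 0 (k = 0 when M = N).
    """
    N = 2**n_qubits
    if not 1 <= M <= N:
        raise ValueError("require 1 <= M <= N")
    theta = math.asin(math.sqrt(M / N))
    k = math.floor(math.pi / (4.0 * theta) - 0.5 + 0.5)  # round half-up
    return max(k, 0)


@dataclass(frozen=True)
class GroverResult:
    measured: int
    success_probability: float
    iterations: int
    state: QuantumState


def grover_search(
    n_qubits: int,
    oracle: OracleSpec,
    iterations: int | Literal["auto"] = "auto",
    seed: int | None = None,
) -> GroverResult:
    """Run Grover's algorithm and sample one measurement.

    Initializes the uniform superposition, applies (oracle; diffusion) k
    times, reports the total probability on the solution set (which equals
    sin^2((2k+1) asin(sqrt(M/N))) exactly), and samples a basis index with
    the given seed (reproducible bit-exact).
    """
    if oracle.M == 0:
        raise ValueError("oracle has no solutions: nothing to search for")
    if oracle.n_qubits != n_qubits:
        raise ValueError("oracle dimension mismatch")
    k = optimal_iterations(n_qubits, oracle.M) if iterations == "auto" else int(iterations)
    if k < 0:
        raise ValueError("iterations must be >= 0")
    state = hadamard_all(QuantumState.zero(n_qubits))
    for _ in range(k):
        state = grover_diffusion(apply_oracle(state, oracle))
    probs = state.probabilities()
    success = float(sum(probs[i] for i in oracle.solution_set))
    rng = np.random.default_rng(seed)
    p = probs / probs.sum()
    measured = int(rng.choice(2**n_qubits, p=p))
    return GroverResult(measured, success, k, state)


def classical_expected_queries(n_qubits: int, M: int) -> float:
    """Expected sequential queries to first hit, uniform random placement.

    Exact enumeration over the position of the first solution under a
    uniform random permutation of N items containing M solutions:
    E[T] = sum_{k>=0} P(T > k) with P(T > k) = prod_{j<k} (N-M-j)/(N-j).
    (Closed form: (N+1)/(M+1).)
    """
    N = 2**n_qubits
    if not 1 <= M <= N:
        raise ValueError("require 1 <= M <= N")
    expected = 0.0
    surv = 1.0
    for k in range(N - M + 1):
        expected += surv
        surv *= (N - M - k) / (N - k)
    return expected


def query_count_comparison(n_qubits: int, M: int) -> tuple[float, int]:
    """(classical expected queries, Grover iteration count) for one register."""
    return classical_expected_queries(n_qubits, M), optimal_iterations(n_qubits, M)


def query_bound(n_qubits: int, M: int) -> int:
    """O(sqrt(N/M)) query-complexity bound ceil((pi/4) sqrt(N/M)).

    Upper-bounds :func:`optimal_iterations` by at most one iteration; the
    quadratic speed-up scaling law is stated against this bound (the
    rounded optimal count obeys the same asymptotics but its log-log fit
    over small N is biased by integer rounding at N = 4).
    """
    N = 2**n_qubits
    if not 1 <= M <= N:
        raise ValueError("require 1 <= M <= N")
    return math.ceil(math.pi / 4.0 * math.sqrt(N / M))


_BELL = {
    "00": np.array([1, 0, 0, 1], dtype=complex) / math.sqrt(2),   # (|00>+|11>)/sqrt2
    "01": np.array([0, 1, 1, 0], dtype=complex) / math.sqrt(2),   # (|01>+|10>)/sqrt2
    "10": np.array([1, 0, 0, -1], dtype=complex) / math.sqrt(2),  # (|00>-|11>)/sqrt2
    "11": np.array([0, 1, -1, 0], dtype=complex) / math.sqrt(2),  # (|01>-|10>)/sqrt2
}


def _normalize_bits(bits: str | tuple[int, int] | Iterable[int]) -> str:
    if isinstance(bits, str):
        s = bits
    else:
        s = "".join(str(int(b)) for b in bits)
    if s not in ("00", "01", "10", "11"):
        raise ValueError(f"bits must be a 2-bit string, got {bits!r}")
    return s


def bell_state(bits: str | tuple[int, int]) -> QuantumState:
    """The four orthonormal Bell (EPR) states |psi>_b1b2."""
    return QuantumState(2, _BELL[_normalize_bits(bits)].copy())


def _apply_first_qubit(amps: np.ndarray, gate: np.ndarray) -> np.ndarray:
    # first qubit = most significant bit of the 2-qubit index
    a = amps.reshape(2, 2)
    return (gate @ a).reshape(-1)


_X = np.array([[0, 1], [1, 0]], dtype=complex)
_Z = np.array([[1, 0], [0, -1]], dtype=complex)


def superdense_encode(bits: str | tuple[int, int]) -> QuantumState:
    """Encode two classical bits on the first qubit of a shared |psi>_00 pair.

    I / X / Z / ZX on the first qubit map |psi>_00 to the four Bell states
    (up to a global phase for '11').
    """
    s = _normalize_bits(bits)
    amps = _BELL["00"].copy()
    if s[1] == "1":
        amps = _apply_first_qubit(amps, _X)
    if s[0] == "1":
        amps = _apply_first_qubit(amps, _Z)
    return QuantumState(2, amps)


@dataclass(frozen=True)
class DecodeResult:
    bits: str
    probability: float
    deterministic: bool


def superdense_decode(state: QuantumState) -> DecodeResult:
    """Reverse Bell measurement: project onto the four Bell states.

    For a proper superdense-coded state one overlap is 1 and the result is
    deterministic; for any other 2-qubit input the argmax basis outcome is
    returned with its probability and flagged non-deterministic.
    """
    if state.n_qubits != 2:
        raise ValueError("superdense decoding requires a 2-qubit state")
    probs = {
        b: float(abs(np.vdot(v, state.amplitudes)) ** 2) for b, v in _BELL.items()
    }
    best = max(probs, key=lambda b: probs[b])
    p = probs[best]
    return DecodeResult(best, p, deterministic=abs(p - 1.0) < 1e-9)


@dataclass(frozen=True)
class MonomerRegister:
    """3-bit conformational register of one IP3R monomer.

    Bit order: (IP3 site, high-affinity Ca2+ site, low-affinity Ca2+ site);
    1 = ligand bound. '100' is activation-primed (closed), '110' open.
    """

    bits: str

    def __post_init__(self) -> None:
        if len(self.bits) != 3 or any(b not in "01" for b in self.bits):
            raise ValueError(f"bits must be a 3-bit string, got {self.bits!r}")


def theta_conformation(
    reg: MonomerRegister, open_configuration: str = "110"
) -> int:
    """theta = 1 iff the register matches the open (conducting) pattern."""
    return 1 if reg.bits == open_configuration else 0


def count_primed_configurations(Mn: int) -> int:
    """Superposed activation-primed combinations Mn!/(Mn-1)! (= Mn)."""
    if Mn < 1:
        raise ValueError("Mn must be >= 1")
    return math.factorial(Mn) // math.factorial(Mn - 1)
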