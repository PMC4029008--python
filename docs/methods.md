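# Methods

## The model

`calwave` simulates calcium-induced calcium release (CICR) along a 1-D chain
of intracellular release sites (IP₃ receptor channels or channel clusters on
the ER membrane) with the fire-diffuse-fire model. The cytosolic Ca²⁺
concentration c(x, t), averaged over directions perpendicular to
propagation, obeys

    ∂c/∂t = D ∂²c/∂x² + Σᵢ (σ/d²τ) δ(x − xᵢ) H(t − tᵢ) H(tᵢ + τ − t)

where D is the Ca²⁺ diffusion coefficient (μm²/s), d the inter-site spacing
(μm), σ the quantity released per site event (carried in code as the
released concentration σ/d³ in μM), τ the channel open duration (s), and tᵢ
the first time site i reaches the firing threshold [Ca²⁺]_T above basal
[Ca²⁺]_b. Sites fire exactly once (deterministic refractoriness) and the
model carries no re-uptake or extrusion terms; buffering is treated as
instantaneous and absorbed into σ.

Two dimensionless groups control the dynamics:

- Γ = (σ/d³)/([Ca²⁺]_T − [Ca²⁺]_b) — ignition strength; how many
  thresholds' worth of Ca²⁺ one event liberates.
- β — propagation mode. β ≫ 1 gives a continuous, release-limited front
  with the Luther velocity v ≈ Γ^½·(D/τ)^½; β ≪ 1 gives a saltatory front
  hopping site to site at v ≈ (D/d)·g⁻¹Γ.

**β convention.** The compact definition β = (D/τ)/d² is inconsistent with
every worked numerical example this package reproduces (D = 190 μm²/s,
τ = 0.04 s, d = 2 μm is quoted as β = 1.9 = D·τ/d², not (D/τ)/d² = 1187.5).
`compute_beta` therefore defaults to the `worked_example` form D·τ/d² and
keeps the literal `as_printed` form behind a flag; nothing reconciles the
two silently. A related residual: the Γ-recovery identities are
convention-split — Γ_S = τ·v·g/(β·d) returns Γ exactly under
`worked_example`, while Γ_C = v·f/(β^½·d) returns Γ^½ exactly under
`as_printed` (and Γ^½/τ under `worked_example`). Both identities are
asserted in the test suite as stated here.

The unspecified inverse functions g⁻¹ and f⁻¹ multiplying the velocity laws
are collapsed into a single configurable `geometry_factor` defaulting to 1,
which is exactly the usage in the worked examples (v ≈ D/d ≈ 7.5 μm/s,
v ≈ (D/τ)^½ ≈ 69 μm/s).

## Numerics of the simulator

- Explicit FTCS integration in flux form. Reflecting (zero-flux) boundaries
  make the scheme exactly conservative: the final integrated concentration
  equals the initial mass plus σ/d² per completed release event to machine
  precision (asserted at 10⁻⁶ relative; measured ~10⁻¹⁵). Absorbing
  boundaries are available.
- Defaults dx = d/20 and dt = 0.4·dx²/(2D), safely inside the stability
  limit dt ≤ dx²/(2D); an unstable dt is rejected with a diagnostic rather
  than integrated.
- The δ source is deposited at the grid node nearest the site as the flux
  (σ/d²τ)/dx. The deposit uses the fractional overlap of each time step
  with the open window [tᵢ, tᵢ + τ], so a completed event injects exactly
  σ/d² regardless of whether τ is a multiple of dt.
- Threshold detection reads the node nearest each site after every step;
  sites crossing within the same step receive identical firing times, with
  ordering ties broken by lower site index.
- Front velocity is the least-squares slope of site distance versus firing
  time over the trailing half of fired sites (the initiation transient is
  discarded); fewer than three firings yields an explicit failure flag, not
  a number.
- Halving dx (with dt retied to dx²) moves the continuous-regime velocity
  by ~10⁻⁴ relative, far inside the 5 % convergence requirement.

## Regime classification

`classify_regime` labels a (Γ, β, D, d) point: failure if the point would
be saltatory with D < 10 μm²/s, if d > 3 μm, or if Γ falls outside a
configured band (default 0.1–1000; "extremely small or large Γ" is
qualitative, so the band is a config value); otherwise continuous for
β ≥ 1, saltatory for β ≤ 0.5, mixed between. The β thresholds are likewise
configuration, since only β ≫ 1 is stated qualitatively. The reported
model velocity uses the leading-order laws, with τ recovered from β via
the worked-example convention for the continuous branch.

## Study conditions for the simulation properties

No simulation table accompanies the velocity laws, so the scaling claims
are verified as properties under fixed synthetic conditions chosen once:
basal 0.1 μM, threshold 0.6 μM, σ/d³ = 5 μM (Γ = 10 — strong, reliable
ignition), d = 2 μm, 24 sites (12 for the refinement pair), triggered at
the left end.

- Continuous scan: D ∈ {100, 190, 400, 1000} μm²/s at τ = 0.04 s
  (β = 1–10). Measured log–log slope of velocity vs D ≈ 0.55 (law: 0.5).
- Saltatory scan: D ∈ {12, 24, 60, 120} μm²/s at τ = 0.001 s
  (β = 0.003–0.03). τ sits at the millisecond scale so that release is
  effectively instantaneous relative to the inter-site diffusion time
  d²/D ≥ 33 ms; this is the premise under which the linear law v ∝ D/d
  holds at all. (At τ = 5 ms the firing delay at D = 120 μm²/s is already
  comparable to τ and the scan visibly bends below linear.) Measured
  slope ≈ 0.96 (law: 1.0).
- Luther-asymptote band: over Γ ∈ [5, 40] at D = 190 μm²/s the simulated
  front runs at 0.80–0.92 of Γ^½(D/τ)^½, consistent with the asymptote
  being a large-Γ leading-order form; tests assert the ratio in
  [0.75, 1.00].

What these synthetic conditions do not emulate: stochastic channel
gating, mobile buffers, ER re-uptake, 2-D/3-D geometry, or irregular site
placement (supported by the API but not exercised by the scaling tests).
Passing tests show the integrator reproduces the fire-diffuse-fire limit
laws, not that real cytosol follows them.

## IP₃R gating

`open_probability` implements the steady-state open probability

    p_O = [ ca·ip3·K_CaI / ((ca·ip3 + ip3·K_CaI + K_IP3_1·K_CaI
             + ca·K_IP3_2)(ca + K_CaA)) ]³

the cube reflecting that three of four monomers must be activated. For
positive constants the denominator strictly dominates the numerator, so
p_O ∈ [0, 1) for all nonnegative inputs, p_O = 0 without either ligand,
and the response in Ca²⁺ at fixed IP₃ is bell-shaped with a single
interior maximum (≈ 0.28 μM at saturating IP₃ under the default
constants) — verified by brute-force grid scan.

The flux-based Γ = (Φ₁ − Φ₂ − Φ₃)/([Ca²⁺]_T − [Ca²⁺]_b) extends the
release-only Γ with re-uptake (Hill, n = 2) and buffering (mass-action)
sinks. The windowed denominator notation in the source formulation is
identified with the threshold difference [Ca²⁺]_T − [Ca²⁺]_b — an
assumption, recorded here. Negative Γ (sinks dominate) is returned as a
value, not an error; it means no wave can ignite and classifies as
failure downstream. Default constants are repo defaults with
DeYoung–Keizer-style magnitudes (K_CaA = 0.082 μM, K_CaI = 1.05 μM,
K_IP3_1 = 0.13 μM, K_IP3_2 = 0.94 μM, and flux scales of order
0.1–6 μM/s with ca_ER = 250 μM); they are documented placeholders, not
fitted values — supply measured constants for scientific use. Note the
Φ₁ expression inherits a unit mismatch from its source (a μM/s flux scale
multiplied by a concentration difference); it is implemented as written.

## Quantum search

Dense statevector simulation (complex128, n ≲ 20 qubits), no gate
decomposition. The Hadamard layer is the fast Walsh–Hadamard butterfly;
the oracle is a direct conditional phase flip (−1)^θ(x); the diffusion
operator is inversion about the mean, verified against the dense matrix
2|ψ⟩⟨ψ| − I for n ≤ 6. The ancilla-based oracle — an extra qubit in
(|0⟩ − |1⟩)/√2 flipped conditionally on θ (phase kickback) — is
implemented too and unit-tested equal to the phase-flip form for n ≤ 4.

Iteration count: k = round(π/(4·arcsin√(M/N)) − ½), rounded half-up,
clamped ≥ 0 (k = 0 when M = N; k = 1 with success probability exactly 1
at N = 4, M = 1). The success probability after k iterations equals
sin²((2k+1)·arcsin√(M/N)) to better than 10⁻¹⁰ for every n ≤ 5, M ≤ N
(exhaustively tested). Measurement sampling uses `numpy.random.default_rng`
with a caller seed and is bit-reproducible.

The classical baseline is the exact expected sequential-probe count to the
first of M solutions under a uniform random permutation, computed by
enumeration of the survival function (closed form (N+1)/(M+1), used as a
cross-check only). The quadratic speed-up law is stated against the
O(√(N/M)) query bound ⌈(π/4)√(N/M)⌉: over N = 4…1024 with one target the
log–log slope of classical/bound is 0.520. The rounded optimal count obeys
the same asymptotics, but its regression over this small range is biased
to ≈ 0.42 by integer rounding at the small-N end (k = 1 at N = 4), so the
bound is the right object for the scaling statement; both quantities are
exposed (`optimal_iterations`, `query_bound`).

Superdense coding follows the standard Bell-basis convention
(|ψ⟩₀₀ = (|00⟩ + |11⟩)/√2, …): encoding applies X^b₂ then Z^b₁ to the
first qubit, decoding projects onto the four Bell states. Non-Bell inputs
decode to the argmax outcome with its probability and a non-deterministic
flag. The 3-bit monomer register orders its sites (IP₃, high-affinity
Ca²⁺, low-affinity Ca²⁺); θ = 1 only for |110⟩ (open channel), and the
tetramer count Mn!/(Mn−1)! = Mn is computed, not assumed.

## Correspondence layer

`build_search_register` classifies a grid of (Γ, D) points and maps them
one-to-one onto register indices in input order (the default grid sweeps
D linearly; geometric spacing is available). Continuous points form the
solution subset i_M; saltatory, mixed, failed and padding entries form
i_F. Padding to the next power of two always adds failure entries, so it
can never create spurious solutions. An empty i_M is legal and flagged
(`no_solution`), and the CLI exits with a distinct code 2.

`algorithmic_search_time` returns the order bound ⌈√(D_max/D_C)⌉ together
with the realized optimal Grover count for the register's (N, M). The
relation v_C = v_S² is dimensionally inconsistent as stated (μm/s vs
(μm/s)²); `verify_quadratic_relations` evaluates v_C ≥ v_S² numerically in
μm/s only and records the outcome as a flag beside an explicit warning —
it is never enforced. The end-to-end pipeline is deterministic given a
seed (byte-identical report JSON).

## Problem sizes

Defaults keep every computation desk-scale: FDF runs use ≤ 24 sites on
~600–1300-node grids (seconds each), exhaustive quantum checks stop at
n = 5 qubits (n = 6 for dense-matrix cross-checks), and the speed-up
series stops at N = 1024. The full test suite runs in well under a
minute.

## Known limitations

- 1-D only; no stochastic gating, mobile buffers, or store re-uptake in
  the wave equation (the flux-based Γ folds those effects into a scalar).
- The saltatory velocity law is only recovered when τ is small against
  d²/D; the simulator itself is valid outside that window, but the linear
  scaling claim is not.
- The regime thresholds (β_lo, β_hi, Γ band) are conventions with
  defaults, not measured boundaries.
- The quantum layer is a mathematical simulation of the algorithm; no
  claim is made about physical realization in receptor proteins, and
  decoherence is out of scope.
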