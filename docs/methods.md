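# Methods

## Model overview

`qgdm` models a protein interaction network as an open quantum system.
Each protein i is a two-level site: basis state `c0` is the
ground/closed conformation, `c1` the binding-competent conformation.
A per-protein conformational dimension d_i ≥ 2 is supported by the state
and operator layer, but the operators that involve Pauli-Z (on-site
energy terms, dephasing and binding channels) require two-level sites and
raise otherwise.  A spin degree of freedom can be modeled by doubling the
local dimension, but no operator in the package couples to it, so the
default keeps sites two-level.

The network state is a density matrix on the ordered tensor product of
the sites.  Site order is canonical — first-appearance order from the
edge-list file, construction order otherwise — and `site_order[0]` is the
leftmost (most significant) Kronecker factor.  Every matrix in the
package uses this single convention, which is what makes brute-force
index-loop oracles feasible in the tests.

Exact dense simulation is a deliberate design choice: the composite
dimension is capped at 4096 (12 two-level sites).  Larger networks are
handled by the pair/module subspace strategy of the scoring layer, never
by approximate compression.

## Operators

The extended quantum graph Laplacian is

    L̂_Q = Σ_{(i,j)∈E} W_ij (Î − P̂_ij) + Σ_i ħ ω_i σ̂_z^(i),

with swap operators P̂_ij.  The topological part is positive
semidefinite and annihilates fully symmetric product states |ψ⟩^⊗n; the
on-site term uses the convention σ_z|c0⟩ = +|c0⟩, so ħω_i σ_z has
eigenvalues ±ħω_i as the operator is written (not ±ħω_i/2).  ħ defaults
to 1 (natural units); only the products ħω enter any result.

The n×n vertex-space companion, `quantum_enhanced_laplacian`, realizes
the quantum correction as ħ·diag(ω_i) added to the classical L = D − A:
on-site frequencies are the only quantum correction used anywhere in the
model, so the correction term mirrors them at the classical level.

The commutator-based edge gradient `(∇f̂)(i,j) = √W_ij [f̂(j), f̂(i)]` and
anticommutator divergence `(div F̂)(i) = Σ_j √W_ij {F̂(i,j), ρ̂_i}` accept
arbitrary operators on one shared space.  Operators confined to disjoint
tensor factors commute, which would make every gradient vanish; a helper
(`lift_site_operators`) embeds site-local operators for callers who want
that reading anyway.  Note the gradient is bilinear in the field
(scaling f by c scales the gradient by c²), and antisymmetric in edge
orientation.

## Dynamics

Time evolution follows the Lindblad master equation with Hamiltonian
Ĥ = γL̂_Q + V̂ and three per-site channel families:

| channel   | jump operator        | default rate (units of γ) |
|-----------|----------------------|---------------------------|
| dephasing | √γ_deph σ̂_z         | 0.1                       |
| binding   | √γ_bind σ̂_− = √γ|c0⟩⟨c1| | 0.05                 |
| thermal   | √γ_therm (â + â†)    | 0.01                      |

The binding channel relaxes the binding-competent state toward the
ground conformation; the thermal operator truncates to σ_x on two-level
sites and uses the truncated harmonic ladder for d > 2.  The rate
defaults are package choices, documented as such — no measured values
exist for them; they are ordered to reflect that conformational
dephasing is the fastest environmental process and thermal excitation
the slowest.

The generator is vectorized column-stacking (vec(AXB) = (Bᵀ⊗A) vec X).
Propagation uses the exact matrix exponential when the vectorized
dimension D² ≤ 4096, caching the propagator per unique grid step so
uniform grids cost one exponential; beyond that a fixed-step classical
RK4 integrator on the vectorized state is used with step
dt = min(0.01, 0.02/‖𝓛‖_∞).  The step constant keeps the global O(dt⁴)
error near 1e−8 so the RK4 path agrees with the exact path to better
than 1e−7 in Frobenius norm (the suite checks this on random
specifications).  Because every term of the RK4 update contains at least
one application of the generator, and the adjoint generator annihilates
the identity, RK4 preserves the trace to round-off just like the exact
path.

Output states land exactly on the requested time grid (propagator
multiplication, never interpolation).  Every output state is validated:
trace drift ≤ 1e−8, Hermiticity ≤ 1e−8, eigenvalues ≥ −1e−9.  A breach
raises with diagnostics; nothing is clipped or renormalized beyond a
within-tolerance re-symmetrization of the accepted state.  Steady states
come from the null space of the generator and are rejected when the
kernel is degenerate (e.g. pure dephasing, whose stationary manifold is
the whole diagonal subspace).

## Information measures

Entropies default to log base 2 (bits), so `log d` in the modular
entanglement bound counts qubits; natural log is available.  The
`0·log 0` limit is handled by an eigenvalue floor (1e−12), not by
dropping eigenvalues, keeping downstream finite-difference gradients
deterministic.

The interaction entropy follows the model's printed sign convention
H(i,j) = S(ρ_ij) − S(ρ_i) − S(ρ_j), the *negative* of conventional
mutual information (a Bell pair gives −2 bits).  A `conventional=True`
flag returns the standard sign.  The correlation measure across a
partition, S(A:B) = S(ρ_A) + S(ρ_B) − S(ρ_AB), is nonnegative by
subadditivity and equals 2S(ρ_A) for globally pure states.

The hierarchical bound for modular networks, E_inter(m,n) ≤
min{|V_m|,|V_n|}·log d, is checked in two readings: the entanglement
entropy S(ρ_m) of the reduced module pair, which provably satisfies the
bound and is the one asserted, and the mutual information S(m:n), which
reaches twice the bound for maximally entangled module pairs and is
reported for reference only.

The cooperativity factor η = 1 + αS(A:B) multiplies a base binding
probability (capped at 1); α is a free cooperativity strength with no
canonical value.

## Pair scoring

The score of a candidate pair at horizon t is P_ij(t) = Tr[M̂_ij(t)ρ(t)]
with

    M̂_ij(t) = N⁻¹ ∫₀ᵗ e^{−λ(t−t′)} Π(t′) Ô_int Π(t′) dt′.

Design choices that the model statement leaves open, fixed here:

* **Interaction operator.**  Ô_int = s_ij |c1 c1⟩⟨c1 c1| — the joint
  binding-competent projector weighted by feature similarity
  s_ij = (1 + cos θ_ij)/2 ∈ [0,1] (1.0 when features are absent).  This
  is the minimal choice for which the pair probability reduces to the
  |α|²-weighted conformational sum for product states.  The construction
  is pluggable: `measurement_operator` accepts any fixed operator or
  time-dependent callable.
* **Conformational projection.**  Π(t′) is realized as basis-diagonal
  sandwiching in the fixed computational basis; time-dependent rotating
  conformational bases are not tracked, as nothing defines their motion.
* **Normalization.**  N is the trapezoid quadrature of the kernel on the
  same grid (equal to (1−e^{−λt})/λ up to quadrature accuracy), so a
  time-constant integrand reproduces itself exactly, the operator
  spectrum stays in [0,1], and P is a proper probability.  The
  un-normalized raw integral is available via `normalize=False`.
* **Defaults.**  λ = 1.0 (memory comparable to the coupling timescale),
  horizon t = 2.0, grid step 0.05.  These are package choices; nothing
  pins them externally.

For networks above the 12-site cap, each candidate pair is simulated on
a subspace: when both proteins share a module of at most 6 sites, the
whole module is evolved jointly (cached per module) and partial-traced
to the pair at every grid time; otherwise the pair is evolved in
isolation with its direct edge weight as the coupling.  Held-out
candidate pairs are non-edges, so isolated-pair dynamics are identical
across candidates and discrimination is then carried by the
module-correlated feature similarity s_ij — the module path adds
topological context only when it fits the cap.  The initial state is the
uniform superposition product state, which populates every conformational
configuration and carries maximal basis coherence.

## Synthetic networks

The generator emulates the modular organization of curated PPI networks
with a planted-partition model: 24 proteins in 3 modules by default,
intra-module edge probability 0.6, inter-module 0.05, edge weights
uniform on (0.5, 1.5), and 8-dimensional features per protein drawn as
module centroid (standard normal) plus isotropic noise of scale 0.2.
Held-out positives are sampled intra-module non-edges; negatives are
inter-module non-edges.  What it does *not* emulate: degree
heterogeneity (hubs), weight–evidence correlation, overlapping modules,
and biologically structured features.  Passing the planted-network
discrimination test therefore shows the machinery ranks structurally
plausible pairs above implausible ones under assortative conditions — it
is not a claim about accuracy on curated interactome databases.

## Variational training

The VQE layer uses a hardware-efficient, graph-aware ansatz: per-site
Ry and Rz rotations per layer followed by fixed √SWAP gates along graph
edges (2 layers by default).  The √SWAP gate is used because the full
SWAP, being a permutation of product states, creates no entanglement.
Energies are exact statevector expectations — no shot noise — so
training is bit-reproducible given the seed.  Gradients use the
parameter-shift rule g_k = [E(θ+π/2 e_k) − E(θ−π/2 e_k)]/2, exact for
the ±½-spectrum rotation generators; Hamiltonian-coefficient entries of
θ are linear in the energy and differentiate to plain expectations;
central finite differences (step 1e−6) are the fallback for arbitrary
gates.  The optimizer is standard bias-corrected Adam (step 0.05,
β₁ = 0.9, β₂ = 0.999).  The regularized loss
L_total = L_quantum + λ₁·(l1 coherence of the ansatz state) + λ₂·‖θ‖₁
subgradients the non-smooth terms (sign for the l1 penalty, finite
differences for coherence).  How the variational energy objective should
connect to the supervised classification loss of the scoring layer is
left open by the model; both are provided independently.

## Problem sizes and tolerances

The test suite and the acceptance script use desk-scale problems chosen
so every quantity has an independent oracle: Lindblad specs on ≤ 3 sites
(exact-exponential reference), 1000 random states of dimension ≤ 16 for
subadditivity, 50 random specs for the RK4 oracle, memory-integral grids
of 10³ vs 10⁵ points, VQE on 1–2 qubits against exact diagonalization,
and 5 planted networks of 24 proteins for ranking.  Validation
tolerances: Hermiticity/trace 1e−10 on construction, trace drift 1e−8
and positivity −1e−9 along trajectories, state normalization 1e−10.

## Known limitations

* Exact density-matrix simulation limits joint dynamics to 12 two-level
  sites; module context beyond 6 sites is not folded into pair scores.
* The Markovian master equation has no memory; memory enters only
  through the scoring kernel.
* Feature vectors are opaque user input; no feature engineering from
  structure or sequence is performed.
* Multilayer networks are stored but not fused; scoring uses one layer.
* The probability scale of P_ij depends on the initial-state population
  of the binding subspace; thresholds are dataset-dependent and the
  ranking (ROC) is the primary readout.
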