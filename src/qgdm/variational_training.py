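"""Hybrid variational optimization of the network Hamiltonian.

The quantum component is a variational eigensolver: a parameterized network
Hamiltonian H(theta) = sum_i c_i P_i over Pauli strings, a hardware-efficient
graph-aware ansatz |psi(theta)> (per-site Ry/Rz rotations interleaved with
fixed entangling sqrt-SWAP gates along graph edges), and the energy
objective E(theta) = <psi(theta)| H(theta) |psi(theta)>.  Gradients come
from the parameter-shift rule (exact for the ±1/2-spectrum rotation
generators) or a finite-difference fallback; the classical loop is Adam.
The regularized loss is

    L_total = L_quantum + lambda1 * L_coherence + lambda2 * L_sparsity

with L_coherence the l1 coherence of the ansatz state and L_sparsity the
l1 norm of theta.  Expectations use exact statevector simulation — no shot
noise — so training is bit-reproducible given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .graph_operators import SIGMA_X, SIGMA_Y, SIGMA_Z
from .hilbert_space import CompositeSpace, PureState, embed_local
from .quantum_measures import l1_coherence

PAULIS = {"X": SIGMA_X, "Y": SIGMA_Y, "Z": SIGMA_Z}

# sqrt-SWAP: the entangling member of the swap-gate family
_SQRT_SWAP = np.array(
    [
        [1, 0, 0, 0],
        [0, 0.5 + 0.5j, 0.5 - 0.5j, 0],
        [0, 0.5 - 0.5j, 0.5 + 0.5j, 0],
        [0, 0, 0, 1],
    ],
    dtype=complex,
)


@dataclass(frozen=True)
class PauliTerm:
    """One Pauli string with a coefficient, fixed or taken from theta.

    ``factors`` maps site -> 'X' | 'Y' | 'Z' (identity on every other
    site).  When ``coefficient_index`` is set, the coefficient is
    ``theta[coefficient_index]``; otherwise ``coefficient`` is used.
    """

    factors: tuple[tuple[str, str], ...]
    coefficient: float = 1.0
    coefficient_index: int | None = None

    def __post_init__(self) -> None:
        if not self.factors:
            raise ValueError("PauliTerm needs at least one non-identity factor")
        for _site, p in self.factors:
            if p not in PAULIS:
                raise ValueError(f"unknown Pauli label {p!r}")

    def matrix(self, space: CompositeSpace) -> np.ndarray:
        out = np.eye(space.total_dim, dtype=complex)
        for site, p in self.factors:
            out = out @ embed_local(PAULIS[p], site, space)
        return out


@dataclass(frozen=True)
class Rotation:
    """Parameterized single-site rotation exp(-i theta_k P / 2)."""

    axis: Literal["X", "Y", "Z"]
    site: str
    parameter_index: int


@dataclass(frozen=True)
class Entangler:
    """Fixed sqrt-SWAP gate along one graph edge."""

    sites: tuple[str, str]


@dataclass
class Ansatz:
    """Layered graph-aware circuit acting on |0...0>.

    Each layer applies Ry then Rz on every site, followed by sqrt-SWAP
    entanglers along the graph edges in canonical edge order.
    """

    space: CompositeSpace
    gates: list[Rotation | Entangler]
    n_params: int

    def __post_init__(self) -> None:
        idx = sorted(
            {g.parameter_index for g in self.gates if isinstance(g, Rotation)}
        )
        if idx != list(range(self.n_params)):
            raise ValueError("rotation parameter indices must be dense 0..n_params-1")

    @classmethod
    def hardware_efficient(
        cls,
        space: CompositeSpace,
        edges: Sequence[tuple[str, str]] = (),
        n_layers: int = 2,
    ) -> "Ansatz":
        gates: list[Rotation | Entangler] = []
        k = 0
        for _ in range(n_layers):
            for site in space.site_order:
                gates.append(Rotation("Y", site, k))
                k += 1
                gates.append(Rotation("Z", site, k))
                k += 1
            for e in edges:
                gates.append(Entangler((e[0], e[1])))
        return cls(space, gates, k)

    def statevector(self, theta: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        d = space_dim = self.space.total_dim
        psi = np.zeros(space_dim, dtype=complex)
        psi[0] = 1.0
        for g in self.gates:
            if isinstance(g, Rotation):
                ang = theta[g.parameter_index]
                p = PAULIS[g.axis]
                local = np.cos(ang / 2) * np.eye(2) - 1j * np.sin(ang / 2) * p
                u = embed_local(local, g.site, self.space)
            else:
                u = embed_local(_SQRT_SWAP, list(g.sites), self.space)
            psi = u @ psi
        assert psi.shape == (d,)
        return psi

    def state(self, theta: np.ndarray) -> PureState:
        return PureState(self.space, self.statevector(theta))


def assemble_hamiltonian(
    terms: Sequence[PauliTerm], theta: np.ndarray, space: CompositeSpace
) -> np.ndarray:
    h = np.zeros((space.total_dim, space.total_dim), dtype=complex)
    for t in terms:
        c = theta[t.coefficient_index] if t.coefficient_index is not None else t.coefficient
        h += c * t.matrix(space)
    return h


def energy(
    theta: np.ndarray, hamiltonian: Sequence[PauliTerm], ansatz: Ansatz
) -> float:
    """E(theta) = <psi(theta)| H(theta) |psi(theta)> (exact statevector)."""
    theta = np.asarray(theta, dtype=float)
    for t in hamiltonian:
        if t.coefficient_index is not None and t.coefficient_index >= len(theta):
            raise IndexError(
                f"coefficient index {t.coefficient_index} out of range for "
                f"theta of length {len(theta)}"
            )
    psi = ansatz.statevector(theta)
    h = assemble_hamiltonian(hamiltonian, theta, ansatz.space)
    e = np.vdot(psi, h @ psi)
    return float(e.real)


GradientMode = Literal["parameter_shift", "finite_difference"]


def gradient(
    theta: np.ndarray,
    hamiltonian: Sequence[PauliTerm],
    ansatz: Ansatz,
    mode: GradientMode = "parameter_shift",
) -> np.ndarray:
    """dE/dtheta by the parameter-shift rule or central finite differences.

    Parameter-shift (exact for rotation generators P/2 with spectrum ±1/2):
        g_k = [E(theta + pi/2 e_k) - E(theta - pi/2 e_k)] / 2
    Hamiltonian-coefficient entries are linear, so their derivative is the
    expectation <psi| P_k |psi>, computed directly.
    """
    theta = np.asarray(theta, dtype=float)
    g = np.zeros_like(theta)
    if mode == "finite_difference":
        h = 1e-6
        for k in range(len(theta)):
            e_k = np.zeros_like(theta)
            e_k[k] = h
            g[k] = (
                energy(theta + e_k, hamiltonian, ansatz)
                - energy(theta - e_k, hamiltonian, ansatz)
            ) / (2 * h)
        return g
    if mode != "parameter_shift":
        raise ValueError(f"unknown gradient mode {mode!r}")
    coeff_indices = {
        t.coefficient_index for t in hamiltonian if t.coefficient_index is not None
    }
    psi = ansatz.statevector(theta)
    for k in range(len(theta)):
        if k in coeff_indices:
            # linear dependence: dE/dc_k = sum of <P_t> over terms with this index
            val = 0.0
            for t in hamiltonian:
                if t.coefficient_index == k:
                    val += float(np.vdot(psi, t.matrix(ansatz.space) @ psi).real)
            g[k] = val
            continue
        if k < ansatz.n_params:
            shift = np.zeros_like(theta)
            shift[k] = np.pi / 2
            g[k] = (
                energy(theta + shift, hamiltonian, ansatz)
                - energy(theta - shift, hamiltonian, ansatz)
            ) / 2
        # parameters used by neither circuit nor Hamiltonian have zero gradient
    return g


@dataclass(frozen=True)
class AdamParams:
    step_size: float = 0.05
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8


@dataclass(frozen=True)
class TrainingConfig:
    """Regularization weights, optimizer settings and reproducibility seed."""

    lambda1: float = 0.0  # coherence weight
    lambda2: float = 0.0  # sparsity weight
    adam: AdamParams = field(default_factory=AdamParams)
    max_iters: int = 500
    gradient_mode: GradientMode = "parameter_shift"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("regularization weights must be >= 0")


@dataclass
class LossComponents:
    total: float
    quantum: float
    coherence: float
    sparsity: float


def total_loss(
    e_quantum: float,
    state: PureState,
    theta: np.ndarray,
    cfg: TrainingConfig,
) -> LossComponents:
    """Regularized loss L_total = L_quantum + l1*L_coherence + l2*L_sparsity."""
    coh = l1_coherence(state.to_density())
    sparsity = float(np.sum(np.abs(theta)))
    total = e_quantum + cfg.lambda1 * coh + cfg.lambda2 * sparsity
    return LossComponents(total, e_quantum, coh, sparsity)


@dataclass
class TrainingResult:
    theta: np.ndarray
    loss_trace: list[LossComponents]

    @property
    def final_loss(self) -> LossComponents:
        return self.loss_trace[-1]


def train(
    hamiltonian: Sequence[PauliTerm],
    ansatz: Ansatz,
    cfg: TrainingConfig | None = None,
    theta0: np.ndarray | None = None,
) -> TrainingResult:
    """Adam minimization of the regularized energy; deterministic per seed.

    theta is initialized uniformly on (-pi, pi) from the seeded generator
    unless an explicit ``theta0`` is supplied.  Raises on NaN loss with the
    trace attached.
    """
    cfg = cfg or TrainingConfig()
    rng = np.random.default_rng(cfg.seed)
    n_extra = max(
        (t.coefficient_index + 1 for t in hamiltonian if t.coefficient_index is not None),
        default=0,
    )
    n = max(ansatz.n_params, n_extra)
    theta = (
        np.asarray(theta0, dtype=float).copy()
        if theta0 is not None
        else rng.uniform(-np.pi, np.pi, size=n)
    )
    m = np.zeros_like(theta)
    v = np.zeros_like(theta)
    a = cfg.adam
    trace: list[LossComponents] = []
    for it in range(1, cfg.max_iters + 1):
        e = energy(theta, hamiltonian, ansatz)
        loss = total_loss(e, ansatz.state(theta), theta, cfg)
        trace.append(loss)
        if not np.isfinite(loss.total):
            raise RuntimeError(
                f"training diverged (loss {loss.total}) at iteration {it}; "
                f"trace length {len(trace)}"
            )
        g = gradient(theta, hamiltonian, ansatz, cfg.gradient_mode)
        if cfg.lambda2 > 0:
            g = g + cfg.lambda2 * np.sign(theta)
        if cfg.lambda1 > 0:
            g = g + cfg.lambda1 * _coherence_gradient_fd(theta, ansatz)
        m = a.beta1 * m + (1 - a.beta1) * g
        v = a.beta2 * v + (1 - a.beta2) * g * g
        m_hat = m / (1 - a.beta1**it)
        v_hat = v / (1 - a.beta2**it)
        theta = theta - a.step_size * m_hat / (np.sqrt(v_hat) + a.epsilon)
    e = energy(theta, hamiltonian, ansatz)
    trace.append(total_loss(e, ansatz.state(theta), theta, cfg))
    return TrainingResult(theta, trace)


def _coherence_gradient_fd(theta: np.ndarray, ansatz: Ansatz, h: float = 1e-6) -> np.ndarray:
    """Finite-difference gradient of the (non-smooth) l1 coherence term."""
    g = np.zeros_like(theta)
    for k in range(min(len(theta), ansatz.n_params)):
        e_k = np.zeros_like(theta)
        e_k[k] = h
        c_plus = l1_coherence(ansatz.state(theta + e_k).to_density())
        c_minus = l1_coherence(ansatz.state(theta - e_k).to_density())
        g[k] = (c_plus - c_minus) / (2 * h)
    return g
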