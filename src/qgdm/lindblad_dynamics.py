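"""Open-system dynamics of the network density matrix.

The network state evolves under the Markovian (GKSL) master equation

    d rho / dt = -(i/hbar) [H, rho]
                 + sum_k ( L_k rho L_k^dag - 1/2 {L_k^dag L_k, rho} )

with Hamiltonian H = gamma * L_Q_hat + V (extended quantum graph Laplacian
plus an optional potential) and three physically motivated decoherence
channels per site:

* ``dephasing``  — conformational dephasing,    L = sqrt(gamma) sigma_z
* ``binding``    — binding/unbinding relaxation, L = sqrt(gamma) sigma_-
  (|c0><c1|: decay of the binding-competent conformation)
* ``thermal``    — thermal fluctuations,         L = sqrt(gamma) (a + a^dag)
  (truncated harmonic ladder; sigma_x for two-level sites)

Propagation uses the column-stacked vectorization vec(A X B) =
(B^T kron A) vec(X): small systems are propagated by the exact matrix
exponential of the Liouvillian, larger ones by fixed-step RK4 whose
accuracy is cross-checked against the exact path in the test suite.
States are validated at every output time; violations raise with
diagnostics — nothing is clipped silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import scipy.linalg

from .graph_operators import (
    SIGMA_MINUS,
    SIGMA_Z,
    ExtendedLaplacianSpec,
    extended_quantum_laplacian,
)
from .hilbert_space import (
    CompositeSpace,
    DensityMatrix,
    embed_local,
    validate_density,
)

ChannelKind = Literal["dephasing", "binding", "thermal"]

#: Above this vectorized dimension (D^2), `evolve` switches from the exact
#: exponential propagator to fixed-step RK4.
EXACT_PROPAGATION_MAX_VEC_DIM = 4096

TRACE_DRIFT_TOL = 1e-8
POSITIVITY_TOL = 1e-9


def ladder_operator(d: int) -> np.ndarray:
    """Truncated harmonic annihilation operator a on a d-level site."""
    a = np.zeros((d, d), dtype=complex)
    for n in range(1, d):
        a[n - 1, n] = np.sqrt(n)
    return a


@dataclass(frozen=True)
class LindbladChannel:
    """One decoherence channel: kind, target site and rate gamma_k (1/time)."""

    kind: ChannelKind
    site: str
    rate: float

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError(f"channel rate must be >= 0, got {self.rate}")
        if self.kind not in ("dephasing", "binding", "thermal"):
            raise ValueError(f"unknown channel kind {self.kind!r}")

    def operator(self, space: CompositeSpace) -> np.ndarray:
        """Jump operator sqrt(gamma) * local operator, embedded in the space."""
        d = space.dim_of(self.site)
        if self.kind == "dephasing":
            if d != 2:
                raise ValueError("dephasing channel requires a two-level site")
            local = SIGMA_Z
        elif self.kind == "binding":
            if d != 2:
                raise ValueError("binding channel requires a two-level site")
            local = SIGMA_MINUS
        else:  # thermal: a + a^dag, truncates to sigma_x at d=2
            a = ladder_operator(d)
            local = a + a.conj().T
        return np.sqrt(self.rate) * embed_local(local, self.site, space)


@dataclass
class HamiltonianSpec:
    """System Hamiltonian H = coupling * L_Q_hat + V."""

    laplacian: ExtendedLaplacianSpec
    coupling: float = 1.0
    potential: np.ndarray | None = None

    def build(self, space: CompositeSpace) -> np.ndarray:
        h = self.coupling * extended_quantum_laplacian(self.laplacian, space)
        if self.potential is not None:
            v = np.asarray(self.potential, dtype=complex)
            if np.max(np.abs(v - v.conj().T)) > 1e-10:
                raise ValueError("potential V must be Hermitian")
            if v.shape != h.shape:
                raise ValueError(
                    f"potential shape {v.shape} != Hamiltonian shape {h.shape}"
                )
            h = h + v
        return h


@dataclass
class EvolutionResult:
    """Trajectory rho(t) with worst-case validity diagnostics."""

    times: np.ndarray
    states: list[DensityMatrix]
    trace_drift: float
    min_eigenvalue: float

    @property
    def final(self) -> DensityMatrix:
        return self.states[-1]


class EvolutionError(RuntimeError):
    """Physicality tolerance breached during propagation; carries diagnostics."""


def build_liouvillian(
    h: HamiltonianSpec | np.ndarray,
    channels: Sequence[LindbladChannel],
    space: CompositeSpace,
) -> np.ndarray:
    """Vectorized GKSL generator (D^2 x D^2), column-stacking convention.

    The adjoint generator annihilates the identity (trace preservation):
    vec(I)^T  L = 0.
    """
    if isinstance(h, HamiltonianSpec):
        hbar = h.laplacian.hbar
        hmat = h.build(space)
    else:
        hbar = 1.0
        hmat = np.asarray(h, dtype=complex)
    d = space.total_dim
    if hmat.shape != (d, d):
        raise ValueError(f"Hamiltonian shape {hmat.shape} != ({d}, {d})")
    ident = np.eye(d)
    liou = (-1j / hbar) * (np.kron(ident, hmat) - np.kron(hmat.T, ident))
    for ch in channels:
        lk = ch.operator(space)
        lkd_lk = lk.conj().T @ lk
        liou += (
            np.kron(lk.conj(), lk)
            - 0.5 * np.kron(ident, lkd_lk)
            - 0.5 * np.kron(lkd_lk.T, ident)
        )
    return liou


def _rk4_step_size(liou: np.ndarray) -> float:
    # fixed step, no adaptive embedding: the exact-exponential path is the
    # accuracy oracle.  0.02/||L|| keeps the global O(dt^4) error near 1e-8.
    norm = np.linalg.norm(liou, np.inf)
    if norm == 0:
        return 0.01
    return min(0.01, 0.02 / norm)


def evolve(
    rho0: DensityMatrix,
    h: HamiltonianSpec | np.ndarray,
    channels: Sequence[LindbladChannel],
    times: Sequence[float],
    method: Literal["auto", "expm", "rk4"] = "auto",
) -> EvolutionResult:
    """Propagate rho0 along the requested time grid.

    Output states land exactly on the requested times (propagator
    multiplication between grid points, no interpolation).  Every output
    state is checked for trace drift (<= 1e-8), Hermiticity and positivity
    (eigenvalues >= -1e-9); a breach raises :class:`EvolutionError`.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) == 0:
        raise ValueError("times must be a nonempty 1-D grid")
    if times[0] < 0 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be increasing and start at t >= 0")
    space = rho0.space
    liou = build_liouvillian(h, channels, space)
    d = space.total_dim
    use_expm = method == "expm" or (method == "auto" and d * d <= EXACT_PROPAGATION_MAX_VEC_DIM)
    vec = rho0.matrix.reshape(-1, order="F")

    states: list[DensityMatrix] = []
    drift = 0.0
    min_eig = np.inf
    t_prev = 0.0
    propagators: dict[float, np.ndarray] = {}  # uniform grids reuse one expm
    for t in times:
        dt_seg = t - t_prev
        if dt_seg > 0:
            if use_expm:
                key = round(float(dt_seg), 12)
                if key not in propagators:
                    propagators[key] = scipy.linalg.expm(liou * dt_seg)
                vec = propagators[key] @ vec
            else:
                vec = _rk4_propagate(liou, vec, dt_seg)
        t_prev = t
        m = vec.reshape(d, d, order="F")
        report = validate_density(m)
        drift = max(drift, report.trace_violation)
        min_eig = min(min_eig, report.min_eigenvalue)
        if (
            report.trace_violation > TRACE_DRIFT_TOL
            or report.min_eigenvalue < -POSITIVITY_TOL
            or report.hermiticity_violation > 1e-8
        ):
            raise EvolutionError(
                f"state at t={t} breached physicality tolerances: {report.summary()} "
                f"(trace drift {report.trace_violation:.3e}, "
                f"min eigenvalue {report.min_eigenvalue:.3e})"
            )
        # re-symmetrize within tolerance so DensityMatrix construction is stable
        m = (m + m.conj().T) / 2
        m = m / np.trace(m).real
        states.append(DensityMatrix(space, m))
    return EvolutionResult(times, states, drift, float(min_eig))


def _rk4_propagate(liou: np.ndarray, vec: np.ndarray, duration: float) -> np.ndarray:
    dt = _rk4_step_size(liou)
    n_steps = max(1, int(np.ceil(duration / dt)))
    dt = duration / n_steps
    for _ in range(n_steps):
        k1 = liou @ vec
        k2 = liou @ (vec + 0.5 * dt * k1)
        k3 = liou @ (vec + 0.5 * dt * k2)
        k4 = liou @ (vec + dt * k3)
        vec = vec + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    return vec


def steady_state(
    h: HamiltonianSpec | np.ndarray,
    channels: Sequence[LindbladChannel],
    space: CompositeSpace,
) -> DensityMatrix:
    """Stationary state: the (unique) kernel vector of the Liouvillian.

    Raises if the kernel is degenerate (e.g. pure dephasing, whose steady
    manifold is the whole diagonal subspace) — the caller must then pick an
    initial condition and evolve instead.
    """
    liou = build_liouvillian(h, channels, space)
    kernel = scipy.linalg.null_space(liou, rcond=1e-10)
    if kernel.shape[1] != 1:
        raise ValueError(
            f"Liouvillian kernel is {kernel.shape[1]}-dimensional; steady state "
            "not unique"
        )
    d = space.total_dim
    m = kernel[:, 0].reshape(d, d, order="F")
    m = (m + m.conj().T) / 2
    tr = np.trace(m).real
    if abs(tr) < 1e-12:
        raise ValueError("kernel vector is traceless; no valid steady state")
    m = m / tr
    residual = np.linalg.norm(liou @ m.reshape(-1, order="F"))
    if residual > 1e-9:
        raise ValueError(f"steady-state residual {residual:.3e} exceeds 1e-9")
    return DensityMatrix(space, m)
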