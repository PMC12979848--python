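"""Interaction-probability scoring of protein pairs.

The score of a candidate pair (i, j) at horizon t is

    P_ij(t) = Tr[ M_ij(t) rho(t) ]

with the memory-kernel measurement operator

    M_ij(t) = N^-1  ∫_0^t  e^{-lambda (t - t')}  Pi(t') O_int Pi(t')  dt'

where lambda is the binding memory decay rate, Pi projects onto the
conformational (computational) basis — realized as basis-diagonal
sandwiching in the fixed basis — and N = (1 - e^{-lambda t}) / lambda
normalizes the kernel so that P is a proper probability.  The interaction
operator O_int is the similarity-weighted joint binding-competent
projector

    O_int = s_ij * |c1><c1|_i (x) |c1><c1|_j ,   s_ij in [0, 1]

with s_ij the cosine feature similarity mapped to [0, 1] (1.0 when no
features are supplied).  The construction rule is pluggable via
``interaction_rule``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .graph_operators import ExtendedLaplacianSpec
from .hilbert_space import (
    CompositeSpace,
    DensityMatrix,
    PureState,
    embed_local,
    partial_trace,
)
from .lindblad_dynamics import EvolutionResult, HamiltonianSpec, LindbladChannel, evolve
from .network_core import ProteinGraph

#: A module-level joint simulation is used (then partial-traced to the pair)
#: only when the module has at most this many sites; beyond it, pairs are
#: simulated in isolation.  Keeps exact density-matrix propagation tractable.
MODULE_SIM_MAX_SITES = 6


def feature_similarity(
    features: Mapping[str, np.ndarray] | None, i: str, j: str
) -> float:
    """Cosine similarity of the two feature vectors mapped to [0, 1].

    Returns 1.0 when features are absent (the quantum machinery then runs
    on topology alone).
    """
    if features is None or i not in features or j not in features:
        return 1.0
    u, v = np.asarray(features[i], float), np.asarray(features[j], float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 1.0
    cos = float(np.dot(u, v) / (nu * nv))
    return float(np.clip((1.0 + cos) / 2.0, 0.0, 1.0))


def binding_projector(space: CompositeSpace, i: str, j: str) -> np.ndarray:
    """|c1><c1|_i (x) |c1><c1|_j embedded in the composite space."""
    p1 = np.array([[0, 0], [0, 1]], dtype=complex)
    return embed_local(p1, i, space) @ embed_local(p1, j, space)


def interaction_operator(
    i: str,
    j: str,
    features: Mapping[str, np.ndarray] | None,
    space: CompositeSpace,
) -> np.ndarray:
    """Similarity-weighted joint binding projector; spectrum in [0, 1]."""
    for v in (i, j):
        if space.dim_of(v) != 2:
            raise ValueError(f"interaction operator requires two-level site {v!r}")
    return feature_similarity(features, i, j) * binding_projector(space, i, j)


@dataclass(frozen=True)
class MeasurementSpec:
    """Memory-kernel measurement parameters.

    lambda_decay — binding memory decay rate (1/time); horizon — final time
    t; grid_step — trajectory grid spacing dt; normalize — divide by
    N = (1 - e^{-lambda t})/lambda so the operator spectrum stays in [0,1].
    """

    lambda_decay: float = 1.0
    horizon: float = 2.0
    grid_step: float = 0.05
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.lambda_decay <= 0:
            raise ValueError("lambda_decay must be > 0")
        if not (0 < self.grid_step <= self.horizon):
            raise ValueError("need 0 < grid_step <= horizon")

    @property
    def times(self) -> np.ndarray:
        n = int(round(self.horizon / self.grid_step))
        return np.linspace(0.0, self.horizon, n + 1)

    @property
    def kernel_norm(self) -> float:
        return (1.0 - np.exp(-self.lambda_decay * self.horizon)) / self.lambda_decay


def conformational_projection(op: np.ndarray) -> np.ndarray:
    """Sandwich by the conformational-basis projectors: keeps the diagonal
    part of the operator in the fixed computational basis."""
    return np.diag(np.diag(op)).astype(complex)


def measurement_operator(
    spec: MeasurementSpec,
    trajectory: EvolutionResult,
    integrand: np.ndarray | Callable[[float], np.ndarray],
) -> np.ndarray:
    """Exponential-memory time integral of the projected interaction operator.

    ``integrand`` is either a fixed operator O (the usual case: the
    conformational projection of O_int is time-independent in the fixed
    basis) or a callable t' -> O(t').  The integral uses the trapezoid rule
    on the trajectory grid; with ``normalize=True`` a constant integrand
    reproduces itself exactly.
    """
    times = np.asarray(trajectory.times)
    if abs(times[-1] - spec.horizon) > 1e-9:
        raise ValueError(
            f"trajectory horizon {times[-1]} does not match spec horizon {spec.horizon}"
        )
    t_end = times[-1]
    kernel = np.exp(-spec.lambda_decay * (t_end - times))
    if callable(integrand):
        ops = np.array([conformational_projection(integrand(t)) for t in times])
    else:
        o = conformational_projection(np.asarray(integrand, dtype=complex))
        ops = np.array([o] * len(times))
    m = np.trapezoid(kernel[:, None, None] * ops, times, axis=0)
    if spec.normalize:
        # normalize by the same quadrature of the kernel (equals the analytic
        # (1 - e^{-lambda t})/lambda up to quadrature accuracy): a constant
        # integrand then reproduces itself exactly and the spectrum stays in
        # [0, 1] for integrands bounded by 1
        m = m / np.trapezoid(kernel, times)
    return m


def interaction_probability(rho_t: DensityMatrix, m: np.ndarray) -> float:
    """P = Tr[M rho]; real for Hermitian M, in [0, 1] when M is normalized."""
    m = np.asarray(m, dtype=complex)
    if m.shape != rho_t.matrix.shape:
        raise ValueError(
            f"measurement operator shape {m.shape} != state shape {rho_t.matrix.shape}"
        )
    p = complex(np.trace(m @ rho_t.matrix))
    if abs(p.imag) > 1e-10:
        raise ValueError(f"interaction probability has imaginary part {p.imag:.3e}")
    return float(p.real)


@dataclass(frozen=True)
class DynamicsConfig:
    """Physical parameters of the scoring simulations.

    Channel rates default to (dephasing, binding, thermal) =
    (0.1, 0.05, 0.01) in units of the Laplacian coupling; the model source
    reports no measured values, so these are documented package defaults.
    """

    coupling: float = 1.0
    omega_default: float = 0.5
    hbar: float = 1.0
    rate_dephasing: float = 0.1
    rate_binding: float = 0.05
    rate_thermal: float = 0.01
    max_module_sites: int = MODULE_SIM_MAX_SITES


@dataclass
class PPIPrediction:
    pair: tuple[str, str]
    probability: float
    label: int
    integrand_trace: np.ndarray | None = None


def _channels_for(space: CompositeSpace, cfg: DynamicsConfig) -> list[LindbladChannel]:
    chans = []
    for v in space.site_order:
        if cfg.rate_dephasing > 0:
            chans.append(LindbladChannel("dephasing", v, cfg.rate_dephasing))
        if cfg.rate_binding > 0:
            chans.append(LindbladChannel("binding", v, cfg.rate_binding))
        if cfg.rate_thermal > 0:
            chans.append(LindbladChannel("thermal", v, cfg.rate_thermal))
    return chans


def _uniform_superposition(space: CompositeSpace) -> DensityMatrix:
    d = space.total_dim
    vec = np.full(d, 1.0 / np.sqrt(d), dtype=complex)
    return PureState(space, vec).to_density()


def _simulate_subgraph(
    sub: ProteinGraph, cfg: DynamicsConfig, spec: MeasurementSpec
) -> EvolutionResult:
    space = CompositeSpace(sub.vertices, 2)
    lap = ExtendedLaplacianSpec(
        sub, {v: cfg.omega_default for v in sub.vertices}, cfg.hbar
    )
    h = HamiltonianSpec(lap, cfg.coupling)
    rho0 = _uniform_superposition(space)
    return evolve(rho0, h, _channels_for(space, cfg), spec.times)


def pair_trajectory(
    g: ProteinGraph,
    i: str,
    j: str,
    cfg: DynamicsConfig,
    spec: MeasurementSpec,
    _module_cache: dict | None = None,
) -> EvolutionResult:
    """Two-site reduced trajectory for a candidate pair.

    If both proteins share a module of at most ``cfg.max_module_sites``
    vertices, the whole module is simulated jointly (cached per module) and
    partial-traced to the pair at every time point; otherwise the pair is
    simulated in isolation with its direct edge weight as the coupling.
    """
    mods = g.modules or {}
    same_module = (
        i in mods and j in mods and mods[i] == mods[j]
    )
    if same_module:
        members = [v for v in g.vertices if mods.get(v) == mods[i]]
        if len(members) <= cfg.max_module_sites:
            key = mods[i]
            cache = _module_cache if _module_cache is not None else {}
            if key not in cache:
                cache[key] = _simulate_subgraph(g.subgraph(members), cfg, spec)
            traj = cache[key]
            states = [partial_trace(s, [i, j]) for s in traj.states]
            return EvolutionResult(traj.times, states, traj.trace_drift, traj.min_eigenvalue)
    pair_graph = g.subgraph([i, j])
    return _simulate_subgraph(pair_graph, cfg, spec)


def score_pair(
    g: ProteinGraph,
    i: str,
    j: str,
    cfg: DynamicsConfig,
    spec: MeasurementSpec,
    threshold: float = 0.5,
    _module_cache: dict | None = None,
    keep_integrand: bool = False,
) -> PPIPrediction:
    a, b = sorted((i, j), key=g.vertices.index)
    traj = pair_trajectory(g, a, b, cfg, spec, _module_cache)
    space = traj.states[0].space
    o_int = interaction_operator(a, b, g.features, space)
    m = measurement_operator(spec, traj, o_int)
    p = interaction_probability(traj.final, m)
    p = float(np.clip(p, 0.0, 1.0)) if spec.normalize else p
    integrand = None
    if keep_integrand:
        proj = conformational_projection(o_int)
        integrand = np.array(
            [interaction_probability(s, proj) for s in traj.states]
        )
    label = int(p >= threshold)  # ties at threshold predict interaction
    return PPIPrediction((a, b), p, label, integrand)


def score_all_pairs(
    g: ProteinGraph,
    candidates: Sequence[tuple[str, str]],
    cfg: DynamicsConfig | None = None,
    spec: MeasurementSpec | None = None,
    threshold: float = 0.5,
) -> list[PPIPrediction]:
    """Score every candidate pair; deterministic given the configuration.

    P(i, j) = P(j, i) exactly: pairs are canonicalized to vertex order
    before simulation.
    """
    cfg = cfg or DynamicsConfig()
    spec = spec or MeasurementSpec()
    vset = set(g.vertices)
    for a, b in candidates:
        if a not in vset or b not in vset:
            raise ValueError(f"candidate pair ({a!r}, {b!r}) not in graph")
    cache: dict = {}
    return [
        score_pair(g, a, b, cfg, spec, threshold, _module_cache=cache)
        for a, b in candidates
    ]
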