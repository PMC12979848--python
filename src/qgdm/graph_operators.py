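"""Quantum operators derived from the interaction graph.

Two levels of description coexist:

* an n-dimensional *vertex-space* operator, the quantum-enhanced Laplacian
  ``L_Q = L + hbar * diag(omega)`` — the classical Laplacian with on-site
  frequency corrections; and
* a many-body operator on the composite Hilbert space, the extended quantum
  graph Laplacian

      L_Q_hat = sum_{(i,j) in E} W_ij (I - P_ij) + sum_i hbar * omega_i * sigma_z^(i)

  whose topological part penalizes local-state disagreement across edges via
  swap operators P_ij, and whose energy part encodes conformational energy
  splittings (sign convention: sigma_z |c0> = +|c0>).

Also provided: the commutator-based quantum graph gradient on edges and the
anticommutator-based quantum graph divergence on vertices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hilbert_space import CompositeSpace, DensityMatrix, embed_local
from .network_core import ProteinGraph

SIGMA_X = np.array([[0, 1], [1, 0]], dtype=complex)
SIGMA_Y = np.array([[0, -1j], [1j, 0]], dtype=complex)
SIGMA_Z = np.array([[1, 0], [0, -1]], dtype=complex)
SIGMA_MINUS = np.array([[0, 1], [0, 0]], dtype=complex)  # |c0><c1|


@dataclass
class ExtendedLaplacianSpec:
    """Graph, on-site frequencies and hbar convention for the extended Laplacian.

    ``omegas`` maps vertex -> frequency (energy / hbar); missing vertices
    default to 0.  ``hbar`` defaults to 1 (natural units) — only the
    products hbar*omega enter any operator.
    """

    graph: ProteinGraph
    omegas: dict[str, float] = field(default_factory=dict)
    hbar: float = 1.0

    def omega(self, v: str) -> float:
        return float(self.omegas.get(v, 0.0))


def quantum_enhanced_laplacian(
    g: ProteinGraph, omegas: dict[str, float] | None = None, hbar: float = 1.0
) -> np.ndarray:
    """Vertex-space Laplacian with on-site quantum corrections.

    Realizes the correction term as ``hbar * diag(omega_i)``, mirroring the
    on-site energy term of the many-body operator at the classical level.
    With ``hbar = 0`` this is exactly the classical Laplacian.
    """
    from .network_core import classical_laplacian

    omegas = omegas or {}
    lap = classical_laplacian(g)
    diag = np.array([float(omegas.get(v, 0.0)) for v in g.vertices])
    return lap + hbar * np.diag(diag)


def swap_operator(space: CompositeSpace, i: str, j: str) -> np.ndarray:
    """Swap (exchange) operator P_ij on two equal-dimension sites.

    Acts on computational basis states by exchanging the local states of
    sites i and j: P|..a..b..> = |..b..a..>.  Hermitian, unitary, P^2 = I.
    """
    if i == j:
        raise ValueError("swap sites must be distinct")
    di, dj = space.dim_of(i), space.dim_of(j)
    if di != dj:
        raise ValueError(f"swap requires equal local dims, got {di} and {dj}")
    # two-site swap |a b> -> |b a> on the pair factor, embedded in the space
    p = np.zeros((di * dj, di * dj), dtype=complex)
    for a in range(di):
        for b in range(dj):
            p[b * di + a, a * dj + b] = 1.0
    return embed_local(p, [i, j], space)


def extended_quantum_laplacian(
    spec: ExtendedLaplacianSpec, space: CompositeSpace
) -> np.ndarray:
    """Many-body extended quantum graph Laplacian on the composite space.

    Hermitian; the topological part is PSD and annihilates fully symmetric
    product states |psi>^(tensor n).  On-site sigma_z terms require d=2
    sites wherever omega_i != 0.
    """
    vset = set(space.site_order)
    for v in spec.graph.vertices:
        if v not in vset:
            raise ValueError(f"space is missing graph vertex {v!r}")
    d = space.total_dim
    op = np.zeros((d, d), dtype=complex)
    ident = np.eye(d)
    for (a, b), w in spec.graph.weights.items():
        op += w * (ident - swap_operator(space, a, b))
    for v in spec.graph.vertices:
        w_i = spec.omega(v)
        if w_i == 0.0:
            continue
        if space.dim_of(v) != 2:
            raise ValueError(
                f"on-site frequency term needs a two-level site, but {v!r} has "
                f"dimension {space.dim_of(v)}"
            )
        op += spec.hbar * w_i * embed_local(SIGMA_Z, v, space)
    return op


@dataclass
class VertexOperatorField:
    """Operator-valued function on vertices, all on one shared space."""

    operators: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        shapes = {np.asarray(m).shape for m in self.operators.values()}
        if len(shapes) > 1:
            raise ValueError(f"operators have mixed shapes {shapes}")
        self.operators = {k: np.asarray(v, dtype=complex) for k, v in self.operators.items()}

    def __getitem__(self, v: str) -> np.ndarray:
        if v not in self.operators:
            raise KeyError(f"no operator for vertex {v!r}")
        return self.operators[v]


@dataclass
class EdgeOperatorField:
    """Operator-valued function on directed edges, all on one shared space."""

    operators: dict[tuple[str, str], np.ndarray]

    def __post_init__(self) -> None:
        self.operators = {k: np.asarray(v, dtype=complex) for k, v in self.operators.items()}

    def __getitem__(self, edge: tuple[str, str]) -> np.ndarray:
        if edge not in self.operators:
            raise KeyError(f"no operator for directed edge {edge}")
        return self.operators[edge]


def lift_site_operators(
    site_ops: dict[str, np.ndarray], space: CompositeSpace
) -> VertexOperatorField:
    """Lift per-site local operators to the shared composite space."""
    return VertexOperatorField(
        {v: embed_local(m, v, space) for v, m in site_ops.items()}
    )


def quantum_gradient(f: VertexOperatorField, g: ProteinGraph) -> EdgeOperatorField:
    """Commutator gradient on edges: (grad f)(i,j) = sqrt(W_ij) [f(j), f(i)].

    Antisymmetric in orientation and zero whenever the two vertex operators
    commute; both orientations of every edge are returned.
    """
    out: dict[tuple[str, str], np.ndarray] = {}
    for (a, b), w in g.weights.items():
        fa, fb = f[a], f[b]
        comm = fb @ fa - fa @ fb
        out[(a, b)] = np.sqrt(w) * comm
        out[(b, a)] = -np.sqrt(w) * comm
    return EdgeOperatorField(out)


def quantum_divergence(
    field: EdgeOperatorField,
    g: ProteinGraph,
    rho_local: dict[str, DensityMatrix],
) -> VertexOperatorField:
    """Anticommutator divergence at vertices.

    (div F)(i) = sum_{j ~ i} sqrt(W_ij) {F(i,j), rho_i}, with i the center
    vertex of each directed edge operator.  Hermitian whenever the edge
    operators are Hermitian.  Isolated vertices get the zero operator.
    """
    out: dict[str, np.ndarray] = {}
    shape = None
    for v in g.vertices:
        acc = None
        for u in g.neighbors(v):
            w = g.weight(v, u)
            f_vu = field[(v, u)]
            rho = rho_local[v].matrix
            if f_vu.shape != rho.shape:
                raise ValueError(
                    f"edge operator shape {f_vu.shape} != local density shape {rho.shape}"
                )
            term = np.sqrt(w) * (f_vu @ rho + rho @ f_vu)
            acc = term if acc is None else acc + term
            shape = term.shape
        out[v] = acc
    if shape is None:
        # graph has no edges at all; fall back to local density dims
        any_rho = next(iter(rho_local.values()), None)
        shape = any_rho.matrix.shape if any_rho is not None else (1, 1)
    for v, m in out.items():
        if m is None:
            out[v] = np.zeros(shape, dtype=complex)
    return VertexOperatorField(out)
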