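"""Finite-dimensional quantum algebra on graph vertices.

Each protein (vertex) carries a small local Hilbert space of conformational
basis states; the network lives on the tensor product of the selected sites.
This module provides composite spaces, pure states, density matrices,
operator embedding, partial traces and validation.  Exact dense simulation
is intentional: the dimension is capped so that every downstream operator
can be checked against brute-force constructions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

#: Hard cap on the composite dimension (12 qubits).  Larger graphs must be
#: simulated on pair or module subspaces (see :mod:`qgdm.ppi_scoring`).
MAX_TOTAL_DIM = 4096

HERMITICITY_TOL = 1e-10
TRACE_TOL = 1e-10
POSITIVITY_TOL = 1e-9
NORM_TOL = 1e-10


class DimensionCapError(ValueError):
    """Raised when a composite space would exceed ``MAX_TOTAL_DIM``."""


@dataclass(frozen=True)
class LocalSpace:
    """Local Hilbert space of one protein.

    Parameters
    ----------
    dimension:
        Number of conformational basis states (>= 2).  The default two-level
        site has ``c0`` = ground/closed and ``c1`` = binding-competent
        conformation.
    basis_labels:
        Optional labels; default ``c0, c1, ...``.
    """

    dimension: int = 2
    basis_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.dimension < 2:
            raise ValueError(f"local dimension must be >= 2, got {self.dimension}")
        if not self.basis_labels:
            object.__setattr__(
                self, "basis_labels", tuple(f"c{k}" for k in range(self.dimension))
            )
        if len(self.basis_labels) != self.dimension:
            raise ValueError("basis_labels length must equal dimension")


@dataclass(frozen=True)
class CompositeSpace:
    """Ordered tensor product of local spaces over named sites.

    ``site_order[0]`` is the leftmost (most significant) Kronecker factor;
    every matrix in the package indexes the composite basis in this order.
    """

    site_order: tuple[str, ...]
    local_dims: tuple[int, ...]

    def __init__(self, site_order: Sequence[str], local_dims: Sequence[int] | int = 2):
        sites = tuple(site_order)
        if len(set(sites)) != len(sites):
            raise ValueError("duplicate sites in site_order")
        if not sites:
            raise ValueError("site_order must be nonempty")
        if isinstance(local_dims, int):
            dims = (local_dims,) * len(sites)
        else:
            dims = tuple(int(d) for d in local_dims)
        if len(dims) != len(sites):
            raise ValueError("local_dims length must match site_order")
        if any(d < 2 for d in dims):
            raise ValueError("all local dimensions must be >= 2")
        total = int(np.prod(dims))
        if total > MAX_TOTAL_DIM:
            raise DimensionCapError(
                f"total dimension {total} exceeds cap {MAX_TOTAL_DIM}; "
                "simulate on a pair or module subspace instead"
            )
        object.__setattr__(self, "site_order", sites)
        object.__setattr__(self, "local_dims", dims)

    @property
    def n_sites(self) -> int:
        return len(self.site_order)

    @property
    def total_dim(self) -> int:
        return int(np.prod(self.local_dims))

    def index_of(self, site: str) -> int:
        try:
            return self.site_order.index(site)
        except ValueError:
            raise KeyError(f"site {site!r} not in composite space") from None

    def dim_of(self, site: str) -> int:
        return self.local_dims[self.index_of(site)]

    def subspace(self, sites: Sequence[str]) -> "CompositeSpace":
        """Composite space over a subset of sites, preserving order."""
        keep = [s for s in self.site_order if s in set(sites)]
        if len(keep) != len(set(sites)):
            missing = set(sites) - set(self.site_order)
            raise KeyError(f"unknown sites {sorted(missing)}")
        dims = [self.dim_of(s) for s in keep]
        return CompositeSpace(keep, dims)


@dataclass
class PureState:
    """Normalized state vector on a composite space."""

    space: CompositeSpace
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        amp = np.asarray(self.amplitudes, dtype=complex).ravel()
        if amp.size != self.space.total_dim:
            raise ValueError(
                f"amplitude vector length {amp.size} != total_dim {self.space.total_dim}"
            )
        norm = float(np.vdot(amp, amp).real)
        if abs(norm - 1.0) > NORM_TOL:
            raise ValueError(f"state not normalized: |psi|^2 = {norm}")
        self.amplitudes = amp

    @classmethod
    def from_product(cls, space: CompositeSpace, locals_: Sequence[np.ndarray]) -> "PureState":
        """Tensor product of per-site vectors, normalizing the result."""
        if len(locals_) != space.n_sites:
            raise ValueError("need one local vector per site")
        vec = np.array([1.0 + 0j])
        for v in locals_:
            vec = np.kron(vec, np.asarray(v, dtype=complex).ravel())
        vec = vec / np.linalg.norm(vec)
        return cls(space, vec)

    @classmethod
    def basis_state(cls, space: CompositeSpace, occupations: Sequence[int]) -> "PureState":
        """Computational basis state |k_0 k_1 ...> with per-site levels."""
        locals_ = []
        for k, d in zip(occupations, space.local_dims, strict=True):
            v = np.zeros(d)
            v[k] = 1.0
            locals_.append(v)
        return cls.from_product(space, locals_)

    def to_density(self) -> "DensityMatrix":
        return DensityMatrix(self.space, np.outer(self.amplitudes, self.amplitudes.conj()))


@dataclass
class DensityMatrix:
    """Trace-one, Hermitian, PSD operator on a composite space."""

    space: CompositeSpace
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=complex)
        report = validate_density(m)
        if not report.valid:
            raise ValueError(f"invalid density matrix: {report.summary()}")
        if m.shape[0] != self.space.total_dim:
            raise ValueError(
                f"matrix dim {m.shape[0]} != space total_dim {self.space.total_dim}"
            )
        self.matrix = m

    @property
    def dim(self) -> int:
        return self.matrix.shape[0]

    def purity(self) -> float:
        return float(np.trace(self.matrix @ self.matrix).real)

    @classmethod
    def maximally_mixed(cls, space: CompositeSpace) -> "DensityMatrix":
        d = space.total_dim
        return cls(space, np.eye(d) / d)


@dataclass
class ValidationReport:
    """Outcome of density-matrix validation with worst violation magnitudes."""

    valid: bool
    hermiticity_violation: float
    trace_violation: float
    min_eigenvalue: float
    violations: list[str] = field(default_factory=list)

    def summary(self) -> str:
        return "; ".join(self.violations) if self.violations else "valid"


def validate_density(m: np.ndarray) -> ValidationReport:
    """Check Hermiticity, unit trace and positivity of a candidate density.

    Returns a report rather than raising, so integrators can attach the
    worst violation to their diagnostics.  Nothing is clipped.
    """
    m = np.asarray(m, dtype=complex)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        return ValidationReport(False, np.inf, np.inf, -np.inf, ["matrix not square"])
    herm = float(np.max(np.abs(m - m.conj().T)))
    tr = float(abs(np.trace(m) - 1.0))
    # eigvalsh on the Hermitian part; for valid input they coincide
    eigs = np.linalg.eigvalsh((m + m.conj().T) / 2)
    min_eig = float(eigs[0])
    violations = []
    if herm > HERMITICITY_TOL:
        violations.append(f"hermiticity violation {herm:.3e}")
    if tr > TRACE_TOL:
        violations.append(f"trace violation {tr:.3e}")
    if min_eig < -POSITIVITY_TOL:
        violations.append(f"negative eigenvalue {min_eig:.3e}")
    return ValidationReport(not violations, herm, tr, min_eig, violations)


def embed_local(
    op: np.ndarray, sites: str | Sequence[str], space: CompositeSpace
) -> np.ndarray:
    """Embed an operator on one or more sites into the full composite space.

    The operator acts as the identity on every other tensor factor; the
    Kronecker ordering follows ``space.site_order``.  Multi-site operators on
    non-adjacent factors are handled by permuting axes of the full tensor.
    """
    if isinstance(sites, str):
        sites = [sites]
    sites = list(sites)
    if len(set(sites)) != len(sites):
        raise ValueError("duplicate sites in embedding")
    positions = [space.index_of(s) for s in sites]
    op = np.asarray(op, dtype=complex)
    sub_dim = int(np.prod([space.local_dims[p] for p in positions]))
    if op.shape != (sub_dim, sub_dim):
        raise ValueError(
            f"operator shape {op.shape} does not match sites {sites} "
            f"(expected {(sub_dim, sub_dim)})"
        )
    n = space.n_sites
    dims = space.local_dims
    rest = [p for p in range(n) if p not in positions]
    rest_dim = int(np.prod([dims[p] for p in rest])) if rest else 1
    full = np.kron(op, np.eye(rest_dim))
    # full currently orders factors as sites + rest; permute back to site_order
    order = positions + rest
    perm = np.argsort(order)  # target position -> index in current order
    tensor = full.reshape([dims[p] for p in order] * 2)
    axes = list(perm) + [n + p for p in perm]
    tensor = tensor.transpose(axes)
    d = space.total_dim
    return np.ascontiguousarray(tensor.reshape(d, d))


def partial_trace(rho: DensityMatrix, keep: Iterable[str]) -> DensityMatrix:
    """Trace out every site not in ``keep``; marginal on the kept sites."""
    keep = list(keep)
    if not keep:
        raise ValueError("keep must be nonempty")
    keep_set = set(keep)
    space = rho.space
    for s in keep_set:
        space.index_of(s)  # raises KeyError on unknown sites
    if keep_set == set(space.site_order):
        return rho
    n = space.n_sites
    dims = list(space.local_dims)
    keep_pos = [p for p in range(n) if space.site_order[p] in keep_set]
    trace_pos = [p for p in range(n) if p not in keep_pos]
    tensor = rho.matrix.reshape(dims * 2)
    for p in sorted(trace_pos, reverse=True):
        tensor = np.trace(tensor, axis1=p, axis2=p + tensor.ndim // 2)
    sub = space.subspace([space.site_order[p] for p in keep_pos])
    d = sub.total_dim
    return DensityMatrix(sub, tensor.reshape(d, d))


def random_density(space: CompositeSpace, rng: np.random.Generator, rank: int | None = None) -> DensityMatrix:
    """Random density matrix from the Ginibre construction G G† / Tr."""
    d = space.total_dim
    r = rank or d
    g = rng.standard_normal((d, r)) + 1j * rng.standard_normal((d, r))
    m = g @ g.conj().T
    return DensityMatrix(space, m / np.trace(m))


def random_pure_state(space: CompositeSpace, rng: np.random.Generator) -> PureState:
    d = space.total_dim
    v = rng.standard_normal(d) + 1j * rng.standard_normal(d)
    return PureState(space, v / np.linalg.norm(v))


# ---------------------------------------------------------------------------
# JSON serialization (plain-text container; no binary formats)

def density_to_json(rho: DensityMatrix) -> str:
    return json.dumps(
        {
            "site_order": list(rho.space.site_order),
            "local_dims": list(rho.space.local_dims),
            "real": rho.matrix.real.ravel().tolist(),
            "imag": rho.matrix.imag.ravel().tolist(),
        }
    )


def density_from_json(text: str) -> DensityMatrix:
    obj = json.loads(text)
    space = CompositeSpace(obj["site_order"], obj["local_dims"])
    d = space.total_dim
    m = np.array(obj["real"], dtype=float).reshape(d, d) + 1j * np.array(
        obj["imag"], dtype=float
    ).reshape(d, d)
    return DensityMatrix(space, m)
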