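"""Quantum-information measures on network states.

Entropies are in bits by default (log base 2), so the hierarchical
entanglement bound's ``log d`` counts qubits; natural log is available via
:class:`EntropyOptions`.  The interaction entropy follows the model's
printed sign convention, which is the *negative* of conventional mutual
information; the ``conventional`` flag returns the sign-flipped quantity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .hilbert_space import DensityMatrix, partial_trace


@dataclass(frozen=True)
class EntropyOptions:
    """log base (2 = bits, e = nats) and the eigenvalue floor under which
    p log p is taken as 0 (handled by flooring, not by dropping eigenvalues,
    so downstream gradients stay deterministic)."""

    log_base: float = 2.0
    eigenvalue_floor: float = 1e-12

    def __post_init__(self) -> None:
        if self.eigenvalue_floor <= 0:
            raise ValueError("eigenvalue_floor must be > 0")
        if self.log_base not in (2.0, np.e):
            raise ValueError("log_base must be 2 or e")


DEFAULT_OPTS = EntropyOptions()


def von_neumann_entropy(rho: DensityMatrix, opts: EntropyOptions = DEFAULT_OPTS) -> float:
    """S(rho) = -Tr(rho log rho); 0 for pure states, log(D) when maximally mixed."""
    eigs = np.linalg.eigvalsh(rho.matrix)
    eigs = eigs[eigs > opts.eigenvalue_floor]
    if eigs.size == 0:
        return 0.0
    s = float(-np.sum(eigs * np.log(eigs)) / np.log(opts.log_base))
    return max(s, 0.0)


def interaction_entropy(
    rho_joint: DensityMatrix,
    opts: EntropyOptions = DEFAULT_OPTS,
    conventional: bool = False,
) -> float:
    """Interaction entropy of a two-protein joint state.

    Model convention: H(i,j) = S(rho_ij) - S(rho_i) - S(rho_j), i.e. the
    negative of the mutual information (zero for product states, -2 bits
    for a Bell pair).  With ``conventional=True`` the standard
    mutual-information sign is returned instead.
    """
    if rho_joint.space.n_sites != 2:
        raise ValueError(
            f"interaction entropy needs a two-site joint state, got "
            f"{rho_joint.space.n_sites} sites"
        )
    i, j = rho_joint.space.site_order
    s_ij = von_neumann_entropy(rho_joint, opts)
    s_i = von_neumann_entropy(partial_trace(rho_joint, [i]), opts)
    s_j = von_neumann_entropy(partial_trace(rho_joint, [j]), opts)
    h = s_ij - s_i - s_j
    return -h if conventional else h


def l1_coherence(rho: DensityMatrix) -> float:
    """Sum of absolute off-diagonal elements in the computational basis.

    Basis-dependent by construction: a unitary rotation generally changes it.
    """
    m = np.abs(rho.matrix)
    return float(m.sum() - np.trace(m))


def entanglement_entropy(
    rho: DensityMatrix,
    partition: tuple[Sequence[str], Sequence[str]],
    opts: EntropyOptions = DEFAULT_OPTS,
) -> float:
    """Correlation measure S(A:B) = S(rho_A) + S(rho_B) - S(rho_AB).

    Nonnegative by subadditivity; zero for product states; for a globally
    pure state equals 2 S(rho_A).
    """
    a, b = list(partition[0]), list(partition[1])
    sites = set(rho.space.site_order)
    if not a or not b:
        raise ValueError("both partition blocks must be nonempty")
    if set(a) & set(b):
        raise ValueError("partition blocks must be disjoint")
    if set(a) | set(b) != sites:
        raise ValueError("partition must cover all sites of the state")
    s_a = von_neumann_entropy(partial_trace(rho, a), opts)
    s_b = von_neumann_entropy(partial_trace(rho, b), opts)
    s_ab = von_neumann_entropy(rho, opts)
    return max(s_a + s_b - s_ab, 0.0)


@dataclass(frozen=True)
class CooperativityParams:
    """Cooperativity strength alpha and the binding-site bipartition (A, B)."""

    alpha: float
    site_partition: tuple[tuple[str, ...], tuple[str, ...]]

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        a, b = self.site_partition
        if not a or not b or set(a) & set(b):
            raise ValueError("site partition blocks must be disjoint and nonempty")


def cooperativity_factor(s_ab: float, alpha: float) -> float:
    """Cooperative binding enhancement eta = 1 + alpha * S(A:B).

    eta = 1 (independent binding) when either the entanglement between the
    binding sites or the cooperativity strength vanishes.
    """
    if s_ab < 0 or alpha < 0:
        raise ValueError("S(A:B) and alpha must both be >= 0")
    return 1.0 + alpha * s_ab


def cooperative_probability(
    rho: DensityMatrix, params: CooperativityParams, base_probability: float,
    opts: EntropyOptions = DEFAULT_OPTS,
) -> float:
    """Base interaction probability scaled by the cooperativity factor,
    capped at 1."""
    s = entanglement_entropy(rho, params.site_partition, opts)
    return min(1.0, base_probability * cooperativity_factor(s, params.alpha))


@dataclass(frozen=True)
class ModulePartition:
    """Exact partition of the sites into modules, with local dimension d."""

    modules: tuple[tuple[str, ...], ...]
    local_dim: int = 2

    def __post_init__(self) -> None:
        all_sites = [s for m in self.modules for s in m]
        if len(all_sites) != len(set(all_sites)):
            raise ValueError("modules overlap")
        if any(not m for m in self.modules):
            raise ValueError("empty module")
        if self.local_dim < 2:
            raise ValueError("local_dim must be >= 2")

    @property
    def sites(self) -> set[str]:
        return {s for m in self.modules for s in m}


@dataclass
class EntanglementBound:
    """Right-hand side of the hierarchical modular entanglement bound."""

    pairwise: dict[tuple[int, int], float]
    intra: dict[int, float]
    total: float


def entanglement_bound(
    partition: ModulePartition,
    e_intra: dict[int, float] | None = None,
    opts: EntropyOptions = DEFAULT_OPTS,
) -> EntanglementBound:
    """Hierarchical bound: E_inter(m,n) <= min{|V_m|, |V_n|} log d per module
    pair, summed with any supplied intra-module entanglements E_intra(m)."""
    log_d = np.log(partition.local_dim) / np.log(opts.log_base)
    pairwise = {}
    mods = partition.modules
    for m in range(len(mods)):
        for n in range(m + 1, len(mods)):
            pairwise[(m, n)] = min(len(mods[m]), len(mods[n])) * log_d
    intra = dict(e_intra or {m: 0.0 for m in range(len(mods))})
    total = sum(intra.values()) + sum(pairwise.values())
    return EntanglementBound(pairwise, intra, total)


@dataclass
class BoundCheck:
    holds: bool
    worst_margin: float
    details: dict[tuple[int, int], dict[str, float]]


def check_bound(
    rho: DensityMatrix,
    partition: ModulePartition,
    opts: EntropyOptions = DEFAULT_OPTS,
) -> BoundCheck:
    """Check the inter-module bound across every module bipartition.

    For each module pair (m, n), the state is reduced to the union of the
    two modules and compared against min{|V_m|, |V_n|} log d in two
    readings: the entanglement-entropy reading S(rho_m) of the reduced
    state (which provably satisfies the bound and is the one asserted) and
    the mutual-information reading S(m:n) (reported for reference — it can
    reach twice the bound for maximally entangled states).
    """
    if partition.sites != set(rho.space.site_order):
        raise ValueError("partition must cover exactly the state's sites")
    bound = entanglement_bound(partition, opts=opts)
    mods = partition.modules
    worst = np.inf
    holds = True
    details: dict[tuple[int, int], dict[str, float]] = {}
    for (m, n), b in bound.pairwise.items():
        joint = partial_trace(rho, list(mods[m]) + list(mods[n]))
        rho_m = partial_trace(joint, list(mods[m]))
        s_m = von_neumann_entropy(rho_m, opts)
        mi = entanglement_entropy(joint, (mods[m], mods[n]), opts)
        margin = b - s_m
        details[(m, n)] = {
            "bound": b,
            "entanglement_entropy": s_m,
            "mutual_information": mi,
            "margin": margin,
        }
        worst = min(worst, margin)
        if margin < -1e-9:
            holds = False
    if not details:
        worst = 0.0
    return BoundCheck(holds, float(worst), details)
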