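"""Classical graph layer: weighted protein interaction graphs.

Loads and saves plain-text edge lists, computes classical spectral objects,
and generates synthetic modular (planted-partition) networks with held-out
positive/negative candidate pairs and correlated node features for testing
the quantum scoring machinery without external interaction databases.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd


class EdgeListParseError(ValueError):
    """Malformed edge-list line; message names the offending line number."""


@dataclass
class ProteinGraph:
    """Weighted undirected protein interaction graph.

    Vertex order is canonical (first-appearance from file, construction
    order otherwise); every matrix produced downstream indexes rows and
    columns by this order, which also fixes tensor-factor ordering in the
    quantum layer.

    Attributes
    ----------
    vertices:
        Ordered unique protein identifiers.
    edges:
        Unordered vertex pairs stored as sorted-by-vertex-order tuples.
    weights:
        Edge -> positive interaction strength.
    features:
        Optional per-vertex real feature vectors (shared length).
    modules:
        Optional per-vertex integer module labels.
    """

    vertices: list[str]
    weights: dict[tuple[str, str], float] = field(default_factory=dict)
    features: dict[str, np.ndarray] | None = None
    modules: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if len(set(self.vertices)) != len(self.vertices):
            raise ValueError("duplicate vertex identifiers")
        vset = set(self.vertices)
        canon = {}
        for (a, b), w in self.weights.items():
            if a == b:
                raise ValueError(f"self-loop on vertex {a!r}")
            if a not in vset or b not in vset:
                raise ValueError(f"edge ({a!r}, {b!r}) references unknown vertex")
            if not w > 0:
                raise ValueError(f"edge ({a!r}, {b!r}) has nonpositive weight {w}")
            key = self._canon_edge(a, b)
            if key in canon and abs(canon[key] - w) > 0:
                raise ValueError(
                    f"conflicting weights for edge {key}: {canon[key]} vs {w}"
                )
            canon[key] = float(w)
        self.weights = canon
        if self.features is not None:
            lengths = {len(v) for v in self.features.values()}
            if len(lengths) > 1:
                raise ValueError(f"feature vectors have mixed lengths {sorted(lengths)}")
            self.features = {k: np.asarray(v, dtype=float) for k, v in self.features.items()}

    def _canon_edge(self, a: str, b: str) -> tuple[str, str]:
        ia, ib = self.vertices.index(a), self.vertices.index(b)
        return (a, b) if ia < ib else (b, a)

    @property
    def n(self) -> int:
        return len(self.vertices)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return list(self.weights)

    def weight(self, a: str, b: str) -> float:
        return self.weights.get(self._canon_edge(a, b), 0.0)

    def has_edge(self, a: str, b: str) -> bool:
        return self._canon_edge(a, b) in self.weights

    def neighbors(self, v: str) -> list[str]:
        out = []
        for a, b in self.weights:
            if a == v:
                out.append(b)
            elif b == v:
                out.append(a)
        return out

    def degree(self, v: str, weighted: bool = True) -> float:
        return sum(
            w if weighted else 1
            for (a, b), w in self.weights.items()
            if v in (a, b)
        )

    def max_degree(self) -> float:
        return max((self.degree(v, weighted=False) for v in self.vertices), default=0)

    def adjacency(self) -> np.ndarray:
        idx = {v: i for i, v in enumerate(self.vertices)}
        a = np.zeros((self.n, self.n))
        for (u, v), w in self.weights.items():
            a[idx[u], idx[v]] = w
            a[idx[v], idx[u]] = w
        return a

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.vertices)
        for (u, v), w in self.weights.items():
            g.add_edge(u, v, weight=w)
        return g

    def subgraph(self, vertices: Sequence[str]) -> "ProteinGraph":
        vset = set(vertices)
        keep = [v for v in self.vertices if v in vset]
        weights = {e: w for e, w in self.weights.items() if e[0] in vset and e[1] in vset}
        feats = (
            {v: self.features[v] for v in keep if v in self.features}
            if self.features
            else None
        )
        mods = {v: self.modules[v] for v in keep} if self.modules else None
        return ProteinGraph(keep, weights, feats or None, mods)


@dataclass
class MultilayerNetwork:
    """Ordered layers of interaction graphs over one shared vertex list."""

    layers: list[ProteinGraph]
    layer_names: list[str]

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("need at least one layer")
        if len(self.layers) != len(self.layer_names):
            raise ValueError("layer_names length mismatch")
        v0 = self.layers[0].vertices
        for g in self.layers[1:]:
            if g.vertices != v0:
                raise ValueError("all layers must share one vertex list")


def read_edge_list(path: str | Path, directed_flag: bool = False) -> ProteinGraph:
    """Parse a whitespace/TSV edge list: ``node_a node_b [weight]`` per line.

    Lines starting with ``#`` are comments.  A missing third field defaults
    the weight to 1.0.  The graph is undirected; ``directed_flag`` exists so
    callers can flag directed input, which is symmetrized with an error on
    conflicting reciprocal weights.
    """
    path = Path(path)
    vertices: list[str] = []
    seen = set()
    weights: dict[tuple[str, str], float] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) not in (2, 3):
                raise EdgeListParseError(
                    f"{path}:{lineno}: expected 2 or 3 fields, got {len(parts)}"
                )
            a, b = parts[0], parts[1]
            if a == b:
                raise EdgeListParseError(f"{path}:{lineno}: self-loop on {a!r}")
            if len(parts) == 3:
                try:
                    w = float(parts[2])
                except ValueError:
                    raise EdgeListParseError(
                        f"{path}:{lineno}: weight {parts[2]!r} is not a number"
                    ) from None
                if not w > 0:
                    raise EdgeListParseError(
                        f"{path}:{lineno}: nonpositive weight {w}"
                    )
            else:
                w = 1.0
            for v in (a, b):
                if v not in seen:
                    seen.add(v)
                    vertices.append(v)
            key = (a, b) if vertices.index(a) < vertices.index(b) else (b, a)
            if key in weights and weights[key] != w:
                raise EdgeListParseError(
                    f"{path}:{lineno}: conflicting weight for edge {key}: "
                    f"{weights[key]} vs {w}"
                )
            weights[key] = w
    return ProteinGraph(vertices, weights)


def read_features(path: str | Path) -> dict[str, np.ndarray]:
    """Read a per-vertex feature table (TSV with header: id, f1..fd)."""
    df = pd.read_csv(path, sep="\t")
    ids = df.iloc[:, 0].astype(str)
    mat = df.iloc[:, 1:].to_numpy(dtype=float)
    return {i: mat[k] for k, i in enumerate(ids)}


def read_modules(path: str | Path) -> dict[str, int]:
    """Read a module-assignment table (TSV: vertex, module id; no header)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    return {str(r[0]): int(r[1]) for r in df.itertuples(index=False)}


def classical_laplacian(g: ProteinGraph) -> np.ndarray:
    """Weighted graph Laplacian L = D - A indexed by canonical vertex order."""
    a = g.adjacency()
    return np.diag(a.sum(axis=1)) - a


def connected_components(g: ProteinGraph) -> int:
    return nx.number_connected_components(g.to_networkx())


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-partition generator.

    Defaults define the desk-scale study conditions used throughout the
    test surface: 24 proteins in 3 modules with assortative wiring
    (p_intra=0.6 >> p_inter=0.05) and module-correlated features with
    moderate noise.
    """

    n_vertices: int = 24
    n_modules: int = 3
    p_intra: float = 0.6
    p_inter: float = 0.05
    feature_dim: int = 8
    feature_noise: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_modules > self.n_vertices:
            raise ValueError("n_modules cannot exceed n_vertices")
        if not (0 <= self.p_inter <= self.p_intra <= 1):
            raise ValueError("require 0 <= p_inter <= p_intra <= 1 (assortative)")
        if self.feature_dim < 1 or self.feature_noise < 0:
            raise ValueError("feature_dim >= 1 and feature_noise >= 0 required")


@dataclass
class SyntheticNetwork:
    graph: ProteinGraph
    positives: list[tuple[str, str]]  # held-out intra-module non-edges
    negatives: list[tuple[str, str]]  # sampled inter-module non-edges


def generate_synthetic_network(
    spec: SyntheticSpec,
    n_positives: int = 20,
    n_negatives: int = 20,
) -> SyntheticNetwork:
    """Planted-partition graph with features and held-out candidate pairs.

    Vertices ``P000..`` are assigned to modules round-robin.  Edges are
    drawn independently with probability ``p_intra`` within modules and
    ``p_inter`` across; weights ~ Uniform(0.5, 1.5).  Each vertex's feature
    vector is its module centroid (standard normal draw per module) plus
    isotropic Gaussian noise of scale ``feature_noise``.  Positives are a
    sample of intra-module non-edges (structurally plausible missing links);
    negatives a sample of inter-module non-edges.  Fully reproducible given
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_vertices
    vertices = [f"P{i:03d}" for i in range(n)]
    modules = {v: i % spec.n_modules for i, v in enumerate(vertices)}

    centroids = rng.standard_normal((spec.n_modules, spec.feature_dim))
    features = {
        v: centroids[modules[v]] + spec.feature_noise * rng.standard_normal(spec.feature_dim)
        for v in vertices
    }

    weights: dict[tuple[str, str], float] = {}
    intra_non_edges: list[tuple[str, str]] = []
    inter_non_edges: list[tuple[str, str]] = []
    for a, b in itertools.combinations(vertices, 2):
        intra = modules[a] == modules[b]
        p = spec.p_intra if intra else spec.p_inter
        if rng.random() < p:
            weights[(a, b)] = float(rng.uniform(0.5, 1.5))
        elif intra:
            intra_non_edges.append((a, b))
        else:
            inter_non_edges.append((a, b))

    if not intra_non_edges or not inter_non_edges:
        raise ValueError(
            "generator produced empty positive or negative candidate set; "
            "adjust n_vertices/p_intra/p_inter"
        )
    k_pos = min(n_positives, len(intra_non_edges))
    k_neg = min(n_negatives, len(inter_non_edges))
    pos_idx = rng.choice(len(intra_non_edges), size=k_pos, replace=False)
    neg_idx = rng.choice(len(inter_non_edges), size=k_neg, replace=False)
    positives = [intra_non_edges[i] for i in sorted(pos_idx)]
    negatives = [inter_non_edges[i] for i in sorted(neg_idx)]

    graph = ProteinGraph(vertices, weights, features, modules)
    return SyntheticNetwork(graph, positives, negatives)


def write_predictions(
    pairs: Sequence[tuple[str, str, float, int]], path: str | Path
) -> None:
    """Write ranked predictions as TSV.

    Columns: protein_a, protein_b, p_interaction, predicted.  Rows sorted by
    descending probability, ties broken lexicographically by the pair.
    """
    for a, b, p, _lab in pairs:
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"probability {p} for pair ({a}, {b}) outside [0, 1]")
    ordered = sorted(pairs, key=lambda r: (-r[2], r[0], r[1]))
    df = pd.DataFrame(ordered, columns=["protein_a", "protein_b", "p_interaction", "predicted"])
    df.to_csv(path, sep="\t", index=False)


def write_edge_list(g: ProteinGraph, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("# protein_a\tprotein_b\tweight\n")
        for (a, b), w in sorted(g.weights.items()):
            fh.write(f"{a}\t{b}\t{w:.6g}\n")


def write_features(features: Mapping[str, np.ndarray], path: str | Path) -> None:
    rows = {k: list(v) for k, v in features.items()}
    d = len(next(iter(rows.values())))
    df = pd.DataFrame.from_dict(rows, orient="index", columns=[f"f{i}" for i in range(d)])
    df.index.name = "protein"
    df.to_csv(path, sep="\t")


def write_modules(modules: Mapping[str, int], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for v, m in modules.items():
            fh.write(f"{v}\t{m}\n")
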