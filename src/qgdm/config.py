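"""Run configuration and the end-to-end scoring pipeline.

A YAML config parameterizes the reconstructed prediction pipeline
(generate/load -> build operators -> evolve -> score -> optional train ->
report).  Validation happens at load time; CLI flags override config
values.  Identical config + seed yields byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import metrics as _metrics
from .network_core import (
    ProteinGraph,
    SyntheticSpec,
    generate_synthetic_network,
    read_edge_list,
    read_features,
    read_modules,
    write_predictions,
)
from .ppi_scoring import DynamicsConfig, MeasurementSpec, score_all_pairs

log = logging.getLogger("qgdm")


@dataclass
class RunConfig:
    """Resolved pipeline configuration (flat; see from_yaml for sections)."""

    # input paths; all None -> synthetic generation
    graph_path: str | None = None
    features_path: str | None = None
    modules_path: str | None = None
    pairs_path: str | None = None
    # synthetic generation
    synthetic: SyntheticSpec = field(default_factory=SyntheticSpec)
    # physics
    local_dim: int = 2
    omega_default: float = 0.5
    hbar: float = 1.0
    coupling: float = 1.0
    rate_dephasing: float = 0.1
    rate_binding: float = 0.05
    rate_thermal: float = 0.01
    # measurement
    lambda_decay: float = 1.0
    horizon: float = 2.0
    grid_step: float = 0.05
    threshold: float = 0.5
    # outputs
    predictions_path: str = "predictions.tsv"
    report_path: str = "report.json"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.local_dim != 2:
            raise ValueError("the scoring pipeline currently requires local_dim = 2")
        for name in ("rate_dephasing", "rate_binding", "rate_thermal"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.lambda_decay <= 0 or self.horizon <= 0 or self.grid_step <= 0:
            raise ValueError("lambda_decay, horizon and grid_step must be > 0")
        if not (0.0 <= self.threshold <= 1.0):
            raise ValueError("threshold must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        flat: dict[str, Any] = {}
        for key, value in raw.items():
            if key == "synthetic" and isinstance(value, dict):
                flat["synthetic"] = SyntheticSpec(**value)
            elif isinstance(value, dict):
                # sectioned layout: {inputs: {...}, physics: {...}, ...}
                for k2, v2 in value.items():
                    if k2 not in known:
                        raise ValueError(f"unknown config key {key}.{k2}")
                    flat[k2] = v2
            elif key in known:
                flat[key] = value
            else:
                raise ValueError(f"unknown config key {key}")
        flat.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**flat)

    def dynamics(self) -> DynamicsConfig:
        return DynamicsConfig(
            coupling=self.coupling,
            omega_default=self.omega_default,
            hbar=self.hbar,
            rate_dephasing=self.rate_dephasing,
            rate_binding=self.rate_binding,
            rate_thermal=self.rate_thermal,
        )

    def measurement(self) -> MeasurementSpec:
        return MeasurementSpec(
            lambda_decay=self.lambda_decay,
            horizon=self.horizon,
            grid_step=self.grid_step,
        )


def _load_inputs(cfg: RunConfig):
    if cfg.graph_path is None:
        spec = replace(cfg.synthetic, seed=cfg.seed)
        net = generate_synthetic_network(spec)
        candidates = net.positives + net.negatives
        labels = [1] * len(net.positives) + [0] * len(net.negatives)
        return net.graph, candidates, labels
    graph = read_edge_list(cfg.graph_path)
    if cfg.features_path:
        p = Path(cfg.features_path)
        if not p.exists():
            raise FileNotFoundError(f"features file not found: {p}")
        graph.features = read_features(p)
    if cfg.modules_path:
        graph.modules = read_modules(cfg.modules_path)
    if cfg.pairs_path:
        candidates, labels = read_candidate_pairs(cfg.pairs_path)
    else:
        # all non-edges are candidates; no labels
        candidates = [
            (a, b)
            for i, a in enumerate(graph.vertices)
            for b in graph.vertices[i + 1 :]
            if not graph.has_edge(a, b)
        ]
        labels = None
    return graph, candidates, labels


def read_candidate_pairs(path: str | Path):
    """TSV of candidate pairs: protein_a, protein_b[, label]; # comments."""
    candidates, labels = [], []
    have_labels = False
    with Path(path).open() as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) not in (2, 3):
                raise ValueError(f"{path}:{lineno}: expected 2 or 3 fields")
            candidates.append((parts[0], parts[1]))
            if len(parts) == 3:
                labels.append(int(parts[2]))
                have_labels = True
    if have_labels and len(labels) != len(candidates):
        raise ValueError(f"{path}: labels present for only some pairs")
    return candidates, (labels if have_labels else None)


def run_pipeline(cfg: RunConfig) -> dict[str, Any]:
    """Execute the full prediction pipeline and write predictions + report.

    Returns the metrics report (also written as JSON).  Every stage logs
    its parameters; the resolved config and seed go into the report for
    reproducibility.
    """
    log.info("resolved config: %s", asdict(cfg))
    graph, candidates, labels = _load_inputs(cfg)
    log.info(
        "graph: %d vertices, %d edges, %d candidate pairs",
        graph.n, len(graph.edges), len(candidates),
    )
    preds = score_all_pairs(
        graph, candidates, cfg.dynamics(), cfg.measurement(), cfg.threshold
    )
    rows = [(p.pair[0], p.pair[1], p.probability, p.label) for p in preds]
    write_predictions(rows, cfg.predictions_path)
    log.info("wrote %d predictions to %s", len(rows), cfg.predictions_path)

    report: dict[str, Any] = {
        "n_vertices": graph.n,
        "n_edges": len(graph.edges),
        "n_candidates": len(candidates),
        "threshold": cfg.threshold,
        "seed": cfg.seed,
        "config": _jsonable(asdict(cfg)),
    }
    if labels is not None:
        scores = np.array([p.probability for p in preds])
        labs = np.array(labels)
        tm = _metrics.threshold_metrics(labs, scores, cfg.threshold)
        report["metrics"] = {
            "roc_auc": _metrics.roc_auc(labs, scores),
            "precision": tm.precision,
            "recall": tm.recall,
            "f1": tm.f1,
            "accuracy": tm.accuracy,
        }
        log.info("metrics: %s", report["metrics"])
    with Path(cfg.report_path).open("w") as fh:
        json.dump(report, fh, indent=2)
    return report


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
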