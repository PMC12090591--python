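"""End-to-end reproducible runs: configuration, staging, exports, manifest.

``run_pipeline`` chains descriptives -> network estimation -> centrality ->
(optionally) bootstrap accuracy/difference tests and case-dropping
stability, writing every table as CSV, the network as GraphML + edge list,
and a machine-readable JSON manifest (config hash, seeds, versions, stage
wall times, output inventory).  Numeric exports are the contract; figure
rendering is deliberately out of scope.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .centrality import centrality_table
from .datasets import SymptomDataset
from .descriptives import plan_sample_size, summarize_symptoms
from .network import WeightedNetwork, estimate_network
from .stability import (
    DEFAULT_DROP_GRID,
    bootstrap_network,
    case_dropping,
    edge_difference_test,
    node_difference_test,
)
from .synthetic import generate_dataset, study_true_network, table2_marginals

ALPHA_DEFAULT = 0.05


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for one pipeline run.

    ``input_csv`` loads an existing score matrix; leaving it ``None``
    simulates a study-scale synthetic dataset (p = 19, published marginals)
    with ``synthetic_n`` patients instead.  Unknown keys in a config file
    are rejected rather than silently ignored.
    """

    input_csv: str | None = None
    synthetic_n: int = 367
    gamma: float = 0.5
    n_lambda: int = 100
    min_ratio: float = 0.01
    edge_threshold: float | None = None  # None = plain estimator; >0 prunes weak edges
    bootstrap_B: int = 1000
    stability_B: int = 1000
    drop_grid: tuple[float, ...] = DEFAULT_DROP_GRID
    alpha: float = ALPHA_DEFAULT
    seed: int = 0
    out_dir: str = "results/run"
    run_bootstrap: bool = True
    run_stability: bool = True
    run_layout: bool = True
    stability_indices: tuple[str, ...] = ("strength", "expected_influence")

    def __post_init__(self) -> None:
        if not (0 <= self.gamma <= 1):
            raise ValueError("gamma must lie in [0, 1]")
        if self.n_lambda < 2:
            raise ValueError("n_lambda must be >= 2")
        if not (0 < self.min_ratio < 1):
            raise ValueError("min_ratio must lie in (0, 1)")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.bootstrap_B < 100 or self.stability_B < 50:
            raise ValueError("bootstrap_B >= 100 and stability_B >= 50 required")
        if self.synthetic_n < 2:
            raise ValueError("synthetic_n must be >= 2")
        if any(not (0 < q < 1) for q in self.drop_grid):
            raise ValueError("drop proportions must lie in (0, 1)")
        object.__setattr__(self, "drop_grid", tuple(float(q) for q in self.drop_grid))
        object.__setattr__(self, "stability_indices", tuple(self.stability_indices))

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        raw = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
        if not isinstance(raw, dict):
            raise ValueError("config file must contain a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("drop_grid", "stability_indices"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class LayoutCoordinates:
    """Deterministic force-directed node positions for plotting."""

    x: np.ndarray
    y: np.ndarray
    labels: tuple[str, ...]
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"node": list(self.labels), "x": self.x, "y": self.y})


def compute_layout(net: WeightedNetwork, seed: int = 0, iterations: int = 200) -> LayoutCoordinates:
    """Fruchterman-Reingold embedding with |weight| as attraction.

    Strongly tied nodes are pulled together; deterministic given the seed.
    """
    g = net.to_graph()
    pos = nx.spring_layout(g, weight="abs_weight", seed=seed, iterations=iterations)
    x = np.array([pos[lab][0] for lab in net.labels])
    y = np.array([pos[lab][1] for lab in net.labels])
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise RuntimeError("layout produced non-finite coordinates")
    return LayoutCoordinates(x, y, net.labels, seed)


def _float_fmt(df: pd.DataFrame) -> pd.DataFrame:
    # pin the CSV dialect: plain '.' decimals, stable float repr
    return df


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the manifest dictionary.

    Any stage error aborts with the stage name attached; files written
    before the failure are flagged as partial in the raised error's context.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "symptomnet",
        "version": __version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "alpha": config.alpha,
        "stages": {},
        "outputs": [],
        "network_input": "ebic_glasso_partial_correlations",
    }
    written: list[str] = []

    def _write_csv(df: pd.DataFrame, name: str) -> None:
        path = out / name
        _float_fmt(df).to_csv(path, index=False)
        written.append(name)

    def _stage(name: str):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                manifest["stages"][name] = {
                    "seconds": round(time.perf_counter() - self_inner.t0, 3),
                    "ok": exc_type is None,
                }
                if exc_type is not None:
                    manifest["outputs"] = written
                    manifest["partial"] = True
                    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
                    raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
                return False

        return _Timer()

    with _stage("load_or_simulate"):
        if config.input_csv is not None:
            data = SymptomDataset.from_csv(config.input_csv)
        else:
            truth = study_true_network()
            data = generate_dataset(truth, table2_marginals(warn=False), config.synthetic_n, config.seed)
            truth.to_json(out / "true_network.json", seed=config.seed)
            written.append("true_network.json")
            data.to_csv(out / "scores.csv")
            written.append("scores.csv")
        manifest["n"], manifest["p"] = data.n, data.p

    with _stage("descriptives"):
        _write_csv(summarize_symptoms(data), "symptom_summary.csv")
        plan = plan_sample_size(data.p)
        (out / "sample_size_plan.json").write_text(json.dumps(asdict(plan), indent=2))
        written.append("sample_size_plan.json")

    est_kwargs = {
        "gamma": config.gamma,
        "n_lambda": config.n_lambda,
        "min_ratio": config.min_ratio,
        "edge_threshold": config.edge_threshold,
    }

    with _stage("network"):
        net = estimate_network(data, **est_kwargs)
        _write_csv(net.edge_list(), "edges.csv")
        net.to_graphml(out / "network.graphml")
        written.append("network.graphml")
        (out / "network_selection.json").write_text(
            json.dumps(
                {
                    "gamma": net.ebic_gamma,
                    "lambda_selected": net.lambda_selected,
                    "edge_count": net.edge_count,
                    "lambda_path": list(net.lambdas),
                    "ebic": list(net.ebics),
                },
                indent=2,
            )
        )
        written.append("network_selection.json")

    with _stage("centrality"):
        _write_csv(centrality_table(net), "centrality.csv")

    if config.run_layout:
        with _stage("layout"):
            _write_csv(compute_layout(net, seed=config.seed).to_frame(), "layout.csv")

    if config.run_bootstrap:
        with _stage("bootstrap"):
            boot = bootstrap_network(
                data, B=config.bootstrap_B, seed=config.seed, estimator_kwargs=est_kwargs
            )
            _write_csv(boot.edge_ci(), "edge_ci.csv")
            edge_diff = edge_difference_test(boot, alpha=config.alpha)
            edge_diff.to_frame().to_csv(out / "edge_difference.csv")
            written.append("edge_difference.csv")
            node_diff = node_difference_test(boot, "expected_influence", alpha=config.alpha)
            node_diff.to_frame().to_csv(out / "node_difference.csv")
            written.append("node_difference.csv")

    if config.run_stability:
        with _stage("stability"):
            stab = case_dropping(
                data,
                index=config.stability_indices,
                drop_grid=config.drop_grid,
                B=config.stability_B,
                seed=config.seed,
                estimator_kwargs=est_kwargs,
            )
            frames = []
            report = {}
            for ix, res in stab.items():
                df = res.to_frame()
                df.insert(0, "index", ix)
                frames.append(df)
                report[ix] = {
                    "cs_coefficient": res.cs_coefficient,
                    "criterion_correlation": res.criterion_correlation,
                    "confidence": res.confidence,
                    "drop_proportions": list(res.drop_proportions),
                    "mean_correlation": res.summary()["mean_correlation"].tolist(),
                }
            _write_csv(pd.concat(frames, ignore_index=True), "stability.csv")
            (out / "stability_report.json").write_text(json.dumps(report, indent=2))
            written.append("stability_report.json")

    manifest["outputs"] = sorted(written)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
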