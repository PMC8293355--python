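"""Orchestration of the single-layer, multilayer and sensitivity analyses.

A :class:`RunConfig` fixes the input (a named preset + seed, or a CSV), the
age handling mode, estimator settings and bootstrap settings; the run
functions execute the estimation chain

    pairwise Pearson -> PSD repair -> EBIC graphical lasso
        -> edge summary -> (strength | walktrap -> modularity -> bridge strength)
        -> case-drop bootstrap -> CS coefficient

and return a :class:`RunReport` whose every number is regenerable from the
config and seed. Reports serialize to JSON + CSV only.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .centrality import BridgeTable, CentralityTable, bridge_strength, strength
from .community import CommunityPartition, walktrap
from .estimation import (
    EdgeSummary,
    PcorNetwork,
    ebic_glasso,
    edge_list,
    edge_summary,
    nearest_psd,
    pairwise_pearson,
    to_graphml,
    unregularized_network,
)
from .presets import PRESET_NAMES, build_preset
from .simulate import MissingnessSpec, MultilayerDataset, mask_outliers, read_dataset
from .simulate import simulate as simulate_dataset
from .stability import StabilityReport, case_drop_bootstrap

__all__ = [
    "RunConfig",
    "RunReport",
    "load_data",
    "estimate_network",
    "strength_statistic",
    "bridge_statistic",
    "run_single_layer",
    "run_multilayer",
    "run_sensitivity",
]

AGE_MODES = ("include_node", "regress_out", "exclude")
ESTIMATORS = ("glasso", "unregularized")
REPORT_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Configuration of one analysis run. Exactly one input source is allowed."""

    preset: str | None = None
    input_csv: str | None = None
    n: int | None = None
    seed: int = 1
    missingness: str = "none"  # 'none' | 'calm'
    age_mode: str = "include_node"
    estimator: str = "glasso"
    gamma: float = 0.5
    path_size: int = 100
    min_ratio: float = 0.01
    bootstrap_B: int = 0  # 0 disables stability bootstrapping
    drop_fractions: list[float] | None = None
    bootstrap_path_size: int = 25
    outlier_k: float | None = None
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if (self.preset is None) == (self.input_csv is None):
            raise ValueError("exactly one of preset or input_csv must be set")
        if self.preset is not None:
            if self.preset not in PRESET_NAMES:
                raise ValueError(
                    f"unknown preset {self.preset!r}; available: {PRESET_NAMES}"
                )
            if self.n is None:
                raise ValueError("n is required when simulating from a preset")
        if self.age_mode not in AGE_MODES:
            raise ValueError(f"age_mode must be one of {AGE_MODES}, got {self.age_mode!r}")
        if self.estimator not in ESTIMATORS:
            raise ValueError(f"estimator must be one of {ESTIMATORS}")
        if self.missingness not in ("none", "calm"):
            raise ValueError("missingness must be 'none' or 'calm'")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")
        if not 0 < self.min_ratio < 1:
            raise ValueError("min_ratio must lie in (0, 1)")
        if self.outlier_k is not None and not self.outlier_k > 0:
            raise ValueError("outlier_k must be positive when set")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        payload = json.loads(Path(path).read_text())
        payload.pop("layers", None)  # handled by the caller
        return cls(**payload)


def load_data(config: RunConfig) -> MultilayerDataset:
    if config.preset is not None:
        ggm = build_preset(config.preset)
        spec = MissingnessSpec.calm() if config.missingness == "calm" else MissingnessSpec.none()
        return simulate_dataset(ggm, n=config.n, spec=spec, seed=config.seed)
    return read_dataset(config.input_csv)


def _apply_age_mode(data: MultilayerDataset, age_mode: str) -> MultilayerDataset:
    age_cols = data.layer_columns("age")
    if not age_cols or age_mode == "include_node":
        return data
    if age_mode == "exclude":
        keep = [c for c in data.node_labels if c not in age_cols]
        return data.select(keep)
    # regress_out: residualize every other column on age, pairwise complete
    age = data.values[age_cols[0]]
    df = data.values.copy()
    for col in df.columns:
        if col in age_cols:
            continue
        both = df[col].notna() & age.notna()
        if both.sum() < 3 or age[both].std(ddof=1) == 0:
            continue
        slope = np.cov(df.loc[both, col], age[both])[0, 1] / age[both].var(ddof=1)
        intercept = df.loc[both, col].mean() - slope * age[both].mean()
        df[col] = df[col] - (intercept + slope * age)
    keep = [c for c in df.columns if c not in age_cols]
    return MultilayerDataset(
        values=df[keep], layer_of={c: data.layer_of[c] for c in keep}, meta=dict(data.meta)
    )


def _select_layers(data: MultilayerDataset, layers: list[str]) -> MultilayerDataset:
    available = sorted(set(data.layer_of.values()) - {"age"})
    bad = [t for t in layers if t not in available]
    if bad:
        raise ValueError(f"layer(s) {bad} not in data; available layers: {available}")
    cols = [c for c in data.node_labels if data.layer_of[c] in list(layers) + ["age"]]
    return data.select(cols)


def estimate_network(data: MultilayerDataset, config: RunConfig, fast: bool = False) -> PcorNetwork:
    """Run the configured estimation chain on a prepared dataset.

    ``fast=True`` uses the shorter bootstrap penalty path; used inside
    resampling loops where the full 100-point path would dominate runtime.
    """
    corr = pairwise_pearson(data)
    corr.R = nearest_psd(corr.R)
    if config.estimator == "unregularized":
        return unregularized_network(corr)
    return ebic_glasso(
        corr,
        gamma=config.gamma,
        path_size=config.bootstrap_path_size if fast else config.path_size,
        min_ratio=config.min_ratio,
    )


def strength_statistic(config: RunConfig, layers: list[str]):
    """Centrality extractor: data -> per-node strength (non-age nodes)."""

    def stat(data: MultilayerDataset) -> pd.Series:
        prepared = _apply_age_mode(_select_layers(data, layers), config.age_mode)
        net = estimate_network(prepared, config, fast=True)
        return strength(net).values()

    return stat


def bridge_statistic(config: RunConfig, layers: list[str]):
    """Centrality extractor re-deriving the Walktrap partition per resample."""

    def stat(data: MultilayerDataset) -> pd.Series:
        prepared = _apply_age_mode(_select_layers(data, layers), config.age_mode)
        net = estimate_network(prepared, config, fast=True)
        partition = walktrap(net)
        return bridge_strength(net, partition).values()

    return stat


@dataclass
class RunReport:
    """All artifacts of one analysis run."""

    kind: str
    layers: list[str]
    network: PcorNetwork
    summary: EdgeSummary
    centrality: CentralityTable
    partition: CommunityPartition | None = None
    bridge: BridgeTable | None = None
    stability: StabilityReport | None = None
    config: dict = field(default_factory=dict)
    schema_version: int = REPORT_SCHEMA_VERSION
    version: str = __version__

    def to_dict(self) -> dict:
        out = {
            "schema_version": self.schema_version,
            "software_version": self.version,
            "kind": self.kind,
            "layers": self.layers,
            "config": self.config,
            "edge_summary": asdict(self.summary),
            "lambda_selected": self.network.lambda_selected,
            "gamma": self.network.gamma,
            "n_effective": self.network.n_effective,
            "nodes": self.network.node_labels,
            "weights": self.network.W.tolist(),
            "centrality": json.loads(self.centrality.table.to_json(orient="index")),
        }
        if self.partition is not None:
            out["community"] = {
                "assignment": self.partition.assignment,
                "Q": self.partition.Q,
                "Q_label": self.partition.Q_label,
                "steps": self.partition.steps,
                "merge_history": self.partition.merge_history,
            }
        if self.bridge is not None:
            out["bridge"] = json.loads(self.bridge.table.to_json(orient="index"))
        if self.stability is not None:
            out["stability"] = self.stability.to_dict()
        return out

    def save(self, outdir) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))
        edge_list(self.network, include_zeros=True).to_csv(outdir / "edges.csv", index=False)
        self.centrality.table.to_csv(outdir / "centrality.csv")
        if self.bridge is not None:
            self.bridge.table.to_csv(outdir / "bridge_centrality.csv")
        if self.partition is not None:
            pd.Series(self.partition.assignment, name="community").rename_axis("node").to_csv(
                outdir / "community.csv"
            )
        to_graphml(self.network, outdir / "network.graphml")
        return outdir / "report.json"


def run_single_layer(config: RunConfig, layer: str) -> RunReport:
    """Single-layer analysis: estimation, edge summary, strength, stability."""
    data = _select_layers(load_data(config), [layer])
    if config.outlier_k is not None:
        data = mask_outliers(data, k=config.outlier_k)
    prepared = _apply_age_mode(data, config.age_mode)
    net = estimate_network(prepared, config)
    cent = strength(net)
    stab = None
    if config.bootstrap_B:
        stab = case_drop_bootstrap(
            data,
            strength_statistic(config, [layer]),
            fractions=config.drop_fractions,
            B=config.bootstrap_B,
            seed=config.seed + 1,
        )
    report = RunReport(
        kind="single_layer",
        layers=[layer],
        network=net,
        summary=edge_summary(net),
        centrality=cent,
        stability=stab,
        config=config.to_dict() | {"layer": layer},
    )
    if config.output_dir:
        report.save(config.output_dir)
    return report


def run_multilayer(config: RunConfig, layers: list[str]) -> RunReport:
    """Multilayer analysis: the Walktrap partition (not the layer labels)
    pre-assigns communities for bridge strength."""
    layers = list(layers)
    if len(layers) < 2:
        raise ValueError(f"multilayer run needs at least 2 layers, got {layers}")
    data = _select_layers(load_data(config), layers)
    if config.outlier_k is not None:
        data = mask_outliers(data, k=config.outlier_k)
    prepared = _apply_age_mode(data, config.age_mode)
    net = estimate_network(prepared, config)
    partition = walktrap(net)
    bridge = bridge_strength(net, partition)
    stab = None
    if config.bootstrap_B:
        stab = case_drop_bootstrap(
            data,
            bridge_statistic(config, layers),
            fractions=config.drop_fractions,
            B=config.bootstrap_B,
            seed=config.seed + 1,
        )
    report = RunReport(
        kind="multilayer",
        layers=layers,
        network=net,
        summary=edge_summary(net),
        centrality=strength(net),
        partition=partition,
        bridge=bridge,
        stability=stab,
        config=config.to_dict() | {"layers": layers},
    )
    if config.output_dir:
        report.save(config.output_dir)
    return report


def run_sensitivity(config: RunConfig, layers: list[str]) -> tuple[RunReport, RunReport, pd.DataFrame]:
    """Re-run an analysis with and without +/- k SD outlier masking.

    Returns (raw report, masked report, per-edge weight differences).
    """
    if config.outlier_k is None:
        raise ValueError("outlier_k must be set for a sensitivity run (default 4)")
    layers = list(layers)
    runner = run_single_layer if len(layers) == 1 else run_multilayer
    arg = layers[0] if len(layers) == 1 else layers

    raw_cfg = _replace_config(config, outlier_k=None, output_dir=None)
    masked_cfg = _replace_config(config, output_dir=None)
    raw = runner(raw_cfg, arg)
    masked = runner(masked_cfg, arg)

    diff = edge_list(raw.network, include_zeros=True).rename(columns={"weight": "weight_raw"})
    diff["weight_masked"] = edge_list(masked.network, include_zeros=True)["weight"]
    diff["difference"] = diff["weight_masked"] - diff["weight_raw"]
    if config.output_dir:
        out = Path(config.output_dir)
        raw.save(out / "raw")
        masked.save(out / "masked")
        diff.to_csv(out / "edge_differences.csv", index=False)
    return raw, masked, diff


def _replace_config(config: RunConfig, **overrides) -> RunConfig:
    payload = config.to_dict()
    payload.update(overrides)
    return RunConfig(**payload)
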