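"""Multilayer Gaussian data simulation with nested missingness.

The generator draws multivariate-normal samples from a planted population
GGM and then imposes the observational structure of a nested neuroimaging
cohort: every subject has behavioral data, a subset also has grey-matter
imaging, and a subset of those has diffusion imaging. Whole-layer
missingness is applied first, then per-variable missing-completely-at-random
(MCAR) cell dropout at configurable rates.

The default :meth:`MissingnessSpec.calm` emulates the CALM cohort: layer
sample sizes 805 (behavioral) / 246 (cortical volume) / 165 (fractional
anisotropy) and the published per-task missing-data percentages.
"""
from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ggm import PopulationGGM

__all__ = [
    "MissingnessSpec",
    "MultilayerDataset",
    "simulate",
    "mask_outliers",
    "write_dataset",
    "read_dataset",
]

log = logging.getLogger(__name__)

# Published per-task missing-data fractions (CALM behavioral battery).
CALM_MCAR_RATES = {
    "NO": 0.0994,
    "Read": 0.0248,
    "Spell": 0.0335,
    "Pea": 0.0112,
    "MR": 0.0012,
    "DR": 0.0050,
    "BDR": 0.0311,
    "Dot": 0.0075,
    "MrX": 0.0124,
    "Ins": 0.0683,
}

# Layer sample sizes of the cohort the generator emulates.
CALM_N = {"cognition": 805, "grey": 246, "white": 165}


@dataclass(frozen=True)
class MissingnessSpec:
    """Per-variable MCAR rates and per-layer possession proportions.

    ``layer_proportion`` gives the fraction of subjects possessing each layer
    (unlisted layers default to 1.0). Layers are nested in the order given:
    subjects possessing a later-listed layer are drawn from those possessing
    the previous one, so e.g. every diffusion subject also has grey-matter
    data.
    """

    mcar_rate: dict[str, float] = field(default_factory=dict)
    layer_proportion: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, r in self.mcar_rate.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"MCAR rate for {name!r} outside [0, 1]: {r}")
        for layer, p in self.layer_proportion.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"layer proportion for {layer!r} outside [0, 1]: {p}")

    @classmethod
    def none(cls) -> "MissingnessSpec":
        return cls()

    @classmethod
    def calm(cls) -> "MissingnessSpec":
        """The CALM-like default: nested imaging layers and published task rates."""
        n_beh = CALM_N["cognition"]
        return cls(
            mcar_rate=dict(CALM_MCAR_RATES),
            layer_proportion={
                "cognition": 1.0,
                "grey": CALM_N["grey"] / n_beh,
                "white": CALM_N["white"] / n_beh,
            },
        )


@dataclass
class MultilayerDataset:
    """Subject x variable table with explicit missingness and layer labels."""

    values: pd.DataFrame
    layer_of: dict[str, str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = [c for c in self.values.columns if c not in self.layer_of]
        if unknown:
            raise ValueError(f"columns without a layer label: {unknown}")

    @property
    def node_labels(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_subjects(self) -> int:
        return len(self.values)

    def layer_columns(self, tag: str) -> list[str]:
        return [c for c in self.values.columns if self.layer_of[c] == tag]

    @property
    def n_layer(self) -> dict[str, int]:
        """Subjects with at least one observed cell per layer."""
        out = {}
        for tag in sorted(set(self.layer_of.values())):
            cols = self.layer_columns(tag)
            out[tag] = int(self.values[cols].notna().any(axis=1).sum())
        return out

    def select(self, columns) -> "MultilayerDataset":
        columns = list(columns)
        return MultilayerDataset(
            values=self.values[columns].copy(),
            layer_of={c: self.layer_of[c] for c in columns},
            meta=dict(self.meta),
        )

    def subset_subjects(self, index) -> "MultilayerDataset":
        return MultilayerDataset(
            values=self.values.iloc[index].reset_index(drop=True),
            layer_of=dict(self.layer_of),
            meta=dict(self.meta),
        )


def simulate(
    ggm: PopulationGGM,
    n: int,
    spec: MissingnessSpec | None = None,
    seed: int = 0,
) -> MultilayerDataset:
    """Draw ``n`` subjects from the population GGM and impose missingness.

    Whole-layer missingness (nesting) is applied before cell-level MCAR, so
    a subject lacking a layer has every cell of that layer missing. The same
    seed yields bit-identical output.
    """
    if n < 10:
        raise ValueError(f"need at least 10 subjects, got {n}")
    if n < ggm.n_nodes:
        warnings.warn(
            f"n={n} is smaller than the number of variables ({ggm.n_nodes}); "
            "downstream estimation may fail",
            stacklevel=2,
        )
    spec = spec or MissingnessSpec.none()
    rng = np.random.default_rng(seed)
    X = rng.multivariate_normal(
        mean=np.zeros(ggm.n_nodes), cov=ggm.Sigma, size=n, method="cholesky"
    )
    df = pd.DataFrame(X, columns=list(ggm.node_labels))

    # Layer nesting first: later layers are sampled within the previous one.
    eligible = np.arange(n)
    for layer, prop in spec.layer_proportion.items():
        cols = [c for c in df.columns if ggm.layer_of[c] == layer]
        if not cols:
            continue
        keep_count = int(round(prop * n))
        keep_count = min(keep_count, len(eligible))
        keep = rng.choice(eligible, size=keep_count, replace=False)
        keep.sort()
        drop = np.setdiff1d(np.arange(n), keep)
        df.loc[drop, cols] = np.nan
        eligible = keep

    # Then cell-level MCAR on observed cells.
    for colname, rate in spec.mcar_rate.items():
        if colname not in df.columns or rate == 0.0:
            continue
        mask = rng.random(n) < rate
        df.loc[mask, colname] = np.nan

    return MultilayerDataset(
        values=df,
        layer_of=dict(ggm.layer_of),
        meta={"seed": int(seed), "n": int(n)},
    )


def mask_outliers(
    data: MultilayerDataset, k: float = 4.0, return_counts: bool = False
):
    """Set cells beyond mean +/- k*SD of their column (observed cells) to missing.

    Columns with zero variance are skipped with a log notice. ``k`` must be
    positive; the default of 4 matches the sensitivity analysis convention of
    treating values beyond four standard deviations as potential outliers.
    """
    if not k > 0:
        raise ValueError(f"SD multiplier k must be positive, got {k}")
    df = data.values.copy()
    counts: dict[str, int] = {}
    for col in df.columns:
        obs = df[col].dropna()
        sd = obs.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            log.info("mask_outliers: column %s has zero variance, skipped", col)
            counts[col] = 0
            continue
        mu = obs.mean()
        out = (df[col] - mu).abs() > k * sd
        counts[col] = int(out.sum())
        df.loc[out, col] = np.nan
    if any(counts.values()):
        log.info("mask_outliers: masked cells per column: %s", counts)
    masked = MultilayerDataset(
        values=df, layer_of=dict(data.layer_of), meta=dict(data.meta)
    )
    if return_counts:
        return masked, counts
    return masked


def write_dataset(
    data: MultilayerDataset, csv_path, sidecar_path=None, float_format=None
) -> None:
    """Write one row per subject with 'NA' markers, plus a JSON sidecar."""
    csv_path = Path(csv_path)
    data.values.to_csv(csv_path, index=False, na_rep="NA", float_format=float_format)
    sidecar = Path(sidecar_path) if sidecar_path else csv_path.with_suffix(".json")
    sidecar.write_text(
        json.dumps({"layer_of": data.layer_of, **data.meta}, indent=2, sort_keys=True)
    )


def read_dataset(csv_path, sidecar_path=None) -> MultilayerDataset:
    csv_path = Path(csv_path)
    sidecar = Path(sidecar_path) if sidecar_path else csv_path.with_suffix(".json")
    df = pd.read_csv(csv_path, na_values=["NA"])
    meta = json.loads(sidecar.read_text())
    layer_of = meta.pop("layer_of")
    return MultilayerDataset(values=df, layer_of=layer_of, meta=meta)
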