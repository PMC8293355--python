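"""Calibrated population networks emulating the CALM study's layer structure.

Each preset is an explicit numeric fixture (CSV shipped with the package)
holding a planted partial-correlation matrix whose off-diagonal summary
statistics over the non-age entries reproduce the published edge summaries
of the corresponding CALM layer:

* ``calm_cognitive`` -- 10 cognitive task scores + age. Mean 0.08, median
  0.07, range 0-0.63, with the reading-spelling edge planted at 0.63 and all
  other task-task edges in [0, 0.27].
* ``calm_cv`` -- 10 grey-matter cortical-volume ROIs + age. Mean 0.09,
  median 0, range -0.15-0.52; the single negative edge is caudal middle
  frontal - frontal pole at -0.15.
* ``calm_fa`` -- 10 white-matter fractional-anisotropy tracts + age. Mean
  0.08, median 0, range 0-0.44.
* ``calm_trilayer`` -- all 30 variables + age, with sparse small cross-layer
  edges (|p| <= 0.15, mixed sign). Cross-layer values are plausible
  calibration, not published ground truth.

The assignment of the remaining (non-extreme) weights to node pairs is a
fixture design choice; tests validate the printed-summary calibration and
positive definiteness rather than any particular pair placement.
"""
from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from ..ggm import PopulationGGM

__all__ = ["PRESET_NAMES", "build_preset", "preset_layer_map"]

COGNITIVE_NODES = ("MR", "Pea", "Spell", "Read", "NO", "DR", "BDR", "Dot", "MrX", "Ins")
CV_NODES = ("CAC", "CMF", "FP", "MOF", "RAC", "RMF", "SFG", "STG", "SMG", "TTG")
FA_NODES = ("ATR", "CST", "CING", "CINGh", "FMaj", "FMin", "IFOF", "ILF", "SLF", "UNC")

PRESET_NAMES = ("calm_cognitive", "calm_cv", "calm_fa", "calm_trilayer")

_LAYER_BY_NODE = (
    {n: "cognition" for n in COGNITIVE_NODES}
    | {n: "grey" for n in CV_NODES}
    | {n: "white" for n in FA_NODES}
    | {"Age": "age"}
)


def preset_layer_map(node_labels) -> dict[str, str]:
    """Layer tag for each node label used by the presets."""
    unknown = [l for l in node_labels if l not in _LAYER_BY_NODE]
    if unknown:
        raise KeyError(f"nodes without a known layer: {unknown}")
    return {l: _LAYER_BY_NODE[l] for l in node_labels}


def _load_matrix(name: str) -> pd.DataFrame:
    ref = resources.files(__name__).joinpath(f"{name}.csv")
    with ref.open("r") as fh:
        return pd.read_csv(fh, index_col=0)


def build_preset(name: str) -> PopulationGGM:
    """Load a named preset as a :class:`PopulationGGM`.

    Raises ``KeyError`` for unknown names and ``ValueError`` if the stored
    matrix fails positive-definiteness validation.
    """
    if name not in PRESET_NAMES:
        raise KeyError(f"unknown preset {name!r}; available: {PRESET_NAMES}")
    df = _load_matrix(name)
    labels = tuple(df.columns)
    if tuple(df.index) != labels:
        raise ValueError(f"preset {name}: row/column labels disagree")
    return PopulationGGM(
        node_labels=labels,
        layer_of=preset_layer_map(labels),
        P=np.asarray(df.values, dtype=float),
    )
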