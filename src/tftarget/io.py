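"""Readers and writers for the TSV formats used across the pipeline."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import ExpressionSet, TrainingNetwork, VARIANCE_FLOOR

__all__ = [
    "read_expression",
    "write_expression",
    "read_network",
    "write_network",
    "write_scores",
    "read_scores",
    "load_config",
    "provenance_block",
]


def read_expression(path, variance_floor: float = VARIANCE_FLOOR) -> ExpressionSet:
    """Read a long-form expression TSV/CSV.

    Expected columns: gene, condition, replicate, time, value and optionally
    variance (missing variances fall back to the configured floor).
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    frame = pd.read_csv(path, sep=sep)
    return ExpressionSet(frame, variance_floor=variance_floor)


def write_expression(es: ExpressionSet, path) -> None:
    es.frame.to_csv(path, sep="\t", index=False)


def read_network(path, tf_names=None) -> TrainingNetwork:
    """Read a genes x TFs binary matrix TSV (first column = gene ids)."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if frame.empty:
        raise ValueError(f"network file {path} is empty")
    if tf_names is not None:
        unknown = [c for c in frame.columns if c not in tf_names]
        if unknown:
            raise ValueError(
                f"unknown TF columns {unknown}; expected a subset of {list(tf_names)}"
            )
        frame = frame.reindex(columns=list(tf_names))
        if frame.isna().any().any():
            raise ValueError("network file missing required TF columns")
    return TrainingNetwork(frame)


def write_network(net: TrainingNetwork, path) -> None:
    net.frame.to_csv(path, sep="\t")


def write_scores(table, path) -> None:
    """Write a :class:`~tftarget.predict.ModelScoreTable` to TSV."""
    table.frame.to_csv(path, sep="\t", index=False)


def read_scores(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"map_structure": str})


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a mapping")
    return cfg


def provenance_block(seed, config: dict) -> dict:
    """Provenance metadata recorded next to every run's outputs."""
    from . import __version__

    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return {
        "seed": int(seed),
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "tftarget_version": __version__,
        "numpy_version": np.__version__,
    }


def write_provenance(path, seed, config: dict) -> None:
    Path(path).write_text(json.dumps(provenance_block(seed, config), indent=2) + "\n")
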