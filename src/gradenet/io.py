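"""Readers and writers for the pipeline's tabular formats.

Everything is plain text: TSV with headers for edge lists, expression
matrices, survival tables, probe maps and FFL lists; JSON for reports and
manifests. Gene identifiers are opaque strings throughout.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping

import pandas as pd

from .errors import ConfigurationError
from .network import DirectedNetwork
from .synth import FFLInstance

logger = logging.getLogger(__name__)


def read_edge_list(path: str | Path, grade: str | None = None) -> DirectedNetwork:
    """Read a 2+-column TSV (regulator, target) into a simple digraph.

    Duplicate rows are collapsed with a logged warning; self-loop rows are
    dropped with a logged count; malformed rows raise with their line number.
    """
    path = Path(path)
    edges: list[tuple[str, str]] = []
    with path.open() as fh:
        header = fh.readline()
        if not header.strip():
            raise ConfigurationError(f"{path}: empty file")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or not parts[0] or not parts[1]:
                raise ConfigurationError(f"{path}:{lineno}: malformed row {line!r}")
            edges.append((parts[0], parts[1]))
    n_self = sum(1 for u, v in edges if u == v)
    if n_self:
        logger.warning("%s: dropped %d self-loop rows", path, n_self)
    edges = [(u, v) for u, v in edges if u != v]
    unique = set(edges)
    if len(unique) < len(edges):
        logger.warning("%s: collapsed %d duplicate rows", path,
                       len(edges) - len(unique))
    return DirectedNetwork.from_edges(unique, grade=grade)


def write_edge_list(net: DirectedNetwork, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        fh.write("regulator\ttarget\n")
        for u, v in sorted(net.edges):
            fh.write(f"{u}\t{v}\n")


def read_expression(path: str | Path) -> pd.DataFrame:
    """TSV expression matrix: first column = TF symbols, rest = samples."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ConfigurationError(f"{path}: duplicated TF symbols")
    return df


def write_expression(matrix: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    matrix.to_csv(path, sep="\t", index_label="tf")


def read_survival(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "time", "event"}
    if not required <= set(df.columns):
        raise ConfigurationError(f"{path}: needs columns {sorted(required)}")
    return df


def write_survival(surv: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    surv.to_csv(path, sep="\t", index=False)


def read_probe_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ConfigurationError(f"{path}: probe map needs 2 columns")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def read_ffl_list(path: str | Path) -> list[FFLInstance]:
    df = pd.read_csv(path, sep="\t")
    return [FFLInstance(r.top, r.middle, r.bottom) for r in df.itertuples()]


def write_ffl_list(ffls: list[FFLInstance], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"top": [f.top for f in ffls],
                  "middle": [f.middle for f in ffls],
                  "bottom": [f.bottom for f in ffls]}).to_csv(
        path, sep="\t", index=False)


def write_json(obj: Mapping, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonify)
        fh.write("\n")


def _jsonify(obj):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset, tuple)):
        return sorted(obj) if isinstance(obj, (set, frozenset)) else list(obj)
    if isinstance(obj, FFLInstance):
        return list(obj.tfs)
    raise TypeError(f"not JSON serializable: {type(obj)}")
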