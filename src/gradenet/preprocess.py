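"""Minimal expression preprocessing: probe collapsing, quantile
normalization, log transform and low-expression filtering.

Expression matrices are pandas DataFrames with one row per probe/gene (index)
and one column per sample. These are the small, well-defined steps applied to
each dataset before network construction; raw-array processing (background
subtraction, RMA) is upstream of this package.
"""
from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError


def collapse_probes(matrix: pd.DataFrame,
                    probe_to_gene: Mapping[str, str]) -> pd.DataFrame:
    """Average redundant probes into one row per gene.

    Probes without a gene assignment are dropped; each output row is the
    arithmetic mean of its probes' rows. Gene order follows first appearance
    of each gene among the mapped probes.
    """
    if not probe_to_gene:
        raise ConfigurationError("probe-to-gene mapping is empty")
    mapped = [p for p in matrix.index if p in probe_to_gene]
    sub = matrix.loc[mapped]
    genes = pd.Index([probe_to_gene[p] for p in mapped], name=matrix.index.name)
    order = genes.drop_duplicates()
    out = sub.groupby(genes, sort=False).mean()
    return out.loc[order]


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every sample (column) onto the common mean quantile profile.

    The reference distribution is the row-wise mean of the sorted columns;
    each column's values are replaced by the reference value at their rank,
    with ties receiving the average of their tied positions. After the
    transform all columns have identical sorted values.
    """
    if matrix.shape[1] < 2:
        raise ConfigurationError("quantile normalization needs >= 2 samples")
    x = matrix.to_numpy(dtype=float)
    reference = np.sort(x, axis=0).mean(axis=1)
    ranks = pd.DataFrame(x).rank(method="average").to_numpy() - 1.0  # 0-based
    lo = np.floor(ranks).astype(int)
    hi = np.ceil(ranks).astype(int)
    frac = ranks - lo
    normalized = reference[lo] * (1 - frac) + reference[hi] * frac
    return pd.DataFrame(normalized, index=matrix.index, columns=matrix.columns)


def log_transform(matrix: pd.DataFrame, already_log: bool = False) -> pd.DataFrame:
    """log2(x + 1) on non-negative values; identity when flagged as log-scale."""
    if already_log:
        return matrix.copy()
    if (matrix.to_numpy() < 0).any():
        raise ConfigurationError("negative values: data looks already log-scale")
    return np.log2(matrix + 1.0)


def filter_low_expressed(matrix: pd.DataFrame, fraction: float = 0.01) -> pd.DataFrame:
    """Drop the ``ceil(fraction * n_genes)`` genes with lowest mean expression.

    Mean is taken across all samples of the dataset. Ties at the cutoff are
    broken by stable input order (earlier rows dropped first), so the result
    is deterministic. ``fraction=0`` is the identity.
    """
    if not 0.0 <= fraction < 1.0:
        raise ConfigurationError("fraction must be in [0, 1)")
    n_drop = int(np.ceil(fraction * matrix.shape[0]))
    if n_drop == 0:
        return matrix.copy()
    means = matrix.mean(axis=1).to_numpy()
    drop_pos = np.argsort(means, kind="stable")[:n_drop]
    keep = np.ones(matrix.shape[0], dtype=bool)
    keep[drop_pos] = False
    return matrix.iloc[keep]
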