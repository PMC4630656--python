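"""Grade-specific network construction.

A prior edge (regulator -> target, from the binding prior) is promoted into
the grade network only if the two TFs are significantly co-expressed —
|r| above a threshold with p below a threshold — in at least ``min_datasets``
independent expression datasets of that grade, optionally with a consistent
correlation sign across the supporting datasets. Edge direction is inherited
from the prior; the coexpression filter only decides which prior edges are
functionally active in the grade.

Correlations are Spearman by default (Pearson available as a switch);
p-values come from the t approximation with n - 2 degrees of freedom, with
no multiple-testing correction (the filter operates on raw thresholds).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, UndefinedCorrelationError
from .network import DirectedNetwork

logger = logging.getLogger(__name__)


def _t_pvalue(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for correlation r via t = r sqrt((n-2)/(1-r^2)), n-2 df."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return np.where(np.abs(r) >= 1.0, 0.0, p)


def pair_correlation(x: np.ndarray, y: np.ndarray,
                     method: str = "spearman") -> tuple[float, float]:
    """Correlation and two-sided t-approximation p-value for one TF pair.

    Raises :class:`UndefinedCorrelationError` on constant input — callers
    exclude the pair rather than aborting a run.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ConfigurationError("x and y must be 1-D vectors of equal length")
    n = len(x)
    if n < 4:
        raise ConfigurationError("need at least 4 samples per vector")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise UndefinedCorrelationError("constant expression vector")
    if method == "spearman":
        x = stats.rankdata(x)
        y = stats.rankdata(y)
    elif method != "pearson":
        raise ConfigurationError(f"unknown correlation method {method!r}")
    r = float(np.corrcoef(x, y)[0, 1])
    return r, float(_t_pvalue(np.array(r), n))


@dataclass
class EdgeEvidence:
    """Per-dataset coexpression evidence for one prior edge."""

    regulator: str
    target: str
    per_dataset_r: dict[str, float] = field(default_factory=dict)
    per_dataset_p: dict[str, float] = field(default_factory=dict)
    n_supporting: int = 0


def _correlation_matrices(expr: pd.DataFrame, method: str
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All-pairs correlation/p matrices over the rows of one dataset.

    Returns (r, p, defined) where ``defined[i]`` is False for constant rows
    (their correlations are undefined and must be excluded).
    """
    x = expr.to_numpy(dtype=float)
    n = x.shape[1]
    defined = np.ptp(x, axis=1) > 0.0
    if method == "spearman":
        x = stats.rankdata(x, axis=1)
    sd = x.std(axis=1)
    sd[sd == 0.0] = 1.0
    z = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    r = z @ z.T / n
    np.clip(r, -1.0, 1.0, out=r)
    p = _t_pvalue(r, n)
    return r, p, defined


def build_grade_network(prior: DirectedNetwork,
                        expr_by_dataset: dict[str, pd.DataFrame],
                        grade: str | None = None,
                        r_threshold: float = 0.5,
                        p_threshold: float = 0.01,
                        min_datasets: int = 2,
                        require_sign_consistency: bool = True,
                        method: str = "spearman",
                        ) -> tuple[DirectedNetwork, list[EdgeEvidence]]:
    """Filter the binding prior by replicated coexpression in one grade.

    An edge u -> v is retained iff |r| > ``r_threshold`` and
    p < ``p_threshold`` in at least ``min_datasets`` datasets — counting,
    when ``require_sign_consistency``, only the largest same-sign subset of
    supporting datasets. Prior TFs missing from any dataset's expression are
    skipped with a logged warning; self-loops never survive. Network nodes
    are the TFs incident to at least one retained edge.
    """
    if method not in ("spearman", "pearson"):
        raise ConfigurationError(f"unknown correlation method {method!r}")
    if len(expr_by_dataset) < min_datasets:
        raise ConfigurationError(
            f"need >= {min_datasets} expression datasets, got {len(expr_by_dataset)}")
    datasets = sorted(expr_by_dataset)
    mats: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    indexes: dict[str, dict[str, int]] = {}
    for name in datasets:
        expr = expr_by_dataset[name]
        if expr.shape[1] < 4:
            raise ConfigurationError(f"dataset {name} has fewer than 4 samples")
        mats[name] = _correlation_matrices(expr, method)
        indexes[name] = {t: i for i, t in enumerate(expr.index)}

    evidence: list[EdgeEvidence] = []
    retained: set[tuple[str, str]] = set()
    n_missing = 0
    for u, v in sorted(prior.edges):
        if u == v:
            continue
        ev = EdgeEvidence(regulator=u, target=v)
        pos = neg = 0
        for name in datasets:
            idx = indexes[name]
            if u not in idx or v not in idx:
                n_missing += 1
                continue
            r_mat, p_mat, defined = mats[name]
            iu, iv = idx[u], idx[v]
            if not (defined[iu] and defined[iv]):
                continue
            r, p = float(r_mat[iu, iv]), float(p_mat[iu, iv])
            ev.per_dataset_r[name] = r
            ev.per_dataset_p[name] = p
            if abs(r) > r_threshold and p < p_threshold:
                if r > 0:
                    pos += 1
                else:
                    neg += 1
        ev.n_supporting = max(pos, neg) if require_sign_consistency else pos + neg
        evidence.append(ev)
        if ev.n_supporting >= min_datasets:
            retained.add((u, v))
    if n_missing:
        logger.warning("%d prior edge endpoints missing from expression; skipped",
                       n_missing)
    net = DirectedNetwork.from_edges(retained, grade=grade)
    net.nodes = net.subgraph_nodes()
    return net, evidence


def network_summary(net: DirectedNetwork,
                    prior: DirectedNetwork | None = None) -> dict:
    """Edge/node counts and, given the prior, the activated-edge fraction."""
    summary = {
        "grade": net.grade,
        "n_edges": net.n_edges,
        "n_nodes": len(net.subgraph_nodes()),
    }
    if prior is not None and prior.n_edges > 0:
        summary["prior_edges"] = prior.n_edges
        summary["activated_fraction"] = net.n_edges / prior.n_edges
    elif prior is not None:
        summary["prior_edges"] = 0
        summary["activated_fraction"] = 0.0
    return summary
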