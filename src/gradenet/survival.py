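"""Cox-weighted risk scores and the two-stage prognostic FFL screen.

For each candidate FFL, the three member TFs are fit in separate univariate
Cox proportional-hazards models on the training half of the cohort; the
per-patient risk score is the linear combination of the three expression
values weighted by those coefficients (the FFL's internal wiring is not used
in scoring). Patients are dichotomized at the training-set median risk
score, the high/low groups are compared by the log-rank test, and the
training coefficients *and* threshold are applied unchanged to the test
half. An FFL is a prognostic biomarker when the log-rank p-value is below
alpha in both halves. Independent validation clusters the three TFs'
expression with k-means (k = 2) in a second cohort and log-rank-tests the
two clusters; running identification in cohort A with validation in B and
vice versa, then intersecting, gives the final biomarker set.

The univariate Cox fit is a 1-D Newton maximization of the Breslow partial
likelihood with a Wald p-value; it is exercised against a brute-force
partial-likelihood grid in the test suite.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test as _lifelines_logrank
from scipy import stats
from sklearn.cluster import KMeans

from .errors import (ConfigurationError, UndefinedCorrelationError,
                     ValidationFailedError)
from .synth import FFLInstance

logger = logging.getLogger(__name__)


def _check_survival(surv: pd.DataFrame) -> pd.DataFrame:
    required = {"sample_id", "time", "event"}
    if not required <= set(surv.columns):
        raise ConfigurationError(f"survival table needs columns {sorted(required)}")
    if surv["sample_id"].duplicated().any():
        raise ConfigurationError("duplicate sample ids in survival table")
    if (surv["time"] <= 0).any():
        raise ConfigurationError("survival times must be positive")
    if not surv["event"].isin([0, 1]).all():
        raise ConfigurationError("event indicator must be 0/1")
    return surv


def split_train_test(samples: list[str], seed: int,
                     train_fraction: float = 0.5) -> tuple[list[str], list[str]]:
    """Random disjoint, exhaustive train/test partition of the sample ids."""
    if len(samples) < 8:
        raise ConfigurationError("need at least 8 samples to split")
    if not 0.0 < train_fraction < 1.0:
        raise ConfigurationError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(samples))
    n_train = int(round(train_fraction * len(samples)))
    train = [samples[i] for i in sorted(order[:n_train])]
    test = [samples[i] for i in sorted(order[n_train:])]
    return train, test


# ---------------------------------------------------------------------------
# Univariate Cox (Breslow ties)


def _breslow_terms(beta: float, x: np.ndarray, time: np.ndarray,
                   event: np.ndarray) -> tuple[float, float, float]:
    """(log partial likelihood, score U, information I) at beta."""
    order = np.argsort(time, kind="stable")
    x, time, event = x[order], time[order], event[order]
    eta = beta * x
    eta -= eta.max()  # overflow guard; PL is invariant to the shift
    w = np.exp(eta)
    # reverse cumulative sums over the risk set {j : t_j >= t_i}
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum((w * x)[::-1])[::-1]
    s2 = np.cumsum((w * x * x)[::-1])[::-1]
    first = np.searchsorted(time, time, side="left")  # tie-group start
    ev = event == 1
    f = first[ev]
    mean = s1[f] / s0[f]
    loglik = float(np.sum(eta[ev] - np.log(s0[f])))
    score = float(np.sum(x[ev] - mean))
    info = float(np.sum(s2[f] / s0[f] - mean ** 2))
    return loglik, score, info


def cox_loglik(beta: float, x: np.ndarray, time: np.ndarray,
               event: np.ndarray) -> float:
    """Breslow log partial likelihood (exposed for oracle comparisons)."""
    return _breslow_terms(beta, np.asarray(x, float), np.asarray(time, float),
                          np.asarray(event, int))[0]


def cox_univariate(x: np.ndarray, surv: pd.DataFrame,
                   max_iter: int = 100, tol: float = 1e-10) -> tuple[float, float]:
    """Maximum-partial-likelihood coefficient and Wald two-sided p-value.

    ``x`` must be aligned with the rows of ``surv``. Breslow tie handling;
    Newton iteration with step halving from beta = 0.
    """
    surv = _check_survival(surv)
    x = np.asarray(x, dtype=float)
    if len(x) != len(surv):
        raise ConfigurationError("x and survival table misaligned")
    if int(surv["event"].sum()) < 1:
        raise ConfigurationError("no observed events")
    if np.ptp(x) == 0.0:
        raise UndefinedCorrelationError("constant covariate; Cox fit undefined")
    time = surv["time"].to_numpy(dtype=float)
    event = surv["event"].to_numpy(dtype=int)

    beta = 0.0
    loglik, score, info = _breslow_terms(beta, x, time, event)
    for _ in range(max_iter):
        if info <= 0.0:
            break
        step = score / info
        new_beta = beta + step
        new_ll, new_sc, new_in = _breslow_terms(new_beta, x, time, event)
        halvings = 0
        while new_ll < loglik - 1e-12 and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_sc, new_in = _breslow_terms(new_beta, x, time, event)
            halvings += 1
        converged = abs(step) < tol
        beta, loglik, score, info = new_beta, new_ll, new_sc, new_in
        if converged or abs(beta) > 50.0:
            break
    se = 1.0 / math.sqrt(info) if info > 0 else float("inf")
    z = beta / se if np.isfinite(se) and se > 0 else 0.0
    p = 2.0 * stats.norm.sf(abs(z))
    return float(beta), float(p)


# ---------------------------------------------------------------------------
# Risk model


@dataclass
class RiskModel:
    """Three Cox-weighted TFs and the training-median dichotomization threshold."""

    tf_ids: tuple[str, str, str]
    betas: tuple[float, float, float]
    threshold: float
    cox_pvalues: tuple[float, float, float] | None = None


def risk_scores(model: RiskModel, expr: pd.DataFrame) -> pd.Series:
    """score_j = sum_i beta_i * x_ij over the model's TFs, per sample."""
    for tf in model.tf_ids:
        if tf not in expr.index:
            raise ConfigurationError(f"model TF {tf} missing from expression")
    x = expr.loc[list(model.tf_ids)].to_numpy(dtype=float)
    return pd.Series(np.asarray(model.betas, float) @ x, index=expr.columns)


def dichotomize(scores: pd.Series, threshold: float) -> pd.Series:
    """'high' for score > threshold, 'low' otherwise (ties go low)."""
    return pd.Series(np.where(scores.to_numpy() > threshold, "high", "low"),
                     index=scores.index)


def logrank(groups: pd.Series, surv: pd.DataFrame) -> tuple[float, float]:
    """Two-group log-rank chi-square (1 df) and upper-tail p-value."""
    surv = _check_survival(surv).set_index("sample_id").loc[groups.index]
    labels = groups.unique()
    if len(labels) != 2:
        raise ConfigurationError("log-rank needs exactly two nonempty groups")
    a = surv.loc[groups[groups == labels[0]].index]
    b = surv.loc[groups[groups == labels[1]].index]
    if int(surv["event"].sum()) < 1:
        raise ConfigurationError("no observed events")
    res = _lifelines_logrank(a["time"], b["time"],
                             event_observed_A=a["event"],
                             event_observed_B=b["event"])
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# Screening


@dataclass
class ScreenResult:
    ffl: FFLInstance
    model: RiskModel
    p_train: float
    p_test: float
    retained: bool


def _align(expr: pd.DataFrame, surv: pd.DataFrame,
           samples: list[str]) -> tuple[pd.DataFrame, pd.DataFrame]:
    surv = surv.set_index("sample_id").loc[samples].reset_index()
    return expr[samples], surv


def screen_ffls(ffls: list[FFLInstance], expr: pd.DataFrame, surv: pd.DataFrame,
                seed: int, alpha: float = 0.05, train_fraction: float = 0.5,
                bh_correct: bool = False) -> list[ScreenResult]:
    """Two-stage train/test log-rank screen over candidate FFLs.

    Returns one result per screenable FFL with ``retained`` marking the
    prognostic ones (p < alpha in both halves; with ``bh_correct``,
    Benjamini–Hochberg-adjusted p-values are compared to alpha instead).
    FFLs with a constant-expression TF or a degenerate dichotomization are
    skipped with a log entry.
    """
    surv = _check_survival(surv)
    samples = [s for s in expr.columns if s in set(surv["sample_id"])]
    train_ids, test_ids = split_train_test(samples, seed=seed,
                                           train_fraction=train_fraction)
    expr_tr, surv_tr = _align(expr, surv, train_ids)
    expr_te, surv_te = _align(expr, surv, test_ids)
    results: list[ScreenResult] = []
    for f in ffls:
        try:
            betas, pvals = [], []
            for tf in f.tfs:
                if tf not in expr.index:
                    raise ConfigurationError(f"FFL TF {tf} missing from expression")
                b, p = cox_univariate(expr_tr.loc[tf].to_numpy(), surv_tr)
                betas.append(b)
                pvals.append(p)
            model = RiskModel(tf_ids=f.tfs, betas=tuple(betas),
                              threshold=0.0, cox_pvalues=tuple(pvals))
            s_tr = risk_scores(model, expr_tr)
            model.threshold = float(np.median(s_tr))
            g_tr = dichotomize(s_tr, model.threshold)
            g_te = dichotomize(risk_scores(model, expr_te), model.threshold)
            if g_tr.nunique() < 2 or g_te.nunique() < 2:
                raise ConfigurationError("degenerate risk dichotomization")
            _, p_tr = logrank(g_tr, surv_tr)
            _, p_te = logrank(g_te, surv_te)
        except (ConfigurationError, UndefinedCorrelationError) as exc:
            logger.info("skipping FFL %s: %s", f.tfs, exc)
            continue
        results.append(ScreenResult(ffl=f, model=model, p_train=p_tr,
                                    p_test=p_te, retained=False))
    if bh_correct and results:
        p_tr_adj = _bh(np.array([r.p_train for r in results]))
        p_te_adj = _bh(np.array([r.p_test for r in results]))
        for r, a_tr, a_te in zip(results, p_tr_adj, p_te_adj):
            r.retained = bool(a_tr < alpha and a_te < alpha)
    else:
        for r in results:
            r.retained = bool(r.p_train < alpha and r.p_test < alpha)
    return results


def _bh(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values."""
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


def retained_ffls(results: list[ScreenResult]) -> list[FFLInstance]:
    return [r.ffl for r in results if r.retained]


# ---------------------------------------------------------------------------
# Validation


def validate_kmeans(ffl: FFLInstance, expr: pd.DataFrame, surv: pd.DataFrame,
                    seed: int, standardize: bool = True,
                    n_init: int = 10) -> tuple[float, pd.Series]:
    """k-means (k = 2) validation of an FFL in an independent cohort.

    Clusters the samples on the three TFs' expression (per-TF standardized
    by default), then log-rank-tests survival between the two clusters.
    """
    surv = _check_survival(surv)
    samples = [s for s in expr.columns if s in set(surv["sample_id"])]
    if len(samples) < 6:
        raise ConfigurationError("need at least 6 validation samples")
    expr_v, surv_v = _align(expr, surv, samples)
    for tf in ffl.tfs:
        if tf not in expr.index:
            raise ConfigurationError(f"FFL TF {tf} missing from expression")
    x = expr_v.loc[list(ffl.tfs)].to_numpy(dtype=float).T  # samples x 3
    if standardize:
        sd = x.std(axis=0)
        if (sd == 0).any():
            raise ValidationFailedError("constant TF expression in validation set")
        x = (x - x.mean(axis=0)) / sd
    km = KMeans(n_clusters=2, n_init=n_init, random_state=seed % (2 ** 31))
    labels = pd.Series(km.fit_predict(x), index=samples)
    if labels.nunique() < 2:
        raise ValidationFailedError("k-means produced an empty cluster")
    groups = labels.map({0: "cluster0", 1: "cluster1"})
    _, p = logrank(groups, surv)
    return float(p), labels


def fisher_idh(groups: pd.Series, idh_status: pd.Series) -> float:
    """Two-sided Fisher's exact p for risk group vs IDH mutation status."""
    groups, idh_status = groups.align(idh_status, join="inner")
    table = pd.crosstab(groups, idh_status)
    if table.shape != (2, 2) or (table.sum(axis=0) == 0).any() \
            or (table.sum(axis=1) == 0).any():
        raise ConfigurationError("need a 2x2 table with positive margins")
    _, p = stats.fisher_exact(table.to_numpy(), alternative="two-sided")
    return float(p)


def bidirectional_biomarkers(ffls: list[FFLInstance],
                             expr_a: pd.DataFrame, surv_a: pd.DataFrame,
                             expr_b: pd.DataFrame, surv_b: pd.DataFrame,
                             seed: int, alpha: float = 0.05) -> dict:
    """Identify in A, validate in B; identify in B, validate in A; intersect.

    Mirrors the bidirectional protocol of screening one cohort's train/test
    split and confirming survivors by k-means clustering in the other
    cohort; the final biomarkers are the FFLs surviving both directions.
    """

    def one_direction(expr_i, surv_i, expr_v, surv_v, tag: int) -> set[FFLInstance]:
        results = screen_ffls(ffls, expr_i, surv_i, seed=seed + tag, alpha=alpha)
        confirmed = set()
        for f in retained_ffls(results):
            try:
                p, _ = validate_kmeans(f, expr_v, surv_v, seed=seed + tag)
            except (ValidationFailedError, ConfigurationError):
                continue
            if p < alpha:
                confirmed.add(f)
        return confirmed

    a_to_b = one_direction(expr_a, surv_a, expr_b, surv_b, 0)
    b_to_a = one_direction(expr_b, surv_b, expr_a, surv_a, 1)
    return {"a_to_b": a_to_b, "b_to_a": b_to_a, "final": a_to_b & b_to_a}
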