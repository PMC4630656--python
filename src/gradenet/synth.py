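"""Synthetic study generator with planted ground truth.

Emulates the data a grade-stratified TF-network study consumes, with nothing
downloaded: a binding prior (an Erdős–Rényi digraph standing in for a
promoter motif-scan), per-dataset per-grade TF expression matrices in which a
configurable set of prior edges carries real coexpression signal, and
survival tables whose hazard depends on the expression of one planted
feedforward loop (FFL).

Planted structures come in two shapes, both drawn from the prior:

* *pair* — a single regulator->target edge whose target tracks its regulator
  linearly at a target absolute correlation;
* *ffl* — a (top, middle, bottom) triple whose three edges
  top->middle, top->bottom, middle->bottom each carry the target correlation.
  FFL triples are required to realize the FFL pattern *exactly* (no other
  prior edge among the three TFs), so a correctly recovered triple is an
  induced FFL downstream.

Within a grade, structures are node-disjoint and pair edges are required to
have no reverse edge in the prior. Both restrictions exist so that the only
prior edges carrying supra-threshold correlation are exactly the planted
ones: recovery metrics then measure the network-construction filter itself
rather than correlation leakage between overlapping planted structures.

Grade-to-grade dynamics: each structure survives into the next grade with
probability ``1 - edge_turnover`` and is otherwise replaced by a freshly
drawn one, which reproduces, qualitatively, the grade-specific rewiring of
the real networks.

Reproducibility: one global seed; every component (prior, truth, each
(dataset, grade) expression matrix, each survival table) draws from its own
child stream keyed by the global seed plus a fixed component tag, so
regenerating any single component is bit-identical to generating the bundle.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import ConfigurationError, ConsistencyError
from .network import DirectedNetwork, Edge

# component tags for child RNG streams
_TAG_PRIOR, _TAG_TRUTH, _TAG_EXPR, _TAG_SURV = 0, 1, 2, 3

#: default mean of the simulated log-scale expression values
EXPRESSION_MEAN = 8.0


@dataclass(frozen=True)
class FFLInstance:
    """An ordered feedforward-loop triple.

    ``top`` regulates both others, ``middle`` is regulated by ``top`` and
    regulates ``bottom``, ``bottom`` is regulated by both.
    """

    top: str
    middle: str
    bottom: str

    @property
    def tfs(self) -> tuple[str, str, str]:
        return (self.top, self.middle, self.bottom)

    @property
    def edges(self) -> frozenset[Edge]:
        return frozenset({(self.top, self.middle), (self.top, self.bottom),
                          (self.middle, self.bottom)})


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the synthetic cohort.

    Defaults mirror the scale of a three-grade glioma TF study: ~500 TFs, a
    binding prior covering ~30% of ordered TF pairs, two independent
    expression datasets with 60 samples per grade each, planted coexpressed
    edges at |r| ≈ 0.8, and survival for the highest grade driven by one
    planted FFL with log-hazard weights (0.8, 0.8, 0.8) per expression unit.
    """

    n_tfs: int = 500
    prior_density: float = 0.3
    grades: tuple[str, ...] = ("II", "III", "IV")
    n_datasets: int = 2
    samples_per_grade_per_dataset: int = 60
    planted_edges_per_grade: int = 50
    planted_ffls_per_grade: int = 21
    planted_correlation: float = 0.8
    noise_sd: float = 1.0
    ffl_betas: tuple[float, float, float] = (0.8, 0.8, 0.8)
    censoring_rate: float = 0.2
    edge_turnover: float = 0.7
    idh_mutant_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tfs < 3:
            raise ConfigurationError("n_tfs must be >= 3")
        if not 0.0 < self.prior_density < 1.0:
            raise ConfigurationError("prior_density must be in (0, 1)")
        if len(set(self.grades)) != len(self.grades) or not self.grades:
            raise ConfigurationError("grade labels must be unique and non-empty")
        if self.n_datasets < 2:
            raise ConfigurationError("need at least 2 independent datasets")
        if not 0.0 < self.planted_correlation <= 1.0:
            raise ConfigurationError("planted_correlation must be in (0, 1]")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if not 0.0 <= self.censoring_rate < 1.0:
            raise ConfigurationError("censoring_rate must be in [0, 1)")
        if not 0.0 <= self.edge_turnover <= 1.0:
            raise ConfigurationError("edge_turnover must be in [0, 1]")
        needed = 2 * self.planted_edges_per_grade + 3 * self.planted_ffls_per_grade
        if needed > self.n_tfs:
            raise ConfigurationError(
                f"planted structures need {needed} distinct TFs but n_tfs={self.n_tfs}")

    @property
    def dataset_names(self) -> tuple[str, ...]:
        return tuple(f"D{i + 1}" for i in range(self.n_datasets))

    def tf_names(self) -> list[str]:
        width = len(str(self.n_tfs))
        return [f"TF{i:0{width}d}" for i in range(1, self.n_tfs + 1)]


@dataclass
class PlantedTruth:
    """Ground truth of the simulation, for parameter-recovery tests."""

    prior_edges: set[Edge]
    active_edges_by_grade: dict[str, set[Edge]]
    ffls_by_grade: dict[str, list[FFLInstance]]
    prognostic_ffl: Optional[FFLInstance]
    true_betas: tuple[float, float, float]

    def __post_init__(self) -> None:
        for grade, active in self.active_edges_by_grade.items():
            if not active <= self.prior_edges:
                raise ConsistencyError(f"active edges of grade {grade} not all in prior")
        if self.prognostic_ffl is not None:
            last = list(self.active_edges_by_grade)[-1]
            if not self.prognostic_ffl.edges <= self.active_edges_by_grade[last]:
                raise ConsistencyError("prognostic FFL edges not active in the last grade")


def _rng(config_seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng([config_seed, *tags])


def generate_prior(config: SimulationConfig) -> DirectedNetwork:
    """Sample the binding prior: an Erdős–Rényi simple digraph on the TFs.

    Each ordered TF pair (u, v), u != v, carries an edge independently with
    probability ``prior_density``. Deterministic given ``config.seed``.
    """
    rng = _rng(config.seed, _TAG_PRIOR)
    tfs = config.tf_names()
    n = config.n_tfs
    mask = rng.random((n, n)) < config.prior_density
    np.fill_diagonal(mask, False)
    rows, cols = np.nonzero(mask)
    edges = {(tfs[i], tfs[j]) for i, j in zip(rows.tolist(), cols.tolist())}
    return DirectedNetwork(nodes=set(tfs), edges=edges)


# ---------------------------------------------------------------------------
# Planted truth


def _draw_structures(prior_adj: dict[str, set[str]], tfs: list[str],
                     n_pairs: int, n_ffls: int, used: set[str],
                     rng: np.random.Generator,
                     max_tries: int = 200_000) -> tuple[list[Edge], list[FFLInstance]]:
    """Draw node-disjoint planted structures from the prior.

    Pairs are prior edges with no reverse edge; FFLs are triples realizing
    the FFL pattern exactly (no other prior edge among the three).
    """
    pairs: list[Edge] = []
    ffls: list[FFLInstance] = []

    def has(u: str, v: str) -> bool:
        return v in prior_adj[u]

    tries = 0
    while len(ffls) < n_ffls:
        tries += 1
        if tries > max_tries:
            raise ConsistencyError(
                "could not find enough induced FFL triples in the prior; "
                "increase prior_density or n_tfs")
        ia, ib, ic = rng.choice(len(tfs), size=3, replace=False)
        a, b, c = tfs[ia], tfs[ib], tfs[ic]
        if a in used or b in used or c in used:
            continue
        present = [(u, v) for u in (a, b, c) for v in (a, b, c)
                   if u != v and has(u, v)]
        if len(present) != 3:
            continue
        out_deg = {t: sum(1 for u, _ in present if u == t) for t in (a, b, c)}
        in_deg = {t: sum(1 for _, v in present if v == t) for t in (a, b, c)}
        top = [t for t in (a, b, c) if out_deg[t] == 2]
        bot = [t for t in (a, b, c) if in_deg[t] == 2]
        if len(top) != 1 or len(bot) != 1 or top[0] == bot[0]:
            continue  # pattern is a cycle or fan, not an FFL
        mid = ({a, b, c} - {top[0], bot[0]}).pop()
        ffls.append(FFLInstance(top[0], mid, bot[0]))
        used.update((a, b, c))

    tries = 0
    while len(pairs) < n_pairs:
        tries += 1
        if tries > max_tries:
            raise ConsistencyError(
                "could not find enough disjoint one-way prior edges to plant")
        iu, iv = rng.choice(len(tfs), size=2, replace=False)
        u, v = tfs[iu], tfs[iv]
        if u in used or v in used:
            continue
        if has(u, v) and not has(v, u):
            pairs.append((u, v))
            used.update((u, v))
    return pairs, ffls


def plant_truth(prior: DirectedNetwork, config: SimulationConfig) -> PlantedTruth:
    """Choose the active (signal-carrying) structures for every grade.

    The first grade draws ``planted_edges_per_grade`` pair edges and
    ``planted_ffls_per_grade`` FFL triples; each later grade keeps every
    structure of the previous grade independently with probability
    ``1 - edge_turnover`` and redraws the rest. The prognostic FFL is the
    first FFL of the last grade (``None`` if no FFLs are planted).
    """
    rng = _rng(config.seed, _TAG_TRUTH)
    tfs = config.tf_names()
    adj: dict[str, set[str]] = {t: set() for t in tfs}
    for u, v in prior.edges:
        adj[u].add(v)
    if config.planted_edges_per_grade > prior.n_edges:
        raise ConsistencyError("more planted edges requested than prior edges")

    active: dict[str, set[Edge]] = {}
    ffls_by_grade: dict[str, list[FFLInstance]] = {}
    prev_pairs: list[Edge] = []
    prev_ffls: list[FFLInstance] = []
    for gi, grade in enumerate(config.grades):
        if gi == 0:
            kept_pairs, kept_ffls = [], []
        else:
            kept_pairs = [e for e in prev_pairs
                          if rng.random() >= config.edge_turnover]
            kept_ffls = [f for f in prev_ffls
                         if rng.random() >= config.edge_turnover]
        used = {t for e in kept_pairs for t in e}
        used |= {t for f in kept_ffls for t in f.tfs}
        new_pairs, new_ffls = _draw_structures(
            adj, tfs,
            config.planted_edges_per_grade - len(kept_pairs),
            config.planted_ffls_per_grade - len(kept_ffls),
            used, rng)
        pairs = kept_pairs + new_pairs
        ffls = kept_ffls + new_ffls
        active[grade] = set(pairs) | {e for f in ffls for e in f.edges}
        ffls_by_grade[grade] = ffls
        prev_pairs, prev_ffls = pairs, ffls

    last = config.grades[-1]
    prognostic = ffls_by_grade[last][0] if ffls_by_grade[last] else None
    return PlantedTruth(prior_edges=set(prior.edges),
                        active_edges_by_grade=active,
                        ffls_by_grade=ffls_by_grade,
                        prognostic_ffl=prognostic,
                        true_betas=config.ffl_betas)


# ---------------------------------------------------------------------------
# Expression


def _plant_pair(x: np.ndarray, iu: int, iv: int, rho: float, sigma: float,
                mu: float, rng: np.random.Generator) -> None:
    """Overwrite row iv with a linear response to row iu at correlation rho."""
    n = x.shape[1]
    zu = x[iu] - mu
    if rho >= 1.0 or sigma == 0.0:
        x[iv] = mu + zu
        return
    a = sigma * rho / np.sqrt(1.0 - rho ** 2)
    x[iv] = mu + a * zu + sigma * rng.standard_normal(n)


def _plant_ffl(x: np.ndarray, idx: tuple[int, int, int], rho: float,
               sigma: float, mu: float, rng: np.random.Generator) -> None:
    """Plant an FFL: each of the three edges carries correlation rho.

    middle responds to top; bottom responds to the (standardized) sum of top
    and middle with a weight chosen so corr(bottom, top) = corr(bottom,
    middle) = rho, using corr(top, middle) = rho.
    """
    it, im, ib = idx
    n = x.shape[1]
    _plant_pair(x, it, im, rho, sigma, mu, rng)
    if rho >= 1.0 or sigma == 0.0:
        x[ib] = x[it]
        return
    zt = (x[it] - mu)                                  # sd 1
    zm = (x[im] - mu) / np.sqrt((sigma * rho / np.sqrt(1 - rho ** 2)) ** 2
                                + sigma ** 2)          # sd 1
    # weight w on (zt + zm) giving corr rho with each parent:
    w = rho * sigma / np.sqrt((1 + rho) * (1 - rho) * (1 + 2 * rho))
    x[ib] = mu + w * (zt + zm) + sigma * rng.standard_normal(n)


def generate_expression(prior: DirectedNetwork, truth: PlantedTruth,
                        config: SimulationConfig
                        ) -> dict[tuple[str, str], pd.DataFrame]:
    """Simulate every (dataset, grade) expression matrix (TFs x samples).

    Non-planted TFs are iid Gaussian around :data:`EXPRESSION_MEAN` with unit
    sd; planted targets are linear responses to their regulators with
    residual sd ``noise_sd``, calibrated so each planted edge's expected
    |correlation| equals ``planted_correlation``. Deterministic given the
    config seed; every (dataset, grade) block has its own child stream.
    """
    for grade, active in truth.active_edges_by_grade.items():
        if not active <= prior.edges:
            raise ConsistencyError(f"planted edge of grade {grade} not in prior")
    tfs = config.tf_names()
    index = {t: i for i, t in enumerate(tfs)}
    rho, sigma, mu = config.planted_correlation, config.noise_sd, EXPRESSION_MEAN
    out: dict[tuple[str, str], pd.DataFrame] = {}
    for di, dataset in enumerate(config.dataset_names):
        for gi, grade in enumerate(config.grades):
            rng = _rng(config.seed, _TAG_EXPR, di, gi)
            n = config.samples_per_grade_per_dataset
            x = mu + rng.standard_normal((config.n_tfs, n))
            ffl_nodes = {t for f in truth.ffls_by_grade.get(grade, [])
                         for t in f.tfs}
            for u, v in sorted(truth.active_edges_by_grade[grade]):
                if u in ffl_nodes or v in ffl_nodes:
                    continue  # FFL edges handled as a unit below
                _plant_pair(x, index[u], index[v], rho, sigma, mu, rng)
            for f in truth.ffls_by_grade.get(grade, []):
                _plant_ffl(x, (index[f.top], index[f.middle], index[f.bottom]),
                           rho, sigma, mu, rng)
            cols = [f"{dataset}_{grade}_s{j + 1:03d}" for j in range(n)]
            out[(dataset, grade)] = pd.DataFrame(x, index=tfs, columns=cols)
    return out


# ---------------------------------------------------------------------------
# Survival


def _uniform_censoring_horizon(rates: np.ndarray, target: float) -> float:
    """Horizon c of Uniform(0, c) censoring achieving the target censor rate.

    For exponential survival with rate lambda and independent C ~ U(0, c),
    P(censored) = (1 - exp(-lambda c)) / (lambda c); the sample-averaged rate
    is monotone decreasing in c, so the horizon solves a 1-D root problem.
    """

    def mean_censor_rate(c: float) -> float:
        lc = rates * c
        return float(np.mean((1.0 - np.exp(-lc)) / lc))

    lo, hi = 1e-9, 1e12
    return brentq(lambda c: mean_censor_rate(c) - target, lo, hi, xtol=1e-10)


def generate_survival(expression: pd.DataFrame, ffl: FFLInstance,
                      betas: Sequence[float], config: SimulationConfig,
                      ) -> pd.DataFrame:
    """Simulate a survival table whose hazard follows the planted FFL.

    Each sample's survival time is exponential with rate
    ``lambda_0 * exp(sum_i beta_i * (x_i - mean(x_i)))`` where x are the
    expression rows of the FFL's TFs (centering keeps the baseline scale
    independent of the expression offset); lambda_0 = 1/12 puts the null
    median around 8 time units (months, nominally). Censoring is independent
    Uniform(0, c) with c solved so the expected censored fraction equals
    ``censoring_rate``. Deterministic given config seed and sample IDs.
    """
    for tf in ffl.tfs:
        if tf not in expression.index:
            raise ConsistencyError(f"FFL TF {tf} absent from expression matrix")
    if len(betas) != 3:
        raise ConfigurationError("exactly three log-hazard weights required")
    key = zlib.crc32("|".join(expression.columns).encode()) % (2 ** 31)
    rng = _rng(config.seed, _TAG_SURV, key)
    x = expression.loc[list(ffl.tfs)].to_numpy(dtype=float)
    eta = np.asarray(betas, dtype=float) @ (x - x.mean(axis=1, keepdims=True))
    base_rate = 1.0 / 12.0
    rates = base_rate * np.exp(eta)
    t_event = rng.exponential(1.0 / rates)
    if config.censoring_rate > 0.0:
        horizon = _uniform_censoring_horizon(rates, config.censoring_rate)
        t_cens = rng.uniform(0.0, horizon, size=len(t_event))
        event = (t_event <= t_cens).astype(int)
        time = np.minimum(t_event, t_cens)
    else:
        event = np.ones(len(t_event), dtype=int)
        time = t_event
    idh = np.where(rng.random(len(t_event)) < config.idh_mutant_rate,
                   "mutant", "wildtype")
    return pd.DataFrame({
        "sample_id": list(expression.columns),
        "time": np.maximum(time, 1e-8),
        "event": event,
        "idh_status": idh,
    })


# ---------------------------------------------------------------------------
# Whole-study bundle


@dataclass
class SimulationBundle:
    """Everything one synthetic study produces."""

    config: SimulationConfig
    prior: DirectedNetwork
    truth: PlantedTruth
    expression: dict[tuple[str, str], pd.DataFrame] = field(repr=False)
    survival: dict[str, pd.DataFrame] = field(repr=False)


def simulate_study(config: SimulationConfig) -> SimulationBundle:
    """Run the full generator: prior, truth, expression, last-grade survival."""
    prior = generate_prior(config)
    truth = plant_truth(prior, config)
    expression = generate_expression(prior, truth, config)
    last = config.grades[-1]
    survival: dict[str, pd.DataFrame] = {}
    if truth.prognostic_ffl is not None:
        for dataset in config.dataset_names:
            survival[dataset] = generate_survival(
                expression[(dataset, last)], truth.prognostic_ffl,
                truth.true_betas, config)
    return SimulationBundle(config=config, prior=prior, truth=truth,
                            expression=expression, survival=survival)
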