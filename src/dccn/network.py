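"""Co-consumption network construction by stability-selected partial
Spearman correlation.

Edge weights are partial Spearman correlations between food-group intakes,
adjusted for total energy intake and sex: every variable is rank-transformed
(average ranks for ties), the two food rank vectors are residualized on the
ranked covariates plus an intercept by least squares, and the Pearson
correlation of the residuals is the partial rank correlation. Significance
uses the t reference with n - 2 - k degrees of freedom.

Stability selection subsamples the group's dataset (default 50% without
replacement, 100 iterations); an edge is retained only when the mean
correlation magnitude across iterations exceeds the threshold (default 0.2)
and the correlation is significant (default p < 0.05) in every iteration.
One subsample per iteration is shared by all food pairs, which both mirrors
dataset-level subsampling and lets each iteration's full correlation matrix
be computed in a single vectorized pass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, DegenerateInputError

logger = logging.getLogger(__name__)


@dataclass
class StabilityParams:
    """Tuning parameters of the stability-selection stage."""

    n_iter: int = 100
    subsample_frac: float = 0.5
    r_threshold: float = 0.2
    alpha: float = 0.05
    with_replacement: bool = False
    seed: int = 0


@dataclass
class EdgeCandidate:
    """An unordered food pair with its stability-selection diagnostics."""

    food_a: str
    food_b: str
    mean_r: float
    n_significant: int
    n_iter: int
    sign_consistency: float = 1.0  # fraction of iterations agreeing with sign(mean_r)
    rs: np.ndarray | None = None  # per-iteration r values

    def __post_init__(self) -> None:
        if self.food_a == self.food_b:
            raise DataError("self-loop edge candidate")
        if self.food_a > self.food_b:
            self.food_a, self.food_b = self.food_b, self.food_a


@dataclass
class CoConsumptionNetwork:
    """Undirected signed weighted food–food network, isolates included."""

    nodes: list[str]
    edges: list[EdgeCandidate]
    group: str = ""
    params: StabilityParams | None = None
    degenerate_foods: list[str] = field(default_factory=list)

    def edge_set(self) -> set[tuple[str, str]]:
        return {(e.food_a, e.food_b) for e in self.edges}

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(group=self.group)
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(e.food_a, e.food_b, weight=e.mean_r,
                       n_significant=e.n_significant)
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph, group: str | None = None):
        edges = [
            EdgeCandidate(a, b, float(d["weight"]),
                          int(d.get("n_significant", 0)),
                          int(d.get("n_significant", 0)))
            for a, b, d in g.edges(data=True)
        ]
        return cls(sorted(g.nodes), edges, group or g.graph.get("group", ""))


def _ranks(a: np.ndarray) -> np.ndarray:
    return stats.rankdata(a, axis=0)


def _rank_residual_corr(
    X: np.ndarray, C: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Correlation matrix of covariate-residualized ranks.

    Returns ``(R, P, degenerate)``: the p × p partial-correlation and
    two-sided p-value matrices, and a boolean mask of columns with zero
    residual variance (their rows/columns are set to r = 0, p = 1).
    """
    n, p = X.shape
    k = 0 if C is None or C.size == 0 else C.shape[1]
    rx = _ranks(X)
    design = np.ones((n, 1 + k))
    if k:
        design[:, 1:] = _ranks(C)
    beta, *_ = np.linalg.lstsq(design, rx, rcond=None)
    resid = rx - design @ beta
    norms = np.linalg.norm(resid, axis=0)
    degenerate = norms <= 1e-10 * max(1.0, n)
    safe = np.where(degenerate, 1.0, norms)
    z = resid / safe
    R = np.clip(z.T @ z, -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    df = n - 2 - k
    if df <= 0:
        raise DataError(f"too few rows ({n}) for {k} covariates")
    with np.errstate(divide="ignore", invalid="ignore"):
        t = R * np.sqrt(df / np.maximum(1.0 - R * R, 1e-300))
    P = 2.0 * stats.t.sf(np.abs(t), df)
    R[degenerate, :] = 0.0
    R[:, degenerate] = 0.0
    P[degenerate, :] = 1.0
    P[:, degenerate] = 1.0
    return R, P, degenerate


def partial_spearman(
    x: Sequence[float],
    y: Sequence[float],
    covariates: np.ndarray | pd.DataFrame | None = None,
) -> tuple[float, float]:
    """Partial Spearman correlation of ``x`` and ``y`` given covariates.

    With no covariates this reduces to the plain Spearman rank correlation.
    Raises :class:`DegenerateInputError` when either variable is constant
    after ranking.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    C = None
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
    k = 0 if C is None else C.shape[1]
    if len(x) != len(y) or (C is not None and len(C) != len(x)):
        raise DataError("x, y and covariates must have equal length")
    if len(x) < k + 4:
        raise DataError(f"need at least {k + 4} observations, got {len(x)}")
    R, P, degenerate = _rank_residual_corr(np.column_stack([x, y]), C)
    if degenerate.any():
        which = ["x", "y"][int(np.flatnonzero(degenerate)[0])]
        raise DegenerateInputError(
            f"variable {which} has zero variance after ranking/residualization"
        )
    return float(R[0, 1]), float(P[0, 1])


def stability_edges(
    intake: pd.DataFrame,
    covariates: pd.DataFrame | None,
    params: StabilityParams | None = None,
    group: str = "",
    keep_iterations: bool = True,
) -> CoConsumptionNetwork:
    """Stability-selected co-consumption network for one outcome group.

    ``intake`` is a participants × foods cumulative-intake frame restricted
    to the group; ``covariates`` (same index) are the adjustment variables,
    typically energy and sex. Edge weight is the mean signed partial
    correlation across iterations.
    """
    params = params or StabilityParams()
    n, p = intake.shape
    m = int(np.floor(params.subsample_frac * n))
    foods = list(intake.columns)
    if n < 2 / params.subsample_frac:
        raise DataError(f"group too small for subsampling: n={n}")
    X = intake.to_numpy(dtype=float)
    C = None
    if covariates is not None and covariates.shape[1]:
        if not covariates.index.equals(intake.index):
            covariates = covariates.reindex(intake.index)
            if covariates.isna().any().any():
                raise DataError("covariates missing for some participants")
        C = covariates.to_numpy(dtype=float)

    rng = np.random.default_rng(params.seed)
    sum_r = np.zeros((p, p))
    sig = np.zeros((p, p), dtype=int)
    pos = np.zeros((p, p), dtype=int)
    ever_ok = np.zeros(p, dtype=bool)
    r_iter = np.empty((params.n_iter, p, p)) if keep_iterations else None
    for it in range(params.n_iter):
        idx = rng.choice(n, size=m, replace=params.with_replacement)
        R, P, degenerate = _rank_residual_corr(
            X[idx], None if C is None else C[idx]
        )
        sum_r += R
        sig += P < params.alpha
        pos += R > 0
        ever_ok |= ~degenerate
        if r_iter is not None:
            r_iter[it] = R

    mean_r = sum_r / params.n_iter
    dead = [f for f, ok in zip(foods, ever_ok) if not ok]
    for f in dead:
        logger.warning("food %r constant in every subsample; kept as isolate", f)

    edges = []
    iu, ju = np.triu_indices(p, k=1)
    for i, j in zip(iu, ju):
        if abs(mean_r[i, j]) > params.r_threshold and sig[i, j] == params.n_iter:
            frac_pos = pos[i, j] / params.n_iter
            edges.append(
                EdgeCandidate(
                    foods[i],
                    foods[j],
                    float(mean_r[i, j]),
                    int(sig[i, j]),
                    params.n_iter,
                    sign_consistency=frac_pos if mean_r[i, j] > 0 else 1 - frac_pos,
                    rs=r_iter[:, i, j].copy() if r_iter is not None else None,
                )
            )
    net = CoConsumptionNetwork(foods, edges, group=group, params=params,
                               degenerate_foods=dead)
    net._mean_r = mean_r  # diagnostics for sensitivity sweeps
    net._sig = sig
    net._r_iter = r_iter
    return net


def _edge_set(mean_r, sig_counts, foods, r_threshold, n_iter):
    iu, ju = np.triu_indices(len(foods), k=1)
    return {
        (foods[i], foods[j])
        for i, j in zip(iu, ju)
        if abs(mean_r[i, j]) > r_threshold and sig_counts[i, j] == n_iter
    }


def jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def threshold_sensitivity(
    intake: pd.DataFrame,
    covariates: pd.DataFrame | None,
    r_grid: Sequence[float] = (0.15, 0.2, 0.25, 0.30),
    n_iter_grid: Sequence[int] = (50, 75, 100),
    params: StabilityParams | None = None,
    group: str = "",
) -> pd.DataFrame:
    """Edge-set overlap with the default configuration over a parameter grid.

    One stability run at ``max(n_iter_grid)`` iterations supplies the
    per-iteration correlations; each grid point's edge set is derived from
    its first ``n_iter`` iterations and compared with the default
    configuration by Jaccard overlap.
    """
    params = params or StabilityParams()
    top = max(max(n_iter_grid), params.n_iter)
    run = StabilityParams(**{**params.__dict__, "n_iter": top})
    net = stability_edges(intake, covariates, run, group=group, keep_iterations=True)
    r_iter = net._r_iter
    foods = net.nodes

    def edges_at(r_thr: float, n_it: int) -> set:
        rs = r_iter[:n_it]
        mean_r = rs.mean(axis=0)
        # per-iteration significance recomputed from stored r (same t ref)
        n_rows = int(np.floor(params.subsample_frac * len(intake)))
        k = 0 if covariates is None else covariates.shape[1]
        df = n_rows - 2 - k
        t = rs * np.sqrt(df / np.maximum(1.0 - rs * rs, 1e-300))
        P = 2.0 * stats.t.sf(np.abs(t), df)
        sig = (P < params.alpha).sum(axis=0)
        return _edge_set(mean_r, sig, foods, r_thr, n_it)

    default = edges_at(params.r_threshold, params.n_iter)
    rows = []
    for n_it in n_iter_grid:
        for r_thr in r_grid:
            es = edges_at(r_thr, n_it)
            rows.append(
                {
                    "r_threshold": r_thr,
                    "n_iter": n_it,
                    "n_edges": len(es),
                    "jaccard_vs_default": jaccard(es, default),
                }
            )
    return pd.DataFrame(rows)
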