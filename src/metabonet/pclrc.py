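"""Probabilistic Context Likelihood of Relatedness on Correlation (PCLRC).

PCLRC infers a metabolite-metabolite association network for one sample
group.  Repeatedly (default 1000 iterations) a fraction of the samples
(default 75%) is drawn without replacement; the Spearman correlation
matrix of the subsample is background-corrected with the Context
Likelihood of Relatedness (CLR) filter applied to squared correlations,
and the top fraction (default 30%) of the nonzero CLR scores is marked
as "kept".  The probability ``p_ij`` of an association is the fraction
of iterations in which edge (i, j) was kept.  Networks are then built by
thresholding on ``p_ij`` and on the full-data Spearman ``|r_ij|``.

Squaring the correlations before CLR treats strong negative
associations as strong associations (CLR needs a non-negative relevance
measure); the sign is restored from the full-data correlation matrix
when networks are built and results reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from .data_io import AbundanceMatrix

__all__ = [
    "PclrcResult",
    "AssociationNetwork",
    "spearman_matrix",
    "clr_filter",
    "pclrc_infer",
    "build_network",
]


def _as_matrix(data) -> tuple[np.ndarray, list[str]]:
    if isinstance(data, AbundanceMatrix):
        return data.values.to_numpy(), data.metabolite_names
    x = np.asarray(data, dtype=float)
    return x, [f"var_{j + 1}" for j in range(x.shape[1])]


def spearman_matrix(data) -> np.ndarray:
    """Pairwise Spearman correlation matrix (average-rank ties).

    Accepts an AbundanceMatrix (or group subset) or a plain samples x
    variables array.  Constant columns get correlation 0 with a warning;
    the diagonal is 1.
    """
    x, _ = _as_matrix(data)
    if x.shape[0] < 4:
        raise ValueError("need at least 4 samples for Spearman correlation")
    r = _spearman_fast(x)
    const = x.std(axis=0) == 0
    if const.any():
        warnings.warn(
            f"constant columns at indices {np.flatnonzero(const).tolist()}; "
            "their correlations are set to 0"
        )
    return r


def _spearman_fast(x: np.ndarray) -> np.ndarray:
    """Rank columns (average ties) then Pearson; NaN from zero variance -> 0."""
    ranks = stats.rankdata(x, axis=0, method="average")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(ranks, rowvar=False)
    r = np.nan_to_num(r, nan=0.0)
    np.fill_diagonal(r, 1.0)
    return np.clip((r + r.T) / 2.0, -1.0, 1.0)


def _has_ties(x: np.ndarray) -> bool:
    xs = np.sort(x, axis=0)
    return bool((xs[1:] == xs[:-1]).any())


def _spearman_noties(x: np.ndarray) -> np.ndarray:
    """Spearman for tie-free columns via one matmul.

    Without ties every column's ranks are a permutation of 1..n, so rank
    mean and variance are constants and the correlation is
    ``c' c / (n (n^2 - 1) / 12)`` with c the centered ranks.
    """
    n, p = x.shape
    idx = np.argsort(x, axis=0)
    c = np.empty((n, p))
    ar = (np.arange(1, n + 1, dtype=float) - (n + 1) / 2.0)[:, None]
    np.put_along_axis(c, idx, np.broadcast_to(ar, (n, p)), axis=0)
    r = (c.T @ c) / (n * (n * n - 1) / 12.0)
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def clr_filter(m: np.ndarray) -> np.ndarray:
    """Context Likelihood of Relatedness scores of an association matrix.

    For a symmetric non-negative matrix M, each entry is z-scored against
    its row (excluding the diagonal): ``z_i|j = (M_ij - mean_i) / sd_i``;
    the CLR score combines the two directions,
    ``z_ij = sqrt(max(0, z_i|j)^2 + max(0, z_j|i)^2)``.  Rows with zero
    spread contribute 0.  Output is symmetric with zero diagonal.
    """
    m = np.asarray(m, dtype=float)
    p = m.shape[0]
    if m.shape != (p, p):
        raise ValueError("CLR needs a square matrix")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError("CLR needs a symmetric matrix")
    if m.min() < 0:
        raise ValueError("CLR needs a non-negative association matrix")
    if p < 3:
        raise ValueError("CLR needs at least 3 variables")
    off = ~np.eye(p, dtype=bool)
    # row mean/sd (ddof=1) over the p-1 off-diagonal entries, via sums
    diag = np.diag(m)
    row_mean = (m.sum(axis=1) - diag) / (p - 1)
    row_sq = (m * m).sum(axis=1) - diag * diag
    row_var = np.maximum(row_sq - (p - 1) * row_mean**2, 0.0) / (p - 2)
    # guard against catastrophic cancellation on (near-)constant rows
    row_var[row_var <= 1e-13 * np.maximum(row_mean**2, 1e-30)] = 0.0
    row_sd = np.sqrt(row_var)
    safe_sd = np.where(row_sd > 0, row_sd, 1.0)
    z_rows = (m - row_mean[:, None]) / safe_sd[:, None]
    z_rows[row_sd == 0, :] = 0.0
    z_rows = np.maximum(z_rows, 0.0)
    z = np.sqrt(z_rows**2 + z_rows.T**2)
    z[~off] = 0.0
    return z


@dataclass
class PclrcResult:
    """Edge probabilities P and full-data Spearman R for one group."""

    P: np.ndarray
    R: np.ndarray
    metabolite_names: list[str]
    settings: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert np.allclose(self.P, self.P.T, atol=1e-12)
        assert np.all((self.P >= 0) & (self.P <= 1))
        assert np.all(np.diag(self.P) == 0)


@dataclass
class AssociationNetwork:
    """Thresholded weighted undirected graph derived from (P, R)."""

    graph: nx.Graph
    p_min: float
    r_min: float

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def _kept_edges(x: np.ndarray, idx: np.ndarray, retention_quantile: float,
                iu: tuple[np.ndarray, np.ndarray], tie_free: bool = False) -> np.ndarray:
    """One PCLRC iteration: boolean upper-triangle mask of retained edges."""
    xs = x[idx]
    r = _spearman_noties(xs) if tie_free else _spearman_fast(xs)
    c = clr_filter(r**2)
    vals = c[iu]
    pos = vals[vals > 0]
    if pos.size == 0:
        return np.zeros_like(vals, dtype=bool)
    thr = np.quantile(pos, 1.0 - retention_quantile)
    return vals >= thr


def pclrc_infer(
    data,
    n_iterations: int = 1000,
    subsample_fraction: float = 0.75,
    retention_quantile: float = 0.30,
    seed: int | np.random.SeedSequence = 0,
) -> PclrcResult:
    """Infer the PCLRC edge-probability matrix for one group's samples.

    Deterministic given ``seed``.  With ``subsample_fraction=1.0`` every
    iteration sees the full data, so P is binary: 1 for edges in the top
    ``retention_quantile`` of full-data CLR scores, 0 elsewhere.
    """
    x, names = _as_matrix(data)
    n = x.shape[0]
    if n < 20:
        raise ValueError("PCLRC needs at least 20 samples per group")
    if n < 40:
        warnings.warn(f"only {n} samples; PCLRC probabilities will be noisy")
    if not (0.0 < subsample_fraction <= 1.0):
        raise ValueError("subsample_fraction must be in (0, 1]")
    if not (0.0 < retention_quantile < 1.0):
        raise ValueError("retention_quantile must be in (0, 1)")
    m = int(np.floor(subsample_fraction * n))
    if m < 5:
        raise ValueError("subsample too small (< 5 samples)")
    rng = np.random.default_rng(seed)
    p = x.shape[1]
    iu = np.triu_indices(p, k=1)
    counts = np.zeros(iu[0].size)
    tie_free = not _has_ties(x)  # tie-free data stays tie-free in subsamples
    for _ in range(n_iterations):
        idx = rng.choice(n, size=m, replace=False)
        counts += _kept_edges(x, idx, retention_quantile, iu, tie_free)
    prob = counts / n_iterations
    P = np.zeros((p, p))
    P[iu] = prob
    P += P.T
    R = _spearman_fast(x)
    seed_repr = seed if isinstance(seed, int) else "seedsequence"
    return PclrcResult(
        P=P,
        R=R,
        metabolite_names=names,
        settings={
            "n_iterations": n_iterations,
            "subsample_fraction": subsample_fraction,
            "retention_quantile": retention_quantile,
            "seed": seed_repr,
        },
    )


def build_network(res: PclrcResult, p_min: float = 0.95, r_min: float = 0.6) -> AssociationNetwork:
    """Threshold (P, R) into an association network.

    Edges require ``p_ij >= p_min`` and ``|r_ij| >= r_min``; all
    metabolites remain as nodes, possibly isolated.  Edge ``weight`` is
    the signed full-data Spearman correlation, ``probability`` is p_ij.
    """
    g = nx.Graph()
    g.add_nodes_from(res.metabolite_names)
    p = len(res.metabolite_names)
    iu = np.triu_indices(p, k=1)
    for i, j in zip(*iu):
        if res.P[i, j] > 0 and res.P[i, j] >= p_min and abs(res.R[i, j]) >= r_min:
            g.add_edge(
                res.metabolite_names[i],
                res.metabolite_names[j],
                weight=float(res.R[i, j]),
                probability=float(res.P[i, j]),
            )
    return AssociationNetwork(graph=g, p_min=p_min, r_min=r_min)
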