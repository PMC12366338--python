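"""PCNM spatial eigenvectors and permutation-based forward selection.

PCNM (principal coordinates of neighbour matrices) turns quadrat
coordinates into orthogonal spatial eigenvectors spanning all scales the
sampling design can resolve: the Euclidean distance matrix is truncated
at the largest minimum-spanning-tree edge (keeping the neighbour graph
connected), distances beyond the threshold are replaced by 4x the
threshold, the matrix is Gower-centred, and the positive-eigenvalue
eigenvectors (scaled by the square root of their eigenvalue) are
retained as candidate spatial predictors.

Forward selection follows the vegan-style double stopping rule: at each
step the axis giving the largest R² increase enters if its permutation
p-value is <= alpha, and selection also stops once the cumulative
adjusted R² exceeds that of the full-axis model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger("genspec")


@dataclass
class PcnmResult:
    eigenvectors: pd.DataFrame  # samples x axes, columns PCNM1..k
    eigenvalues: np.ndarray
    truncation_threshold: float
    selected: list[str] = field(default_factory=list)
    selection_stats: pd.DataFrame | None = None


def pcnm_eigenvectors(coords: np.ndarray, truncation: float | None = None) -> PcnmResult:
    """Positive-eigenvalue PCNM axes from point coordinates.

    The default truncation threshold is the largest edge of the minimum
    spanning tree of the Euclidean distance graph (the spacing itself on
    a regular grid).
    """
    coords = np.asarray(coords, dtype=float)
    if len(coords) < 3:
        raise ValueError("need at least 3 points")
    if len(np.unique(coords, axis=0)) != len(coords):
        raise ValueError("duplicate coordinates")
    d = squareform(pdist(coords))
    if truncation is None:
        mst = minimum_spanning_tree(d).toarray()
        truncation = float(mst.max())
    trunc = d.copy()
    # relative tolerance so distances exactly at the threshold (grid spacing)
    # survive coordinate rotation round-off
    trunc[trunc > truncation * (1 + 1e-8)] = 4.0 * truncation

    n = len(coords)
    # Gower double-centring of -0.5 * D^2
    a = -0.5 * trunc**2
    centred = a - a.mean(axis=0) - a.mean(axis=1)[:, None] + a.mean()
    eigval, eigvec = np.linalg.eigh(centred)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    positive = eigval > max(1e-8, 1e-10 * abs(eigval).max())
    eigval = eigval[positive]
    eigvec = eigvec[:, positive] * np.sqrt(eigval)
    cols = [f"PCNM{i + 1}" for i in range(eigvec.shape[1])]
    return PcnmResult(
        eigenvectors=pd.DataFrame(eigvec, columns=cols),
        eigenvalues=eigval,
        truncation_threshold=truncation,
    )


def _r_squared(x: np.ndarray, y: np.ndarray) -> float:
    """OLS R² of y on x (with intercept)."""
    x = np.column_stack([np.ones(len(y)), x])
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    sst = ((y - y.mean()) ** 2).sum()
    return 1.0 - (resid**2).sum() / sst if sst > 0 else 0.0


def _adjusted(r2: float, n: int, k: int) -> float:
    if n - k - 1 <= 0:
        return -np.inf
    return 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)


def _gains(x_resid: np.ndarray, norms2: np.ndarray, y: np.ndarray, sst: float) -> np.ndarray:
    """R² gain of adding each residualised candidate, as a share of SST."""
    num = x_resid.T @ (y - y.mean())
    with np.errstate(divide="ignore", invalid="ignore"):
        g = num**2 / norms2 / sst
    g[norms2 <= 1e-12 * norms2.max()] = -np.inf  # candidates absorbed by the model
    return g


def forward_select(
    vectors: pd.DataFrame,
    response: np.ndarray | pd.Series,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[list[str], pd.DataFrame]:
    """Greedy forward selection of axes against a response.

    At each step the candidate with the largest R² gain enters if the
    permutation p-value of that maximal gain (response permuted,
    ``n_perm`` replicates, the maximum recomputed over all remaining
    candidates so that screening many axes does not inflate the error
    rate) is <= alpha. A second stopping rule ends selection once the
    cumulative adjusted R² exceeds the adjusted R² of the full-axis
    model. Ties break by axis order. Returns (selected names, per-step
    statistics).
    """
    y = np.asarray(response, dtype=float)
    x_all = vectors.to_numpy()
    n = len(y)
    if x_all.shape[0] != n:
        raise ValueError("vectors and response are not aligned")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    full_adj = _adjusted(_r_squared(x_all, y), n, x_all.shape[1])
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0:
        return [], pd.DataFrame()

    selected: list[int] = []
    stats_rows = []
    remaining = list(range(x_all.shape[1]))
    current_r2 = 0.0
    while remaining:
        # residualise remaining candidates on the selected set (+ intercept)
        base = np.column_stack([np.ones(n)] + [x_all[:, j] for j in selected])
        q, _ = np.linalg.qr(base)
        xr = x_all[:, remaining]
        xr = xr - q @ (q.T @ xr)
        norms2 = (xr**2).sum(axis=0)
        yr = y - q @ (q.T @ y)
        gains = _gains(xr, norms2, yr, sst)
        best_pos = int(np.argmax(gains))  # argmax takes the first on ties
        gain = float(gains[best_pos])
        # permutation null of the maximal gain over all remaining candidates
        exceed = 0
        for _ in range(n_perm):
            yp = rng.permutation(yr)
            if _gains(xr, norms2, yp, sst).max() >= gain:
                exceed += 1
        p = float((1 + exceed) / (n_perm + 1))
        if p > alpha:
            break
        j_best = remaining[best_pos]
        candidate_r2 = _r_squared(x_all[:, selected + [j_best]], y)
        adj = _adjusted(candidate_r2, n, len(selected) + 1)
        stats_rows.append(
            {
                "axis": vectors.columns[j_best],
                "r2_gain": candidate_r2 - current_r2,
                "cum_r2": candidate_r2,
                "cum_adj_r2": adj,
                "p_value": p,
            }
        )
        selected.append(j_best)
        remaining.remove(j_best)
        current_r2 = candidate_r2
        if adj > full_adj:
            logger.info("stopping: cumulative adjusted R² exceeded the full model's")
            break
    if not selected:
        logger.info("forward selection found no significant axis")
    names = [vectors.columns[j] for j in selected]
    return names, pd.DataFrame(stats_rows)


def pcnm_with_selection(
    coords: np.ndarray,
    response: np.ndarray | pd.Series,
    truncation: float | None = None,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int = 0,
) -> PcnmResult:
    """Convenience wrapper: PCNM axes then forward selection."""
    res = pcnm_eigenvectors(coords, truncation)
    names, stats_ = forward_select(res.eigenvectors, response, alpha, n_perm, seed)
    res.selected = names
    res.selection_stats = stats_
    return res
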