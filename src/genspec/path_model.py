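"""Partial least squares path modelling (PLS-PM) for environmental effects.

Latent variables (light, spatial, plant, topography, richness) are each
measured by a block of indicators. Latent scores are estimated by the
Lohmöller iteration with reflective (mode A) outer weighting and either
the path or centroid inner scheme; inner path coefficients come from
OLS of each endogenous latent on its predecessors. Effects decompose by
the path-tracing rule (total = direct + sum of products along indirect
routes) and overall quality is the goodness of fit

    GoF = sqrt(mean communality x mean R²),

with communality the squared loading of each indicator on its own
latent, averaged over all indicators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("genspec")


@dataclass
class PathModelSpec:
    """Blocks of indicators plus the inner (latent-level) path diagram."""

    blocks: dict[str, tuple[str, ...]]
    inner_paths: list[tuple[str, str]]
    response: str = "richness"
    inner_scheme: str = "path"  # or "centroid"

    def __post_init__(self) -> None:
        names = set(self.blocks)
        for a, b in self.inner_paths:
            if a not in names or b not in names:
                raise ValueError(f"path {a}->{b} references an unknown block")
        if self.response not in names:
            raise ValueError(f"response block {self.response!r} not among blocks")
        order = self.topological_order()
        exog = [b for b in self.blocks if not self.predecessors(b)]
        reach = {self.response}
        changed = True
        while changed:
            changed = False
            for a, b in self.inner_paths:
                if b in reach and a not in reach:
                    reach.add(a)
                    changed = True
        unreachable = [b for b in exog if b not in reach]
        if unreachable:
            raise ValueError(f"response not reachable from blocks: {unreachable}")
        del order

    def predecessors(self, block: str) -> list[str]:
        return [a for a, b in self.inner_paths if b == block]

    def successors(self, block: str) -> list[str]:
        return [b for a, b in self.inner_paths if a == block]

    def topological_order(self) -> list[str]:
        order: list[str] = []
        pending = dict.fromkeys(self.blocks)
        while pending:
            ready = [b for b in pending if all(p in order for p in self.predecessors(b))]
            if not ready:
                raise ValueError("inner path diagram contains a cycle")
            for b in ready:
                order.append(b)
                del pending[b]
        return order

    @classmethod
    def default(cls, spatial_indicators: tuple[str, ...] = ("PCNM1", "PCNM2")) -> "PathModelSpec":
        blocks = {
            "light": ("CC", "SR", "LT"),
            "spatial": spatial_indicators,
            "plant": ("BA", "DEN"),
            "topography": ("ASP",),
            "richness": ("richness",),
        }
        paths = [(b, "richness") for b in ("light", "spatial", "plant", "topography")]
        return cls(blocks=blocks, inner_paths=paths)


@dataclass
class PathModelResult:
    outer_weights: pd.Series
    loadings: pd.Series
    scores: pd.DataFrame
    path_coefficients: pd.DataFrame  # index=source, columns=target, NaN where no edge
    r_squared: dict[str, float]
    effects: pd.DataFrame  # per (block -> response): direct, indirect, total
    gof: float
    n_iter: int
    boot_ci: pd.DataFrame | None = None

    def coefficient(self, source: str, target: str) -> float:
        return float(self.path_coefficients.loc[source, target])


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean(axis=0)) / x.std(axis=0, ddof=0)


def fit_plspm(
    data: pd.DataFrame,
    spec: PathModelSpec,
    tol: float = 1e-6,
    max_iter: int = 300,
) -> PathModelResult:
    """Fit the PLS path model on a per-sample indicator table.

    Rows with missing values are dropped with a warning; indicators are
    standardised internally. Raises on non-convergence with the trace of
    outer-weight changes.
    """
    indicators = [c for cols in spec.blocks.values() for c in cols]
    missing_cols = [c for c in indicators if c not in data.columns]
    if missing_cols:
        raise ValueError(f"data lacks indicator columns: {missing_cols}")
    sub = data[indicators]
    if sub.isna().any().any():
        n0 = len(sub)
        sub = sub.dropna()
        logger.warning("dropped %d rows with missing indicators", n0 - len(sub))
    x = {b: _standardize(sub[list(cols)].to_numpy(dtype=float)) for b, cols in spec.blocks.items()}
    for b, mat in x.items():
        if mat.shape[1] > 1:
            cond = np.linalg.cond(mat.T @ mat)
            if cond > 1e6:
                logger.warning("block %r indicators nearly collinear (cond=%.2g)", b, cond)
    n = len(sub)
    blocks = list(spec.blocks)
    adjacency = {
        b: sorted(set(spec.predecessors(b)) | set(spec.successors(b))) for b in blocks
    }

    weights = {b: np.ones(x[b].shape[1]) for b in blocks}

    def latent_scores(w: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        scores = {}
        for b in blocks:
            y = x[b] @ w[b]
            sd = y.std(ddof=0)
            scores[b] = y / (sd if sd > 0 else 1.0)
        return scores

    trace = []
    y = latent_scores(weights)
    for it in range(max_iter):
        # inner approximation
        z = {}
        for b in blocks:
            zb = np.zeros(n)
            if spec.inner_scheme == "centroid":
                for other in adjacency[b]:
                    r = np.corrcoef(y[b], y[other])[0, 1]
                    zb += np.sign(r) * y[other]
            elif spec.inner_scheme == "path":
                preds = spec.predecessors(b)
                if preds:
                    xp = np.column_stack([y[p] for p in preds])
                    beta, *_ = np.linalg.lstsq(xp, y[b], rcond=None)
                    zb += xp @ beta
                for succ in spec.successors(b):
                    r = np.corrcoef(y[b], y[succ])[0, 1]
                    zb += r * y[succ]
            else:
                raise ValueError(f"unknown inner scheme {spec.inner_scheme!r}")
            sd = zb.std(ddof=0)
            z[b] = zb / (sd if sd > 0 else 1.0)
        # outer update, mode A
        new_w = {}
        delta = 0.0
        for b in blocks:
            w = x[b].T @ z[b] / n  # correlations (indicators standardised)
            norm = np.linalg.norm(w)
            w = w / (norm if norm > 0 else 1.0)
            old = weights[b] / (np.linalg.norm(weights[b]) or 1.0)
            delta = max(delta, float(np.abs(w - old).max()))
            new_w[b] = w
        weights = new_w
        y = latent_scores(weights)
        trace.append(delta)
        if delta < tol:
            break
    else:
        raise RuntimeError(f"PLS-PM did not converge in {max_iter} iterations; trace={trace[-10:]}")

    # orient each latent with its block (positive mean loading)
    loadings_list = []
    weights_list = []
    for b in blocks:
        load = x[b].T @ y[b] / n
        if load.sum() < 0:
            y[b] = -y[b]
            weights[b] = -weights[b]
            load = -load
        for c, l_, w_ in zip(spec.blocks[b], load, weights[b]):
            loadings_list.append((c, l_))
            weights_list.append((c, w_))
    loadings = pd.Series(dict(loadings_list), name="loading")
    outer_weights = pd.Series(dict(weights_list), name="weight")
    scores = pd.DataFrame({b: y[b] for b in blocks}, index=sub.index)

    # inner path coefficients by OLS
    coef = pd.DataFrame(np.nan, index=blocks, columns=blocks)
    r_squared: dict[str, float] = {}
    for b in blocks:
        preds = spec.predecessors(b)
        if not preds:
            continue
        xp = np.column_stack([y[p] for p in preds])
        beta, *_ = np.linalg.lstsq(xp, y[b], rcond=None)
        fitted = xp @ beta
        r_squared[b] = float(1.0 - ((y[b] - fitted) ** 2).sum() / (y[b] ** 2).sum())
        for p, bt in zip(preds, beta):
            coef.loc[p, b] = float(bt)

    # effects decomposition by path tracing
    bmat = coef.fillna(0.0).to_numpy()
    total = np.zeros_like(bmat)
    power = np.eye(len(blocks))
    for _ in range(len(blocks)):
        power = power @ bmat
        total += power
    ti = {b: i for i, b in enumerate(blocks)}
    rows = []
    for b in blocks:
        if b == spec.response:
            continue
        direct = coef.loc[b, spec.response]
        direct = 0.0 if pd.isna(direct) else float(direct)
        tot = float(total[ti[b], ti[spec.response]])
        rows.append({"block": b, "direct": direct, "indirect": tot - direct, "total": tot})
    effects = pd.DataFrame(rows).set_index("block")

    communality = float((loadings**2).mean())
    mean_r2 = float(np.mean(list(r_squared.values()))) if r_squared else np.nan
    gof = float(np.sqrt(communality * mean_r2))

    return PathModelResult(
        outer_weights=outer_weights,
        loadings=loadings,
        scores=scores,
        path_coefficients=coef,
        r_squared=r_squared,
        effects=effects,
        gof=gof,
        n_iter=it + 1,
    )


def bootstrap_paths(
    data: pd.DataFrame,
    spec: PathModelSpec,
    n_boot: int = 500,
    seed: int = 0,
    **fit_kwargs,
) -> pd.DataFrame:
    """Percentile bootstrap CIs for the direct paths into the response."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = {b: [] for b in spec.predecessors(spec.response)}
    n = len(data)
    for _ in range(n_boot):
        idx = rng.integers(n, size=n)
        try:
            res = fit_plspm(data.iloc[idx], spec, **fit_kwargs)
        except (RuntimeError, np.linalg.LinAlgError):
            continue
        for b in rows:
            rows[b].append(res.coefficient(b, spec.response))
    out = []
    for b, vals in rows.items():
        v = np.array(vals)
        out.append(
            {
                "block": b,
                "n_boot": len(v),
                "mean": v.mean(),
                "ci_low": np.percentile(v, 2.5),
                "ci_high": np.percentile(v, 97.5),
            }
        )
    return pd.DataFrame(out).set_index("block")


def effect_shares(result: PathModelResult) -> pd.DataFrame:
    """Per-block |direct| and |total| effects as % of the summed |total|.

    Signs are reported separately; shares of |total| sum to 100%.
    """
    eff = result.effects
    denom = eff["total"].abs().sum()
    if denom == 0:
        raise ValueError("all total effects are zero; shares undefined")
    return pd.DataFrame(
        {
            "direct_share_pct": 100.0 * eff["direct"].abs() / denom,
            "total_share_pct": 100.0 * eff["total"].abs() / denom,
            "direct_sign": np.sign(eff["direct"]),
            "total_sign": np.sign(eff["total"]),
        }
    )


def fit_per_subcommunity(
    data: pd.DataFrame,
    richness_by_category: pd.DataFrame,
    spec: PathModelSpec,
    **fit_kwargs,
) -> tuple[dict[str, PathModelResult], pd.DataFrame]:
    """One PLS-PM fit per richness column (overall / generalist / ...).

    Returns the fitted models and a side-by-side table of direct paths
    into the response plus GoF. Constant responses are skipped with a
    warning.
    """
    results: dict[str, PathModelResult] = {}
    rows = []
    for col in richness_by_category.columns:
        y = richness_by_category[col]
        if y.std() == 0:
            logger.warning("response %r is constant; fit skipped", col)
            continue
        d = data.copy()
        d[spec.blocks[spec.response][0]] = y.to_numpy(dtype=float)
        res = fit_plspm(d, spec, **fit_kwargs)
        results[col] = res
        row = {"response": col, "gof": res.gof, "r2": res.r_squared.get(spec.response, np.nan)}
        for b in spec.predecessors(spec.response):
            row[f"path_{b}"] = res.coefficient(b, spec.response)
        rows.append(row)
    return results, pd.DataFrame(rows).set_index("response")
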