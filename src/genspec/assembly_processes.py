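"""Deterministic vs stochastic community assembly.

Four complementary analyses:

* **βMNTD / βNTI** — abundance-weighted between-community mean
  nearest-taxon phylogenetic distance, standardised against a
  tip-label-shuffling null. |βNTI| > 2 indicates deterministic selection
  (heterogeneous when βNTI > +2, homogeneous when < −2).
* **RC-Bray** — Raup–Crick metric on Bray–Curtis dissimilarity against
  richness- and occupancy-constrained null assemblages, rescaled to
  [−1, 1]; splits the |βNTI| ≤ 2 pairs into dispersal limitation
  (> +0.95), homogenising dispersal (< −0.95), and drift.
* **Sloan neutral community model** — one free parameter, the migration
  rate m, predicting each OTU's occurrence frequency from its mean
  relative abundance via the Beta stationary approximation; goodness of
  fit is Östman's R².
* **C-score / SES** — mean checkerboard units over OTU pairs,
  standardised against sequential-swap (fixed row and column totals)
  null matrices; positive SES means segregation, negative aggregation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy import optimize, stats
from scipy.spatial.distance import pdist, squareform
from skbio import TreeNode
from statsmodels.stats.proportion import proportion_confint

from .io_formats import OtuTable, check_tree_covers

logger = logging.getLogger("genspec")

PROCESSES = (
    "heterogeneous_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "drift",
)


# ---------------------------------------------------------------------------
# beta-MNTD / beta-NTI

def _patristic_matrix(tree: TreeNode, otu_ids: list[str]) -> np.ndarray:
    dm = tree.tip_tip_distances(endpoints=list(otu_ids))
    # reorder to table order
    idx = [dm.ids.index(o) for o in otu_ids]
    return dm.data[np.ix_(idx, idx)]


@njit(cache=True)
def _nearest_taxon_mins(sorted_idx, dist, perm, member, mind):  # pragma: no cover
    """mind[j, l] = min patristic distance from (permuted) OTU j to sample l.

    ``member[l, t] = True`` iff permuted-tip t occurs in sample l; rows of
    ``sorted_idx`` walk each distance row in increasing order, so the
    first member hit is the nearest taxon.
    """
    n_otus, n_samples = mind.shape
    for j in range(n_otus):
        pj = perm[j]
        row = sorted_idx[pj]
        for l in range(n_samples):
            for t_i in range(n_otus):
                t = row[t_i]
                if member[l, t]:
                    mind[j, l] = dist[pj, t]
                    break


def beta_mntd(table: OtuTable, tree: TreeNode, weighted: bool = True) -> pd.DataFrame:
    """Pairwise abundance-weighted beta mean nearest taxon distance.

    For samples k, l:
    ``0.5 * (sum_j f_jk min_{j' in l} d(j, j') + sum_j f_jl min_{j' in k} d(j, j'))``
    with f the within-sample relative abundances (presence weights 1/S if
    ``weighted=False``). Identical communities score 0.
    """
    check_tree_covers(tree, table.otu_ids)
    dist = _patristic_matrix(tree, table.otu_ids)
    mntd = _beta_mntd_from_dist(table, dist, weighted)
    return pd.DataFrame(mntd, index=table.sample_ids, columns=table.sample_ids)


def _weights(table: OtuTable, weighted: bool) -> np.ndarray:
    if weighted:
        return table.relative_abundance().T  # otus x samples
    pa = table.presence_absence().T.astype(float)
    return pa / pa.sum(axis=0, keepdims=True)


def _beta_mntd_from_dist(
    table: OtuTable, dist: np.ndarray, weighted: bool, perm: np.ndarray | None = None
) -> np.ndarray:
    n_otus, n_samples = table.n_otus, table.n_samples
    pres = table.presence_absence().astype(bool)  # samples x otus
    if perm is None:
        perm = np.arange(n_otus)
    member = np.empty_like(pres)
    member[:, perm] = pres
    sorted_idx = np.argsort(dist, axis=1).astype(np.int32)
    mind = np.empty((n_otus, n_samples))
    _nearest_taxon_mins(sorted_idx, dist, perm.astype(np.int64), member, mind)
    f = _weights(table, weighted)
    m = f.T @ mind
    out = (m + m.T) / 2.0
    np.fill_diagonal(out, 0.0)
    return out


def beta_nti(
    table: OtuTable,
    tree: TreeNode,
    n_null: int = 999,
    seed: int = 0,
    weighted: bool = True,
) -> pd.DataFrame:
    """βNTI: z-score of observed βMNTD against tip-shuffling nulls.

    Pairs whose null βMNTD distribution has zero spread (e.g. on a star
    tree) are reported as NaN with a warning.
    """
    check_tree_covers(tree, table.otu_ids)
    dist = _patristic_matrix(tree, table.otu_ids)
    sorted_idx = np.argsort(dist, axis=1).astype(np.int32)
    pres = table.presence_absence().astype(bool)
    f = _weights(table, weighted)
    n_otus, n_samples = table.n_otus, table.n_samples

    def mntd_for(perm: np.ndarray) -> np.ndarray:
        member = np.empty_like(pres)
        member[:, perm] = pres
        mind = np.empty((n_otus, n_samples))
        _nearest_taxon_mins(sorted_idx, dist, perm, member, mind)
        m = f.T @ mind
        out = (m + m.T) / 2.0
        np.fill_diagonal(out, 0.0)
        return out

    obs = mntd_for(np.arange(n_otus))
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    s1 = np.zeros_like(obs)
    s2 = np.zeros_like(obs)
    for _ in range(n_null):
        null = mntd_for(rng.permutation(n_otus))
        s1 += null
        s2 += null**2
    mean = s1 / n_null
    var = s2 / n_null - mean**2
    sd = np.sqrt(np.clip(var, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (obs - mean) / sd
    degenerate = sd <= 1e-12
    np.fill_diagonal(degenerate, False)
    if degenerate.any():
        logger.warning(
            "βNTI undefined for %d sample pairs (zero null spread)", int(degenerate.sum()) // 2
        )
        z[degenerate] = np.nan
    np.fill_diagonal(z, 0.0)
    return pd.DataFrame(z, index=table.sample_ids, columns=table.sample_ids)


# ---------------------------------------------------------------------------
# Raup-Crick (Bray-Curtis) null model

def raup_crick_bray(table: OtuTable, n_null: int = 999, seed: int = 0) -> pd.DataFrame:
    """RC-Bray matrix in [−1, 1], seed-deterministic.

    Null assemblages preserve each sample's observed richness and total
    reads: species are drawn without replacement with probability
    proportional to their occurrence frequency, then individuals are
    assigned proportionally to mean relative abundance. RC is the
    fraction of null Bray–Curtis values below the observed one (ties
    count half), rescaled to ``2 (RC - 0.5)``.
    """
    counts = table.counts
    richness = (counts > 0).sum(axis=1)
    if (richness == 0).any():
        raise ValueError("samples with zero richness are not allowed")
    totals = counts.sum(axis=1)
    occ_freq = (counts > 0).mean(axis=0).astype(float)
    mean_rel = table.relative_abundance().mean(axis=0)
    n_samples, n_otus = counts.shape

    obs_bc = pdist(counts, metric="braycurtis")
    less = np.zeros_like(obs_bc)
    equal = np.zeros_like(obs_bc)

    logw = np.log(np.where(occ_freq > 0, occ_freq, 1e-300))
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    for _ in range(n_null):
        # Gumbel top-k: weighted sampling without replacement, all samples at once
        keys = logw[None, :] + rng.gumbel(size=(n_samples, n_otus))
        order = np.argsort(-keys, axis=1)
        null = np.zeros((n_samples, n_otus), dtype=np.int64)
        for i in range(n_samples):
            chosen = order[i, : richness[i]]
            p = mean_rel[chosen]
            p = p / p.sum()
            null[i, chosen] = 1 + rng.multinomial(totals[i] - richness[i], p)
        bc = pdist(null, metric="braycurtis")
        less += bc < obs_bc
        equal += bc == obs_bc
    rc = (less + 0.5 * equal) / n_null
    rc = 2.0 * (rc - 0.5)
    return pd.DataFrame(
        squareform(rc), index=table.sample_ids, columns=table.sample_ids
    )


# ---------------------------------------------------------------------------
# Process partitioning

@dataclass
class AssemblyResult:
    """Pairwise βNTI and RC-Bray with the five-process partition."""

    bnti: pd.DataFrame
    rc_bray: pd.DataFrame
    process_fractions: pd.Series
    stochastic_fraction: float
    deterministic_fraction: float
    n_pairs: int
    n_excluded: int = 0

    def pair_table(self) -> pd.DataFrame:
        ids = list(self.bnti.index)
        rows = []
        b = self.bnti.to_numpy()
        r = self.rc_bray.to_numpy()
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                rows.append((ids[i], ids[j], b[i, j], r[i, j], _process(b[i, j], r[i, j])))
        return pd.DataFrame(rows, columns=["sample_i", "sample_j", "bnti", "rc_bray", "process"])


def _process(b: float, r: float, bnti_cut: float = 2.0, rc_cut: float = 0.95) -> str:
    if np.isnan(b):
        return "undefined"
    if b > bnti_cut:
        return "heterogeneous_selection"
    if b < -bnti_cut:
        return "homogeneous_selection"
    if r > rc_cut:
        return "dispersal_limitation"
    if r < -rc_cut:
        return "homogenizing_dispersal"
    return "drift"


def partition_processes(
    bnti: pd.DataFrame,
    rc_bray: pd.DataFrame,
    bnti_cut: float = 2.0,
    rc_cut: float = 0.95,
) -> AssemblyResult:
    """Assign each sample pair to one of five assembly processes.

    βNTI > +cut: heterogeneous selection; < −cut: homogeneous selection;
    otherwise RC-Bray > +rc_cut: dispersal limitation, < −rc_cut:
    homogenising dispersal, else drift. Stochastic fraction = dispersal
    limitation + homogenising dispersal + drift. Pairs with undefined
    βNTI are excluded from the denominator.
    """
    if list(bnti.index) != list(rc_bray.index):
        raise ValueError("bnti and rc_bray must be aligned on the same samples")
    n = bnti.shape[0]
    iu = np.triu_indices(n, k=1)
    b = bnti.to_numpy()[iu]
    r = rc_bray.to_numpy()[iu]
    labels = np.array([_process(bi, ri, bnti_cut, rc_cut) for bi, ri in zip(b, r)])
    valid = labels != "undefined"
    n_excluded = int((~valid).sum())
    total = int(valid.sum())
    if total == 0:
        raise ValueError("no sample pairs with defined βNTI")
    fractions = pd.Series(
        {p: float((labels == p).sum()) / total for p in PROCESSES}, name="fraction"
    )
    det = fractions["heterogeneous_selection"] + fractions["homogeneous_selection"]
    return AssemblyResult(
        bnti=bnti,
        rc_bray=rc_bray,
        process_fractions=fractions,
        stochastic_fraction=1.0 - det,
        deterministic_fraction=det,
        n_pairs=total,
        n_excluded=n_excluded,
    )


# ---------------------------------------------------------------------------
# Sloan neutral community model

@dataclass
class NcmFit:
    """Fitted Sloan neutral model: migration rate m and Östman R²."""

    m: float
    N: float
    r_squared: float
    per_otu: pd.DataFrame  # p, freq_obs, freq_pred, lower, upper, position
    detection_limit: float

    @property
    def Nm(self) -> float:
        return self.N * self.m


def sloan_predicted_frequency(
    p: np.ndarray, m: float, N: float, detection_limit: float
) -> np.ndarray:
    """Probability a local community contains the OTU above detection.

    ``1 - BetaCDF(d; N m p, N m (1 - p))`` — the stationary distribution
    of local relative abundance under migration-drift balance.
    """
    a = N * m * p
    b = N * m * (1.0 - p)
    return 1.0 - stats.beta.cdf(detection_limit, a, b)


def fit_sloan_ncm(
    table_or_freqs,
    detection_limit: float | None = None,
    n_samples: int | None = None,
    N: float | None = None,
) -> NcmFit:
    """Fit m by nonlinear least squares on occurrence frequencies.

    Accepts an :class:`OtuTable`, or a tuple ``(p, freq_obs)`` of mean
    relative abundances and observed frequencies (then ``n_samples`` and
    ``N`` must be given). R² = 1 − SSE/SST may be negative when the
    neutral curve fits worse than a constant.
    """
    if isinstance(table_or_freqs, OtuTable):
        table = table_or_freqs
        if table.n_otus < 10:
            raise ValueError("need at least 10 OTUs to fit the neutral model")
        N = float(table.counts.sum(axis=1).mean())
        p = table.relative_abundance().mean(axis=0)
        freq_obs = (table.counts > 0).mean(axis=0)
        n_samples = table.n_samples
        index = pd.Index(table.otu_ids, name="otu_id")
    else:
        p, freq_obs = (np.asarray(v, dtype=float) for v in table_or_freqs)
        if n_samples is None or N is None:
            raise ValueError("n_samples and N are required with raw frequencies")
        index = pd.RangeIndex(len(p))
    if detection_limit is None:
        # Under multinomial read sampling at depth N an OTU at relative
        # abundance x is seen with probability 1 - (1 - x)^N; the hard
        # threshold matching its half-detection point is ln(2)/N. A 1/N
        # threshold overestimates m noticeably at high migration rates.
        detection_limit = float(np.log(2.0)) / N

    keep = p > 0
    p, freq_obs = p[keep], freq_obs[keep]
    index = index[keep]

    def sse(log_m: float) -> float:
        pred = sloan_predicted_frequency(p, 10.0**log_m, N, detection_limit)
        return float(((freq_obs - pred) ** 2).sum())

    res = optimize.minimize_scalar(sse, bounds=(-7.0, 2.0), method="bounded",
                                   options={"xatol": 1e-12})
    if not res.success:
        grid = np.linspace(-7, 2, 19)
        profile = {10.0**g: sse(g) for g in grid}
        raise RuntimeError(f"NCM fit did not converge; SSE profile over m grid: {profile}")
    m = float(10.0**res.x)
    pred = sloan_predicted_frequency(p, m, N, detection_limit)
    sse_val = float(((freq_obs - pred) ** 2).sum())
    sst = float(((freq_obs - freq_obs.mean()) ** 2).sum())
    if sst == 0:
        logger.warning("all OTUs share one occurrence frequency; R² undefined")
        r2 = np.nan
    else:
        r2 = 1.0 - sse_val / sst

    lower, upper = proportion_confint(
        np.round(pred * n_samples), n_samples, alpha=0.05, method="wilson"
    )
    position = np.where(freq_obs > upper, "above", np.where(freq_obs < lower, "below", "within"))
    per_otu = pd.DataFrame(
        {
            "mean_relative_abundance": p,
            "freq_obs": freq_obs,
            "freq_pred": pred,
            "pred_lower": lower,
            "pred_upper": upper,
            "position": position,
        },
        index=index,
    )
    return NcmFit(m=m, N=N, r_squared=r2, per_otu=per_otu, detection_limit=detection_limit)


# ---------------------------------------------------------------------------
# C-score and sequential-swap SES

def c_score(pa: np.ndarray) -> float:
    """Mean checkerboard units over OTU pairs (OTUs as rows).

    CU_ij = (r_i − S_ij)(r_j − S_ij) with r the row totals and S the
    number of shared samples.
    """
    pa = np.asarray(pa)
    if pa.ndim != 2 or pa.shape[0] < 2:
        raise ValueError("need a binary matrix with at least 2 OTU rows")
    pa = (pa > 0).astype(np.int64)
    r = pa.sum(axis=1)
    s = pa @ pa.T
    cu = (r[:, None] - s) * (r[None, :] - s)
    iu = np.triu_indices(pa.shape[0], k=1)
    return float(cu[iu].mean())


@njit(cache=True)
def _sequential_swap_cscores(pa, n_sim, burn_in, thin, seed):  # pragma: no cover
    """Checkerboard-swap chain; returns C-score of each retained matrix.

    Swaps count only when a 2x2 checkerboard submatrix is found and
    flipped (row and column totals preserved exactly). Returns an array
    of length n_sim, or fewer-than-requested values flagged by NaN if
    the chain cannot find swaps (checkerboard-free matrix).
    """
    np.random.seed(seed)
    nr, nc = pa.shape
    out = np.full(n_sim, np.nan)
    swaps_done = 0
    target = burn_in
    attempts_cap = 2_000_000 + 200 * (burn_in + n_sim * thin)
    attempts = 0
    k = 0
    while k < n_sim and attempts < attempts_cap:
        attempts += 1
        i1 = np.random.randint(nr)
        i2 = np.random.randint(nr)
        j1 = np.random.randint(nc)
        j2 = np.random.randint(nc)
        if i1 == i2 or j1 == j2:
            continue
        a = pa[i1, j1]
        b = pa[i1, j2]
        c = pa[i2, j1]
        d = pa[i2, j2]
        if a == 1 and d == 1 and b == 0 and c == 0:
            pa[i1, j1] = 0
            pa[i2, j2] = 0
            pa[i1, j2] = 1
            pa[i2, j1] = 1
        elif a == 0 and d == 0 and b == 1 and c == 1:
            pa[i1, j1] = 1
            pa[i2, j2] = 1
            pa[i1, j2] = 0
            pa[i2, j1] = 0
        else:
            continue
        swaps_done += 1
        if swaps_done >= target:
            # C-score of current matrix
            r = np.zeros(nr, dtype=np.int64)
            for i in range(nr):
                for j in range(nc):
                    r[i] += pa[i, j]
            total = 0.0
            for i in range(nr):
                for i2_ in range(i + 1, nr):
                    s = 0
                    for j in range(nc):
                        s += pa[i, j] * pa[i2_, j]
                    total += (r[i] - s) * (r[i2_] - s)
            out[k] = total / (nr * (nr - 1) / 2.0)
            k += 1
            target += thin
    return out


@njit(cache=True)
def _sequential_swap_matrices(pa, n_keep, burn_in, thin, seed):  # pragma: no cover
    """Like the C-score chain, but returns the retained binary matrices."""
    np.random.seed(seed)
    nr, nc = pa.shape
    out = np.zeros((n_keep, nr, nc), dtype=np.int8)
    swaps_done = 0
    target = burn_in
    attempts_cap = 2_000_000 + 200 * (burn_in + n_keep * thin)
    attempts = 0
    k = 0
    while k < n_keep and attempts < attempts_cap:
        attempts += 1
        i1 = np.random.randint(nr)
        i2 = np.random.randint(nr)
        j1 = np.random.randint(nc)
        j2 = np.random.randint(nc)
        if i1 == i2 or j1 == j2:
            continue
        a = pa[i1, j1]
        b = pa[i1, j2]
        c = pa[i2, j1]
        d = pa[i2, j2]
        if a == 1 and d == 1 and b == 0 and c == 0:
            pa[i1, j1] = 0
            pa[i2, j2] = 0
            pa[i1, j2] = 1
            pa[i2, j1] = 1
        elif a == 0 and d == 0 and b == 1 and c == 1:
            pa[i1, j1] = 1
            pa[i2, j2] = 1
            pa[i1, j2] = 0
            pa[i2, j1] = 0
        else:
            continue
        swaps_done += 1
        if swaps_done >= target:
            out[k] = pa
            k += 1
            target += thin
    return out[:k]


def sequential_swap_nulls(
    table: OtuTable,
    n_sim: int = 100,
    seed: int = 0,
    burn_in: int = 30_000,
    thin: int = 1000,
) -> np.ndarray:
    """Retained null binary matrices (n_sim x OTUs x samples) from the swap chain."""
    pa = table.presence_absence().T.astype(np.int64)
    chain_seed = int(np.random.default_rng(np.random.SeedSequence(seed)).integers(2**31 - 1))
    return _sequential_swap_matrices(pa, n_sim, burn_in, thin, chain_seed)


@dataclass
class CScoreResult:
    observed_c: float
    sim_mean: float
    sim_sd: float
    ses: float
    p_upper: float
    p_lower: float
    n_sim: int


def c_score_ses(
    table: OtuTable,
    n_sim: int = 1000,
    seed: int = 0,
    burn_in: int = 30_000,
    thin: int = 1000,
) -> CScoreResult:
    """Standardised effect size of the C-score under sequential swaps.

    The table is binarised (count > 0) with OTUs as rows. SES =
    (observed − null mean)/null sd; SES > 0 indicates segregation,
    SES < 0 aggregation. A matrix with no swappable checkerboard yields
    sd 0 and an undefined (NaN) SES, reported with a warning.
    """
    pa = table.presence_absence().T.copy()  # otus x samples
    obs = c_score(pa)
    chain_seed = int(np.random.default_rng(np.random.SeedSequence(seed)).integers(2**31 - 1))
    sims = _sequential_swap_cscores(pa.astype(np.int64), n_sim, burn_in, thin, chain_seed)
    sims = sims[~np.isnan(sims)]
    if len(sims) < n_sim:
        logger.warning("sequential swap retained only %d/%d matrices", len(sims), n_sim)
    if len(sims) == 0 or sims.std(ddof=1) == 0:
        logger.warning("degenerate null distribution; SES undefined")
        mean = float(sims.mean()) if len(sims) else np.nan
        return CScoreResult(obs, mean, 0.0, np.nan, np.nan, np.nan, len(sims))
    mean = float(sims.mean())
    sd = float(sims.std(ddof=1))
    ses = (obs - mean) / sd
    p_upper = float((1 + (sims >= obs).sum()) / (len(sims) + 1))
    p_lower = float((1 + (sims <= obs).sum()) / (len(sims) + 1))
    return CScoreResult(obs, mean, sd, ses, p_upper, p_lower, len(sims))
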