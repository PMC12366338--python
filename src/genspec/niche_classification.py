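"""Levins niche breadth and generalist / specialist / neutral classification.

The niche breadth of OTU j over N samples ("habitats") is

    B_j = 1 / sum_i P_ij^2,

with P_ij the proportion of OTU j's total abundance found in sample i
(so sum_i P_ij = 1 and 1 <= B_j <= N). Observed B_j is compared with its
null distribution over quasiswap-randomised tables — nonnegative integer
matrices with exactly the observed row sums, column sums, and fill — and
an OTU is called a generalist when B exceeds the upper (1 - alpha/2) null
quantile, a specialist when it falls below the lower alpha/2 quantile,
and neutral otherwise. Classification on occurrence (number of occupied
samples) instead of B is available via ``statistic="occurrence"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats

from .io_formats import OtuTable

logger = logging.getLogger("genspec")

CATEGORIES = ("generalist", "specialist", "neutral")


def levins_niche_breadth(table: OtuTable, normalization: str = "per_otu") -> pd.Series:
    """Levins B per OTU.

    ``normalization="per_otu"`` (default, the standard Levins convention)
    divides each OTU's counts by its own total, giving B in [1, N].
    ``"within_sample"`` uses within-sample relative abundances instead
    (provided for comparability; B is then not bounded by N).
    """
    counts = table.counts.astype(float)
    if normalization == "per_otu":
        totals = counts.sum(axis=0)
        if (totals == 0).any():
            raise ValueError("all-zero OTUs must be dropped before computing B")
        p = counts / totals
    elif normalization == "within_sample":
        rel = table.relative_abundance()
        totals = rel.sum(axis=0)
        if (totals == 0).any():
            raise ValueError("all-zero OTUs must be dropped before computing B")
        p = rel / totals
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    b = 1.0 / (p**2).sum(axis=0)
    return pd.Series(b, index=table.otu_ids, name="levins_B")


# ---------------------------------------------------------------------------
# Quasiswap null tables

def _random_marginal_table(
    row_sums: np.ndarray, col_labels: np.ndarray, rng: np.random.Generator, n_cols: int
) -> np.ndarray:
    """Random contingency table with the given marginals.

    Shuffles the pooled individuals (labelled by column) and deals them
    out to rows by their row sums — the multivariate-hypergeometric
    distribution over fixed-marginal tables, i.e. the r2dtable model.
    """
    rng.shuffle(col_labels)
    out = np.empty((len(row_sums), n_cols), dtype=np.int64)
    start = 0
    for i, r in enumerate(row_sums):
        out[i] = np.bincount(col_labels[start : start + r], minlength=n_cols)
        start += r
    return out


@njit(cache=True)
def _quasiswap_fill(mat, target_fill, seed, mix_attempts):  # pragma: no cover - numba
    """Unit 2x2 swaps that preserve marginals and drive fill to target.

    Starting from an r2dtable draw (whose fill is almost always above the
    observed fill), repeatedly pick a random 2x2 submatrix and apply the
    unit diagonal shift that does not increase fill; stop when the fill
    matches, then make ``mix_attempts`` further fill-neutral swap
    attempts to decorrelate the result from the greedy descent path.
    Uses an inline xorshift64* generator: the chain makes millions of
    proposals per emitted matrix.
    """
    nr, nc = mat.shape
    fill = 0
    for i in range(nr):
        for j in range(nc):
            if mat[i, j] > 0:
                fill += 1
    state = np.uint64(seed * 2685821657736338717 + 1442695040888963407)
    unr = np.uint64(nr)
    unc = np.uint64(nc)
    sixteen = np.uint64(16)
    mask16 = np.uint64(0xFFFF)
    max_attempts = 400 * nr * nc + 1_000_000
    attempts = 0
    while fill != target_fill and attempts < max_attempts:
        attempts += 1
        state ^= state << np.uint64(13)
        state ^= state >> np.uint64(7)
        state ^= state << np.uint64(17)
        r = state
        i1 = int((r & mask16) % unr)
        r >>= sixteen
        i2 = int((r & mask16) % unr)
        r >>= sixteen
        j1 = int((r & mask16) % unc)
        r >>= sixteen
        j2 = int((r & mask16) % unc)
        if i1 == i2 or j1 == j2:
            continue
        a = mat[i1, j1]
        b = mat[i1, j2]
        c = mat[i2, j1]
        d = mat[i2, j2]
        # move 1: a-1, d-1, b+1, c+1 ; move 2: the reverse
        d1 = 100
        d2 = 100
        if a > 0 and d > 0:
            d1 = (1 if b == 0 else 0) + (1 if c == 0 else 0) - (1 if a == 1 else 0) - (1 if d == 1 else 0)
        if b > 0 and c > 0:
            d2 = (1 if a == 0 else 0) + (1 if d == 0 else 0) - (1 if b == 1 else 0) - (1 if c == 1 else 0)
        if fill > target_fill:
            if d1 < d2:
                delta, pick = d1, 1
            else:
                delta, pick = d2, 2
            if delta > 0:
                continue
        else:  # fill < target_fill: need fill-increasing moves
            if d1 > d2 and d1 < 100:
                delta, pick = d1, 1
            elif d2 < 100:
                delta, pick = d2, 2
            else:
                continue
            if delta < 0:
                continue
        if pick == 1:
            mat[i1, j1] = a - 1
            mat[i2, j2] = d - 1
            mat[i1, j2] = b + 1
            mat[i2, j1] = c + 1
        else:
            mat[i1, j2] = b - 1
            mat[i2, j1] = c - 1
            mat[i1, j1] = a + 1
            mat[i2, j2] = d + 1
        fill += delta
    reached = fill == target_fill
    # fill-neutral mixing attempts
    for _ in range(mix_attempts):
        state ^= state << np.uint64(13)
        state ^= state >> np.uint64(7)
        state ^= state << np.uint64(17)
        r = state
        i1 = int((r & mask16) % unr)
        r >>= sixteen
        i2 = int((r & mask16) % unr)
        r >>= sixteen
        j1 = int((r & mask16) % unc)
        r >>= sixteen
        j2 = int((r & mask16) % unc)
        if i1 == i2 or j1 == j2:
            continue
        a = mat[i1, j1]
        b = mat[i1, j2]
        c = mat[i2, j1]
        d = mat[i2, j2]
        if a > 0 and d > 0:
            if ((1 if b == 0 else 0) + (1 if c == 0 else 0)
                    - (1 if a == 1 else 0) - (1 if d == 1 else 0)) == 0:
                mat[i1, j1] = a - 1
                mat[i2, j2] = d - 1
                mat[i1, j2] = b + 1
                mat[i2, j1] = c + 1
                continue
        if b > 0 and c > 0:
            if ((1 if a == 0 else 0) + (1 if d == 0 else 0)
                    - (1 if b == 1 else 0) - (1 if c == 1 else 0)) == 0:
                mat[i1, j2] = b - 1
                mat[i2, j1] = c - 1
                mat[i1, j1] = a + 1
                mat[i2, j2] = d + 1
    return reached


def quasiswap_nulls(table: OtuTable, n_perm: int, seed: int, burn_in_factor: int = 10):
    """Yield ``n_perm`` quasiswap null count matrices (seed-deterministic).

    Every emitted matrix has exactly the observed row sums, column sums,
    and number of nonzero cells. Each null starts from an independent
    r2dtable draw, so consecutive nulls are independent randomisations
    rather than steps of one Markov chain; the first matrix additionally
    receives ``burn_in_factor x fill`` fill-neutral mixing attempts.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if table.n_samples < 2 or table.n_otus < 2:
        raise ValueError("need at least a 2x2 table for quasiswap")
    if max(table.counts.shape) >= 2**16:
        raise ValueError("quasiswap supports at most 65535 samples / OTUs")
    counts = table.counts
    row_sums = counts.sum(axis=1)
    col_sums = counts.sum(axis=0)
    target_fill = int((counts > 0).sum())
    col_labels = np.repeat(np.arange(table.n_otus, dtype=np.int32), col_sums)
    ss = np.random.SeedSequence(seed)
    for k, child in enumerate(ss.spawn(n_perm)):
        rng = np.random.default_rng(child)
        null = _random_marginal_table(row_sums, col_labels, rng, table.n_otus)
        swap_seed = int(rng.integers(2**31 - 1))
        mix = burn_in_factor * target_fill if k == 0 else 0
        reached = _quasiswap_fill(null, target_fill, swap_seed, mix)
        if not reached:
            logger.warning("quasiswap could not reach the observed fill; emitting anyway")
        yield null


# ---------------------------------------------------------------------------
# Classification

@dataclass
class NicheClassification:
    """Per-OTU niche breadth, null envelope, and category label."""

    per_otu: pd.DataFrame  # levins_B, occurrence, null_low, null_high, category
    n_perm: int
    alpha: float
    statistic: str = "levins_B"

    @property
    def categories(self) -> pd.Series:
        return self.per_otu["category"]

    def counts(self) -> pd.Series:
        return self.categories.value_counts().reindex(CATEGORIES, fill_value=0)

    def proportions(self) -> pd.Series:
        c = self.counts()
        return c / c.sum()

    def otus_in(self, category: str) -> list[str]:
        return list(self.per_otu.index[self.per_otu["category"] == category])

    def write(self, path) -> None:
        self.per_otu.to_csv(path, sep="\t", index_label="otu_id")


def classify_taxa(
    table: OtuTable,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    statistic: str = "levins_B",
) -> NicheClassification:
    """Classify OTUs as generalist / specialist / neutral.

    Observed Levins B (or occurrence) per OTU is compared with the
    empirical (alpha/2, 1 - alpha/2) quantiles of its own null
    distribution across ``n_perm`` quasiswap tables. Values strictly
    above the upper quantile are generalists, strictly below the lower
    quantile specialists, and ties resolve to neutral.
    """
    if statistic not in ("levins_B", "occurrence"):
        raise ValueError(f"unknown statistic {statistic!r}")
    if n_perm < 2 / alpha:
        logger.warning(
            "n_perm=%d is small for alpha=%g (recommend >= %d)", n_perm, alpha, int(2 / alpha)
        )
    table = table.drop_empty_otus()
    b_obs = levins_niche_breadth(table)
    occ = pd.Series((table.counts > 0).sum(axis=0), index=table.otu_ids, name="occurrence")
    obs = b_obs.to_numpy() if statistic == "levins_B" else occ.to_numpy().astype(float)

    null_stats = np.empty((n_perm, table.n_otus))
    for k, null in enumerate(quasiswap_nulls(table, n_perm, seed)):
        if statistic == "levins_B":
            totals = null.sum(axis=0).astype(float)
            totals[totals == 0] = np.nan
            p = null / totals
            null_stats[k] = 1.0 / np.nansum(p**2, axis=0)
        else:
            null_stats[k] = (null > 0).sum(axis=0)

    null_low = np.nanquantile(null_stats, alpha / 2, axis=0)
    null_high = np.nanquantile(null_stats, 1 - alpha / 2, axis=0)
    category = np.where(obs > null_high, "generalist", np.where(obs < null_low, "specialist", "neutral"))

    per_otu = pd.DataFrame(
        {
            "levins_B": b_obs,
            "occurrence": occ,
            "null_low": null_low,
            "null_high": null_high,
            "category": category,
        },
        index=table.otu_ids,
    )
    result = NicheClassification(per_otu, n_perm=n_perm, alpha=alpha, statistic=statistic)
    logger.info("classification proportions: %s", result.proportions().round(4).to_dict())
    return result


def group_richness_test(
    table: OtuTable, classification: NicheClassification
) -> tuple[pd.DataFrame, float, float]:
    """Per-sample richness by category plus a Kruskal-Wallis test.

    Returns (richness table with columns overall/generalist/specialist/
    neutral, H statistic, p-value). Categories with no OTUs are omitted
    from the test with a warning.
    """
    richness = {"overall": table.richness()}
    for cat in CATEGORIES:
        otus = classification.otus_in(cat)
        if not otus:
            logger.warning("category %r has no OTUs; omitted from richness test", cat)
            continue
        sub = table.subset_otus(otus)
        richness[cat] = sub.richness()
    df = pd.DataFrame(richness, index=table.sample_ids)
    groups = [df[c].to_numpy() for c in df.columns]
    if all(np.array_equal(g, groups[0]) for g in groups[1:]):
        return df, 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return df, float(h), float(p)
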