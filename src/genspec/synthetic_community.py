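"""Synthetic soil-community generator with known ground truth.

Emulates the study design the pipeline targets: a 120-quadrat forest plot
(12 x 10 grid at 20 m spacing) sampled for 16S OTU tables, with planted
habitat generalists (broad, even occupancy), habitat specialists
(Gaussian environmental filtering on a spatially autocorrelated latent
gradient), an OTU phylogeny carrying phylogenetic signal in habitat
preference, Sloan-neutral communities with a known migration rate, and
spatially autocorrelated environmental covariate blocks with known path
effects on richness.

Every generator draws all randomness from a single integer seed through
:class:`numpy.random.SeedSequence` spawning; repeated calls with the same
arguments are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .io_formats import DEFAULT_BLOCKS, OtuTable, SampleMetadata

logger = logging.getLogger("genspec")


@dataclass
class SyntheticScenario:
    """Parameters of one synthetic community experiment.

    Defaults mirror the field design: 120 samples on a 12 x 10 grid with
    20 m spacing, 10^4 reads per sample. ``sigma`` is the width of the
    Gaussian filtering kernel (in standard deviations of the latent
    environmental gradient); the default is set so planted specialists
    occupy roughly 10-20% of samples at the default depth.
    """

    n_samples: int = 120
    grid_shape: tuple[int, int] = (12, 10)
    grid_spacing: float = 20.0
    n_otus: int = 1000
    n_generalists: int = 100
    n_specialists: int = 300
    community_size: int = 10_000
    migration_rate_m: float = 0.1
    env_effect_sizes: dict[str, float] = field(
        default_factory=lambda: {"light": -0.4, "spatial": 0.4, "plant": 0.15, "topography": 0.1}
    )
    sigma: float = 0.15
    neutral_noise_sd: float = 1.0
    autocorr_range: float = 60.0
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 2.0
    planted_lognormal_mu: float = 1.5
    planted_lognormal_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0 or self.n_otus <= 0:
            raise ValueError("n_samples and n_otus must be positive")
        if self.community_size <= 0:
            raise ValueError("community_size must be positive")
        if self.n_generalists + self.n_specialists > self.n_otus:
            raise ValueError("n_generalists + n_specialists exceeds n_otus")
        if self.grid_shape[0] * self.grid_shape[1] != self.n_samples:
            raise ValueError("grid_shape product must equal n_samples")

    def grid_coords(self) -> np.ndarray:
        nx, ny = self.grid_shape
        xx, yy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        return np.column_stack([xx.ravel(), yy.ravel()]).astype(float) * self.grid_spacing

    def sample_ids(self) -> list[str]:
        return [f"S{i:03d}" for i in range(self.n_samples)]

    def otu_ids(self) -> list[str]:
        return [f"OTU{j:04d}" for j in range(self.n_otus)]


@dataclass
class GroundTruth:
    """True per-OTU labels and parameters behind a synthetic table."""

    labels: pd.Series  # index = otu id, values in {generalist, specialist, neutral}
    env_optimum: pd.Series  # NaN for unfiltered OTUs
    migration_rate: float | None = None
    path_coefficients: dict[str, float] = field(default_factory=dict)
    all_zero_otus: list[str] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"true_label": self.labels, "env_optimum": self.env_optimum})


# ---------------------------------------------------------------------------
# Gaussian random fields

def gaussian_field(coords: np.ndarray, autocorr_range: float, rng: np.random.Generator) -> np.ndarray:
    """One draw of a unit-variance Gaussian field with exponential covariance.

    cov(h) = exp(-h / range). A nonpositive range degrades to white noise
    (with a warning), matching the limit of the model.
    """
    n = len(coords)
    if autocorr_range <= 0:
        logger.warning("autocorr_range <= 0: generating spatially white noise")
        return rng.standard_normal(n)
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    cov = np.exp(-d / autocorr_range)
    cov[np.diag_indices(n)] += 1e-9
    chol = np.linalg.cholesky(cov)
    return chol @ rng.standard_normal(n)


# ---------------------------------------------------------------------------
# Structured (generalist / specialist) tables

def simulate_structured_table(
    scenario: SyntheticScenario,
    specialist_optima: np.ndarray | None = None,
) -> tuple[OtuTable, GroundTruth, SampleMetadata]:
    """Generate an OTU table with planted generalists and specialists.

    Generalist OTUs have uniform expected relative abundance across
    samples. Specialists are filtered by a Gaussian kernel
    ``exp(-(env - optimum)^2 / (2 sigma^2))`` on a spatially
    autocorrelated standardised gradient. Remaining OTUs ("neutral"
    background) carry aspatial lognormal overdispersion so their evenness
    sits between the two planted extremes. Reads are drawn per sample by a
    multinomial at ``community_size`` depth, so every row sum equals the
    configured depth exactly.
    """
    ss = np.random.SeedSequence(scenario.seed)
    rng_env, rng_base, rng_opt, rng_noise, rng_reads = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    coords = scenario.grid_coords()
    env = gaussian_field(coords, scenario.autocorr_range, rng_env)
    env = (env - env.mean()) / env.std()

    n, g, s = scenario.n_otus, scenario.n_generalists, scenario.n_specialists
    # Background OTUs follow the full lognormal SAD; planted generalists and
    # specialists are drawn from its abundant portion — a niche label for a
    # taxon observed a handful of times is not meaningful ground truth.
    base = rng_base.lognormal(scenario.lognormal_mu, scenario.lognormal_sigma, size=n)
    base[: g + s] = rng_base.lognormal(
        scenario.planted_lognormal_mu, scenario.planted_lognormal_sigma, size=g + s
    )

    labels = np.array(["neutral"] * n, dtype=object)
    labels[:g] = "generalist"
    labels[g : g + s] = "specialist"
    optima = np.full(n, np.nan)
    if specialist_optima is not None:
        if len(specialist_optima) != s:
            raise ValueError("specialist_optima must have length n_specialists")
        optima[g : g + s] = np.asarray(specialist_optima, dtype=float)
    else:
        optima[g : g + s] = rng_opt.uniform(env.min(), env.max(), size=s)

    # expected relative weight per (sample, otu)
    weights = np.tile(base, (scenario.n_samples, 1))
    if s:
        if scenario.sigma == 0:
            kern = (env[:, None] == optima[None, g : g + s]).astype(float)
        else:
            kern = np.exp(
                -((env[:, None] - optima[None, g : g + s]) ** 2) / (2 * scenario.sigma**2)
            )
        # mass-normalised kernel: filtering concentrates a specialist in its
        # niche instead of thinning it out of the metacommunity
        kmean = kern.mean(axis=0, keepdims=True)
        ok = kmean[0] > 0
        kern[:, ok] = kern[:, ok] / kmean[:, ok]
        weights[:, g : g + s] *= kern
    n_neutral = n - g - s
    if n_neutral:
        noise = rng_noise.normal(0.0, scenario.neutral_noise_sd, size=(scenario.n_samples, n_neutral))
        weights[:, g + s :] *= np.exp(noise)

    probs = weights / weights.sum(axis=1, keepdims=True)
    counts = np.vstack(
        [rng_reads.multinomial(scenario.community_size, probs[i]) for i in range(scenario.n_samples)]
    )

    otu_ids = scenario.otu_ids()
    sample_ids = scenario.sample_ids()
    all_zero = [otu_ids[j] for j in np.flatnonzero(counts.sum(axis=0) == 0)]
    if all_zero:
        logger.warning("%d OTUs received zero reads everywhere", len(all_zero))

    table = OtuTable(counts, sample_ids, otu_ids)
    truth = GroundTruth(
        labels=pd.Series(labels, index=otu_ids, name="true_label"),
        env_optimum=pd.Series(optima, index=otu_ids, name="env_optimum"),
        all_zero_otus=all_zero,
    )
    meta = SampleMetadata(
        pd.DataFrame(
            {"x": coords[:, 0], "y": coords[:, 1], "env_gradient": env}, index=sample_ids
        )
    )
    return table, truth, meta


# ---------------------------------------------------------------------------
# Sloan-neutral tables

def lognormal_metacommunity(
    n_otus: int, rng: np.random.Generator, mu: float = 0.0, sigma: float = 2.0
) -> np.ndarray:
    """Lognormal species-abundance distribution, normalised to sum to 1."""
    a = rng.lognormal(mu, sigma, size=n_otus)
    return a / a.sum()


def simulate_neutral_table(
    scenario: SyntheticScenario, metacommunity_abundances: np.ndarray | None = None
) -> OtuTable:
    """Generate a table under Sloan's neutral stationary approximation.

    For metacommunity frequency ``p`` each local relative abundance is
    drawn from ``Beta(N m p, N m (1 - p))`` with ``N = community_size``
    and ``m = migration_rate_m``, renormalised across OTUs, then
    multinomial-sampled to ``N`` reads. OTUs with ``p = 0`` are absent
    everywhere and dropped with a warning.
    """
    if scenario.migration_rate_m <= 0:
        raise ValueError("migration_rate_m must be positive")
    ss = np.random.SeedSequence(scenario.seed)
    rng_meta, rng_beta, rng_reads = (np.random.default_rng(s) for s in ss.spawn(3))

    if metacommunity_abundances is None:
        p = lognormal_metacommunity(
            scenario.n_otus, rng_meta, scenario.lognormal_mu, scenario.lognormal_sigma
        )
    else:
        p = np.asarray(metacommunity_abundances, dtype=float)
        if not np.isclose(p.sum(), 1.0):
            raise ValueError("metacommunity_abundances must sum to 1")

    otu_ids = [f"OTU{j:04d}" for j in range(len(p))]
    nonzero = p > 0
    if not nonzero.all():
        logger.warning("dropping %d OTUs with zero metacommunity frequency", int((~nonzero).sum()))
        p = p[nonzero]
        otu_ids = [o for o, keep in zip(otu_ids, nonzero) if keep]

    nm = scenario.community_size * scenario.migration_rate_m
    a = nm * p
    b = nm * (1.0 - p)
    local = rng_beta.beta(a[None, :], b[None, :], size=(scenario.n_samples, len(p)))
    local = np.clip(local, 1e-300, None)
    local /= local.sum(axis=1, keepdims=True)
    counts = np.vstack(
        [rng_reads.multinomial(scenario.community_size, local[i]) for i in range(scenario.n_samples)]
    )
    return OtuTable(counts, scenario.sample_ids(), otu_ids)


# ---------------------------------------------------------------------------
# Phylogeny with tunable signal in habitat preference

def simulate_phylogeny(
    n_otus: int, signal_strength: float, seed: int, otu_ids: list[str] | None = None
) -> tuple[TreeNode, pd.Series]:
    """Yule-topology phylogeny plus per-tip environmental optima.

    Optima evolve by Brownian motion along branches; ``signal_strength``
    in [0, 1] blends the Brownian values with an independent draw, so 1
    gives fully heritable habitat preference and 0 gives optima
    independent of the tree.
    """
    if n_otus < 2:
        raise ValueError("need at least 2 OTUs for a phylogeny")
    if not 0.0 <= signal_strength <= 1.0:
        raise ValueError("signal_strength must lie in [0, 1]")
    ss = np.random.SeedSequence(seed)
    rng_topo, rng_bm, rng_ind = (np.random.default_rng(s) for s in ss.spawn(3))

    if otu_ids is None:
        otu_ids = [f"OTU{j:04d}" for j in range(n_otus)]

    # Yule process: exponential waiting times, uniform choice of splitting tip
    root = TreeNode(length=0.0)
    tips = [TreeNode(length=0.0), TreeNode(length=0.0)]
    root.extend(tips)
    while len(tips) < n_otus:
        wait = rng_topo.exponential(1.0 / len(tips))
        for t in tips:
            t.length += wait
        k = rng_topo.integers(len(tips))
        parent = tips.pop(k)
        children = [TreeNode(length=0.0), TreeNode(length=0.0)]
        parent.extend(children)
        tips.extend(children)
    final = rng_topo.exponential(1.0 / len(tips))
    for t in tips:
        t.length += final
    order = rng_topo.permutation(n_otus)
    for t, k in zip(tips, order):
        t.name = otu_ids[k]

    # Brownian motion from the root
    values: dict[int, float] = {id(root): 0.0}
    for node in root.preorder():
        if node is root:
            continue
        step = rng_bm.normal(0.0, np.sqrt(max(node.length, 0.0)))
        values[id(node)] = values[id(node.parent)] + step
    bm = np.array([values[id(t)] for t in root.tips()])
    names = [t.name for t in root.tips()]
    bm = (bm - bm.mean()) / (bm.std() if bm.std() > 0 else 1.0)
    ind = rng_ind.standard_normal(n_otus)
    ind = (ind - ind.mean()) / ind.std()
    mixed = np.sqrt(signal_strength) * bm + np.sqrt(1.0 - signal_strength) * ind
    optima = pd.Series(mixed, index=names, name="env_optimum").loc[otu_ids]
    return root, optima


# ---------------------------------------------------------------------------
# Environmental covariates

def simulate_environment(
    coords: np.ndarray,
    blocks: dict[str, tuple[str, ...]] | None = None,
    autocorr_range: float = 60.0,
    seed: int = 0,
    indicator_loading: float = 0.8,
) -> SampleMetadata:
    """Spatially autocorrelated covariates grouped into named blocks.

    Each block has one latent Gaussian field; its indicators load on the
    latent with the given loading plus independent noise, so
    within-block indicators are correlated the way a reflective latent
    block expects.
    """
    coords = np.asarray(coords, dtype=float)
    if len(np.unique(coords, axis=0)) != len(coords):
        raise ValueError("coordinates must be distinct")
    if blocks is None:
        blocks = dict(DEFAULT_BLOCKS)
    ss = np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(len(blocks) + 1)]
    n = len(coords)
    data: dict[str, np.ndarray] = {"x": coords[:, 0], "y": coords[:, 1]}
    latents: dict[str, np.ndarray] = {}
    for (name, cols), rng in zip(blocks.items(), rngs):
        latent = gaussian_field(coords, autocorr_range, rng)
        latent = (latent - latent.mean()) / latent.std()
        latents[name] = latent
        resid = np.sqrt(1.0 - indicator_loading**2)
        for col in cols:
            data[col] = indicator_loading * latent + resid * rng.standard_normal(n)
    sample_ids = [f"S{i:03d}" for i in range(n)]
    meta = SampleMetadata(pd.DataFrame(data, index=sample_ids), dict(blocks))
    meta.latents = latents  # stashed for response generation
    return meta


def simulate_response(
    meta: SampleMetadata,
    effects: dict[str, float],
    noise_sd: float | None = None,
    seed: int = 0,
) -> pd.Series:
    """Response variable with known path coefficients on the block latents.

    ``effects`` maps block names (or metadata column names, e.g. a PCNM
    axis) to standardised path coefficients; the response is the linear
    combination of the latent block scores plus Gaussian noise. The
    default noise level completes the response variance to 1 (sources
    are independent unit-variance latents), so the nominal coefficients
    are already on the standardised scale a path model estimates. Used
    to test path-coefficient recovery.
    """
    if noise_sd is None:
        explained = sum(c**2 for c in effects.values())
        if explained >= 1:
            raise ValueError("sum of squared effects must be < 1 for the default noise level")
        noise_sd = float(np.sqrt(1.0 - explained))
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = len(meta.data)
    y = np.zeros(n)
    latents = getattr(meta, "latents", {})
    for name, coef in effects.items():
        if name in latents:
            z = latents[name]
        elif name in meta.data.columns:
            col = meta.data[name].to_numpy(dtype=float)
            z = (col - col.mean()) / col.std()
        elif name in meta.blocks:
            cols = meta.data[list(meta.blocks[name])].to_numpy(dtype=float)
            cols = (cols - cols.mean(0)) / cols.std(0)
            z = cols.mean(axis=1)
            z = (z - z.mean()) / z.std()
        else:
            raise KeyError(f"unknown effect source {name!r}")
        y += coef * z
    y += rng.normal(0.0, noise_sd, size=n)
    return pd.Series(y, index=meta.data.index, name="response")
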