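"""End-to-end orchestration: classify -> assembly -> network -> spatial -> path model.

One :class:`RunConfig` drives the whole analysis. Every stochastic stage
derives its seed deterministically from the master seed and the stage
name, so a rerun with the same config writes byte-identical outputs.
Stage outputs are tab-delimited tables plus a machine-readable JSON run
report carrying all parameters, derived seeds, library versions, and
summary statistics.
"""

from __future__ import annotations

import json
import logging
import sys
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assembly_processes import (
    beta_nti,
    c_score_ses,
    fit_sloan_ncm,
    partition_processes,
    raup_crick_bray,
)
from .cooccurrence_network import (
    build_network,
    correlation_screen,
    detect_modules,
    keystone_taxa,
    module_composition,
    topology,
)
from .io_formats import (
    OtuTable,
    SampleMetadata,
    read_metadata,
    read_otu_table,
    read_tree,
    prune_tree,
    write_metadata,
    write_otu_table,
    write_tree,
)
from .niche_classification import classify_taxa, group_richness_test
from .path_model import PathModelSpec, fit_per_subcommunity
from .spatial_environment import forward_select, pcnm_eigenvectors
from .synthetic_community import (
    SyntheticScenario,
    simulate_environment,
    simulate_phylogeny,
    simulate_structured_table,
)

logger = logging.getLogger("genspec")


def setup_logging(log_file: str | Path | None = None, level: int = logging.INFO) -> None:
    """Structured logs to stderr and, optionally, a file."""
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if log_file is not None:
        handlers.append(logging.FileHandler(log_file))
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    root = logging.getLogger("genspec")
    root.setLevel(level)
    root.handlers = []
    for h in handlers:
        h.setFormatter(fmt)
        root.addHandler(h)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return int(
        np.random.SeedSequence([master_seed, zlib.crc32(stage.encode())]).generate_state(1)[0]
        % (2**31 - 1)
    )


@dataclass
class RunConfig:
    """Everything one pipeline run needs.

    Either the three input paths or a synthetic scenario must be given.
    Null/permutation counts default to the standard choices (1000
    classification permutations, 999 nulls); ``fast=True`` scales them
    down for quick runs.
    """

    table_path: str | None = None
    tree_path: str | None = None
    metadata_path: str | None = None
    scenario: SyntheticScenario | None = None
    out_dir: str = "genspec_run"
    master_seed: int = 0
    n_perm: int = 1000
    n_null: int = 999
    n_cscore_sim: int = 1000
    alpha: float = 0.05
    r_min: float = 0.6
    p_max: float = 0.05
    min_prevalence: float = 0.2
    correlation_method: str = "spearman"
    fast: bool = False
    run_assembly: bool = True
    run_network: bool = True
    run_path_model: bool = True
    prune_subcommunity_tree: bool = True

    def __post_init__(self) -> None:
        if self.fast:
            self.n_perm = min(self.n_perm, 200)
            self.n_null = min(self.n_null, 199)
            self.n_cscore_sim = min(self.n_cscore_sim, 200)

    def validate(self) -> None:
        if self.scenario is None:
            if self.table_path is None:
                raise ValueError("either a table path or a synthetic scenario is required")
            if self.run_assembly and self.tree_path is None:
                raise ValueError("assembly stage enabled but no tree provided")
            if self.run_path_model and self.metadata_path is None:
                raise ValueError("path-model stage enabled but no metadata provided")


def _subcommunity_table(table: OtuTable, otus: list[str]) -> OtuTable | None:
    """Subset to a category's OTUs, dropping now-empty samples."""
    if len(otus) < 2:
        return None
    idx = [table.otu_ids.index(o) for o in otus]
    counts = table.counts[:, idx]
    keep = counts.sum(axis=1) > 0
    if keep.sum() < 3:
        return None
    if not keep.all():
        logger.warning("subcommunity drops %d empty samples", int((~keep).sum()))
    return OtuTable(counts[keep], [s for s, k in zip(table.sample_ids, keep) if k], list(otus))


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the run report (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    setup_logging(out / "run.log")

    report: dict = {
        "genspec_version": __version__,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "parameters": {
            # out_dir is a run location, not a parameter of the analysis;
            # keeping it out makes reports byte-identical across reruns
            k: v for k, v in asdict(config).items() if k not in ("scenario", "out_dir")
        },
        "seeds": {},
        "stages": {},
    }

    # ------------------------------------------------------------------ inputs
    if config.scenario is not None:
        sc = config.scenario
        report["parameters"]["scenario"] = asdict(sc)
        tree, tree_optima = simulate_phylogeny(
            sc.n_otus, 1.0, stage_seed(config.master_seed, "phylogeny")
        )
        spec_opt = tree_optima.iloc[sc.n_generalists : sc.n_generalists + sc.n_specialists]
        table, truth, meta_grad = simulate_structured_table(sc, specialist_optima=spec_opt.to_numpy())
        env_meta = simulate_environment(
            sc.grid_coords(), autocorr_range=sc.autocorr_range,
            seed=stage_seed(config.master_seed, "environment"),
        )
        meta = SampleMetadata(
            pd.concat([meta_grad.data, env_meta.data.drop(columns=["x", "y"])], axis=1),
            dict(env_meta.blocks),
        )
        truth.to_dataframe().to_csv(out / "ground_truth.tsv", sep="\t", index_label="otu_id")
        write_otu_table(table, out / "table.tsv")
        write_tree(tree, out / "tree.nwk")
        write_metadata(meta, out / "metadata.tsv")
    else:
        table = read_otu_table(config.table_path)
        tree = read_tree(config.tree_path) if config.tree_path else None
        meta = read_metadata(config.metadata_path) if config.metadata_path else None
        if meta is not None:
            meta = meta.align_to(table)

    table = table.drop_empty_otus()

    # ------------------------------------------------------------ classification
    seed_cls = stage_seed(config.master_seed, "classify")
    report["seeds"]["classify"] = seed_cls
    classification = classify_taxa(
        table, n_perm=config.n_perm, alpha=config.alpha, seed=seed_cls
    )
    classification.write(out / "niche_classification.tsv")
    richness_df, kw_h, kw_p = group_richness_test(table, classification)
    richness_df.to_csv(out / "richness_by_category.tsv", sep="\t", index_label="sample_id")
    report["stages"]["classification"] = {
        "counts": {k: int(v) for k, v in classification.counts().items()},
        "proportions": {k: round(float(v), 6) for k, v in classification.proportions().items()},
        "kruskal_wallis_H": round(kw_h, 6),
        "kruskal_wallis_p": float(f"{kw_p:.6g}"),
    }

    subcommunities = {"overall": table}
    for cat in ("generalist", "specialist", "neutral"):
        sub = _subcommunity_table(table, classification.otus_in(cat))
        if sub is not None:
            subcommunities[cat] = sub

    # ---------------------------------------------------------------- assembly
    if config.run_assembly and tree is not None:
        assembly_report = {}
        for name, sub in subcommunities.items():
            seed_a = stage_seed(config.master_seed, f"assembly:{name}")
            sub_tree = prune_tree(tree, sub.otu_ids) if config.prune_subcommunity_tree else tree
            bnti = beta_nti(sub, sub_tree, n_null=config.n_null, seed=seed_a)
            rc = raup_crick_bray(sub, n_null=config.n_null, seed=seed_a + 1)
            part = partition_processes(bnti, rc)
            part.pair_table().to_csv(out / f"assembly_pairs_{name}.tsv", sep="\t", index=False)
            entry = {
                "process_fractions": {k: round(float(v), 6) for k, v in part.process_fractions.items()},
                "stochastic_fraction": round(part.stochastic_fraction, 6),
                "deterministic_fraction": round(part.deterministic_fraction, 6),
                "n_pairs": part.n_pairs,
            }
            if sub.n_otus >= 10:
                ncm = fit_sloan_ncm(sub)
                ncm.per_otu.to_csv(out / f"ncm_{name}.tsv", sep="\t", index_label="otu_id")
                entry["ncm"] = {
                    "m": round(ncm.m, 6),
                    "Nm": round(ncm.Nm, 4),
                    "r_squared": round(ncm.r_squared, 6),
                }
            cs = c_score_ses(sub, n_sim=config.n_cscore_sim, seed=seed_a + 2)
            entry["c_score"] = {
                "observed": round(cs.observed_c, 6),
                "ses": round(cs.ses, 6) if np.isfinite(cs.ses) else None,
                "p_upper": cs.p_upper,
            }
            assembly_report[name] = entry
        report["stages"]["assembly"] = assembly_report
        report["seeds"]["assembly"] = {
            name: stage_seed(config.master_seed, f"assembly:{name}") for name in subcommunities
        }

    # ----------------------------------------------------------------- network
    if config.run_network:
        seed_net = stage_seed(config.master_seed, "network")
        report["seeds"]["network"] = seed_net
        corr, p_adj = correlation_screen(
            table, method=config.correlation_method, min_prevalence=config.min_prevalence
        )
        try:
            net = build_network(corr, p_adj, r_min=config.r_min, p_max=config.p_max)
        except ValueError as exc:
            logger.warning("network stage skipped: %s", exc)
            report["stages"]["network"] = {"skipped": str(exc)}
            net = None
        if net is not None:
            net = detect_modules(net, seed=seed_net)
            topo = topology(net)
            comp = module_composition(net, classification)
            comp.to_csv(out / "module_composition.tsv", sep="\t")
            roles = keystone_taxa(net)
            roles.to_csv(out / "node_roles.tsv", sep="\t", index_label="otu_id")
            net.edge_table().to_csv(out / "edges.tsv", sep="\t", index=False)
            report["stages"]["network"] = {
                "topology": {k: round(float(v), 6) for k, v in topo.items()},
                "n_modules": int(len(comp)),
                "n_keystones": int(roles["keystone"].sum()),
            }

    # ---------------------------------------------------- spatial + path model
    if config.run_path_model and meta is not None:
        seed_sp = stage_seed(config.master_seed, "spatial")
        report["seeds"]["spatial"] = seed_sp
        pcnm = pcnm_eigenvectors(meta.coords())
        pcnm.eigenvectors.index = meta.data.index
        overall_richness = pd.Series(table.richness(), index=table.sample_ids, dtype=float)
        overall_richness = overall_richness.reindex(meta.data.index).fillna(0.0)
        selected, sel_stats = forward_select(
            pcnm.eigenvectors, overall_richness, alpha=config.alpha,
            n_perm=min(config.n_null, 999), seed=seed_sp,
        )
        sel_stats.to_csv(out / "pcnm_selection.tsv", sep="\t", index=False)
        pcnm.eigenvectors.to_csv(out / "pcnm_axes.tsv", sep="\t", index_label="sample_id")
        spatial_axes = selected if len(selected) >= 1 else list(pcnm.eigenvectors.columns[:2])
        spatial_axes = spatial_axes[:3]
        report["stages"]["spatial"] = {
            "truncation_threshold": pcnm.truncation_threshold,
            "n_axes": int(pcnm.eigenvectors.shape[1]),
            "selected": selected,
            "axes_used_in_path_model": spatial_axes,
        }

        data = meta.data.join(pcnm.eigenvectors)
        blocks = {name: cols for name, cols in meta.blocks.items()}
        blocks["spatial"] = tuple(spatial_axes)
        blocks["richness"] = ("richness",)
        inner = [(b, "richness") for b in blocks if b != "richness"]
        pm_spec = PathModelSpec(blocks=blocks, inner_paths=inner)
        rich_cols = richness_df.reindex(meta.data.index).fillna(0.0)
        fits, comparison = fit_per_subcommunity(data, rich_cols, pm_spec)
        comparison.to_csv(out / "plspm_comparison.tsv", sep="\t")
        report["stages"]["path_model"] = {
            resp: {
                "gof": round(float(res.gof), 6),
                "r_squared": round(float(res.r_squared.get("richness", np.nan)), 6),
                "paths": {
                    b: round(res.coefficient(b, "richness"), 6)
                    for b in pm_spec.predecessors("richness")
                },
            }
            for resp, res in fits.items()
        }

    report_path = out / "run_report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    logger.info("run report written to %s", report_path)
    return report


def make_fixtures(out_dir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write a miniature scenario (24 samples, 200 OTUs) plus toy matrices."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sc = SyntheticScenario(
        n_samples=24, grid_shape=(6, 4), n_otus=200, n_generalists=20,
        n_specialists=60, community_size=2000, seed=seed,
    )
    tree, optima = simulate_phylogeny(sc.n_otus, 1.0, seed)
    spec_opt = optima.iloc[sc.n_generalists : sc.n_generalists + sc.n_specialists]
    table, truth, meta_grad = simulate_structured_table(sc, specialist_optima=spec_opt.to_numpy())
    env = simulate_environment(sc.grid_coords(), seed=seed + 1)
    meta = SampleMetadata(
        pd.concat([meta_grad.data, env.data.drop(columns=["x", "y"])], axis=1),
        dict(env.blocks),
    )
    paths = {
        "table": out / "fixture_table.tsv",
        "tree": out / "fixture_tree.nwk",
        "metadata": out / "fixture_metadata.tsv",
        "truth": out / "fixture_truth.tsv",
        "toy_table": out / "toy_table.tsv",
    }
    write_otu_table(table, paths["table"])
    write_tree(tree, paths["tree"])
    write_metadata(meta, paths["metadata"])
    truth.to_dataframe().to_csv(paths["truth"], sep="\t", index_label="otu_id")
    toy = OtuTable(np.array([[5, 0], [0, 5]]), ["A", "B"], ["x", "y"])
    write_otu_table(toy, paths["toy_table"])
    return paths
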