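"""End-to-end orchestration: configuration, seed management, staged runs.

``run_pipeline`` chains prevalence filtering and rarefaction into the four
analysis stages (network, neutral model, assembly partition, environmental
association), writes each stage's tables under the output directory, and
records a provenance manifest sufficient to re-run any stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from .assembly import AssemblyModel
from .core import CommunityTable, PhyloTree, SampleFrame, alpha_diversity, bray_curtis
from .envstats import bioenv, module_env_mantel
from .ncm import SloanNCM
from .network import CooccurrenceNetwork
from .stats import compare_strata, spawn_seeds

logger = logging.getLogger("riparia")

__all__ = ["PipelineConfig", "run_pipeline", "compare_strata"]


@dataclass
class PipelineConfig:
    """Flat, typed pipeline configuration.

    Defaults mirror the analysis conventions documented in docs/methods.md:
    rarefaction to 30,082 reads, a 20% prevalence filter, |rho| > 0.8 with
    q < 0.01 edges, bins of >= 24 taxa from the top 7,000 taxa, 1,000 null
    randomisations, and 9,999 Mantel permutations.
    """

    table_path: str | None = None
    tree_path: str | None = None
    samples_path: str | None = None
    output_dir: str = "riparia_out"
    rarefaction_depth: int = 30_082
    prevalence_fraction: float = 0.20
    rho_min: float = 0.8
    alpha: float = 0.01
    removal_order: str = "random"
    robustness_reps: int = 100
    random_reps: int = 100
    top_k: int = 7_000
    n_min: int = 24
    n_null: int = 1_000
    mantel_permutations: int = 9_999
    seed: int = 0
    stages: tuple = ("network", "ncm", "assembly", "envassoc")

    def __post_init__(self):
        if not 0 < self.prevalence_fraction <= 1:
            raise ValueError("prevalence_fraction must be in (0, 1]")
        if self.rarefaction_depth < 1:
            raise ValueError("rarefaction_depth must be >= 1")
        if not 0 < self.rho_min < 1:
            raise ValueError("rho_min must be in (0, 1)")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.removal_order not in ("random", "degree"):
            raise ValueError("removal_order must be 'random' or 'degree'")
        unknown = set(self.stages) - {"network", "ncm", "assembly", "envassoc"}
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["stages"] = list(data["stages"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_inputs(config, table, tree, frame):
    if table is None:
        if config.table_path is None:
            raise ValueError("no community table provided")
        table = rio.read_community_table(config.table_path)
    if tree is None and config.tree_path:
        tree = rio.read_newick(config.tree_path)
    if frame is None and config.samples_path:
        frame = rio.read_samples(config.samples_path, table=None)
    if "assembly" in config.stages and tree is None:
        raise ValueError("assembly stage requires a phylogenetic tree")
    if "envassoc" in config.stages and frame is None:
        raise ValueError("envassoc stage requires a sample metadata frame")
    return table, tree, frame


def run_pipeline(
    config: PipelineConfig,
    table: CommunityTable | None = None,
    tree: PhyloTree | None = None,
    frame: SampleFrame | None = None,
) -> dict:
    """Execute the configured stages; returns a dict of result objects.

    All stage randomness derives from ``config.seed`` through a documented
    stream split, so identical configs give identical outputs.
    """
    from . import __version__

    table, tree, frame = _load_inputs(config, table, tree, frame)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = dict(
        zip(["rarefy", "network", "ncm", "assembly", "envassoc"],
            spawn_seeds(config.seed, 5))
    )
    manifest = {
        "config": dataclasses.asdict(config),
        "config_digest": config.digest(),
        "seeds": seeds,
        "versions": {"riparia": __version__, "numpy": np.__version__},
        "stages": {},
    }
    results: dict = {}

    def _stage(name):
        def wrap(fn):
            t0 = time.time()
            try:
                out = fn()
            except Exception as exc:
                manifest["stages"][name] = {"status": "failed", "error": str(exc)}
                (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                                 default=str))
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            manifest["stages"][name] = {
                "status": "ok",
                "seconds": round(time.time() - t0, 3),
            }
            return out
        return wrap

    # preprocessing ---------------------------------------------------
    def preprocess():
        filtered = table
        from .core import prevalence_filter, rarefy

        rarefied = rarefy(table, config.rarefaction_depth, seeds["rarefy"])
        filtered = prevalence_filter(rarefied, config.prevalence_fraction)
        logger.info("preprocess: %d samples x %d taxa after rarefaction+filter",
                    filtered.n_samples, filtered.n_taxa)
        return rarefied, filtered

    rarefied, filtered = _stage("preprocess")(preprocess)
    if frame is not None:
        frame = frame.subset(rarefied.sample_ids)
    results["rarefied"], results["filtered"] = rarefied, filtered

    if "network" in config.stages:
        def run_network():
            model = CooccurrenceNetwork(filtered, rho_min=config.rho_min,
                                        alpha=config.alpha)
            res = model.fit(seed=seeds["network"])
            res.edge_table().to_csv(outdir / "network_edges.tsv", sep="\t",
                                    index=False)
            res.node_metrics().to_csv(outdir / "network_nodes.tsv", sep="\t")
            res.topology().as_series().to_csv(outdir / "network_topology.tsv",
                                              sep="\t", header=False)
            return res
        results["network"] = _stage("network")(run_network)

    if "ncm" in config.stages:
        def run_ncm():
            out = {"all": SloanNCM(rarefied).fit()}
            if frame is not None:
                for season in sorted(set(frame.data["season"])):
                    ids = [s for s in rarefied.sample_ids
                           if frame.data.loc[s, "season"] == season]
                    if len(ids) >= 5:
                        out[season] = SloanNCM(rarefied.select_samples(ids)).fit()
            (outdir / "ncm_summary.json").write_text(
                json.dumps({k: v.to_dict() for k, v in out.items()}, indent=2)
            )
            out["all"].taxon_table().to_csv(outdir / "ncm_taxa.tsv", sep="\t")
            return out
        results["ncm"] = _stage("ncm")(run_ncm)

    if "assembly" in config.stages:
        def run_assembly():
            model = AssemblyModel(rarefied, tree, frame=frame,
                                  top_k=config.top_k, n_min=config.n_min,
                                  n_null=config.n_null)
            res = model.fit(seed=seeds["assembly"])
            res.calls.to_csv(outdir / "assembly_calls.tsv", sep="\t", index=False)
            part = res.partition("all")
            part.bin_fractions.to_csv(outdir / "assembly_partition.tsv", sep="\t")
            summary = {"all": part.community.to_dict()}
            if frame is not None:
                for season in sorted(set(frame.data["season"])):
                    try:
                        summary[season] = res.partition(season).community.to_dict()
                    except ValueError:
                        pass
            (outdir / "assembly_summary.json").write_text(
                json.dumps(summary, indent=2)
            )
            return res
        results["assembly"] = _stage("assembly")(run_assembly)

    if "envassoc" in config.stages:
        def run_envassoc():
            dm = bray_curtis(rarefied)
            frame_sub = frame.subset(rarefied.sample_ids)
            be = bioenv(dm, frame_sub)
            out = {"bioenv_best": list(be.best_subset), "bioenv_r": be.best_r}
            grid = None
            if "network" in results:
                grid = module_env_mantel(
                    results["network"].modules, rarefied, frame_sub, tree=tree,
                    n_perm=config.mantel_permutations, seed=seeds["envassoc"],
                )
                grid.to_csv(outdir / "module_env_mantel.tsv", sep="\t", index=False)
            (outdir / "envassoc.json").write_text(json.dumps(out, indent=2))
            return {"bioenv": be, "module_grid": grid}
        results["envassoc"] = _stage("envassoc")(run_envassoc)

    if frame is not None:
        results["alpha"] = alpha_diversity(rarefied, tree)
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str)
    )
    results["manifest"] = manifest
    return results
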