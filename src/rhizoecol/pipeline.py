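"""End-to-end orchestration of the bulk-soil vs rhizosphere analysis.

``RunConfig`` gathers file paths (or a synthetic-data block), stage
toggles, thresholds and the master seed; ``run_pipeline`` executes the
enabled stages in dependency order (preprocess → diversity →
assembly / neutral_niche / network / sources), writes artifacts to the
output directory and returns a machine-readable :class:`RunReport`.

All randomized stages derive independent named seeds from the master
seed: ``seed_for(master, name)`` feeds ``SeedSequence([master,
crc32(name)])`` and reduces the first generated word modulo 2**31.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import networkx as nx
import yaml

from . import assembly as asm
from . import diversity as div
from . import io as rio
from . import network as net
from . import neutral as ncm
from . import sources as src
from . import synthetic as syn
from .containers import CommunityTable
from .errors import InvalidInputError, MissingLeafError, RhizoecolError

log = logging.getLogger(__name__)

STAGES = ("preprocess", "diversity", "assembly", "neutral_niche", "network", "sources")


def seed_for(master: int, name: str) -> int:
    """Independent per-stage seed derived from the master seed (< 2**31)."""
    child = np.random.SeedSequence([int(master), zlib.crc32(name.encode())])
    return int(child.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    """Full configuration of a pipeline run."""

    # file inputs (all optional when synthetic is true)
    bacteria_counts: str | None = None
    fungi_counts: str | None = None
    bacteria_tree: str | None = None
    fungi_tree: str | None = None
    metadata: str | None = None
    synthetic: bool = True
    synthetic_params: dict = field(default_factory=dict)
    # preprocessing
    rarefaction_depth: dict = field(default_factory=dict)  # per kingdom; empty = skip
    # thresholds (sized for synthetic-scale runs; library defaults are larger)
    r_threshold: float = 0.6
    n_null: int = 199
    n_perm: int = 199
    n_resample: int = 20
    prevalence: float = 0.25
    legend_convention: bool = False
    seed: int = 0
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})

    def __post_init__(self):
        for s in STAGES:
            self.stages.setdefault(s, True)
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise InvalidInputError(f"unknown stages in config: {unknown}")
        if self.n_null < 99 or self.n_perm < 99:
            raise InvalidInputError("n_null and n_perm must be >= 99")
        if not 0 < self.r_threshold < 1:
            raise InvalidInputError("r_threshold must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


@dataclass
class InputBundle:
    tables: dict  # kingdom -> CommunityTable
    trees: dict  # kingdom -> TreeNode or None
    assembly_usable: dict  # kingdom -> bool
    warnings: list


def default_synthetic_bundle(seed: int = 0, n_samples_per_compartment: int = 8,
                             n_taxa_bacteria: int = 60, n_taxa_fungi: int = 25,
                             depth: int = 1000) -> InputBundle:
    """Generate a small paired bacteria/fungi BS-vs-RS dataset.

    Both kingdoms are neutral metacommunity assemblies; the two
    compartments differ in immigration rate (BS better connected to the
    pool than RS), and sample coordinates sit on a shared transect so
    distance-based analyses are exercised.
    """
    tables, trees, usable = {}, {}, {}
    for kingdom, n_taxa, k_seed in (
        ("bacteria", n_taxa_bacteria, seed_for(seed, "bacteria")),
        ("fungi", n_taxa_fungi, seed_for(seed, "fungi")),
    ):
        tree = syn.simulate_phylogeny(n_taxa, seed=k_seed)
        profile = syn.lognormal_metacommunity(n_taxa, sigma=2.0, seed=k_seed + 1)
        parts = []
        for comp, m, offset in (("BS", 0.3, 2), ("RS", 0.1, 3)):
            params = syn.NeutralSimParams(
                metacommunity_profile=profile,
                local_size=depth,
                migration_rate=m,
                n_samples=n_samples_per_compartment,
                n_generations=2,
                seed=k_seed + offset,
            )
            t = syn.simulate_neutral_metacommunity(params)
            t.counts.index = [f"{comp}{i}" for i in range(n_samples_per_compartment)]
            t.compartment = pd.Series(comp, index=t.counts.index)
            parts.append(t)
        counts = pd.concat([p.counts for p in parts])
        compartment = pd.concat([p.compartment for p in parts])
        rng = np.random.default_rng(k_seed + 7)
        n_total = counts.shape[0]
        lons = np.tile(np.linspace(100.0, 110.0, n_samples_per_compartment), 2)
        lats = 30.0 + rng.normal(0.0, 0.2, n_total)
        coords = pd.DataFrame(
            {"longitude": lons, "latitude": lats}, index=counts.index
        )
        tables[kingdom] = CommunityTable(
            counts,
            kingdom=pd.Series(kingdom, index=counts.columns),
            compartment=compartment,
            coordinates=coords,
        )
        trees[kingdom] = tree
        usable[kingdom] = True
    return InputBundle(tables=tables, trees=trees, assembly_usable=usable, warnings=[])


def load_inputs(config: RunConfig) -> InputBundle:
    """Load and cross-validate tables, trees and metadata.

    Samples present in a table but absent from the metadata are a hard
    error; taxa missing from a tree do not block loading but mark the
    assembly stage unusable for that kingdom.
    """
    if config.synthetic:
        return default_synthetic_bundle(seed=config.seed, **config.synthetic_params)
    warnings_: list = []
    tables, trees, usable = {}, {}, {}
    meta = rio.read_metadata_csv(config.metadata) if config.metadata else None
    for kingdom, counts_path, tree_path in (
        ("bacteria", config.bacteria_counts, config.bacteria_tree),
        ("fungi", config.fungi_counts, config.fungi_tree),
    ):
        if counts_path is None:
            continue
        table = rio.read_counts_tsv(counts_path)
        table.kingdom = pd.Series(kingdom, index=table.counts.columns)
        if meta is not None:
            table = rio.attach_metadata(table, meta)
        tables[kingdom] = table
        trees[kingdom] = None
        usable[kingdom] = False
        if tree_path:
            tree = rio.read_tree(tree_path)
            tips = {t.name for t in tree.tips()}
            missing = [t for t in table.taxon_ids if t not in tips]
            if missing:
                warnings_.append(
                    f"{kingdom}: {len(missing)} taxa missing from tree; assembly stage unusable"
                )
            else:
                usable[kingdom] = True
            trees[kingdom] = tree
    if not tables:
        raise InvalidInputError("no count tables configured")
    return InputBundle(tables=tables, trees=trees, assembly_usable=usable, warnings=warnings_)


@dataclass
class RunReport:
    config: dict
    stages: dict = field(default_factory=dict)
    version: str = ""
    warnings: list = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)


def _write_json(obj, path):
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=float)


def run_pipeline(config: RunConfig, outdir) -> RunReport:
    """Run all enabled stages, writing artifacts under ``outdir``.

    The run is deterministic for a fixed config + seed.  A stage
    failure is recorded in the report and its dependents are skipped.
    """
    from . import __version__

    out = rio.ensure_dir(outdir)
    report = RunReport(config=dataclasses.asdict(config), version=__version__)
    bundle = load_inputs(config)
    report.warnings.extend(bundle.warnings)
    tables = bundle.tables

    def run_stage(name, fn):
        if not config.stages.get(name, True):
            report.stages[name] = {"status": "skipped", "runtime_s": 0.0, "outputs": []}
            return
        t0 = time.monotonic()
        try:
            outputs = fn()
            report.stages[name] = {
                "status": "ok",
                "runtime_s": round(time.monotonic() - t0, 3),
                "outputs": [str(p) for p in outputs],
            }
            log.info("stage %s done in %.1fs", name, time.monotonic() - t0)
        except RhizoecolError as exc:
            report.stages[name] = {
                "status": "failed",
                "runtime_s": round(time.monotonic() - t0, 3),
                "outputs": [],
                "error": f"{type(exc).__name__}: {exc}",
            }
            log.error("stage %s failed: %s", name, exc)

    # ---- preprocess ----------------------------------------------------
    def stage_preprocess():
        outputs = []
        for kingdom, table in list(tables.items()):
            depth = config.rarefaction_depth.get(kingdom)
            if depth:
                tables[kingdom] = div.rarefy(
                    table, int(depth), seed=seed_for(config.seed, f"rarefy-{kingdom}")
                )
            path = out / f"counts_{kingdom}.tsv"
            rio.write_counts_tsv(tables[kingdom], path)
            rio.write_metadata_csv(tables[kingdom], out / f"metadata_{kingdom}.csv")
            outputs += [path, out / f"metadata_{kingdom}.csv"]
        return outputs

    run_stage("preprocess", stage_preprocess)
    preprocess_ok = report.stages["preprocess"]["status"] == "ok"

    # ---- diversity -----------------------------------------------------
    def stage_diversity():
        outputs = []
        alphas = {}
        bc = {}
        for kingdom, table in tables.items():
            alpha = div.chao1_per_sample(table)
            alphas[kingdom] = alpha
            alpha.to_csv(out / f"chao1_{kingdom}.csv")
            bc[kingdom] = div.bray_curtis_matrix(table)
            rio.write_distance_matrix(bc[kingdom], out / f"bray_curtis_{kingdom}.csv")
            deco = div.decompose_beta(table)
            deco.pairs.to_csv(out / f"beta_decomposition_{kingdom}.csv", index=False)
            deco.contributions.to_csv(
                out / f"beta_contributions_{kingdom}.csv", index=False
            )
            outputs += [
                out / f"chao1_{kingdom}.csv",
                out / f"bray_curtis_{kingdom}.csv",
                out / f"beta_decomposition_{kingdom}.csv",
                out / f"beta_contributions_{kingdom}.csv",
            ]
            if table.coordinates is not None:
                ddr = div.distance_decay_fit(
                    bc[kingdom],
                    table.coordinates,
                    permutations=config.n_perm,
                    seed=seed_for(config.seed, f"ddr-{kingdom}"),
                )
                _write_json(ddr, out / f"distance_decay_{kingdom}.json")
                outputs.append(out / f"distance_decay_{kingdom}.json")
        if {"bacteria", "fungi"} <= set(tables):
            shared = [s for s in bc["bacteria"].ids if s in set(bc["fungi"].ids)]
            if len(shared) >= 3:
                m = div.mantel_test(
                    bc["bacteria"].filter(shared),
                    bc["fungi"].filter(shared),
                    permutations=config.n_perm,
                    seed=seed_for(config.seed, "mantel"),
                )
                _write_json(m, out / "mantel_bacteria_vs_fungi.json")
                outputs.append(out / "mantel_bacteria_vs_fungi.json")
            ratio = div.bf_ratio(alphas["bacteria"], alphas["fungi"])
            ratio.to_csv(out / "bf_ratio.csv")
            outputs.append(out / "bf_ratio.csv")
        return outputs

    if preprocess_ok:
        run_stage("diversity", stage_diversity)
    else:
        report.stages["diversity"] = {"status": "skipped", "runtime_s": 0.0, "outputs": []}

    # ---- assembly ------------------------------------------------------
    def stage_assembly():
        outputs = []
        for kingdom, table in tables.items():
            tree = bundle.trees.get(kingdom)
            if tree is None or not bundle.assembly_usable.get(kingdom):
                raise MissingLeafError([f"<{kingdom}: tree unusable>"])
            result = asm.assembly_analysis(
                table,
                tree,
                n_null=config.n_null,
                seed=seed_for(config.seed, f"assembly-{kingdom}"),
                legend_convention=config.legend_convention,
                on_degenerate="zero",
            )
            result.pairs.to_csv(out / f"assembly_pairs_{kingdom}.csv", index=False)
            summary = {
                "process_fractions": result.process_fractions,
                "fraction_stochastic": result.fraction_stochastic,
                "fraction_deterministic": result.fraction_deterministic,
            }
            _write_json(summary, out / f"assembly_summary_{kingdom}.json")
            mst = asm.mst_ratio(
                table, n_null=config.n_null, seed=seed_for(config.seed, f"mst-{kingdom}")
            )
            mst.pairs.to_csv(out / f"mst_{kingdom}.csv", index=False)
            outputs += [
                out / f"assembly_pairs_{kingdom}.csv",
                out / f"assembly_summary_{kingdom}.json",
                out / f"mst_{kingdom}.csv",
            ]
        return outputs

    if preprocess_ok:
        run_stage("assembly", stage_assembly)
    else:
        report.stages["assembly"] = {"status": "skipped", "runtime_s": 0.0, "outputs": []}

    # ---- neutral / niche ----------------------------------------------
    def stage_neutral():
        outputs = []
        for kingdom, table in tables.items():
            fit = ncm.fit_ncm(table)
            _write_json(fit.to_dict(), out / f"ncm_{kingdom}.json")
            fit.taxa.to_csv(out / f"ncm_taxa_{kingdom}.csv", index=False)
            niche = ncm.classify_niche_strategy(
                table, n_perm=config.n_perm, seed=seed_for(config.seed, f"niche-{kingdom}")
            )
            pd.DataFrame(
                {"levins_B": niche.breadth, "strategy": niche.strategy}
            ).to_csv(out / f"niche_{kingdom}.csv")
            _write_json(
                {"bcom": niche.bcom, "strategy_fractions": niche.strategy_fractions},
                out / f"niche_summary_{kingdom}.json",
            )
            outputs += [
                out / f"ncm_{kingdom}.json",
                out / f"ncm_taxa_{kingdom}.csv",
                out / f"niche_{kingdom}.csv",
                out / f"niche_summary_{kingdom}.json",
            ]
        return outputs

    if preprocess_ok:
        run_stage("neutral_niche", stage_neutral)
    else:
        report.stages["neutral_niche"] = {"status": "skipped", "runtime_s": 0.0, "outputs": []}

    # ---- network -------------------------------------------------------
    def stage_network():
        outputs = []
        merged = _merge_kingdoms(tables)
        corr = net.sparcc_correlation(
            merged,
            n_resample=config.n_resample,
            seed=seed_for(config.seed, "sparcc"),
            prevalence=config.prevalence,
        )
        graph = net.build_network(
            corr, r_threshold=config.r_threshold, kingdom=merged.kingdom
        )
        roles = net.node_roles(graph, seed=seed_for(config.seed, "modules"))
        metrics = {
            "n_nodes": graph.n_nodes,
            "n_edges": graph.n_edges,
            "n_isolated": len(graph.isolated),
            "edge_partition": net.edge_partition(graph),
        }
        if graph.n_edges > 0:
            for node, row in roles.iterrows():
                graph.graph.nodes[node]["module"] = int(row.module)
                graph.graph.nodes[node]["zi"] = float(row.zi)
                graph.graph.nodes[node]["pi"] = float(row.pi)
                graph.graph.nodes[node]["role"] = row.role
            metrics["robustness_random_50pct"] = net.robustness_removal(
                graph,
                "random_fraction",
                fraction=0.5,
                reps=50,
                seed=seed_for(config.seed, "robustness"),
            )["mean"]
            metrics["robustness_targeted_hubs"] = net.robustness_removal(
                graph, "targeted_hubs", n_hubs=10, roles=roles,
                seed=seed_for(config.seed, "robustness-hubs"),
            )["mean"]
            metrics["natural_connectivity"] = net.natural_connectivity(graph.graph)
            if graph.n_nodes >= 3:
                metrics["vulnerability"] = net.vulnerability_index(graph)
            curve = net.natural_connectivity_curve(
                graph, reps=10, seed=seed_for(config.seed, "natconn")
            )
            curve.to_csv(out / "natural_connectivity_curve.csv", index=False)
            outputs.append(out / "natural_connectivity_curve.csv")
            nx.write_graphml(graph.graph, out / "network.graphml")
            edges = nx.to_pandas_edgelist(graph.graph)
            edges.to_csv(out / "network_edges.csv", index=False)
            roles.to_csv(out / "node_roles.csv")
            outputs += [out / "network.graphml", out / "network_edges.csv", out / "node_roles.csv"]
        cohesion = net.cohesion_metrics(
            merged, n_null=100, seed=seed_for(config.seed, "cohesion")
        )
        cohesion.cohesion.to_csv(out / "cohesion.csv")
        _write_json(metrics, out / "network_metrics.json")
        outputs += [out / "cohesion.csv", out / "network_metrics.json"]
        return outputs

    if preprocess_ok:
        run_stage("network", stage_network)
    else:
        report.stages["network"] = {"status": "skipped", "runtime_s": 0.0, "outputs": []}

    # ---- sources -------------------------------------------------------
    def stage_sources():
        outputs = []
        for kingdom, table in tables.items():
            groups = table.by_compartment()
            if not {"BS", "RS"} <= set(groups):
                log.warning("sources: need BS and RS compartments for %s; skipping", kingdom)
                continue
            sink = groups["RS"].values().sum(axis=0)
            source = groups["BS"].values().sum(axis=0)
            est = src.em_source_apportionment(
                sink, [source], unknown=True,
                seed=seed_for(config.seed, f"sources-{kingdom}"),
                source_names=["BS"],
            )
            _write_json(est.as_dict(), out / f"source_apportionment_{kingdom}.json")
            outputs.append(out / f"source_apportionment_{kingdom}.json")
        return outputs

    if preprocess_ok:
        run_stage("sources", stage_sources)
    else:
        report.stages["sources"] = {"status": "skipped", "runtime_s": 0.0, "outputs": []}

    report.to_json(out / "report.json")
    return report


def _merge_kingdoms(tables: dict) -> CommunityTable:
    """Join bacteria + fungi tables on shared samples for interkingdom analysis."""
    kingdoms = list(tables)
    shared = set(tables[kingdoms[0]].sample_ids)
    for k in kingdoms[1:]:
        shared &= set(tables[k].sample_ids)
    order = [s for s in tables[kingdoms[0]].sample_ids if s in shared]
    if len(order) < 3:
        raise InvalidInputError("kingdom tables share too few samples to merge")
    counts = pd.concat(
        [tables[k].counts.loc[order].add_prefix(f"{k[0].upper()}_") for k in kingdoms], axis=1
    )
    kingdom = pd.concat(
        [
            pd.Series(k, index=tables[k].counts.add_prefix(f"{k[0].upper()}_").columns)
            for k in kingdoms
        ]
    )
    first = tables[kingdoms[0]]
    return CommunityTable(
        counts,
        kingdom=kingdom,
        compartment=first.compartment.loc[order],
        coordinates=None if first.coordinates is None else first.coordinates.loc[order],
    )
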