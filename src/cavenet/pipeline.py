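"""End-to-end orchestration: tables -> diversity -> associations -> network -> roles.

``AnalysisConfig`` holds every tunable threshold of the analysis with the
study defaults (0.1% mean relative abundance, 20% occurrence, |rho| >= 0.7,
BH-adjusted q < 0.05, Zi/Pi thresholds 2.5/0.62, 9,999 Mantel permutations,
large modules above 5% of nodes).  ``run_all`` executes the stages in order
and writes every intermediate artifact plus a run log.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import diversity, envassoc, netbuild, netroles, tables

__all__ = ["AnalysisConfig", "run_all", "PipelineError"]

log = logging.getLogger("cavenet")


class PipelineError(RuntimeError):
    """A stage failure, wrapped with the stage name."""


@dataclass
class AnalysisConfig:
    rarefaction_depth: int = 8000
    rarefaction_seed: int = 0
    min_mean_relabund: float = 0.001
    min_occurrence: float = 0.2
    rho_min: float = 0.7
    alpha: float = 0.05
    p_adjust: str = "fdr_bh"  # "none" switches the edge cut to raw p
    zi_thr: float = 2.5
    pi_thr: float = 0.62
    mantel_permutations: int = 9999
    mantel_seed: int = 0
    module_seed: int = 0
    large_module_frac: float = 0.05
    group_variable: str = "cave"
    env_variables: list[str] = field(default_factory=list)
    output_dir: str = "results/run"

    def validate(self) -> "AnalysisConfig":
        checks = [
            ("rarefaction_depth", self.rarefaction_depth > 0),
            ("min_mean_relabund", 0 <= self.min_mean_relabund <= 1),
            ("min_occurrence", 0 <= self.min_occurrence <= 1),
            ("rho_min", 0 <= self.rho_min <= 1),
            ("alpha", 0 < self.alpha <= 1),
            ("zi_thr", self.zi_thr == self.zi_thr),
            ("pi_thr", self.pi_thr == self.pi_thr),
            ("mantel_permutations", self.mantel_permutations >= 99),
            ("large_module_frac", 0 <= self.large_module_frac < 1),
            ("p_adjust", self.p_adjust in ("fdr_bh", "none")),
        ]
        bad = [name for name, ok in checks if not ok]
        if bad:
            raise ValueError(f"invalid configuration fields: {bad}")
        return self

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data).validate()


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - annotate and re-raise
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return inner

    return wrap


def run_all(
    config: AnalysisConfig,
    table: tables.FeatureTable,
    taxonomy: tables.TaxonomyMap | None = None,
    metadata: tables.SampleMetadata | None = None,
) -> dict:
    """Run the full analysis and write artifacts under ``config.output_dir``.

    Returns a bundle dict with the in-memory results; every table is also
    written as TSV/CSV (plus newick and GraphML) under the output directory.
    Reruns with the same config and inputs are deterministic.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if metadata is not None:
        metadata.check_covers(table)

    rare = _stage("rarefy")(tables.rarefy)(
        table, config.rarefaction_depth, config.rarefaction_seed, drop_small=True
    )
    tables.write_feature_table(rare, out / "rarefied_table.tsv")

    alpha_df = _stage("alpha_diversity")(diversity.alpha_diversity_table)(rare)
    if metadata is not None and config.group_variable in metadata.df.columns:
        groups = metadata.df.loc[rare.sample_ids, config.group_variable].to_numpy()
        kw = {}
        for index in ("chao1", "shannon"):
            h, p = diversity.kruskal_wallis(alpha_df[index].to_numpy(), groups)
            kw[index] = {"H": h, "p": p}
        alpha_kw = pd.DataFrame(kw).T
        alpha_kw.to_csv(out / "alpha_kruskal_wallis.tsv", sep="\t")
    alpha_df.to_csv(out / "alpha_diversity.tsv", sep="\t")

    bc = _stage("bray_curtis")(diversity.bray_curtis)(rare)
    ord_res = _stage("pcoa")(diversity.pcoa)(bc)
    coords = ord_res.to_frame()
    coords.to_csv(out / "pcoa_coordinates.tsv", sep="\t")
    pd.DataFrame(
        {"eigenvalue": ord_res.eigenvalues, "explained_pct": ord_res.explained}
    ).to_csv(out / "pcoa_eigen.tsv", sep="\t", index_label="axis")
    tree = _stage("upgma")(diversity.upgma)(bc)
    (out / "upgma.nwk").write_text(tree.to_newick() + "\n")

    mantel_df = None
    if metadata is not None:
        env_vars = config.env_variables or list(
            metadata.numeric().columns
        )
        mantel_df = _stage("mantel")(envassoc.mantel_table)(
            bc,
            metadata,
            env_vars,
            n_perm=config.mantel_permutations,
            seed=config.mantel_seed,
        )
        mantel_df.to_csv(out / "mantel.tsv", sep="\t")

    filtered = _stage("prevalence_filter")(tables.prevalence_filter)(
        rare, config.min_mean_relabund, config.min_occurrence
    )
    tables.write_feature_table(filtered, out / "filtered_table.tsv")

    screen = _stage("pairwise_spearman")(netbuild.pairwise_spearman)(filtered)
    net = _stage("build_network")(netbuild.build_network)(
        screen,
        rho_min=config.rho_min,
        alpha=config.alpha,
        taxonomy=taxonomy,
        use_raw_p=config.p_adjust == "none",
    )
    partition, q = _stage("detect_modules")(netbuild.detect_modules)(
        net, seed=config.module_seed
    )
    topo = _stage("topology")(netbuild.topology)(net, partition=partition)
    topo.to_frame().to_csv(out / "topology.tsv", sep="\t", index=False)
    census = netbuild.module_census(partition, net, config.large_module_frac)
    census.to_csv(out / "modules.tsv", sep="\t")
    netbuild.write_edge_list(net, out / "edges.csv")
    netbuild.write_graphml(net, out / "network.graphml", partition=partition)

    roles = _stage("node_roles")(netroles.node_role_table)(
        net, partition, taxonomy=taxonomy, zi_thr=config.zi_thr, pi_thr=config.pi_thr
    )
    roles.to_csv(out / "node_roles.tsv", sep="\t")
    role_pct = netroles.role_percentages(roles)
    role_pct.to_csv(out / "role_percentages.tsv", sep="\t", header=["percent"])
    keystones = netroles.keystone_summary(roles, taxonomy)
    keystones.to_csv(out / "keystone_summary.tsv", sep="\t")

    logpath = out / "run_log.json"
    logpath.write_text(
        json.dumps(
            {
                "config": dataclasses.asdict(config),
                "n_input_features": table.n_features,
                "n_input_samples": table.n_samples,
                "n_filtered_features": filtered.n_features,
                "network_nodes": topo.nodes,
                "network_edges": topo.edges,
                "modularity": topo.modularity,
            },
            indent=2,
        )
    )
    log.info("analysis complete: %s nodes, %s edges", topo.nodes, topo.edges)

    return {
        "rarefied": rare,
        "alpha": alpha_df,
        "bray_curtis": bc,
        "pcoa": ord_res,
        "upgma": tree,
        "mantel": mantel_df,
        "filtered": filtered,
        "screen": screen,
        "network": net,
        "partition": partition,
        "modularity": q,
        "topology": topo,
        "module_census": census,
        "roles": roles,
        "role_percentages": role_pct,
        "keystones": keystones,
    }
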