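"""Config-driven orchestration of the full analysis over three domains and
two groups, with a machine-readable results bundle and run manifest.

A single global seed is expanded into per-stage seeds through
``numpy.random.SeedSequence(seed).spawn`` in a fixed order
(diversity, network, niche, assembly, environment, simulation), so any
stage can be rerun in isolation and reproduce its outputs bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assembly import beta_nti, classify_processes, raup_crick_bray
from .cooccurrence import account_network, build_network, edge_table, spearman_matrix
from .diversity import alpha_diversity, bray_curtis, group_compare_rank, pcoa, permanova
from .environment import abt_influence, community_response, compare_chemistry, db_rda
from .io_core import (
    CommunityTable,
    DOMAINS,
    SampleMetadata,
    filter_prevalence_abundance,
    read_community_table,
    read_metadata,
    read_newick,
    read_taxonomy,
)
from .niche import classify_generalists, fit_neutral_model, levins_breadth
from .synthetic import SimulationConfig, simulate_dataset

logger = logging.getLogger(__name__)

ALL_STAGES = ("diversity", "networks", "niche", "assembly", "environment")
_STAGE_SEED_ORDER = ("diversity", "networks", "niche", "assembly",
                     "environment", "simulation")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Everything a run needs: inputs (or a simulation), per-stage
    parameters, and the output directory."""

    output_dir: str = "results"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    simulate: bool = False
    simulation: dict = field(default_factory=dict)
    # per-domain paths: {domain: {"table": ..., "taxonomy": ..., "tree": ...}}
    inputs: dict = field(default_factory=dict)
    metadata_path: str | None = None
    min_prevalence: float = 0.25
    top_n: int = 50
    rank: str = "phylum"
    rho_threshold: float = 0.8
    network_alpha: float = 0.05
    n_permutations: int = 999
    n_null: int = 999
    generalist_null: int = 1000
    generalist_ci: float = 0.95
    bnti_threshold: float = 2.0
    rc_threshold: float = 0.95
    chemistry_variables: list[str] = field(
        default_factory=lambda: ["TN", "FA", "ammonia", "nitrate", "nitrite",
                                 "EN", "ON"])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def stage_seeds(self) -> dict[str, int]:
        children = np.random.SeedSequence(self.seed).spawn(
            len(_STAGE_SEED_ORDER))
        return {name: int(child.generate_state(1)[0] % (2 ** 31))
                for name, child in zip(_STAGE_SEED_ORDER, children)}


@dataclass
class ResultsBundle:
    manifest: dict
    output_dir: Path

    def path(self, name: str) -> Path:
        return self.output_dir / name


def _load_inputs(config: RunConfig):
    if config.simulate:
        sim = SimulationConfig(seed=config.seed, **config.simulation)
        ds = simulate_dataset(sim)
        return ds["tables"], ds["taxonomies"], ds["trees"], ds["metadata"]
    tables, taxonomies, trees = {}, {}, {}
    for domain, paths in config.inputs.items():
        if domain not in DOMAINS:
            raise PipelineError(f"unknown domain {domain!r}")
        tables[domain] = read_community_table(paths["table"], domain)
        taxonomies[domain] = read_taxonomy(paths["taxonomy"])
        trees[domain] = read_newick(paths["tree"]) if paths.get("tree") else None
    if config.metadata_path is None:
        raise PipelineError("metadata_path required when not simulating")
    metadata = read_metadata(config.metadata_path)
    return tables, taxonomies, trees, metadata


def run_pipeline(config: RunConfig) -> ResultsBundle:
    """Execute the requested stages in dependency order, writing tidy TSV
    outputs and a JSON manifest.  Partial results are preserved on stage
    failure; the manifest records the failing stage and cause."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = config.stage_seeds()
    config_yaml = yaml.safe_dump(asdict(config), sort_keys=True)
    manifest: dict = {
        "version": __version__,
        "config_hash": hashlib.sha256(config_yaml.encode()).hexdigest(),
        "seed": config.seed,
        "stage_seeds": seeds,
        "stages": {},
        "files": [],
        "warnings": [],
    }

    def _write(frame: pd.DataFrame, name: str, **kwargs) -> None:
        p = outdir / name
        frame.to_csv(p, sep="\t", **kwargs)
        manifest["files"].append(name)

    failure: tuple[str, str] | None = None
    try:
        tables, taxonomies, trees, metadata = _load_inputs(config)
        for table in tables.values():
            metadata.check_covers(table)
        groups = metadata.groups
        filtered = {
            d: filter_prevalence_abundance(t, config.min_prevalence, config.top_n)
            for d, t in tables.items()
        }
        per_group_samples = {
            g: list(groups.index[groups == g]) for g in metadata.group_labels()
        }
        dists = {d: bray_curtis(t) for d, t in tables.items()}

        for stage in config.stages:
            if stage not in ALL_STAGES:
                raise PipelineError(f"unknown stage {stage!r}")
            t0 = time.perf_counter()
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                if stage == "diversity":
                    _run_diversity(config, tables, taxonomies, metadata,
                                   dists, seeds["diversity"], _write)
                elif stage == "networks":
                    _run_networks(config, filtered, taxonomies,
                                  per_group_samples, _write)
                elif stage == "niche":
                    _run_niche(config, tables, per_group_samples,
                               seeds["niche"], _write)
                elif stage == "assembly":
                    _run_assembly(config, tables, trees, groups,
                                  seeds["assembly"], _write)
                elif stage == "environment":
                    _run_environment(config, metadata, dists,
                                     seeds["environment"], _write)
            for w in caught:
                manifest["warnings"].append(f"{stage}: {w.message}")
            manifest["stages"][stage] = {
                "status": "ok",
                "wall_time_s": round(time.perf_counter() - t0, 3),
            }
    except Exception as exc:  # record, then re-raise after writing manifest
        stage_name = next(
            (s for s in config.stages if s not in manifest["stages"]), "input")
        manifest["stages"][stage_name] = {"status": "failed", "error": str(exc)}
        failure = (stage_name, str(exc))

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    (outdir / "config.yaml").write_text(config_yaml)
    manifest["files"].extend(["manifest.json", "config.yaml"])
    if failure is not None:
        raise PipelineError(
            f"stage {failure[0]!r} failed: {failure[1]}") from None
    return ResultsBundle(manifest=manifest, output_dir=outdir)


# ---------------------------------------------------------------------------
# stage bodies


def _run_diversity(config, tables, taxonomies, metadata, dists, seed, _write):
    alpha_frames, pcoa_frames, permanova_rows, compare_frames = [], [], [], []
    for domain, table in tables.items():
        a = alpha_diversity(table)
        a.insert(0, "domain", domain)
        alpha_frames.append(a)
        res = pcoa(dists[domain], n_axes=2)
        coords = res.coordinates.copy()
        coords.insert(0, "domain", domain)
        for k in range(min(2, len(res.proportion_explained))):
            coords[f"prop_axis{k + 1}"] = res.proportion_explained[k]
        pcoa_frames.append(coords)
        perm = permanova(dists[domain], metadata.groups,
                         config.n_permutations, seed)
        permanova_rows.append((domain, perm.f_statistic, perm.p_value,
                               perm.n_permutations))
        comp = group_compare_rank(table, taxonomies[domain], metadata,
                                  config.rank)
        comp.insert(0, "domain", domain)
        compare_frames.append(comp)
    _write(pd.concat(alpha_frames), "alpha_diversity.tsv",
           index_label="sample_id")
    _write(pd.concat(pcoa_frames), "pcoa_coordinates.tsv",
           index_label="sample_id")
    _write(pd.DataFrame(permanova_rows,
                        columns=["domain", "pseudo_F", "p_value",
                                 "n_permutations"]).set_index("domain"),
           "permanova.tsv")
    _write(pd.concat(compare_frames), "rank_comparison.tsv",
           index_label="lineage")


def _run_networks(config, filtered, taxonomies, per_group_samples, _write):
    edge_frames, account_rows = [], []
    for group, samples in per_group_samples.items():
        sub = [CommunityTable(t.data.loc[samples], t.domain)
               for t in filtered.values()]
        corr = spearman_matrix(sub)
        net = build_network(corr, config.rho_threshold, config.network_alpha,
                            taxonomies=taxonomies, group=group)
        acct = account_network(net)
        edges = edge_table(net)
        edges.insert(0, "group", group)
        edge_frames.append(edges)
        for d, cnt in acct.nodes_per_domain.items():
            account_rows.append((group, "nodes", d, cnt))
        for d, cnt in acct.intra_edges.items():
            account_rows.append((group, "intra_edges", d, cnt))
        for (a, b), cnt in acct.inter_edges.items():
            account_rows.append((group, "inter_edges", f"{a}-{b}", cnt))
    _write(pd.concat(edge_frames, ignore_index=True), "network_edges.tsv",
           index=False)
    _write(pd.DataFrame(account_rows,
                        columns=["group", "kind", "unit", "count"]),
           "network_accounting.tsv", index=False)


def _run_niche(config, tables, per_group_samples, seed, _write):
    taxon_frames, summary_rows = [], []
    for domain, table in tables.items():
        for group, samples in per_group_samples.items():
            sub_data = table.data.loc[samples]
            sub_data = sub_data.loc[:, sub_data.sum(axis=0) > 0]
            sub = CommunityTable(sub_data, table.domain)
            nb = levins_breadth(sub)
            cls = classify_generalists(sub, config.generalist_null,
                                       config.generalist_ci, seed)
            fit = fit_neutral_model(sub)
            per_taxon = cls.table.join(fit.table, how="left")
            per_taxon.insert(0, "group", group)
            per_taxon.insert(0, "domain", domain)
            taxon_frames.append(per_taxon)
            summary_rows.append((
                domain, group, nb.b_community.mean(), fit.m, fit.nt,
                fit.r_squared,
                cls.fractions["generalist"], cls.fractions["specialist"],
                cls.fractions["neither"],
            ))
    _write(pd.concat(taxon_frames), "niche_taxa.tsv", index_label="taxon_id")
    _write(pd.DataFrame(summary_rows, columns=[
        "domain", "group", "mean_community_breadth", "sloan_m", "sloan_nt",
        "sloan_r2", "generalist_fraction", "specialist_fraction",
        "neither_fraction"]), "niche_summary.tsv", index=False)


def _run_assembly(config, tables, trees, groups, seed, _write):
    pair_frames, fraction_rows = [], []
    for domain, table in tables.items():
        tree = trees.get(domain)
        if tree is None:
            raise PipelineError(
                f"assembly stage needs a phylogeny for domain {domain!r}: "
                "supply a newick tree or disable the assembly stage")
        bnti = beta_nti(table, tree, config.n_null, seed)
        rc = raup_crick_bray(table, config.n_null, seed + 1)
        cls = classify_processes(bnti, rc, groups,
                                 config.bnti_threshold, config.rc_threshold)
        pairs = cls.pair_labels.copy()
        pairs.insert(0, "domain", domain)
        pair_frames.append(pairs)
        for scope, fracs in [("all", cls.fractions),
                             *cls.group_fractions.items()]:
            for label, frac in fracs.items():
                fraction_rows.append((domain, scope, label, frac))
        fraction_rows.append((domain, "all", "deterministic",
                              cls.deterministic_fraction))
        fraction_rows.append((domain, "all", "stochastic",
                              cls.stochastic_fraction))
    _write(pd.concat(pair_frames, ignore_index=True), "assembly_pairs.tsv",
           index=False)
    _write(pd.DataFrame(fraction_rows,
                        columns=["domain", "scope", "process", "fraction"]),
           "assembly_fractions.tsv", index=False)


def _run_environment(config, metadata, dists, seed, _write):
    env = metadata.frame
    chem = compare_chemistry(env, variables=tuple(config.chemistry_variables))
    _write(chem, "chemistry_comparison.tsv")
    rda_rows, abt_frames = [], []
    for domain, dist in dists.items():
        rda = db_rda(dist, env, list(config.chemistry_variables),
                     config.n_permutations, seed)
        rda_rows.append((domain, rda.constrained_proportion, rda.f_statistic,
                         rda.p_value, rda.n_permutations))
        response = community_response(dist)
        abt = abt_influence(response, env, list(config.chemistry_variables),
                            seed=seed)
        frame = abt.influence.rename("influence_pct").to_frame()
        frame.insert(0, "domain", domain)
        abt_frames.append(frame)
    _write(pd.DataFrame(rda_rows, columns=[
        "domain", "constrained_proportion", "pseudo_F", "p_value",
        "n_permutations"]).set_index("domain"), "dbrda.tsv")
    _write(pd.concat(abt_frames), "abt_influence.tsv",
           index_label="variable")
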