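"""Seeded generators for ASV tables, phylogenies, and sediment chemistry.

The generators emulate the statistical structure of a two-group benthic
mesocosm design: two groups of six replicate sediment samples, three
microbial domains of differing richness (bacteria > protists > fungi),
lognormal metacommunity abundance distributions, and sediment nitrogen
chemistry whose derived pools obey their defining arithmetic exactly.

Community regimes:

* ``neutral`` — Dirichlet-multinomial sampling around a shared
  metacommunity.  The Dirichlet concentration ``Nt * m * meta`` maps the
  migration parameter ``m`` of the neutral community model directly onto
  among-sample variance: small ``m`` means dispersal limitation, ``m = 1``
  near mass-action.  This makes the generator the generative counterpart of
  the Sloan fit the pipeline estimates, closing the recovery loop.
* ``homogeneous_selection`` / ``heterogeneous_selection`` — each taxon
  carries an environmental optimum evolved by Brownian motion along the
  phylogeny, and sampling weights are Gaussian-filtered around the sample's
  environment.  Brownian (rather than independent) optima give selection
  the phylogenetic signal that βNTI assumes; identical environments across
  samples yield consistent filtering, divergent group environments yield
  divergent filtering.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .io_core import (
    CommunityTable,
    PhyloTree,
    SampleMetadata,
    TaxonomyMap,
    write_community_table,
    write_metadata,
    write_newick,
    write_taxonomy,
)

REGIMES = ("neutral", "homogeneous_selection", "heterogeneous_selection",
           "dispersal_limited")

DEFAULT_RICHNESS = {"bacteria": 300, "fungi": 100, "protist": 150}

_PHYLUM_POOLS = {
    "bacteria": ["Proteobacteria", "Acidobacteriota", "Bacteroidota",
                 "Chloroflexi", "Firmicutes", "Actinobacteriota",
                 "Myxococcota", "Gemmatimonadota"],
    "fungi": ["Ascomycota", "Chytridiomycota", "Mucoromycota",
              "Basidiomycota", "Zoopagomycota"],
    "protist": ["Opisthokonta", "Alveolata", "Rhizaria", "Stramenopiles",
                "Chlorophyta", "Tubulinea"],
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study design.

    Defaults mirror the emulated design: two groups of six replicates,
    richness 300 (bacteria), 100 (fungi), 150 (protists), lognormal
    metacommunity, local community size ``nt`` reads per sample.
    """

    seed: int = 0
    n_samples_per_group: int = 6
    richness: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_RICHNESS))
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 1.5
    regime: str = "neutral"
    migration_m: float = 0.3
    nt: int = 10_000
    selection_strength: float = 20.0
    env_effect: float = 1.0

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"regime must be one of {REGIMES}, got {self.regime!r}")
        if not 0 < self.migration_m <= 1:
            raise ValueError("migration_m must be in (0, 1]")


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_tree(n_taxa: int, seed: int | np.random.Generator) -> PhyloTree:
    """Pure-birth (Yule) ultrametric tree with tips ``ASV_1..ASV_n``.

    Built by forward simulation: exponential waiting times with rate
    proportional to the number of extant lineages, a uniformly chosen
    lineage splitting at each event, and all pendant edges extended to the
    present, which makes the tree exactly ultrametric.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    rng = _rng(seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = True
    root = tree.seed_node
    leaves = [root.new_child(edge_length=0.0), root.new_child(edge_length=0.0)]
    while len(leaves) < n_taxa:
        wait = rng.exponential(1.0 / len(leaves))
        for leaf in leaves:
            leaf.edge.length += wait
        idx = rng.integers(len(leaves))
        parent = leaves.pop(idx)
        leaves.append(parent.new_child(edge_length=0.0))
        leaves.append(parent.new_child(edge_length=0.0))
    wait = rng.exponential(1.0 / len(leaves))
    for leaf in leaves:
        leaf.edge.length += wait
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon = taxa.new_taxon(label=f"ASV_{i}")
    return PhyloTree(tree=tree)


def simulate_metacommunity(
    n_taxa: int, mu: float = 0.0, sigma: float = 1.5,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Lognormal relative-abundance vector, strictly positive, summing to 1."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    rng = _rng(seed)
    raw = rng.lognormal(mean=mu, sigma=sigma, size=n_taxa)
    return raw / raw.sum()


def _sample_ids(n_samples: int, prefix: str = "S") -> list[str]:
    return [f"{prefix}{i + 1}" for i in range(n_samples)]


def simulate_neutral_communities(
    meta: np.ndarray,
    m: float,
    nt: int,
    n_samples: int,
    seed: int | np.random.Generator = 0,
    domain: str = "bacteria",
    sample_ids: Sequence[str] | None = None,
    taxon_ids: Sequence[str] | None = None,
) -> CommunityTable:
    """Dirichlet-multinomial local communities around a metacommunity.

    Each sample's composition is a Dirichlet draw with concentration
    ``nt * m * meta`` followed by a multinomial of size ``nt``, so
    per-sample totals equal ``nt`` exactly and small ``m`` produces high
    among-sample variance (dispersal limitation).
    """
    if not 0 < m <= 1:
        raise ValueError("m must be in (0, 1]")
    if nt < 100:
        raise ValueError("nt must be >= 100")
    rng = _rng(seed)
    meta = np.asarray(meta, dtype=float)
    alpha = nt * m * meta
    counts = np.empty((n_samples, meta.size), dtype=np.int64)
    for i in range(n_samples):
        p = rng.dirichlet(alpha)
        counts[i] = rng.multinomial(nt, p)
    if sample_ids is None:
        sample_ids = _sample_ids(n_samples)
    if taxon_ids is None:
        taxon_ids = [f"ASV_{j + 1}" for j in range(meta.size)]
    frame = pd.DataFrame(counts, index=list(sample_ids), columns=list(taxon_ids))
    return CommunityTable(data=frame, domain=domain)


def brownian_optima(
    tree: PhyloTree, seed: int | np.random.Generator = 0, sigma: float = 1.0,
    root_value: float = 0.0,
) -> pd.Series:
    """Trait optima evolved by Brownian motion along the tree.

    Each edge adds a Normal(0, sigma^2 * branch_length) increment, so
    closely related tips receive correlated optima — the phylogenetic
    signal that selection regimes need for βNTI to detect them.
    """
    rng = _rng(seed)
    values: dict[int, float] = {id(tree.tree.seed_node): root_value}
    out = {}
    for node in tree.tree.preorder_node_iter():
        if node is tree.tree.seed_node:
            continue
        bl = node.edge.length or 0.0
        parent_val = values[id(node.parent_node)]
        val = parent_val + rng.normal(0.0, sigma * np.sqrt(bl))
        values[id(node)] = val
        if node.is_leaf():
            out[node.taxon.label] = val
    return pd.Series(out)


def simulate_selected_communities(
    tree: PhyloTree,
    env: Sequence[float],
    strength: float,
    nt: int,
    seed: int | np.random.Generator = 0,
    meta: np.ndarray | None = None,
    domain: str = "bacteria",
    sample_ids: Sequence[str] | None = None,
    bm_sigma: float = 1.0,
) -> CommunityTable:
    """Communities under environmental filtering with phylogenetically
    conserved optima.

    Sampling weights for sample ``s`` are ``meta_j * exp(-strength *
    (env_s - optimum_j)^2)``.  ``strength = 0`` reduces to mass-action
    neutral sampling from ``meta``.  Identical ``env`` across samples gives
    a homogeneous-selection regime; strongly divergent group environments
    give a heterogeneous-selection regime.
    """
    if strength < 0:
        raise ValueError("strength must be >= 0")
    rng = _rng(seed)
    taxa = tree.tip_labels
    if meta is None:
        meta = simulate_metacommunity(len(taxa), seed=rng)
    meta = np.asarray(meta, dtype=float)
    optima = brownian_optima(tree, seed=rng, sigma=bm_sigma).loc[taxa].to_numpy()
    env = np.asarray(env, dtype=float)
    counts = np.empty((env.size, len(taxa)), dtype=np.int64)
    for i, e in enumerate(env):
        w = meta * np.exp(-strength * (e - optima) ** 2)
        if w.sum() == 0:
            w = meta.copy()
        counts[i] = rng.multinomial(nt, w / w.sum())
    if sample_ids is None:
        sample_ids = _sample_ids(env.size)
    frame = pd.DataFrame(counts, index=list(sample_ids), columns=taxa)
    return CommunityTable(data=frame, domain=domain)


def simulate_selection_regime(
    tree: PhyloTree,
    n_samples: int,
    nt: int,
    seed: int | np.random.Generator = 0,
    meta: np.ndarray | None = None,
    n_traits: int = 8,
    tolerance_quantile: float = 0.2,
    kernel_exponent: float = 3.0,
    occupancy: float = 0.6,
    group_mask: Sequence[bool] | None = None,
    domain: str = "bacteria",
    sample_ids: Sequence[str] | None = None,
) -> CommunityTable:
    """Strong-selection communities with the phylogenetic turnover structure
    that makes selection detectable by nearest-taxon null models.

    Niches are multivariate Brownian trait vectors (``n_traits`` independent
    traits evolved on the tree); a single trait is a weak proxy for clade
    membership because distant clades revisit the same value, while the
    squared multivariate trait distance concentrates around the patristic
    distance.  The environment is placed at the optimum of the taxon whose
    trait neighbourhood is most phylogenetically compact, and the filter is
    a plateau kernel ``exp(-(d2/s)^kernel_exponent)`` with a hard tolerance
    limit (zero weight beyond the ``tolerance_quantile`` trait-distance
    radius): taxa outside the tolerated clade cannot occur at all, which is
    what keeps turnover inside the clade.  Within the tolerated pool each
    sample hosts a weighted random subset (fraction ``occupancy``) — a
    competitive lottery that supplies among-sample turnover of close
    relatives without collapsing evenness.

    With ``group_mask`` given, the two groups are filtered toward two
    disjoint clades (heterogeneous selection); otherwise all samples share
    one clade (homogeneous selection).
    """
    rng = _rng(seed)
    taxa = tree.tip_labels
    s_taxa = len(taxa)
    if meta is None:
        meta = simulate_metacommunity(s_taxa, sigma=1.0, seed=rng)
    meta = np.asarray(meta, dtype=float)
    from .io_core import patristic_distances

    dmat = patristic_distances(tree).loc[taxa, taxa].to_numpy()
    opts = np.column_stack(
        [brownian_optima(tree, seed=rng).loc[taxa].to_numpy()
         for _ in range(n_traits)])
    k = max(4, int(s_taxa * tolerance_quantile))

    def _anchor_scores() -> np.ndarray:
        scores = np.empty(s_taxa)
        for a in range(s_taxa):
            d2 = ((opts - opts[a]) ** 2).sum(axis=1)
            pool = np.argsort(d2)[:k]
            scores[a] = dmat[np.ix_(pool, pool)].mean()
        return scores

    scores = _anchor_scores()
    anchors = [int(np.argmin(scores))]
    if group_mask is not None:
        # second anchor: most compact neighbourhood disjoint from the first
        d2_first = ((opts - opts[anchors[0]]) ** 2).sum(axis=1)
        first_pool = set(np.argsort(d2_first)[:k].tolist())
        order = np.argsort(scores)
        for a in order:
            d2a = ((opts - opts[a]) ** 2).sum(axis=1)
            if not first_pool & set(np.argsort(d2a)[:k].tolist()):
                anchors.append(int(a))
                break
        else:
            anchors.append(int(order[1]))

    weights = []
    for a in anchors:
        d2 = ((opts - opts[a]) ** 2).sum(axis=1)
        scale = np.quantile(d2[d2 > 0], tolerance_quantile)
        w = meta * np.exp(-(d2 / scale) ** kernel_exponent)
        w[d2 > scale] = 0.0
        weights.append(w / w.sum())

    counts = np.zeros((n_samples, s_taxa), dtype=np.int64)
    group_mask = (np.zeros(n_samples, dtype=bool) if group_mask is None
                  else np.asarray(group_mask, dtype=bool))
    for i in range(n_samples):
        w = weights[1] if (len(weights) > 1 and group_mask[i]) else weights[0]
        pool = np.nonzero(w)[0]
        r = max(2, int(round(occupancy * pool.size)))
        keys = np.log(w[pool]) + rng.gumbel(size=pool.size)
        hosted = pool[np.argpartition(-keys, r - 1)[:r]]
        counts[i, hosted] = rng.multinomial(nt, np.full(r, 1.0 / r))
    if sample_ids is None:
        sample_ids = _sample_ids(n_samples)
    frame = pd.DataFrame(counts, index=list(sample_ids), columns=taxa)
    return CommunityTable(data=frame, domain=domain)


# ---------------------------------------------------------------------------
# chemistry

CHEMISTRY_BASELINES = {
    # µg/g dry sediment; freshwater pond sediment scale
    "TN": (1000.0, 50.0),
    "FA": (120.0, 10.0),
    "ammonia": (30.0, 4.0),
    "nitrate": (12.0, 2.0),
    "nitrite": (1.5, 0.3),
}

DEFAULT_CHEMISTRY_OFFSETS = {"FA": 40.0, "ammonia": 15.0}


def simulate_chemistry(
    groups: Mapping[str, str] | pd.Series,
    offsets: Mapping[str, float] | None = None,
    treatment_group: str = "BG",
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Sediment nitrogen chemistry with group offsets on the treatment group.

    Measured pools (TN, FA, ammonia, nitrate, nitrite) are drawn around
    realistic baselines; EN and ON are then filled by the derivation
    operations so EN = ammonia + nitrate + nitrite and ON = TN - EN - FA
    hold exactly.  With the default offsets (FA and ammonia elevated in the
    treatment group, TN unchanged) the treatment group shows higher FA, EN
    and ammonia and lower ON.
    """
    from .environment import derive_nitrogen

    groups = pd.Series(groups)
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {labels}")
    if offsets is None:
        offsets = DEFAULT_CHEMISTRY_OFFSETS
    rng = _rng(seed)
    frame = pd.DataFrame(index=groups.index)
    for var, (mean, sd) in CHEMISTRY_BASELINES.items():
        vals = rng.normal(mean, sd, size=len(groups))
        if var in offsets:
            vals = vals + np.where(groups == treatment_group, offsets[var], 0.0)
        frame[var] = np.maximum(vals, sd * 0.1)  # keep strictly positive
    frame = derive_nitrogen(frame)
    frame["group"] = groups
    return frame


# ---------------------------------------------------------------------------
# taxonomy + full fixture


def simulate_taxonomy(
    taxon_ids: Sequence[str], domain: str, seed: int | np.random.Generator = 0,
    unclassified_fraction: float = 0.05,
) -> TaxonomyMap:
    """Random phylum assignments from a per-domain pool of realistic names."""
    rng = _rng(seed)
    pool = _PHYLUM_POOLS[domain]
    weights = rng.dirichlet(np.full(len(pool), 2.0))
    lineages = {}
    for taxon in taxon_ids:
        if rng.random() < unclassified_fraction:
            continue
        lineages[taxon] = str(rng.choice(pool, p=weights))
    return TaxonomyMap.from_lineage_strings(lineages)


def simulate_dataset(config: SimulationConfig) -> dict:
    """Generate the full two-group, three-domain study fixture.

    Returns a dict with per-domain ``tables``, ``trees``, ``taxonomies``,
    plus ``metadata`` (group labels + chemistry).  Group-linked
    compositional shifts come from the regime: neutral regimes share a
    metacommunity across groups; selection regimes filter on a group-linked
    environment (difference ``env_effect`` between groups under
    heterogeneous selection).
    """
    ss = np.random.SeedSequence(config.seed)
    domain_seeds = {d: s for d, s in zip(sorted(config.richness),
                                         ss.spawn(len(config.richness)))}
    chem_seed, = ss.spawn(1)
    n = config.n_samples_per_group
    sample_ids = [f"BG_{i+1}" for i in range(n)] + [f"CG_{i+1}" for i in range(n)]
    groups = pd.Series(["BG"] * n + ["CG"] * n, index=sample_ids)

    tables, trees, taxonomies = {}, {}, {}
    for domain, dseed in domain_seeds.items():
        rng = np.random.default_rng(dseed)
        s_taxa = int(config.richness[domain])
        tree = simulate_tree(s_taxa, rng)
        meta = simulate_metacommunity(
            s_taxa, config.lognormal_mu, config.lognormal_sigma, rng)
        if config.regime in ("neutral", "dispersal_limited"):
            m = config.migration_m if config.regime == "neutral" else min(
                config.migration_m, 0.01)
            table = simulate_neutral_communities(
                meta, m, config.nt, 2 * n, rng, domain=domain,
                sample_ids=sample_ids, taxon_ids=tree.tip_labels)
        else:
            mask = (None if config.regime == "homogeneous_selection"
                    else (groups == "BG").to_numpy())
            table = simulate_selection_regime(
                tree, 2 * n, config.nt, rng, meta=meta, group_mask=mask,
                domain=domain, sample_ids=sample_ids)
        tables[domain] = table
        trees[domain] = tree
        taxonomies[domain] = simulate_taxonomy(tree.tip_labels, domain, rng)

    chemistry = simulate_chemistry(groups, seed=np.random.default_rng(chem_seed))
    metadata = SampleMetadata(frame=chemistry)
    return {"tables": tables, "trees": trees, "taxonomies": taxonomies,
            "metadata": metadata, "config": config}


def write_dataset(dataset: dict, outdir: str | Path) -> list[Path]:
    """Write a simulated dataset in the TSV/newick dialects io_core reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for domain, table in dataset["tables"].items():
        p = outdir / f"{domain}_counts.tsv"
        write_community_table(table, p)
        written.append(p)
        p = outdir / f"{domain}_taxonomy.tsv"
        write_taxonomy(dataset["taxonomies"][domain], p)
        written.append(p)
        p = outdir / f"{domain}_tree.nwk"
        write_newick(dataset["trees"][domain], p)
        written.append(p)
    p = outdir / "metadata.tsv"
    write_metadata(dataset["metadata"], p)
    written.append(p)
    return written
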