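"""Spearman-threshold co-occurrence networks across bacteria, fungi, and
protist tables, with intra-/inter-domain node and edge accounting.

Edges require |rho| > rho_threshold AND p < alpha, both strict, on
relative abundances computed within each domain.  Both correlation signs
form edges (magnitude thresholding); the sign is stored on the edge.  At
the study's per-group sample size (n = 6) the t approximation for the
Spearman p-value is crude, so an exact permutation p (full enumeration of
the n! orderings) is the default for n <= 8.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import permutations as iter_permutations

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata
from scipy.stats.distributions import t as t_dist

from .io_core import CommunityTable, TaxonomyMap, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class SpearmanResult:
    """Pairwise Spearman rho and p over the merged multi-domain taxon set.

    Node identifiers are ``domain:taxon_id`` so identically named ASVs from
    different domains never collide.
    """

    rho: pd.DataFrame
    p: pd.DataFrame
    domains: pd.Series          # node -> domain
    n_samples: int
    dropped_constant: list[str] = field(default_factory=list)


@dataclass
class NetworkAccounting:
    nodes_per_domain: dict[str, int]
    intra_edges: dict[str, int]
    inter_edges: dict[tuple[str, str], int]

    @property
    def total_edges(self) -> int:
        return sum(self.intra_edges.values()) + sum(self.inter_edges.values())


def spearman_matrix(
    tables: list[CommunityTable], exact_p: bool | None = None
) -> SpearmanResult:
    """Spearman correlations (average ranks, mid-rank ties) between all taxa
    of the merged domain tables, which must share the same sample set/order.

    p-values come from full enumeration of sample orderings when
    ``exact_p`` (default for n <= 8), else from the two-sided t
    approximation (requires n >= 4).  Taxa with constant abundance have
    undefined rho; they are excluded and logged.
    """
    if not tables:
        raise ValidationError("at least one community table required")
    sample_ids = tables[0].sample_ids
    for t in tables[1:]:
        if t.sample_ids != sample_ids:
            raise ValidationError(
                "all domain tables must share an identical sample set and order"
            )
    n = len(sample_ids)
    if exact_p is None:
        exact_p = n <= 8
    cols, domains, dropped = [], {}, []
    blocks = []
    for t in tables:
        rel = t.relative_abundance()
        for taxon in rel.columns:
            node = f"{t.domain}:{taxon}"
            if rel[taxon].nunique() <= 1:
                dropped.append(node)
                continue
            cols.append(node)
            domains[node] = t.domain
            blocks.append(rel[taxon].to_numpy(dtype=float))
    if dropped:
        logger.info("excluded %d constant taxa from correlation: %s",
                    len(dropped), dropped[:10])
    x = np.column_stack(blocks)
    ranks = rankdata(x, axis=0)
    z = ranks - ranks.mean(axis=0)
    norms = np.sqrt((z ** 2).sum(axis=0))
    zn = z / norms
    rho = np.clip(zn.T @ zn, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)

    if exact_p:
        perms = np.array(list(iter_permutations(range(n))))
        abs_obs = np.abs(rho)
        count = np.zeros_like(rho)
        for perm in perms:
            rho_perm = np.abs(zn.T @ zn[perm])
            count += rho_perm >= abs_obs - 1e-12
        p = count / len(perms)
    else:
        if n < 4:
            raise ValidationError("t-approximation p requires n >= 4 samples")
        r = np.clip(rho, -0.9999999999, 0.9999999999)
        tstat = r * np.sqrt((n - 2) / (1.0 - r ** 2))
        p = 2.0 * t_dist.sf(np.abs(tstat), df=n - 2)
    np.fill_diagonal(p, 0.0)
    rho_df = pd.DataFrame(rho, index=cols, columns=cols)
    p_df = pd.DataFrame(p, index=cols, columns=cols)
    return SpearmanResult(rho=rho_df, p=p_df, domains=pd.Series(domains),
                          n_samples=n, dropped_constant=dropped)


def build_network(
    result: SpearmanResult,
    rho_threshold: float = 0.8,
    alpha: float = 0.05,
    signed: bool = False,
    taxonomies: dict[str, TaxonomyMap] | None = None,
    group: str | None = None,
) -> nx.Graph:
    """Retain unordered taxon pairs with |rho| > rho_threshold (strict) and
    p < alpha (strict); nodes are only taxa incident to a retained edge.

    ``signed=True`` restricts edges to positive correlations only.  An
    empty network is a valid result.
    """
    if not (0 < rho_threshold < 1) or not (0 < alpha < 1):
        raise ValidationError("thresholds must be in (0, 1)")
    g = nx.Graph(rho_threshold=rho_threshold, alpha=alpha, group=group)
    nodes = list(result.rho.index)
    rho = result.rho.to_numpy()
    p = result.p.to_numpy()
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            r = rho[i, j]
            magnitude = r if signed else abs(r)
            if magnitude > rho_threshold and p[i, j] < alpha:
                g.add_edge(nodes[i], nodes[j], rho=float(r),
                           p=float(p[i, j]), sign=1 if r > 0 else -1)
    for node in g.nodes:
        domain = result.domains[node]
        g.nodes[node]["domain"] = domain
        if taxonomies and domain in taxonomies:
            taxon = node.split(":", 1)[1]
            g.nodes[node]["phylum"] = taxonomies[domain].get(taxon, "phylum")
    return g


def account_network(net: nx.Graph, domains=("bacteria", "fungi", "protist")
                    ) -> NetworkAccounting:
    """Intra-domain and inter-domain edge counts plus per-domain node counts
    (a node counts only if incident to >= 1 retained edge)."""
    nodes_per_domain = {d: 0 for d in domains}
    intra = {d: 0 for d in domains}
    inter = {}
    for a, b in ((x, y) for i, x in enumerate(domains) for y in domains[i + 1:]):
        inter[(a, b)] = 0
    for node, data in net.nodes(data=True):
        nodes_per_domain[data["domain"]] += 1
    for u, v in net.edges:
        du, dv = net.nodes[u]["domain"], net.nodes[v]["domain"]
        if du == dv:
            intra[du] += 1
        else:
            key = tuple(sorted((du, dv), key=list(domains).index))
            inter[key] += 1
    return NetworkAccounting(nodes_per_domain=nodes_per_domain,
                             intra_edges=intra, inter_edges=inter)


def edge_table(net: nx.Graph) -> pd.DataFrame:
    rows = [
        (u, v, net.nodes[u]["domain"], net.nodes[v]["domain"],
         d["rho"], d["p"], d["sign"])
        for u, v, d in net.edges(data=True)
    ]
    return pd.DataFrame(
        rows, columns=["source", "target", "source_domain", "target_domain",
                       "rho", "p_value", "sign"])
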