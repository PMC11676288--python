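"""Alpha diversity, Bray–Curtis beta diversity, PCoA, PERMANOVA, and
two-group rank-sum comparisons at a taxonomic rank.

Conventions: Shannon entropy in nats (so Pielou's J = H / ln S holds),
Simpson as the Gini–Simpson index 1 - sum(p^2), Chao1 in its bias-corrected
form S + F1(F1-1)/(2(F2+1)) which is well defined when doubletons are
absent.  Diversity is computed on raw counts; no rarefaction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import mannwhitneyu

from .io_core import CommunityTable, SampleMetadata, TaxonomyMap, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class PairwiseMatrix:
    """Symmetric sample x sample matrix of a dissimilarity or statistic."""

    values: pd.DataFrame
    metric: str = "braycurtis"

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        if v.shape[0] != v.shape[1]:
            raise ValidationError("pairwise matrix must be square")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValidationError("pairwise matrix must be symmetric")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    def condensed(self) -> np.ndarray:
        return squareform(self.values.to_numpy(dtype=float), checks=False)


@dataclass
class PcoaResult:
    coordinates: pd.DataFrame        # samples x retained positive axes
    eigenvalues: np.ndarray          # positive eigenvalues, descending
    proportion_explained: np.ndarray # against the sum of positive eigenvalues


@dataclass
class PermanovaResult:
    f_statistic: float
    p_value: float
    n_permutations: int


def alpha_diversity(table: CommunityTable) -> pd.DataFrame:
    """Per-sample Shannon (nats), Gini–Simpson, bias-corrected Chao1,
    Pielou's J, and observed richness.

    Pielou's J is undefined for single-taxon samples; those rows carry NaN
    with ``pielou_defined`` False rather than a spurious 0/0.
    """
    counts = table.counts().astype(float)
    rows = []
    for i, sample in enumerate(table.sample_ids):
        x = counts[i]
        x = x[x > 0]
        p = x / x.sum()
        shannon = float(-(p * np.log(p)).sum())
        simpson = float(1.0 - (p ** 2).sum())
        s_obs = x.size
        f1 = int((x == 1).sum())
        f2 = int((x == 2).sum())
        chao1 = s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
        pielou = shannon / np.log(s_obs) if s_obs > 1 else np.nan
        rows.append((sample, shannon, simpson, chao1, pielou, s_obs, s_obs > 1))
    out = pd.DataFrame(
        rows,
        columns=["sample_id", "shannon", "simpson", "chao1", "pielou",
                 "richness", "pielou_defined"],
    ).set_index("sample_id")
    return out


def bray_curtis(table: CommunityTable, weighted: bool = True) -> PairwiseMatrix:
    """Bray–Curtis dissimilarity on counts (weighted) or presence/absence."""
    if table.n_samples < 2:
        raise ValidationError("bray_curtis needs >= 2 samples")
    x = table.counts().astype(float)
    if not weighted:
        x = (x > 0).astype(float)
    d = squareform(pdist(x, metric="braycurtis"))
    frame = pd.DataFrame(d, index=table.sample_ids, columns=table.sample_ids)
    return PairwiseMatrix(values=frame, metric="braycurtis")


def pcoa(dist: PairwiseMatrix, n_axes: int | None = None) -> PcoaResult:
    """Principal coordinates analysis by Gower double-centering.

    Negative eigenvalues (non-Euclidean input) are dropped from the
    coordinates and excluded from the proportion-explained denominator.
    Axis signs follow a fixed convention: the first nonzero loading of each
    axis is made positive, so results are reproducible across BLAS builds.
    """
    d = dist.values.to_numpy(dtype=float)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(abs(eigval).max(), 1.0) * 1e-10
    pos = eigval > tol
    if not pos.any():
        raise ValidationError("no positive eigenvalues; cannot embed distances")
    eigval_pos = eigval[pos]
    coords = eigvec[:, pos] * np.sqrt(eigval_pos)
    for k in range(coords.shape[1]):
        nonzero = np.nonzero(np.abs(coords[:, k]) > tol)[0]
        if nonzero.size and coords[nonzero[0], k] < 0:
            coords[:, k] *= -1
    if n_axes is not None:
        coords = coords[:, :n_axes]
        prop = eigval_pos[:n_axes] / eigval_pos.sum()
        eigval_out = eigval_pos[:n_axes]
    else:
        prop = eigval_pos / eigval_pos.sum()
        eigval_out = eigval_pos
    frame = pd.DataFrame(
        coords, index=dist.sample_ids,
        columns=[f"PCo{k + 1}" for k in range(coords.shape[1])],
    )
    return PcoaResult(coordinates=frame, eigenvalues=eigval_out,
                      proportion_explained=prop)


def _permanova_f(d2: np.ndarray, codes: np.ndarray, sizes: np.ndarray) -> float:
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g, size in enumerate(sizes):
        mask = codes == g
        ss_within += d2[np.ix_(mask, mask)].sum() / (2.0 * size)
    a = sizes.size
    ss_among = ss_total - ss_within
    return (ss_among / (a - 1)) / (ss_within / (n - a))


def permanova(
    dist: PairwiseMatrix,
    groups,
    n_permutations: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """One-way PERMANOVA with seeded label permutations.

    p follows the add-one rule p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).
    """
    groups = pd.Series(groups)
    if not groups.index.equals(dist.values.index):
        groups = groups.reindex(dist.sample_ids)
    codes, uniques = pd.factorize(groups.to_numpy())
    sizes = np.bincount(codes)
    if uniques.size < 2:
        raise ValidationError("permanova needs >= 2 groups")
    if (sizes < 2).any():
        raise ValidationError("every group needs >= 2 samples")
    d2 = dist.values.to_numpy(dtype=float) ** 2
    f_obs = _permanova_f(d2, codes, sizes)
    rng = np.random.default_rng(seed)
    n = codes.size
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        if _permanova_f(d2, codes[perm], sizes) >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return PermanovaResult(f_statistic=float(f_obs), p_value=float(p),
                           n_permutations=n_permutations)


def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney U): exact for small
    tie-free samples, normal approximation with tie correction otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    res = mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def group_compare_rank(
    table: CommunityTable,
    taxonomy: TaxonomyMap,
    metadata: SampleMetadata,
    rank: str = "phylum",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-lineage two-group rank-sum test on relative abundances at a rank.

    No multiple-testing correction is applied; lineages are flagged at the
    raw ``alpha`` threshold.
    """
    from .io_core import aggregate_to_rank

    g1, g2 = metadata.require_two_groups()
    metadata.check_covers(table)
    agg = aggregate_to_rank(table, taxonomy, rank)
    rel = agg.relative_abundance()
    labels = metadata.groups.reindex(rel.index)
    rows = []
    for lineage in rel.columns:
        vals = rel[lineage]
        if (agg.data[lineage] == 0).all():
            logger.info("lineage %s absent from all samples; skipped", lineage)
            continue
        stat, p = rank_sum_test(vals[labels == g1], vals[labels == g2])
        rows.append((lineage, vals[labels == g1].mean(),
                     vals[labels == g2].mean(), stat, p, p < alpha))
    return pd.DataFrame(
        rows, columns=["lineage", f"mean_{g1}", f"mean_{g2}", "statistic",
                       "p_value", "significant"],
    ).set_index("lineage")
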