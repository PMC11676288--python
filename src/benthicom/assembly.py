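"""Null-model partitioning of community assembly processes.

The framework combines two null-model statistics per sample pair:

* βNTI — the z-score of the observed abundance-weighted β-mean nearest
  taxon distance (βMNTD) against a taxa-shuffle null in which taxon labels
  are permuted across the tips of the phylogeny (richness and abundances
  preserved).  |βNTI| > 2 indicates selection: βNTI < -2 homogeneous
  selection (less phylogenetic turnover than expected), βNTI > +2
  heterogeneous selection.
* RC_bray — Bray–Curtis Raup–Crick: the observed Bray–Curtis dissimilarity
  ranked within a null ensemble that preserves each sample's richness and
  total abundance, drawing species identities weighted by occupancy
  frequency and allocating individuals weighted by metacommunity relative
  abundance, rescaled to [-1, 1].  For pairs without significant
  phylogenetic signal, RC > +0.95 indicates dispersal limitation,
  RC < -0.95 homogenizing dispersal, and the remainder drift.

Thresholds (+-2, +-0.95) follow the standard convention of this framework
and are exposed as parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diversity import PairwiseMatrix
from .io_core import CommunityTable, PhyloTree, ValidationError, patristic_distances

logger = logging.getLogger(__name__)

PROCESS_LABELS = (
    "heterogeneous selection",
    "homogeneous selection",
    "dispersal limitation",
    "homogenizing dispersal",
    "drift",
)
DETERMINISTIC = {"heterogeneous selection", "homogeneous selection"}


@dataclass
class BetaNtiResult:
    bmntd_observed: PairwiseMatrix
    bnti: PairwiseMatrix
    null_mean: PairwiseMatrix
    null_sd: PairwiseMatrix
    n_null: int
    degenerate: pd.DataFrame = field(default=None)  # boolean mask (null SD == 0)


@dataclass
class RaupCrickResult:
    rc: PairwiseMatrix
    n_null: int


@dataclass
class AssemblyClassification:
    pair_labels: pd.DataFrame    # one row per unordered sample pair
    fractions: dict[str, float]
    group_fractions: dict[str, dict[str, float]]
    deterministic_fraction: float
    stochastic_fraction: float


# ---------------------------------------------------------------------------
# βMNTD / βNTI


def beta_mntd_matrix(counts: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """Abundance-weighted βMNTD for every sample pair.

    For samples A, B: 0.5 * [ sum_{i in A} f_i^A min_{j in B} d(i, j)
    + sum_{j in B} f_j^B min_{i in A} d(j, i) ] with f the within-sample
    relative abundances; a taxon shared by both samples contributes 0
    because the minimum includes its own zero self-distance.
    """
    counts = np.asarray(counts, dtype=float)
    n, s = counts.shape
    if np.any(counts.sum(axis=1) == 0):
        raise ValidationError("empty sample in βMNTD input")
    present = counts > 0
    minmat = np.empty((s, n))
    for k in range(n):
        minmat[:, k] = dist[:, present[k]].min(axis=1)
    f = counts / counts.sum(axis=1, keepdims=True)
    g = f @ minmat          # g[a, b] = mean distance from A's taxa to B
    return 0.5 * (g + g.T)


def beta_mntd(
    x: np.ndarray, y: np.ndarray, dist: np.ndarray
) -> float:
    """βMNTD between two abundance vectors over a shared taxon set."""
    return float(beta_mntd_matrix(np.vstack([x, y]), dist)[0, 1])


def beta_nti(
    table: CommunityTable,
    tree: PhyloTree,
    n_null: int = 999,
    seed: int = 0,
    dist: pd.DataFrame | None = None,
) -> BetaNtiResult:
    """βNTI per sample pair against the taxa-shuffle null.

    The null permutes which taxon occupies which tip of the phylogeny
    (equivalently, permutes rows/columns of the tip distance matrix),
    leaving richness and abundances intact.  Pairs whose null SD is zero
    (e.g. identical communities) are flagged degenerate and carry NaN.
    """
    if n_null < 99:
        raise ValidationError("n_null must be >= 99")
    missing = sorted(set(table.taxon_ids) - set(tree.tip_labels))
    if missing:
        raise ValidationError(f"table taxa missing from tree: {missing[:10]}")
    if dist is None:
        dist = patristic_distances(tree, table.taxon_ids)
    d = dist.loc[table.taxon_ids, table.taxon_ids].to_numpy(dtype=float)
    counts = table.counts()
    obs = beta_mntd_matrix(counts, d)
    rng = np.random.default_rng(seed)
    s = counts.shape[1]
    acc = np.zeros_like(obs)
    acc2 = np.zeros_like(obs)
    for _ in range(n_null):
        perm = rng.permutation(s)
        null = beta_mntd_matrix(counts[:, perm], d)
        acc += null
        acc2 += null ** 2
    mean = acc / n_null
    var = np.maximum(acc2 / n_null - mean ** 2, 0.0)
    sd = np.sqrt(var)
    degenerate = sd <= 1e-12
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (obs - mean) / sd
    z[degenerate] = np.nan
    np.fill_diagonal(z, 0.0)
    np.fill_diagonal(degenerate, False)
    ids = table.sample_ids
    if degenerate.any():
        logger.info("%d degenerate pairs (null SD = 0) excluded from βNTI",
                    int(degenerate[np.triu_indices_from(degenerate, 1)].sum()))

    def _pm(a, metric):
        return PairwiseMatrix(pd.DataFrame(a, index=ids, columns=ids), metric)

    return BetaNtiResult(
        bmntd_observed=_pm(obs, "bMNTD"),
        bnti=_pm(z, "bNTI"),
        null_mean=_pm(mean, "bMNTD_null_mean"),
        null_sd=_pm(sd, "bMNTD_null_sd"),
        n_null=n_null,
        degenerate=pd.DataFrame(degenerate, index=ids, columns=ids),
    )


# ---------------------------------------------------------------------------
# Raup–Crick (Bray–Curtis)


def _weighted_sample_without_replacement(
    weights: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Efraimidis–Spirakis via Gumbel keys; zero-weight items never chosen."""
    with np.errstate(divide="ignore"):
        keys = np.log(weights) + rng.gumbel(size=weights.size)
    return np.argpartition(-keys, k - 1)[:k]


def _null_community(
    richness: int, total: int, occ_freq: np.ndarray, meta: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    chosen = _weighted_sample_without_replacement(occ_freq, richness, rng)
    out = np.zeros(occ_freq.size)
    out[chosen] = 1.0
    if total > richness:
        w = meta[chosen]
        extra = rng.multinomial(total - richness, w / w.sum())
        out[chosen] += extra
    return out


def _bray(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.abs(x - y).sum() / (x + y).sum())


def raup_crick_bray(
    table: CommunityTable, n_null: int = 999, seed: int = 0,
    context: CommunityTable | None = None,
) -> RaupCrickResult:
    """Bray–Curtis Raup–Crick per sample pair, rescaled to [-1, 1].

    Null communities preserve each sample's observed richness and total
    abundance: species identities are drawn (without replacement) weighted
    by occupancy frequency across samples, then the remaining individuals
    are allocated multinomially weighted by metacommunity relative
    abundance.  RC = 2 * ((#null < obs) + 0.5 * (#null == obs)) / n_null - 1.

    ``context`` optionally supplies the regional pool (occupancy
    frequencies and metacommunity abundances) from a larger reference
    table sharing the same taxon set.
    """
    if n_null < 99:
        raise ValidationError("n_null must be >= 99")
    counts = table.counts().astype(float)
    n = counts.shape[0]
    pool = counts if context is None else context.counts().astype(float)
    if pool.shape[1] != counts.shape[1]:
        raise ValidationError("context must share the table's taxon set")
    occ_freq = (pool > 0).mean(axis=0)
    meta = pool.sum(axis=0) / pool.sum()
    richness = (counts > 0).sum(axis=1)
    totals = counts.sum(axis=1).astype(int)
    rng = np.random.default_rng(seed)
    rc = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            obs = _bray(counts[i], counts[j])
            less = equal = 0
            for _ in range(n_null):
                a = _null_community(richness[i], totals[i], occ_freq, meta, rng)
                b = _null_community(richness[j], totals[j], occ_freq, meta, rng)
                nb = _bray(a, b)
                if nb < obs - 1e-12:
                    less += 1
                elif abs(nb - obs) <= 1e-12:
                    equal += 1
            frac = (less + 0.5 * equal) / n_null
            rc[i, j] = rc[j, i] = 2.0 * (frac - 0.5)
    ids = table.sample_ids
    return RaupCrickResult(
        rc=PairwiseMatrix(pd.DataFrame(rc, index=ids, columns=ids), "RC_bray"),
        n_null=n_null,
    )


# ---------------------------------------------------------------------------
# classification


def classify_processes(
    bnti: BetaNtiResult,
    rc: RaupCrickResult,
    groups: pd.Series | None = None,
    bnti_threshold: float = 2.0,
    rc_threshold: float = 0.95,
) -> AssemblyClassification:
    """Five-way ecological-process call per sample pair.

    βNTI > +t: heterogeneous selection; βNTI < -t: homogeneous selection;
    otherwise RC > +r: dispersal limitation; RC < -r: homogenizing
    dispersal; else drift.  Degenerate βNTI pairs are excluded from all
    denominators.  Per-group fractions use only pairs whose two samples
    share a group label.
    """
    ids = bnti.bnti.sample_ids
    if rc.rc.sample_ids != ids:
        raise ValidationError("βNTI and RC must cover the same sample set")
    z = bnti.bnti.values.to_numpy()
    r = rc.rc.values.to_numpy()
    degenerate = bnti.degenerate.to_numpy()
    rows = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if degenerate[i, j]:
                label = None
            elif z[i, j] > bnti_threshold:
                label = "heterogeneous selection"
            elif z[i, j] < -bnti_threshold:
                label = "homogeneous selection"
            elif r[i, j] > rc_threshold:
                label = "dispersal limitation"
            elif r[i, j] < -rc_threshold:
                label = "homogenizing dispersal"
            else:
                label = "drift"
            rows.append((ids[i], ids[j], z[i, j], r[i, j], label))
    frame = pd.DataFrame(
        rows, columns=["sample_a", "sample_b", "bnti", "rc", "process"])

    def _fractions(sub: pd.DataFrame) -> dict[str, float]:
        valid = sub.dropna(subset=["process"])
        if len(valid) == 0:
            return {lab: np.nan for lab in PROCESS_LABELS}
        counts = valid["process"].value_counts(normalize=True)
        return {lab: float(counts.get(lab, 0.0)) for lab in PROCESS_LABELS}

    fractions = _fractions(frame)
    group_fractions = {}
    if groups is not None:
        groups = pd.Series(groups)
        for g in sorted(groups.unique()):
            members = set(groups.index[groups == g])
            sub = frame[frame["sample_a"].isin(members)
                        & frame["sample_b"].isin(members)]
            group_fractions[g] = _fractions(sub)
    det = sum(fractions[lab] for lab in PROCESS_LABELS if lab in DETERMINISTIC)
    return AssemblyClassification(
        pair_labels=frame,
        fractions=fractions,
        group_fractions=group_fractions,
        deterministic_fraction=float(det),
        stochastic_fraction=float(1.0 - det) if not np.isnan(det) else np.nan,
    )
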