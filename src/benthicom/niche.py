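"""Levins niche breadth, generalist/specialist classification against a
permutation null, and Sloan neutral-model dispersal estimation.

Levins' index for taxon j is B_j = 1 / sum_i P_ij^2 where P_ij is the
proportion of taxon j's reads found in sample i; B ranges from 1 (all
reads in one sample) to N (spread evenly over N samples).  The
community-level habitat niche breadth of a sample is the
abundance-weighted mean of its members' B_j.

Generalists/specialists are called against a null distribution of B from
randomized tables in which each sample's counts are redrawn multinomially
from the pooled metacommunity relative abundances with per-sample totals
preserved — a totals-preserving resampling null, simpler and seedable
compared with fixed-fixed swap algorithms.

Dispersal ability is quantified as the migration parameter m of Sloan's
neutral community model, fitted by least squares of observed occupancy
against the beta-distribution prediction 1 - BetaCDF(d | N m p, N m (1-p))
with detection limit d = 1/N.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import beta as beta_dist
from scipy.stats import binom

from .io_core import CommunityTable, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class NicheBreadthResult:
    b_taxon: pd.Series       # Levins B per taxon, in [1, n_samples]
    b_community: pd.Series   # abundance-weighted mean B per sample


@dataclass
class ClassificationResult:
    table: pd.DataFrame      # per taxon: b_obs, null lower/upper, class
    fractions: dict[str, float]
    n_null: int
    ci: float


@dataclass
class NeutralFitResult:
    m: float
    nt: int
    r_squared: float
    table: pd.DataFrame      # per taxon: p, occupancy, predicted, lower, upper
    boundary_warning: bool = False


def levins_breadth(table: CommunityTable) -> NicheBreadthResult:
    """Levins B per taxon and abundance-weighted community breadth per sample."""
    if table.n_samples < 2:
        raise ValidationError("levins_breadth needs >= 2 samples")
    counts = table.counts().astype(float)
    totals = counts.sum(axis=0)
    present = totals > 0
    if not present.all():
        logger.info("excluded %d zero-total taxa from niche breadth",
                    int((~present).sum()))
    p = counts[:, present] / totals[present]
    b = 1.0 / (p ** 2).sum(axis=0)
    b_taxon = pd.Series(b, index=np.array(table.taxon_ids)[present])
    rel = counts[:, present] / counts[:, present].sum(axis=1, keepdims=True)
    b_com = pd.Series(rel @ b, index=table.sample_ids)
    return NicheBreadthResult(b_taxon=b_taxon, b_community=b_com)


def _null_breadths(counts: np.ndarray, rng: np.random.Generator,
                   n_null: int) -> np.ndarray:
    """Null Levins B: (n_null, n_taxa) with NaN where a taxon drew 0 reads."""
    totals = counts.sum(axis=1)
    meta = counts.sum(axis=0) / counts.sum()
    n_samples, n_taxa = counts.shape
    null_counts = np.empty((n_null, n_samples, n_taxa), dtype=np.int64)
    for i in range(n_samples):
        null_counts[:, i, :] = rng.multinomial(totals[i], meta, size=n_null)
    col_tot = null_counts.sum(axis=1).astype(float)  # (n_null, n_taxa)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = null_counts / col_tot[:, None, :]
        b = 1.0 / (p ** 2).sum(axis=1)
    b[col_tot == 0] = np.nan
    return b


def classify_generalists(
    table: CommunityTable,
    n_null: int = 1000,
    ci: float = 0.95,
    seed: int = 0,
) -> ClassificationResult:
    """Classify taxa as generalist / specialist / neither by comparing
    observed Levins B with the central ``ci`` band of the resampling null."""
    if n_null < 100:
        raise ValidationError("n_null must be >= 100")
    obs = levins_breadth(table).b_taxon
    counts = table.data[obs.index].to_numpy()
    rng = np.random.default_rng(seed)
    null_b = _null_breadths(counts, rng, n_null)
    lo_q, hi_q = (1 - ci) / 2, 1 - (1 - ci) / 2
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        lower = np.nanquantile(null_b, lo_q, axis=0)
        upper = np.nanquantile(null_b, hi_q, axis=0)
    cls = np.where(obs.to_numpy() > upper, "generalist",
                   np.where(obs.to_numpy() < lower, "specialist", "neither"))
    cls[np.isnan(lower)] = "neither"
    frame = pd.DataFrame({
        "b_obs": obs, "null_lower": lower, "null_upper": upper,
        "classification": cls,
    })
    fracs = frame["classification"].value_counts(normalize=True).to_dict()
    fractions = {k: float(fracs.get(k, 0.0))
                 for k in ("generalist", "specialist", "neither")}
    return ClassificationResult(table=frame, fractions=fractions,
                                n_null=n_null, ci=ci)


def sloan_occupancy(p: np.ndarray, m: float, nt: float) -> np.ndarray:
    """Predicted occupancy under the neutral model with detection limit 1/nt."""
    d = 1.0 / nt
    return 1.0 - beta_dist.cdf(d, nt * m * p, nt * m * (1.0 - p))


def fit_neutral_model(table: CommunityTable, ci: float = 0.95) -> NeutralFitResult:
    """Fit Sloan's neutral community model by bounded least squares on the
    occupancy scale.

    N is the median per-sample total; p_j the mean relative abundance of
    taxon j; occupancy the fraction of samples where the taxon is detected.
    R^2 is computed against the mean observed occupancy and can be
    negative when the model fits worse than a constant.
    """
    if table.n_samples < 5:
        raise ValidationError("fit_neutral_model needs >= 5 samples")
    counts = table.counts().astype(float)
    nt = int(np.median(counts.sum(axis=1)))
    rel = counts / counts.sum(axis=1, keepdims=True)
    p = rel.mean(axis=0)
    keep = p > 0
    p = p[keep]
    occ = (counts[:, keep] > 0).mean(axis=0)

    def sse(m: float) -> float:
        pred = sloan_occupancy(p, m, nt)
        return float(((occ - pred) ** 2).sum())

    res = minimize_scalar(sse, bounds=(1e-6, 1.0), method="bounded",
                          options={"xatol": 1e-8})
    m_hat = float(res.x)
    boundary = False
    if np.all(occ == 1.0):
        boundary = True
        warnings.warn("all taxa occur in all samples; m is at the upper "
                      "bound and not identified", stacklevel=2)
    pred = sloan_occupancy(p, m_hat, nt)
    sst = float(((occ - occ.mean()) ** 2).sum())
    r2 = 1.0 - sse(m_hat) / sst if sst > 0 else np.nan
    n_samp = table.n_samples
    lo, hi = binom.interval(ci, n_samp, np.clip(pred, 0, 1))
    frame = pd.DataFrame({
        "mean_relative_abundance": p,
        "occupancy": occ,
        "predicted_occupancy": pred,
        "pred_lower": np.asarray(lo) / n_samp,
        "pred_upper": np.asarray(hi) / n_samp,
    }, index=np.array(table.taxon_ids)[keep])
    return NeutralFitResult(m=m_hat, nt=nt, r_squared=float(r2),
                            table=frame, boundary_warning=boundary)
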