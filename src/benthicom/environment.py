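"""Sediment nitrogen derivations, chemistry group comparison, db-RDA, and
boosted-tree relative influence.

Derived nitrogen pools: exchangeable nitrogen EN = ammonia + nitrate +
nitrite; organic nitrogen ON = TN - EN - FA.  Both identities hold to
machine precision; a negative derived ON is flagged as a measurement
inconsistency, never silently clipped.

db-RDA: principal coordinates of the community dissimilarity matrix (all
positive axes) regressed on z-scored environmental variables.  The
constrained space is the column space of the least-squares fitted values;
its eigendecomposition yields the constrained axes, and overall
significance comes from permuting sample rows of the environment table
(seeded, add-one rule).

ABT: stochastic gradient-boosted regression trees (squared-error loss)
whose per-variable relative influence is the normalized sum of
split-improvement across all trees; the default community response is the
sample score on PCoA axis 1 of the Bray–Curtis matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor

from .diversity import PairwiseMatrix, PcoaResult, pcoa, rank_sum_test
from .io_core import ValidationError

logger = logging.getLogger(__name__)

MEASURED_FIELDS = ("TN", "FA", "ammonia", "nitrate", "nitrite")
CHEMISTRY_FIELDS = MEASURED_FIELDS + ("EN", "ON")

ABT_DEFAULTS = dict(n_trees=500, interaction_depth=3, learning_rate=0.01,
                    bag_fraction=0.5)


@dataclass
class DbRdaResult:
    constrained_eigenvalues: np.ndarray
    constrained_proportion: float        # of total positive-axis inertia
    sample_scores: pd.DataFrame          # samples x constrained axes
    biplot_scores: pd.DataFrame          # variables x constrained axes
    p_value: float
    f_statistic: float
    n_permutations: int
    total_inertia: float = 0.0


@dataclass
class AbtResult:
    influence: pd.Series                 # percent per predictor, sums to 100
    settings: dict = field(default_factory=dict)


def derive_nitrogen(measured: pd.DataFrame) -> pd.DataFrame:
    """Fill EN and ON from the measured pools.

    Raises when a measured field is missing; adds a boolean
    ``on_negative`` flag where the derived ON is below zero.
    """
    missing = [f for f in MEASURED_FIELDS if f not in measured.columns]
    if missing:
        raise ValidationError(f"missing measured chemistry fields: {missing}")
    out = measured.copy()
    out["EN"] = out["ammonia"] + out["nitrate"] + out["nitrite"]
    out["ON"] = out["TN"] - out["EN"] - out["FA"]
    out["on_negative"] = out["ON"] < 0
    if out["on_negative"].any():
        bad = list(out.index[out["on_negative"]])
        logger.warning("derived ON negative for samples %s (measurement "
                       "inconsistency)", bad)
    return out


def compare_chemistry(
    env: pd.DataFrame, group_col: str = "group",
    variables: tuple[str, ...] = CHEMISTRY_FIELDS,
) -> pd.DataFrame:
    """Two-group rank-sum test per chemistry variable."""
    labels = sorted(env[group_col].unique())
    if len(labels) != 2:
        raise ValidationError(f"exactly two groups required, got {labels}")
    g1, g2 = labels
    rows = []
    for var in variables:
        x = env.loc[env[group_col] == g1, var]
        y = env.loc[env[group_col] == g2, var]
        stat, p = rank_sum_test(x, y)
        rows.append((var, x.mean(), y.mean(), stat, p))
    return pd.DataFrame(
        rows, columns=["variable", f"mean_{g1}", f"mean_{g2}", "statistic",
                       "p_value"],
    ).set_index("variable")


def db_rda(
    dist: PairwiseMatrix,
    env: pd.DataFrame,
    variables: list[str],
    n_permutations: int = 999,
    seed: int = 0,
) -> DbRdaResult:
    """Distance-based redundancy analysis with a row-permutation test."""
    if len(variables) < 2:
        raise ValidationError("db_rda needs >= 2 environmental variables")
    ids = dist.sample_ids
    x = env.loc[ids, variables].to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValidationError("constant environmental variable")
    x = (x - x.mean(axis=0)) / sd
    if np.linalg.cond(x) > 1e8:
        warnings.warn("collinear environmental variables; using pseudo-inverse",
                      stacklevel=2)
    ord_res: PcoaResult = pcoa(dist)
    y = ord_res.coordinates.to_numpy()
    y = y - y.mean(axis=0)
    n, q = x.shape

    def _fit_stats(xmat: np.ndarray):
        beta, *_ = np.linalg.lstsq(xmat, y, rcond=None)
        fitted = xmat @ beta
        constrained = float((fitted ** 2).sum())
        return fitted, constrained

    fitted, constrained = _fit_stats(x)
    total = float((y ** 2).sum())
    resid = total - constrained
    dof_resid = n - 1 - q
    f_obs = (constrained / q) / (resid / dof_resid) if dof_resid > 0 else np.inf

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        _, c_perm = _fit_stats(x[rng.permutation(n)])
        r_perm = total - c_perm
        f_perm = (c_perm / q) / (r_perm / dof_resid) if dof_resid > 0 else np.inf
        if f_perm >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_permutations)

    u, s, vt = np.linalg.svd(fitted, full_matrices=False)
    eig = s ** 2
    keep = eig > max(eig.max(), 1.0) * 1e-12 if eig.size else np.array([], bool)
    eig = eig[keep]
    scores = u[:, keep] * s[keep]
    for k in range(scores.shape[1]):
        nz = np.nonzero(np.abs(scores[:, k]) > 1e-12)[0]
        if nz.size and scores[nz[0], k] < 0:
            scores[:, k] *= -1
    axes = [f"dbRDA{k + 1}" for k in range(scores.shape[1])]
    sample_scores = pd.DataFrame(scores, index=ids, columns=axes)
    biplot = pd.DataFrame(
        np.corrcoef(np.column_stack([x, scores]), rowvar=False)[:q, q:],
        index=variables, columns=axes,
    )
    return DbRdaResult(
        constrained_eigenvalues=eig,
        constrained_proportion=constrained / total,
        sample_scores=sample_scores,
        biplot_scores=biplot,
        p_value=float(p),
        f_statistic=float(f_obs),
        n_permutations=n_permutations,
        total_inertia=total,
    )


def community_response(dist: PairwiseMatrix, axis: int = 1) -> pd.Series:
    """Default ABT response: sample scores on a PCoA axis of the
    community dissimilarity matrix."""
    res = pcoa(dist)
    return res.coordinates.iloc[:, axis - 1]


def abt_influence(
    response: pd.Series,
    env: pd.DataFrame,
    variables: list[str],
    seed: int = 0,
    n_trees: int = ABT_DEFAULTS["n_trees"],
    interaction_depth: int = ABT_DEFAULTS["interaction_depth"],
    learning_rate: float = ABT_DEFAULTS["learning_rate"],
    bag_fraction: float = ABT_DEFAULTS["bag_fraction"],
) -> AbtResult:
    """Relative influence (%) of environmental predictors from stochastic
    gradient-boosted regression trees with squared-error loss."""
    response = pd.Series(response)
    x = env.loc[response.index, variables].to_numpy(dtype=float)
    if len(response) < 8:
        warnings.warn("fewer than 8 samples: boosted-tree influences are "
                      "descriptive only", stacklevel=2)
    model = GradientBoostingRegressor(
        loss="squared_error",
        n_estimators=n_trees,
        max_depth=interaction_depth,
        learning_rate=learning_rate,
        subsample=bag_fraction,
        random_state=seed,
    )
    model.fit(x, response.to_numpy(dtype=float))
    imp = model.feature_importances_
    total = imp.sum()
    influence = (imp / total * 100.0) if total > 0 else np.full(len(variables),
                                                               100.0 / len(variables))
    settings = dict(n_trees=n_trees, interaction_depth=interaction_depth,
                    learning_rate=learning_rate, bag_fraction=bag_fraction,
                    seed=seed)
    return AbtResult(influence=pd.Series(influence, index=variables),
                     settings=settings)
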