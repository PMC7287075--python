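"""Population-level analyses: temporal-profile clustering, preferred-condition
sorting, and optimal-linear-estimator (OLE) decoding with bootstrap CIs.

Units are grouped by agglomerative hierarchical clustering of their z-scored
temporal response profiles under correlation distance (1 − Pearson r),
average linkage, cut at r = 0.7; leaves are optimally ordered to minimise
adjacent dissimilarity.  The OLE is the least-squares linear readout of a
scalar trial variable (joint rank or symbolic distance) from the population
vector of z-scored rates; uncertainty comes from bootstrap resampling of
trials (resample, refit, predict).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "ClusterConfig",
    "ClusterResult",
    "OleModel",
    "cluster_profiles",
    "linkage_to_newick",
    "preferred_condition_sort",
    "ole_fit",
    "ole_decode_with_bootstrap",
    "build_pseudopopulation",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClusterConfig:
    """Correlation-distance agglomerative clustering configuration."""

    cutoff_r: float = 0.7
    linkage: str = "average"

    def __post_init__(self) -> None:
        if not 0.0 < self.cutoff_r < 1.0:
            raise ValueError("cutoff_r must lie in (0, 1)")


@dataclass
class ClusterResult:
    labels: np.ndarray          # cluster id per included unit, 1..k
    included: np.ndarray        # indices of units that were clusterable
    excluded: np.ndarray        # constant-profile units left out
    linkage_matrix: np.ndarray
    leaf_order: np.ndarray      # optimal ordering of included units

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) if self.labels.size else 0


def cluster_profiles(
    profiles: np.ndarray, config: ClusterConfig | None = None
) -> ClusterResult:
    """Cluster per-unit temporal profiles at the correlation cutoff.

    ``profiles`` is (n_units, n_time); rows with zero variance (undefined
    correlation) are excluded with a log notice.  Clusters are formed by
    cutting the average-linkage dendrogram at distance 1 − cutoff_r.
    """
    config = config or ClusterConfig()
    profiles = np.asarray(profiles, float)
    if profiles.ndim != 2 or profiles.shape[0] < 2:
        raise ValueError("need at least two equal-length profiles")
    sd = profiles.std(axis=1)
    tol = 1e-10 * (np.abs(profiles).max(axis=1) + 1.0)
    constant = sd <= tol
    included = np.nonzero(~constant)[0]
    excluded = np.nonzero(constant)[0]
    if excluded.size:
        log.info("cluster_profiles: excluding %d constant profile(s)", excluded.size)
    if included.size < 2:
        raise ValueError("fewer than two non-constant profiles")
    dist = pdist(profiles[included], metric="correlation")
    link = hierarchy.linkage(dist, method=config.linkage)
    link = hierarchy.optimal_leaf_ordering(link, dist)
    labels = hierarchy.fcluster(link, t=1.0 - config.cutoff_r, criterion="distance")
    order = hierarchy.leaves_list(link)
    return ClusterResult(labels, included, excluded, link, included[order])


def linkage_to_newick(link: np.ndarray, leaf_names: list[str] | None = None) -> str:
    """Serialise a SciPy linkage dendrogram as a Newick string."""
    tree = hierarchy.to_tree(link)
    n_leaves = link.shape[0] + 1
    if leaf_names is None:
        leaf_names = [f"u{i}" for i in range(n_leaves)]

    def recurse(node, parent_dist):
        length = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:g}"
        left = recurse(node.left, node.dist)
        right = recurse(node.right, node.dist)
        return f"({left},{right}):{length:g}"

    return recurse(tree, tree.dist) + ";"


def preferred_condition_sort(mean_z: pd.DataFrame) -> np.ndarray:
    """Order units by the condition level evoking their maximal mean z-rate.

    ``mean_z`` has one row per unit (index = unit id) and one column per
    condition level; every level must be estimated for every unit.  The sort
    is stable with ties broken by unit id.  Returns the ordered unit ids.
    """
    if mean_z.isna().any().any():
        raise ValueError("every unit needs every level estimated")
    levels = np.asarray(mean_z.columns, float)
    pref = levels[np.argmax(mean_z.to_numpy(), axis=1)]
    order = np.lexsort((np.asarray(mean_z.index), pref))
    return np.asarray(mean_z.index)[order]


# ---------------------------------------------------------------------------
# Optimal linear estimator
# ---------------------------------------------------------------------------

@dataclass
class OleModel:
    """Least-squares linear readout: predict = intercept + rates @ weights."""

    weights: np.ndarray
    intercept: float
    train_index: np.ndarray

    def predict(self, rates: np.ndarray) -> np.ndarray:
        return self.intercept + np.asarray(rates, float) @ self.weights


def ole_fit(rates: np.ndarray, target: np.ndarray,
            train_index: np.ndarray | None = None) -> OleModel:
    """Fit the OLE by ordinary least squares on (trials × units) z-rates.

    Rank-deficient designs fall back to the minimum-norm solution with a
    warning.  Requires more training trials than units and a varying target.
    """
    rates = np.asarray(rates, float)
    target = np.asarray(target, float)
    if train_index is None:
        train_index = np.arange(rates.shape[0])
    X = rates[train_index]
    y = target[train_index]
    if X.shape[0] < X.shape[1] + 1:
        raise ValueError("need more trials than units to fit the OLE")
    if np.ptp(y) == 0:
        return OleModel(np.zeros(X.shape[1]), float(y[0]) if y.size else 0.0, train_index)
    design = np.column_stack([np.ones(X.shape[0]), X])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        log.warning("ole_fit: rank-deficient design (rank %d < %d); "
                    "minimum-norm solution", rank, design.shape[1])
    return OleModel(coef[1:], float(coef[0]), np.asarray(train_index))


def ole_decode_with_bootstrap(
    rates: np.ndarray,
    target: np.ndarray,
    n_boot: int = 10_000,
    rng_seed: int = 0,
    groups: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-level OLE decoding with bootstrap 95% confidence intervals.

    Fits the OLE on all trials and reports, per target level (optionally per
    ``groups`` label, e.g. early vs late trials), the mean prediction with
    percentile CIs from ``n_boot`` trial resamples (each resample refits the
    estimator).  Returns a tidy frame [group, level, estimate, ci_lo, ci_hi].
    """
    rates = np.asarray(rates, float)
    target = np.asarray(target, float)
    n = rates.shape[0]
    if groups is None:
        groups = np.zeros(n, dtype=int)
    groups = np.asarray(groups)
    rng = np.random.default_rng(rng_seed)

    levels = np.unique(target)
    group_ids = np.unique(groups)
    model = ole_fit(rates, target)
    pred = model.predict(rates)

    cells = [(g, lv, (groups == g) & (target == lv)) for g in group_ids for lv in levels]
    boot = np.full((n_boot, len(cells)), np.nan)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        m = ole_fit(rates[idx], target[idx])
        p = m.predict(rates[idx])
        g_b, t_b = groups[idx], target[idx]
        for j, (g, lv, _) in enumerate(cells):
            mask = (g_b == g) & (t_b == lv)
            if mask.any():
                boot[b, j] = p[mask].mean()

    rows = []
    for j, (g, lv, mask) in enumerate(cells):
        if not mask.any():
            continue
        col = boot[:, j]
        col = col[np.isfinite(col)]
        lo, hi = (np.percentile(col, [2.5, 97.5]) if col.size else (np.nan, np.nan))
        rows.append((g, lv, float(pred[mask].mean()), float(lo), float(hi)))
    return pd.DataFrame(rows, columns=["group", "level", "estimate", "ci_lo", "ci_hi"])


def build_pseudopopulation(
    sessions: list[tuple[pd.DataFrame, np.ndarray]],
) -> tuple[np.ndarray, pd.DataFrame]:
    """Assemble a pseudo-population rate matrix from separate sessions.

    Each element of ``sessions`` is (choice-trial table, per-trial z-rates of
    that session's unit).  Trials are aligned across sessions on (pair,
    arrangement, occurrence index); only keys present in every session are
    kept.  Returns (trials × units rate matrix, aligned trial metadata from
    the first session).
    """
    keyed = []
    for trials, rates in sessions:
        trials = trials.reset_index(drop=True)
        occ = trials.groupby(["rank_low", "rank_high", "in_rf_item"]).cumcount()
        keys = list(zip(trials["rank_low"], trials["rank_high"],
                        trials["in_rf_item"], occ))
        keyed.append((trials, np.asarray(rates, float), dict(zip(keys, range(len(keys))))))
    common = set(keyed[0][2])
    for _, _, kmap in keyed[1:]:
        common &= set(kmap)
    common = sorted(common)
    if not common:
        raise ValueError("sessions share no aligned trials")
    mat = np.column_stack([
        rates[[kmap[k] for k in common]] for _, rates, kmap in keyed
    ])
    meta = keyed[0][0].iloc[[keyed[0][2][k] for k in common]].reset_index(drop=True)
    return mat, meta
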