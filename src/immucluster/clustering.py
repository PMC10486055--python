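"""Resampling consensus k-means clustering and immune cluster naming.

Samples are clustered repeatedly on random subsamples; the consensus matrix
entry for a pair of samples is the fraction of co-sampled runs in which the
pair co-clustered. The number of clusters is selected by the proportion of
ambiguous clustering (PAC): the fraction of off-diagonal consensus entries
falling strictly inside an intermediate band, minimized over k.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .scoring import ScaledMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ConsensusResult",
    "ClusterLabels",
    "consensus_cluster",
    "label_clusters",
    "adjust_batch_medians",
    "CLUSTER_NAMES",
]

#: Canonical immune cluster names, from most to least immune-infiltrated.
CLUSTER_NAMES = (
    "Paediatric Inflamed",
    "Myeloid Predominant",
    "Immune Neutral",
    "Immune Desert",
)


@dataclass
class ConsensusResult:
    """Per-k consensus matrices, assignments and k-selection statistics."""

    consensus: dict[int, pd.DataFrame]
    assignments: dict[int, pd.Series]
    pac: pd.Series
    chosen_k: int
    params: dict = field(default_factory=dict)


@dataclass
class ClusterLabels:
    """Named per-sample cluster labels plus the centroid table used to name
    them (cluster x geneset median z-scores)."""

    labels: pd.Series
    centroid_table: pd.DataFrame


def consensus_cluster(
    z: ScaledMatrix | pd.DataFrame,
    k_range: Sequence[int] = range(2, 9),
    reps: int = 200,
    p_sample: float = 0.8,
    p_feature: float = 1.0,
    seed: int | None = None,
    n_init: int = 1,
    pac_band: tuple[float, float] = (0.1, 0.9),
    collect_reps: bool = False,
) -> ConsensusResult:
    """Consensus k-means clustering of samples (columns) of a scaled matrix.

    For each of ``reps`` repetitions, ``floor(p_sample * n)`` samples and
    ``floor(p_feature * p)`` features are drawn without replacement and
    clustered with Euclidean k-means (k-means++ initialisation) for every k
    in ``k_range``; the same subsample is reused across k within one rep.
    Consensus ``M[i, j]`` is the co-cluster count divided by the co-sample
    count. Final per-k assignments come from average-linkage hierarchical
    clustering of ``1 - M`` cut at k. ``chosen_k`` is the PAC argmin
    (ties resolved toward the smallest k) and can be overridden downstream.

    Per-rep RNG substreams are derived from ``(seed, rep)`` so results do
    not depend on execution order.
    """
    frame = z.values if isinstance(z, ScaledMatrix) else z
    if seed is None:
        raise ValueError("a seed is required for reproducible consensus runs")
    k_range = list(k_range)
    if not k_range or any(k < 2 for k in k_range):
        raise ValueError("k_range must contain integers >= 2")
    X = frame.to_numpy(dtype=float).T  # samples x features
    n, p = X.shape
    if n < 2 * max(k_range):
        raise ValueError(
            f"need at least {2 * max(k_range)} samples for k up to {max(k_range)}"
        )
    n_sub = int(np.floor(p_sample * n))
    p_sub = int(np.floor(p_feature * p))
    if n_sub < max(k_range) or p_sub < 1:
        raise ValueError("subsample too small for the requested k range")

    co_cluster = {k: np.zeros((n, n)) for k in k_range}
    co_sample = np.zeros((n, n))
    reps_log: list[tuple[np.ndarray, dict[int, np.ndarray]]] = []
    used = 0
    for rep in range(reps):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), rep]))
        cols = np.sort(rng.choice(n, size=n_sub, replace=False))
        feats = (np.sort(rng.choice(p, size=p_sub, replace=False))
                 if p_sub < p else slice(None))
        sub = X[np.ix_(cols, np.arange(p))] if p_sub == p else X[np.ix_(cols, feats)]
        if np.unique(sub, axis=0).shape[0] < max(k_range):
            logger.info("rep %d skipped: fewer distinct samples than max k", rep)
            continue
        co_sample[np.ix_(cols, cols)] += 1.0
        rep_labels: dict[int, np.ndarray] = {}
        for k in k_range:
            km = KMeans(
                n_clusters=k,
                init="k-means++",
                n_init=n_init,
                random_state=int(rng.integers(2**31 - 1)),
            )
            labels = km.fit_predict(sub)
            same = labels[:, None] == labels[None, :]
            co_cluster[k][np.ix_(cols, cols)] += same
            rep_labels[k] = labels
        if collect_reps:
            reps_log.append((cols.copy(), rep_labels))
        used += 1
    if used == 0:
        raise RuntimeError("all consensus repetitions were skipped")

    consensus: dict[int, pd.DataFrame] = {}
    assignments: dict[int, pd.Series] = {}
    pac_vals: dict[int, float] = {}
    lo, hi = pac_band
    off_diag = ~np.eye(n, dtype=bool)
    samples = frame.columns
    for k in k_range:
        with np.errstate(invalid="ignore"):
            M = np.where(co_sample > 0, co_cluster[k] / np.where(co_sample, co_sample, 1), 0.0)
        np.fill_diagonal(M, 1.0)
        M = (M + M.T) / 2.0  # numerical symmetry
        consensus[k] = pd.DataFrame(M, index=samples, columns=samples)
        link = linkage(squareform(1.0 - M, checks=False), method="average")
        labels = fcluster(link, t=k, criterion="maxclust")
        assignments[k] = pd.Series(labels, index=samples, name=f"k{k}")
        vals = M[off_diag]
        pac_vals[k] = float(np.mean((vals > lo) & (vals < hi)))

    pac = pd.Series(pac_vals, name="pac")
    chosen_k = int(pac.index[np.argmin(pac.to_numpy())])
    return ConsensusResult(
        consensus=consensus,
        assignments=assignments,
        pac=pac,
        chosen_k=chosen_k,
        params={"reps": reps, "p_sample": p_sample, "p_feature": p_feature,
                "seed": seed, "n_init": n_init, "used_reps": used,
                **({"reps_log": reps_log} if collect_reps else {})},
    )


def _name_four_clusters(
    centroids: pd.DataFrame,
    lymphoid_sets: Sequence[str],
    myeloid_sets: Sequence[str],
    t_hi: float,
    t_lo: float,
) -> dict:
    """Apply the centroid naming rules; fall back to rank-wise naming on
    collisions. ``centroids`` is cluster x geneset median z."""
    lym = list(lymphoid_sets)
    mye = list(myeloid_sets)
    lym_median = centroids[lym].median(axis=1)
    proposed: dict = {}
    for cl in centroids.index:
        row = centroids.loc[cl]
        if (row < t_lo).all():
            proposed[cl] = "Immune Desert"
        elif (row > t_hi).all() or (
            (row[lym] > 0).all() and (row[mye] > 0).all()
            and lym_median[cl] == lym_median.max()
        ):
            proposed[cl] = "Paediatric Inflamed"
        elif (row[mye] > 0).all() and (row[lym] <= 0).all():
            proposed[cl] = "Myeloid Predominant"
        else:
            proposed[cl] = "Immune Neutral"
    if len(set(proposed.values())) == len(proposed):
        return proposed
    # deterministic fallback: order clusters by total median score and hand
    # out canonical names rank-wise
    order = centroids.sum(axis=1).sort_values(ascending=False).index
    return {cl: CLUSTER_NAMES[i] for i, cl in enumerate(order)}


def label_clusters(
    assignments: pd.Series,
    z: ScaledMatrix | pd.DataFrame,
    lymphoid_sets: Sequence[str],
    myeloid_sets: Sequence[str],
    t_hi: float = 0.5,
    t_lo: float = -0.5,
) -> ClusterLabels:
    """Name clusters from their geneset median z-score centroids.

    Rules (four clusters): a cluster is *Immune Desert* when every geneset
    median is below ``t_lo``; *Paediatric Inflamed* when every median exceeds
    ``t_hi``, or when all lymphoid and myeloid medians are positive and it
    attains the maximum lymphoid median across clusters; *Myeloid
    Predominant* when myeloid medians are positive
    but lymphoid medians are not; *Immune Neutral* otherwise. Name
    collisions fall back to ranking clusters on total median score. For
    ``k != 4`` generic ``C1..Ck`` names are emitted with the centroid table.
    """
    frame = z.values if isinstance(z, ScaledMatrix) else z
    missing = [s for s in list(lymphoid_sets) + list(myeloid_sets)
               if s not in frame.index]
    if missing:
        raise KeyError(f"genesets not present in score matrix: {missing}")
    clusters = pd.unique(assignments)
    centroids = pd.DataFrame(
        {gs: [frame.loc[gs, assignments[assignments == cl].index].median()
              for cl in clusters] for gs in frame.index},
        index=pd.Index(clusters, name="cluster"),
    )
    if len(clusters) == 4:
        name_map = _name_four_clusters(centroids, lymphoid_sets, myeloid_sets,
                                       t_hi, t_lo)
    else:
        order = centroids.sum(axis=1).sort_values(ascending=False).index
        name_map = {cl: f"C{i + 1}" for i, cl in enumerate(order)}
    labels = assignments.map(name_map)
    labels.name = "immune_cluster"
    centroids.index = pd.Index([name_map[cl] for cl in centroids.index],
                               name="cluster")
    return ClusterLabels(labels=labels, centroid_table=centroids)


def adjust_batch_medians(scores: pd.DataFrame, batch: pd.Series) -> pd.DataFrame:
    """Optional batch hook: subtract the per-batch median from every geneset
    row, batch by batch. A coarse location adjustment only — empirical-Bayes
    batch correction is deliberately out of scope."""
    adjusted = scores.copy()
    for b in pd.unique(batch):
        cols = batch[batch == b].index
        med = adjusted.loc[:, cols].median(axis=1)
        adjusted.loc[:, cols] = adjusted.loc[:, cols].sub(med, axis=0)
    return adjusted
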