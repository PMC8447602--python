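"""Co-regulation clustering of z-scored time-course profiles.

Dynamic interactions and modification sites that respond to pathway
activation on similar schedules (early peak, late rise, decay, ...) are
grouped by clustering their time profiles.  Each feature is reduced to one
value per time point (the median of its normalized replicate values), the
profile is z-scored across time points (removing scale and offset so only
the *shape* matters), and profiles are clustered hierarchically on
1 - Pearson correlation distance.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io_maxquant import SampleAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "build_zscored_profiles",
    "pearson_distance_matrix",
    "cluster_profiles",
    "summarize_cluster",
]


def build_zscored_profiles(normalized: pd.DataFrame,
                           annotation: SampleAnnotation,
                           min_valid_fraction: float = 0.7) -> pd.DataFrame:
    """Per-time-point median then z-score across time points.

    Features with less than ``min_valid_fraction`` valid values across the
    samples feeding the profile are removed, as are features whose median
    profile is constant (their z-score is undefined).  Z-scoring uses the
    population standard deviation, so each retained profile has mean 0 and
    standard deviation 1 exactly.

    Returns features x timepoints (columns sorted by time, in minutes).
    """
    timepoints = annotation.timepoints
    if len(timepoints) < 3:
        raise ValueError("need at least 3 time points to build profiles")
    cols = [s for s in normalized.columns
            if s in set(annotation.sample_ids)]
    frac_valid = normalized[cols].notna().mean(axis=1)
    kept = normalized.loc[frac_valid >= min_valid_fraction, cols]

    medians = pd.DataFrame(index=kept.index, columns=timepoints, dtype=float)
    for t in timepoints:
        tcols = [s for s in annotation.samples_at_time(t) if s in kept.columns]
        medians[t] = kept[tcols].median(axis=1)
    medians = medians.dropna()

    sd = medians.std(axis=1, ddof=0)
    constant = sd == 0
    if constant.any():
        logger.warning("%d constant profile(s) removed (undefined z-score)",
                       int(constant.sum()))
    medians = medians.loc[~constant]
    z = medians.sub(medians.mean(axis=1), axis=0).div(sd[~constant], axis=0)
    return z


def pearson_distance_matrix(profiles: pd.DataFrame) -> np.ndarray:
    """1 - Pearson r between profile rows; symmetric, zero diagonal, in [0,2]."""
    corr = np.corrcoef(profiles.to_numpy(dtype=float))
    corr = np.atleast_2d(corr)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    return dist


def cluster_profiles(profiles: pd.DataFrame, k: int = 7) -> pd.Series:
    """Average-linkage hierarchical clustering into ``k`` clusters.

    Distance is 1 - Pearson correlation between z-scored profiles.  Cluster
    labels are contiguous 1..k, ordered by descending cluster size, ties by
    earliest peak time of the cluster mean profile.  Deterministic.
    """
    if k < 2 or k > len(profiles):
        raise ValueError(f"k={k} must be in [2, #profiles={len(profiles)}]")
    dist = pearson_distance_matrix(profiles)
    link = hierarchy.average(squareform(dist, checks=False))
    raw = hierarchy.fcluster(link, t=k, criterion="maxclust")

    times = np.asarray(profiles.columns, dtype=float)
    order = []
    for label in np.unique(raw):
        members = raw == label
        peak_time = times[int(np.argmax(profiles.to_numpy()[members].mean(axis=0)))]
        order.append((-(members.sum()), peak_time, label))
    relabel = {old: new for new, (_, _, old) in enumerate(sorted(order), start=1)}
    labels = pd.Series([relabel[x] for x in raw], index=profiles.index,
                       name="cluster")
    return labels


def summarize_cluster(profiles: pd.DataFrame, assignment: pd.Series,
                      cluster_label: int, ci_level: float = 0.95,
                      smoother_span: float = 0.75, *,
                      n_boot: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Per-time-point median of member z-profiles with a bootstrap CI and a
    locally-weighted (lowess) smooth through the member points.

    Returns one row per time point: ``median``, ``lower``/``upper`` (the
    ``ci_level`` bootstrap percentile band of the median), ``smoothed`` and
    the member count ``n``.  A single-member cluster's band collapses onto
    the member's own profile.
    """
    members = assignment.index[assignment == cluster_label]
    if len(members) == 0:
        raise ValueError(f"unknown or empty cluster label {cluster_label!r}")
    block = profiles.loc[members].to_numpy(dtype=float)
    times = np.asarray(profiles.columns, dtype=float)
    med = np.median(block, axis=0)

    rng = np.random.default_rng(seed)
    if block.shape[0] == 1:
        lower = upper = med.copy()
    else:
        boots = np.empty((n_boot, block.shape[1]))
        for b in range(n_boot):
            idx = rng.integers(0, block.shape[0], block.shape[0])
            boots[b] = np.median(block[idx], axis=0)
        alpha = (1.0 - ci_level) / 2.0
        lower = np.quantile(boots, alpha, axis=0)
        upper = np.quantile(boots, 1.0 - alpha, axis=0)

    x = np.repeat(times, block.shape[0])
    y = block.T.ravel()
    smoothed = lowess(y, x, frac=min(1.0, smoother_span), xvals=times,
                      return_sorted=False)
    return pd.DataFrame({
        "time_min": times, "median": med, "lower": lower, "upper": upper,
        "smoothed": np.atleast_1d(smoothed), "n": block.shape[0],
    })
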