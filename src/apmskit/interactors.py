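"""Bait-vs-complement interactor calling with permutation-based FDR.

Each pull-down enriches the tagged bait and its binding partners on top of a
population of background binders shared by all pull-downs.  Interactors are
therefore called by a two-sided two-sample Student's t-test of the bait's
replicates against the *complement* — all other pull-downs within the same
background control group — combined with a fold-enrichment threshold.  The
false-discovery rate is estimated SAM-style by permuting sample labels:
for each observed |t| cutoff, the expected number of null exceedances
(averaged over random relabelings that preserve group sizes) is divided by
the observed number of exceedances.

Control groups themselves come from hierarchical clustering of sample
profiles on 1 - Pearson correlation distance: pull-downs sharing a
background binder population correlate highly and cluster together.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.special import stdtr
from sklearn.metrics import silhouette_score

from .io_maxquant import SampleAnnotation
from .preprocess import IntensityMatrix

__all__ = [
    "ControlGroupAssignment",
    "build_control_groups",
    "bait_vs_complement_test",
    "permutation_fdr",
    "call_interactors",
    "whole_proteome_diff",
]

RESULT_COLUMNS = ["bait_id", "protein_id", "log2_difference", "t_statistic",
                  "p_value", "q_value", "fold_enrichment", "significant",
                  "testable", "n_valid_bait", "n_valid_complement", "rank"]


@dataclass(frozen=True)
class ControlGroupAssignment:
    """Partition of samples into background control groups."""

    groups: dict[str, list[str]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for gid, members in self.groups.items():
            if len(members) < 2:
                raise ValueError(f"control group {gid!r} is a singleton")
            overlap = seen.intersection(members)
            if overlap:
                raise ValueError(f"samples in multiple groups: {sorted(overlap)}")
            seen.update(members)

    def group_of(self, sample_id: str) -> str:
        for gid, members in self.groups.items():
            if sample_id in members:
                return gid
        raise KeyError(sample_id)

    def members(self, group_id: str) -> list[str]:
        return list(self.groups[group_id])

    @property
    def n_groups(self) -> int:
        return len(self.groups)


def _pairwise_pearson(values: np.ndarray, min_shared: int = 10) -> np.ndarray:
    """Pairwise-complete Pearson correlation between columns.

    Requires at least ``min_shared`` cells observed in both columns of every
    pair; otherwise the correlation is undefined and an error is raised.
    """
    n = values.shape[1]
    finite = np.isfinite(values)
    if finite.all():
        if values.shape[0] < min_shared:
            raise ValueError(
                f"only {values.shape[0]} shared observations per pair "
                f"(< {min_shared}); impute or filter first")
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(values.T)
        corr = np.nan_to_num(corr, nan=0.0)
        np.fill_diagonal(corr, 1.0)
        return corr
    corr = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            shared = finite[:, i] & finite[:, j]
            if shared.sum() < min_shared:
                raise ValueError(
                    f"samples {i} and {j} share only {int(shared.sum())} "
                    f"observations (< {min_shared}); impute or filter first")
            x, y = values[shared, i], values[shared, j]
            sx, sy = x.std(), y.std()
            if sx == 0 or sy == 0:
                r = 1.0 if np.allclose(x, y) else 0.0
            else:
                r = float(np.corrcoef(x, y)[0, 1])
            corr[i, j] = corr[j, i] = r
    return corr


def build_control_groups(matrix: IntensityMatrix, annotation: SampleAnnotation,
                         n_groups: int | str = "auto",
                         min_shared: int = 10) -> ControlGroupAssignment:
    """Cluster samples into background control groups.

    Average-linkage hierarchical clustering on distance 1 - Pearson r between
    sample intensity profiles (pairwise-complete over observed cells), cut
    into ``n_groups`` clusters.  ``n_groups="auto"`` picks the cut maximising
    the mean silhouette over 2..min(6, #baits - 1).  Each bait's samples are
    assigned as a block to the group holding the majority of them, so a bait
    is never split across control groups.
    """
    sample_ids = matrix.sample_ids
    if len(sample_ids) < 2:
        raise ValueError("need at least 2 samples to build control groups")
    ann = annotation.table.set_index("sample_id").loc[sample_ids]
    baits = list(dict.fromkeys(ann["bait_id"]))
    if isinstance(n_groups, int) and n_groups > len(baits):
        raise ValueError(f"n_groups={n_groups} exceeds the number of baits "
                         f"({len(baits)})")

    # observed and imputed cells are finite; missing-unimputed cells are NaN
    values = matrix.values.to_numpy(dtype=float)
    corr = _pairwise_pearson(values, min_shared=min_shared)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    link = hierarchy.average(squareform(dist, checks=False))

    if n_groups == "auto":
        best_k, best_score = 1, -np.inf
        for k in range(2, min(6, len(baits) - 1) + 1):
            labels = hierarchy.fcluster(link, t=k, criterion="maxclust")
            if len(set(labels)) < 2:
                continue
            score = silhouette_score(dist, labels, metric="precomputed")
            if score > best_score:
                best_k, best_score = k, score
        n_groups = best_k if best_k > 1 else 1

    if n_groups == 1:
        labels = np.ones(len(sample_ids), dtype=int)
    else:
        labels = hierarchy.fcluster(link, t=n_groups, criterion="maxclust")

    # majority vote per bait keeps each bait's replicates in one group
    by_sample = pd.Series(labels, index=sample_ids)
    bait_group = {
        b: int(by_sample[[s for s in annotation.samples_for_bait(b)
                          if s in set(sample_ids)]].mode().iloc[0])
        for b in baits}
    groups: dict[str, list[str]] = {}
    for label in sorted(set(bait_group.values())):
        members = [s for s in sample_ids if bait_group[ann.loc[s, "bait_id"]] == label]
        groups[f"group{len(groups) + 1}"] = members
    return ControlGroupAssignment(groups=groups)


def _pooled_t(values: np.ndarray, in_group1: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised two-sample Student's t (pooled variance) per row.

    Returns (difference group1 - group2, t, two-sided p).  Rows with zero
    pooled variance get t = 0, p = 1 when the means agree and t = +/-inf,
    p = 0 otherwise.
    """
    g1 = values[:, in_group1]
    g2 = values[:, ~in_group1]
    n1, n2 = g1.shape[1], g2.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need at least 2 samples")
    m1, m2 = g1.mean(axis=1), g2.mean(axis=1)
    v1 = g1.var(axis=1, ddof=1)
    v2 = g2.var(axis=1, ddof=1)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    diff = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / np.where(se > 0, se, 1.0),
                     np.where(diff == 0, 0.0, np.sign(diff) * np.inf))
    p = np.where(np.isinf(t), 0.0, 2.0 * stdtr(df, -np.abs(np.where(np.isinf(t), 0.0, t))))
    return diff, t, p


def bait_vs_complement_test(matrix: IntensityMatrix, annotation: SampleAnnotation,
                            bait: str, groups: ControlGroupAssignment,
                            min_valid: int = 10) -> pd.DataFrame:
    """Test every protein for enrichment in one bait's pull-downs.

    Group 1 is the bait's samples; group 2 ("complement") is every other
    sample in the bait's control group.  The matrix must be imputed (no NaN
    among tested cells).  Proteins with fewer than ``min_valid``
    originally-observed (non-imputed) values in the bait group are marked
    untestable: imputed cells are pseudo-data and must not drive calls.

    Returns a per-protein frame with ``log2_difference`` (bait mean minus
    complement mean), ``t_statistic``, ``p_value``, valid-value counts and
    the ``testable`` flag.
    """
    bait_samples = [s for s in annotation.samples_for_bait(bait)
                    if s in set(matrix.sample_ids)]
    if not bait_samples:
        raise ValueError(f"bait {bait!r} not present in the annotation/matrix")
    gid = groups.group_of(bait_samples[0])
    group_samples = [s for s in matrix.sample_ids if s in set(groups.members(gid))]
    complement = [s for s in group_samples if s not in set(bait_samples)]
    if not complement:
        raise ValueError(f"complement of bait {bait!r} is empty in group {gid!r}")

    sub = matrix.subset_samples(group_samples)
    in_bait = np.array([s in set(bait_samples) for s in group_samples])
    values = sub.values.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("matrix contains missing cells; impute first")
    diff, t, p = _pooled_t(values, in_bait)

    observed = sub.observed_mask.to_numpy()
    n_valid_bait = observed[:, in_bait].sum(axis=1)
    n_valid_comp = observed[:, ~in_bait].sum(axis=1)
    return pd.DataFrame({
        "bait_id": bait,
        "protein_id": sub.feature_ids,
        "log2_difference": diff,
        "t_statistic": t,
        "p_value": p,
        "n_valid_bait": n_valid_bait,
        "n_valid_complement": n_valid_comp,
        "testable": n_valid_bait >= min_valid,
    })


def _relabelings(n_total: int, n_group1: int, n_permutations: int,
                 rng: np.random.Generator,
                 observed: np.ndarray) -> np.ndarray:
    """Boolean membership matrix (n_perm x n_total) of pseudo-group-1 labels.

    Relabelings that reproduce the observed partition (the observed group-1
    set, or its complement when group sizes are equal) are excluded: they
    carry no null information and would floor the attainable q on small
    designs.  When all remaining distinct relabelings fit in the budget they
    are enumerated exhaustively; otherwise sampled uniformly (with
    replacement).
    """
    obs_set = frozenset(np.flatnonzero(observed))
    mirror = (frozenset(np.flatnonzero(~observed))
              if 2 * n_group1 == n_total else None)

    def is_observed(combo: frozenset) -> bool:
        return combo == obs_set or (mirror is not None and combo == mirror)

    total = math.comb(n_total, n_group1)
    if total <= n_permutations + (2 if mirror else 1):
        rows = [list(c) for c in itertools.combinations(range(n_total), n_group1)
                if not is_observed(frozenset(c))]
        out = np.zeros((len(rows), n_total), dtype=bool)
        for i, combo in enumerate(rows):
            out[i, combo] = True
        return out
    out = np.zeros((n_permutations, n_total), dtype=bool)
    for i in range(n_permutations):
        while True:
            pick = rng.choice(n_total, size=n_group1, replace=False)
            if not is_observed(frozenset(pick)):
                break
        out[i, pick] = True
    return out


def permutation_fdr(stats: pd.DataFrame, matrix: IntensityMatrix,
                    bait_samples: list[str], group_samples: list[str],
                    n_permutations: int = 250, *, seed: int) -> pd.DataFrame:
    """Attach SAM-style permutation q-values to bait-vs-complement results.

    For each random relabeling of the group's samples (bait-group size
    preserved), |t| is recomputed for all testable proteins.  For the cutoff
    c = |t_i| of each observed protein,

        q_i = min(1, mean over permutations of #{|t_perm| >= c}
                     / #{observed |t| >= c})

    then q is made monotone non-increasing in |t| by a step-up pass (each q
    is replaced by the minimum raw q among proteins with smaller-or-equal
    |t|, mirroring Benjamini-Hochberg enforcement).  Untestable proteins get
    q = 1.  The same seed reproduces q exactly; designs small enough for
    exhaustive enumeration are enumerated, making the estimate exact.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    out = stats.copy()
    testable = out["testable"].to_numpy()
    out["q_value"] = 1.0
    if not testable.any():
        return out

    sub = matrix.subset_samples(list(group_samples))
    values = sub.values.loc[out.loc[testable, "protein_id"]].to_numpy(dtype=float)
    n_total = len(group_samples)
    observed_labels = np.array([s in set(bait_samples) for s in group_samples])
    n1 = int(observed_labels.sum())
    perms = _relabelings(n_total, n1, n_permutations, rng, observed_labels)

    obs_abs = np.abs(out.loc[testable, "t_statistic"].to_numpy(dtype=float))
    perm_abs = np.empty((perms.shape[0], values.shape[0]))
    for k in range(perms.shape[0]):
        _, t_k, _ = _pooled_t(values, perms[k])
        perm_abs[k] = np.abs(t_k)

    flat = np.sort(perm_abs.ravel())
    order = np.argsort(obs_abs)  # ascending
    sorted_abs = obs_abs[order]
    finite = np.where(np.isfinite(sorted_abs), sorted_abs, np.finfo(float).max)
    # permuted exceedances of each cutoff, averaged over permutations
    exceed_perm = (flat.size - np.searchsorted(flat, finite, side="left")) / perms.shape[0]
    # observed exceedances: count of observed |t| >= cutoff
    exceed_obs = len(sorted_abs) - np.searchsorted(sorted_abs, sorted_abs, side="left")
    raw_q = np.minimum(1.0, exceed_perm / exceed_obs)
    # step-up: running min from least significant toward largest |t| makes q
    # monotone non-increasing in |t| (the array is in ascending |t| order)
    mono_q = np.minimum.accumulate(raw_q)
    q = np.empty_like(mono_q)
    q[order] = mono_q
    out.loc[testable, "q_value"] = q
    return out


def call_interactors(results: pd.DataFrame, fdr: float = 0.01,
                     enrichment: float = 2.0) -> pd.DataFrame:
    """Apply the significance thresholds and rank the calls.

    A protein is a significant interactor iff it is testable, its
    permutation q-value is below ``fdr`` and its linear fold enrichment
    (2**log2_difference) exceeds ``enrichment``.  Results are ranked by
    ascending q, then descending difference, ties broken by protein id.
    """
    out = results.copy()
    out["fold_enrichment"] = np.power(2.0, out["log2_difference"])
    out["significant"] = (out["testable"] & (out["q_value"] < fdr)
                          & (out["fold_enrichment"] > enrichment))
    out = out.sort_values(
        ["q_value", "log2_difference", "protein_id"],
        ascending=[True, False, True], kind="mergesort").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out[[c for c in RESULT_COLUMNS if c in out.columns]]


def call_bait(matrix: IntensityMatrix, annotation: SampleAnnotation, bait: str,
              groups: ControlGroupAssignment, *, fdr: float = 0.01,
              enrichment: float = 2.0, min_valid: int = 10,
              n_permutations: int = 250, seed: int) -> pd.DataFrame:
    """Full per-bait pipeline: test, permutation FDR, thresholding."""
    stats = bait_vs_complement_test(matrix, annotation, bait, groups,
                                    min_valid=min_valid)
    bait_samples = [s for s in annotation.samples_for_bait(bait)
                    if s in set(matrix.sample_ids)]
    gid = groups.group_of(bait_samples[0])
    group_samples = [s for s in matrix.sample_ids
                     if s in set(groups.members(gid))]
    stats = permutation_fdr(stats, matrix, bait_samples, group_samples,
                            n_permutations=n_permutations, seed=seed)
    return call_interactors(stats, fdr=fdr, enrichment=enrichment)


def whole_proteome_diff(matrix: IntensityMatrix, annotation: SampleAnnotation,
                        group_a: list[str], group_b: list[str], *,
                        fdr: float = 0.05, enrichment: float = 2.0,
                        min_valid: int = 2, n_permutations: int = 250,
                        seed: int) -> pd.DataFrame:
    """Differential abundance between two full proteomes.

    Same machinery as interactor calling with the whole-proteome defaults:
    permutation FDR < 0.05, enrichment > 2, minimum 2 valid values in the
    first group.
    """
    samples = list(group_a) + list(group_b)
    sub = matrix.subset_samples(samples)
    in_a = np.array([s in set(group_a) for s in samples])
    values = sub.values.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("matrix contains missing cells; impute first")
    diff, t, p = _pooled_t(values, in_a)
    observed = sub.observed_mask.to_numpy()
    stats = pd.DataFrame({
        "bait_id": "groupA",
        "protein_id": sub.feature_ids,
        "log2_difference": diff,
        "t_statistic": t,
        "p_value": p,
        "n_valid_bait": observed[:, in_a].sum(axis=1),
        "n_valid_complement": observed[:, ~in_a].sum(axis=1),
    })
    stats["testable"] = stats["n_valid_bait"] >= min_valid
    stats = permutation_fdr(stats, sub, list(group_a), samples,
                            n_permutations=n_permutations, seed=seed)
    return call_interactors(stats, fdr=fdr, enrichment=enrichment)
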