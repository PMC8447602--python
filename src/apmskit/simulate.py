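"""Synthetic AP-MS LFQ data with known ground truth.

The generator reproduces the statistical structure the calling procedure
assumes, so that every stage of the pipeline can be benchmarked against a
truth table:

* **shared background** — every pull-down captures the same population of
  non-specific matrix binders; their log2 intensities share a per-protein
  latent level across all samples, inducing the high inter-sample Pearson
  correlations seen in real pull-down batches (> 0.9 between replicates);
* **bait self-enrichment** — the tagged bait's own row is strongly
  up-shifted in its own pull-downs;
* **spiked true interactors** — a configurable number of preys per bait are
  up-shifted by a configurable log2 effect only in that bait's samples;
* **replicate noise** — i.i.d. Gaussian noise on the log2 scale per cell;
* **MNAR dropout** — each cell is set to 0 (not quantified) with logistic
  probability increasing as the intensity approaches the detection limit;
* **time-course profile classes** — dynamic preys and modification sites
  follow multiplicative trajectories (early peak, late rise, decay, flat)
  over the activation time course.

Default magnitudes are modelled on a typical deep AP-MS study: thousands of
background proteins at log2 LFQ ~ Normal(24, 2^2), replicate sd 0.3 log2
units, a handful to a few dozen genuine interactors per bait, bait
self-enrichment of ~6 log2 units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .io_maxquant import (ModifiedPeptideTable, ProteinQuantTable,
                          SampleAnnotation)

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "generate_apms_dataset",
    "apply_mnar_missingness",
    "generate_timecourse_dataset",
    "PROFILE_CLASSES",
]

PROFILE_CLASSES = ("early_up", "late_up", "down", "flat")


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic AP-MS experiment (log2-scale parameters)."""

    n_baits: int = 20
    n_background: int = 2000
    interactors_per_bait: int = 15
    log2_effect: float = 3.0           # mean bait-vs-complement enrichment
    bait_self_effect: float = 6.0      # log2 self-enrichment of the bait row
    replicate_sd: float = 0.3          # per-cell log2 noise
    background_mean: float = 24.0
    background_sd: float = 2.0
    replicates: int = 4
    timepoints: tuple = (0.0, 5.0, 15.0, 30.0)
    dynamic_fraction: float = 0.5
    profile_classes: tuple = PROFILE_CLASSES
    dynamic_amplitude: float = 1.5     # log2 peak modulation of dynamic features
    n_ptm_sites: int = 0               # per bait, time-course generator only
    mnar_midpoint: float = 21.0        # log2 intensity at 50% dropout
    mnar_slope: float = 0.8            # logistic steepness, per log2 unit
    interactor_overlap: int = 0        # preys shared between consecutive baits
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_baits, self.n_background, self.interactors_per_bait,
               self.replicates) < 1:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.dynamic_fraction <= 1.0:
            raise ValueError("dynamic_fraction must be in [0, 1]")
        bad = set(self.profile_classes) - set(PROFILE_CLASSES)
        if bad:
            raise ValueError(f"unknown profile classes: {sorted(bad)}")
        if self.replicate_sd < 0 or self.background_sd <= 0:
            raise ValueError("standard deviations must be positive")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of one generated dataset.

    ``features`` has one row per protein/site: ``role`` (``bait``,
    ``true_interactor``, ``background`` or ``ptm_site``), the owning
    ``bait_id`` (empty for background), ``true_log2_effect`` and
    ``profile_class``.  ``pre_dropout`` holds the linear intensities before
    MNAR dropout; ``dropout_mask`` flags the cells zeroed by dropout (filled
    by :func:`apply_mnar_missingness`).
    """

    features: pd.DataFrame = field(repr=False)
    pre_dropout: pd.DataFrame = field(repr=False)
    dropout_mask: pd.DataFrame | None = field(default=None, repr=False)

    def interactors_of(self, bait_id: str) -> set[str]:
        f = self.features
        return set(f.index[(f["role"] == "true_interactor")
                           & (f["bait_id"] == bait_id)])

    @property
    def bait_ids(self) -> list[str]:
        f = self.features
        return list(f.index[f["role"] == "bait"])


def _feature_frame(config: SimulationConfig, rng: np.random.Generator):
    """Truth skeleton: ids, roles, owning bait, baseline log2 levels."""
    rows = []
    for b in range(config.n_baits):
        rows.append((f"BAIT{b + 1:02d}", "bait", f"BAIT{b + 1:02d}",
                     config.bait_self_effect))
    for b in range(config.n_baits):
        bait = f"BAIT{b + 1:02d}"
        for i in range(config.interactors_per_bait):
            rows.append((f"INT_{bait}_{i + 1:02d}", "true_interactor", bait,
                         config.log2_effect))
    for k in range(config.n_background):
        rows.append((f"BG{k + 1:04d}", "background", "", 0.0))
    feats = pd.DataFrame(rows, columns=["protein_id", "role", "bait_id",
                                        "true_log2_effect"]).set_index("protein_id")
    # shared preys between consecutive baits exercise network degree logic
    if config.interactor_overlap > 0 and config.n_baits > 1:
        extra = []
        for b in range(config.n_baits - 1):
            bait_a, bait_b = f"BAIT{b + 1:02d}", f"BAIT{b + 2:02d}"
            for i in range(config.interactor_overlap):
                pid = f"SHARED_{bait_a}_{bait_b}_{i + 1}"
                extra.append((pid, "true_interactor", f"{bait_a};{bait_b}",
                              config.log2_effect))
        feats = pd.concat([feats, pd.DataFrame(
            extra, columns=["protein_id", "role", "bait_id",
                            "true_log2_effect"]).set_index("protein_id")])
    feats["baseline_log2"] = rng.normal(config.background_mean,
                                        config.background_sd, len(feats))
    feats["profile_class"] = "flat"
    return feats


def _annotation(config: SimulationConfig, timepoints=None) -> SampleAnnotation:
    times = list(timepoints) if timepoints is not None else [0.0]
    rows = []
    for b in range(config.n_baits):
        bait = f"BAIT{b + 1:02d}"
        for t in times:
            for r in range(1, config.replicates + 1):
                sid = (f"{bait}_t{t:g}_r{r}" if len(times) > 1
                       else f"{bait}_r{r}")
                rows.append({"sample_id": sid, "bait_id": bait,
                             "condition": "activated" if t > 0 else "untreated",
                             "time_min": float(t), "replicate": r})
    return SampleAnnotation(pd.DataFrame(rows))


def _owned_by(feats: pd.DataFrame, bait: str) -> np.ndarray:
    """Rows whose owning bait list contains ``bait`` (';'-separated)."""
    return feats["bait_id"].str.split(";").apply(lambda bs: bait in bs).to_numpy()


def generate_apms_dataset(config: SimulationConfig
                          ) -> tuple[ProteinQuantTable, SampleAnnotation, SyntheticTruth]:
    """Single-time-point AP-MS design: one pull-down per bait, replicated.

    Background proteins share their latent log2 level across all samples;
    the bait row and its true interactors are up-shifted only in that bait's
    samples.  Intensities are exponentiated to the linear LFQ scale.
    Deterministic given ``config.seed``.  No dropout is applied here — pass
    the result through :func:`apply_mnar_missingness`.
    """
    rng = np.random.default_rng(config.seed)
    feats = _feature_frame(config, rng)
    annotation = _annotation(config)
    sample_ids = annotation.sample_ids

    log2 = np.tile(feats["baseline_log2"].to_numpy()[:, None],
                   (1, len(sample_ids)))
    for bait in annotation.bait_ids:
        cols = [sample_ids.index(s) for s in annotation.samples_for_bait(bait)]
        owned = _owned_by(feats, bait)
        log2[np.ix_(owned, cols)] += feats.loc[owned, "true_log2_effect"].to_numpy()[:, None]
    log2 = log2 + rng.normal(0.0, config.replicate_sd, log2.shape)

    linear = np.power(2.0, log2)
    intens = pd.DataFrame(linear, index=feats.index, columns=sample_ids)
    meta = pd.DataFrame({
        "gene_name": feats.index,
        "peptide_count": 5,
        "is_contaminant": False,
        "is_reverse": False,
        "only_identified_by_site": False,
    }, index=feats.index)
    table = ProteinQuantTable(meta=meta, intensities=intens)
    truth = SyntheticTruth(features=feats, pre_dropout=intens.copy())
    return table, annotation, truth


def apply_mnar_missingness(table: ProteinQuantTable, config: SimulationConfig,
                           truth: SyntheticTruth | None = None
                           ) -> tuple[ProteinQuantTable, SyntheticTruth | None]:
    """Zero out cells with intensity-dependent (logistic) dropout probability.

    P(dropout) = logistic((mnar_midpoint - log2 intensity) * mnar_slope):
    0.5 exactly at the midpoint, rising toward low intensities.  Dropout
    uses its own stream derived from the seed, so the pre-dropout data are
    unchanged by re-application.
    """
    rng = np.random.default_rng((config.seed, 0xD20))
    linear = table.intensities.to_numpy(dtype=float)
    if (linear <= 0).any():
        raise ValueError("apply_mnar_missingness expects positive intensities")
    p = expit((config.mnar_midpoint - np.log2(linear)) * config.mnar_slope)
    drop = rng.random(p.shape) < p
    out = table.intensities.mask(
        pd.DataFrame(drop, index=table.intensities.index,
                     columns=table.intensities.columns), 0.0)
    new_table = ProteinQuantTable(meta=table.meta, intensities=out)
    if truth is not None:
        truth = replace(truth, dropout_mask=pd.DataFrame(
            drop, index=out.index, columns=out.columns))
    return new_table, truth


def _trajectory(profile_class: str, times: np.ndarray,
                amplitude: float) -> np.ndarray:
    """Multiplicative log2 modulation over the time course (0 at time 0)."""
    t = np.asarray(times, dtype=float)
    span = t.max() if t.max() > 0 else 1.0
    active = t[t > 0]
    first_active = active.min() if active.size else span
    if profile_class == "flat":
        return np.zeros_like(t)
    if profile_class == "early_up":
        # peak at the first activated time point, then decay
        out = amplitude * (t / first_active) * np.exp(1.0 - t / first_active)
        out[t == 0] = 0.0
        return out
    if profile_class == "late_up":
        return amplitude * t / span
    if profile_class == "down":
        return -amplitude * t / span
    raise ValueError(f"unknown profile class {profile_class!r}")


def generate_timecourse_dataset(config: SimulationConfig
                                ) -> tuple[ProteinQuantTable, ModifiedPeptideTable,
                                           SampleAnnotation, SyntheticTruth]:
    """Activation time course: every bait measured at each time point.

    A ``dynamic_fraction`` of each bait's true interactors (and of the PTM
    sites, when ``n_ptm_sites > 0``) is assigned a profile class; the class
    scales the feature's intensity multiplicatively over the time course
    while the bait row stays flat, so bait-normalized ratios trace the
    class trajectory.  PTM site intensities are generated as carrier protein
    intensity x occupancy trajectory x noise.  Requires >= 3 time points.
    """
    if len(config.timepoints) < 3:
        raise ValueError("need at least 3 time points for a time course")
    rng = np.random.default_rng((config.seed, 0x71))
    feats = _feature_frame(config, rng)
    annotation = _annotation(config, config.timepoints)
    sample_ids = annotation.sample_ids
    ann = annotation.table.set_index("sample_id")
    times = np.asarray(sorted(set(config.timepoints)), dtype=float)

    # assign profile classes to dynamic interactors (round-robin over classes)
    classes = list(config.profile_classes)
    int_idx = feats.index[feats["role"] == "true_interactor"]
    n_dynamic = int(round(config.dynamic_fraction * len(int_idx)))
    dynamic_ids = list(int_idx[:n_dynamic])
    for i, fid in enumerate(dynamic_ids):
        feats.loc[fid, "profile_class"] = classes[i % len(classes)]

    log2 = np.tile(feats["baseline_log2"].to_numpy()[:, None],
                   (1, len(sample_ids)))
    traj = {(fid, t): 0.0 for fid in feats.index for t in times}
    for fid in feats.index:
        cls = feats.loc[fid, "profile_class"]
        if cls != "flat":
            mod = _trajectory(cls, times, config.dynamic_amplitude)
            for t, m in zip(times, mod):
                traj[(fid, t)] = m
    for bait in annotation.bait_ids:
        owned = _owned_by(feats, bait)
        for sid in annotation.samples_for_bait(bait):
            j = sample_ids.index(sid)
            t = float(ann.loc[sid, "time_min"])
            log2[owned, j] += feats.loc[owned, "true_log2_effect"].to_numpy()
            log2[owned, j] += np.array(
                [traj[(fid, t)] for fid in feats.index[owned]])
    log2 = log2 + rng.normal(0.0, config.replicate_sd, log2.shape)
    linear = np.power(2.0, log2)
    intens = pd.DataFrame(linear, index=feats.index, columns=sample_ids)

    meta = pd.DataFrame({
        "gene_name": feats.index, "peptide_count": 5,
        "is_contaminant": False, "is_reverse": False,
        "only_identified_by_site": False,
    }, index=feats.index)
    table = ProteinQuantTable(meta=meta, intensities=intens)

    # PTM sites ride on their carrier protein's intensity
    ptm_rows, ptm_intens = [], []
    site_truth = []
    for b, bait in enumerate(annotation.bait_ids):
        carriers = [fid for fid in feats.index
                    if _owned_by(feats, bait)[feats.index.get_loc(fid)]
                    and feats.loc[fid, "role"] == "true_interactor"]
        for s in range(config.n_ptm_sites):
            carrier = carriers[s % len(carriers)] if carriers else bait
            cls = classes[s % len(classes)] if (
                s < round(config.dynamic_fraction * config.n_ptm_sites)) else "flat"
            pos = 10 * (s + 1)
            pep_id = f"PTM_{carrier}_S{pos}"
            mod = _trajectory(cls, times, config.dynamic_amplitude)
            occupancy_log2 = {t: -1.0 + m for t, m in zip(times, mod)}
            row_int = np.empty(len(sample_ids))
            for j, sid in enumerate(sample_ids):
                t = float(ann.loc[sid, "time_min"])
                noise = rng.normal(0.0, config.replicate_sd)
                row_int[j] = linear[feats.index.get_loc(carrier), j] * \
                    2.0 ** (occupancy_log2[t] + noise)
            ptm_rows.append({"peptide_id": pep_id, "protein_id": carrier,
                             "mod_type": "phospho", "site_position": pos,
                             "residue": "S"})
            ptm_intens.append(row_int)
            site_truth.append((f"{carrier}_phospho_{pos}", "ptm_site", bait,
                               0.0, cls))
    if ptm_rows:
        ptm_meta = pd.DataFrame(ptm_rows).set_index("peptide_id")
        ptm_table = ModifiedPeptideTable(
            meta=ptm_meta,
            intensities=pd.DataFrame(np.vstack(ptm_intens),
                                     index=ptm_meta.index, columns=sample_ids))
        extra = pd.DataFrame(site_truth, columns=[
            "protein_id", "role", "bait_id", "true_log2_effect",
            "profile_class"]).set_index("protein_id")
        extra["baseline_log2"] = np.nan
        feats = pd.concat([feats, extra])
    else:
        ptm_table = ModifiedPeptideTable(
            meta=pd.DataFrame(columns=["protein_id", "mod_type",
                                       "site_position", "residue"],
                              index=pd.Index([], name="peptide_id")),
            intensities=pd.DataFrame(columns=sample_ids,
                                     index=pd.Index([], name="peptide_id")))

    truth = SyntheticTruth(features=feats, pre_dropout=intens.copy())
    return table, ptm_table, annotation, truth
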