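"""Time-course quantification of dynamic interactions and modification sites.

Activation time courses are analysed on *ratios*, not raw intensities:

* prey (interactor) LFQ intensities are divided, per sample, by the LFQ
  intensity of the bait in that same pull-down — removing loading artifacts
  (a sample loaded at twice the amount scales bait and preys alike, so the
  ratio is untouched);
* modified-peptide intensities are divided by the intensity of the carrier
  protein, which converts site intensity into a relative-occupancy proxy and
  lowers the coefficient of variation.

No imputation is ever applied on the modification branch: a site must be
quantified in at least 3 replicates of at least one time point to enter the
analysis at all, and tests use observed values only.  Per activated time
point, each feature is compared to the untreated (time 0) condition with a
two-sided Student's t-test at per-test alpha = 0.05 (no multiplicity
correction across time points or features, by design).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .io_maxquant import ModifiedPeptideTable, SampleAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "normalize_prey_to_bait",
    "aggregate_sites",
    "normalize_ptm_to_protein",
    "timecourse_significance",
]


def normalize_prey_to_bait(linear_intensities: pd.DataFrame, bait_protein: str,
                           preys: list[str] | None = None) -> pd.DataFrame:
    """Divide each prey's linear LFQ intensity by the bait's, per sample.

    ``linear_intensities`` is features x samples on the raw (non-log) scale
    with NaN or 0 for missing.  A sample in which the bait itself was not
    quantified yields missing ratios for every prey in that sample (the
    count of such samples is logged).
    """
    if bait_protein not in linear_intensities.index:
        raise ValueError(f"bait protein {bait_protein!r} absent from the matrix")
    mat = linear_intensities.replace(0.0, np.nan)
    bait_row = mat.loc[bait_protein]
    n_flagged = int(bait_row.isna().sum())
    if n_flagged:
        logger.warning("bait %s unquantified in %d sample(s); prey ratios "
                       "there are missing", bait_protein, n_flagged)
    if preys is None:
        preys = [p for p in mat.index if p != bait_protein]
    return mat.loc[preys].div(bait_row, axis=1)


def aggregate_sites(mod_table: ModifiedPeptideTable) -> pd.DataFrame:
    """Sum peptide-level intensities per (protein, mod_type, position) site.

    Returns a sites x samples frame indexed by "protein_mod_position" ids,
    with 0 converted to NaN (not quantified).
    """
    intens = mod_table.intensities.replace(0.0, np.nan)
    key = (mod_table.meta["protein_id"] + "_" + mod_table.meta["mod_type"]
           + "_" + mod_table.meta["site_position"].astype(str))
    return intens.groupby(key.to_numpy()).sum(min_count=1)


def normalize_ptm_to_protein(mod_table: ModifiedPeptideTable,
                             protein_intensities: pd.DataFrame,
                             annotation: SampleAnnotation,
                             min_valid_per_timepoint: int = 3) -> pd.DataFrame:
    """Site intensity divided by the carrier protein's intensity, per sample.

    Sites whose protein has no row in ``protein_intensities`` are skipped
    with a warning.  Sites lacking ``min_valid_per_timepoint`` valid ratios
    in every time point are dropped.  Never imputes.
    """
    sites = aggregate_sites(mod_table)
    prot = protein_intensities.replace(0.0, np.nan)
    ratios = {}
    for site_id in sites.index:
        protein_id = site_id.rsplit("_", 2)[0]
        if protein_id not in prot.index:
            logger.warning("site %s skipped: protein %s not quantified",
                           site_id, protein_id)
            continue
        ratios[site_id] = sites.loc[site_id] / prot.loc[protein_id]
    if not ratios:
        return pd.DataFrame(columns=sites.columns)
    out = pd.DataFrame(ratios).T
    out = out[list(sites.columns)]

    keep = []
    for site_id in out.index:
        ok = False
        for t in annotation.timepoints:
            cols = [s for s in annotation.samples_at_time(t) if s in out.columns]
            if out.loc[site_id, cols].notna().sum() >= min_valid_per_timepoint:
                ok = True
                break
        if ok:
            keep.append(site_id)
    return out.loc[keep]


def timecourse_significance(normalized: pd.DataFrame,
                            annotation: SampleAnnotation,
                            alpha: float = 0.05, *,
                            log_ratios: bool = True,
                            min_valid: int = 2) -> pd.DataFrame:
    """Per-feature, per-activated-time-point t-test against time 0.

    ``normalized`` holds positive ratios (features x samples).  By default
    tests run on log2 ratios (symmetric around no-change); ``log_ratios=False``
    tests the raw ratios.  Time points with fewer than ``min_valid`` observed
    values in either group give p = NaN (untested).  No multiple-testing
    correction is applied.

    Returns a frame indexed by feature with one ``p_<t>min`` column per
    activated time point plus ``min_p`` and ``significant_any_time``.
    """
    t0_samples = [s for s in annotation.samples_at_time(0)
                  if s in normalized.columns]
    if not t0_samples:
        raise ValueError("no time-0 (untreated) samples in the annotation")
    activated = [t for t in annotation.timepoints if t != 0]
    data = np.log2(normalized) if log_ratios else normalized

    out = pd.DataFrame(index=normalized.index)
    for t in activated:
        cols = [s for s in annotation.samples_at_time(t) if s in data.columns]
        pvals = np.full(len(data), np.nan)
        for i, fid in enumerate(data.index):
            x = data.loc[fid, t0_samples].dropna().to_numpy(dtype=float)
            y = data.loc[fid, cols].dropna().to_numpy(dtype=float)
            if len(x) < min_valid or len(y) < min_valid:
                continue
            pvals[i] = sstats.ttest_ind(y, x, equal_var=True).pvalue
        out[f"p_{t:g}min"] = pvals
    pcols = list(out.columns)
    out["min_p"] = out[pcols].min(axis=1) if pcols else np.nan
    out["significant_any_time"] = out["min_p"] < alpha
    return out


def tidy_timecourse(normalized: pd.DataFrame, annotation: SampleAnnotation,
                    significance: pd.DataFrame, feature_kind: str) -> pd.DataFrame:
    """Long-format table (feature, kind, time, replicate, value, flags)."""
    ann = annotation.table.set_index("sample_id")
    rows = []
    for fid in normalized.index:
        for sid in normalized.columns:
            if sid not in ann.index:
                continue
            rows.append({
                "feature_id": fid,
                "feature_kind": feature_kind,
                "sample_id": sid,
                "time_min": ann.loc[sid, "time_min"],
                "replicate": ann.loc[sid, "replicate"],
                "normalized_value": normalized.loc[fid, sid],
                "significant_any_time": bool(
                    significance.loc[fid, "significant_any_time"])
                if fid in significance.index else False,
            })
    return pd.DataFrame(rows)
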