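"""Identification filtering, log2 transform and downshifted-Gaussian imputation.

The interactome workflow prepares the intensity matrix in four steps:

1. drop decoys, contaminants and site-only identifications, and require more
   than one razor+unique peptide;
2. log2-transform, converting 0 ("not quantified") to missing;
3. keep proteins quantified in more than 60% of the replicates of at least
   one bait cell line;
4. fill the remaining missing cells from a narrow Gaussian shifted below the
   per-sample detection limit (width 0.3, downshift 1.8, in units of the
   observed standard deviation of that sample).

Step 4 encodes the missing-not-at-random structure of label-free data:
values are absent mostly because they sit near the detection limit, so they
are replaced by plausibly-low draws rather than by the column average.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_maxquant import ProteinQuantTable, SampleAnnotation

__all__ = [
    "IntensityMatrix",
    "filter_identifications",
    "log2_transform",
    "filter_valid_values",
    "impute_missing",
]


@dataclass(frozen=True)
class IntensityMatrix:
    """Log2 intensity matrix (features x samples) with missingness bookkeeping.

    ``missing_mask`` flags cells that were not quantified in the raw data;
    ``imputed_mask`` flags the subset of those later filled by imputation.
    Cells missing and not imputed hold NaN.
    """

    values: pd.DataFrame = field(repr=False)
    missing_mask: pd.DataFrame = field(repr=False)
    imputed_mask: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        v, m, i = self.values, self.missing_mask, self.imputed_mask
        if not (v.index.equals(m.index) and v.index.equals(i.index)
                and v.columns.equals(m.columns) and v.columns.equals(i.columns)):
            raise ValueError("values and masks must share index and columns")
        if (i.to_numpy() & ~m.to_numpy()).any():
            raise ValueError("imputed_mask must be a subset of missing_mask")
        defined = ~m.to_numpy() | i.to_numpy()
        if not np.isfinite(v.to_numpy()[defined]).all():
            raise ValueError("observed or imputed cells must be finite")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def observed_mask(self) -> pd.DataFrame:
        """Cells quantified in the raw data (neither missing nor imputed)."""
        return ~self.missing_mask

    def subset_features(self, feature_ids) -> "IntensityMatrix":
        idx = self.values.index.intersection(feature_ids, sort=False)
        return IntensityMatrix(self.values.loc[idx], self.missing_mask.loc[idx],
                               self.imputed_mask.loc[idx])

    def subset_samples(self, sample_ids: list[str]) -> "IntensityMatrix":
        return IntensityMatrix(self.values[sample_ids],
                               self.missing_mask[sample_ids],
                               self.imputed_mask[sample_ids])


def filter_identifications(table: ProteinQuantTable,
                           min_peptides: int = 2) -> ProteinQuantTable:
    """Remove decoy, contaminant and site-only rows and low-evidence proteins.

    Keeps proteins identified with at least ``min_peptides`` razor+unique
    peptides (default 2, i.e. "more than one peptide"); survivor order is
    preserved.
    """
    m = table.meta
    keep = (~m["is_contaminant"] & ~m["is_reverse"]
            & ~m["only_identified_by_site"]
            & (m["peptide_count"] >= min_peptides))
    return ProteinQuantTable(meta=m[keep], intensities=table.intensities[keep.to_numpy()])


def log2_transform(table: ProteinQuantTable) -> IntensityMatrix:
    """Log2-transform raw LFQ intensities; 0 becomes missing (NaN)."""
    raw = table.intensities.to_numpy(dtype=float)
    if (raw < 0).any():
        raise ValueError("negative intensity cannot be log-transformed")
    missing = raw == 0
    with np.errstate(divide="ignore"):
        values = np.where(missing, np.nan, np.log2(np.where(missing, 1.0, raw)))
    idx, cols = table.intensities.index, table.intensities.columns
    return IntensityMatrix(
        values=pd.DataFrame(values, index=idx, columns=cols),
        missing_mask=pd.DataFrame(missing, index=idx, columns=cols),
        imputed_mask=pd.DataFrame(False, index=idx, columns=cols),
    )


def filter_valid_values(matrix: IntensityMatrix, annotation: SampleAnnotation,
                        group_by: str = "bait_id",
                        min_fraction: float = 0.6) -> IntensityMatrix:
    """Keep features quantified in more than ``min_fraction`` of the replicates
    of at least one group (strict inequality: 60% exactly is removed).

    Grouping defaults to the bait cell line; any annotation column works for
    other designs (e.g. group by time point in a time course).
    """
    ann = annotation.table.set_index("sample_id").loc[matrix.sample_ids]
    observed = ~matrix.missing_mask
    keep = pd.Series(False, index=matrix.values.index)
    for group, members in ann.groupby(group_by, sort=False).groups.items():
        samples = list(members)
        if len(samples) == 0:
            raise ValueError(f"group {group!r} has no samples")
        frac = observed[samples].mean(axis=1)
        keep |= frac > min_fraction
    return matrix.subset_features(matrix.values.index[keep])


def impute_missing(matrix: IntensityMatrix, width: float = 0.3,
                   downshift: float = 1.8, *, seed: int) -> IntensityMatrix:
    """Fill missing cells with draws from a downshifted Gaussian, per sample.

    For each sample (column) with observed mean ``m`` and standard deviation
    ``s``, missing cells are drawn independently from
    ``Normal(m - downshift*s, (width*s)**2)`` — a narrow distribution centred
    just below that sample's detection limit.  Observed cells are untouched;
    the same seed reproduces the matrix bit-exactly.
    """
    rng = np.random.default_rng(seed)
    values = matrix.values.to_numpy(dtype=float).copy()
    missing = matrix.missing_mask.to_numpy()
    imputed = matrix.imputed_mask.to_numpy().copy()
    for j, sample in enumerate(matrix.sample_ids):
        obs = values[~missing[:, j], j]
        fill = missing[:, j] & ~imputed[:, j]
        if not fill.any():
            continue
        if obs.size < 2:
            raise ValueError(
                f"sample {sample!r} has fewer than 2 observed values; "
                "cannot estimate its detection limit")
        m, s = obs.mean(), obs.std(ddof=1)
        values[fill, j] = rng.normal(m - downshift * s, width * s, fill.sum())
        imputed[fill, j] = True
    idx, cols = matrix.values.index, matrix.values.columns
    return IntensityMatrix(
        values=pd.DataFrame(values, index=idx, columns=cols),
        missing_mask=matrix.missing_mask.copy(),
        imputed_mask=pd.DataFrame(imputed, index=idx, columns=cols),
    )
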