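import numpy as np
import pandas as pd
import pytest

from apmskit.io_maxquant import ProteinQuantTable, SampleAnnotation
from apmskit.preprocess import IntensityMatrix


@pytest.fixture
def annotation_4x4() -> SampleAnnotation:
    """Two baits x four replicates, single time point."""
    rows = []
    for bait in ("BAITA", "BAITB"):
        for r in range(1, 5):
            rows.append({"sample_id": f"{bait}_r{r}", "bait_id": bait,
                         "condition": "untreated", "time_min": 0.0,
                         "replicate": r})
    return SampleAnnotation(pd.DataFrame(rows))


@pytest.fixture
def timecourse_annotation() -> SampleAnnotation:
    """One bait, four time points (0/5/15/30 min), four replicates."""
    rows = []
    for t in (0.0, 5.0, 15.0, 30.0):
        for r in range(1, 5):
            rows.append({"sample_id": f"B_t{t:g}_r{r}", "bait_id": "B",
                         "condition": "activated" if t else "untreated",
                         "time_min": t, "replicate": r})
    return SampleAnnotation(pd.DataFrame(rows))


def make_table(values: np.ndarray, annotation: SampleAnnotation,
               protein_ids=None, **meta_overrides) -> ProteinQuantTable:
    """Linear-scale quant table from a dense array (no missing values)."""
    values = np.asarray(values, dtype=float)
    ids = protein_ids or [f"P{i + 1}" for i in range(values.shape[0])]
    meta = pd.DataFrame({
        "gene_name": ids,
        "peptide_count": meta_overrides.get("peptide_count", 5),
        "is_contaminant": meta_overrides.get("is_contaminant", False),
        "is_reverse": meta_overrides.get("is_reverse", False),
        "only_identified_by_site": meta_overrides.get(
            "only_identified_by_site", False),
    }, index=pd.Index(ids, name="protein_id"))
    intens = pd.DataFrame(values, index=meta.index,
                          columns=annotation.sample_ids)
    return ProteinQuantTable(meta=meta, intensities=intens)


def make_matrix(log2_values: np.ndarray, sample_ids, feature_ids=None,
                observed_mask=None) -> IntensityMatrix:
    """IntensityMatrix from a log2 array; NaN cells are missing-unimputed
    unless listed in ``observed_mask`` (True = observed)."""
    arr = np.asarray(log2_values, dtype=float)
    fids = feature_ids or [f"P{i + 1}" for i in range(arr.shape[0])]
    idx = pd.Index(fids, name="protein_id")
    missing = (np.isnan(arr) if observed_mask is None
               else ~np.asarray(observed_mask, dtype=bool))
    # finite cells flagged as not-observed count as imputed pseudo-data
    imputed = missing & ~np.isnan(arr)
    return IntensityMatrix(
        values=pd.DataFrame(arr, index=idx, columns=list(sample_ids)),
        missing_mask=pd.DataFrame(missing, index=idx, columns=list(sample_ids)),
        imputed_mask=pd.DataFrame(np.asarray(imputed, dtype=bool), index=idx,
                                  columns=list(sample_ids)),
    )
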