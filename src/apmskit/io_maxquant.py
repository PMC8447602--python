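"""Readers and writers for MaxQuant-style quantification tables.

The pipeline consumes three tab-separated inputs:

* a ``proteinGroups``-style table with per-sample LFQ intensities,
* modification-specific site tables (phospho/acetyl/methyl/...) with
  per-sample intensities, and
* a sample annotation mapping each measured sample to its bait, condition,
  activation time point and replicate.

A raw intensity of 0 encodes "not quantified" (the MaxQuant convention);
readers preserve the 0 and the preprocessing stage converts it to missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "SampleAnnotation",
    "ProteinQuantTable",
    "ModifiedPeptideTable",
    "read_sample_annotation",
    "read_protein_groups",
    "read_modified_peptide_sites",
    "write_protein_groups",
]


class FormatError(ValueError):
    """Raised when an input table violates the expected dialect."""


_TRUE_MARKS = {"+", "true", "True", "TRUE", "yes", "1"}

ANNOTATION_COLUMNS = ["sample_id", "bait_id", "condition", "time_min", "replicate"]


@dataclass(frozen=True)
class SampleAnnotation:
    """Experimental design: one row per measured sample.

    Columns: ``sample_id``, ``bait_id`` (tagged bait, or ``control``),
    ``condition``, ``time_min`` (minutes after activation; 0 = untreated),
    ``replicate`` (positive integer) and optional ``control_group``.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in ANNOTATION_COLUMNS if c not in t.columns]
        if missing:
            raise FormatError(f"annotation missing columns: {missing}")
        if t["sample_id"].duplicated().any():
            dups = sorted(t.loc[t["sample_id"].duplicated(), "sample_id"])
            raise FormatError(f"duplicate sample_id values: {dups}")
        if not pd.api.types.is_numeric_dtype(t["time_min"]):
            raise FormatError("time_min must be numeric (minutes)")
        if (t["time_min"] < 0).any():
            raise FormatError("time_min must be non-negative")
        if (t["replicate"] < 1).any():
            raise FormatError("replicate indices must be positive")
        cell = ["bait_id", "condition", "time_min"]
        if t.duplicated(subset=cell + ["replicate"]).any():
            raise FormatError("replicate indices must be unique within a "
                              "(bait_id, condition, time_min) cell")
        if "control_group" not in t.columns:
            object.__setattr__(
                self, "table", t.assign(control_group=pd.NA))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def bait_ids(self) -> list[str]:
        """Distinct bait identifiers, in order of first appearance."""
        return list(dict.fromkeys(self.table["bait_id"]))

    @property
    def timepoints(self) -> list[float]:
        return sorted(set(self.table["time_min"]))

    def samples_for_bait(self, bait_id: str) -> list[str]:
        t = self.table
        return list(t.loc[t["bait_id"] == bait_id, "sample_id"])

    def samples_at_time(self, time_min: float) -> list[str]:
        t = self.table
        return list(t.loc[t["time_min"] == time_min, "sample_id"])

    def subset(self, sample_ids: list[str]) -> "SampleAnnotation":
        t = self.table
        return SampleAnnotation(
            t[t["sample_id"].isin(set(sample_ids))].reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.table)


@dataclass(frozen=True)
class ProteinQuantTable:
    """Per-protein identification metadata plus raw per-sample LFQ intensities.

    ``meta`` is indexed by ``protein_id`` and carries ``gene_name``,
    ``peptide_count`` (razor + unique) and the ``is_contaminant``,
    ``is_reverse`` and ``only_identified_by_site`` flags.  ``intensities``
    shares the index and has exactly the annotation's sample columns, in
    annotation order; 0 means not quantified.
    """

    meta: pd.DataFrame = field(repr=False)
    intensities: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.meta.index.duplicated().any():
            dups = sorted(self.meta.index[self.meta.index.duplicated()])
            raise FormatError(f"duplicate protein_id values: {dups}")
        if not self.meta.index.equals(self.intensities.index):
            raise FormatError("meta and intensity indices differ")
        if (self.intensities.to_numpy() < 0).any():
            raise FormatError("negative LFQ intensity encountered")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.meta.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.columns)

    def __len__(self) -> int:
        return len(self.meta)


@dataclass(frozen=True)
class ModifiedPeptideTable:
    """Modification-specific peptide/site intensities.

    One row per quantified modified peptide; several rows may map to the
    same site ``(protein_id, mod_type, site_position)`` and are aggregated
    downstream.  ``intensities`` shares the ``peptide_id`` index.
    """

    meta: pd.DataFrame = field(repr=False)
    intensities: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = ["protein_id", "mod_type", "site_position", "residue"]
        missing = [c for c in required if c not in self.meta.columns]
        if missing:
            raise FormatError(f"modified peptide table missing: {missing}")
        if (self.meta["site_position"] < 1).any():
            raise FormatError("site_position must be >= 1 (1-based)")
        if not self.meta.index.equals(self.intensities.index):
            raise FormatError("meta and intensity indices differ")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.columns)

    def __len__(self) -> int:
        return len(self.meta)


def read_sample_annotation(path) -> SampleAnnotation:
    """Read a tab-separated sample annotation table."""
    table = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "bait_id": str})
    try:
        table["time_min"] = pd.to_numeric(table["time_min"])
        table["replicate"] = pd.to_numeric(table["replicate"], downcast=None)
    except (ValueError, KeyError) as exc:
        raise FormatError(f"annotation has non-numeric time/replicate: {exc}")
    return SampleAnnotation(table.reset_index(drop=True))


def _parse_flag(series: pd.Series) -> pd.Series:
    """Accept MaxQuant '+' marks as well as boolean literals."""
    return series.astype(str).str.strip().isin(_TRUE_MARKS)


def _intensity_columns(header: list[str], annotation: SampleAnnotation,
                       prefix: str) -> dict[str, str]:
    """Map sample_id -> column name, trying the prefixed form first."""
    mapping: dict[str, str] = {}
    absent: list[str] = []
    for sid in annotation.sample_ids:
        prefixed = f"{prefix}{sid}"
        if prefixed in header:
            mapping[sid] = prefixed
        elif sid in header:
            mapping[sid] = sid
        else:
            absent.append(sid)
    if absent:
        raise FormatError(
            f"annotation samples absent from table header: {absent}")
    return mapping


def read_protein_groups(path, annotation: SampleAnnotation, *,
                        intensity_prefix: str = "LFQ intensity ",
                        contaminant_prefix: str = "CON__",
                        reverse_prefix: str = "REV__") -> ProteinQuantTable:
    """Read a MaxQuant proteinGroups-style TSV.

    Intensity columns may be named ``"LFQ intensity <sample_id>"`` or plainly
    ``<sample_id>``.  Flags are taken from the ``Reverse``,
    ``Potential contaminant`` and ``Only identified by site`` columns when
    present, and additionally inferred from ``CON__``/``REV__`` id prefixes.
    Unknown columns are ignored.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    id_col = _first_present(raw, ["protein_id", "Protein IDs", "Majority protein IDs"])
    if id_col is None:
        raise FormatError("missing required column: protein_id / 'Protein IDs'")
    # leading id of the protein group, exact case-sensitive match downstream
    protein_id = raw[id_col].str.split(";").str[0]
    gene_col = _first_present(raw, ["gene_name", "Gene names"])
    genes = raw[gene_col].str.split(";").str[0] if gene_col else protein_id
    pep_col = _first_present(
        raw, ["peptide_count", "Razor + unique peptides", "Peptides"])
    if pep_col is None:
        raise FormatError("missing required column: peptide_count / "
                          "'Razor + unique peptides'")
    peptide_count = pd.to_numeric(raw[pep_col]).astype(int)

    def flag(names: list[str], prefix: str | None) -> pd.Series:
        col = _first_present(raw, names)
        out = _parse_flag(raw[col]) if col else pd.Series(False, index=raw.index)
        if prefix:
            out = out | raw[id_col].str.startswith(prefix)
        return out

    meta = pd.DataFrame({
        "gene_name": genes.fillna(""),
        "peptide_count": peptide_count,
        "is_contaminant": flag(["is_contaminant", "Potential contaminant",
                                "Contaminant"], contaminant_prefix),
        "is_reverse": flag(["is_reverse", "Reverse"], reverse_prefix),
        "only_identified_by_site": flag(
            ["only_identified_by_site", "Only identified by site"], None),
    })
    meta.index = pd.Index(protein_id, name="protein_id")

    colmap = _intensity_columns(list(raw.columns), annotation, intensity_prefix)
    intens = pd.DataFrame(
        {sid: pd.to_numeric(raw[col]).fillna(0.0).to_numpy(dtype=float)
         for sid, col in colmap.items()},
        index=meta.index)
    # never reorder samples relative to the annotation
    intens = intens[annotation.sample_ids]
    return ProteinQuantTable(meta=meta, intensities=intens)


def read_modified_peptide_sites(path, annotation: SampleAnnotation,
                                mod_type: str, *,
                                intensity_prefix: str = "Intensity ") -> ModifiedPeptideTable:
    """Read a MaxQuant modification-site-style TSV.

    Rows with an empty/unparseable position are rejected with a row-level
    warning rather than silently dropped.  Duplicate (protein, position)
    rows are kept; site-level aggregation happens downstream.

    The reader expects site-table (not evidence-level) quantification; if
    your workflow exported evidence-level peptides, aggregate them to sites
    first.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    prot_col = _first_present(raw, ["protein_id", "Protein", "Proteins"])
    pos_col = _first_present(raw, ["site_position", "Position", "Positions within proteins"])
    if prot_col is None or pos_col is None:
        missing = "protein_id / 'Protein'" if prot_col is None else "site_position / 'Position'"
        raise FormatError(f"missing required column: {missing}")
    pos = pd.to_numeric(raw[pos_col], errors="coerce")
    bad = pos.isna() | (pos < 1)
    for i in raw.index[bad]:
        logger.warning("row %d of %s rejected: empty or invalid site position", i, path)
    raw = raw[~bad]
    pos = pos[~bad].astype(int)

    res_col = _first_present(raw, ["residue", "Amino acid"])
    pep_col = _first_present(raw, ["peptide_id", "id"])
    peptide_id = (raw[pep_col] if pep_col else
                  raw[prot_col].str.split(";").str[0] + "_" + pos.astype(str))
    meta = pd.DataFrame({
        "protein_id": raw[prot_col].str.split(";").str[0].to_numpy(),
        "mod_type": mod_type,
        "site_position": pos.to_numpy(),
        "residue": (raw[res_col].to_numpy() if res_col else "X"),
    }, index=pd.Index(peptide_id, name="peptide_id"))

    colmap = _intensity_columns(list(raw.columns), annotation, intensity_prefix)
    intens = pd.DataFrame(
        {sid: pd.to_numeric(raw[col]).fillna(0.0).to_numpy(dtype=float)
         for sid, col in colmap.items()},
        index=meta.index)[annotation.sample_ids]
    return ModifiedPeptideTable(meta=meta, intensities=intens)


def write_protein_groups(table: ProteinQuantTable, path) -> None:
    """Write a ProteinQuantTable as TSV in the dialect ``read_protein_groups``
    accepts, with full float precision (round-trips bit-exactly)."""
    out = table.meta.copy()
    for sid in table.sample_ids:
        out[sid] = table.intensities[sid]
    out.reset_index().to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_sample_annotation(annotation: SampleAnnotation, path) -> None:
    annotation.table.to_csv(path, sep="\t", index=False)


def write_modified_peptide_sites(table: ModifiedPeptideTable, path) -> None:
    out = table.meta.copy()
    for sid in table.sample_ids:
        out[sid] = table.intensities[sid]
    out.reset_index().to_csv(path, sep="\t", index=False, float_format="%.17g")


def _first_present(frame: pd.DataFrame, names: list[str]) -> str | None:
    for name in names:
        if name in frame.columns:
            return name
    return None
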