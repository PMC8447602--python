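"""End-to-end orchestration of the interactome and dynamics workflows.

A run is described by a :class:`PipelineConfig` (built directly or loaded
from YAML).  Outputs are plain TSV tables plus a JSON manifest recording
every stage parameter, the global seed and SHA-256 checksums of the inputs,
so a run can be reproduced bit-exactly from the manifest alone.  The single
global seed is fanned out to per-stage child seeds by a fixed derivation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import build_zscored_profiles, cluster_profiles, summarize_cluster
from .dynamics import (normalize_prey_to_bait, normalize_ptm_to_protein,
                       timecourse_significance)
from .interactors import build_control_groups, call_bait
from .io_maxquant import (SampleAnnotation, read_modified_peptide_sites,
                          read_protein_groups, read_sample_annotation)
from .network import (annotate_known, build_network, read_known_pairs,
                      write_edge_list, write_graphml)
from .preprocess import (filter_identifications, filter_valid_values,
                         impute_missing, log2_transform)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_interactome", "run_dynamics"]

# fixed per-stage offsets for deriving child seeds from the global seed
_STAGE_SEEDS = {"impute": 11, "permute": 23, "cluster_ci": 37}


def child_seed(global_seed: int, stage: str, index: int = 0) -> int:
    return (global_seed * 1_000_003 + _STAGE_SEEDS[stage] * 101 + index) % (2**31)


@dataclass
class PipelineConfig:
    """Paths and stage parameters of one pipeline run."""

    protein_groups: str
    annotation: str
    output_dir: str
    sites_tables: dict[str, str] = field(default_factory=dict)  # mod_type -> path
    known_pairs: str | None = None
    seed: int = 0
    min_peptides: int = 2
    min_valid_fraction: float = 0.6
    impute_width: float = 0.3
    impute_downshift: float = 1.8
    n_control_groups: int | str = "auto"
    fdr: float = 0.01
    enrichment: float = 2.0
    min_valid: int = 10
    n_permutations: int = 250
    k_clusters: int = 7
    profile_min_valid_fraction: float = 0.7
    alpha: float = 0.05
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def validate_paths(self, require_sites: bool = False) -> None:
        for label, p in [("protein_groups", self.protein_groups),
                         ("annotation", self.annotation)]:
            if not Path(p).exists():
                raise FileNotFoundError(f"{label} path does not exist: {p}")
        if self.known_pairs and not Path(self.known_pairs).exists():
            raise FileNotFoundError(f"known_pairs path does not exist: "
                                    f"{self.known_pairs}")
        for mod, p in self.sites_tables.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"sites table ({mod}) does not exist: {p}")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(config: PipelineConfig, outdir: Path, stages: list[str]) -> None:
    manifest = {
        "apmskit_version": __version__,
        "parameters": asdict(config),
        "stages": stages,
        "input_checksums": {
            "protein_groups": _sha256(config.protein_groups),
            "annotation": _sha256(config.annotation),
            **{f"sites:{m}": _sha256(p)
               for m, p in config.sites_tables.items()},
        },
    }
    if config.known_pairs:
        manifest["input_checksums"]["known_pairs"] = _sha256(config.known_pairs)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     sort_keys=True) + "\n")


def _prepare_matrix(config: PipelineConfig):
    annotation = read_sample_annotation(config.annotation)
    table = read_protein_groups(config.protein_groups, annotation)
    table = filter_identifications(table, min_peptides=config.min_peptides)
    matrix = log2_transform(table)
    matrix = filter_valid_values(matrix, annotation,
                                 min_fraction=config.min_valid_fraction)
    imputed = impute_missing(matrix, width=config.impute_width,
                             downshift=config.impute_downshift,
                             seed=child_seed(config.seed, "impute"))
    return table, annotation, imputed


def run_interactome(config: PipelineConfig) -> Path:
    """Filter -> impute -> control groups -> per-bait calling -> network.

    Writes the filtered/imputed matrix, control-group assignment, one
    volcano table per bait, the significant-interactor table, the network
    (GraphML + edge list) and the run manifest.  Any stage error aborts with
    the stage name and cause.
    """
    config.validate_paths()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "read/preprocess"
    try:
        table, annotation, matrix = _prepare_matrix(config)
        matrix.values.to_csv(outdir / "imputed_matrix.tsv", sep="\t",
                             float_format="%.17g")

        stage = "control_groups"
        groups = build_control_groups(matrix, annotation,
                                      n_groups=config.n_control_groups)
        pd.DataFrame([(g, s) for g, ms in groups.groups.items() for s in ms],
                     columns=["group_id", "sample_id"]).to_csv(
            outdir / "control_groups.tsv", sep="\t", index=False)

        stage = "interactor_calling"
        calls: dict[str, pd.DataFrame] = {}
        for i, bait in enumerate(annotation.bait_ids):
            result = call_bait(
                matrix, annotation, bait, groups, fdr=config.fdr,
                enrichment=config.enrichment, min_valid=config.min_valid,
                n_permutations=config.n_permutations,
                seed=child_seed(config.seed, "permute", i))
            result.to_csv(outdir / f"volcano_{bait}.tsv", sep="\t",
                          index=False, float_format="%.17g")
            calls[bait] = result
        significant = pd.concat([c[c["significant"]] for c in calls.values()],
                                ignore_index=True)
        significant.to_csv(outdir / "significant_interactors.tsv", sep="\t",
                           index=False, float_format="%.17g")

        stage = "network"
        net = build_network(calls)
        if config.known_pairs:
            net = annotate_known(net, read_known_pairs(config.known_pairs))
        write_edge_list(net, outdir / "network_edges.tsv")
        write_graphml(net, outdir / "network.graphml")
    except Exception as exc:
        raise RuntimeError(f"interactome pipeline failed at stage "
                           f"{stage!r}: {exc}") from exc
    _write_manifest(config, outdir,
                    ["read/preprocess", "control_groups",
                     "interactor_calling", "network"])
    return outdir


def run_dynamics(config: PipelineConfig,
                 interactors: dict[str, list[str]] | None = None) -> Path:
    """Bait-normalized PPI and protein-normalized PTM time-course analysis.

    ``interactors`` maps bait_id to the prey ids to follow over time; if
    omitted, all non-bait proteins are followed.  Writes normalized ratio
    tables, per-time-point significance, z-scored profiles, cluster
    assignments and per-cluster summaries.  PTM branch runs only for the
    configured sites tables (a missing table downgrades to a PPI-only run
    with a warning).
    """
    config.validate_paths()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "read"
    try:
        annotation = read_sample_annotation(config.annotation)
        table = read_protein_groups(config.protein_groups, annotation)
        table = filter_identifications(table, min_peptides=config.min_peptides)
        linear = table.intensities

        stage = "normalize_ppi"
        baits = (list(interactors) if interactors
                 else [b for b in annotation.bait_ids
                       if b in set(linear.index)])
        ratio_frames = []
        for bait in baits:
            preys = (interactors.get(bait) if interactors else None)
            sub = annotation.subset(annotation.samples_for_bait(bait))
            ratios = normalize_prey_to_bait(
                linear[sub.sample_ids], bait, preys)
            ratios.index = [f"{bait}:{p}" for p in ratios.index]
            ratio_frames.append((bait, sub, ratios))

        stage = "normalize_ptm"
        ptm_ratios = None
        if config.sites_tables:
            frames = []
            for mod, path in config.sites_tables.items():
                sites = read_modified_peptide_sites(path, annotation, mod)
                frames.append(normalize_ptm_to_protein(sites, linear, annotation))
            ptm_ratios = pd.concat(frames) if frames else None
        else:
            logger.warning("no PTM sites table supplied; PPI-only run")

        stage = "significance"
        sig_frames, profile_frames = [], []
        for bait, sub, ratios in ratio_frames:
            sig = timecourse_significance(ratios, sub, alpha=config.alpha)
            sig.insert(0, "feature_kind", "PPI")
            sig_frames.append(sig)
            profile_frames.append(build_zscored_profiles(
                ratios, sub, min_valid_fraction=config.profile_min_valid_fraction))
        if ptm_ratios is not None and len(ptm_ratios):
            sig = timecourse_significance(ptm_ratios, annotation,
                                          alpha=config.alpha)
            sig.insert(0, "feature_kind", "PTM")
            sig_frames.append(sig)
            profile_frames.append(build_zscored_profiles(
                ptm_ratios, annotation,
                min_valid_fraction=config.profile_min_valid_fraction))
        significance = pd.concat(sig_frames)
        significance.to_csv(outdir / "timecourse_significance.tsv", sep="\t",
                            float_format="%.17g")

        stage = "clustering"
        profiles = pd.concat(profile_frames)
        profiles.to_csv(outdir / "z_profiles.tsv", sep="\t",
                        float_format="%.17g")
        k = min(config.k_clusters, max(2, len(profiles) - 1))
        assignment = cluster_profiles(profiles, k=k)
        assignment.rename("cluster").to_frame().to_csv(
            outdir / "cluster_assignment.tsv", sep="\t")
        summaries = []
        for label in sorted(assignment.unique()):
            s = summarize_cluster(profiles, assignment, label,
                                  seed=child_seed(config.seed, "cluster_ci",
                                                  label))
            s.insert(0, "cluster", label)
            summaries.append(s)
        pd.concat(summaries, ignore_index=True).to_csv(
            outdir / "cluster_summaries.tsv", sep="\t", index=False,
            float_format="%.17g")
    except Exception as exc:
        raise RuntimeError(f"dynamics pipeline failed at stage {stage!r}: "
                           f"{exc}") from exc
    _write_manifest(config, outdir, ["read", "normalize_ppi", "normalize_ptm",
                                     "significance", "clustering"])
    return outdir
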