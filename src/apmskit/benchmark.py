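"""Ground-truth benchmarks of the calling procedure on synthetic data.

These routines generate data with :mod:`apmskit.simulate`, run the complete
interactome workflow, and score the calls against the generator's truth
table.  They are the package's evidence that the permutation-FDR procedure
controls the false-discovery proportion and recovers spiked interactors at
realistic effect sizes.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .interactors import build_control_groups, call_bait
from .preprocess import (filter_identifications, filter_valid_values,
                         impute_missing, log2_transform)
from .simulate import (SimulationConfig, apply_mnar_missingness,
                       generate_apms_dataset)

__all__ = ["run_calling_on_truth", "fdr_benchmark", "imputation_benchmark"]


def run_calling_on_truth(config: SimulationConfig, *, fdr: float = 0.01,
                         enrichment: float = 2.0, min_valid: int = 3,
                         n_permutations: int = 250, dropout: bool = True,
                         n_groups: int | str = 1) -> dict:
    """Generate one dataset, call interactors for every bait, score vs truth.

    ``min_valid`` defaults to 3 observed values out of 4 bait replicates —
    the analogue, for a 4-replicate design, of requiring most of the bait
    group to be genuinely observed.  The bait's own row is excluded from
    scoring: its self-enrichment is real, so recovering it is neither a true
    nor a false interactor call.

    Returns counts (true/false positives, called, truth size), the
    false-discovery proportion and recall, plus the per-bait call tables.
    """
    table, annotation, truth = generate_apms_dataset(config)
    if dropout:
        table, truth = apply_mnar_missingness(table, config, truth)
    table = filter_identifications(table)
    matrix = log2_transform(table)
    matrix = filter_valid_values(matrix, annotation)
    matrix = impute_missing(matrix, seed=(config.seed * 2 + 1) % (2**31))
    groups = build_control_groups(matrix, annotation, n_groups=n_groups)

    tp = fp = called = truth_total = 0
    calls: dict[str, pd.DataFrame] = {}
    for i, bait in enumerate(annotation.bait_ids):
        result = call_bait(matrix, annotation, bait, groups, fdr=fdr,
                           enrichment=enrichment, min_valid=min_valid,
                           n_permutations=n_permutations,
                           seed=(config.seed * 131 + i) % (2**31))
        calls[bait] = result
        true_set = truth.interactors_of(bait)
        truth_total += len(true_set)
        picked = set(result.loc[result["significant"], "protein_id"]) - {bait}
        called += len(picked)
        tp += len(picked & true_set)
        fp += len(picked - true_set)
    return {
        "true_positives": tp, "false_positives": fp, "called": called,
        "truth_total": truth_total,
        "fdp": fp / called if called else 0.0,
        "recall": tp / truth_total if truth_total else 1.0,
        "calls": calls, "truth": truth,
    }


def fdr_benchmark(config: SimulationConfig, n_seeds: int = 20, *,
                  fdr: float = 0.01, enrichment: float = 2.0,
                  min_valid: int = 3, n_permutations: int = 250,
                  dropout: bool = True, base_seed: int = 0) -> dict:
    """Mean false-discovery proportion and recall over ``n_seeds`` datasets.

    With ``dropout=True`` the full MNAR + imputation pipeline runs; with
    ``dropout=False`` the benchmark isolates the test's power under
    replicate noise alone (no missing cells, imputation is a no-op).
    """
    fdps, recalls = [], []
    for s in range(n_seeds):
        res = run_calling_on_truth(
            replace(config, seed=(base_seed * 7919 + s) % (2**31)),
            fdr=fdr, enrichment=enrichment, min_valid=min_valid,
            n_permutations=n_permutations, dropout=dropout)
        fdps.append(res["fdp"])
        recalls.append(res["recall"])
    return {"mean_fdp": float(np.mean(fdps)),
            "mean_recall": float(np.mean(recalls)),
            "fdp_per_seed": fdps, "recall_per_seed": recalls}


def imputation_benchmark(n_observed: int = 100_000, n_missing: int = 100_000,
                         mean: float = 25.0, sd: float = 2.0, *,
                         width: float = 0.3, downshift: float = 1.8,
                         seed: int = 0) -> dict:
    """Measure the realised downshift and width of the imputation Gaussian.

    Builds one column with ``n_observed`` observed log2 values drawn from
    Normal(mean, sd^2) and ``n_missing`` missing cells, imputes, and reports
    the shift of the imputed mean below the observed mean in units of the
    observed standard deviation, and the ratio of imputed to observed
    standard deviation.
    """
    from .preprocess import IntensityMatrix  # local import avoids cycle at doc build

    rng = np.random.default_rng(seed)
    observed = rng.normal(mean, sd, n_observed)
    values = np.concatenate([observed, np.full(n_missing, np.nan)])
    n = values.size
    idx = pd.Index([f"f{i}" for i in range(n)])
    matrix = IntensityMatrix(
        values=pd.DataFrame({"s1": values}, index=idx),
        missing_mask=pd.DataFrame({"s1": np.isnan(values)}, index=idx),
        imputed_mask=pd.DataFrame({"s1": False}, index=idx),
    )
    out = impute_missing(matrix, width=width, downshift=downshift,
                         seed=(seed + 1) % (2**31))
    imp = out.values.to_numpy()[out.imputed_mask.to_numpy()]
    obs_mean, obs_sd = observed.mean(), observed.std(ddof=1)
    return {
        "downshift_in_sd_units": float((obs_mean - imp.mean()) / obs_sd),
        "width_ratio": float(imp.std(ddof=1) / obs_sd),
        "n_imputed": int(imp.size),
    }
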