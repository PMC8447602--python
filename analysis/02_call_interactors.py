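#!/usr/bin/env python
"""Call interactors on the simulated dataset and score against the truth.

Runs the complete interactome workflow (identification filtering, log2
transform, valid-value filtering, downshifted-Gaussian imputation, control
grouping, bait-vs-complement t-tests with permutation FDR at 250
randomizations, q < 0.01 and fold enrichment > 2) via the pipeline
orchestrator, then compares the called set with the generator's truth.

Requires 01_simulate_apms.py to have run first.  min_valid is 3 of the 4
bait replicates here; see docs/methods.md for the rationale.
"""

import sys
from pathlib import Path

import pandas as pd

from apmskit.pipeline import PipelineConfig, run_interactome

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    sim = ROOT / "simulated"
    if not (sim / "protein_groups.tsv").exists():
        raise SystemExit("run analysis/01_simulate_apms.py first")
    config = PipelineConfig(
        protein_groups=str(sim / "protein_groups.tsv"),
        annotation=str(sim / "annotation.tsv"),
        output_dir=str(ROOT / "interactome"),
        seed=SEED, n_control_groups=1, min_valid=3)
    outdir = run_interactome(config)

    truth = pd.read_csv(sim / "truth.tsv", sep="\t").set_index("protein_id")
    sig = pd.read_csv(outdir / "significant_interactors.tsv", sep="\t")
    baits = set(truth.index[truth["role"] == "bait"])
    called = sig[~sig["protein_id"].isin(baits)]
    tp = sum(truth.loc[p, "role"] == "true_interactor"
             and b in str(truth.loc[p, "bait_id"]).split(";")
             for b, p in zip(called["bait_id"], called["protein_id"]))
    n_true = int((truth["role"] == "true_interactor").sum())
    print(f"called {len(called)} bait-prey pairs across "
          f"{sig['bait_id'].nunique()} baits")
    print(f"true positives {tp}, false positives {len(called) - tp} "
          f"(FDP {(len(called) - tp) / max(len(called), 1):.3f}); "
          f"recall {tp / n_true:.3f} of {n_true} spiked interactors")
    print(f"volcano tables and network in {outdir}")


if __name__ == "__main__":
    main()
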