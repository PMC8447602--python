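#!/usr/bin/env python
"""Assemble the multi-bait interaction network and annotate known preys.

Reads the per-bait volcano tables written by 02_call_interactors.py,
builds the merged bait-prey graph (shared preys connect pull-down
experiments), and annotates preys as known vs novel against a small
synthetic reference list constructed here from a subset of the generator's
truth (standing in for an offline export of a published-interaction
database).  Writes GraphML + edge list under results/network/.
"""

from pathlib import Path

import pandas as pd

from apmskit.network import (annotate_known, build_network, read_known_pairs,
                             write_edge_list, write_graphml)

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    interactome = ROOT / "interactome"
    volcanoes = sorted(interactome.glob("volcano_*.tsv"))
    if not volcanoes:
        raise SystemExit("run analysis/02_call_interactors.py first")
    calls = {p.stem.replace("volcano_", ""): pd.read_csv(p, sep="\t")
             for p in volcanoes}

    outdir = ROOT / "network"
    outdir.mkdir(parents=True, exist_ok=True)
    # synthetic known-interaction list: every second true pair of the truth
    truth = pd.read_csv(ROOT / "simulated" / "truth.tsv", sep="\t")
    known = truth[truth["role"] == "true_interactor"].iloc[::2]
    known_path = outdir / "known_pairs_synthetic.tsv"
    with open(known_path, "w") as fh:
        fh.write("# synthetic reference list from generator truth\n")
        for _, row in known.iterrows():
            for bait in str(row["bait_id"]).split(";"):
                fh.write(f"{bait}\t{row['protein_id']}\n")

    net = build_network(calls)
    net = annotate_known(net, read_known_pairs(known_path))
    write_edge_list(net, outdir / "edges.tsv")
    write_graphml(net, outdir / "network.graphml")

    novelty = pd.Series({n: d["novelty"] for n, d in net.nodes(data=True)})
    shared = [n for n, deg in net.degree if novelty[n] != "bait" and deg > 1]
    print(f"network: {net.number_of_nodes()} nodes, "
          f"{net.number_of_edges()} edges")
    print("prey novelty:", novelty[novelty != "bait"].value_counts().to_dict())
    print(f"{len(shared)} preys shared between baits")
    print(f"graph files in {outdir}")


if __name__ == "__main__":
    main()
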