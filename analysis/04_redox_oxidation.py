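#!/usr/bin/env python
"""Cysteine oxidation percentages and the DDW-vs-control redox contrast.

Computes peptide- and protein-level Ox% from the paired iodoTMT channels,
keeps complete cases (all replicates of all conditions quantified), writes
average oxidation per condition, and contrasts DDW against the NW control
in a volcano (mean Ox% ratio vs two-tailed unpaired t test).
"""

from pathlib import Path

import pandas as pd

from mstriad import redox as rx
from mstriad.quantio import read_design

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"
OUT = ROOT / "results" / "redox"
OUT.mkdir(parents=True, exist_ok=True)


def main() -> None:
    peptides = pd.read_csv(DATA / "redox_peptides.tsv", sep="\t",
                           dtype={"126": float})
    design = pd.read_csv(DATA / "redox_design.tsv", sep="\t",
                         dtype={"channel_label": str})

    protein = rx.complete_case_filter(rx.aggregate_protein_oxidation(peptides, design))
    rx.write_oxidation_table(protein, OUT / "protein_oxidation.tsv")
    peptide = rx.complete_case_filter(rx.peptide_oxidation_table(peptides, design))
    rx.write_oxidation_table(peptide, OUT / "peptide_oxidation.tsv")
    print(f"{len(protein.values)} proteins / {len(peptide.values)} peptides "
          f"with complete Ox% across all conditions")

    for cond in protein.conditions:
        print(f"  average oxidation in {cond}: "
              f"{rx.average_oxidation_level(protein, cond):.1f}%")

    volcano = rx.redox_volcano(protein, "DDW", "NW", ratio_threshold=2, p_threshold=0.05)
    volcano.to_csv(OUT / "volcano_DDW_vs_NW.tsv", sep="\t")
    hits = volcano[volcano["hit"]]
    print(f"volcano: {len(hits)} proteins pass ratio >= 2 (or <= 0.5) and p < 0.05")

    truth = pd.read_csv(DATA / "redox_ground_truth.tsv", sep="\t", index_col=0)
    means = protein.condition_means()
    err = (means - truth[means.columns].loc[means.index]).abs()
    print(f"condition means within 2 points of truth: "
          f"{(err.to_numpy() <= 2).mean() * 100:.1f}% of proteins")


if __name__ == "__main__":
    main()
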