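#!/usr/bin/env python
"""Generate the four synthetic datasets that the downstream analyses read.

Emulates the study layout: a TMT10 expression experiment (control + four
treatments, 4 replicates, bridge/reference vehicle channels per set), a
five-timepoint time course, an iodoTMT sixplex redox experiment
(3 conditions x 3 replicates), and a two-condition TPP series at ten
temperatures. Data land under results/data/ in the same TSV dialects the
pipeline parses, with ground-truth tables alongside.
"""

from pathlib import Path

from mstriad import synthetic as syn
from mstriad.quantio import write_matrix

SEED = 1
ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "data"
OUT.mkdir(parents=True, exist_ok=True)


def main() -> None:
    expr, expr_truth = syn.simulate_expression(
        800, n_specific=20, n_shared=30, seed=SEED
    )
    for set_id in expr.design["set_id"].unique():
        syn.write_protein_groups(expr, OUT / f"expression_{set_id}_proteinGroups.txt", set_id)
    syn.write_design(expr.design, OUT / "expression_design.tsv")
    expr_truth.write(OUT / "expression_ground_truth.tsv")
    print(f"expression: {expr.n_proteins} proteins, "
          f"{expr.abundances.shape[1]} channels over "
          f"{expr.design['set_id'].nunique()} TMT10 sets")

    tc, tc_truth = syn.simulate_timecourse(
        120, onset_h=26.0, effect_log2=0.32, noise_sd_log2=0.1, seed=SEED
    )
    write_matrix(tc, OUT / "timecourse_ratios.tsv", sig_digits=None)
    syn.write_design(tc.design, OUT / "timecourse_design.tsv")
    tc_truth.write(OUT / "timecourse_ground_truth.tsv")
    print(f"timecourse: onset planted at {tc_truth.onset_h} h")

    pep, design, redox_truth = syn.simulate_redox(300, shifted_fraction=0.05, seed=SEED)
    pep.to_csv(OUT / "redox_peptides.tsv", sep="\t", index=False)
    syn.write_design(design, OUT / "redox_design.tsv")
    redox_truth.write(OUT / "redox_ground_truth.tsv")
    print(f"redox: {len(pep)} peptide rows, {len(redox_truth.shifted)} proteins "
          f"planted +16 Ox points in {redox_truth.target_condition}")

    tpp_tab, tpp_truth = syn.simulate_tpp(60, shifted_fraction=0.15, seed=SEED)
    tpp_tab.to_csv(OUT / "tpp_long.tsv", sep="\t", index=False)
    tpp_truth.write(OUT / "tpp_ground_truth.tsv")
    print(f"tpp: {tpp_tab['protein_id'].nunique()} proteins, "
          f"{len(tpp_truth.shifted)} planted +2 degC shifts")


if __name__ == "__main__":
    main()
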