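#!/usr/bin/env python
"""Join the three evidence streams into the ranked candidate ledger.

Every protein from the expression top-50 lists gets one row, annotated with
its DDW/NW oxidation ratio and its Tm shift where the redox and thermal
assays quantified it ("/" where they did not), ranked by evidence count
then VIP.
"""

from pathlib import Path

import pandas as pd

from mstriad import integrate as it
from mstriad import redox as rx
from mstriad import tpp
from mstriad.fitexp import ContrastResult

ROOT = Path(__file__).resolve().parents[1]
RES = ROOT / "results"
OUT = RES / "candidates"
OUT.mkdir(parents=True, exist_ok=True)


def main() -> None:
    up = pd.read_csv(RES / "expression" / "top50_up.tsv", sep="\t")
    down = pd.read_csv(RES / "expression" / "top50_down.tsv", sep="\t")
    contrast = ContrastResult("DDW", up, down, model=None)

    flat = pd.read_csv(RES / "redox" / "protein_oxidation.tsv", sep="\t", index_col=0)
    cols = pd.MultiIndex.from_tuples(
        [(c.rsplit("_rep", 1)[0], int(c.rsplit("_rep", 1)[1])) for c in flat.columns],
        names=["condition", "replicate"],
    )
    flat.columns = cols
    redox_table = rx.OxidationTable("protein", flat)

    fit_rows = pd.read_csv(RES / "tpp" / "melting_fits.tsv", sep="\t")
    shifts = tpp.all_shifts(fit_rows, "DDW", "NW")

    rows = it.rank_candidates(
        it.build_candidate_table(contrast, redox_table, shifts,
                                 treatment="DDW", control="NW")
    )
    frame = it.candidate_frame(rows)
    frame.to_csv(OUT / "candidates.tsv", sep="\t", index=False)
    (OUT / "candidates.txt").write_text(it.render_text(rows) + "\n", encoding="utf-8")

    n3 = (frame["evidence_count"] == 3).sum()
    n2 = (frame["evidence_count"] == 2).sum()
    print(f"{len(frame)} candidates: {n3} with all three evidence types, "
          f"{n2} with two, {len(frame) - n3 - n2} expression-only")
    print("top of the ledger:")
    print(frame.head(5).to_string(index=False))


if __name__ == "__main__":
    main()
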