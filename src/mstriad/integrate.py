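"""Join the three per-protein evidence streams into a candidate ledger.

One row per protein in the expression-contrast top lists, annotated with
its relative oxidation (treatment/control ratio of protein Ox%) and its
melting-temperature shift where those assays quantified it. A missing
assay renders as "/" in the text output. Rows are joined on protein
accession; gene-name fallback joining is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from mstriad.errors import ValidationError
from mstriad.fitexp import ContrastResult
from mstriad.redox import OxidationTable
from mstriad.tpp import TmShift


@dataclass
class CandidateRow:
    protein_id: str
    gene_name: str
    regulation: str  # "up" | "down"
    vip: float
    relative_oxidation: float | None
    delta_tm_C: float | None

    @property
    def evidence_count(self) -> int:
        n = 1  # always present: the regulation evidence that seeded the row
        if self.relative_oxidation is not None:
            n += 1
        if self.delta_tm_C is not None:
            n += 1
        return n


def build_candidate_table(
    contrast: ContrastResult,
    redox_table: OxidationTable | None,
    tm_shifts: list[TmShift] | None,
    treatment: str | None = None,
    control: str | None = None,
    gene_name_fallback: bool = False,
) -> list[CandidateRow]:
    """One candidate row per protein of the up/down lists.

    ``relative_oxidation`` is the treatment/control ratio of condition-mean
    protein Ox% from ``redox_table`` (conditions default to the contrast
    target and the first other condition); ``delta_tm_C`` comes from the
    TPP shift list. Either assay missing a protein leaves its field absent.
    """
    ox_ratio: dict[str, float] = {}
    if redox_table is not None and len(redox_table.values):
        conds = redox_table.conditions
        trt = treatment if treatment in conds else (
            contrast.target_condition if contrast.target_condition in conds else conds[0]
        )
        ctl = control if control in conds else next(c for c in conds if c != trt)
        means = redox_table.condition_means()
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = means[trt] / means[ctl]
        ox_ratio = {str(k): float(v) for k, v in ratio.items() if np.isfinite(v)}
    dtm: dict[str, float] = {}
    if tm_shifts:
        for s in tm_shifts:
            if np.isfinite(s.delta_tm_C):
                dtm[s.protein_id] = float(s.delta_tm_C)

    rows: list[CandidateRow] = []
    for regulation, lst in (("up", contrast.up), ("down", contrast.down)):
        if lst["protein_id"].duplicated().any():
            dup = lst.loc[lst["protein_id"].duplicated(), "protein_id"].iloc[0]
            raise ValidationError(f"duplicate protein id {dup!r} in {regulation} list")
        for _, r in lst.iterrows():
            pid = str(r["protein_id"])
            gene = str(r.get("gene_name", ""))
            keys = [pid] + ([gene] if gene_name_fallback and gene else [])
            rel_ox = next((ox_ratio[k] for k in keys if k in ox_ratio), None)
            shift = next((dtm[k] for k in keys if k in dtm), None)
            rows.append(
                CandidateRow(
                    protein_id=pid,
                    gene_name=gene,
                    regulation=regulation,
                    vip=float(r["vip"]),
                    relative_oxidation=rel_ox,
                    delta_tm_C=shift,
                )
            )
    return rows


def rank_candidates(rows: list[CandidateRow]) -> list[CandidateRow]:
    """Stable sort by (evidence count desc, VIP desc, protein id asc)."""
    return sorted(rows, key=lambda r: (-r.evidence_count, -r.vip, r.protein_id))


def candidate_frame(rows: list[CandidateRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "protein_id": [r.protein_id for r in rows],
            "gene_name": [r.gene_name for r in rows],
            "regulation": [r.regulation for r in rows],
            "vip": [r.vip for r in rows],
            "relative_oxidation": [
                np.nan if r.relative_oxidation is None else r.relative_oxidation
                for r in rows
            ],
            "delta_tm_C": [
                np.nan if r.delta_tm_C is None else r.delta_tm_C for r in rows
            ],
            "evidence_count": [r.evidence_count for r in rows],
        }
    )


def render_text(rows: list[CandidateRow]) -> str:
    """Human-readable ledger: arrows for regulation, "/" for absent assays."""
    lines = ["protein_id\tgene\tregulation\trelative_oxidation\tdelta_tm_C\tevidence"]
    for r in rows:
        arrow = "↑" if r.regulation == "up" else "↓"
        ox = "/" if r.relative_oxidation is None else f"{r.relative_oxidation:.2f}"
        dt = "/" if r.delta_tm_C is None else f"{r.delta_tm_C:.2f}"
        lines.append(
            f"{r.protein_id}\t{r.gene_name}\t{arrow}\t{ox}\t{dt}\t{r.evidence_count}"
        )
    return "\n".join(lines)
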