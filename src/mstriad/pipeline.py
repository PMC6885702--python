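"""End-to-end drivers tying the three assay arms together.

Each arm runs the full stage on synthetic data with serialized ground
truth: expression (simulate -> bridge-normalize -> OPLS-DA contrast),
redox (simulate -> aggregate -> complete cases -> volcano), and thermal
profiling (simulate -> fit curves -> Tm shifts -> volcano). The three
generators share a protein-id namespace, so the planted treatment-specific
proteins are the same accessions across assays and the integrated
candidate table can be checked against truth end to end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from mstriad import fitexp, integrate, quantio, redox, synthetic, tpp


@dataclass
class TripleResult:
    candidates: pd.DataFrame
    contrast: fitexp.ContrastResult
    redox_table: redox.OxidationTable
    redox_volcano: pd.DataFrame
    tpp_volcano: pd.DataFrame
    truths: dict


def expression_arm(
    seed: int,
    n_proteins: int = 2000,
    n_specific: int = 20,
    n_shared: int = 30,
    k: int = 50,
    target: str = "DDW",
    **sim_kw,
):
    """Simulate, normalize through the bridges, and contrast the target."""
    matrix, truth = synthetic.simulate_expression(
        n_proteins, n_specific=n_specific, n_shared=n_shared, seed=seed,
        target_condition=target, **sim_kw,
    )
    filtered, _ = quantio.filter_quantifiable(matrix, min_peptides=2)
    joined, _ = quantio.bridge_normalize(quantio.split_sets(filtered))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        contrast = fitexp.contrast_topk(joined, target, k=k)
    return contrast, truth


def redox_arm(
    seed: int,
    n_proteins: int = 500,
    shifted_fraction: float = 0.04,
    treatment: str = "DDW",
    control: str = "NW",
    **sim_kw,
):
    """Simulate the sixplex, aggregate to proteins, filter, and contrast."""
    peptides, design, truth = synthetic.simulate_redox(
        n_proteins, shifted_fraction=shifted_fraction, seed=seed, **sim_kw
    )
    table = redox.aggregate_protein_oxidation(peptides, design)
    table = redox.complete_case_filter(table)
    volcano = redox.redox_volcano(table, treatment, control)
    return table, volcano, truth


def tpp_arm(
    seed: int,
    n_proteins: int = 100,
    shifted_fraction: float = 0.1,
    treatment: str = "DDW",
    control: str = "NW",
    **sim_kw,
):
    """Simulate melting series, fit every curve, and compute Tm shifts."""
    table, truth = synthetic.simulate_tpp(
        n_proteins, shifted_fraction=shifted_fraction, seed=seed, **sim_kw
    )
    curves = tpp.curves_from_long(table, normalize=False)
    fits = tpp.fit_all_curves(curves)
    shifts = tpp.all_shifts(fits, treatment, control)
    volcano = tpp.tpp_volcano(shifts)
    return fits, shifts, volcano, truth


def run_triple(
    seed: int,
    n_expression: int = 800,
    n_redox: int = 300,
    n_tpp: int = 60,
    k: int = 50,
    target: str = "DDW",
) -> TripleResult:
    """Full three-armed pipeline into the ranked candidate table.

    Sub-seeds for the three arms derive deterministically from ``seed``.
    Protein ids are shared across arms, so candidates picked by the
    expression contrast carry redox and thermal evidence whenever those
    assays covered the same accession.
    """
    contrast, truth_e = expression_arm(seed * 3 + 1, n_proteins=n_expression, k=k)
    redox_table, redox_vol, truth_r = redox_arm(seed * 3 + 2, n_proteins=n_redox)
    _, shifts, tpp_vol, truth_t = tpp_arm(seed * 3 + 3, n_proteins=n_tpp)
    rows = integrate.build_candidate_table(
        contrast, redox_table, shifts, treatment=target, control="NW"
    )
    ranked = integrate.rank_candidates(rows)
    return TripleResult(
        candidates=integrate.candidate_frame(ranked),
        contrast=contrast,
        redox_table=redox_table,
        redox_volcano=redox_vol,
        tpp_volcano=tpp_vol,
        truths={"expression": truth_e, "redox": truth_r, "tpp": truth_t},
    )
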