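"""Cysteine redox proteomics from paired iodoTMT sixplex channels.

Switch labeling: free thiols are blocked with the first three iodoTMT
reagents (126-128); reversibly oxidized cysteines are then reduced with
TCEP and labeled with the last three (129-131). Each replicate therefore
owns one *free* and one *oxidized* channel, and the oxidation percentage of
a peptide (or protein) is

    Ox% = 100 * oxidized / (free + oxidized)

which cancels any per-replicate labeling-efficiency or loading factor.
Protein-level values default to intensity-weighted aggregation (sum the
free and oxidized intensities over the protein's cysteine peptides, then
take the ratio), which downweights noisy low-intensity peptides;
mean-of-peptide-percentages is available for per-peptide reporting.

Only proteins (or peptides) with oxidation values in every replicate of
every condition survive the complete-case filter before contrasts. The
volcano contrast uses a two-tailed unpaired t test (equal-variance by
default, Welch optional) and the ratio of condition-mean percentages; no
multiple-testing correction is applied by default, with Benjamini-Hochberg
behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from mstriad.errors import ConfigurationError, ValidationError

SIXPLEX_LABELS = ("126", "127", "128", "129", "130", "131")


def pair_channels(design: pd.DataFrame) -> dict[int, tuple[str, str]]:
    """Pair free and oxidized channels per replicate.

    The design must flag exactly three channels ``free`` and three
    ``oxidized`` (column ``role``). Pairing follows label order — with the
    standard sixplex, 126<->129, 127<->130, 128<->131 — unless an explicit
    ``pair`` column assigns partners.
    """
    free = design[design["role"] == "free"]
    oxid = design[design["role"] == "oxidized"]
    if len(free) != len(oxid):
        raise ConfigurationError(
            f"{len(free)} free vs {len(oxid)} oxidized channels; counts must match"
        )
    if len(free) == 0:
        raise ConfigurationError("no free/oxidized channels in design")
    if "pair" in design.columns and design["pair"].notna().any():
        pairs = {}
        for rep, (_, frow) in enumerate(free.iterrows(), start=1):
            partner = oxid[oxid["pair"] == frow["pair"]]
            if len(partner) != 1:
                raise ConfigurationError(
                    f"pair tag {frow['pair']!r} has no unique oxidized partner"
                )
            rep_id = int(frow["replicate"]) if "replicate" in frow else rep
            pairs[rep_id] = (frow["channel_label"], partner["channel_label"].iloc[0])
        return pairs
    free_sorted = free.sort_values("channel_label")
    oxid_sorted = oxid.sort_values("channel_label")
    pairs = {}
    for rep, (f, o) in enumerate(
        zip(free_sorted["channel_label"], oxid_sorted["channel_label"]), start=1
    ):
        rep_id = rep
        if "replicate" in free_sorted.columns:
            rep_id = int(free_sorted["replicate"].iloc[rep - 1])
        pairs[rep_id] = (f, o)
    return pairs


def oxidation_percentage(free, oxidized):
    """Ox% = 100 * oxidized / (free + oxidized); missing when both absent.

    Vectorized over array inputs; zeros count as missing signal, and a pair
    with no signal in either channel yields a missing value.
    """
    free = np.asarray(free, dtype=float)
    oxidized = np.asarray(oxidized, dtype=float)
    f = np.where(np.isnan(free), 0.0, free)
    o = np.where(np.isnan(oxidized), 0.0, oxidized)
    total = f + o
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(total > 0, 100.0 * o / total, np.nan)
    if pct.ndim == 0:
        return float(pct)
    return pct


@dataclass
class OxidationTable:
    """Per-id oxidation percentages per (condition, replicate).

    ``values`` has a two-level column index (condition, replicate) and is
    indexed by peptide or protein id; all entries are percentages in
    [0, 100] or missing.
    """

    level: str  # "peptide" | "protein"
    values: pd.DataFrame
    meta: pd.DataFrame | None = None

    def condition_means(self) -> pd.DataFrame:
        return self.values.T.groupby(level="condition").mean().T

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.values.columns.get_level_values("condition")))


def peptide_oxidation_table(
    peptides: pd.DataFrame,
    design: pd.DataFrame,
    intensity_columns: dict[str, str] | None = None,
) -> OxidationTable:
    """Per-peptide Ox% from a sixplex peptide table.

    ``peptides`` carries one row per (cysteine peptide, condition) with
    columns ``peptide_sequence``, ``protein_id``, ``condition``, and one
    intensity column per channel label. The design supplies the
    free/oxidized pairing.
    """
    pairs = pair_channels(design)
    id_cols = ["protein_id", "peptide_sequence"]
    frames = {}
    for rep, (f_ch, o_ch) in pairs.items():
        f_col = intensity_columns[f_ch] if intensity_columns else f_ch
        o_col = intensity_columns[o_ch] if intensity_columns else o_ch
        for col in (f_col, o_col):
            if col not in peptides.columns:
                raise ConfigurationError(f"missing intensity column {col!r}")
        pct = oxidation_percentage(
            peptides[f_col].to_numpy(), peptides[o_col].to_numpy()
        )
        frames[rep] = pct
    out = peptides[id_cols + ["condition"]].copy()
    for rep, pct in frames.items():
        out[rep] = pct
    long = out.melt(
        id_vars=id_cols + ["condition"], var_name="replicate", value_name="ox"
    )
    wide = long.pivot_table(
        index=id_cols,
        columns=["condition", "replicate"],
        values="ox",
        aggfunc="mean",
    )
    wide.columns = wide.columns.set_names(["condition", "replicate"])
    meta = wide.index.to_frame(index=False).set_index("peptide_sequence")
    values = wide.droplevel("protein_id")
    return OxidationTable(level="peptide", values=values, meta=meta)


def aggregate_protein_oxidation(
    peptides: pd.DataFrame,
    design: pd.DataFrame,
    method: str = "intensity_weighted",
    intensity_columns: dict[str, str] | None = None,
) -> OxidationTable:
    """Protein-level Ox% per (condition, replicate).

    ``intensity_weighted`` (default) sums free and oxidized intensities over
    the protein's cysteine peptides before taking the percentage;
    ``mean_of_peptides`` averages per-peptide percentages instead. A protein
    with no quantified cysteine peptide in a replicate is missing there.
    """
    if method not in ("intensity_weighted", "mean_of_peptides"):
        raise ValueError(f"unknown aggregation method {method!r}")
    pairs = pair_channels(design)
    records = []
    for rep, (f_ch, o_ch) in pairs.items():
        f_col = intensity_columns[f_ch] if intensity_columns else f_ch
        o_col = intensity_columns[o_ch] if intensity_columns else o_ch
        for col in (f_col, o_col):
            if col not in peptides.columns:
                raise ConfigurationError(f"missing intensity column {col!r}")
        if method == "intensity_weighted":
            grp = peptides.groupby(["protein_id", "condition"])[[f_col, o_col]].sum(
                min_count=1
            )
            pct = oxidation_percentage(
                grp[f_col].to_numpy(), grp[o_col].to_numpy()
            )
            part = pd.Series(pct, index=grp.index)
        else:
            pct = oxidation_percentage(
                peptides[f_col].to_numpy(), peptides[o_col].to_numpy()
            )
            part = (
                peptides.assign(_ox=pct)
                .groupby(["protein_id", "condition"])["_ox"]
                .mean()
            )
        records.append(part.rename(rep))
    wide = pd.concat(records, axis=1)
    wide.columns.name = "replicate"
    values = wide.unstack("condition").swaplevel(axis=1)
    values.columns = values.columns.set_names(["condition", "replicate"])
    values = values.sort_index(axis=1)
    return OxidationTable(level="protein", values=values)


def complete_case_filter(
    t: OxidationTable, conditions=None
) -> OxidationTable:
    """Keep only rows quantified in every replicate of every condition."""
    values = t.values
    if conditions is not None:
        values = values.loc[:, values.columns.get_level_values("condition").isin(conditions)]
    keep = values.notna().all(axis=1)
    return OxidationTable(
        level=t.level,
        values=values.loc[keep],
        meta=None if t.meta is None else t.meta.loc[keep[keep].index],
    )


def redox_volcano(
    t: OxidationTable,
    condition_a: str,
    condition_b: str,
    ratio_threshold: float = 2.0,
    p_threshold: float = 0.05,
    equal_var: bool = True,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Condition contrast of oxidation percentages.

    Per row: ratio of mean Ox% (a over b) and a two-tailed unpaired t test
    on the replicate values (Student by default, Welch with
    ``equal_var=False``). Hits satisfy ratio >= threshold or <= 1/threshold
    together with p < ``p_threshold``. Optional Benjamini-Hochberg adjusted
    p in column ``p_adj``; the hit flag then uses the adjusted values.
    """
    for cond in (condition_a, condition_b):
        if cond not in t.conditions:
            raise ConfigurationError(f"condition {cond!r} not in table")
    a = t.values[condition_a]
    b = t.values[condition_b]
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = mean_a / mean_b
    ratio = ratio.mask(mean_b == 0)
    res = stats.ttest_ind(
        a.to_numpy(dtype=float),
        b.to_numpy(dtype=float),
        axis=1,
        equal_var=equal_var,
        nan_policy="omit",
    )
    p = pd.Series(res.pvalue, index=t.values.index)
    out = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "ratio": ratio,
            "p_value": p,
        }
    )
    decision_p = p
    if bh_correct:
        out["p_adj"] = _benjamini_hochberg(p.to_numpy())
        decision_p = out["p_adj"]
    effect = (ratio >= ratio_threshold) | (ratio <= 1.0 / ratio_threshold)
    out["hit"] = effect.fillna(False) & (decision_p < p_threshold)
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = np.isfinite(p).sum()
    order = np.argsort(np.where(np.isfinite(p), p, np.inf))
    adj = np.full_like(p, np.nan, dtype=float)
    prev = 1.0
    for rank_from_end, idx in enumerate(order[:n][::-1]):
        rank = n - rank_from_end
        prev = min(prev, p[idx] * n / rank)
        adj[idx] = prev
    return adj


def average_oxidation_level(t: OxidationTable, condition: str) -> float:
    """Mean over rows of the condition-mean oxidation percentage."""
    if len(t.values) == 0:
        raise ValidationError("empty oxidation table")
    if condition not in t.conditions:
        raise ConfigurationError(f"condition {condition!r} not in table")
    return float(t.values[condition].mean(axis=1).mean())


def write_oxidation_table(t: OxidationTable, path, sig_digits: int = 6) -> None:
    flat = t.values.copy()
    flat.columns = [f"{c}_rep{r}" for c, r in flat.columns]
    flat.to_csv(path, sep="\t", float_format=f"%.{sig_digits}g")
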