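"""Reporter-ion quantification I/O, filtering, and normalization.

Shared data model for all downstream stages. Input tables follow the
MaxQuant ``proteinGroups.txt`` dialect: tab-separated, one row per protein
group, reporter-ion intensities in columns named ``<prefix> <channel>``,
decoy rows flagged "+" in ``Reverse`` and contaminants in
``Potential contaminant``.

Design notes
------------
* A reporter intensity of 0 in the input means "not quantified" and is
  stored as missing, never as a true zero -- isobaric reporters of a
  detected peptide are never exactly zero.
* Normalization to the reference channel is a per-protein (row-wise) ratio,
  producing the dimensionless relative abundances used throughout; an
  optional column-median loading normalization is available as a pre-step.
* Channel labels are opaque strings matched exactly against the design.
* Multiplexed sets are combined by dividing each row by the geometric mean
  of its bridge-channel values (the vehicle controls carried in every set),
  then joining sets on shared proteins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from mstriad.errors import ConfigurationError, ValidationError

DESIGN_COLUMNS = [
    "set_id",
    "channel_label",
    "condition",
    "replicate",
    "timepoint_h",
    "temperature_C",
    "role",
]

ROLES = {"sample", "bridge", "reference", "free", "oxidized"}


def _column_key(set_id: object, channel_label: str) -> str:
    """Stable key for a (set, channel) slot used as a matrix column name."""
    if set_id is None or (isinstance(set_id, float) and math.isnan(set_id)):
        return str(channel_label)
    return f"{set_id}:{channel_label}"


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    """Check sample-design invariants and return a normalized copy.

    Within each labeling set: channel labels are unique, at most one channel
    has role ``reference``, and (condition, replicate) pairs of ``sample``
    channels are unique.
    """
    d = design.copy()
    if "set_id" not in d.columns:
        d["set_id"] = "set1"
    d["set_id"] = d["set_id"].fillna("set1")
    for col in ("timepoint_h", "temperature_C"):
        if col not in d.columns:
            d[col] = np.nan
    if "replicate" not in d.columns:
        d["replicate"] = 1
    d["channel_label"] = d["channel_label"].astype(str)
    bad_roles = set(d["role"]) - ROLES
    if bad_roles:
        raise ValidationError(f"unknown design roles: {sorted(bad_roles)}")
    for set_id, grp in d.groupby("set_id"):
        if grp["channel_label"].duplicated().any():
            dup = grp.loc[grp["channel_label"].duplicated(), "channel_label"].iloc[0]
            raise ValidationError(
                f"duplicate channel label {dup!r} in set {set_id!r}"
            )
        if (grp["role"] == "reference").sum() > 1:
            raise ValidationError(f"more than one reference channel in set {set_id!r}")
        samples = grp[grp["role"] == "sample"]
        # timepoint / temperature series legitimately repeat a replicate
        pairs = list(
            zip(
                samples["condition"],
                samples["replicate"],
                samples["timepoint_h"].fillna(-1.0),
                samples["temperature_C"].fillna(-1.0),
            )
        )
        if len(pairs) != len(set(pairs)):
            raise ValidationError(
                f"duplicate (condition, replicate) sample pair in set {set_id!r}"
            )
    d = d.reset_index(drop=True)
    d.index = pd.Index(
        [_column_key(s, c) for s, c in zip(d["set_id"], d["channel_label"])],
        name="column_key",
    )
    return d[DESIGN_COLUMNS]


def read_design(path) -> pd.DataFrame:
    """Read a channel design file (CSV or TSV, sniffed by header)."""
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    raw = pd.read_csv(path, sep=sep)
    return validate_design(raw)


@dataclass
class ReporterMatrix:
    """Proteins x channels reporter-abundance matrix with metadata.

    ``abundances`` is indexed by protein id, columns keyed by
    ``set_id:channel_label``; missing values are NaN. ``meta`` carries
    per-protein ``gene_name``, ``peptide_count``, ``is_reverse``,
    ``is_contaminant`` on the same index. ``design`` maps each column key to
    its channel annotation.
    """

    abundances: pd.DataFrame
    meta: pd.DataFrame
    design: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        if len(self.abundances) != len(self.meta):
            raise ValidationError("abundance rows and metadata rows differ in count")
        if not self.abundances.index.equals(self.meta.index):
            raise ValidationError("abundance and metadata indexes differ")
        missing = [c for c in self.abundances.columns if c not in self.design.index]
        if missing:
            raise ValidationError(f"columns absent from design: {missing}")
        with np.errstate(invalid="ignore"):
            if (self.abundances.to_numpy(dtype=float) < 0).any():
                raise ValidationError("negative reporter abundances")

    @property
    def protein_ids(self) -> pd.Index:
        return self.abundances.index

    @property
    def n_proteins(self) -> int:
        return len(self.abundances)

    def columns_with_role(self, *roles: str) -> list[str]:
        d = self.design.loc[self.abundances.columns]
        return list(d.index[d["role"].isin(roles)])

    def subset(self, protein_ids: Sequence[str]) -> "ReporterMatrix":
        return replace(
            self,
            abundances=self.abundances.loc[protein_ids],
            meta=self.meta.loc[protein_ids],
        )


@dataclass
class FilterReport:
    """Row counts removed per reason; a row counts once, first reason wins
    (reverse, then contaminant, then low peptide count)."""

    removed_reverse: int = 0
    removed_contaminant: int = 0
    removed_low_peptides: int = 0
    dropped_missing_reference: int = 0
    dropped_missing_bridge: int = 0
    retained: int = 0

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"reason": list(vars(self)), "count": list(vars(self).values())}
        )


def read_protein_groups(
    path,
    design: pd.DataFrame,
    reporter_column_prefix: str = "Reporter intensity corrected",
    id_column: str = "Majority protein IDs",
    gene_column: str = "Gene names",
    peptide_column: str = "Razor + unique peptides",
) -> ReporterMatrix:
    """Parse a proteinGroups-style TSV into a :class:`ReporterMatrix`.

    Reporter columns are located as ``"<prefix> <channel_label>"`` for every
    channel in the design; a designed channel without a matching column is a
    configuration error naming the channel. Zero intensities are stored as
    missing. Rows keep file order.
    """
    table = pd.read_csv(path, sep="\t", dtype={id_column: str}, float_precision="round_trip")
    design = validate_design(design)
    cols = {}
    for key, row in design.iterrows():
        col = f"{reporter_column_prefix} {row['channel_label']}"
        if col not in table.columns:
            raise ConfigurationError(
                f"no reporter column for designed channel {row['channel_label']!r} "
                f"(expected column {col!r})"
            )
        cols[key] = col
    ids = table[id_column].astype(str)
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise ValidationError(f"duplicate protein id {dup!r}")
    abundances = table[list(cols.values())].astype(float)
    abundances.columns = list(cols)
    abundances = abundances.mask(abundances == 0)  # 0 means not quantified
    abundances.index = pd.Index(ids, name="protein_id")
    meta = pd.DataFrame(
        {
            "gene_name": table.get(gene_column, pd.Series([""] * len(table))).fillna("").astype(str).values,
            "peptide_count": table.get(peptide_column, pd.Series([0] * len(table))).fillna(0).astype(int).values,
            "is_reverse": (table.get("Reverse", pd.Series([""] * len(table))).fillna("") == "+").values,
            "is_contaminant": (
                table.get("Potential contaminant", pd.Series([""] * len(table))).fillna("") == "+"
            ).values,
        },
        index=abundances.index,
    )
    return ReporterMatrix(abundances, meta, design)


def filter_quantifiable(
    m: ReporterMatrix, min_peptides: int = 2
) -> tuple[ReporterMatrix, FilterReport]:
    """Drop decoy, contaminant, and under-quantified proteins.

    Keeps rows that are neither reverse hits nor known contaminants and have
    at least ``min_peptides`` razor+unique peptides. Row order is preserved.
    """
    if min_peptides < 1:
        raise ValueError("min_peptides must be >= 1")
    rev = m.meta["is_reverse"].to_numpy()
    con = m.meta["is_contaminant"].to_numpy() & ~rev
    low = (m.meta["peptide_count"].to_numpy() < min_peptides) & ~rev & ~con
    keep = ~(rev | con | low)
    report = FilterReport(
        removed_reverse=int(rev.sum()),
        removed_contaminant=int(con.sum()),
        removed_low_peptides=int(low.sum()),
        retained=int(keep.sum()),
    )
    out = replace(m, abundances=m.abundances.loc[keep], meta=m.meta.loc[keep])
    return out, report


def normalize_columns_median(m: ReporterMatrix) -> ReporterMatrix:
    """Optional loading normalization: scale each channel so that column
    medians are equal (to the grand median). Off by default in the pipeline."""
    med = m.abundances.median(axis=0, skipna=True)
    grand = float(np.nanmedian(m.abundances.to_numpy(dtype=float)))
    scaled = m.abundances.mul(grand / med, axis=1)
    return replace(m, abundances=scaled)


def normalize_to_reference(
    m: ReporterMatrix,
) -> tuple[ReporterMatrix, FilterReport]:
    """Divide every row by its reference-channel value, per labeling set.

    Each set in the design must carry exactly one ``reference`` channel.
    Rows whose reference value is missing (or zero, which reads as missing)
    in any set are dropped and reported. Idempotent: reference columns of
    the output are identically 1.
    """
    design = m.design.loc[m.abundances.columns]
    out = m.abundances.copy()
    drop = pd.Series(False, index=out.index)
    for set_id, grp in design.groupby("set_id"):
        refs = grp.index[grp["role"] == "reference"]
        if len(refs) != 1:
            raise ConfigurationError(
                f"set {set_id!r} needs exactly one reference channel, found {len(refs)}"
            )
        ref_vals = out[refs[0]]
        drop |= ~(ref_vals > 0)
        out.loc[:, list(grp.index)] = out[list(grp.index)].div(ref_vals, axis=0)
    keep = ~drop
    report = FilterReport(
        dropped_missing_reference=int(drop.sum()), retained=int(keep.sum())
    )
    result = replace(
        m, abundances=out.loc[keep], meta=m.meta.loc[keep], normalized=True
    )
    return result, report


def _geometric_mean_rows(frame: pd.DataFrame) -> pd.Series:
    logs = np.log(frame.to_numpy(dtype=float))
    return pd.Series(np.exp(logs.mean(axis=1)), index=frame.index)


def bridge_normalize(
    sets: Iterable[ReporterMatrix],
) -> tuple[ReporterMatrix, FilterReport]:
    """Combine multiplexed sets through their shared bridge channels.

    Within each set every row is divided by the geometric mean of its
    bridge-channel values (symmetric in the two vehicle controls and stable
    on ratios); sets are then inner-joined on protein id. Proteins missing a
    bridge value in any set are dropped and reported. Bridge columns are
    retained with their role flag.
    """
    sets = list(sets)
    if not sets:
        raise ValueError("no sets given")
    normalized_parts: list[pd.DataFrame] = []
    metas: list[pd.DataFrame] = []
    designs: list[pd.DataFrame] = []
    dropped = 0
    for m in sets:
        bridge_cols = m.columns_with_role("bridge")
        if not bridge_cols:
            raise ConfigurationError("a set has no bridge channel")
        geo = _geometric_mean_rows(m.abundances[bridge_cols])
        ok = geo.notna() & (geo > 0)
        dropped += int((~ok).sum())
        part = m.abundances.loc[ok].div(geo[ok], axis=0)
        normalized_parts.append(part)
        metas.append(m.meta.loc[ok])
        designs.append(m.design.loc[m.abundances.columns])
    shared = normalized_parts[0].index
    for part in normalized_parts[1:]:
        shared = shared.intersection(part.index)
    joined = pd.concat([p.loc[shared] for p in normalized_parts], axis=1)
    meta = metas[0].loc[shared]
    design = pd.concat(designs)
    design = design[~design.index.duplicated()]
    report = FilterReport(dropped_missing_bridge=dropped, retained=len(shared))
    return ReporterMatrix(joined, meta, design, normalized=True), report


def split_sets(m: ReporterMatrix) -> list[ReporterMatrix]:
    """Split a multi-set matrix into one matrix per labeling set."""
    design = m.design.loc[m.abundances.columns]
    out = []
    for _, grp in design.groupby("set_id", sort=False):
        cols = list(grp.index)
        out.append(replace(m, abundances=m.abundances[cols]))
    return out


# ---------------------------------------------------------------------------
# TSV output


def write_matrix(m: ReporterMatrix, path, sig_digits: int | None = 6) -> None:
    """Write the abundance matrix (with gene names) as TSV.

    ``sig_digits=6`` gives the compact report format; pass ``None`` for a
    full-precision, bit-for-bit round-trippable dump.
    """
    out = pd.concat([m.meta[["gene_name"]], m.abundances], axis=1)
    fmt = f"%.{sig_digits}g" if sig_digits is not None else None
    out.to_csv(path, sep="\t", float_format=fmt)


def read_matrix(path, design: pd.DataFrame) -> ReporterMatrix:
    """Read back a matrix written by :func:`write_matrix`."""
    table = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    design = validate_design(design) if "channel_label" in design.columns else design
    keys = [k for k in design.index if k in table.columns]
    meta = pd.DataFrame(
        {
            "gene_name": table["gene_name"].fillna("").astype(str),
            "peptide_count": 0,
            "is_reverse": False,
            "is_contaminant": False,
        },
        index=table.index,
    )
    return ReporterMatrix(table[keys].astype(float), meta, design)


def write_filter_report(report: FilterReport, path) -> None:
    report.as_frame().to_csv(path, sep="\t", index=False)
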