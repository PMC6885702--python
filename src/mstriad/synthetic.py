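"""Ground-truth-annotated synthetic datasets for every pipeline stage.

Each generator is a pure function of its parameters and seed and emulates
the statistical structure of one experimental design:

* ``simulate_expression`` -- a multiplexed TMT10 expression experiment:
  control plus four treatments, four replicates each, spread over sets of
  eight sample channels with a reference and a bridge vehicle channel per
  set. Planted structure includes treatment-*specific* regulation (what the
  contrast must find) and *shared* death/survival regulation present in
  every treatment (what it must reject), plus per-set batch factors that
  only the bridge channels can remove.
* ``simulate_redox`` -- an iodoTMT sixplex per condition: three replicates,
  channels 126-128 free / 129-131 oxidized, 1-5 cysteine peptides per
  protein, log-normal intensity noise that cancels in the Ox% ratio.
  Baseline oxidation sits near 18% with planted shifts of about +16 points,
  the magnitudes the redox contrast is meant to resolve.
* ``simulate_tpp`` -- melting series at the canonical ten temperatures
  (37-67 degC), two conditions, two replicates, additive Gaussian noise on
  soluble fractions, a planted subset thermally shifted by +2 degC.
* ``simulate_timecourse`` -- five timepoints (4-48 h), planted up/down
  protein groups stepping at a chosen onset, abundances already expressed
  relative to the late vehicle bridge.

Noise model: multiplicative log-normal (CV-parameterized) for reporter
intensities; additive Gaussian for normalized soluble fractions. All truth
tables are serialized next to the data and share protein ids with it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from mstriad.errors import ValidationError
from mstriad.quantio import ReporterMatrix, validate_design
from mstriad.tpp import TPP_TEMPERATURES, sigmoid_fraction

TMT10_LABELS = (
    "126", "127N", "127C", "128N", "128C",
    "129N", "129C", "130N", "130C", "131",
)
SIXPLEX_FREE = ("126", "127", "128")
SIXPLEX_OXIDIZED = ("129", "130", "131")

DEFAULT_CONDITIONS = ("NW", "DDW", "CAMP", "MTX", "PCTL")


@dataclass
class GroundTruth:
    """Planted truth serialized alongside every synthetic dataset."""

    proteins: pd.DataFrame  # indexed by protein_id
    specific_up: list[str] = field(default_factory=list)
    specific_down: list[str] = field(default_factory=list)
    shared: list[str] = field(default_factory=list)
    shifted: list[str] = field(default_factory=list)
    onset_h: float | None = None
    target_condition: str | None = None

    def write(self, path) -> None:
        self.proteins.to_csv(path, sep="\t")


def validate_ground_truth(data_ids, truth: GroundTruth) -> None:
    """Referential integrity: every truth id must exist in the data."""
    data_ids = set(map(str, data_ids))
    missing = set(truth.proteins.index.astype(str)) - data_ids
    if missing:
        raise ValidationError(f"truth ids absent from data: {sorted(missing)[:5]}")


def _protein_ids(n: int) -> list[str]:
    return [f"P{i:05d}" for i in range(n)]


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with the given coefficient of variation."""
    if cv <= 0:
        return 1.0 if size is None else np.ones(size)
    sigma = np.sqrt(np.log(1.0 + cv**2))
    return rng.lognormal(mean=-(sigma**2) / 2, sigma=sigma, size=size)


def simulate_expression(
    n_proteins: int,
    conditions=DEFAULT_CONDITIONS,
    n_reps: int = 4,
    n_specific: int = 20,
    n_shared: int = 30,
    effect_log2: float = 0.8,
    tech_cv: float = 0.1,
    seed: int = 0,
    target_condition: str | None = None,
    batch_sd_log2: float = 0.5,
    samples_per_set: int = 8,
) -> tuple[ReporterMatrix, GroundTruth]:
    """TMT10 expression experiment with planted specific and shared effects.

    The first condition is the untreated control. Specific proteins (half
    up, half down by ``effect_log2``) respond only in ``target_condition``
    (default: second condition); shared death/survival proteins respond
    identically in every non-control condition. Reporter intensity is
    ``2**(base + batch + effect + N(0, log2(1+cv)))``; each set carries a
    reference channel (126) and a bridge channel (131), both vehicle.
    """
    if n_specific + n_shared > n_proteins:
        raise ValidationError("planted proteins exceed n_proteins")
    if n_reps < 1 or n_proteins < 1:
        raise ValidationError("invalid sizes")
    conditions = list(conditions)
    control = conditions[0]
    if target_condition is None:
        target_condition = conditions[1]
    rng = np.random.default_rng(seed)
    ids = _protein_ids(n_proteins)
    base = rng.uniform(20.0, 30.0, n_proteins)
    sigma = np.log2(1.0 + tech_cv) if tech_cv > 0 else 0.0

    n_up = n_specific // 2
    specific_up = ids[:n_up]
    specific_down = ids[n_up:n_specific]
    shared = ids[n_specific : n_specific + n_shared]
    shared_sign = rng.choice([-1.0, 1.0], size=n_shared)

    effect = np.zeros((n_proteins, len(conditions)))
    tgt = conditions.index(target_condition)
    effect[:n_up, tgt] = effect_log2
    effect[n_up:n_specific, tgt] = -effect_log2
    for j, cond in enumerate(conditions):
        if cond == control:
            continue
        effect[n_specific : n_specific + n_shared, j] += shared_sign * effect_log2

    # replicate-major order spreads every condition across labeling sets,
    # so no treatment is confounded with a set's shared bridge noise
    pairs = [(c, r) for r in range(1, n_reps + 1) for c in conditions]
    n_sets = int(np.ceil(len(pairs) / samples_per_set))
    design_rows = []
    columns = {}
    for s in range(n_sets):
        set_id = f"set{s + 1}"
        batch = rng.normal(0.0, batch_sd_log2, n_proteins)
        chunk = pairs[s * samples_per_set : (s + 1) * samples_per_set]
        slots = [("reference", control, 1, TMT10_LABELS[0])]
        for i, (cond, rep) in enumerate(chunk):
            slots.append(("sample", cond, rep, TMT10_LABELS[1 + i]))
        slots.append(("bridge", control, 2, TMT10_LABELS[-1]))
        for role, cond, rep, label in slots:
            j = conditions.index(cond)
            eff = effect[:, j] if role == "sample" else np.zeros(n_proteins)
            noise = rng.normal(0.0, sigma, n_proteins) if sigma > 0 else 0.0
            key = f"{set_id}:{label}"
            columns[key] = 2.0 ** (base + batch + eff + noise)
            design_rows.append(
                dict(
                    set_id=set_id, channel_label=label, condition=cond,
                    replicate=rep, timepoint_h=np.nan, temperature_C=np.nan,
                    role=role,
                )
            )
    design = validate_design(pd.DataFrame(design_rows))
    abundances = pd.DataFrame(columns, index=pd.Index(ids, name="protein_id"))
    meta = pd.DataFrame(
        {
            "gene_name": [f"G{i}" for i in range(n_proteins)],
            "peptide_count": rng.integers(2, 15, n_proteins),
            "is_reverse": False,
            "is_contaminant": False,
        },
        index=abundances.index,
    )
    matrix = ReporterMatrix(abundances, meta, design)
    truth_frame = pd.DataFrame(
        {
            "base_log2_abundance": base,
            "class": ["specific_up"] * n_up
            + ["specific_down"] * (n_specific - n_up)
            + ["shared"] * n_shared
            + ["background"] * (n_proteins - n_specific - n_shared),
            "shared_sign": np.concatenate(
                [np.zeros(n_specific), shared_sign, np.zeros(n_proteins - n_specific - n_shared)]
            ),
        },
        index=abundances.index,
    )
    truth = GroundTruth(
        proteins=truth_frame,
        specific_up=specific_up,
        specific_down=specific_down,
        shared=shared,
        target_condition=target_condition,
    )
    return matrix, truth


def simulate_redox(
    n_proteins: int,
    conditions=("NW", "auranofin", "DDW"),
    n_reps: int = 3,
    base_ox_percent: float = 18.0,
    shifted_fraction: float = 0.05,
    shift_points: float = 16.0,
    intensity_cv: float = 0.1,
    seed: int = 0,
    target_condition: str | None = None,
    base_sd_points: float = 6.0,
    max_peptides: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """iodoTMT sixplex redox experiment with planted oxidation shifts.

    Returns ``(peptide_table, design, truth)``. Per protein, a baseline Ox%
    is drawn around ``base_ox_percent``; the planted subset is shifted by
    ``shift_points`` in ``target_condition`` (default: last condition).
    Each protein carries 1-``max_peptides`` cysteine peptides; per replicate
    the peptide's total intensity is log-normal and splits into free and
    oxidized channels with independent log-normal noise of the given CV.
    """
    if not (0 < base_ox_percent < 100):
        raise ValidationError("base_ox_percent must be in (0, 100)")
    conditions = list(conditions)
    if target_condition is None:
        target_condition = conditions[-1]
    if n_reps != len(SIXPLEX_FREE):
        raise ValidationError("sixplex design carries exactly 3 replicates")
    rng = np.random.default_rng(seed)
    ids = _protein_ids(n_proteins)
    n_shift = int(round(shifted_fraction * n_proteins))
    shifted = ids[:n_shift]

    base_ox = np.clip(
        rng.normal(base_ox_percent, base_sd_points, n_proteins), 2.0, 90.0
    )
    true_ox = pd.DataFrame(
        {c: base_ox.copy() for c in conditions}, index=pd.Index(ids, name="protein_id")
    )
    true_ox.loc[shifted, target_condition] += shift_points
    if ((true_ox <= 0) | (true_ox >= 100)).any().any():
        raise ValidationError("planted shifts push Ox% outside (0, 100)")

    n_pep = rng.integers(1, max_peptides + 1, n_proteins)
    rows = []
    for i, pid in enumerate(ids):
        for pep in range(n_pep[i]):
            seq = f"PEP{pid}_{pep}"
            pep_base_intensity = rng.lognormal(mean=np.log(1e6), sigma=1.0)
            for cond in conditions:
                ox = true_ox.loc[pid, cond] / 100.0
                row = {"protein_id": pid, "peptide_sequence": seq, "condition": cond}
                for r in range(n_reps):
                    total = pep_base_intensity * _lognormal_noise(rng, 0.2, None)
                    nf = _lognormal_noise(rng, intensity_cv, None)
                    no = _lognormal_noise(rng, intensity_cv, None)
                    row[SIXPLEX_FREE[r]] = total * (1.0 - ox) * nf
                    row[SIXPLEX_OXIDIZED[r]] = total * ox * no
                rows.append(row)
    peptides = pd.DataFrame(rows)
    design = pd.DataFrame(
        dict(
            set_id="iodoTMT",
            channel_label=list(SIXPLEX_FREE + SIXPLEX_OXIDIZED),
            condition="*",
            replicate=[1, 2, 3, 1, 2, 3],
            role=["free"] * 3 + ["oxidized"] * 3,
        )
    )
    truth = GroundTruth(
        proteins=true_ox, shifted=shifted, target_condition=target_condition
    )
    return peptides, design, truth


def simulate_tpp(
    n_proteins: int,
    conditions=("NW", "DDW"),
    n_reps: int = 2,
    tm_range=(44.0, 58.0),
    plateau_range=(0.0, 0.25),
    slope_range=(1.0, 4.0),
    shifted_fraction: float = 0.1,
    shift_C: float = 2.0,
    noise_sd: float = 0.03,
    seed: int = 0,
    temperatures=TPP_TEMPERATURES,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Melting-curve experiment: long table plus per-condition true Tm.

    Soluble fraction is the plateaued sigmoid evaluated at the ten design
    temperatures plus additive N(0, noise_sd), clipped at zero. The planted
    subset's Tm moves by ``shift_C`` in the treatment (second) condition.
    """
    if not (30.0 <= tm_range[0] <= tm_range[1] <= 75.0):
        raise ValidationError("tm_range outside fitting bounds")
    if not (0.0 <= plateau_range[0] <= plateau_range[1] < 1.0):
        raise ValidationError("invalid plateau range")
    if not (0.1 <= slope_range[0] <= slope_range[1] <= 20.0):
        raise ValidationError("slope range outside fitting bounds")
    conditions = list(conditions)
    control, treatment = conditions[0], conditions[-1]
    rng = np.random.default_rng(seed)
    ids = _protein_ids(n_proteins)
    n_shift = int(round(shifted_fraction * n_proteins))
    shifted = ids[:n_shift]
    tm = rng.uniform(*tm_range, n_proteins)
    pl = rng.uniform(*plateau_range, n_proteins)
    s = rng.uniform(*slope_range, n_proteins)
    true_tm = pd.DataFrame(
        {c: tm.copy() for c in conditions}, index=pd.Index(ids, name="protein_id")
    )
    true_tm.loc[shifted, treatment] += shift_C

    T = np.asarray(temperatures, dtype=float)
    rows = []
    for i, pid in enumerate(ids):
        for cond in conditions:
            for rep in range(1, n_reps + 1):
                frac = sigmoid_fraction(T, true_tm.loc[pid, cond], s[i], pl[i])
                if noise_sd > 0:
                    frac = frac + rng.normal(0.0, noise_sd, len(T))
                frac = np.clip(frac, 0.0, None)
                for t, f in zip(T, frac):
                    rows.append(
                        dict(
                            protein_id=pid, condition=cond, replicate=rep,
                            temperature_C=t, abundance=f,
                        )
                    )
    table = pd.DataFrame(rows)
    truth_frame = true_tm.copy()
    truth_frame["slope_s"] = s
    truth_frame["plateau_pl"] = pl
    truth = GroundTruth(
        proteins=truth_frame, shifted=shifted, target_condition=treatment
    )
    return table, truth


def simulate_timecourse(
    n_proteins: int,
    timepoints_h=(4.0, 15.0, 26.0, 38.0, 48.0),
    onset_h: float = 26.0,
    effect_log2: float = 0.4,
    n_reps: int = 2,
    n_up: int = 50,
    n_down: int = 50,
    noise_sd_log2: float = 0.0,
    seed: int = 0,
    condition: str = "DDW",
) -> tuple[ReporterMatrix, GroundTruth]:
    """Time-course ratios to the late vehicle bridge with a planted onset.

    Planted up (down) proteins sit at ratio 1 before ``onset_h`` and at
    ``2**effect_log2`` (``2**-effect_log2``) from the onset onward; all
    other proteins stay at 1. Gaussian noise of ``noise_sd_log2`` acts on
    the log2 ratio. ``onset_h`` past the last timepoint plants no change.
    """
    timepoints = sorted(float(t) for t in timepoints_h)
    if onset_h < timepoints[0] and onset_h != timepoints[0]:
        raise ValidationError("onset before the first timepoint")
    if n_up + n_down > n_proteins:
        raise ValidationError("planted proteins exceed n_proteins")
    rng = np.random.default_rng(seed)
    ids = _protein_ids(n_proteins)
    up = ids[:n_up]
    down = ids[n_up : n_up + n_down]
    sign = np.zeros(n_proteins)
    sign[:n_up] = 1.0
    sign[n_up : n_up + n_down] = -1.0

    columns = {}
    design_rows = []
    for tp in timepoints:
        active = tp >= onset_h
        for rep in range(1, n_reps + 1):
            log2_ratio = sign * effect_log2 if active else np.zeros(n_proteins)
            if noise_sd_log2 > 0:
                log2_ratio = log2_ratio + rng.normal(0.0, noise_sd_log2, n_proteins)
            key = f"t{tp:g}_r{rep}"
            columns[key] = 2.0**log2_ratio
            design_rows.append(
                dict(
                    set_id=key, channel_label="126", condition=condition,
                    replicate=rep, timepoint_h=tp, temperature_C=np.nan,
                    role="sample",
                )
            )
    design = pd.DataFrame(design_rows)
    design = validate_design(design)
    abundances = pd.DataFrame(columns, index=pd.Index(ids, name="protein_id"))
    abundances.columns = list(design.index)
    meta = pd.DataFrame(
        {
            "gene_name": [f"G{i}" for i in range(n_proteins)],
            "peptide_count": 2,
            "is_reverse": False,
            "is_contaminant": False,
        },
        index=abundances.index,
    )
    matrix = ReporterMatrix(abundances, meta, design, normalized=True)
    truth_frame = pd.DataFrame(
        {
            "class": ["up"] * n_up + ["down"] * n_down + ["background"] * (n_proteins - n_up - n_down),
            "effect_log2": sign * effect_log2,
        },
        index=abundances.index,
    )
    reached = onset_h <= timepoints[-1]
    truth = GroundTruth(
        proteins=truth_frame,
        specific_up=up,
        specific_down=down,
        onset_h=onset_h if reached else None,
        target_condition=condition,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# TSV export in the dialects the pipeline reads


def write_protein_groups(
    m: ReporterMatrix, path, set_id: str, prefix: str = "Reporter intensity corrected"
) -> None:
    """Write one labeling set as a proteinGroups-style TSV."""
    design = m.design[m.design["set_id"] == set_id]
    out = pd.DataFrame(
        {
            "Majority protein IDs": m.abundances.index,
            "Gene names": m.meta["gene_name"].to_numpy(),
            "Razor + unique peptides": m.meta["peptide_count"].to_numpy(),
            "Reverse": np.where(m.meta["is_reverse"], "+", ""),
            "Potential contaminant": np.where(m.meta["is_contaminant"], "+", ""),
        }
    )
    for key, row in design.iterrows():
        out[f"{prefix} {row['channel_label']}"] = m.abundances[key].to_numpy()
    out.to_csv(path, sep="\t", index=False)


def write_design(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index=False)
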