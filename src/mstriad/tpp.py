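"""Thermal proteome profiling: sigmoid melting curves and Tm shifts.

Soluble protein remaining after a brief heat challenge decays with
temperature; per protein, condition and replicate the fraction (relative to
the lowest temperature) is fitted to a plateaued sigmoid

    f(T) = pl + (1 - pl) / (1 + exp((T - Tm) / s))

so that the melting temperature Tm is literally the curve's middle point:
f(Tm) = (1 + pl) / 2. A Savitski-style alternative
``f(T) = (1 - pl)/(1 + exp(b - a/T)) + pl`` is provided, with its Tm solved
numerically from the same midpoint condition.

Fits are bounded nonlinear least squares with deterministic multi-start
initialization; refitting identical input is bit-identical. The shift
dTm = mean Tm(treatment) - mean Tm(control) is positive when the treatment
thermally stabilizes the protein, tested with a two-tailed unpaired t test
on per-replicate Tm values. With two replicates per condition that test has
2 degrees of freedom and little power, so a seeded residual-bootstrap p is
available as a secondary readout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from mstriad.errors import ValidationError

TPP_TEMPERATURES = (37.0, 41.0, 44.0, 47.0, 50.0, 53.0, 56.0, 59.0, 63.0, 67.0)

# fitting bounds: pl in [0, 1), s in [0.1, 20] degC, Tm in [30, 75] degC
BOUNDS_LO = np.array([30.0, 0.1, 0.0])
BOUNDS_HI = np.array([75.0, 20.0, 0.999])
MIN_POINTS = 5


def sigmoid_fraction(T, tm, s, pl):
    """Plateaued melting sigmoid; equals (1+pl)/2 at T = tm."""
    T = np.asarray(T, dtype=float)
    return pl + (1.0 - pl) / (1.0 + np.exp((T - tm) / s))


def savitski_fraction(T, a, b, pl):
    """Alternative parameterization with 1/T temperature dependence."""
    T = np.asarray(T, dtype=float)
    return (1.0 - pl) / (1.0 + np.exp(b - a / T)) + pl


def savitski_tm(a, b, pl, bracket=(20.0, 95.0)):
    """Midpoint temperature of the 1/T sigmoid, solved numerically from
    f(Tm) = (1 + pl) / 2."""
    target = (1.0 + pl) / 2.0

    def g(T):
        return savitski_fraction(T, a, b, pl) - target

    lo, hi = bracket
    if g(lo) * g(hi) > 0:
        return float("nan")
    return float(optimize.brentq(g, lo, hi, xtol=1e-10))


@dataclass
class MeltingCurve:
    """One replicate's soluble-fraction series over the temperature ladder."""

    protein_id: str
    condition: str
    replicate: int
    temperatures_C: np.ndarray
    soluble_fraction: np.ndarray

    @property
    def n_points(self) -> int:
        return int(np.isfinite(self.soluble_fraction).sum())


@dataclass
class MeltingFit:
    """Fitted sigmoid parameters for one melting curve."""

    protein_id: str
    condition: str
    replicate: int
    tm_C: float
    slope_s: float
    plateau_pl: float
    r2_fit: float
    converged: bool
    reason: str = ""


def normalize_to_lowest_temperature(abundances) -> np.ndarray:
    """Soluble fraction: divide by the abundance at the lowest (first)
    temperature; missing interior points stay missing."""
    a = np.asarray(abundances, dtype=float)
    if not np.isfinite(a[0]) or a[0] <= 0:
        raise ValidationError("missing or zero abundance at the lowest temperature")
    return a / a[0]


def _initial_starts(T: np.ndarray, y: np.ndarray) -> list[np.ndarray]:
    """Deterministic multi-start grid: data-driven start plus three offsets."""
    lo, hi = float(np.nanmin(y)), float(np.nanmax(y))
    half = (lo + hi) / 2.0
    tm0 = float(T[np.nanargmin(np.abs(y - half))])
    tm0 = float(np.clip(tm0, BOUNDS_LO[0], BOUNDS_HI[0]))
    pl0 = float(np.clip(lo, 0.0, 0.399))
    starts = [np.array([tm0, 2.0, pl0])]
    for dtm, s0 in ((-5.0, 5.0), (0.0, 5.0), (5.0, 5.0)):
        starts.append(
            np.array([np.clip(tm0 + dtm, BOUNDS_LO[0], BOUNDS_HI[0]), s0, pl0])
        )
    return starts


def fit_melting_curve(
    curve: MeltingCurve,
    r2_threshold: float = 0.8,
    model: str = "midpoint",
) -> MeltingFit:
    """Bounded least-squares fit of the melting sigmoid.

    Requires at least 5 quantified points. Runs every deterministic start
    and keeps the lowest residual sum of squares. ``converged`` requires
    optimizer success, an interior melting transition, and
    ``r2_fit >= r2_threshold``. With ``model="savitski"`` the 1/T
    parameterization is fitted and Tm recovered from its midpoint.
    """
    mask = np.isfinite(curve.soluble_fraction)
    T = np.asarray(curve.temperatures_C, dtype=float)[mask]
    y = np.asarray(curve.soluble_fraction, dtype=float)[mask]
    base = dict(
        protein_id=curve.protein_id,
        condition=curve.condition,
        replicate=curve.replicate,
    )
    if len(y) < MIN_POINTS:
        return MeltingFit(
            **base, tm_C=np.nan, slope_s=np.nan, plateau_pl=np.nan,
            r2_fit=np.nan, converged=False, reason=f"only {len(y)} points",
        )
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if model == "savitski":
        return _fit_savitski(base, T, y, ss_tot, r2_threshold)

    def resid(theta):
        return sigmoid_fraction(T, *theta) - y

    best = None
    for x0 in _initial_starts(T, y):
        sol = optimize.least_squares(
            resid, x0, bounds=(BOUNDS_LO, BOUNDS_HI), method="trf", xtol=1e-12,
            ftol=1e-12, gtol=1e-12,
        )
        if best is None or sol.cost < best.cost - 1e-15:
            best = sol
    tm, s, pl = best.x
    ss_res = float(2.0 * best.cost)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    # a flat series has no transition: the sigmoid explains nothing beyond
    # the mean, so r2 stays near or below 0 and the fit is not accepted;
    # pl >= 0.5 means the "melted" state keeps most of the signal — not a
    # usable transition either
    converged = bool(best.success) and r2 >= r2_threshold and pl < 0.5
    reason = "" if converged else f"r2={r2:.3f} below threshold or pl={pl:.2f} >= 0.5"
    if not best.success:
        reason = "optimizer failure"
    return MeltingFit(
        **base, tm_C=float(tm), slope_s=float(s), plateau_pl=float(pl),
        r2_fit=float(r2), converged=converged, reason=reason,
    )


def _fit_savitski(base, T, y, ss_tot, r2_threshold):
    def resid(theta):
        return savitski_fraction(T, *theta) - y

    lo = np.array([1.0, 0.0, 0.0])
    hi = np.array([1e5, 2000.0, 0.999])
    best = None
    for a0 in (1000.0, 3000.0, 6000.0):
        x0 = np.array([a0, a0 / 50.0, max(float(y.min()), 0.0)])
        sol = optimize.least_squares(resid, x0, bounds=(lo, hi), method="trf")
        if best is None or sol.cost < best.cost - 1e-15:
            best = sol
    a, b, pl = best.x
    ss_res = float(2.0 * best.cost)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    tm = savitski_tm(a, b, pl)
    converged = bool(best.success) and r2 >= r2_threshold and np.isfinite(tm)
    return MeltingFit(
        **base, tm_C=tm, slope_s=np.nan, plateau_pl=float(pl),
        r2_fit=float(r2), converged=converged,
        reason="" if converged else "poor fit",
    )


@dataclass
class TmShift:
    """Melting-temperature shift of one protein between two conditions."""

    protein_id: str
    delta_tm_C: float
    p_value: float
    n_reps: tuple[int, int]
    mean_tm_treatment: float = np.nan
    mean_tm_control: float = np.nan
    reason: str = ""


def delta_tm(
    treatment_fits: list[MeltingFit],
    control_fits: list[MeltingFit],
    equal_var: bool = True,
) -> TmShift:
    """dTm = mean Tm(treatment) - mean Tm(control), positive = stabilized.

    Only converged fits enter. The p value is a two-tailed unpaired t test
    on the per-replicate Tm values and requires at least two converged fits
    per condition; otherwise the shift is reported with a missing p.
    """
    trt = [f.tm_C for f in treatment_fits if f.converged]
    ctl = [f.tm_C for f in control_fits if f.converged]
    pid = (treatment_fits + control_fits)[0].protein_id if (treatment_fits or control_fits) else ""
    if not trt or not ctl:
        return TmShift(
            protein_id=pid, delta_tm_C=np.nan, p_value=np.nan,
            n_reps=(len(trt), len(ctl)), reason="no converged fit in a condition",
        )
    delta = float(np.mean(trt) - np.mean(ctl))
    if len(trt) >= 2 and len(ctl) >= 2:
        p = float(stats.ttest_ind(trt, ctl, equal_var=equal_var).pvalue)
        reason = ""
    else:
        p = np.nan
        reason = "fewer than 2 converged fits per condition; p not computed"
    return TmShift(
        protein_id=pid, delta_tm_C=delta, p_value=p,
        n_reps=(len(trt), len(ctl)),
        mean_tm_treatment=float(np.mean(trt)), mean_tm_control=float(np.mean(ctl)),
        reason=reason,
    )


def bootstrap_delta_tm_p(
    treatment_curves: list[MeltingCurve],
    control_curves: list[MeltingCurve],
    n_boot: int = 999,
    seed: int = 0,
) -> float:
    """Curve-level residual-bootstrap p for dTm (secondary to the t test).

    Pools residuals from the per-replicate fits, resamples them onto the
    fitted curves under the no-shift null (common Tm), and counts bootstrap
    |dTm*| at least as large as observed. Seeded and deterministic.
    """
    rng = np.random.default_rng(seed)
    fits = {
        "t": [fit_melting_curve(c) for c in treatment_curves],
        "c": [fit_melting_curve(c) for c in control_curves],
    }
    if not all(f.converged for fs in fits.values() for f in fs):
        return float("nan")
    obs = np.mean([f.tm_C for f in fits["t"]]) - np.mean([f.tm_C for f in fits["c"]])
    # null: every curve shares the pooled mean Tm but keeps its own s, pl
    pooled_tm = float(np.mean([f.tm_C for fs in fits.values() for f in fs]))
    resid_pool = []
    for curves, fs in ((treatment_curves, fits["t"]), (control_curves, fits["c"])):
        for c, f in zip(curves, fs):
            pred = sigmoid_fraction(c.temperatures_C, f.tm_C, f.slope_s, f.plateau_pl)
            resid_pool.extend(np.asarray(c.soluble_fraction) - pred)
    resid_pool = np.asarray(resid_pool)
    count = 0
    for _ in range(n_boot):
        deltas = {"t": [], "c": []}
        for arm, (curves, fs) in (
            ("t", (treatment_curves, fits["t"])),
            ("c", (control_curves, fits["c"])),
        ):
            for c, f in zip(curves, fs):
                null_pred = sigmoid_fraction(
                    c.temperatures_C, pooled_tm, f.slope_s, f.plateau_pl
                )
                yb = null_pred + rng.choice(resid_pool, size=len(null_pred))
                fb = fit_melting_curve(
                    MeltingCurve(c.protein_id, c.condition, c.replicate,
                                 np.asarray(c.temperatures_C, dtype=float), yb),
                    r2_threshold=0.0,
                )
                deltas[arm].append(fb.tm_C)
        db = np.mean(deltas["t"]) - np.mean(deltas["c"])
        if abs(db) >= abs(obs):
            count += 1
    return float((count + 1) / (n_boot + 1))


def curves_from_long(table: pd.DataFrame, normalize: bool = True) -> list[MeltingCurve]:
    """Build curves from a long table (protein_id, condition, replicate,
    temperature_C, abundance), sorting each series by temperature."""
    curves = []
    for (pid, cond, rep), grp in table.groupby(
        ["protein_id", "condition", "replicate"], sort=True
    ):
        grp = grp.sort_values("temperature_C")
        y = grp["abundance"].to_numpy(dtype=float)
        if normalize:
            try:
                y = normalize_to_lowest_temperature(y)
            except ValidationError:
                # unusable curve: no anchor at the lowest temperature
                y = np.full_like(y, np.nan)
        curves.append(
            MeltingCurve(
                protein_id=str(pid), condition=str(cond), replicate=int(rep),
                temperatures_C=grp["temperature_C"].to_numpy(dtype=float),
                soluble_fraction=y,
            )
        )
    return curves


def fit_all_curves(curves: list[MeltingCurve], **kw) -> pd.DataFrame:
    """Fit every curve; returns one row per (protein, condition, replicate)."""
    rows = [vars(fit_melting_curve(c, **kw)) for c in curves]
    return pd.DataFrame(rows)


def all_shifts(
    fits: pd.DataFrame, treatment: str, control: str, equal_var: bool = True
) -> list[TmShift]:
    """dTm for every protein with fits in both conditions."""
    shifts = []
    for pid, grp in fits.groupby("protein_id", sort=True):
        trt = [MeltingFit(**r) for r in grp[grp["condition"] == treatment].to_dict("records")]
        ctl = [MeltingFit(**r) for r in grp[grp["condition"] == control].to_dict("records")]
        if not trt or not ctl:
            continue
        shifts.append(delta_tm(trt, ctl, equal_var=equal_var))
    return shifts


def tpp_volcano(
    shifts: list[TmShift],
    dtm_threshold: float = 1.5,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Flag proteins with |dTm| >= threshold and p < threshold."""
    rows = []
    for s in shifts:
        rows.append(
            {
                "protein_id": s.protein_id,
                "delta_tm_C": s.delta_tm_C,
                "p_value": s.p_value,
                "n_treatment": s.n_reps[0],
                "n_control": s.n_reps[1],
                "hit": bool(
                    np.isfinite(s.delta_tm_C)
                    and np.isfinite(s.p_value)
                    and abs(s.delta_tm_C) >= dtm_threshold
                    and s.p_value < p_threshold
                ),
            }
        )
    return pd.DataFrame(rows)
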