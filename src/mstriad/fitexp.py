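"""Treatment-specific protein ranking by OPLS-DA, and time-course statistics.

The expression contrast asks which proteins respond to ONE treatment
specifically, against a background of co-treatments chosen to be equally
growth-suppressive. Proteins regulated by cell death or survival programs
move in *every* treatment; the orthogonal component of an OPLS-DA model
absorbs exactly that class-independent variation, so the predictive
component (and its VIP) ranks treatment-specific regulation.

Model construction (orthogonal signal correction, single predictive
component): with column-scaled ``X`` and centered class code ``y``,

1. ``w = X'y / ||X'y||``
2. for each orthogonal component: ``t = Xw``, ``p = X't/t't``,
   ``w_o = p - (w'p)w`` (normalized), ``t_o = Xw_o``,
   ``p_o = X't_o/t_o't_o``, deflate ``X <- X - t_o p_o'``
3. refit ``w`` on the deflated ``X`` and take the one-component PLS
   solution ``t = Xw``, ``p = X't/t't``, ``c = y't/t't``.

Orthogonal scores are exactly uncorrelated with ``y`` by construction.

VIP is defined on the single predictive component: ``vip_j = sqrt(K)|w_j|``
with unit-norm ``w`` over the K retained variables, so mean(vip^2) = 1.

Model quality is reported as R2X[cum], R2Y, cross-validated Q2 (7-fold,
deterministic venetian-blind fold assignment: sample i -> fold i mod 7) and
a CV-ANOVA p value (F comparison of the cross-validated residual sum of
squares against the total corrected sum of squares of y).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from mstriad.errors import ConfigurationError, ValidationError
from mstriad.quantio import ReporterMatrix

SCALINGS = ("uv", "pareto", "center-only")


@dataclass
class OplsModel:
    """Fitted OPLS-DA model with one predictive component.

    Weights, loadings and VIP are indexed over the retained (non-constant)
    variables; ``retained`` maps them back to the input columns.
    """

    weights_w: np.ndarray
    predictive_scores_t: np.ndarray
    predictive_loadings_p: np.ndarray
    y_loading_c: float
    orthogonal_scores_T: np.ndarray
    orthogonal_loadings_P: np.ndarray
    orthogonal_weights_W: np.ndarray
    vip: np.ndarray
    r2x_cum: float
    r2y: float
    scaling: str
    column_means: np.ndarray
    column_scales: np.ndarray
    y_mean: float
    classes: tuple
    retained: np.ndarray
    variable_names: np.ndarray
    q2_cum: float = np.nan
    cvanova_p: float = np.nan

    @property
    def n_ortho(self) -> int:
        return self.orthogonal_scores_T.shape[1]

    def transform(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Project new samples: returns (predictive score, orthogonal scores)."""
        Xs = (np.asarray(X, dtype=float)[:, self.retained] - self.column_means) / self.column_scales
        T_o = np.empty((Xs.shape[0], self.n_ortho))
        for i in range(self.n_ortho):
            t_o = Xs @ self.orthogonal_weights_W[:, i]
            Xs = Xs - np.outer(t_o, self.orthogonal_loadings_P[:, i])
            T_o[:, i] = t_o
        return Xs @ self.weights_w, T_o

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Numeric class prediction (class code scale, mean added back)."""
        t, _ = self.transform(X)
        return t * self.y_loading_c + self.y_mean


def _encode_classes(y) -> tuple[np.ndarray, tuple]:
    y = np.asarray(y)
    # sorted so the coding is identical in every cross-validation fold
    classes = tuple(np.unique(y))
    if len(classes) != 2:
        raise ValidationError(f"need exactly 2 classes, got {len(classes)}")
    code = np.where(y == classes[1], 1.0, -1.0)
    return code, classes


def _scale_columns(X: np.ndarray, scaling: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    means = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if scaling == "uv":
        scales = sd
    elif scaling == "pareto":
        scales = np.sqrt(sd)
    elif scaling == "center-only":
        scales = np.ones_like(sd)
    else:
        raise ValueError(f"unknown scaling {scaling!r}; choose from {SCALINGS}")
    return (X - means) / scales, means, scales


def fit_oplsda(
    X,
    y,
    n_ortho: int = 1,
    scaling: str = "uv",
    variable_names=None,
) -> OplsModel:
    """Fit an OPLS-DA model with one predictive and ``n_ortho`` orthogonal
    components.

    Zero-variance variables are removed before scaling (their indicator is
    kept in ``model.retained``). Requires at least two samples per class and
    ``n_ortho`` strictly below the rank of the scaled matrix.
    """
    X = np.asarray(X, dtype=float)
    if np.isnan(X).any():
        raise ValidationError("X contains missing values; complete cases required")
    code, classes = _encode_classes(y)
    if min((code == -1).sum(), (code == 1).sum()) < 2:
        raise ValidationError("need at least 2 samples per class")
    if variable_names is None:
        variable_names = np.array([f"v{j}" for j in range(X.shape[1])])
    else:
        variable_names = np.asarray(variable_names)

    retained = X.std(axis=0, ddof=1) > 0
    Xr = X[:, retained]
    if Xr.shape[1] == 0:
        raise ValidationError("all variables have zero variance")
    Xs, means, scales = _scale_columns(Xr, scaling)
    rank = np.linalg.matrix_rank(Xs)
    if n_ortho < 0:
        raise ValueError("n_ortho must be non-negative")
    if n_ortho >= rank:
        raise ValidationError(f"n_ortho={n_ortho} must be below rank(X)={rank}")
    yc = code - code.mean()
    ss_x = (Xs**2).sum()
    ss_y = (yc**2).sum()

    Xd = Xs.copy()
    K = Xd.shape[1]
    W_o = np.empty((K, n_ortho))
    T_o = np.empty((Xd.shape[0], n_ortho))
    P_o = np.empty((K, n_ortho))
    for i in range(n_ortho):
        w = Xd.T @ yc
        w /= np.linalg.norm(w)
        t = Xd @ w
        p = Xd.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        norm = np.linalg.norm(w_o)
        if norm < 1e-12:
            raise ValidationError(
                "no class-orthogonal variation left; reduce n_ortho"
            )
        w_o /= norm
        t_o = Xd @ w_o
        p_o = Xd.T @ t_o / (t_o @ t_o)
        Xd = Xd - np.outer(t_o, p_o)
        W_o[:, i], T_o[:, i], P_o[:, i] = w_o, t_o, p_o

    w = Xd.T @ yc
    w /= np.linalg.norm(w)
    t = Xd @ w
    p = Xd.T @ t / (t @ t)
    c = float(yc @ t / (t @ t))

    modeled = np.outer(t, p) + T_o @ P_o.T
    r2x = float((modeled**2).sum() / ss_x)
    r2y = float(1.0 - ((yc - t * c) ** 2).sum() / ss_y)
    vip = np.sqrt(K) * np.abs(w)
    return OplsModel(
        weights_w=w,
        predictive_scores_t=t,
        predictive_loadings_p=p,
        y_loading_c=c,
        orthogonal_scores_T=T_o,
        orthogonal_loadings_P=P_o,
        orthogonal_weights_W=W_o,
        vip=vip,
        r2x_cum=r2x,
        r2y=r2y,
        scaling=scaling,
        column_means=means,
        column_scales=scales,
        y_mean=float(code.mean()),
        classes=classes,
        retained=retained,
        variable_names=variable_names,
    )


def vip_predictive(model: OplsModel) -> np.ndarray:
    """VIP of the predictive component: ``sqrt(K)|w_j|`` over K retained
    variables (unit-norm weights), so the mean squared VIP is exactly 1."""
    K = model.weights_w.size
    return np.sqrt(K) * np.abs(model.weights_w)


def _venetian_folds(n: int, folds: int) -> np.ndarray:
    return np.arange(n) % folds


def _cv_predictions(X, y, folds: int, n_ortho: int, scaling: str) -> np.ndarray:
    """Held-out numeric predictions under venetian-blind fold assignment."""
    X = np.asarray(X, dtype=float)
    code, _ = _encode_classes(y)
    n = len(code)
    if folds > n:
        raise ValueError("more folds than samples")
    assign = _venetian_folds(n, folds)
    yhat = np.empty(n)
    for f in range(folds):
        test = assign == f
        train = ~test
        if len(np.unique(code[train])) < 2:
            raise ValidationError(
                f"fold {f} leaves a single class in training; use fewer folds"
            )
        model = fit_oplsda(X[train], code[train], n_ortho=n_ortho, scaling=scaling)
        yhat[test] = model.predict(X[test])
    return yhat


def q2_crossval(
    X, y, folds: int = 7, n_ortho: int = 1, scaling: str = "uv"
) -> float:
    """Cross-validated predictive fraction Q2 = 1 - PRESS/SS.

    PRESS is the squared error of held-out class predictions; SS the total
    corrected sum of squares of the class code. Folds are deterministic
    venetian blinds (sample i -> fold i mod ``folds``); ``folds`` equal to
    the sample count gives leave-one-out. Q2 can be negative.
    """
    code, _ = _encode_classes(y)
    yhat = _cv_predictions(X, y, folds, n_ortho, scaling)
    press = ((code - yhat) ** 2).sum()
    ss = ((code - code.mean()) ** 2).sum()
    return float(1.0 - press / ss)


def cv_anova(X, y, model: OplsModel | None = None, folds: int = 7) -> float:
    """Model-significance p value from an F test on cross-validated residuals.

    Compares the variance explained in cross-validation, ``(SS - PRESS)``
    over the model degrees of freedom (1 predictive + n_ortho components),
    against the cross-validated residual variance ``PRESS`` over the
    remaining degrees of freedom. Scale-invariant in X. A perfectly
    predicted response (PRESS ~ 0) reports the smallest positive float.
    """
    n_ortho = model.n_ortho if model is not None else 1
    scaling = model.scaling if model is not None else "uv"
    code, _ = _encode_classes(y)
    yhat = _cv_predictions(X, y, folds, n_ortho, scaling)
    press = ((code - yhat) ** 2).sum()
    ss = ((code - code.mean()) ** 2).sum()
    n = len(code)
    df_model = 1 + n_ortho
    df_resid = n - 1 - df_model
    if df_resid <= 0:
        raise ValidationError("too few samples for CV-ANOVA degrees of freedom")
    if press <= ss * 1e-12:
        return float(np.finfo(float).tiny)
    F = max(ss - press, 0.0) / df_model / (press / df_resid)
    return float(stats.f.sf(F, df_model, df_resid))


@dataclass
class ContrastResult:
    """Signed top-k protein lists for one treatment-vs-rest contrast."""

    target_condition: str
    up: pd.DataFrame
    down: pd.DataFrame
    model: OplsModel
    dropped_incomplete: int = 0

    def all_rows(self) -> pd.DataFrame:
        up = self.up.assign(regulation="up")
        down = self.down.assign(regulation="down")
        return pd.concat([up, down], ignore_index=True)


def contrast_topk(
    m: ReporterMatrix,
    target_condition: str,
    k: int = 50,
    n_ortho: int = 1,
    scaling: str = "uv",
) -> ContrastResult:
    """Contrast one condition against all pooled others and rank proteins.

    Samples are rows and proteins variables (log2 relative abundances, per
    the multiplicative noise model). The sign of each protein is the sign of
    its predictive weight times the y loading, with the class code oriented
    so that positive means higher in the target condition. The top ``k``
    proteins by VIP are returned per sign; VIP ties break by protein id.
    The model's Q2 and CV-ANOVA p are attached; a contrast with Q2 <= 0 is
    flagged with a warning as non-significant.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not m.normalized:
        raise ValidationError("matrix must be normalized before contrasting")
    sample_cols = m.columns_with_role("sample")
    design = m.design.loc[sample_cols]
    if target_condition not in set(design["condition"]):
        raise ConfigurationError(f"condition {target_condition!r} not in design")
    sub = m.abundances[sample_cols]
    complete = sub.notna().all(axis=1)
    dropped = int((~complete).sum())
    sub = sub.loc[complete]
    X = np.log2(sub.to_numpy(dtype=float)).T  # samples x proteins
    # orient the code so +1 is the target class
    y = np.where(design["condition"].to_numpy() == target_condition, "__target__", "__rest__")
    y = pd.Categorical(y, categories=["__rest__", "__target__"])
    model = fit_oplsda(X, np.asarray(y), n_ortho=n_ortho, scaling=scaling,
                       variable_names=sub.index.to_numpy())
    folds = min(7, X.shape[0])
    model.q2_cum = q2_crossval(X, np.asarray(y), folds=folds, n_ortho=n_ortho, scaling=scaling)
    try:
        model.cvanova_p = cv_anova(X, np.asarray(y), model, folds=folds)
    except ValidationError:
        model.cvanova_p = np.nan
    if model.q2_cum <= 0:
        warnings.warn(
            f"contrast {target_condition!r}: Q2={model.q2_cum:.3f} <= 0, "
            "model not significant",
            stacklevel=2,
        )

    sign = np.sign(model.weights_w * model.y_loading_c)
    ids = model.variable_names[model.retained]
    genes = m.meta.loc[complete, "gene_name"].to_numpy()[model.retained]
    table = pd.DataFrame(
        {"protein_id": ids, "gene_name": genes, "vip": model.vip, "sign": sign}
    )
    table = table.sort_values(
        ["vip", "protein_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    up = table[table["sign"] > 0].head(k).reset_index(drop=True)
    down = table[table["sign"] < 0].head(k).reset_index(drop=True)
    for name, lst in (("up", up), ("down", down)):
        if len(lst) < k:
            warnings.warn(
                f"only {len(lst)} {name}-regulated proteins available (k={k})",
                stacklevel=2,
            )
    return ContrastResult(target_condition, up, down, model, dropped)


@dataclass
class TimecourseResult:
    """Characteristic time of action under the two trigger rules."""

    characteristic_time_h: float | None
    reached: bool
    marker_protein: str
    marker_ratio: dict[float, float]
    per_timepoint_group_p: dict[float, float]
    group_p_time_h: float | None


def characteristic_time(
    timecourse: ReporterMatrix,
    up_set,
    down_set,
    threshold: float = 0.20,
    marker_protein: str | None = None,
    condition: str | None = None,
) -> TimecourseResult:
    """Earliest timepoint of proteome response, by two rules.

    Single-protein rule: the earliest designed timepoint at which the
    marker protein's mean relative abundance deviates from 1 by at least
    ``threshold`` (abundances must already be ratios to the late vehicle
    bridge). Group rule: per timepoint, a Welch t test between the log2
    regulations of the up set and the down set; the earliest timepoint with
    p < 0.05. The marker defaults to the first protein of the up set (the
    highest-VIP upregulated protein).
    """
    up_set = list(up_set)
    down_set = list(down_set)
    if marker_protein is None:
        if not up_set:
            raise ValueError("empty up set and no marker protein given")
        marker_protein = up_set[0]
    if marker_protein not in timecourse.abundances.index:
        raise KeyError(f"marker protein {marker_protein!r} absent from matrix")

    cols = timecourse.columns_with_role("sample")
    design = timecourse.design.loc[cols]
    if condition is not None:
        cols = list(design.index[design["condition"] == condition])
        design = design.loc[cols]
    timepoints = sorted(set(design["timepoint_h"].dropna()))
    if not timepoints:
        raise ConfigurationError("design has no sample timepoints")

    marker_ratio: dict[float, float] = {}
    group_p: dict[float, float] = {}
    char_time: float | None = None
    group_time: float | None = None
    up_ids = [p for p in up_set if p in timecourse.abundances.index]
    down_ids = [p for p in down_set if p in timecourse.abundances.index]
    for tp in timepoints:
        tp_cols = list(design.index[design["timepoint_h"] == tp])
        ratio = float(timecourse.abundances.loc[marker_protein, tp_cols].mean())
        marker_ratio[tp] = ratio
        if char_time is None and abs(ratio - 1.0) >= threshold:
            char_time = tp
        up_vals = np.log2(
            timecourse.abundances.loc[up_ids, tp_cols].mean(axis=1).to_numpy(dtype=float)
        )
        down_vals = np.log2(
            timecourse.abundances.loc[down_ids, tp_cols].mean(axis=1).to_numpy(dtype=float)
        )
        if len(up_vals) >= 2 and len(down_vals) >= 2:
            p = float(stats.ttest_ind(up_vals, down_vals, equal_var=False).pvalue)
        else:
            p = np.nan
        group_p[tp] = p
        if group_time is None and p < 0.05:
            group_time = tp
    return TimecourseResult(
        characteristic_time_h=char_time,
        reached=char_time is not None,
        marker_protein=marker_protein,
        marker_ratio=marker_ratio,
        per_timepoint_group_p=group_p,
        group_p_time_h=group_time,
    )


def model_summary(model: OplsModel) -> dict:
    """JSON-ready model quality summary."""
    return {
        "r2x_cum": model.r2x_cum,
        "r2y": model.r2y,
        "q2_cum": model.q2_cum,
        "cvanova_p": model.cvanova_p,
        "n_ortho": model.n_ortho,
        "scaling": model.scaling,
    }
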