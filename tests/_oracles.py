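"""Independent oracles used by the test suite.

Each oracle computes its quantity by a route independent of the library
implementation it checks: eigen-decomposition instead of the deflation
algorithm, exhaustive grid search instead of nonlinear least squares,
per-row Python loops instead of vectorized predicates.
"""

from __future__ import annotations

import numpy as np


def pls1_scores_eigen(X: np.ndarray, y: np.ndarray, scaling: str = "uv") -> np.ndarray:
    """Predictive scores of a 1-component PLS by eigen-decomposition.

    The PLS1 weight vector is the dominant eigenvector of X'yy'X (a rank-1
    matrix, but extracted through a full symmetric eigensolver rather than
    normalizing X'y directly).
    """
    X = np.asarray(X, dtype=float)
    yc = np.asarray(y, dtype=float)
    yc = yc - yc.mean()
    mu = X.mean(axis=0)
    if scaling == "uv":
        sc = X.std(axis=0, ddof=1)
    elif scaling == "pareto":
        sc = np.sqrt(X.std(axis=0, ddof=1))
    else:
        sc = np.ones(X.shape[1])
    Xs = (X - mu) / sc
    M = np.outer(Xs.T @ yc, yc @ Xs)
    vals, vecs = np.linalg.eigh(M)
    w = vecs[:, np.argmax(vals)]
    return Xs @ w


def grid_search_sigmoid_ss(T: np.ndarray, Y: np.ndarray,
                           tm_grid=None, s_grid=None, pl_grid=None) -> np.ndarray:
    """Exhaustive grid search: minimal residual SS per curve.

    Default grids: Tm 35-70 by 0.05, s 0.5-10 by 0.05, pl 0-0.4 by 0.01.
    ``Y`` is curves x temperatures. Evaluated in chunks via the identity
    SS = ||m||^2 - 2 m.y + ||y||^2 so the full grid never materializes
    against every curve at once.
    """
    T = np.asarray(T, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    tm_grid = np.arange(35.0, 70.0001, 0.05) if tm_grid is None else tm_grid
    s_grid = np.arange(0.5, 10.0001, 0.05) if s_grid is None else s_grid
    pl_grid = np.arange(0.0, 0.40001, 0.01) if pl_grid is None else pl_grid
    y_ss = (Y**2).sum(axis=1)
    best = np.full(Y.shape[0], np.inf)
    for pl in pl_grid:
        for s_chunk in np.array_split(s_grid, max(1, len(s_grid) // 50)):
            M = pl + (1.0 - pl) / (
                1.0 + np.exp((T[None, None, :] - tm_grid[:, None, None]) / s_chunk[None, :, None])
            )
            M2 = M.reshape(-1, len(T))
            ss = (M2**2).sum(axis=1)[:, None] - 2.0 * M2 @ Y.T + y_ss[None, :]
            best = np.minimum(best, ss.min(axis=0))
    return best


def rowwise_filter_oracle(is_reverse, is_contaminant, peptide_count, min_peptides):
    """Plain per-row loop deciding which proteins survive filtering."""
    keep = []
    for rev, con, pep in zip(is_reverse, is_contaminant, peptide_count):
        keep.append((not rev) and (not con) and pep >= min_peptides)
    return keep


def rowwise_complete_oracle(values_2d) -> list[bool]:
    """Per-row loop: complete-case flag for a 2-D array with NaN missing."""
    out = []
    for row in values_2d:
        out.append(all(np.isfinite(v) for v in row))
    return out
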