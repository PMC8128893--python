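"""Cross-tissue expression imputation weights.

Multi-tissue sparse group lasso: for one gene with standardized cis
genotypes X (n x m) and standardized expression y_t per tissue,

    minimize  sum_t (1/2n) ||y_t - X b_t||^2
              + lambda_lasso * sum_{j,t} |b_jt|
              + lambda_group * sum_j ||b_{j.}||_2

where a group is one SNP's coefficient vector across tissues.  Solved by
block coordinate descent with the closed-form proximal update available
when the same standardized design is shared across tissues.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from crosstwas.simulate import Genotypes


def _soft(x: np.ndarray, thr: float) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - thr, 0.0)


def sgl_objective(X: np.ndarray, Y: np.ndarray, B: np.ndarray, lam1: float, lam2: float) -> float:
    """Objective value; Y and B are (n x T) and (m x T)."""
    n = X.shape[0]
    resid = Y - X @ B
    loss = 0.5 / n * float((resid * resid).sum())
    return loss + lam1 * float(np.abs(B).sum()) + lam2 * float(np.linalg.norm(B, axis=1).sum())


def kkt_residual(X: np.ndarray, Y: np.ndarray, B: np.ndarray, lam1: float, lam2: float) -> float:
    """Maximum violation of the sparse-group-lasso stationarity conditions.

    Zero groups: ||soft(-grad_j, lam1)||_2 must not exceed lam2.
    Active groups: grad + lam1*sign + lam2*b/||b|| must vanish where
    b_jt != 0, and |grad_jt + lam2*b_jt/||b_j||| <= lam1 where b_jt = 0.
    """
    n, m = X.shape
    G = -(X.T @ (Y - X @ B)) / n  # gradient of the smooth part
    viol = 0.0
    norms = np.linalg.norm(B, axis=1)
    for j in range(m):
        if norms[j] == 0.0:
            s = _soft(-G[j], lam1)
            viol = max(viol, float(np.linalg.norm(s)) - lam2)
        else:
            grp = lam2 * B[j] / norms[j]
            active = B[j] != 0.0
            stat = G[j] + lam1 * np.sign(B[j]) + grp
            if active.any():
                viol = max(viol, float(np.abs(stat[active]).max()))
            inactive = ~active
            if inactive.any():
                viol = max(viol, float((np.abs(G[j] + grp) - lam1)[inactive].max()))
    return max(viol, 0.0)


@dataclass
class SglFit:
    coef: np.ndarray          # m x T
    objective_path: list[float]
    n_iter: int
    converged: bool


def sparse_group_lasso(
    X: np.ndarray,
    Y: np.ndarray,
    lambda_lasso: float,
    lambda_group: float,
    max_iter: int = 2000,
    tol: float = 1e-8,
) -> SglFit:
    """Fit one gene's multi-tissue weights.

    X and Y must be column-standardized (mean 0, sd 1, ddof 0) so that
    (1/n) x_j'x_j = 1 and the blockwise proximal step is exact.
    """
    if lambda_lasso < 0 or lambda_group < 0:
        raise ValueError("penalties must be non-negative")
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, m = X.shape
    if Y.shape[0] != n:
        raise ValueError("X and Y disagree on sample count")
    T = Y.shape[1]

    B = np.zeros((m, T))
    R = Y.copy()  # residual Y - X B
    path = [sgl_objective(X, Y, B, lambda_lasso, lambda_group)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for j in range(m):
            xj = X[:, j]
            zj = (xj @ R) / n + B[j]
            s = _soft(zj, lambda_lasso)
            ns = np.linalg.norm(s)
            new = np.zeros(T) if ns <= lambda_group else s * (1.0 - lambda_group / ns)
            delta = new - B[j]
            if np.any(delta):
                R -= np.outer(xj, delta)
                B[j] = new
        path.append(sgl_objective(X, Y, B, lambda_lasso, lambda_group))
        rel = abs(path[-2] - path[-1]) / max(abs(path[-2]), 1e-12)
        if rel < tol and kkt_residual(X, Y, B, lambda_lasso, lambda_group) <= 10 * max(tol, 1e-8):
            converged = True
            break
    return SglFit(coef=B, objective_path=path, n_iter=it, converged=converged)


def _standardize(A: np.ndarray) -> np.ndarray:
    mu = A.mean(axis=0)
    sd = A.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (A - mu) / sd


def train_cross_tissue(
    expression: np.ndarray,
    genotypes: Genotypes,
    annotation: pd.DataFrame,
    lambda_lasso: float,
    lambda_group: float,
    max_iter: int = 2000,
    tol: float = 1e-8,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Train a WeightPanel for every gene in the annotation.

    ``expression`` is tissues x subjects x genes from the reference
    cohort.  Returns (panel, fit_log); the panel stores nonzero weights
    on the standardized-genotype scale, the log records convergence per
    gene (non-converged genes keep their partial solution, flagged).
    """
    T = expression.shape[0]
    tissues = [f"tissue{t}" for t in range(T)]
    Xs = genotypes.standardized()
    rows, log = [], []
    for gi, gene in enumerate(annotation["gene_id"]):
        cols = genotypes.gene_columns(gene)
        X = Xs[:, cols]
        Y = _standardize(expression[:, :, gi].T)
        fit = sparse_group_lasso(X, Y, lambda_lasso, lambda_group, max_iter=max_iter, tol=tol)
        log.append({"gene_id": gene, "converged": fit.converged, "n_iter": fit.n_iter})
        block = genotypes.snps.iloc[cols].reset_index(drop=True)
        for t, tissue in enumerate(tissues):
            for j in range(len(cols)):
                w = fit.coef[j, t]
                if w != 0.0:
                    rows.append(
                        {
                            "gene_id": gene,
                            "tissue_id": tissue,
                            "snp_id": block.loc[j, "snp"],
                            "effect_allele": block.loc[j, "a1"],
                            "other_allele": block.loc[j, "a2"],
                            "weight": w,
                        }
                    )
    panel = pd.DataFrame(
        rows,
        columns=["gene_id", "tissue_id", "snp_id", "effect_allele", "other_allele", "weight"],
    )
    return panel, pd.DataFrame(log)


def cross_validate_penalties(
    expression: np.ndarray,
    genotypes: Genotypes,
    annotation: pd.DataFrame,
    grid: list[tuple[float, float]],
    n_folds: int = 5,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> tuple[tuple[float, float], pd.DataFrame]:
    """Pick (lambda_lasso, lambda_group) by k-fold held-out squared error
    summed over tissues and genes.  Folds come from a seeded permutation;
    exact ties break toward the sparser (larger-penalty) point.
    """
    if not grid:
        raise ValueError("penalty grid is empty")
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    n = genotypes.n
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, n_folds)
    Xs_all = genotypes.standardized()

    records = []
    for lam1, lam2 in grid:
        err = 0.0
        for f in range(n_folds):
            test_idx = folds[f]
            train_idx = np.concatenate([folds[k] for k in range(n_folds) if k != f])
            for gi, gene in enumerate(annotation["gene_id"]):
                cols = genotypes.gene_columns(gene)
                Xtr = _standardize(Xs_all[np.ix_(train_idx, cols)])
                Ytr = _standardize(expression[:, train_idx, gi].T)
                fit = sparse_group_lasso(Xtr, Ytr, lam1, lam2, max_iter=max_iter, tol=tol)
                Xte = _standardize(Xs_all[np.ix_(test_idx, cols)])
                Yte = _standardize(expression[:, test_idx, gi].T)
                resid = Yte - Xte @ fit.coef
                err += float((resid * resid).sum()) / len(test_idx)
        records.append({"lambda_lasso": lam1, "lambda_group": lam2, "cv_error": err})
    table = pd.DataFrame(records)
    # prefer sparser models on exact ties
    order = sorted(
        range(len(grid)),
        key=lambda i: (table.loc[i, "cv_error"], -(grid[i][0] + grid[i][1])),
    )
    best = grid[order[0]]
    return best, table
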