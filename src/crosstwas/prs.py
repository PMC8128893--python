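"""Gene-based polygenic scores and incremental-R2 evaluation.

Training: one linear regression per gene of the training phenotype on
its imputed expression plus covariates.  Scoring: at each p-value
cutoff of the threshold grid, the profile is the effect-size-weighted
sum of imputed expressions over the genes passing the cutoff.
Evaluation: nested OLS models

    m1: phenotype ~ covariates
    m2: phenotype ~ TWAS profile + covariates
    m3: phenotype ~ GWAS PRS + covariates
    m4: phenotype ~ TWAS profile + GWAS PRS + covariates

with incremental R2 read off as differences of model R2.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from crosstwas.simulate import Genotypes

DEFAULT_THRESHOLD_GRID: tuple[float, ...] = (
    1.0, 0.8, 0.5, 0.4, 0.3, 0.2, 0.1, 0.08, 0.05, 0.02,
    0.01, 0.001, 1e-4, 1e-5, 1e-6, 1e-7, 5e-8,
)


def validate_grid(grid: tuple[float, ...]) -> tuple[float, ...]:
    grid = tuple(float(g) for g in grid)
    if not grid:
        raise ValueError("threshold grid is empty")
    if any(b >= a for a, b in zip(grid, grid[1:])):
        raise ValueError("threshold grid must be strictly decreasing")
    return grid


def impute_expression(
    genotypes: Genotypes, weights: pd.DataFrame, tissue_id: str | None = None
) -> pd.DataFrame:
    """Subject x gene imputed expression Ê = X_std w for one panel.

    Weights whose effect allele is the genotype table's other allele are
    sign-flipped; mismatching or zero-variance SNPs are excluded.  Genes
    with no usable SNP are skipped.
    """
    if tissue_id is None:
        tissues = weights["tissue_id"].unique()
        if len(tissues) != 1:
            raise ValueError("panel holds several tissues; pass tissue_id")
        tissue_id = tissues[0]
    sub = weights[weights["tissue_id"] == tissue_id]
    snp_tab = genotypes.snps.set_index("snp")
    Xs = genotypes.standardized()
    sd = genotypes.X.astype(float).std(axis=0)
    col_of = {s: i for i, s in enumerate(genotypes.snps["snp"])}

    out: dict[str, np.ndarray] = {}
    for gene, g in sub.groupby("gene_id", sort=True):
        e = np.zeros(genotypes.n)
        used = 0
        for _, r in g.iterrows():
            snp = r["snp_id"]
            if snp not in col_of or sd[col_of[snp]] == 0.0:
                continue
            a1, a2 = snp_tab.loc[snp, "a1"], snp_tab.loc[snp, "a2"]
            if (r["effect_allele"], r["other_allele"]) == (a1, a2):
                sign = 1.0
            elif (r["effect_allele"], r["other_allele"]) == (a2, a1):
                sign = -1.0
            else:
                continue
            e += sign * r["weight"] * Xs[:, col_of[snp]]
            used += 1
        if used:
            out[gene] = e
    return pd.DataFrame(out)


def _ols_r2_and_last_p(X: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """R2 of y on X (with intercept) and the two-sided p of X's last column."""
    n = len(y)
    Z = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
    resid = y - Z @ beta
    sst = float(((y - y.mean()) ** 2).sum())
    ssr = float((resid**2).sum())
    r2 = 0.0 if sst == 0 else 1.0 - ssr / sst
    df = n - Z.shape[1]
    if df <= 0:
        return r2, float("nan")
    sigma2 = ssr / df
    XtX_inv = np.linalg.pinv(Z.T @ Z)
    se = np.sqrt(sigma2 * XtX_inv[-1, -1])
    if se == 0:
        return r2, float("nan")
    t = beta[-1] / se
    return r2, float(2.0 * stats.t.sf(abs(t), df))


def training_covariates(covariates: pd.DataFrame) -> pd.DataFrame:
    """Expand an age/sex frame into the fuller training adjustment set:
    age, age^2, sex, age*sex (age^2*sex when both present)."""
    out = covariates.copy()
    if "age" in out.columns:
        out["age2"] = out["age"] ** 2
        if "sex" in out.columns:
            out["age_sex"] = out["age"] * out["sex"]
            out["age2_sex"] = out["age2"] * out["sex"]
    return out


def train_gene_effects(
    phenotype: np.ndarray,
    expression: pd.DataFrame,
    covariates: pd.DataFrame,
    total_volume: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-gene effect sizes from training data.

    One OLS per gene: phenotype ~ Ê_g + covariates (+ total volume when
    supplied).  Returns gene_id, beta, p; rank-deficient or constant
    expression columns are skipped.
    """
    y = np.asarray(phenotype, dtype=float)
    C = covariates.to_numpy(dtype=float)
    if total_volume is not None:
        C = np.column_stack([C, np.asarray(total_volume, dtype=float)])
    if len(y) <= C.shape[1] + 2:
        raise ValueError("training cohort too small for the covariate set")
    rows = []
    n = len(y)
    for gene in expression.columns:
        e = expression[gene].to_numpy(dtype=float)
        if e.std() == 0:
            continue
        Z = np.column_stack([np.ones(n), C, e])
        if np.linalg.matrix_rank(Z) < Z.shape[1]:
            continue
        beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
        resid = y - Z @ beta
        df = n - Z.shape[1]
        sigma2 = float(resid @ resid) / df
        se = np.sqrt(sigma2 * np.linalg.pinv(Z.T @ Z)[-1, -1])
        t = beta[-1] / se
        rows.append({"gene_id": gene, "beta": float(beta[-1]), "p": float(2.0 * stats.t.sf(abs(t), df))})
    return pd.DataFrame(rows, columns=["gene_id", "beta", "p"])


def build_profiles(
    expression: pd.DataFrame,
    effects: pd.DataFrame,
    grid: tuple[float, ...] = DEFAULT_THRESHOLD_GRID,
) -> pd.DataFrame:
    """One profile per grid threshold: sum over genes with training
    p <= threshold of beta_g * Ê_g.  Thresholds passed by no gene give a
    zero profile, recorded in attrs["empty_thresholds"]."""
    grid = validate_grid(grid)
    eff = effects.set_index("gene_id")
    common = [g for g in expression.columns if g in eff.index]
    E = expression[common].to_numpy(dtype=float)
    beta = eff.loc[common, "beta"].to_numpy(dtype=float)
    pvals = eff.loc[common, "p"].to_numpy(dtype=float)
    cols, empty = {}, []
    for tau in grid:
        mask = pvals <= tau
        cols[tau] = E[:, mask] @ beta[mask] if mask.any() else np.zeros(len(expression))
        if not mask.any():
            empty.append(tau)
    out = pd.DataFrame(cols, index=expression.index)
    out.attrs["empty_thresholds"] = empty
    return out


def evaluate_incremental_r2(
    phenotype: np.ndarray,
    profiles: pd.DataFrame,
    covariates: pd.DataFrame,
    gwas_prs: np.ndarray | None = None,
) -> pd.DataFrame:
    """Incremental R2 per threshold from the nested models m1-m4.

    Evaluation covariates are used as given (age and sex).  Without a
    GWAS PRS, m3/m4 quantities are NaN.  attrs["best_threshold"] holds
    the grid point with the largest TWAS increment (selection optimism
    is the caller's to handle — all thresholds are reported).
    """
    y = np.asarray(phenotype, dtype=float)
    if y.std() == 0:
        raise ValueError("constant phenotype")
    C = covariates.to_numpy(dtype=float)
    r2_m1, _ = _ols_r2_and_last_p(C, y)
    if gwas_prs is not None:
        g = np.asarray(gwas_prs, dtype=float)
        r2_m3, _ = _ols_r2_and_last_p(np.column_stack([C, g]), y)
    rows = []
    for tau in profiles.columns:
        s = profiles[tau].to_numpy(dtype=float)
        r2_m2, p_coef = _ols_r2_and_last_p(np.column_stack([C, s]), y)
        rec = {
            "threshold": float(tau),
            "r2_m1": r2_m1,
            "r2_m2": r2_m2,
            "incr_twas": r2_m2 - r2_m1,
            "p_profile": p_coef,
        }
        if gwas_prs is None:
            rec.update(
                r2_m3=np.nan, r2_m4=np.nan, incr_gwas=np.nan,
                incr_joint=np.nan, incr_twas_given_gwas=np.nan, incr_gwas_given_twas=np.nan,
            )
        else:
            r2_m4, _ = _ols_r2_and_last_p(np.column_stack([C, s, g]), y)
            rec.update(
                r2_m3=r2_m3,
                r2_m4=r2_m4,
                incr_gwas=r2_m3 - r2_m1,
                incr_joint=r2_m4 - r2_m1,
                incr_twas_given_gwas=r2_m4 - r2_m3,
                incr_gwas_given_twas=r2_m4 - r2_m2,
            )
        rows.append(rec)
    out = pd.DataFrame(rows)
    out.attrs["best_threshold"] = float(out.loc[out["incr_twas"].idxmax(), "threshold"])
    return out


def gwas_prs(
    genotypes: Genotypes, gwas: pd.DataFrame, p_threshold: float = 1e-4
) -> np.ndarray:
    """Clumping-free variant-based score: standardized dosages weighted by
    GWAS z for SNPs passing the p cutoff (zero vector if none pass)."""
    sub = gwas[gwas["p"] <= p_threshold]
    if sub.empty:
        return np.zeros(genotypes.n)
    col_of = {s: i for i, s in enumerate(genotypes.snps["snp"])}
    snp_tab = genotypes.snps.set_index("snp")
    Xs = genotypes.standardized()
    score = np.zeros(genotypes.n)
    for _, r in sub.iterrows():
        snp = r["snp"]
        if snp not in col_of:
            continue
        a1, a2 = snp_tab.loc[snp, "a1"], snp_tab.loc[snp, "a2"]
        if (r["a1"], r["a2"]) == (a1, a2):
            sign = 1.0
        elif (r["a1"], r["a2"]) == (a2, a1):
            sign = -1.0
        else:
            continue
        score += sign * r["z"] * Xs[:, col_of[snp]]
    return score


def prs_multiplicity(
    n_roi_traits: int,
    n_roi_cohorts: int,
    n_dti_traits: int,
    n_dti_cohorts: int,
    alpha: float = 0.05,
) -> tuple[int, float]:
    """Number of PRS association tests and the Bonferroni threshold."""
    for v in (n_roi_traits, n_roi_cohorts, n_dti_traits, n_dti_cohorts):
        if v < 1:
            raise ValueError("counts must be positive")
    n_tests = n_roi_traits * n_roi_cohorts + n_dti_traits * n_dti_cohorts
    return n_tests, alpha / n_tests
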