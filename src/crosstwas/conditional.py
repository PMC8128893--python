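"""Conditional association on the top imputation-model variant.

Summary-statistic realization of the two-predictor regression
phenotype ~ imputed expression + variant: correlations are recovered
from the marginal statistics (r = z / sqrt(n - 2 + z^2)), the
expression-variant correlation from the LD matrix, and the partial
correlation of expression with the phenotype given the variant is
mapped to a t-statistic with n - 3 residual degrees of freedom.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

from crosstwas.gbj import gbj_pvalue, tissue_covariance
from crosstwas.twas import HarmonizedGene, twas_z

_COLLINEAR_CUT = 1.0 - 1e-6

PERSISTENCE_CUTS = (0.05, 1e-3, 1e-6)


def pick_top_model_variant(
    weights: pd.DataFrame, gene_id: str, tissue_id: str, gwas: pd.DataFrame
) -> str | None:
    """Among a gene-tissue model's nonzero-weight SNPs present in the GWAS,
    the one with the smallest p (ties: smallest position, then id)."""
    sub = weights[
        (weights["gene_id"] == gene_id)
        & (weights["tissue_id"] == tissue_id)
        & (weights["weight"] != 0.0)
    ]
    if sub.empty:
        return None
    cand = gwas[gwas["snp"].isin(set(sub["snp_id"]))]
    if cand.empty:
        return None
    cand = cand.sort_values(["p", "pos", "snp"], kind="mergesort")
    return str(cand.iloc[0]["snp"])


def _z_to_r(z: float, n: float) -> float:
    return float(z / np.sqrt(n - 2.0 + z * z))


def conditional_z(
    w: np.ndarray,
    z: np.ndarray,
    D: np.ndarray,
    v: int,
    n: float,
    ridge: float = 1e-6,
) -> tuple[float, float, bool]:
    """(conditional z, p, collinear_flag) for expression given variant v.

    Collinear cases (|corr(expression, variant)| ~ 1) are flagged and
    reported as fully explained with p = 1.
    """
    if n <= 3:
        raise ValueError("n must exceed 3")
    w = np.asarray(w, dtype=float)
    z = np.asarray(z, dtype=float)
    zt, _ = twas_z(w, z, D, ridge=ridge)
    r_ey = _z_to_r(zt, n)
    r_vy = _z_to_r(float(z[v]), n)
    denom = np.sqrt(float(w @ (D + ridge * np.eye(len(w))) @ w))
    r_ev = float(w @ D[:, v]) / denom
    if abs(r_ev) >= _COLLINEAR_CUT:
        return 0.0, 1.0, True
    num = r_ey - r_ev * r_vy
    den = np.sqrt((1.0 - r_ev * r_ev) * (1.0 - r_vy * r_vy))
    r_part = np.clip(num / den, -1 + 1e-12, 1 - 1e-12)
    t = r_part * np.sqrt((n - 3.0) / (1.0 - r_part * r_part))
    return float(t), float(2.0 * norm.sf(abs(t))), False


def persistence_class(p: float) -> str:
    """Bucket a conditional p: >0.05 | <=1e-3 | <=1e-6 | in between."""
    if p <= PERSISTENCE_CUTS[2]:
        return "<=1e-6"
    if p <= PERSISTENCE_CUTS[1]:
        return "<=1e-3"
    if p > PERSISTENCE_CUTS[0]:
        return ">0.05"
    return "intermediate"


def conditional_gene(
    hg: HarmonizedGene,
    weights: pd.DataFrame,
    gwas: pd.DataFrame,
    B: int = 2000,
    seed: int = 0,
    ridge: float = 1e-6,
) -> tuple[pd.DataFrame, dict]:
    """Per-tissue conditional tests for one harmonized gene, recombined
    with GBJ using the same tissue covariance as the marginal test.

    Returns (per-tissue table, combined record).  Tissues whose model is
    collinear with its conditioned variant contribute a flagged zero;
    if every tissue is collinear the gene is classed "fully_explained".
    """
    pos = {s: i for i, s in enumerate(hg.snps)}
    rows = []
    for tissue in sorted(hg.weights):
        w = hg.weights[tissue]
        if not np.any(w):
            continue
        top = pick_top_model_variant(weights, hg.gene_id, tissue, gwas)
        if top is None or top not in pos:
            continue
        zc, pc, flag = conditional_z(w, hg.z, hg.D, pos[top], hg.n_gwas, ridge=ridge)
        rows.append(
            {
                "gene_id": hg.gene_id,
                "tissue_id": tissue,
                "conditioned_variant": top,
                "z_cond": zc,
                "p_cond": pc,
                "collinear": flag,
            }
        )
    per_tissue = pd.DataFrame(
        rows, columns=["gene_id", "tissue_id", "conditioned_variant", "z_cond", "p_cond", "collinear"]
    )
    if per_tissue.empty:
        raise ValueError(f"no usable tissue for gene {hg.gene_id}")
    usable = per_tissue[~per_tissue["collinear"]]
    if usable.empty:
        combined = {
            "gene_id": hg.gene_id,
            "gbj_stat": float("nan"),
            "p_gbj": 1.0,
            "class": "fully_explained",
        }
        return per_tissue, combined
    tissues = list(usable["tissue_id"])
    zvec = usable["z_cond"].to_numpy()
    if len(tissues) == 1:
        p = float(2.0 * norm.sf(abs(zvec[0])))
        stat = float("nan")
    else:
        wbt = {t: hg.weights[t] for t in tissues}
        _, sigma, _ = tissue_covariance(wbt, hg.D)
        stat, p = gbj_pvalue(zvec, sigma, B=B, seed=seed)
    combined = {
        "gene_id": hg.gene_id,
        "gbj_stat": stat,
        "p_gbj": p,
        "class": persistence_class(p),
    }
    return per_tissue, combined


def combine_conditional(
    per_tissue: pd.DataFrame,
    sigma: np.ndarray,
    tissues: list[str],
    B: int = 2000,
    seed: int = 0,
) -> dict:
    """GBJ on an already-computed conditional z-vector with a supplied
    tissue covariance (the marginal-test covariance, reused)."""
    usable = per_tissue[~per_tissue["collinear"]]
    if usable.empty:
        return {"gbj_stat": float("nan"), "p_gbj": 1.0, "class": "fully_explained"}
    order = [t for t in tissues if t in set(usable["tissue_id"])]
    zmap = dict(zip(usable["tissue_id"], usable["z_cond"]))
    z = np.array([zmap[t] for t in order])
    idx = [tissues.index(t) for t in order]
    sub_sigma = sigma[np.ix_(idx, idx)]
    if len(order) == 1:
        p = float(2.0 * norm.sf(abs(z[0])))
        return {"gbj_stat": float("nan"), "p_gbj": p, "class": persistence_class(p)}
    stat, p = gbj_pvalue(z, sub_sigma, B=B, seed=seed)
    return {"gbj_stat": stat, "p_gbj": p, "class": persistence_class(p)}
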