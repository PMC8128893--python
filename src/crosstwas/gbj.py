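"""Cross-tissue combination via the generalized Berk-Jones construction.

The statistic scans the upper half of the order statistics of |z|: for
each k whose exceedance fraction k/d beats its null tail probability
p_k = 2*(1 - Phi(|z|_(k))), a binomial-style log generalized likelihood
ratio compares the observed exceedance count k with its null mean d*p_k,
and is deflated by the ratio of the correlation-inflated exceedance-count
variance (pairwise bivariate-normal orthant probabilities under the
tissue covariance) to the binomial variance.  With identity covariance
the statistic reduces exactly to the classical Berk-Jones statistic.

P-values come from Monte-Carlo draws of the null multivariate normal
with the add-one estimator, reproducible given (B, seed).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import norm

from crosstwas._bvn import both_tails_exceed

_DUP_CUT = 0.9999
_P_FLOOR = 1e-300


def tissue_covariance(
    weights_by_tissue: dict[str, np.ndarray], D: np.ndarray
) -> tuple[list[str], np.ndarray, bool]:
    """Correlation of imputed expressions across tissues.

    Sigma_ts = w_t' D w_s / sqrt(w_t' D w_t * w_s' D w_s), clipped to
    [-1, 1]; a nearest-PSD eigenvalue clip is applied if estimation
    noise pushed an eigenvalue below -1e-8.  Returns (tissue order,
    Sigma, projected_flag).
    """
    tissues = sorted(t for t, w in weights_by_tissue.items() if np.any(w))
    if len(tissues) < 2:
        raise ValueError("need at least two tissues with nonzero weights")
    W = np.column_stack([weights_by_tissue[t] for t in tissues])
    G = W.T @ D @ W
    d = np.sqrt(np.diag(G))
    if np.any(d <= 0):
        raise ValueError("non-positive imputed-expression variance")
    S = np.clip(G / np.outer(d, d), -1.0, 1.0)
    np.fill_diagonal(S, 1.0)
    projected = False
    evals = np.linalg.eigvalsh(S)
    if evals.min() < -1e-8:
        projected = True
        lam, V = np.linalg.eigh(S)
        S = (V * np.clip(lam, 0.0, None)) @ V.T
        dd = np.sqrt(np.diag(S))
        S = np.clip(S / np.outer(dd, dd), -1.0, 1.0)
        np.fill_diagonal(S, 1.0)
    return tissues, S, projected


def collapse_duplicate_tissues(
    z: np.ndarray, sigma: np.ndarray, cut: float = _DUP_CUT
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Drop tissues whose null statistics are numerically identical
    (|corr| >= cut) to an earlier kept tissue; avoids singular nulls."""
    keep: list[int] = []
    for i in range(len(z)):
        if all(abs(sigma[i, j]) < cut for j in keep):
            keep.append(i)
    idx = np.array(keep)
    return z[idx], sigma[np.ix_(idx, idx)], idx


def _pair_correlations(sigma: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unique off-diagonal correlations (rounded) with pair counts."""
    d = sigma.shape[0]
    iu = np.triu_indices(d, k=1)
    rho = np.round(sigma[iu], 8)
    uniq, counts = np.unique(rho, return_counts=True)
    return uniq, counts


def gbj_statistic_many(
    Z: np.ndarray, sigma: np.ndarray, binomial_variance: bool = False
) -> np.ndarray:
    """Vectorized statistic for many z-vectors sharing one covariance.

    Z is (M, d); returns (M,).  ``binomial_variance=True`` skips the
    correlation inflation, giving the classical Berk-Jones statistic.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    M, d = Z.shape
    if d < 1:
        raise ValueError("need at least one tissue statistic")
    K = max(d // 2, 1)
    T = np.sort(np.abs(Z), axis=1)[:, ::-1][:, :K]  # (M, K) thresholds
    k = np.arange(1, K + 1, dtype=float)
    p = np.clip(2.0 * norm.sf(T), _P_FLOOR, 1.0 - 1e-16)

    qualifies = (k / d)[None, :] > p
    with np.errstate(divide="ignore", invalid="ignore"):
        bj = k * np.log(k / (d * p)) + (d - k) * np.log((d - k) / (d * (1.0 - p)))
    binom_var = d * p * (1.0 - p)

    if binomial_variance or d == 1:
        stat_k = bj
    else:
        uniq, counts = _pair_correlations(sigma)
        pairsum = np.zeros_like(T)
        for rho, cnt in zip(uniq, counts):
            if rho == 0.0:
                continue
            orth = both_tails_exceed(T, rho)
            pairsum += 2.0 * cnt * (orth - p * p)
        var = binom_var + pairsum
        var = np.maximum(var, 1e-3 * binom_var)
        stat_k = bj * binom_var / var

    stat_k = np.where(qualifies, stat_k, -np.inf)
    out = stat_k.max(axis=1)
    return np.maximum(out, 0.0)


def gbj_statistic(z: np.ndarray, sigma: np.ndarray, binomial_variance: bool = False) -> float:
    """Statistic for a single tissue z-vector (>= 0; 0 when no order
    statistic exceeds its null expectation)."""
    z = np.asarray(z, dtype=float)
    if z.ndim != 1 or z.size == 0:
        raise ValueError("z must be a non-empty 1-d vector")
    return float(gbj_statistic_many(z[None, :], sigma, binomial_variance=binomial_variance)[0])


def _mvn_draws(sigma: np.ndarray, B: int, rng: np.random.Generator) -> np.ndarray:
    lam, V = np.linalg.eigh(sigma)
    root = V * np.sqrt(np.clip(lam, 0.0, None))
    return rng.standard_normal((B, sigma.shape[0])) @ root.T


def gbj_pvalue(
    z: np.ndarray,
    sigma: np.ndarray,
    method: str = "mc",
    B: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """(statistic, p) with a Monte-Carlo null of B draws from MVN(0, Sigma).

    p = (1 + #{draw statistic >= observed}) / (B + 1); bit-reproducible
    given (B, seed).  Duplicate tissues are collapsed first.
    """
    if method != "mc":
        raise ValueError("only the Monte-Carlo method is implemented")
    if B < 1:
        raise ValueError("B must be >= 1")
    if B < 1000:
        warnings.warn(f"B={B} is small for a Monte-Carlo p-value", stacklevel=2)
    z = np.asarray(z, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if z.size == 0:
        raise ValueError("empty statistic vector")
    if sigma.shape != (z.size, z.size):
        raise ValueError("sigma does not conform to z")
    zc, sc, _ = collapse_duplicate_tissues(z, sigma)
    obs = gbj_statistic(zc, sc)
    rng = np.random.default_rng(seed)
    draws = _mvn_draws(sc, B, rng)
    null_stats = gbj_statistic_many(draws, sc)
    p = (1.0 + float(np.sum(null_stats >= obs))) / (B + 1.0)
    return obs, p


def combine_tissues(
    single_tissue: pd.DataFrame,
    weights_by_tissue_by_gene: dict[str, dict[str, np.ndarray]],
    D_by_gene: dict[str, np.ndarray],
    tissue_subset: list[str] | None = None,
    B: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """GBJ-combine per-gene single-tissue results into one row per gene.

    ``tissue_subset`` restricts the combination (brain-only mode);
    running on a subset equals running the all-tissue mode on the same
    subset by construction.  Genes with a single usable tissue fall back
    to that tissue's two-sided normal p.
    """
    rows = []
    for gene, sub in single_tissue.groupby("gene_id", sort=True):
        if tissue_subset is not None:
            sub = sub[sub["tissue_id"].isin(tissue_subset)]
        if sub.empty:
            continue
        tissues = sorted(sub["tissue_id"])
        zmap = dict(zip(sub["tissue_id"], sub["z_twas"]))
        z = np.array([zmap[t] for t in tissues])
        if len(tissues) == 1:
            stat = gbj_statistic(z, np.eye(1))
            p = float(2.0 * norm.sf(abs(z[0])))
        else:
            wbt = {
                t: w
                for t, w in weights_by_tissue_by_gene[gene].items()
                if t in set(tissues) and np.any(w)
            }
            _, sigma, _ = tissue_covariance(wbt, D_by_gene[gene])
            stat, p = gbj_pvalue(z, sigma, B=B, seed=seed)
        rows.append(
            {
                "gene_id": gene,
                "mode": "subset" if tissue_subset is not None else "all",
                "gbj_stat": stat,
                "p_gbj": p,
                "n_tissues": len(tissues),
                "B": B,
                "seed": seed,
            }
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "mode", "gbj_stat", "p_gbj", "n_tissues", "B", "seed"]
    )
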