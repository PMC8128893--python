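"""Discovery bookkeeping: Bonferroni thresholds, dual-reference
consensus calls with the +-1 Mb neighbor rescue, GWAS window lookups,
and summary counts."""

from __future__ import annotations

import numpy as np
import pandas as pd

DEFAULT_WINDOW_BP = 1_000_000
DEFAULT_GWAS_WEAK_CUT = 1e-6


def bonferroni_threshold(alpha: float, n_genes: int, n_traits: int) -> float:
    """Family-wise threshold alpha / n_genes / n_traits."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if n_genes < 1 or n_traits < 1:
        raise ValueError("counts must be >= 1")
    return alpha / n_genes / n_traits


def _neighbors(annotation: pd.DataFrame, window_bp: int) -> dict[str, set[str]]:
    """Gene -> genes whose window-padded body [start-w, end+w] overlaps the
    focal gene's unpadded body (1-based inclusive); symmetric, and a gene
    is not its own neighbor."""
    out: dict[str, set[str]] = {g: set() for g in annotation["gene_id"]}
    by_chr = annotation.groupby("chr")
    for _, sub in by_chr:
        recs = sub[["gene_id", "start", "end"]].to_records(index=False)
        for i in range(len(recs)):
            gi, si, ei = recs[i]
            for j in range(i + 1, len(recs)):
                gj, sj, ej = recs[j]
                if si <= ej + window_bp and sj - window_bp <= ei:
                    out[gi].add(gj)
                    out[gj].add(gi)
    return out


def consensus_calls(
    results_v1: pd.DataFrame,
    results_v2: pd.DataFrame,
    annotation: pd.DataFrame,
    threshold: float,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> pd.DataFrame:
    """Dual-reference consensus: a gene is called when significant in both
    result sets, or significant in one while a neighboring gene (padded
    intervals overlapping within ``window_bp``) is significant in the other.

    Result frames need columns gene_id and p_gbj (optionally trait).
    Genes absent from the annotation are excluded and logged in the
    returned frame's attrs["excluded"].
    """
    ann_genes = set(annotation["gene_id"])
    neighbors = _neighbors(annotation, window_bp)

    def _prep(df: pd.DataFrame) -> pd.DataFrame:
        df = df.copy()
        if "trait" not in df.columns:
            df["trait"] = "trait"
        return df

    v1, v2 = _prep(results_v1), _prep(results_v2)
    excluded = sorted((set(v1["gene_id"]) | set(v2["gene_id"])) - ann_genes)
    v1 = v1[v1["gene_id"].isin(ann_genes)]
    v2 = v2[v2["gene_id"].isin(ann_genes)]

    traits = sorted(set(v1["trait"]) | set(v2["trait"]))
    rows = []
    for trait in traits:
        p1 = dict(zip(v1.loc[v1["trait"] == trait, "gene_id"], v1.loc[v1["trait"] == trait, "p_gbj"]))
        p2 = dict(zip(v2.loc[v2["trait"] == trait, "gene_id"], v2.loc[v2["trait"] == trait, "p_gbj"]))
        sig1 = {g for g, p in p1.items() if p <= threshold}
        sig2 = {g for g, p in p2.items() if p <= threshold}
        for gene in sorted(set(p1) | set(p2)):
            s1, s2 = gene in sig1, gene in sig2
            nb = neighbors.get(gene, set())
            rescue = (s1 and not s2 and bool(nb & sig2)) or (s2 and not s1 and bool(nb & sig1))
            rows.append(
                {
                    "gene_id": gene,
                    "trait": trait,
                    "significant_v1": s1,
                    "significant_v2": s2,
                    "neighbor_rescue": rescue,
                    "final_call": (s1 and s2) or rescue,
                }
            )
    out = pd.DataFrame(
        rows,
        columns=["gene_id", "trait", "significant_v1", "significant_v2", "neighbor_rescue", "final_call"],
    )
    out.attrs["excluded"] = excluded
    return out


def min_gwas_p_in_window(
    gene_id: str,
    annotation: pd.DataFrame,
    gwas: pd.DataFrame,
    window_bp: int = DEFAULT_WINDOW_BP,
    gwas_weak_cut: float = DEFAULT_GWAS_WEAK_CUT,
) -> tuple[float, str | None, bool | str]:
    """Smallest GWAS p among SNPs within the gene body +- window.

    Returns (min_p, snp_id, weak_flag); an empty window yields
    (nan, None, "no_snp").
    """
    row = annotation.loc[annotation["gene_id"] == gene_id]
    if row.empty:
        raise KeyError(f"gene {gene_id!r} not in annotation")
    chrom, start, end = row.iloc[0][["chr", "start", "end"]]
    sub = gwas[
        (gwas["chr"] == chrom)
        & (gwas["pos"] >= start - window_bp)
        & (gwas["pos"] <= end + window_bp)
    ]
    if sub.empty:
        return float("nan"), None, "no_snp"
    i = sub["p"].idxmin()
    min_p = float(sub.loc[i, "p"])
    return min_p, str(sub.loc[i, "snp"]), bool(min_p > gwas_weak_cut)


def summarize_discovery(calls: pd.DataFrame) -> dict[str, int]:
    """Counts over final calls (deduplicated gene-trait pairs)."""
    if calls.empty:
        return {
            "n_associations": 0, "n_genes": 0, "n_traits": 0,
            "n_genes_gt2": 0, "n_genes_gt5": 0, "n_genes_ge10": 0,
        }
    called = calls.loc[calls["final_call"], ["gene_id", "trait"]].drop_duplicates()
    per_gene = called.groupby("gene_id")["trait"].nunique()
    return {
        "n_associations": int(len(called)),
        "n_genes": int(called["gene_id"].nunique()),
        "n_traits": int(called["trait"].nunique()),
        "n_genes_gt2": int((per_gene > 2).sum()),
        "n_genes_gt5": int((per_gene > 5).sum()),
        "n_genes_ge10": int((per_gene >= 10).sum()),
    }
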