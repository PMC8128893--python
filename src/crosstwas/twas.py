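"""Single-panel gene-trait association from summary statistics.

Given imputation weights w on the standardized-genotype scale, GWAS
z-scores z, and an LD correlation matrix D, the gene-tissue statistic is

    z_twas = w'z / sqrt(w' (D + ridge*I) w)

after all three sources are harmonized to the weight panel's effect
allele (GWAS z sign-flipped on swapped alleles, LD rows/columns
sign-flipped likewise, mismatching or strand-ambiguous SNPs dropped).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from crosstwas.simulate import LdReference

_AMBIGUOUS = ({"A", "T"}, {"C", "G"})

DEFAULT_RIDGE = 1e-6
MAX_DROPPED_WEIGHT_FRACTION = 0.5  # gene skipped beyond this (package decision)


@dataclass
class HarmonizedGene:
    """One gene's aligned inputs, shared across tissues."""

    gene_id: str
    snps: list[str]
    z: np.ndarray                        # GWAS z aligned to panel effect alleles
    D: np.ndarray
    weights: dict[str, np.ndarray]       # tissue -> weight vector over `snps`
    gwas_p: np.ndarray
    n_gwas: float
    dropped: pd.DataFrame                # snp, reason
    dropped_weight: dict[str, float]     # tissue -> |w| mass dropped / total


@dataclass
class SingleTissueResult:
    gene_id: str
    tissue_id: str
    z_twas: float
    p: float
    n_snps_used: int
    top_variant: str
    drop_frac: float


def _is_ambiguous(a1: str, a2: str) -> bool:
    return {a1, a2} in _AMBIGUOUS


def harmonize_alleles(
    weights: pd.DataFrame,
    gwas: pd.DataFrame,
    ld: LdReference,
    drop_ambiguous: bool = True,
) -> HarmonizedGene | None:
    """Align one gene's weight slice, GWAS rows, and LD block.

    ``weights`` must cover a single gene (any number of tissues).
    Returns None when no SNP survives the intersection/filters; the
    caller logs the skip.
    """
    genes = weights["gene_id"].unique()
    if len(genes) != 1:
        raise ValueError("harmonize_alleles expects a single-gene weight slice")
    gene = genes[0]
    if gene not in ld:
        return None
    ld_tab = ld.snp_table(gene)
    D_full = ld.matrix(gene)
    gwas_idx = gwas.set_index("snp")

    panel_alleles = (
        weights.drop_duplicates("snp_id")
        .set_index("snp_id")[["effect_allele", "other_allele"]]
    )
    ld_pos = {s: i for i, s in enumerate(ld_tab["snp"])}
    # fix SNP order by the LD reference, not by input row order
    panel_alleles = panel_alleles.loc[
        sorted(panel_alleles.index, key=lambda s: (ld_pos.get(s, len(ld_pos)), s))
    ]

    kept, flips, zs, ps, drops = [], [], [], [], []
    n_vals = []
    for snp, row in panel_alleles.iterrows():
        ea, oa = row["effect_allele"], row["other_allele"]
        if drop_ambiguous and _is_ambiguous(ea, oa):
            drops.append((snp, "strand_ambiguous"))
            continue
        if snp not in gwas_idx.index or snp not in ld_pos:
            drops.append((snp, "missing"))
            continue
        g = gwas_idx.loc[snp]
        if (g["a1"], g["a2"]) == (ea, oa):
            z = float(g["z"])
        elif (g["a1"], g["a2"]) == (oa, ea):
            z = -float(g["z"])
        else:
            drops.append((snp, "allele_mismatch_gwas"))
            continue
        li = ld_pos[snp]
        la1, la2 = ld_tab.loc[li, "a1"], ld_tab.loc[li, "a2"]
        if (la1, la2) == (ea, oa):
            flip = 1.0
        elif (la1, la2) == (oa, ea):
            flip = -1.0
        else:
            drops.append((snp, "allele_mismatch_ld"))
            continue
        kept.append(snp)
        flips.append(flip)
        zs.append(z)
        ps.append(float(g["p"]) if "p" in g.index else 2.0 * norm.sf(abs(z)))
        n_vals.append(float(g["n"]))
    if not kept:
        return None

    idx = np.array([ld_pos[s] for s in kept])
    flips_arr = np.array(flips)
    D = D_full[np.ix_(idx, idx)] * np.outer(flips_arr, flips_arr)

    w_by_tissue: dict[str, np.ndarray] = {}
    dropped_weight: dict[str, float] = {}
    kept_pos = {s: i for i, s in enumerate(kept)}
    for tissue, sub in weights.groupby("tissue_id"):
        w = np.zeros(len(kept))
        total = float(np.abs(sub["weight"]).sum())
        used = 0.0
        for _, r in sub.iterrows():
            if r["snp_id"] in kept_pos:
                w[kept_pos[r["snp_id"]]] = r["weight"]
                used += abs(r["weight"])
        w_by_tissue[tissue] = w
        dropped_weight[tissue] = 0.0 if total == 0 else 1.0 - used / total

    return HarmonizedGene(
        gene_id=gene,
        snps=kept,
        z=np.array(zs),
        D=D,
        weights=w_by_tissue,
        gwas_p=np.array(ps),
        n_gwas=float(np.median(n_vals)),
        dropped=pd.DataFrame(drops, columns=["snp", "reason"]),
        dropped_weight=dropped_weight,
    )


def twas_z(
    w: np.ndarray, z: np.ndarray, D: np.ndarray, ridge: float = DEFAULT_RIDGE
) -> tuple[float, float]:
    """(z_twas, two-sided p) for one gene-tissue pair."""
    w = np.asarray(w, dtype=float)
    z = np.asarray(z, dtype=float)
    if w.shape != z.shape or D.shape != (len(w), len(w)):
        raise ValueError("non-conforming shapes")
    if not np.any(w):
        raise ValueError("zero weight vector")
    denom2 = float(w @ (D + ridge * np.eye(len(w))) @ w)
    if denom2 <= 0:
        raise ValueError("quadratic form not positive after ridge; LD matrix invalid")
    zt = float(w @ z) / np.sqrt(denom2)
    return zt, float(2.0 * norm.sf(abs(zt)))


def run_twas(
    weights: pd.DataFrame,
    gwas: pd.DataFrame,
    ld: LdReference,
    drop_ambiguous: bool = True,
    ridge: float = DEFAULT_RIDGE,
    max_drop: float = MAX_DROPPED_WEIGHT_FRACTION,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All gene-tissue associations for one trait.

    Returns (results, skip/drop log).  A gene-tissue pair is skipped when
    its weight vector vanishes after harmonization or when more than
    ``max_drop`` of its absolute weight mass was dropped.
    """
    results, log = [], []
    for gene, sub in weights.groupby("gene_id", sort=True):
        hg = harmonize_alleles(sub, gwas, ld, drop_ambiguous=drop_ambiguous)
        if hg is None:
            log.append({"gene_id": gene, "tissue_id": "*", "reason": "no_snp_overlap"})
            continue
        for _, r in hg.dropped.iterrows():
            log.append({"gene_id": gene, "tissue_id": "*", "reason": f"{r['reason']}:{r['snp']}"})
        for tissue in sorted(hg.weights):
            w = hg.weights[tissue]
            if hg.dropped_weight[tissue] > max_drop:
                log.append({"gene_id": gene, "tissue_id": tissue, "reason": "weight_mass_dropped"})
                continue
            if not np.any(w):
                log.append({"gene_id": gene, "tissue_id": tissue, "reason": "zero_weights"})
                continue
            zt, p = twas_z(w, hg.z, hg.D, ridge=ridge)
            top = hg.snps[int(np.argmax(np.abs(w)))]
            results.append(
                {
                    "gene_id": gene,
                    "tissue_id": tissue,
                    "z_twas": zt,
                    "p": p,
                    "n_snps_used": int(np.count_nonzero(w)),
                    "top_variant": top,
                    "drop_frac": hg.dropped_weight[tissue],
                }
            )
    cols = ["gene_id", "tissue_id", "z_twas", "p", "n_snps_used", "top_variant", "drop_frac"]
    return pd.DataFrame(results, columns=cols), pd.DataFrame(log, columns=["gene_id", "tissue_id", "reason"])
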