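"""Synthetic study generator.

Produces, from a single :class:`~crosstwas.config.SimulationConfig`, all
inputs the downstream pipeline consumes: LD-blocked genotypes for four
disjoint cohorts, multi-tissue expression with shared cis-eQTL
architecture in the reference cohort, an expression-mediated polygenic
phenotype with marginal-OLS GWAS summary statistics, oracle imputation
weights, per-gene LD matrices, and negative-binomial chromatin
interaction counts.

LD model: each gene block gets latent Gaussian AR(1) haplotypes that are
dichotomized at the MAF quantile; the latent step correlations are
calibrated so the *dosage* correlation of adjacent SNPs matches
``ld_rho``.  High targets are attainable only between SNPs of comparable
MAF (binary dosages bound the correlation); unreachable targets saturate
at the bound.  Blocks of different genes are independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from crosstwas._bvn import bvn_cdf
from crosstwas.config import SimulationConfig

# allele pairs that survive a strand flip unambiguously
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"), ("C", "T")]


# ---------------------------------------------------------------------------
# containers


@dataclass
class Genotypes:
    """Dosage matrix with its sidecar SNP table.

    ``X`` is subjects x SNPs with entries in {0, 1, 2}; ``snps`` has
    columns snp, chr, pos, a1 (counted allele), a2, maf, gene_id.
    """

    X: np.ndarray
    snps: pd.DataFrame

    def __post_init__(self) -> None:
        if self.X.shape[1] != len(self.snps):
            raise ValueError("genotype matrix and SNP table disagree on SNP count")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def standardized(self) -> np.ndarray:
        """Column-standardized dosages; zero-variance columns map to 0."""
        X = self.X.astype(float)
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd_safe = np.where(sd > 0, sd, 1.0)
        return (X - mu) / sd_safe

    def gene_columns(self, gene_id: str) -> np.ndarray:
        return np.flatnonzero((self.snps["gene_id"] == gene_id).to_numpy())


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated study."""

    causal_idx: dict[str, np.ndarray]           # gene -> column indices (within block)
    eqtl_effects: dict[str, np.ndarray]         # gene -> (snps_per_gene, n_tissues)
    mediator_weights: dict[str, np.ndarray]     # gene -> (snps_per_gene,) unit-variance
    alpha: dict[str, float]                     # gene -> mediation effect
    direct_effects: np.ndarray                  # per-SNP, standardized scale
    mediated_h2: float
    direct_h2: float


@dataclass
class Cohort:
    genotypes: Genotypes
    covariates: pd.DataFrame
    phenotype: np.ndarray | None = None


@dataclass
class LdReference:
    """Per-gene SNP correlation matrices estimated from a reference cohort."""

    genes: dict[str, tuple[pd.DataFrame, np.ndarray]] = field(default_factory=dict)

    def snp_table(self, gene_id: str) -> pd.DataFrame:
        return self.genes[gene_id][0]

    def matrix(self, gene_id: str) -> np.ndarray:
        return self.genes[gene_id][1]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes


@dataclass
class SyntheticStudy:
    config: SimulationConfig
    annotation: pd.DataFrame
    truth: SyntheticTruth
    ref: Cohort
    gwas_cohort: Cohort
    train: Cohort
    test: Cohort
    expression: np.ndarray           # tissues x ref subjects x genes
    gwas: pd.DataFrame               # summary statistics of the GWAS cohort
    weights: pd.DataFrame            # oracle WeightPanel rows
    ld: LdReference
    tissues: list[str]


# ---------------------------------------------------------------------------
# annotation and genotypes


def make_annotation(config: SimulationConfig) -> pd.DataFrame:
    """Lay genes along chromosomes with fixed length and spacing (1-based)."""
    rows = []
    per_chr = int(np.ceil(config.n_genes / config.n_chromosomes))
    for g in range(config.n_genes):
        chrom = g // per_chr + 1
        rank = g % per_chr
        start = 1_000_000 + rank * (config.gene_length + config.gene_spacing)
        rows.append(
            {
                "gene_id": f"gene{g:04d}",
                "chr": chrom,
                "start": start,
                "end": start + config.gene_length - 1,
            }
        )
    return pd.DataFrame(rows)


def _binary_corr(latent_rho: float, h1: float, h2: float, p1: float, p2: float) -> float:
    num = float(bvn_cdf(h1, h2, latent_rho)) - p1 * p2
    den = np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))
    return num / den


def _calibrate_latent_rho(target: float, h1: float, h2: float, p1: float, p2: float) -> float:
    """Latent AR(1) step giving adjacent-dosage correlation ``target``."""
    if target <= 0.0:
        return 0.0
    hi = 0.9995
    if _binary_corr(hi, h1, h2, p1, p2) <= target:
        return hi  # target unreachable for these MAFs; saturate
    return brentq(lambda r: _binary_corr(r, h1, h2, p1, p2) - target, 0.0, hi, xtol=1e-6)


def simulate_genotypes(
    n: int,
    annotation: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
    mafs: np.ndarray | None = None,
    alleles: list[tuple[str, str]] | None = None,
) -> Genotypes:
    """Draw Hardy-Weinberg dosages with within-block AR(1) LD.

    Passing ``mafs``/``alleles`` (one per SNP) pins the SNP frame so
    that several cohorts share identical variants.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if len(annotation) == 0:
        raise ValueError("annotation is empty")
    m_per = config.snps_per_gene
    m_total = len(annotation) * m_per
    if mafs is None:
        mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=m_total)
    if alleles is None:
        picks = rng.integers(0, len(_ALLELE_PAIRS), size=m_total)
        alleles = [_ALLELE_PAIRS[i] for i in picks]

    thresholds = norm.ppf(mafs)
    X = np.empty((n, m_total), dtype=np.int8)
    rows = []
    for gi, gene in enumerate(annotation.itertuples(index=False)):
        sl = slice(gi * m_per, (gi + 1) * m_per)
        p = mafs[sl]
        h = thresholds[sl]
        # latent AR(1) haplotypes, step rho calibrated per adjacent pair
        Z = np.empty((2 * n, m_per))
        Z[:, 0] = rng.standard_normal(2 * n)
        for j in range(1, m_per):
            r = _calibrate_latent_rho(config.ld_rho, h[j - 1], h[j], p[j - 1], p[j])
            Z[:, j] = r * Z[:, j - 1] + np.sqrt(1 - r * r) * rng.standard_normal(2 * n)
        B = (Z < h).astype(np.int8)
        X[:, sl] = B[:n] + B[n:]
        positions = np.linspace(gene.start, gene.end, m_per).astype(int)
        for j in range(m_per):
            a1, a2 = alleles[gi * m_per + j]
            rows.append(
                {
                    "snp": f"snp_{gene.gene_id}_{j}",
                    "chr": gene.chr,
                    "pos": int(positions[j]),
                    "a1": a1,
                    "a2": a2,
                    "maf": p[j],
                    "gene_id": gene.gene_id,
                }
            )
    return Genotypes(X=X, snps=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# eQTL architecture and expression


def make_truth(
    genotypes: Genotypes,
    annotation: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> SyntheticTruth:
    """Causal eQTL sets, cross-tissue effect matrices, and mediation effects.

    Per gene: effects share a common factor across tissues so that
    corr(b_t, b_s) = cross_tissue_cor; each tissue's effect vector is
    scaled (against the reference-panel LD) so genetic expression
    variance equals ``cis_h2``.  The mediator is the across-tissue mean
    effect, rescaled to unit genetic variance.
    """
    c = config.cross_tissue_cor
    Xs = genotypes.standardized()
    causal_idx: dict[str, np.ndarray] = {}
    eqtl: dict[str, np.ndarray] = {}
    mediator: dict[str, np.ndarray] = {}

    for gene in annotation["gene_id"]:
        cols = genotypes.gene_columns(gene)
        R = np.corrcoef(Xs[:, cols], rowvar=False)
        R = np.atleast_2d(R)
        idx = np.sort(rng.choice(config.snps_per_gene, config.n_causal_eqtl_per_gene, replace=False))
        shared = rng.standard_normal(config.n_causal_eqtl_per_gene)
        specific = rng.standard_normal((config.n_causal_eqtl_per_gene, config.n_tissues))
        raw = np.sqrt(c) * shared[:, None] + np.sqrt(1 - c) * specific

        B = np.zeros((config.snps_per_gene, config.n_tissues))
        for t in range(config.n_tissues):
            b = np.zeros(config.snps_per_gene)
            b[idx] = raw[:, t]
            gv = b @ R @ b
            if config.cis_h2 > 0 and gv > 0:
                B[:, t] = b * np.sqrt(config.cis_h2 / gv)
        w = B.mean(axis=1)
        gv = w @ R @ w
        if gv > 0:
            w = w / np.sqrt(gv)
        causal_idx[gene] = idx
        eqtl[gene] = B
        mediator[gene] = w

    genes = list(annotation["gene_id"])
    if config.n_causal_genes is None:
        causal_genes = genes
    else:
        pick = rng.choice(len(genes), min(config.n_causal_genes, len(genes)), replace=False)
        causal_genes = [genes[i] for i in sorted(pick)]
    alpha = {g: (float(rng.standard_normal()) if g in set(causal_genes) else 0.0) for g in genes}

    direct = rng.standard_normal(genotypes.X.shape[1])
    return SyntheticTruth(
        causal_idx=causal_idx,
        eqtl_effects=eqtl,
        mediator_weights=mediator,
        alpha=alpha,
        direct_effects=direct,
        mediated_h2=config.mediated_h2,
        direct_h2=config.direct_h2,
    )


def simulate_expression(
    genotypes: Genotypes,
    truth: SyntheticTruth,
    annotation: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Tissue x subject x gene expression: X_std b_t plus scaled noise."""
    Xs = genotypes.standardized()
    n = genotypes.n
    genes = list(annotation["gene_id"])
    E = np.empty((config.n_tissues, n, len(genes)))
    noise_sd = np.sqrt(1.0 - config.cis_h2)
    for gi, gene in enumerate(genes):
        cols = genotypes.gene_columns(gene)
        G = Xs[:, cols] @ truth.eqtl_effects[gene]  # n x tissues
        E[:, :, gi] = G.T + noise_sd * rng.standard_normal((config.n_tissues, n))
    return E


# ---------------------------------------------------------------------------
# phenotype and GWAS summary statistics


def _draw_covariates(n: int, config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    cols = {}
    for j in range(config.n_covariates):
        if j == 1:
            cols["sex"] = rng.integers(0, 2, size=n).astype(float)
        else:
            cols["age" if j == 0 else f"cov{j}"] = rng.standard_normal(n)
    return pd.DataFrame(cols)


def simulate_phenotype(
    genotypes: Genotypes,
    truth: SyntheticTruth,
    annotation: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
    covariates: pd.DataFrame,
) -> np.ndarray:
    """Phenotype = mediated genetic part + direct part + covariates + noise.

    Mediated and direct parts are empirically rescaled so their in-sample
    variance shares hit the configured targets exactly.
    """
    n = genotypes.n
    Xs = genotypes.standardized()
    mediated = np.zeros(n)
    for gene in annotation["gene_id"]:
        a = truth.alpha[gene]
        if a == 0.0:
            continue
        cols = genotypes.gene_columns(gene)
        mediated += a * (Xs[:, cols] @ truth.mediator_weights[gene])
    y = np.zeros(n)
    if config.mediated_h2 > 0:
        sd = mediated.std()
        if sd == 0:
            raise ValueError("mediated_h2 > 0 but no gene mediates the phenotype")
        y += mediated * np.sqrt(config.mediated_h2) / sd
    direct = Xs @ truth.direct_effects
    if config.direct_h2 > 0:
        y += direct * np.sqrt(config.direct_h2) / direct.std()
    gamma = np.asarray(config.covariate_effects)
    y += covariates.to_numpy() @ gamma
    resid_var = 1.0 - config.mediated_h2 - config.direct_h2
    y += np.sqrt(resid_var) * rng.standard_normal(n)
    return y


def gwas_from_cohort(cohort: Cohort) -> pd.DataFrame:
    """Marginal per-SNP OLS summary statistics on the covariate-residualized
    phenotype; z is the marginal t-statistic, p its two-sided normal tail."""
    y = cohort.phenotype
    if y is None:
        raise ValueError("cohort has no phenotype")
    C = np.column_stack([np.ones(len(y)), cohort.covariates.to_numpy()])
    beta, *_ = np.linalg.lstsq(C, y, rcond=None)
    yres = y - C @ beta
    yres = yres - yres.mean()
    X = cohort.genotypes.X.astype(float)
    Xc = X - X.mean(axis=0)
    n = len(y)
    sx = np.sqrt((Xc * Xc).sum(axis=0))
    sy = np.sqrt((yres * yres).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ yres) / (sx * sy)
    r = np.nan_to_num(np.clip(r, -1 + 1e-12, 1 - 1e-12))
    z = r * np.sqrt((n - 2) / (1.0 - r * r))
    out = cohort.genotypes.snps[["snp", "chr", "pos", "a1", "a2"]].copy()
    out["z"] = z
    out["n"] = n
    out["p"] = 2.0 * norm.sf(np.abs(z))
    return out


# ---------------------------------------------------------------------------
# reference products: weights, LD, interactions


def oracle_weight_panel(
    truth: SyntheticTruth, genotypes: Genotypes, tissues: list[str]
) -> pd.DataFrame:
    """True eQTL effect matrices exported as a WeightPanel table
    (standardized-genotype scale, nonzero entries only)."""
    rows = []
    for gene, B in truth.eqtl_effects.items():
        block = genotypes.snps[genotypes.snps["gene_id"] == gene].reset_index(drop=True)
        for t, tissue in enumerate(tissues):
            for j in range(B.shape[0]):
                w = B[j, t]
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
    return pd.DataFrame(
        rows,
        columns=["gene_id", "tissue_id", "snp_id", "effect_allele", "other_allele", "weight"],
    )


def build_ld_reference(genotypes: Genotypes, annotation: pd.DataFrame) -> LdReference:
    """Per-gene empirical correlation matrices from a reference cohort."""
    Xs = genotypes.standardized()
    ld = LdReference()
    for gene in annotation["gene_id"]:
        cols = genotypes.gene_columns(gene)
        D = np.atleast_2d(np.corrcoef(Xs[:, cols], rowvar=False))
        np.fill_diagonal(D, 1.0)
        snp_tab = genotypes.snps.iloc[cols][["snp", "a1", "a2"]].reset_index(drop=True)
        ld.genes[gene] = (snp_tab, D)
    return ld


def simulate_interactions(
    annotation: pd.DataFrame,
    active_genes: set[str],
    rng: np.random.Generator,
    cell_types: tuple[str, ...] = ("excitatory", "hippocampal", "motor", "astrocyte"),
    base_mean: float = 5.0,
    mean_shift: float = 2.0,
    dispersion: float = 5.0,
) -> pd.DataFrame:
    """Negative-binomial interaction counts per gene x cell type, with a
    mean shift for the designated active subset."""
    rows = []
    for gene in annotation["gene_id"]:
        mu = base_mean + (mean_shift if gene in active_genes else 0.0)
        p = dispersion / (dispersion + mu)
        counts = rng.negative_binomial(dispersion, p, size=len(cell_types))
        for ct, cnt in zip(cell_types, counts):
            rows.append({"gene_id": gene, "cell_type": ct, "count": int(cnt)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# orchestrator


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Generate every pipeline input from one config, deterministically.

    Cohorts are disjoint by construction (independent draws from the
    same SNP frame); identical seed gives bit-identical output.
    """
    ss = np.random.SeedSequence(config.seed)
    keys = ss.spawn(10)
    rngs = [np.random.default_rng(k) for k in keys]

    annotation = make_annotation(config)
    m_total = config.n_genes * config.snps_per_gene
    frame_rng = rngs[0]
    mafs = frame_rng.uniform(config.maf_range[0], config.maf_range[1], size=m_total)
    picks = frame_rng.integers(0, len(_ALLELE_PAIRS), size=m_total)
    alleles = [_ALLELE_PAIRS[i] for i in picks]

    ref_geno = simulate_genotypes(config.n_ref, annotation, config, rngs[1], mafs, alleles)
    gwas_geno = simulate_genotypes(config.n_gwas, annotation, config, rngs[2], mafs, alleles)
    train_geno = simulate_genotypes(config.n_train, annotation, config, rngs[3], mafs, alleles)
    test_geno = simulate_genotypes(config.n_test, annotation, config, rngs[4], mafs, alleles)

    truth = make_truth(ref_geno, annotation, config, rngs[5])
    expression = simulate_expression(ref_geno, truth, annotation, config, rngs[6])

    tissues = [f"tissue{t}" for t in range(config.n_tissues)]
    weights = oracle_weight_panel(truth, ref_geno, tissues)
    ld = build_ld_reference(ref_geno, annotation)

    cohorts = {}
    for name, geno, rng in (
        ("gwas", gwas_geno, rngs[7]),
        ("train", train_geno, rngs[8]),
        ("test", test_geno, rngs[9]),
    ):
        cov = _draw_covariates(geno.n, config, rng)
        y = simulate_phenotype(geno, truth, annotation, config, rng, cov)
        cohorts[name] = Cohort(genotypes=geno, covariates=cov, phenotype=y)

    ref = Cohort(genotypes=ref_geno, covariates=_draw_covariates(ref_geno.n, config, rngs[0]))
    gwas = gwas_from_cohort(cohorts["gwas"])

    return SyntheticStudy(
        config=config,
        annotation=annotation,
        truth=truth,
        ref=ref,
        gwas_cohort=cohorts["gwas"],
        train=cohorts["train"],
        test=cohorts["test"],
        expression=expression,
        gwas=gwas,
        weights=weights,
        ld=ld,
        tissues=tissues,
    )
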