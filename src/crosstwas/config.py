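"""Simulation configuration."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study generator.

    Variance shares refer to the GWAS phenotype: ``mediated_h2`` flows
    through genetically regulated expression, ``direct_h2`` through
    SNP effects that bypass expression; their sum must stay below 1.
    """

    n_ref: int = 500
    n_gwas: int = 5000
    n_train: int = 2000
    n_test: int = 1000
    n_genes: int = 20
    snps_per_gene: int = 10
    n_tissues: int = 5
    ld_rho: float = 0.3
    maf_range: tuple[float, float] = (0.1, 0.5)
    cis_h2: float = 0.3
    cross_tissue_cor: float = 0.7
    n_causal_eqtl_per_gene: int = 3
    mediated_h2: float = 0.2
    direct_h2: float = 0.1
    n_causal_genes: int | None = None  # None -> all genes mediate
    n_covariates: int = 2
    covariate_effects: tuple[float, ...] = (0.1, 0.1)
    gene_length: int = 50_000
    gene_spacing: int = 400_000
    n_chromosomes: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError(f"ld_rho must lie in [0, 1), got {self.ld_rho}")
        if not (0.0 <= self.cis_h2 < 1.0):
            raise ValueError(f"cis_h2 must lie in [0, 1), got {self.cis_h2}")
        if not (0.0 <= self.cross_tissue_cor <= 1.0):
            raise ValueError("cross_tissue_cor must lie in [0, 1]")
        if self.mediated_h2 < 0 or self.direct_h2 < 0:
            raise ValueError("variance shares must be non-negative")
        if self.mediated_h2 + self.direct_h2 >= 1.0:
            raise ValueError("mediated_h2 + direct_h2 must be < 1")
        if self.n_causal_eqtl_per_gene > self.snps_per_gene:
            raise ValueError("n_causal_eqtl_per_gene exceeds snps_per_gene")
        if min(self.n_ref, self.n_gwas, self.n_train, self.n_test) <= 0:
            raise ValueError("cohort sizes must be positive")
        if self.n_genes <= 0 or self.snps_per_gene <= 0 or self.n_tissues <= 0:
            raise ValueError("n_genes, snps_per_gene, n_tissues must be positive")
        if len(self.covariate_effects) != self.n_covariates:
            raise ValueError("covariate_effects length must equal n_covariates")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["maf_range"] = list(d["maf_range"])
        d["covariate_effects"] = list(d["covariate_effects"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "maf_range" in d:
            d["maf_range"] = tuple(d["maf_range"])
        if "covariate_effects" in d:
            d["covariate_effects"] = tuple(d["covariate_effects"])
        return cls(**d)
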