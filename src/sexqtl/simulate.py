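"""Synthetic cohorts with a fully known truth table.

Generates genotypes with blockwise LD and X hemizygosity, sex labels and
sample metadata, expression matrices with sex main effects, cis-genetic
effects, genotype-by-sex interactions, hidden-factor confounding and
noise, paired discovery/replication cohorts, and sex-stratified GWAS
summary statistics through a protein-mediated phenotype model. Every draw
is a pure function of (config, seed).

Genotypes come from a thresholded latent-Gaussian haplotype model: each
haplotype's latent vector has within-block correlation rho, and an allele
is carried when the latent value exceeds the 1-MAF quantile, which yields
Hardy-Weinberg genotype frequencies with tunable LD. Males carry a single
X haplotype, so their X dosages are {0, 2}.

The expression model for gene g in sample i is

    y_gi = sum_j beta_cis[j] x_ij + beta_sex s_i
           + sum_j beta_gxs[j] x_ij s_i + sum_f lambda_gf u_if + eps_gi

with s in {0 (male), 1 (female)}; the interaction beta is therefore the
female-minus-male difference in per-allele effect, matching the scan's
convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype import GenotypeMatrix, write_plink
from .expression import ExpressionMatrix

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_genotypes",
    "simulate_sex",
    "simulate_metadata",
    "simulate_expression",
    "simulate_replication_pair",
    "simulate_gwas",
    "write_cohort",
]

GENE_SPACING = 2_000_000  # bp between simulated gene starts
GENE_LENGTH = 10_000
SNP_SPAN = 100_000  # SNPs scattered within +/- span/2 of the gene


@dataclass
class SimConfig:
    """Generative settings; defaults emulate a single-region brain pQTL
    cohort at desk scale (n close to the 716-sample discovery stratum,
    balanced sexes, common variants, moderate LD)."""

    n_samples: int = 716
    n_genes: int = 60
    snps_per_gene: int = 12
    maf_min: float = 0.05
    maf_max: float = 0.5
    ld_block_size: int = 6
    ld_rho: float = 0.8
    fraction_x_genes: float = 0.05
    sex_effect_sd: float = 0.5
    sex_effect_fraction: float = 0.15
    cis_beta_sd: float = 0.4
    cis_fraction: float = 0.5
    interaction_beta_sd: float = 0.4
    interaction_fraction: float = 0.1
    n_x_background: int = 300  # array-style X markers for sex inference
    n_hidden_factors: int = 3
    hidden_loading_sd: float = 0.3
    hidden_fraction: float = 0.3
    hidden_sex_correlation: float = 0.0  # stress mode for confounding checks
    noise_sd: float = 1.0
    replication_overlap: float = 1.0
    gwas_n: int = 20_000
    protein_trait_effect_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.maf_min <= self.maf_max <= 0.5:
            raise ValueError("need 0 < maf_min <= maf_max <= 0.5")
        for name in ("fraction_x_genes", "sex_effect_fraction", "cis_fraction",
                     "interaction_fraction", "hidden_fraction", "replication_overlap"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class SimTruth:
    """Everything the generator decided, for downstream truth checks."""

    sex: np.ndarray  # 0 male / 1 female per sample
    gene_ids: list[str]
    gene_table: pd.DataFrame  # gene_id, chromosome, start, end
    sex_effects: np.ndarray  # per gene
    cis_betas: dict  # gene_id -> per-snp base (male) effect vector
    interaction_betas: dict  # gene_id -> per-snp female-minus-male effect
    hidden_factors: np.ndarray  # samples x f
    hidden_loadings: np.ndarray  # genes x f
    protein_trait_effects: dict = field(default_factory=dict)  # gene -> {male, female}

    def to_json(self, path) -> None:
        payload = {
            "sex": self.sex.tolist(),
            "gene_ids": self.gene_ids,
            "sex_effects": self.sex_effects.tolist(),
            "cis_betas": {g: v.tolist() for g, v in self.cis_betas.items()},
            "interaction_betas": {g: v.tolist() for g, v in self.interaction_betas.items()},
            "hidden_loadings": self.hidden_loadings.tolist(),
            "protein_trait_effects": self.protein_trait_effects,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path, gene_table: pd.DataFrame | None = None) -> "SimTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            sex=np.array(d["sex"]),
            gene_ids=d["gene_ids"],
            gene_table=gene_table if gene_table is not None else pd.DataFrame(),
            sex_effects=np.array(d["sex_effects"]),
            cis_betas={g: np.array(v) for g, v in d["cis_betas"].items()},
            interaction_betas={g: np.array(v) for g, v in d["interaction_betas"].items()},
            hidden_factors=np.empty((0, 0)),
            hidden_loadings=np.array(d["hidden_loadings"]),
            protein_trait_effects=d["protein_trait_effects"],
        )


def _gene_layout(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Place genes on autosomes 1-22 plus X (the configured fraction)."""
    n_x = int(round(cfg.fraction_x_genes * cfg.n_genes))
    rows = []
    for i in range(cfg.n_genes):
        if i < cfg.n_genes - n_x:
            chrom = str((i % 22) + 1)
            rank = i // 22
        else:
            chrom = "X"
            rank = i - (cfg.n_genes - n_x)
        start = 1_000_000 + rank * GENE_SPACING
        rows.append({"gene_id": f"gene{i:04d}", "chromosome": chrom,
                     "start": start, "end": start + GENE_LENGTH})
    return pd.DataFrame(rows)


def simulate_sex(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    return (rng.random(cfg.n_samples) < 0.5).astype(int)


def simulate_genotypes(
    cfg: SimConfig, sex: np.ndarray | None = None, rng: np.random.Generator | None = None,
    n_samples: int | None = None, sample_prefix: str = "S",
    template: tuple[pd.DataFrame, pd.DataFrame] | None = None,
) -> tuple[GenotypeMatrix, np.ndarray, pd.DataFrame]:
    """Draw genotypes for every gene region; returns (G, sex, gene table).

    ``template`` (a prior cohort's variant and gene tables) reuses that
    cohort's variant definitions — positions and population MAFs — so
    paired cohorts sample the same variants from the same population.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    n = n_samples if n_samples is not None else cfg.n_samples
    if sex is None:
        sex = (rng.random(n) < 0.5).astype(int)
    if template is not None:
        tvars, genes = template
        tvars = tvars.set_index("id")
    else:
        tvars = None
        genes = _gene_layout(cfg, rng)

    var_rows, dos_blocks = [], []
    for gidx, gene in enumerate(genes.itertuples(index=False)):
        m = cfg.snps_per_gene
        ids = [f"{gene.gene_id}_snp{j:03d}" for j in range(m)]
        if tvars is not None:
            mafs = tvars.loc[ids, "maf_true"].to_numpy(dtype=float)
            positions = tvars.loc[ids, "position"].to_numpy(dtype=int)
        else:
            mafs = rng.uniform(cfg.maf_min, cfg.maf_max, size=m)
            center = (gene.start + gene.end) // 2
            positions = np.sort(
                rng.choice(np.arange(center - SNP_SPAN // 2, center + SNP_SPAN // 2), m,
                           replace=False)
            )
        is_x = gene.chromosome == "X"
        dos = _draw_region(rng, n, m, mafs, cfg.ld_block_size, cfg.ld_rho, sex, is_x)
        dos_blocks.append(dos)
        for j in range(m):
            var_rows.append(
                {"id": ids[j], "chromosome": gene.chromosome,
                 "position": int(positions[j]), "ref_allele": "A", "alt_allele": "G",
                 "maf_true": float(mafs[j])}
            )
    if cfg.n_x_background:
        # independent X markers far from any gene, as a genotyping array
        # would carry; they anchor heterozygosity-based sex inference
        ids = [f"xbg_snp{j:04d}" for j in range(cfg.n_x_background)]
        if tvars is not None:
            mafs = tvars.loc[ids, "maf_true"].to_numpy(dtype=float)
        else:
            mafs = rng.uniform(cfg.maf_min, cfg.maf_max, size=cfg.n_x_background)
        dos = _draw_region(rng, n, cfg.n_x_background, mafs, 1, 0.0, sex, True)
        dos_blocks.append(dos)
        for j in range(cfg.n_x_background):
            var_rows.append(
                {"id": ids[j], "chromosome": "X",
                 "position": 100_000_000 + j * 10_000, "ref_allele": "A", "alt_allele": "G",
                 "maf_true": float(mafs[j])}
            )
    dosages = np.concatenate(dos_blocks, axis=1)
    sample_ids = [f"{sample_prefix}{i:05d}" for i in range(n)]
    g = GenotypeMatrix(dosages, pd.DataFrame(var_rows), sample_ids)
    return g, sex, genes


def _draw_region(
    rng: np.random.Generator, n: int, m: int, mafs: np.ndarray,
    block: int, rho: float, sex: np.ndarray, is_x: bool,
) -> np.ndarray:
    """Two latent-Gaussian haplotypes thresholded at the 1-MAF quantile."""
    from scipy.stats import norm

    thresh = norm.isf(mafs)  # latent value above this carries the allele

    def _haplotype() -> np.ndarray:
        z = np.empty((n, m))
        for b0 in range(0, m, block):
            b1 = min(b0 + block, m)
            shared = rng.standard_normal(n)[:, None]
            own = rng.standard_normal((n, b1 - b0))
            z[:, b0:b1] = np.sqrt(rho) * shared + np.sqrt(1 - rho) * own
        return (z > thresh).astype(float)

    h1, h2 = _haplotype(), _haplotype()
    dos = h1 + h2
    if is_x:
        male = sex == 0
        dos[male] = 2.0 * h1[male]  # hemizygous: single haplotype, coded 0/2
    return dos


def simulate_metadata(
    cfg: SimConfig, sex: np.ndarray, sample_ids: list[str], rng: np.random.Generator,
) -> pd.DataFrame:
    """Sample table with age, PMI, batch, diagnosis and environment columns.

    Environments are independent of sex unless ``hidden_sex_correlation``
    style stress is wanted, in which case callers can overwrite columns.
    """
    n = len(sample_ids)
    return pd.DataFrame(
        {
            "sample_id": sample_ids,
            "sex": sex,
            "age": np.round(rng.normal(85, 7, n), 1),
            "post_mortem_interval": np.round(rng.gamma(4, 2, n), 1),
            "batch": rng.integers(0, 4, n).astype(str),
            "diagnosis": rng.choice(["normal", "AD", "other"], n, p=[0.4, 0.4, 0.2]),
            "education": np.round(rng.normal(16, 3, n), 0),
            "alcohol": rng.integers(0, 2, n),
            "smoking": rng.integers(0, 2, n),
        }
    )


def simulate_expression(
    g: GenotypeMatrix,
    cfg: SimConfig,
    sex: np.ndarray,
    genes: pd.DataFrame,
    rng: np.random.Generator,
    truth_effects: dict | None = None,
) -> tuple[ExpressionMatrix, SimTruth]:
    """Generate expression from genotypes under the linear interaction model.

    ``truth_effects`` (from a prior cohort) reuses that cohort's effect
    sizes instead of drawing new ones, enabling matched replication draws.
    """
    n = g.n_samples
    n_genes = len(genes)
    var_gene = g.variants["id"].str.rsplit("_", n=1).str[0].to_numpy()

    if truth_effects is None:
        sex_eff = np.where(
            rng.random(n_genes) < cfg.sex_effect_fraction,
            rng.normal(0, cfg.sex_effect_sd, n_genes), 0.0,
        )
        cis, inter = {}, {}
        for i, gid in enumerate(genes["gene_id"]):
            m = int((var_gene == gid).sum())
            cb = np.where(rng.random(m) < cfg.cis_fraction, rng.normal(0, cfg.cis_beta_sd, m), 0.0)
            ib = np.where(
                rng.random(m) < cfg.interaction_fraction,
                rng.normal(0, cfg.interaction_beta_sd, m), 0.0,
            )
            cis[gid], inter[gid] = cb, ib
        loadings = np.where(
            rng.random((n_genes, cfg.n_hidden_factors)) < cfg.hidden_fraction,
            rng.normal(0, cfg.hidden_loading_sd, (n_genes, cfg.n_hidden_factors)), 0.0,
        )
    else:
        sex_eff = truth_effects["sex_effects"]
        cis = truth_effects["cis_betas"]
        inter = truth_effects["interaction_betas"]
        loadings = truth_effects["hidden_loadings"]

    factors = rng.standard_normal((n, cfg.n_hidden_factors))
    if cfg.hidden_sex_correlation > 0 and cfg.n_hidden_factors > 0:
        rho = cfg.hidden_sex_correlation
        s_std = (sex - sex.mean()) / max(sex.std(), 1e-12)
        factors[:, 0] = rho * s_std + np.sqrt(1 - rho**2) * factors[:, 0]

    values = np.empty((n_genes, n))
    for i, gid in enumerate(genes["gene_id"]):
        cols = np.where(var_gene == gid)[0]
        X = np.nan_to_num(g.dosages[:, cols])
        y = X @ cis[gid] + sex_eff[i] * sex + (X * sex[:, None]) @ inter[gid]
        if cfg.n_hidden_factors:
            y = y + factors @ loadings[i]
        y = y + rng.normal(0, cfg.noise_sd, n)
        values[i] = y

    e = ExpressionMatrix(values, list(genes["gene_id"]), list(g.sample_ids),
                         level="protein", stage="residualized")
    truth = SimTruth(
        sex=sex, gene_ids=list(genes["gene_id"]), gene_table=genes,
        sex_effects=sex_eff, cis_betas=cis, interaction_betas=inter,
        hidden_factors=factors, hidden_loadings=loadings,
    )
    return e, truth


def simulate_replication_pair(
    cfg: SimConfig, overlap: float | None = None
) -> tuple[dict, dict, SimTruth]:
    """Discovery and replication cohorts sharing (a fraction of) the truth.

    The replication cohort is an independent sample draw; a fraction
    ``overlap`` of the discovery cohort's nonzero interaction effects is
    retained, the rest zeroed. Returns two cohort dicts (keys: genotypes,
    expression, sex, genes, samples) and the discovery truth.
    """
    if overlap is None:
        overlap = cfg.replication_overlap
    if not 0 <= overlap <= 1:
        raise ValueError("overlap must lie in [0, 1]")
    rng = np.random.default_rng(cfg.seed)

    g_d, sex_d, genes = simulate_genotypes(cfg, rng=rng, sample_prefix="D")
    e_d, truth = simulate_expression(g_d, cfg, sex_d, genes, rng)

    rep_inter = {}
    for gid, ib in truth.interaction_betas.items():
        keep = rng.random(ib.shape) < overlap
        rep_inter[gid] = np.where(keep, ib, 0.0)
    rep_effects = {
        "sex_effects": truth.sex_effects,
        "cis_betas": truth.cis_betas,
        "interaction_betas": rep_inter,
        "hidden_loadings": truth.hidden_loadings,
    }
    g_r, sex_r, _ = simulate_genotypes(cfg, rng=rng, sample_prefix="R",
                                       template=(g_d.variants, genes))
    e_r, _ = simulate_expression(g_r, cfg, sex_r, genes, rng, truth_effects=rep_effects)

    disc = {"genotypes": g_d, "expression": e_d, "sex": sex_d, "genes": genes}
    repl = {"genotypes": g_r, "expression": e_r, "sex": sex_r, "genes": genes}
    truth.protein_trait_effects["replication_interaction_betas"] = {
        g: v.tolist() for g, v in rep_inter.items()
    }
    return disc, repl, truth


def simulate_gwas(
    cfg: SimConfig,
    truth: SimTruth,
    protein_effects: dict[str, dict[str, float]],
    rng: np.random.Generator | None = None,
) -> dict:
    """Sex-stratified GWAS of a protein-mediated phenotype.

    An independent cohort of ``cfg.gwas_n`` individuals is drawn with the
    same genotype law; each individual's proteins follow the cohort truth
    (cis + interaction effects, no hidden factors) and the phenotype is
    sum_g effect_sex(g) * protein_g + noise. Marginal per-variant
    beta/se/z are computed within each sex and jointly. Returns a dict
    with 'male'/'female'/'joint' summary frames (SNP, A1, A2, BETA, SE,
    Z, N) and the GWAS cohort GenotypeMatrix for LD reference.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 7)
    g, sex, genes = simulate_genotypes(cfg, rng=rng, n_samples=cfg.gwas_n, sample_prefix="G")
    var_gene = g.variants["id"].str.rsplit("_", n=1).str[0].to_numpy()

    pheno = rng.standard_normal(cfg.gwas_n)  # unit environmental noise
    for gid, eff in protein_effects.items():
        cols = np.where(var_gene == gid)[0]
        X = np.nan_to_num(g.dosages[:, cols])
        prot = (
            X @ truth.cis_betas[gid]
            + (X * sex[:, None]) @ truth.interaction_betas[gid]
            + rng.normal(0, cfg.noise_sd, cfg.gwas_n)
        )
        eff_vec = np.where(sex == 1, eff.get("female", 0.0), eff.get("male", 0.0))
        pheno = pheno + eff_vec * prot

    out = {}
    for label, mask in (("male", sex == 0), ("female", sex == 1), ("joint", slice(None))):
        Xs = g.dosages[mask]
        ys = pheno[mask]
        n = len(ys)
        Xc = Xs - Xs.mean(axis=0)
        yc = ys - ys.mean()
        xtx = np.einsum("ij,ij->j", Xc, Xc)
        with np.errstate(divide="ignore", invalid="ignore"):
            beta = (Xc.T @ yc) / xtx
            ss = yc @ yc - beta**2 * xtx
            se = np.sqrt(ss / (n - 2) / xtx)
            z = beta / se
        out[label] = pd.DataFrame(
            {"SNP": g.variants["id"], "A1": g.variants["alt_allele"],
             "A2": g.variants["ref_allele"], "BETA": beta, "SE": se, "Z": z, "N": n}
        )
    out["ld_cohort"] = g
    out["sex"] = sex
    return out


def write_cohort(outdir, g: GenotypeMatrix, e: ExpressionMatrix, samples: pd.DataFrame,
                 genes: pd.DataFrame, truth: SimTruth | None = None) -> None:
    """Write a cohort in the package's on-disk formats.

    PLINK trio, expression TSV, sample TSV, gene BED (0-based half-open)
    and, when given, the truth JSON.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_plink(g, outdir / "genotypes", sex=samples["sex"].to_numpy())
    e.write_tsv(outdir / "expression.tsv")
    samples.to_csv(outdir / "samples.tsv", sep="\t", index=False)
    bed = genes.copy()
    bed["start0"] = bed["start"] - 1  # BED is 0-based half-open
    bed[["chromosome", "start0", "end", "gene_id"]].to_csv(
        outdir / "genes.bed", sep="\t", header=False, index=False
    )
    if truth is not None:
        truth.to_json(outdir / "truth.json")
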