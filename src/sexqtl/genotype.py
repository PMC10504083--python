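"""Genotype ingestion and quality control.

Reads PLINK bed/bim/fam trios and VCFs into a dense dosage matrix, applies
the standard QC cascade (sample missingness, variant missingness, MAF,
Hardy–Weinberg), infers genetic sex from X-chromosome heterozygosity,
computes genetic principal components, and prunes related samples with a
correlation-based kinship estimate.

X-chromosome convention: male samples are hemizygous and carry dosages in
{0, 2}; heterozygous male X calls are treated as missing.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .stats import hwe_exact

__all__ = [
    "GenotypeMatrix",
    "QCReport",
    "SexCall",
    "read_genotypes",
    "write_plink",
    "qc_filter",
    "infer_sex",
    "genetic_pcs",
    "kinship_prune",
]

VARIANT_COLUMNS = ["id", "chromosome", "position", "ref_allele", "alt_allele"]


@dataclass
class GenotypeMatrix:
    """Samples x variants dosage matrix with variant metadata.

    ``dosages`` holds counted-allele dosages in {0, 1, 2} with NaN for
    missing. ``variants`` is a DataFrame with at least the columns in
    ``VARIANT_COLUMNS`` (plus optional ``annotation_class``); rows align
    with dosage columns.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def maf(self) -> np.ndarray:
        """Minor allele frequency per variant (counted-allele freq folded)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            freq = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def missing_rate(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=0)

    def sample_missing_rate(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=1)

    def is_x(self) -> np.ndarray:
        c = self.variants["chromosome"].astype(str).str.upper()
        return (c == "X") | (c == "23") | (c == "CHRX")

    def subset(self, samples=None, variants=None) -> "GenotypeMatrix":
        d = self.dosages
        sids = self.sample_ids
        var = self.variants
        if samples is not None:
            samples = np.asarray(samples)
            d = d[samples]
            sids = [sids[i] for i in np.atleast_1d(samples)]
        if variants is not None:
            variants = np.asarray(variants)
            d = d[:, variants]
            var = var.iloc[variants]
        return GenotypeMatrix(d.copy(), var.reset_index(drop=True), list(sids))

    def imputed_standardized(self) -> np.ndarray:
        """Mean-imputed, column-standardized dosage matrix (for PCA/LD/r2)."""
        d = self.dosages.copy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mu = np.nanmean(d, axis=0)
        mu = np.where(np.isnan(mu), 0.0, mu)
        idx = np.where(np.isnan(d))
        d[idx] = mu[idx[1]]
        sd = d.std(axis=0)
        sd[sd == 0] = 1.0
        return (d - mu) / sd


@dataclass
class SexCall:
    sample_id: str
    x_heterozygosity: float
    call: str  # male | female | ambiguous


@dataclass
class QCReport:
    """Per-rule removal counts plus the thresholds actually applied."""

    n_samples_in: int = 0
    n_variants_in: int = 0
    samples_removed_missing: int = 0
    variants_removed_missing: int = 0
    variants_removed_maf: int = 0
    variants_removed_hwe: int = 0
    variants_removed_multiallelic: int = 0
    thresholds: dict = field(default_factory=dict)
    notes: list = field(default_factory=list)

    @property
    def n_samples_out(self) -> int:
        return self.n_samples_in - self.samples_removed_missing

    @property
    def n_variants_out(self) -> int:
        return (
            self.n_variants_in
            - self.variants_removed_missing
            - self.variants_removed_maf
            - self.variants_removed_hwe
        )

    def to_json(self, path=None) -> str:
        payload = {
            "n_samples_in": self.n_samples_in,
            "n_samples_out": self.n_samples_out,
            "n_variants_in": self.n_variants_in,
            "n_variants_out": self.n_variants_out,
            "samples_removed_missing": self.samples_removed_missing,
            "variants_removed_missing": self.variants_removed_missing,
            "variants_removed_maf": self.variants_removed_maf,
            "variants_removed_hwe": self.variants_removed_hwe,
            "variants_removed_multiallelic": self.variants_removed_multiallelic,
            "thresholds": self.thresholds,
            "notes": self.notes,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_genotypes(path, fmt: str | None = None, count_allele: str = "minor") -> GenotypeMatrix:
    """Read genotypes from a PLINK prefix or a VCF file.

    Parameters
    ----------
    path
        PLINK prefix (``prefix`` with ``prefix.bed/.bim/.fam`` present) or
        a ``.vcf``/``.vcf.gz`` path.
    fmt : {"plink", "vcf", None}
        Autodetected from the path when None.
    count_allele : {"minor", "alt"}
        With "minor" (default) dosages are re-oriented so that the counted
        allele is the minor allele recomputed from the data.
    """
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix in {".vcf", ".gz"} or path.name.endswith(".vcf.gz") else "plink"
    if fmt == "plink":
        g = _read_plink(path)
    elif fmt == "vcf":
        g = _read_vcf(path)
    else:
        raise ValueError(f"unknown genotype format {fmt!r}")
    if count_allele == "minor":
        _orient_to_minor(g)
    elif count_allele != "alt":
        raise ValueError("count_allele must be 'minor' or 'alt'")
    return g


def _orient_to_minor(g: GenotypeMatrix) -> None:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        freq = np.nanmean(g.dosages, axis=0) / 2.0
    flip = freq > 0.5
    if flip.any():
        g.dosages[:, flip] = 2.0 - g.dosages[:, flip]
        ref = g.variants.loc[flip, "ref_allele"].copy()
        g.variants.loc[flip, "ref_allele"] = g.variants.loc[flip, "alt_allele"].values
        g.variants.loc[flip, "alt_allele"] = ref.values


def _read_plink(prefix: Path) -> GenotypeMatrix:
    bed, bim, fam = (Path(str(prefix) + s) for s in (".bed", ".bim", ".fam"))
    for f in (bed, bim, fam):
        if not f.exists():
            raise FileNotFoundError(f"missing PLINK file {f}")
    bim_df = pd.read_csv(
        bim,
        sep=r"\s+",
        header=None,
        names=["chromosome", "id", "cm", "position", "a1", "a2"],
        dtype={"chromosome": str, "id": str, "a1": str, "a2": str},
    )
    fam_df = pd.read_csv(fam, sep=r"\s+", header=None, usecols=[1], names=["iid"], dtype=str)
    sample_ids = fam_df["iid"].tolist()
    n, m = len(sample_ids), len(bim_df)

    raw = np.fromfile(bed, dtype=np.uint8)
    if raw.size < 3 or raw[0] != 0x6C or raw[1] != 0x1B:
        raise ValueError(f"{bed} is not a PLINK bed file (bad magic bytes)")
    if raw[2] != 0x01:
        raise ValueError(f"{bed}: only SNP-major bed files are supported")
    bpv = (n + 3) // 4  # bytes per variant
    body = raw[3:]
    if body.size != bpv * m:
        raise ValueError(
            f"{bed}: size implies {body.size // max(bpv, 1)} variants but .bim lists {m} "
            "(sample count mismatch across the PLINK trio?)"
        )
    blocks = body.reshape(m, bpv)
    # unpack 2-bit codes, little-endian within each byte
    codes = np.empty((m, bpv * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (blocks >> (2 * k)) & 0b11
    codes = codes[:, :n]
    lut = np.array([2.0, np.nan, 1.0, 0.0])
    dosages = lut[codes].T  # samples x variants, counting A1

    variants = pd.DataFrame(
        {
            "id": bim_df["id"],
            "chromosome": bim_df["chromosome"],
            "position": bim_df["position"].astype(int),
            "ref_allele": bim_df["a2"],
            "alt_allele": bim_df["a1"],
        }
    )
    return GenotypeMatrix(dosages, variants, sample_ids)


def write_plink(g: GenotypeMatrix, prefix, sex: np.ndarray | None = None) -> None:
    """Write a GenotypeMatrix as a PLINK bed/bim/fam trio (bed v1.00, SNP-major).

    Dosages are written counting the alt allele as A1. ``sex`` (0=male-coded
    as 1, 1=female-coded as 2 in .fam, PLINK convention 1=male/2=female)
    is optional.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = g.n_samples, g.n_variants

    with open(str(prefix) + ".fam", "w") as fh:
        for i, sid in enumerate(g.sample_ids):
            plink_sex = 0
            if sex is not None:
                plink_sex = 1 if sex[i] == 0 else 2
            fh.write(f"{sid} {sid} 0 0 {plink_sex} -9\n")

    with open(str(prefix) + ".bim", "w") as fh:
        for _, v in g.variants.iterrows():
            fh.write(
                f"{v['chromosome']}\t{v['id']}\t0\t{int(v['position'])}"
                f"\t{v['alt_allele']}\t{v['ref_allele']}\n"
            )

    dos = g.dosages
    code = np.full((m, n), 0b01, dtype=np.uint8)  # missing
    dT = dos.T
    code[dT == 2] = 0b00
    code[dT == 1] = 0b10
    code[dT == 0] = 0b11
    bpv = (n + 3) // 4
    padded = np.zeros((m, bpv * 4), dtype=np.uint8)
    padded[:, :n] = code
    packed = np.zeros((m, bpv), dtype=np.uint8)
    for k in range(4):
        packed |= padded[:, k::4] << (2 * k)
    with open(str(prefix) + ".bed", "wb") as fh:
        fh.write(bytes([0x6C, 0x1B, 0x01]))
        fh.write(packed.tobytes())


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    sample_ids = list(vcf.samples)
    rows, dos_cols = [], []
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        rows.append(
            {
                "id": rec.ID or f"{rec.CHROM}:{rec.POS}",
                "chromosome": str(rec.CHROM).removeprefix("chr"),
                "position": int(rec.POS),
                "ref_allele": rec.REF,
                "alt_allele": rec.ALT[0],
            }
        )
        gt = np.asarray(rec.gt_types, dtype=float)  # 0/1/2, 3=missing
        gt[gt == 3] = np.nan
        dos_cols.append(gt)
    if not rows:
        raise ValueError(f"{path}: no biallelic records")
    if n_multi:
        warnings.warn(f"{path}: dropped {n_multi} non-biallelic records", UserWarning, stacklevel=2)
    g = GenotypeMatrix(np.column_stack(dos_cols), pd.DataFrame(rows), sample_ids)
    g.variants.attrs["n_multiallelic_dropped"] = n_multi
    return g


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


def qc_filter(
    g: GenotypeMatrix,
    sample_miss: float = 0.05,
    var_miss: float = 0.05,
    maf_min: float = 0.05,
    hwe_p_min: float = 5e-7,
    sex: np.ndarray | None = None,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the standard QC cascade, samples before variants.

    Removal rules are strict inequalities: a sample is dropped when its
    missing rate exceeds ``sample_miss``; a variant when its missing rate
    exceeds ``var_miss``, its MAF is below ``maf_min``, or its HWE exact
    p-value is below ``hwe_p_min``. On the X chromosome HWE is computed in
    females only (requires ``sex``: 0=male, 1=female; without it X variants
    skip the HWE rule).
    """
    if g.n_variants == 0 or g.n_samples == 0:
        raise ValueError("empty genotype matrix")
    rep = QCReport(
        n_samples_in=g.n_samples,
        n_variants_in=g.n_variants,
        thresholds={
            "sample_miss": sample_miss,
            "var_miss": var_miss,
            "maf_min": maf_min,
            "hwe_p_min": hwe_p_min,
        },
        notes=["kinship/PCA here are correlation-based simplifications of KING/EIGENSTRAT"],
    )
    smiss = g.sample_missing_rate()
    keep_s = smiss <= sample_miss
    rep.samples_removed_missing = int((~keep_s).sum())
    g = g.subset(samples=np.where(keep_s)[0])
    if sex is not None:
        sex = np.asarray(sex)[keep_s]

    vmiss = g.missing_rate()
    fail_miss = vmiss > var_miss
    maf = g.maf()
    fail_maf = (~fail_miss) & (maf < maf_min)

    is_x = g.is_x().to_numpy()
    fail_hwe = np.zeros(g.n_variants, dtype=bool)
    for j in range(g.n_variants):
        if fail_miss[j] or fail_maf[j]:
            continue
        col = g.dosages[:, j]
        if is_x[j]:
            if sex is None:
                continue
            col = col[sex == 1]
        col = col[~np.isnan(col)]
        if col.size == 0:
            continue
        counts = [int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())]
        if hwe_exact(*counts) < hwe_p_min:
            fail_hwe[j] = True

    rep.variants_removed_missing = int(fail_miss.sum())
    rep.variants_removed_maf = int(fail_maf.sum())
    rep.variants_removed_hwe = int(fail_hwe.sum())
    keep_v = ~(fail_miss | fail_maf | fail_hwe)
    if not keep_v.any():
        raise ValueError("all variants removed by QC; review thresholds")
    return g.subset(variants=np.where(keep_v)[0]), rep


def infer_sex(
    g: GenotypeMatrix,
    male_max: float = 0.02,
    female_min: float = 0.15,
    min_x_variants: int = 20,
) -> list[SexCall]:
    """Call genetic sex from X-chromosome heterozygosity.

    Heterozygosity below ``male_max`` calls male, above ``female_min`` calls
    female, between (or with < ``min_x_variants`` informative X variants)
    is ambiguous.
    """
    is_x = g.is_x().to_numpy()
    if not is_x.any():
        raise ValueError("no X-chromosome variants; cannot infer sex")
    x = g.dosages[:, is_x]
    calls = []
    for i, sid in enumerate(g.sample_ids):
        row = x[i]
        ok = ~np.isnan(row)
        n_ok = int(ok.sum())
        het = float((row[ok] == 1).mean()) if n_ok else np.nan
        if n_ok < min_x_variants:
            call = "ambiguous"
        elif het < male_max:
            call = "male"
        elif het > female_min:
            call = "female"
        else:
            call = "ambiguous"
        calls.append(SexCall(sid, het, call))
    return calls


def genetic_pcs(g: GenotypeMatrix, k: int = 10) -> np.ndarray:
    """Principal components of the standardized dosage matrix.

    Missing dosages are mean-imputed per variant. Returned columns are
    orthogonal with unit variance; the sign convention makes the
    largest-magnitude variant loading of each component positive.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > min(g.n_samples, g.n_variants):
        raise ValueError(f"k={k} exceeds matrix rank bound {min(g.n_samples, g.n_variants)}")
    Z = g.imputed_standardized()
    U, s, Vt = np.linalg.svd(Z - Z.mean(axis=0), full_matrices=False)
    rank = int((s > s[0] * 1e-10).sum()) if s.size else 0
    if k > rank:
        raise ValueError(f"k={k} exceeds rank {rank}")
    scores = U[:, :k] * s[:k]
    for j in range(k):
        lead = np.argmax(np.abs(Vt[j]))
        if Vt[j, lead] < 0:
            scores[:, j] = -scores[:, j]
    sd = scores.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return scores / sd


def kinship_matrix(g: GenotypeMatrix) -> np.ndarray:
    """Pairwise kinship as correlation of standardized genotypes over 2."""
    Z = g.imputed_standardized()
    m = Z.shape[1]
    return (Z @ Z.T) / m / 2.0


def kinship_prune(g: GenotypeMatrix, threshold: float = 0.177, seed: int = 0) -> list[str]:
    """Greedy seeded prune of related pairs; returns retained sample ids.

    Kinship above ``threshold`` (default 0.177, second-degree cutoff)
    flags a pair; one member, chosen at random with the given seed, is
    removed until no flagged pair remains.
    """
    if g.n_samples < 2:
        raise ValueError("need at least 2 samples")
    K = kinship_matrix(g)
    rng = np.random.default_rng(seed)
    alive = np.ones(g.n_samples, dtype=bool)
    iu = np.triu_indices(g.n_samples, k=1)
    pairs = [(i, j) for i, j in zip(*iu) if K[i, j] > threshold]
    while True:
        active = [(i, j) for i, j in pairs if alive[i] and alive[j]]
        if not active:
            break
        i, j = active[0]
        alive[i if rng.random() < 0.5 else j] = False
    return [sid for sid, a in zip(g.sample_ids, alive) if a]
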