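"""Synthetic cohort generator for blood methylome-wide association analysis.

Emulates the statistical structure the downstream pipeline assumes:

* LD-correlated biallelic genotypes — a latent multivariate normal with AR(1)
  correlation inside fixed-size blocks, thresholded per haplotype at the
  normal quantile of the minor-allele frequency, so genotype classes follow
  Hardy-Weinberg proportions at the drawn MAF and LD is tunable without an
  external reference panel.
* cis-meQTL architecture — each CpG's latent (M-value-like) methylation is a
  linear combination of a few causal cis SNPs plus Gaussian noise, scaled so
  the realized cis heritability matches ``cis_h2``; array-style beta values
  are the inverse-logit of the latent.
* methylation-mediated expression — each gene's expression is
  ``mediation_beta`` times its CpG's latent methylation plus unit noise.
* liability-threshold case-control GWAS — disease liability is a weighted sum
  of CpG latents plus standard-normal environment; samples above the
  (1 - prevalence) empirical quantile are cases, and per-variant logistic
  regression of case status on dosage yields standard GWAS summary
  statistics (log-OR, SE, Wald p).

One master seed drives everything; per-stage child seeds are derived as
``SeedSequence((seed, STAGE_TAG))`` so each stage is independently
reproducible (the tags are module constants).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "SimConfig",
    "GenotypeMatrix",
    "MolecularMatrix",
    "TruthTable",
    "simulate_genotypes",
    "simulate_methylation_expression",
    "simulate_gwas",
    "simulate_covariates",
    "write_fixture_bundle",
    "read_vcf",
    "read_matrix_tsv",
    "read_bed",
    "read_gwas_tsv",
    "read_truth_tsv",
]

# Child-seed tags: SeedSequence((master_seed, tag)) per stage.
STAGE_GENOTYPES = 11
STAGE_MOLECULAR = 13
STAGE_GWAS = 17
STAGE_COVARIATES = 19

SUMSTATS_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "p", "n_cases", "n_controls",
]

# ref -> non-complementary alt choices (avoids strand-ambiguous A/T, C/G pairs)
_ALT_CHOICES = {"A": ("C", "G"), "T": ("C", "G"), "C": ("A", "T"), "G": ("A", "T")}


class SimConfigError(ValueError):
    """Raised when a simulation configuration is out of range."""


def _stage_rng(seed: int, tag: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), int(tag))))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort.

    ``liability_effects`` maps CpG ids (``cpg00001`` style) to per-unit
    effects of the latent methylation on disease liability; CpGs not listed
    contribute nothing.
    """

    n_samples: int = 1000
    n_snps: int = 200
    n_cpgs: int = 20
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_rho: float = 0.6
    block_size: int = 10
    cis_h2: float = 0.4
    n_causal_per_cpg: int = 2
    mediation_beta: float = -0.5
    prevalence: float = 0.1
    liability_effects: dict[str, float] = field(default_factory=dict)
    seed: int = 0
    chrom: str = "1"
    snp_spacing: int = 1000
    first_pos: int = 10_000

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise SimConfigError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        if not (0.0 <= self.ld_rho < 1.0):
            raise SimConfigError(f"ld_rho must be in [0, 1), got {self.ld_rho}")
        if not (0.0 <= self.cis_h2 < 1.0):
            raise SimConfigError(f"cis_h2 must be in [0, 1), got {self.cis_h2}")
        if not (0.0 < self.prevalence < 1.0):
            raise SimConfigError(f"prevalence must be in (0, 1), got {self.prevalence}")
        if self.n_causal_per_cpg > self.n_snps:
            raise SimConfigError("n_causal_per_cpg cannot exceed n_snps")
        if self.block_size < 1 or self.n_snps < 1 or self.n_samples < 2:
            raise SimConfigError("block_size/n_snps must be >= 1 and n_samples >= 2")


@dataclass
class GenotypeMatrix:
    """Biallelic dosages for a cohort: ``dosages[i, j]`` counts alt alleles."""

    sample_ids: list[str]
    variants: pd.DataFrame  # columns: id, chrom, pos, ref, alt, maf
    dosages: np.ndarray  # (n_samples, n_variants), values in {0, 1, 2}

    def __post_init__(self) -> None:
        if self.variants["id"].duplicated().any():
            raise ValueError("duplicate variant ids")
        pos = self.variants.groupby("chrom", sort=False)["pos"]
        if not all(g.is_monotonic_increasing and g.is_unique for _, g in pos):
            raise ValueError("positions must be strictly increasing within chromosome")
        freq = self.dosages.mean(axis=0) / 2.0
        if np.any(freq <= 0.0) or np.any(freq >= 1.0):
            raise ValueError("monomorphic variant in genotype matrix")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def variant_ids(self) -> list[str]:
        return self.variants["id"].tolist()

    def column_index(self, variant_ids) -> np.ndarray:
        lookup = {v: i for i, v in enumerate(self.variants["id"])}
        return np.array([lookup[v] for v in variant_ids], dtype=int)


@dataclass
class MolecularMatrix:
    """Samples x features molecular matrix (methylation or expression)."""

    feature_ids: list[str]
    coords: pd.DataFrame  # columns: id, chrom, pos (1-based feature anchor)
    values: np.ndarray  # (n_samples, n_features)
    kind: str  # "methylation-beta" | "normalized" | "expression"
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        if self.kind == "methylation-beta":
            if np.any(self.values < 0.0) or np.any(self.values > 1.0):
                raise ValueError("methylation beta values must lie in [0, 1]")
        if self.kind == "normalized":
            means = np.abs(self.values.mean(axis=0))
            if means.size and means.max() >= 1e-8:
                raise ValueError("normalized features must be centered")

    def feature_vector(self, feature_id: str) -> np.ndarray:
        j = self.feature_ids.index(feature_id)
        return self.values[:, j]


@dataclass
class TruthTable:
    """Ground truth of the generative model, for parameter-recovery tests.

    ``cpg_effects`` holds per-dosage effect sizes of each causal variant on
    the latent methylation; ``cpg_latent`` keeps the pre-logit methylation
    matrix so liability can be reconstructed exactly.
    """

    cpg_effects: dict[str, list[tuple[str, float]]]  # cpg -> [(variant, beta)]
    mediation: dict[str, tuple[str, float]]  # gene -> (cpg, coefficient)
    liability_effects: dict[str, float]
    cpg_latent: pd.DataFrame  # samples x cpgs

    def validate_against(self, G: GenotypeMatrix, meth: MolecularMatrix,
                         expr: MolecularMatrix) -> None:
        vids = set(G.variants["id"])
        cids = set(meth.feature_ids)
        for cpg, pairs in self.cpg_effects.items():
            if cpg not in cids:
                raise ValueError(f"truth references unknown CpG {cpg}")
            for vid, _ in pairs:
                if vid not in vids:
                    raise ValueError(f"truth references unknown variant {vid}")
        gids = set(expr.feature_ids)
        for gene, (cpg, _) in self.mediation.items():
            if gene not in gids or cpg not in cids:
                raise ValueError(f"truth references unknown pair {gene}/{cpg}")


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def _ar1_latent(rng: np.random.Generator, n_rows: int, n_snps: int,
                rho: float, block_size: int) -> np.ndarray:
    """Latent N(0,1) with AR(1) correlation rho inside consecutive blocks."""
    z = np.empty((n_rows, n_snps))
    innov = rng.standard_normal((n_rows, n_snps))
    scale = np.sqrt(1.0 - rho * rho)
    for j in range(n_snps):
        if j % block_size == 0:
            z[:, j] = innov[:, j]
        else:
            z[:, j] = rho * z[:, j - 1] + scale * innov[:, j]
    return z


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Draw LD-correlated biallelic dosages under the latent-threshold model.

    Two latent haplotypes per sample are thresholded at ``Phi^{-1}(maf)``, so
    each variant's genotype classes follow Hardy-Weinberg proportions at its
    drawn MAF while the latent AR(1) correlation induces LD within blocks.
    """
    rng = _stage_rng(config.seed, STAGE_GENOTYPES)
    lo, hi = config.maf_range
    mafs = rng.uniform(lo, hi, size=config.n_snps)
    thresholds = norm.ppf(mafs)

    latent = _ar1_latent(rng, 2 * config.n_samples, config.n_snps,
                         config.ld_rho, config.block_size)
    haplos = (latent < thresholds).astype(np.int8)
    dosages = (haplos[: config.n_samples] + haplos[config.n_samples:]).astype(float)

    # Guard against monomorphic draws at small n: flip one haplotype.
    freq = dosages.mean(axis=0) / 2.0
    for j in np.nonzero((freq <= 0.0) | (freq >= 1.0))[0]:
        i = int(rng.integers(config.n_samples))
        dosages[i, j] = 1.0 if freq[j] <= 0.0 else dosages[i, j] - 1.0

    refs = rng.choice(list("ACGT"), size=config.n_snps)
    alts = np.array([_ALT_CHOICES[r][rng.integers(2)] for r in refs])
    positions = config.first_pos + config.snp_spacing * np.arange(config.n_snps)
    variants = pd.DataFrame({
        "id": [f"rs{j + 1:06d}" for j in range(config.n_snps)],
        "chrom": config.chrom,
        "pos": positions,
        "ref": refs,
        "alt": alts,
        "maf": mafs,
    })
    sample_ids = [f"S{i + 1:05d}" for i in range(config.n_samples)]
    return GenotypeMatrix(sample_ids, variants, dosages)


# ---------------------------------------------------------------------------
# Methylation and expression
# ---------------------------------------------------------------------------

def cpg_positions(config: SimConfig) -> pd.DataFrame:
    """Deterministic CpG placement: evenly spread across the SNP span, offset
    half a spacing so CpGs never coincide with SNPs."""
    span = config.n_snps * config.snp_spacing
    step = span / config.n_cpgs
    pos = (config.first_pos + (np.arange(config.n_cpgs) + 0.5) * step).astype(int)
    pos += config.snp_spacing // 2
    return pd.DataFrame({
        "id": [f"cpg{i + 1:05d}" for i in range(config.n_cpgs)],
        "chrom": config.chrom,
        "pos": pos,
    })


def gene_annotations(config: SimConfig) -> pd.DataFrame:
    """One gene per CpG: TSS 5 kb downstream of the CpG, 20 kb body, + strand,
    every fifth gene non-coding."""
    cpgs = cpg_positions(config)
    tss = cpgs["pos"].to_numpy() + 5_000
    return pd.DataFrame({
        "gene_id": [f"gene{i + 1:04d}" for i in range(config.n_cpgs)],
        "cpg_id": cpgs["id"],
        "chrom": config.chrom,
        "tss": tss,
        "tes": tss + 20_000,
        "strand": "+",
        "coding": [(i % 5) != 4 for i in range(config.n_cpgs)],
    })


def simulate_methylation_expression(
    G: GenotypeMatrix, config: SimConfig
) -> tuple[MolecularMatrix, MolecularMatrix, TruthTable]:
    """Plant cis-meQTL effects and methylation-mediated expression.

    Each CpG draws ``n_causal_per_cpg`` causal SNPs within 250 kb; its latent
    methylation is the causal combination rescaled to variance ``cis_h2``
    plus N(0, 1 - cis_h2) noise (so total latent variance is ~1). Beta values
    are ``expit(latent)``. Gene g is ``mediation_beta * latent_g + N(0,1)``.
    """
    if G.dosages.size == 0:
        raise ValueError("empty genotype matrix")
    rng = _stage_rng(config.seed, STAGE_MOLECULAR)
    cpgs = cpg_positions(config)
    genes = gene_annotations(config)
    n = G.n_samples

    snp_pos = G.variants["pos"].to_numpy()
    latent = np.empty((n, config.n_cpgs))
    cpg_effects: dict[str, list[tuple[str, float]]] = {}
    for i, (cpg_id, cpos) in enumerate(zip(cpgs["id"], cpgs["pos"])):
        cis = np.nonzero(np.abs(snp_pos - cpos) <= 250_000)[0]
        if config.cis_h2 > 0 and config.n_causal_per_cpg > 0:
            if len(cis) < config.n_causal_per_cpg:
                raise ValueError(
                    f"{cpg_id}: only {len(cis)} SNPs in cis window, "
                    f"need {config.n_causal_per_cpg}")
            causal = rng.choice(cis, size=config.n_causal_per_cpg, replace=False)
            raw_beta = rng.standard_normal(config.n_causal_per_cpg)
            X = G.dosages[:, causal]
            g = (X - X.mean(axis=0)) @ raw_beta
            sd = g.std()
            if sd < 1e-12:  # degenerate draw; treat as no genetic component
                g = np.zeros(n)
                scale = 0.0
            else:
                scale = np.sqrt(config.cis_h2) / sd
                g = g * scale
            latent[:, i] = g + rng.standard_normal(n) * np.sqrt(1.0 - config.cis_h2)
            cpg_effects[cpg_id] = [
                (G.variants["id"].iat[j], float(b * scale))
                for j, b in zip(causal, raw_beta)
            ]
        else:
            latent[:, i] = rng.standard_normal(n)
            cpg_effects[cpg_id] = []

    beta_values = expit(latent)
    meth = MolecularMatrix(list(cpgs["id"]), cpgs.copy(), beta_values,
                           "methylation-beta", list(G.sample_ids))

    noise = rng.standard_normal((n, config.n_cpgs))
    expr_values = config.mediation_beta * latent + noise
    gene_coords = genes.rename(columns={"gene_id": "id", "tss": "pos"})[
        ["id", "chrom", "pos"]]
    expr = MolecularMatrix(list(genes["gene_id"]), gene_coords, expr_values,
                           "expression", list(G.sample_ids))
    mediation = {g: (c, float(config.mediation_beta))
                 for g, c in zip(genes["gene_id"], genes["cpg_id"])}

    truth = TruthTable(
        cpg_effects=cpg_effects,
        mediation=mediation,
        liability_effects=dict(config.liability_effects),
        cpg_latent=pd.DataFrame(latent, columns=list(cpgs["id"])),
    )
    truth.validate_against(G, meth, expr)
    return meth, expr, truth


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------

def _logistic_scan(y: np.ndarray, X: np.ndarray, max_iter: int = 60,
                   tol: float = 1e-10) -> tuple[np.ndarray, np.ndarray]:
    """Per-column logistic regression y ~ intercept + x, vectorized Newton.

    Returns (beta, se) for the dosage coefficient of every column.
    """
    n, m = X.shape
    a = np.full(m, np.log(y.mean() / (1.0 - y.mean())))
    b = np.zeros(m)
    yc = y[:, None]
    for _ in range(max_iter):
        eta = a[None, :] + X * b[None, :]
        mu = expit(eta)
        w = mu * (1.0 - mu)
        r = yc - mu
        g0 = r.sum(axis=0)
        g1 = (X * r).sum(axis=0)
        h00 = w.sum(axis=0)
        h01 = (w * X).sum(axis=0)
        h11 = (w * X * X).sum(axis=0)
        det = h00 * h11 - h01 * h01
        det = np.where(np.abs(det) < 1e-300, 1e-300, det)
        da = (h11 * g0 - h01 * g1) / det
        db = (h00 * g1 - h01 * g0) / det
        step = np.clip(np.stack([da, db]), -5.0, 5.0)
        a += step[0]
        b += step[1]
        if np.max(np.abs(step)) < tol:
            break
    eta = a[None, :] + X * b[None, :]
    mu = expit(eta)
    w = mu * (1.0 - mu)
    h00 = w.sum(axis=0)
    h01 = (w * X).sum(axis=0)
    h11 = (w * X * X).sum(axis=0)
    det = h00 * h11 - h01 * h01
    se = np.sqrt(np.maximum(h00 / np.maximum(det, 1e-300), 1e-300))
    return b, se


def simulate_gwas(G: GenotypeMatrix, config: SimConfig,
                  truth: TruthTable | None = None) -> "pd.DataFrame":
    """Liability-threshold case-control GWAS on the simulated cohort.

    Liability = sum(liability_effects * CpG latent) + N(0,1); cases are the
    top ``prevalence`` fraction of the empirical liability distribution.
    Per-variant logistic regression of case status on dosage gives beta
    (log-OR for the alt/effect allele), SE and a two-sided Wald p.

    Returns a summary-statistics DataFrame with :data:`SUMSTATS_COLUMNS`.
    """
    if truth is None:
        _, _, truth = simulate_methylation_expression(G, config)
    rng = _stage_rng(config.seed, STAGE_GWAS)
    n = G.n_samples

    liability = rng.standard_normal(n)
    for cpg, eff in config.liability_effects.items():
        if cpg not in truth.cpg_latent.columns:
            raise ValueError(f"liability effect references unknown CpG {cpg}")
        liability = liability + eff * truth.cpg_latent[cpg].to_numpy()
    cutoff = np.quantile(liability, 1.0 - config.prevalence)
    y = (liability > cutoff).astype(float)
    n_cases = int(y.sum())
    n_controls = n - n_cases
    if n_cases == 0 or n_controls == 0:
        raise ValueError("degenerate phenotype: zero cases or zero controls")

    beta, se = _logistic_scan(y, G.dosages)
    z = beta / se
    p = 2.0 * norm.sf(np.abs(z))
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    out = G.variants[["id", "chrom", "pos", "ref", "alt"]].rename(
        columns={"id": "variant_id", "ref": "other_allele", "alt": "effect_allele"})
    out = out.assign(
        eaf=G.dosages.mean(axis=0) / 2.0,
        beta=beta,
        se=se,
        p=p,
        n_cases=n_cases,
        n_controls=n_controls,
    )
    return out[SUMSTATS_COLUMNS]


def simulate_covariates(G: GenotypeMatrix, config: SimConfig,
                        n_pcs: int = 10) -> pd.DataFrame:
    """Age, sex, two cell-type fractions and top genotype PCs, indexed by
    sample id. PCs come from an SVD of the centered dosage matrix."""
    rng = _stage_rng(config.seed, STAGE_COVARIATES)
    n = G.n_samples
    n_pcs = min(n_pcs, min(G.dosages.shape) - 1)
    age = rng.normal(60.0, 10.0, size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    cell = rng.dirichlet((5.0, 3.0, 2.0), size=n)
    Xc = G.dosages - G.dosages.mean(axis=0)
    u, s, _ = np.linalg.svd(Xc, full_matrices=False)
    pcs = u[:, :n_pcs] * s[:n_pcs]
    data = {"age": age, "sex": sex, "cell_frac1": cell[:, 0], "cell_frac2": cell[:, 1]}
    for k in range(n_pcs):
        data[f"PC{k + 1}"] = pcs[:, k]
    return pd.DataFrame(data, index=pd.Index(G.sample_ids, name="sample_id"))


# ---------------------------------------------------------------------------
# Fixture bundle I/O
# ---------------------------------------------------------------------------

def _write_vcf(G: GenotypeMatrix, path: Path) -> None:
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(G.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(G.sample_ids) + "\n")
        for j, row in enumerate(G.variants.itertuples(index=False)):
            gts = "\t".join(gt_map[int(d)] for d in G.dosages[:, j])
            fh.write(f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}"
                     f"\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path) -> GenotypeMatrix:
    """Read a GT-field VCF back into a :class:`GenotypeMatrix`."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, chroms, poss, refs, alts, rows = [], [], [], [], [], []
    for rec in vcf:
        ids.append(rec.ID)
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        g = np.array(rec.genotypes)[:, :2].sum(axis=1).astype(float)
        rows.append(g)
    dosages = np.column_stack(rows) if rows else np.zeros((len(samples), 0))
    variants = pd.DataFrame({
        "id": ids, "chrom": chroms, "pos": poss, "ref": refs, "alt": alts,
        "maf": np.minimum(dosages.mean(axis=0) / 2.0,
                          1.0 - dosages.mean(axis=0) / 2.0),
    })
    return GenotypeMatrix(samples, variants, dosages)


def _write_matrix(m: MolecularMatrix, path: Path) -> None:
    df = pd.DataFrame(m.values.T, index=pd.Index(m.feature_ids, name="feature_id"),
                      columns=m.sample_ids)
    df.to_csv(path, sep="\t", float_format="%.12g")


def read_matrix_tsv(path, coords: pd.DataFrame | None = None,
                    kind: str = "methylation-beta") -> MolecularMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    feats = list(df.index)
    if coords is None:
        coords = pd.DataFrame({"id": feats, "chrom": "NA", "pos": 0})
    return MolecularMatrix(feats, coords, df.to_numpy().T, kind, list(df.columns))


def _write_probe_bed(cpgs: pd.DataFrame, path: Path) -> None:
    # probe interval = CpG position +/- 24 bp (49-mer emulation), BED half-open
    with open(path, "w") as fh:
        for row in cpgs.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.pos - 25}\t{row.pos + 24}\t{row.id}\n")


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :4] if df.shape[1] >= 4 else df
    df.columns = ["chrom", "start", "end", "name"][: df.shape[1]]
    df["chrom"] = df["chrom"].astype(str)
    return df


def _write_gff3(genes: pd.DataFrame, path: Path) -> None:
    """Two-exon gene models; coding genes get UTRs flanking the CDS."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples(index=False):
            gid, start, end = row.gene_id, row.tss, row.tes
            fh.write(f"{row.chrom}\t.\tgene\t{start}\t{end}\t.\t{row.strand}\t.\t"
                     f"ID={gid};Name={gid}\n")
            ttype = "mRNA" if row.coding else "ncRNA"
            tid = f"{gid}.t1"
            fh.write(f"{row.chrom}\t.\t{ttype}\t{start}\t{end}\t.\t{row.strand}\t.\t"
                     f"ID={tid};Parent={gid}\n")
            third = (end - start) // 3
            exon1 = (start, start + third)
            exon2 = (end - third, end)
            for k, (s, e) in enumerate((exon1, exon2), 1):
                fh.write(f"{row.chrom}\t.\texon\t{s}\t{e}\t.\t{row.strand}\t.\t"
                         f"ID={tid}.e{k};Parent={tid}\n")
            if row.coding:
                utr5 = (start, start + 200)
                utr3 = (end - 200, end)
                fh.write(f"{row.chrom}\t.\tfive_prime_UTR\t{utr5[0]}\t{utr5[1]}\t.\t"
                         f"{row.strand}\t.\tID={tid}.u5;Parent={tid}\n")
                fh.write(f"{row.chrom}\t.\tthree_prime_UTR\t{utr3[0]}\t{utr3[1]}\t.\t"
                         f"{row.strand}\t.\tID={tid}.u3;Parent={tid}\n")


def _write_ld_blocks(G: GenotypeMatrix, config: SimConfig, path: Path) -> None:
    pos = G.variants["pos"].to_numpy()
    with open(path, "w") as fh:
        for b0 in range(0, config.n_snps, config.block_size):
            b1 = min(b0 + config.block_size, config.n_snps) - 1
            start = int(pos[b0]) - 1 - config.snp_spacing // 2
            end = int(pos[b1]) + config.snp_spacing // 2
            fh.write(f"{config.chrom}\t{max(start, 0)}\t{end}\t"
                     f"block{b0 // config.block_size + 1}\n")


def _write_truth(truth: TruthTable, path: Path) -> None:
    rows = []
    for cpg, pairs in truth.cpg_effects.items():
        for vid, beta in pairs:
            rows.append(("meqtl", cpg, vid, beta))
    for gene, (cpg, coef) in truth.mediation.items():
        rows.append(("mediation", gene, cpg, coef))
    for cpg, eff in truth.liability_effects.items():
        rows.append(("liability", cpg, "", eff))
    pd.DataFrame(rows, columns=["record_type", "feature_id", "partner_id", "effect"]
                 ).to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_truth_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False)


def read_gwas_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(SUMSTATS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"sumstats file missing columns: {sorted(missing)}")
    return df


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_fixture_bundle(config: SimConfig, out_dir) -> dict:
    """Simulate a full cohort and write it as plain-text files.

    Emits genotypes.vcf, methylation.tsv, expression.tsv, cpg_probes.bed,
    genes.gff3, sumstats.tsv, ld_blocks.bed and truth.tsv plus a
    manifest.json recording the seed and per-file checksums. All files
    round-trip through this module's readers.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create fixture directory {out}: {exc}") from exc

    G = simulate_genotypes(config)
    meth, expr, truth = simulate_methylation_expression(G, config)
    stats = simulate_gwas(G, config, truth)

    files = {
        "genotypes": out / "genotypes.vcf",
        "methylation": out / "methylation.tsv",
        "expression": out / "expression.tsv",
        "cpg_probes": out / "cpg_probes.bed",
        "genes": out / "genes.gff3",
        "sumstats": out / "sumstats.tsv",
        "ld_blocks": out / "ld_blocks.bed",
        "truth": out / "truth.tsv",
    }
    _write_vcf(G, files["genotypes"])
    _write_matrix(meth, files["methylation"])
    _write_matrix(expr, files["expression"])
    _write_probe_bed(cpg_positions(config), files["cpg_probes"])
    _write_gff3(gene_annotations(config), files["genes"])
    stats.to_csv(files["sumstats"], sep="\t", index=False, float_format="%.12g")
    _write_ld_blocks(G, config, files["ld_blocks"])
    _write_truth(truth, files["truth"])

    manifest = {
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(config).items()},
        "files": {k: {"path": p.name, "sha256": _sha256(p)}
                  for k, p in files.items()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
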