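"""Methylation-expression correlation and direction-consistency triangulation.

The three legs of the triangulation are:

* methylation -> risk: log-OR per SD of genetically predicted methylation
  (from the summary-statistic association scan);
* methylation -> expression: Pearson correlation of covariate-adjusted,
  rank-inverse-normalized methylation and expression in the reference
  cohort, for genes whose TSS lies within a pairing window of the CpG;
* expression -> risk: log-OR per SD of genetically predicted expression
  (same summary statistic applied to gene weight models).

A CpG-gene pair is direction-consistent when all three legs are significant
at their FDR thresholds and sign(b_m) = sign(r) * sign(b_e): e.g. higher
methylation raising risk while suppressing a protective gene's expression.

Normalization follows the reference-panel pipeline: quantile normalization
across samples, a per-feature rank-based inverse-normal transform with the
Blom offset, z = Phi^{-1}((rank - 3/8) / (n + 1/4)), then least-squares
residualization on covariates (age, sex, cell-type fractions, genotype PCs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .association import GwasSummaryStats, LdReference, association_test
from .simulate import MolecularMatrix
from .training import WeightModel

__all__ = [
    "CovariateTable",
    "TriangulationRecord",
    "inverse_normal_transform",
    "quantile_normalize",
    "adjust_and_normalize",
    "correlate_pairs",
    "expression_association",
    "triangulate",
]

logger = logging.getLogger(__name__)

TRIANGULATION_COLUMNS = ["cpg_id", "panel", "gene_id", "gene_panel", "or_m",
                         "q_m", "r", "q_r", "or_e", "q_e", "verdict"]


@dataclass
class CovariateTable:
    """Sample covariates: age, sex, cell-type fractions, genotype PCs."""

    table: pd.DataFrame  # indexed by sample id

    def __post_init__(self) -> None:
        if self.table.isna().any().any():
            raise ValueError("covariate table contains missing values")

    def aligned(self, sample_ids: list[str]) -> np.ndarray:
        missing = set(sample_ids) - set(self.table.index)
        if missing:
            raise ValueError(f"covariates missing for samples: {sorted(missing)[:5]}")
        return self.table.loc[sample_ids].to_numpy(dtype=float)


def inverse_normal_transform(x: np.ndarray) -> np.ndarray:
    """Rank-based INT with the Blom offset: Phi^{-1}((r - 3/8)/(n + 1/4))."""
    x = np.asarray(x, dtype=float)
    ranks = sps.rankdata(x, method="average")
    return sps.norm.ppf((ranks - 0.375) / (len(x) + 0.25))


def quantile_normalize(values: np.ndarray) -> np.ndarray:
    """Quantile normalization across samples (rows): every sample's feature
    profile is mapped onto the mean sorted profile."""
    n, m = values.shape
    reference = np.sort(values, axis=1).mean(axis=0)
    out = np.empty_like(values, dtype=float)
    grid = np.arange(1, m + 1)
    for i in range(n):
        ranks = sps.rankdata(values[i], method="average")
        out[i] = np.interp(ranks, grid, reference)
    return out


def _collinear_columns(design: np.ndarray, names: list[str]) -> list[str]:
    _, r = np.linalg.qr(design)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(design.shape) * np.finfo(float).eps
    return [names[j] for j in range(len(names)) if diag[j] <= tol]


def adjust_and_normalize(matrix: MolecularMatrix,
                         covariates: CovariateTable | None = None,
                         quantile: bool = True) -> MolecularMatrix:
    """Quantile-normalize, inverse-normal transform and residualize.

    Constant features cannot be rank-normalized and are excluded with a
    warning. The output is a ``normalized`` matrix whose features have
    |mean| < 1e-8 and zero correlation with every covariate column.
    """
    n = matrix.values.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples to normalize")

    keep = [j for j in range(matrix.values.shape[1])
            if matrix.values[:, j].std() > 1e-12]
    dropped = set(range(matrix.values.shape[1])) - set(keep)
    for j in sorted(dropped):
        logger.warning("constant feature %s excluded from normalization",
                       matrix.feature_ids[j])
    values = matrix.values[:, keep].astype(float)
    feature_ids = [matrix.feature_ids[j] for j in keep]
    coords = matrix.coords[matrix.coords["id"].isin(feature_ids)].reset_index(drop=True)

    if quantile and values.shape[1] > 1:
        values = quantile_normalize(values)
    values = np.column_stack([inverse_normal_transform(values[:, j])
                              for j in range(values.shape[1])])

    if covariates is not None:
        names = list(covariates.table.columns)
        C = covariates.aligned(matrix.sample_ids) if matrix.sample_ids is not None \
            else covariates.table.to_numpy(dtype=float)
        design = np.column_stack([np.ones(n), C])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            bad = _collinear_columns(design, ["intercept"] + names)
            raise ValueError(f"rank-deficient covariates; collinear: {bad}")
        coef, *_ = np.linalg.lstsq(design, values, rcond=None)
        values = values - design @ coef
    values = values - values.mean(axis=0)
    return MolecularMatrix(feature_ids, coords, values, "normalized",
                           matrix.sample_ids)


def correlate_pairs(meth_adj: MolecularMatrix, expr_adj: MolecularMatrix,
                    window: int = 500_000, method: str = "pearson",
                    alpha: float = 0.05) -> pd.DataFrame:
    """Correlate each CpG with genes whose TSS lies within ``window`` bp.

    Returns cpg_id, gene_id, r, p, q (BH across all pairs) plus a
    ``significant`` flag at q < alpha. CpGs with no gene in the window are
    reported with gene_id NA and no statistics.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    n = meth_adj.values.shape[0]
    if n < 10:
        raise ValueError("need >= 10 shared samples")
    if meth_adj.sample_ids != expr_adj.sample_ids:
        raise ValueError("methylation and expression samples are not aligned")

    gene_pos = expr_adj.coords.set_index("id")
    rows = []
    for j, cpg in enumerate(meth_adj.feature_ids):
        crow = meth_adj.coords.set_index("id").loc[cpg]
        near = gene_pos[(gene_pos["chrom"].astype(str) == str(crow["chrom"]))
                        & ((gene_pos["pos"] - int(crow["pos"])).abs() <= window)]
        if len(near) == 0:
            rows.append((cpg, None, np.nan, np.nan))
            continue
        x = meth_adj.values[:, j]
        for gene in near.index:
            y = expr_adj.feature_vector(gene)
            if method == "pearson":
                r, p = sps.pearsonr(x, y)
            else:
                r, p = sps.spearmanr(x, y)
            rows.append((cpg, gene, float(r), float(p)))
    out = pd.DataFrame(rows, columns=["cpg_id", "gene_id", "r", "p"])
    tested = out["p"].notna()
    out["q"] = np.nan
    if tested.any():
        _, q, _, _ = multipletests(out.loc[tested, "p"], alpha=alpha,
                                   method="fdr_bh")
        out.loc[tested, "q"] = q
    out["significant"] = out["q"] < alpha
    return out


def expression_association(gene_models: list[WeightModel],
                           stats: GwasSummaryStats, ld: LdReference,
                           alpha: float = 0.05,
                           policy: str = "drop_ambiguous") -> pd.DataFrame:
    """Predicted-expression association against the same GWAS statistics.

    The statistic is identical to the methylation association test applied
    to gene weight models; BH runs across the genes tested here.
    """
    records = [association_test(m, stats, ld, policy) for m in gene_models]
    testable = [r for r in records if r.testable]
    if testable:
        _, q, _, _ = multipletests([r.p for r in testable], alpha=alpha,
                                   method="fdr_bh")
        for r, qi in zip(testable, q):
            r.q = float(qi)
    rows = [(r.feature_id, r.panel, r.z, r.p, r.q, r.effect,
             r.or_per_sd if np.isfinite(r.effect) else np.nan,
             r.n_snps_used, r.reason) for r in records]
    return pd.DataFrame(rows, columns=["gene_id", "panel", "z", "p", "q",
                                       "effect", "or_per_sd", "n_snps_used",
                                       "reason"])


@dataclass
class TriangulationRecord:
    cpg_id: str
    gene_id: str
    panel: str
    gene_panel: str
    b_m: float  # log-OR methylation -> risk
    r: float  # methylation -> expression correlation
    b_e: float  # log-OR expression -> risk
    verdict: str  # consistent | inconsistent | incomplete

    @staticmethod
    def sign_consistent(b_m: float, r: float, b_e: float) -> bool:
        """The direction rule: methylation's risk direction must equal the
        product of its expression direction and the gene's risk direction."""
        return np.sign(b_m) == np.sign(r) * np.sign(b_e)


def triangulate(cpg_assoc: pd.DataFrame, correlations: pd.DataFrame,
                gene_assoc: pd.DataFrame, alpha: float = 0.05
                ) -> pd.DataFrame:
    """Issue a direction-consistency verdict per CpG-gene-panel combination.

    ``cpg_assoc`` needs feature_id, panel, effect, q; ``correlations`` needs
    cpg_id, gene_id, r, q; ``gene_assoc`` needs gene_id, panel, effect, q.
    Verdicts: *consistent* when all three legs are FDR-significant and the
    sign rule holds; *inconsistent* when all are significant but it fails;
    *incomplete* when any leg is missing or non-significant.
    """
    if cpg_assoc.duplicated(["feature_id", "panel"]).any():
        raise ValueError("duplicate (cpg, panel) association records")
    if gene_assoc.duplicated(["gene_id", "panel"]).any():
        raise ValueError("duplicate (gene, panel) association records")
    corr = correlations[correlations["gene_id"].notna()]
    if corr.duplicated(["cpg_id", "gene_id"]).any():
        raise ValueError("duplicate (cpg, gene) correlation records")

    rows = []
    for pair in corr.itertuples(index=False):
        m_legs = cpg_assoc[cpg_assoc["feature_id"] == pair.cpg_id]
        e_legs = gene_assoc[gene_assoc["gene_id"] == pair.gene_id]
        if len(m_legs) == 0 or len(e_legs) == 0:
            rows.append((pair.cpg_id, "", pair.gene_id, "", np.nan, np.nan,
                         pair.r, pair.q, np.nan, np.nan, "incomplete"))
            continue
        for m in m_legs.itertuples(index=False):
            for e in e_legs.itertuples(index=False):
                b_m, b_e = float(m.effect), float(e.effect)
                sig = (pd.notna(m.q) and m.q <= alpha
                       and pd.notna(pair.q) and pair.q < alpha
                       and pd.notna(e.q) and e.q <= alpha
                       and np.isfinite(b_m) and np.isfinite(b_e)
                       and np.isfinite(pair.r) and pair.r != 0.0)
                if not sig:
                    verdict = "incomplete"
                elif TriangulationRecord.sign_consistent(b_m, pair.r, b_e):
                    verdict = "consistent"
                else:
                    verdict = "inconsistent"
                rows.append((pair.cpg_id, m.panel, pair.gene_id, e.panel,
                             float(np.exp(b_m)), float(m.q), float(pair.r),
                             float(pair.q), float(np.exp(b_e)), float(e.q),
                             verdict))
    return pd.DataFrame(rows, columns=TRIANGULATION_COLUMNS)
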