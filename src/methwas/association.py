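"""Summary-statistic association of genetically predicted methylation with
disease risk.

The test statistic combines per-variant GWAS Z-scores with model weights and
an LD-reference estimate of the predicted level's variance:

    z = sum_l w_l (sigma_l / sigma_g) (beta_l / se_l)

where sigma_l is the dosage SD of variant l in the LD reference and
sigma_g^2 = w' Sigma w with Sigma the dosage covariance of the model's
variants. The accompanying effect size is a log-OR per SD of genetically
predicted methylation,

    effect = sum_l w_l (sigma_l^2 / sigma_g^2) beta_l,    OR = exp(effect).

A single-variant model reduces exactly to that variant's GWAS Z. Multiple
testing across all models of both panels is controlled jointly by
Benjamini-Hochberg, with the Bonferroni threshold alpha / m reported
alongside. Novelty of a significant CpG is judged by its distance to the
nearest known risk variant (> 500 kb, strict, = novel).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .simulate import GenotypeMatrix, SUMSTATS_COLUMNS
from .training import ModelRegistry, WeightModel

__all__ = [
    "GwasSummaryStats",
    "LdReference",
    "AssociationRecord",
    "ScanResult",
    "harmonize_variants",
    "predicted_variance",
    "association_test",
    "bh_adjust",
    "mwas_scan",
]

logger = logging.getLogger(__name__)

AMBIGUOUS_PAIRS = {frozenset("AT"), frozenset("CG")}
NOVEL_DISTANCE_BP = 500_000  # "more than 500 kb" -> strict >

ASSOC_COLUMNS = ["feature_id", "panel", "chrom", "pos", "n_snps_used", "z",
                 "p", "q", "effect", "or_per_sd", "sigma_g", "novelty",
                 "reason"]


class HarmonizationError(ValueError):
    pass


@dataclass
class GwasSummaryStats:
    """Per-variant GWAS summary statistics (beta = log-OR of effect allele)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(SUMSTATS_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"sumstats missing columns: {sorted(missing)}")
        t = self.table
        if t["variant_id"].duplicated().any():
            raise ValueError("duplicate variant ids in sumstats")
        if (t["se"] <= 0).any():
            raise ValueError("all standard errors must be positive")
        if ((t["p"] <= 0) | (t["p"] > 1)).any():
            raise ValueError("p-values must lie in (0, 1]")
        self._by_id = {v: i for i, v in enumerate(t["variant_id"])}
        self._by_pos = {(str(c), int(p)): i
                        for i, (c, p) in enumerate(zip(t["chrom"], t["pos"]))}

    def lookup(self, variant_id: str, chrom: str | None = None,
               pos: int | None = None):
        i = self._by_id.get(variant_id)
        if i is None and chrom is not None and pos is not None:
            i = self._by_pos.get((str(chrom), int(pos)))
        return None if i is None else self.table.iloc[i]


@dataclass
class LdReference:
    """Dosage panel used only for variant-variant covariance."""

    dosages: np.ndarray  # samples x variants, counted on the alt allele
    variant_ids: list[str]
    ridge_eps: float = 1e-6
    alleles: dict[str, tuple[str, str]] | None = None  # id -> (ref, alt)

    def __post_init__(self) -> None:
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    @classmethod
    def from_genotypes(cls, G: GenotypeMatrix, ridge_eps: float = 1e-6
                       ) -> "LdReference":
        alleles = {v: (r, a) for v, r, a in zip(G.variants["id"],
                                                G.variants["ref"],
                                                G.variants["alt"])}
        return cls(G.dosages.copy(), list(G.variants["id"]), ridge_eps,
                   alleles)

    def orientation(self, variant_ids, effect_alleles) -> np.ndarray:
        """+1 where the effect allele is the panel's alt (dosage-counted)
        allele, -1 where it is the ref; panels without allele metadata are
        assumed alt-oriented."""
        if self.alleles is None:
            return np.ones(len(variant_ids))
        signs = np.ones(len(variant_ids))
        for i, (vid, ea) in enumerate(zip(variant_ids, effect_alleles)):
            ref, alt = self.alleles.get(vid, (None, ea))
            if ea == ref:
                signs[i] = -1.0
        return signs

    def has(self, variant_id: str) -> bool:
        return variant_id in self._index

    def submatrix(self, variant_ids) -> np.ndarray:
        cols = [self._index[v] for v in variant_ids]
        return self.dosages[:, cols]

    def covariance(self, variant_ids) -> np.ndarray:
        X = self.submatrix(variant_ids)
        cov = np.atleast_2d(np.cov(X, rowvar=False, ddof=1))
        if np.linalg.eigvalsh(cov).min() < 0.0:
            cov = cov + self.ridge_eps * np.eye(cov.shape[0])
        return cov

    def sd(self, variant_ids) -> np.ndarray:
        return self.submatrix(variant_ids).std(axis=0, ddof=1)


@dataclass
class AssociationRecord:
    feature_id: str
    panel: str
    chrom: str = ""
    pos: int = 0
    z: float = np.nan
    p: float = np.nan
    q: float = np.nan
    effect: float = np.nan  # log-OR per SD of predicted level
    sigma_g: float = np.nan
    n_snps_used: int = 0
    novelty: str = "unassessed"
    reason: str = ""

    @property
    def or_per_sd(self) -> float:
        return float(np.exp(self.effect))

    @property
    def testable(self) -> bool:
        return self.reason == ""


def _is_ambiguous(a1: str, a2: str) -> bool:
    return frozenset((a1, a2)) in AMBIGUOUS_PAIRS


def harmonize_variants(model: WeightModel, stats: GwasSummaryStats,
                       policy: str = "drop_ambiguous") -> pd.DataFrame:
    """Align model entries with GWAS records on the effect allele.

    Matching is by variant id with a chrom+pos fallback. A GWAS record whose
    effect allele equals the model's keeps its beta; a swapped
    effect/other pair negates it; any other allele combination (or no match)
    drops the entry. Strand-ambiguous variants (A/T, C/G) are dropped under
    the default ``drop_ambiguous`` policy and kept verbatim under ``keep``.

    Returns a frame with columns variant_id, weight, beta, se and attrs
    counting the drops.
    """
    if policy not in ("drop_ambiguous", "keep"):
        raise ValueError(f"unknown harmonization policy {policy!r}")
    rows, n_unmatched, n_ambiguous, n_mismatch = [], 0, 0, 0
    for e in model.entries.itertuples(index=False):
        if policy == "drop_ambiguous" and _is_ambiguous(e.effect_allele,
                                                        e.other_allele):
            n_ambiguous += 1
            continue
        rec = stats.lookup(e.variant_id, model.chrom, getattr(e, "pos", None))
        if rec is None:
            n_unmatched += 1
            continue
        if rec["effect_allele"] == e.effect_allele and \
                rec["other_allele"] == e.other_allele:
            beta = float(rec["beta"])
        elif rec["effect_allele"] == e.other_allele and \
                rec["other_allele"] == e.effect_allele:
            beta = -float(rec["beta"])
        else:
            n_mismatch += 1
            continue
        rows.append((e.variant_id, e.effect_allele, float(e.weight), beta,
                     float(rec["se"])))
    out = pd.DataFrame(rows, columns=["variant_id", "effect_allele",
                                      "weight", "beta", "se"])
    out.attrs.update(n_unmatched=n_unmatched, n_ambiguous=n_ambiguous,
                     n_allele_mismatch=n_mismatch)
    return out


def predicted_variance(weights: np.ndarray, variant_ids, ld: LdReference
                       ) -> tuple[float, np.ndarray]:
    """Variance of the model's prediction under the LD reference.

    Returns (sigma_g^2, per-variant dosage SDs). sigma_g^2 = w' Sigma w is
    exactly the sample variance (ddof=1) of the prediction computed
    sample-wise on the panel.
    """
    cov = ld.covariance(variant_ids)
    sigma_l = ld.sd(variant_ids)
    sigma_g2 = float(weights @ cov @ weights)
    return sigma_g2, sigma_l


def association_test(model: WeightModel, stats: GwasSummaryStats,
                     ld: LdReference, policy: str = "drop_ambiguous"
                     ) -> AssociationRecord:
    """Summary-statistic association test for one weight model."""
    rec = AssociationRecord(model.cpg_id, model.panel_label, model.chrom,
                            model.pos)
    aligned = harmonize_variants(model, stats, policy)
    aligned = aligned[[ld.has(v) for v in aligned["variant_id"]]]
    if len(aligned) == 0:
        rec.reason = "no harmonizable variants"
        return rec
    # orient weights and betas onto the LD panel's dosage-counted allele
    signs = ld.orientation(list(aligned["variant_id"]),
                           list(aligned["effect_allele"]))
    w = aligned["weight"].to_numpy(dtype=float) * signs
    beta = aligned["beta"].to_numpy(dtype=float) * signs
    se = aligned["se"].to_numpy(dtype=float)
    if not (np.all(np.isfinite(w)) and np.all(np.isfinite(beta))
            and np.all(np.isfinite(se))):
        rec.reason = "non-finite inputs"
        return rec
    sigma_g2, sigma_l = predicted_variance(w, list(aligned["variant_id"]), ld)
    if sigma_g2 <= 1e-12:
        rec.reason = "variance collapse"
        return rec
    sigma_g = np.sqrt(sigma_g2)
    rec.z = float(np.sum(w * (sigma_l / sigma_g) * (beta / se)))
    rec.effect = float(np.sum(w * (sigma_l ** 2 / sigma_g2) * beta))
    rec.p = float(min(max(2.0 * norm.sf(abs(rec.z)), np.finfo(float).tiny), 1.0))
    rec.sigma_g = float(sigma_g)
    rec.n_snps_used = int(len(aligned))
    return rec


def bh_adjust(p_values, alpha: float = 0.05, m_total: int | None = None
              ) -> tuple[np.ndarray, np.ndarray, float]:
    """Benjamini-Hochberg q-values, q <= alpha flags, Bonferroni threshold.

    ``m_total`` overrides the family size used for the Bonferroni threshold
    (e.g. the total model count across both panels).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool), np.nan
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    flags = q <= alpha
    m = m_total if m_total is not None else p.size
    return q, flags, alpha / m


def _novelty(chrom: str, pos: int, known: pd.DataFrame | None) -> str:
    if known is None:
        return "unassessed"
    if len(known) == 0:
        return "novel"
    same = known[known["chrom"].astype(str) == str(chrom)]
    if len(same) == 0:
        return "novel"
    dmin = (same["pos"].astype(int) - int(pos)).abs().min()
    return "novel" if dmin > NOVEL_DISTANCE_BP else "known-locus"


def _load_known(known_variants: pd.DataFrame | None) -> pd.DataFrame | None:
    if known_variants is None:
        return None
    rows = []
    for r in known_variants.itertuples(index=False):
        try:
            rows.append((str(r.chrom), int(r.pos)))
        except (ValueError, TypeError, AttributeError):
            logger.warning("skipping malformed known-variant row: %r", tuple(r))
    return pd.DataFrame(rows, columns=["chrom", "pos"])


def _excluded(chrom: str, pos: int, bed: pd.DataFrame | None) -> bool:
    if bed is None or len(bed) == 0:
        return False
    hit = ((bed["chrom"].astype(str) == str(chrom))
           & (bed["start"] < pos) & (pos <= bed["end"]))
    return bool(hit.any())


@dataclass
class ScanResult:
    table: pd.DataFrame
    bonferroni_threshold: float
    m_tests: int
    concordance: float  # sign agreement among dual-panel significant CpGs
    n_dual_significant: int
    n_excluded: int = 0


def mwas_scan(registry: ModelRegistry, stats: GwasSummaryStats,
              ld: LdReference, known_variants: pd.DataFrame | None = None,
              exclusion_bed: pd.DataFrame | None = None,
              alpha: float = 0.05, policy: str = "drop_ambiguous"
              ) -> ScanResult:
    """Run the association test over every registry model.

    CpGs overlapping ``exclusion_bed`` (e.g. long-range LD regions) are
    removed before multiple testing; BH runs jointly across all remaining
    tests of both panels. Untestable models are reported with a reason,
    never silently dropped.
    """
    if len(registry) == 0:
        raise ValueError("empty model registry")
    known = _load_known(known_variants)
    records: list[AssociationRecord] = []
    n_excluded = 0
    for model in registry:
        if _excluded(model.chrom, model.pos, exclusion_bed):
            n_excluded += 1
            continue
        records.append(association_test(model, stats, ld, policy))

    testable = [r for r in records if r.testable]
    if testable:
        q, flags, bonf = bh_adjust([r.p for r in testable], alpha=alpha,
                                   m_total=len(testable))
        for r, qi in zip(testable, q):
            r.q = float(qi)
    else:
        bonf = np.nan
    for r in records:
        r.novelty = _novelty(r.chrom, r.pos, known) if r.testable else "unassessed"

    # cross-panel concordance among CpGs significant in both panels
    sig = {}
    for r in testable:
        if r.q <= alpha:
            sig.setdefault(r.feature_id, {})[r.panel] = r.z
    dual = [v for v in sig.values() if len(v) >= 2]
    if dual:
        agree = [len({np.sign(z) for z in v.values()}) == 1 for v in dual]
        concordance = float(np.mean(agree))
    else:
        concordance = np.nan

    rows = [(r.feature_id, r.panel, r.chrom, r.pos, r.n_snps_used, r.z, r.p,
             r.q, r.effect, r.or_per_sd if np.isfinite(r.effect) else np.nan,
             r.sigma_g, r.novelty, r.reason) for r in records]
    table = pd.DataFrame(rows, columns=ASSOC_COLUMNS)
    return ScanResult(table, bonf, len(testable), concordance, len(dual),
                      n_excluded)
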