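"""Functional annotation of CpG sites and category enrichment testing.

Each CpG is assigned exactly one of 13 functional categories from gene
models (exonic, intronic, intergenic, upstream, UTR3, UTR5, ncRNA_intronic,
ncRNA_exonic, splicing, downstream, upstream/downstream, UTR5/UTR3,
exonic/splicing), using a fixed precedence order when a position satisfies
several definitions at once. "Exonic" means a coding transcript's exon
outside its UTRs; "splicing" means within ``splice_margin`` bases of an
internal exon boundary on the intronic side of a coding transcript; the
composite labels fire when two transcripts or genes disagree (e.g. exonic in
one and splicing in another, or upstream of one gene while downstream of its
neighbour). Flanks default to 1 kb.

Enrichment of associated CpGs in a category is a two-proportion Pearson
chi-square (1 df, no continuity correction) of the associated set against
the full tested set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

__all__ = [
    "CATEGORIES",
    "Transcript",
    "GeneModel",
    "CategoryCall",
    "EnrichmentResult",
    "load_gene_models",
    "annotate_cpg",
    "annotate_table",
    "category_enrichment",
    "two_proportion_chi2",
]

logger = logging.getLogger(__name__)

# precedence high -> low; a CpG gets the first label whose definition it meets
CATEGORIES = (
    "exonic/splicing",
    "splicing",
    "exonic",
    "UTR5/UTR3",
    "UTR5",
    "UTR3",
    "ncRNA_exonic",
    "intronic",
    "ncRNA_intronic",
    "upstream/downstream",
    "upstream",
    "downstream",
    "intergenic",
)


@dataclass
class Transcript:
    transcript_id: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    coding: bool
    exons: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        self.exons = _merge_intervals(self.exons)

    def internal_boundaries(self) -> list[int]:
        """Exon edges adjacent to an intron (1-based exon coordinates)."""
        edges = []
        for i, (s, e) in enumerate(self.exons):
            if i > 0:
                edges.append(s)
            if i < len(self.exons) - 1:
                edges.append(e)
        return edges


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not ivs:
        return []
    ivs = sorted(ivs)
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(x) for x in merged]


@dataclass
class GeneModel:
    gene_id: str
    name: str
    chrom: str
    start: int
    end: int
    strand: str
    coding: bool
    transcripts: list[Transcript] = field(default_factory=list)

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tes(self) -> int:
        return self.end if self.strand == "+" else self.start


@dataclass
class CategoryCall:
    cpg_id: str
    category: str
    genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


_CODING_TYPES = {"mRNA"}
_TRANSCRIPT_TYPES = {"mRNA", "ncRNA", "transcript", "lnc_RNA", "miRNA",
                     "snoRNA", "snRNA", "rRNA", "tRNA"}


def load_gene_models(gff3_path) -> list[GeneModel]:
    """Parse GFF3 gene models (gene > transcript > exon/UTR) via gffutils."""
    import gffutils

    db = gffutils.create_db(str(gff3_path), ":memory:", force=True,
                            keep_order=True,
                            merge_strategy="create_unique")
    genes = []
    for g in db.features_of_type("gene"):
        transcripts = []
        for t in db.children(g, level=1):
            if t.featuretype not in _TRANSCRIPT_TYPES:
                continue
            coding = t.featuretype in _CODING_TYPES or any(
                True for _ in db.children(t, featuretype="CDS"))
            exons = [(c.start, c.end) for c in db.children(t, featuretype="exon")]
            utr5 = [(c.start, c.end)
                    for c in db.children(t, featuretype="five_prime_UTR")]
            utr3 = [(c.start, c.end)
                    for c in db.children(t, featuretype="three_prime_UTR")]
            transcripts.append(Transcript(t.id, t.start, t.end, t.strand,
                                          coding, exons, utr5, utr3))
        name = g.attributes.get("Name", [g.id])[0]
        genes.append(GeneModel(g.id, name, str(g.seqid), g.start, g.end,
                               g.strand, any(t.coding for t in transcripts),
                               transcripts))
    return genes


def _in_any(pos: int, ivs: list[tuple[int, int]]) -> bool:
    return any(s <= pos <= e for s, e in ivs)


def annotate_cpg(chrom: str, pos: int, genes: list[GeneModel],
                 flank: int = 1000, splice_margin: int = 2,
                 cpg_id: str = "") -> CategoryCall:
    """Assign one of the 13 functional categories to a CpG position."""
    flags: dict[str, set[str]] = {c: set() for c in CATEGORIES}
    candidates = [g for g in genes if str(g.chrom) == str(chrom)
                  and g.start - flank <= pos <= g.end + flank]

    for g in candidates:
        in_gene = g.start <= pos <= g.end
        if in_gene:
            for t in g.transcripts:
                if not (t.start <= pos <= t.end):
                    continue
                in_exon = _in_any(pos, t.exons)
                if t.coding:
                    if in_exon:
                        if _in_any(pos, t.utr5):
                            flags["UTR5"].add(g.name)
                        elif _in_any(pos, t.utr3):
                            flags["UTR3"].add(g.name)
                        else:
                            flags["exonic"].add(g.name)
                    else:
                        edges = t.internal_boundaries()
                        if edges and min(abs(pos - e) for e in edges) <= splice_margin:
                            flags["splicing"].add(g.name)
                        else:
                            flags["intronic"].add(g.name)
                else:
                    if in_exon:
                        flags["ncRNA_exonic"].add(g.name)
                    else:
                        flags["ncRNA_intronic"].add(g.name)
        else:
            # strand-aware 1 kb neighborhood
            if g.strand == "+":
                upstream = g.start - flank <= pos < g.start
                downstream = g.end < pos <= g.end + flank
            else:
                upstream = g.end < pos <= g.end + flank
                downstream = g.start - flank <= pos < g.start
            if upstream:
                flags["upstream"].add(g.name)
            if downstream:
                flags["downstream"].add(g.name)

    # composite labels
    if flags["exonic"] and flags["splicing"]:
        return CategoryCall(cpg_id, "exonic/splicing",
                            sorted(flags["exonic"] | flags["splicing"]))
    if flags["UTR5"] and flags["UTR3"]:
        return CategoryCall(cpg_id, "UTR5/UTR3",
                            sorted(flags["UTR5"] | flags["UTR3"]))
    if flags["upstream"] and flags["downstream"] and not any(
            flags[c] for c in ("exonic", "splicing", "UTR5", "UTR3",
                               "ncRNA_exonic", "intronic", "ncRNA_intronic")):
        return CategoryCall(cpg_id, "upstream/downstream",
                            sorted(flags["upstream"] | flags["downstream"]))
    for cat in ("splicing", "exonic", "UTR5", "UTR3", "ncRNA_exonic",
                "intronic", "ncRNA_intronic", "upstream", "downstream"):
        if flags[cat]:
            return CategoryCall(cpg_id, cat, sorted(flags[cat]))

    # intergenic: nearest gene(s) on the chromosome
    same = [g for g in genes if str(g.chrom) == str(chrom)]
    if same:
        dist = [(max(g.start - pos, 0, pos - g.end), g.name) for g in same]
        dmin = min(d for d, _ in dist)
        nearest = sorted({n for d, n in dist if d == dmin})
    else:
        nearest = []
    return CategoryCall(cpg_id, "intergenic", nearest)


def annotate_table(cpg_coords: pd.DataFrame, genes: list[GeneModel],
                   flank: int = 1000, splice_margin: int = 2) -> pd.DataFrame:
    """Annotate a CpG coordinate frame (id, chrom, pos, 1-based)."""
    rows = []
    for r in cpg_coords.itertuples(index=False):
        call = annotate_cpg(str(r.chrom), int(r.pos), genes, flank,
                            splice_margin, cpg_id=r.id)
        rows.append((call.cpg_id, call.category, ";".join(call.genes)))
    return pd.DataFrame(rows, columns=["cpg_id", "category", "gene"])


def two_proportion_chi2(count1: int, total1: int, count2: int, total2: int
                        ) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) for two
    proportions; equals the square of the pooled two-proportion z."""
    if min(total1, total2) <= 0:
        raise ValueError("group totals must be positive")
    p1, p2 = count1 / total1, count2 / total2
    pooled = (count1 + count2) / (total1 + total2)
    denom = pooled * (1.0 - pooled) * (1.0 / total1 + 1.0 / total2)
    if denom <= 0.0:
        raise ValueError("degenerate table: zero expected cell")
    chi2 = (p1 - p2) ** 2 / denom
    return float(chi2), float(chi2_dist.sf(chi2, df=1))


@dataclass
class EnrichmentResult:
    category: str
    count_assoc: int
    total_assoc: int
    count_all: int
    total_all: int
    chi2: float
    p: float
    note: str = ""

    @property
    def proportion_assoc(self) -> float:
        return self.count_assoc / self.total_assoc

    @property
    def proportion_all(self) -> float:
        return self.count_all / self.total_all


def category_enrichment(assoc_calls: pd.DataFrame, all_calls: pd.DataFrame,
                        mode: str = "vs_all") -> list[EnrichmentResult]:
    """Per-category enrichment of associated CpGs among all tested CpGs.

    ``mode='vs_all'`` compares the associated set against the full tested
    set (the associated ids must be a subset of the tested ids);
    ``'vs_complement'`` compares against the non-associated remainder.
    """
    if mode not in ("vs_all", "vs_complement"):
        raise ValueError(f"unknown mode {mode!r}")
    assoc_ids = set(assoc_calls["cpg_id"])
    if not assoc_ids <= set(all_calls["cpg_id"]):
        raise ValueError("associated CpGs must be a subset of tested CpGs")
    other = (all_calls[~all_calls["cpg_id"].isin(assoc_ids)]
             if mode == "vs_complement" else all_calls)
    n1, n2 = len(assoc_calls), len(other)
    results = []
    for cat in CATEGORIES:
        c1 = int((assoc_calls["category"] == cat).sum())
        c2 = int((other["category"] == cat).sum())
        try:
            chi2, p = two_proportion_chi2(c1, n1, c2, n2)
            note = ""
        except ValueError:
            chi2, p, note = np.nan, np.nan, "zero expected cell; skipped"
            logger.info("category %s skipped: zero expected cell", cat)
        results.append(EnrichmentResult(cat, c1, n1, c2, n2, chi2, p, note))
    return results
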