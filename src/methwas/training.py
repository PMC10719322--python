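"""Training and QC of cis DNA-methylation genetic prediction models.

Two panel styles are supported, mirroring the two families of published
blood methylation weight sets:

* **FHS-style** — elastic net (mixing 0.5) over all SNPs within a 2 Mb window
  flanking the CpG (|pos - cpg| <= 1,000,000, inclusive), weights on the raw
  dosage scale.
* **BIOS-style** — a marginal cis-meQTL pre-filter first (per SNP-CpG linear
  regression within 250 kb, strict inequality, pooled BH-FDR at 5%); only
  CpGs with at least one significant meQTL are modelled, then the same
  penalized fit is run with weights kept on the standardized-dosage scale
  (to be unstandardized later against reference allele-frequency SDs).

Model quality is the squared correlation between out-of-fold cross-validated
predictions and the observed (normalized) methylation; registry QC keeps
models with cv R^2 >= 0.01 and drops any model containing a SNP inside its
CpG's probe-binding interval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold, cross_val_predict
from statsmodels.stats.multitest import multipletests

from .simulate import GenotypeMatrix, MolecularMatrix

__all__ = [
    "TrainingConfig",
    "WeightModel",
    "ModelRejection",
    "ModelRegistry",
    "meqtl_prefilter",
    "train_cpg_model",
    "train_panel",
    "build_registry",
    "unstandardize_weights",
    "union_count",
    "write_weights_tsv",
    "read_weights_tsv",
]

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")

WEIGHTS_COLUMNS = ["panel", "cpg_id", "chrom", "cpg_pos", "variant_id",
                   "variant_pos", "other_allele", "effect_allele", "weight",
                   "standardized"]


@dataclass(frozen=True)
class TrainingConfig:
    """Panel-style training parameters.

    ``cis_window`` is the one-sided window in bp; FHS-style uses an inclusive
    boundary (a SNP exactly at the window edge is in), BIOS-style a strict
    one ("closer than" the window). ``restrict_to_significant`` optionally
    narrows the BIOS candidate set to SNPs from significant meQTL pairs
    instead of all cis SNPs of a gated CpG.
    """

    panel_label: str = "FHS-style"
    cis_window: int = 1_000_000
    alpha: float = 0.5  # elastic-net mixing (glmnet alpha / sklearn l1_ratio)
    n_folds: int = 5
    meqtl_fdr: float = 0.05
    min_r2: float = 0.01
    maf_min: float = 0.05
    seed: int = 0
    window_inclusive: bool = True
    standardized_weights: bool = False
    restrict_to_significant: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.cis_window <= 0:
            raise ValueError("cis_window must be positive")
        if self.min_r2 < 0:
            raise ValueError("min_r2 must be >= 0")

    @classmethod
    def fhs_style(cls, **kw) -> "TrainingConfig":
        kw.setdefault("panel_label", "FHS-style")
        kw.setdefault("cis_window", 1_000_000)
        kw.setdefault("window_inclusive", True)
        kw.setdefault("standardized_weights", False)
        return cls(**kw)

    @classmethod
    def bios_style(cls, **kw) -> "TrainingConfig":
        kw.setdefault("panel_label", "BIOS-style")
        kw.setdefault("cis_window", 250_000)
        kw.setdefault("window_inclusive", False)
        kw.setdefault("standardized_weights", True)
        return cls(**kw)


@dataclass
class WeightModel:
    """A per-CpG SNP-weight model: predicted methylation = sum(w * dosage)."""

    cpg_id: str
    chrom: str
    pos: int
    panel_label: str
    entries: pd.DataFrame  # variant_id, pos, other_allele, effect_allele, weight
    cv_r2: float
    standardized: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.entries) < 1:
            raise ValueError("a weight model needs at least one entry")
        w = self.entries["weight"].to_numpy(dtype=float)
        if not np.all(np.isfinite(w)) or np.all(w == 0.0):
            raise ValueError("weights must be finite with >= 1 nonzero entry")
        alleles = set(self.entries["other_allele"]) | set(self.entries["effect_allele"])
        if not alleles <= VALID_BASES:
            raise ValueError(f"invalid alleles in model {self.cpg_id}: {alleles}")
        if not (-1.0 <= self.cv_r2 <= 1.0):
            raise ValueError("cv_r2 must lie in [-1, 1]")

    @property
    def n_snps_model(self) -> int:
        return int((self.entries["weight"] != 0.0).sum())

    def predict(self, G: GenotypeMatrix) -> np.ndarray:
        """Predicted methylation on a dosage panel.

        Dosages are oriented onto each entry's effect allele: where the
        effect allele is the panel's ref, the column enters as 2 - dosage.
        """
        cols = G.column_index(self.entries["variant_id"])
        X = G.dosages[:, cols].copy()
        refs = G.variants["ref"].to_numpy()[cols]
        flip = self.entries["effect_allele"].to_numpy() == refs
        X[:, flip] = 2.0 - X[:, flip]
        if self.standardized:
            X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        return X @ self.entries["weight"].to_numpy(dtype=float)

    @property
    def key(self) -> tuple[str, str]:
        return (self.panel_label, self.cpg_id)


@dataclass(frozen=True)
class ModelRejection:
    cpg_id: str
    panel_label: str
    reason: str


def union_count(n_a: int, n_b: int, n_shared: int) -> int:
    """Unique features covered by two panels, by inclusion-exclusion."""
    if n_shared > min(n_a, n_b):
        raise ValueError("intersection cannot exceed either panel count")
    return n_a + n_b - n_shared


@dataclass
class ModelRegistry:
    """Merged two-panel model store with QC accounting."""

    models: dict[tuple[str, str], WeightModel] = field(default_factory=dict)
    counts: dict[str, dict[str, int]] = field(default_factory=dict)

    def add(self, model: WeightModel) -> None:
        if model.key in self.models:
            raise ValueError(f"duplicate model key {model.key}")
        self.models[model.key] = model

    def panel_cpgs(self, panel_label: str) -> set[str]:
        return {c for (p, c) in self.models if p == panel_label}

    @property
    def panels(self) -> list[str]:
        return sorted({p for (p, _) in self.models})

    def union_cpg_count(self) -> int:
        panels = self.panels
        if len(panels) == 1:
            return len(self.panel_cpgs(panels[0]))
        if len(panels) != 2:
            return len({c for (_, c) in self.models})
        a, b = (self.panel_cpgs(p) for p in panels)
        n = union_count(len(a), len(b), len(a & b))
        assert n == len(a | b)
        return n

    def __iter__(self):
        return iter(self.models.values())

    def __len__(self) -> int:
        return len(self.models)


# ---------------------------------------------------------------------------
# meQTL pre-filter (BIOS-style gate)
# ---------------------------------------------------------------------------

def meqtl_prefilter(G: GenotypeMatrix, meth: MolecularMatrix,
                    config: TrainingConfig) -> dict[str, list[str]]:
    """Gate CpGs on having >= 1 significant marginal cis-meQTL.

    Every SNP-CpG pair closer than ``cis_window`` (strict by default for the
    BIOS style) gets a simple linear-regression p-value; BH-FDR is applied
    across all tested pairs jointly. A CpG is retained iff at least one of
    its pairs passes ``meqtl_fdr``; its candidate set is then all of its cis
    variants (the gate acts at CpG level) unless
    ``restrict_to_significant`` is set.
    """
    n = meth.values.shape[0]
    snp_pos = G.variants["pos"].to_numpy()
    snp_chrom = G.variants["chrom"].to_numpy()
    Xs = G.dosages - G.dosages.mean(axis=0)
    x_ss = np.sqrt((Xs ** 2).sum(axis=0))

    pair_p, pair_cpg, pair_idx = [], [], []
    cis_sets: dict[str, list[str]] = {}
    for j, (cpg_id, crow) in enumerate(zip(meth.feature_ids,
                                           meth.coords.itertuples(index=False))):
        dist = np.abs(snp_pos - crow.pos)
        same = snp_chrom == crow.chrom
        mask = same & ((dist <= config.cis_window) if config.window_inclusive
                       else (dist < config.cis_window))
        cis = np.nonzero(mask)[0]
        if cis.size == 0:
            continue
        y = meth.values[:, j]
        ys = y - y.mean()
        y_ss = np.sqrt((ys ** 2).sum())
        if y_ss < 1e-12:
            logger.warning("meqtl_prefilter: constant CpG %s skipped", cpg_id)
            continue
        r = (Xs[:, cis].T @ ys) / (x_ss[cis] * y_ss)
        r = np.clip(r, -1.0, 1.0)
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, 1e-300))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
        pair_p.append(p)
        pair_cpg.extend([cpg_id] * cis.size)
        pair_idx.append(cis)
        cis_sets[cpg_id] = [G.variants["id"].iat[k] for k in cis]

    if not pair_p:
        return {}
    all_p = np.concatenate(pair_p)
    reject, _, _, _ = multipletests(all_p, alpha=config.meqtl_fdr,
                                    method="fdr_bh")
    all_idx = np.concatenate(pair_idx)
    retained: dict[str, list[str]] = {}
    for cpg_id in cis_sets:
        hits = reject[np.array(pair_cpg) == cpg_id]
        if hits.any():
            if config.restrict_to_significant:
                sig_idx = all_idx[(np.array(pair_cpg) == cpg_id) & reject]
                retained[cpg_id] = [G.variants["id"].iat[k] for k in sig_idx]
            else:
                retained[cpg_id] = cis_sets[cpg_id]
    return retained


# ---------------------------------------------------------------------------
# Elastic-net training
# ---------------------------------------------------------------------------

def _cis_candidates(G: GenotypeMatrix, chrom: str, pos: int,
                    config: TrainingConfig,
                    candidate_ids: Iterable[str] | None) -> np.ndarray:
    dist = np.abs(G.variants["pos"].to_numpy() - pos)
    same = G.variants["chrom"].to_numpy() == chrom
    mask = same & ((dist <= config.cis_window) if config.window_inclusive
                   else (dist < config.cis_window))
    maf = np.minimum(G.dosages.mean(axis=0) / 2.0,
                     1.0 - G.dosages.mean(axis=0) / 2.0)
    mask &= maf >= config.maf_min
    if candidate_ids is not None:
        allowed = set(candidate_ids)
        mask &= np.fromiter((v in allowed for v in G.variants["id"]),
                            dtype=bool, count=len(mask))
    return np.nonzero(mask)[0]


def train_cpg_model(G: GenotypeMatrix, meth: MolecularMatrix, cpg_id: str,
                    config: TrainingConfig,
                    candidate_ids: Iterable[str] | None = None
                    ) -> WeightModel | ModelRejection:
    """Fit one CpG's cis elastic-net model with cross-validated penalty.

    The penalty is chosen at the CV-minimum mean squared error; ``cv_r2`` is
    the squared correlation between out-of-fold predictions (same folds,
    chosen penalty) and the observed values. A fit whose weights are all
    zero is a rejection, not an exception.
    """
    crow = meth.coords.set_index("id").loc[cpg_id]
    chrom, pos = str(crow["chrom"]), int(crow["pos"])
    y = meth.feature_vector(cpg_id).astype(float)
    if y.std() < 1e-12:
        return ModelRejection(cpg_id, config.panel_label, "constant methylation")

    cis = _cis_candidates(G, chrom, pos, config, candidate_ids)
    if cis.size == 0:
        return ModelRejection(cpg_id, config.panel_label, "no cis variants")
    if cis.size < 2:
        return ModelRejection(cpg_id, config.panel_label,
                              "fewer than 2 cis variants after MAF filter")

    X = G.dosages[:, cis]
    sd = X.std(axis=0, ddof=1)
    Xz = (X - X.mean(axis=0)) / sd
    yc = y - y.mean()

    # penalty chosen on one fold split; out-of-fold performance measured on
    # an independent split so penalty selection cannot leak into cv_r2
    folds = KFold(n_splits=config.n_folds, shuffle=True,
                  random_state=config.seed)
    eval_folds = KFold(n_splits=config.n_folds, shuffle=True,
                       random_state=config.seed + 104_729)
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore", category=ConvergenceWarning)
        cv_fit = ElasticNetCV(l1_ratio=max(config.alpha, 1e-3), alphas=50,
                              cv=folds, fit_intercept=True, max_iter=5000)
        cv_fit.fit(Xz, yc)
        chosen = ElasticNet(alpha=cv_fit.alpha_, l1_ratio=max(config.alpha, 1e-3),
                            fit_intercept=True, max_iter=5000)
        oof = cross_val_predict(chosen, Xz, yc, cv=eval_folds)
        chosen.fit(Xz, yc)

    coefs = chosen.coef_
    nz = np.abs(coefs) > 1e-10  # coordinate-descent leaves ~1e-16 residue
    if not nz.any():
        return ModelRejection(cpg_id, config.panel_label, "all weights zero")
    if oof.std() < 1e-12:
        cv_r2 = 0.0
    else:
        cv_r2 = float(np.corrcoef(oof, yc)[0, 1] ** 2)

    weights = coefs[nz] if config.standardized_weights else coefs[nz] / sd[nz]
    idx = cis[nz]
    entries = pd.DataFrame({
        "variant_id": G.variants["id"].to_numpy()[idx],
        "pos": G.variants["pos"].to_numpy()[idx],
        "other_allele": G.variants["ref"].to_numpy()[idx],
        "effect_allele": G.variants["alt"].to_numpy()[idx],
        "weight": weights,
    })
    return WeightModel(cpg_id, chrom, pos, config.panel_label, entries,
                       cv_r2, standardized=config.standardized_weights,
                       meta={"penalty": float(cv_fit.alpha_),
                             "penalty_rule": "cv-min",
                             "n_folds": config.n_folds,
                             "seed": config.seed})


def train_panel(G: GenotypeMatrix, meth: MolecularMatrix,
                config: TrainingConfig
                ) -> tuple[list[WeightModel], list[ModelRejection]]:
    """Train a whole panel; BIOS-style panels apply the meQTL gate first."""
    if config.standardized_weights:
        gate = meqtl_prefilter(G, meth, config)
    else:
        gate = None
    models, rejections = [], []
    for cpg_id in meth.feature_ids:
        if gate is not None:
            if cpg_id not in gate:
                rejections.append(ModelRejection(cpg_id, config.panel_label,
                                                 "no significant cis-meQTL"))
                continue
            out = train_cpg_model(G, meth, cpg_id, config,
                                  candidate_ids=gate[cpg_id])
        else:
            out = train_cpg_model(G, meth, cpg_id, config)
        (models if isinstance(out, WeightModel) else rejections).append(out)
    return models, rejections


# ---------------------------------------------------------------------------
# Registry QC
# ---------------------------------------------------------------------------

def build_registry(models: Iterable[WeightModel],
                   probe_intervals: pd.DataFrame,
                   config: TrainingConfig | None = None,
                   min_r2: float = 0.01) -> ModelRegistry:
    """Apply performance and probe-SNP QC and assemble the registry.

    ``probe_intervals`` is BED-like (chrom, start, end, name) with 0-based
    half-open intervals named by CpG id. Models keep their place iff
    cv_r2 >= min_r2 (inclusive) and no weighted SNP falls inside the CpG's
    probe interval. A missing probe interval retains the model with a
    warning (exclusion needs positive evidence of a probe SNP).
    """
    if config is not None:
        min_r2 = config.min_r2
    probes = {str(r.name): (int(r.start), int(r.end))
              for r in probe_intervals.itertuples(index=False)}
    reg = ModelRegistry()
    tallies: dict[str, dict[str, int]] = {}
    for model in models:
        t = tallies.setdefault(model.panel_label,
                               {"trained": 0, "passing_r2": 0,
                                "passing_probe_filter": 0, "rejected": 0})
        t["trained"] += 1
        if model.cv_r2 < min_r2:
            t["rejected"] += 1
            continue
        t["passing_r2"] += 1
        iv = probes.get(model.cpg_id)
        if iv is None:
            logger.warning("no probe interval for %s; model retained",
                           model.cpg_id)
        else:
            start, end = iv
            # variant pos is 1-based; BED half-open [start, end)
            inside = ((model.entries["pos"] - 1 >= start)
                      & (model.entries["pos"] - 1 < end))
            if inside.any():
                t["rejected"] += 1
                continue
        t["passing_probe_filter"] += 1
        reg.add(model)
    for panel, t in tallies.items():
        assert t["trained"] == t["passing_probe_filter"] + t["rejected"]
    reg.counts = tallies
    return reg


def unstandardize_weights(model: WeightModel,
                          ref_sd: Mapping[str, float]) -> WeightModel | ModelRejection:
    """Convert standardized-dosage weights to raw-dosage weights.

    Each weight is divided by the variant's reference dosage standard
    deviation; variants with missing or non-positive SD are dropped with a
    warning. Predictions on raw dosages then equal the standardized model's
    predictions on standardized dosages up to an additive constant.
    """
    if not model.standardized:
        raise ValueError(f"model {model.cpg_id} is not standardized")
    keep_rows = []
    for row in model.entries.itertuples(index=False):
        sd = ref_sd.get(row.variant_id)
        if sd is None or not np.isfinite(sd) or sd <= 0.0:
            logger.warning("unstandardize: dropping %s (sd=%r)", row.variant_id, sd)
            continue
        keep_rows.append((row.variant_id, row.pos, row.other_allele,
                          row.effect_allele, row.weight / sd))
    if not keep_rows:
        return ModelRejection(model.cpg_id, model.panel_label,
                              "no variants with usable reference SD")
    entries = pd.DataFrame(keep_rows, columns=["variant_id", "pos",
                                               "other_allele", "effect_allele",
                                               "weight"])
    return WeightModel(model.cpg_id, model.chrom, model.pos, model.panel_label,
                       entries, model.cv_r2, standardized=False,
                       meta=dict(model.meta))


# ---------------------------------------------------------------------------
# Weight-table I/O
# ---------------------------------------------------------------------------

def write_weights_tsv(models: Iterable[WeightModel], path) -> None:
    rows = []
    for m in models:
        for e in m.entries.itertuples(index=False):
            rows.append((m.panel_label, m.cpg_id, m.chrom, m.pos, e.variant_id,
                         e.pos, e.other_allele, e.effect_allele, e.weight,
                         m.standardized))
    df = pd.DataFrame(rows, columns=WEIGHTS_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def write_model_summary_tsv(models: Iterable[WeightModel], path) -> None:
    rows = [(m.panel_label, m.cpg_id, m.n_snps_model, m.cv_r2) for m in models]
    pd.DataFrame(rows, columns=["panel", "cpg_id", "n_snps_model", "cv_r2"]
                 ).to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_weights_tsv(path, summaries: pd.DataFrame | None = None
                     ) -> list[WeightModel]:
    """Read a weight table back into models (cv_r2 from the optional
    model-summary frame, else 0)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    r2 = {}
    if summaries is not None:
        r2 = {(r.panel, r.cpg_id): float(r.cv_r2)
              for r in summaries.itertuples(index=False)}
    models = []
    for (panel, cpg), grp in df.groupby(["panel", "cpg_id"], sort=False):
        entries = grp.rename(columns={"variant_pos": "pos"})[
            ["variant_id", "pos", "other_allele", "effect_allele", "weight"]
        ].reset_index(drop=True)
        models.append(WeightModel(
            cpg_id=cpg, chrom=str(grp["chrom"].iat[0]),
            pos=int(grp["cpg_pos"].iat[0]), panel_label=panel,
            entries=entries, cv_r2=r2.get((panel, cpg), 0.0),
            standardized=bool(grp["standardized"].iat[0])))
    return models
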