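"""Bayesian fine-mapping of associated CpG sites within LD blocks.

Within each approximately independent LD block, the vector of association
Z-scores of the member CpGs is modelled as multivariate normal. For a causal
configuration c (a subset of members, |c| <= max_causal, plus the null
configuration),

    z | c  ~  N(0, Omega + v * Omega diag(c) Omega)

where Omega is the correlation matrix of the model-predicted methylation
levels across the LD reference panel and v is the prior effect-variance
scale of a causal signal. With an independent per-site causal prior p,

    prior(c) = p^{|c|} (1 - p)^{k - |c|},

posteriors are normalized over the enumerated configurations (the null
always participates, so credible sets can be empty under no signal). The
posterior inclusion probability of site i is the posterior mass of all
configurations containing i, and the rho-credible set is the smallest
PIP-ranked prefix whose normalized PIP mass reaches rho.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.special import logsumexp

from .association import LdReference
from .training import WeightModel

__all__ = [
    "FineMapConfig",
    "LdBlock",
    "CredibleSet",
    "build_blocks",
    "config_posteriors",
    "credible_set",
    "finemap_blocks",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FineMapConfig:
    prior_p: float = 1e-3  # per-site causal prior
    prior_var: float = 40.0  # effect-variance scale v
    max_causal: int = 3
    rho: float = 0.90  # credible level
    ridge_eps: float = 1e-6

    def __post_init__(self) -> None:
        if not (0.0 < self.prior_p < 1.0):
            raise ValueError("prior_p must be in (0, 1)")
        if not (0.0 < self.rho <= 1.0):
            raise ValueError("rho must be in (0, 1]")
        if self.max_causal < 1:
            raise ValueError("max_causal must be >= 1")


@dataclass
class LdBlock:
    """One LD block's members (per-panel association records) and their
    predicted-methylation correlation matrix."""

    block_id: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    member_ids: list[str]  # "panel:cpg" record keys, sorted by position
    positions: np.ndarray
    z: np.ndarray
    omega: np.ndarray

    def __post_init__(self) -> None:
        if not np.allclose(self.omega, self.omega.T, atol=1e-10):
            raise ValueError("omega must be symmetric")
        if not np.allclose(np.diag(self.omega), 1.0, atol=1e-8):
            raise ValueError("omega must have unit diagonal")

    @property
    def k(self) -> int:
        return len(self.member_ids)


@dataclass
class CredibleSet:
    block_id: str
    member_ids: list[str]
    pip: np.ndarray
    credible_members: list[str]
    null_posterior: float
    null_in_credible: bool
    configurations: list[tuple[int, ...]] = field(repr=False, default_factory=list)
    posteriors: np.ndarray = field(repr=False, default=None)


def _predicted_correlation(models: list[WeightModel], ld: LdReference
                           ) -> np.ndarray:
    preds = []
    for m in models:
        ids = list(m.entries["variant_id"])
        # orient onto the panel's counted allele (sign flip only; the
        # 2 - dosage offset does not affect correlations)
        signs = ld.orientation(ids, list(m.entries["effect_allele"]))
        w = m.entries["weight"].to_numpy(dtype=float) * signs
        X = ld.submatrix(ids)
        if m.standardized:
            X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        preds.append(X @ w)
    P = np.column_stack(preds)
    omega = np.corrcoef(P, rowvar=False)
    return np.atleast_2d(omega)


def build_blocks(assoc: pd.DataFrame, models: dict[tuple[str, str], WeightModel],
                 ld: LdReference, block_bed: pd.DataFrame) -> list[LdBlock]:
    """Assign significant association records to LD blocks and compute Omega.

    ``assoc`` needs feature_id, panel, chrom, pos, z rows (already filtered
    to the records worth fine-mapping). Block intervals are 0-based
    half-open: a CpG belongs to the block with start <= pos0 < end. A CpG in
    no block gets a singleton pseudo-block with a warning. Each (panel, CpG)
    record is fine-mapped as its own member, so a CpG modelled by both
    panels contributes two members.
    """
    blocks: dict[str, dict] = {}
    for r in assoc.itertuples(index=False):
        pos0 = int(r.pos) - 1
        hit = block_bed[(block_bed["chrom"].astype(str) == str(r.chrom))
                        & (block_bed["start"] <= pos0)
                        & (pos0 < block_bed["end"])]
        if len(hit) == 0:
            bid = f"singleton:{r.panel}:{r.feature_id}"
            logger.warning("CpG %s (%s) in no LD block; singleton pseudo-block",
                           r.feature_id, r.panel)
            chrom, start, end = str(r.chrom), pos0, pos0 + 1
        else:
            b = hit.iloc[0]
            bid = str(b.get("name", f"{b['chrom']}:{b['start']}-{b['end']}"))
            chrom, start, end = str(b["chrom"]), int(b["start"]), int(b["end"])
        entry = blocks.setdefault(bid, {"chrom": chrom, "start": start,
                                        "end": end, "members": []})
        entry["members"].append((f"{r.panel}:{r.feature_id}", int(r.pos),
                                 float(r.z), models[(r.panel, r.feature_id)]))

    out = []
    for bid, entry in blocks.items():
        members = sorted(entry["members"], key=lambda m: (m[1], m[0]))
        ids = [m[0] for m in members]
        pos = np.array([m[1] for m in members])
        z = np.array([m[2] for m in members])
        omega = _predicted_correlation([m[3] for m in members], ld)
        out.append(LdBlock(bid, entry["chrom"], entry["start"], entry["end"],
                           ids, pos, z, omega))
    return out


def _mvn_logpdf(z: np.ndarray, cov: np.ndarray) -> float:
    k = len(z)
    c, low = cho_factor(cov, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    quad = z @ cho_solve((c, low), z)
    return -0.5 * (k * np.log(2.0 * np.pi) + logdet + quad)


def config_posteriors(z: np.ndarray, omega: np.ndarray,
                      config: FineMapConfig
                      ) -> tuple[list[tuple[int, ...]], np.ndarray]:
    """Posterior over causal configurations up to ``max_causal`` sites.

    Returns the enumerated configurations (index tuples; () is the null) and
    their normalized posterior probabilities.
    """
    z = np.asarray(z, dtype=float)
    omega = np.atleast_2d(np.asarray(omega, dtype=float))
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite z-scores")
    k = len(z)
    if np.linalg.eigvalsh(omega).min() < 1e-8:
        omega = omega + config.ridge_eps * np.eye(k)

    log_p, log_1mp = np.log(config.prior_p), np.log1p(-config.prior_p)
    configs: list[tuple[int, ...]] = []
    log_post: list[float] = []
    for size in range(min(config.max_causal, k) + 1):
        for c in combinations(range(k), size):
            cov = omega.copy()
            if c:
                idx = np.array(c)
                cov = cov + config.prior_var * (omega[:, idx] @ omega[idx, :])
            try:
                ll = _mvn_logpdf(z, cov)
            except np.linalg.LinAlgError:
                try:
                    ll = _mvn_logpdf(z, cov + config.ridge_eps * np.eye(k))
                except np.linalg.LinAlgError as exc:
                    raise np.linalg.LinAlgError(
                        f"non-PSD covariance for configuration {c}") from exc
            configs.append(c)
            log_post.append(ll + size * log_p + (k - size) * log_1mp)

    log_post = np.array(log_post)
    post = np.exp(log_post - logsumexp(log_post))
    return configs, post / post.sum()


def credible_set(configs: list[tuple[int, ...]], posteriors: np.ndarray,
                 member_ids: list[str], positions: np.ndarray,
                 config: FineMapConfig, block_id: str = "") -> CredibleSet:
    """PIPs and the rho-level credible set from configuration posteriors.

    Sites are ranked by PIP descending (ties by genomic position ascending);
    the credible set is the smallest prefix whose normalized PIP mass
    (PIP_i / sum PIP) reaches rho.
    """
    k = len(member_ids)
    pip = np.zeros(k)
    null_post = 0.0
    for c, post in zip(configs, posteriors):
        if not c:
            null_post += float(post)
        for i in c:
            pip[i] += post

    total = pip.sum()
    if total <= 0.0:
        return CredibleSet(block_id, list(member_ids), pip, [],
                           float(null_post), True, configs, posteriors)
    order = sorted(range(k), key=lambda i: (-pip[i], positions[i]))
    cum, members = 0.0, []
    for i in order:
        if pip[i] <= 0.0:
            break
        members.append(member_ids[i])
        cum += pip[i] / total
        if cum >= config.rho - 1e-12:
            break
    null_in = null_post >= (1.0 - config.rho)
    return CredibleSet(block_id, list(member_ids), pip, members,
                       float(null_post), null_in, configs, posteriors)


def finemap_blocks(blocks: list[LdBlock], config: FineMapConfig
                   ) -> tuple[pd.DataFrame, list[CredibleSet]]:
    """Fine-map every block; returns a long table and the credible sets."""
    rows, sets = [], []
    for block in blocks:
        try:
            configs, post = config_posteriors(block.z, block.omega, config)
        except np.linalg.LinAlgError as exc:
            logger.warning("block %s skipped: %s", block.block_id, exc)
            continue
        cs = credible_set(configs, post, block.member_ids, block.positions,
                          config, block.block_id)
        sets.append(cs)
        for i, mid in enumerate(block.member_ids):
            panel, _, cpg = mid.partition(":")
            rows.append((block.block_id, cpg, panel, float(block.z[i]),
                         float(cs.pip[i]), mid in cs.credible_members,
                         cs.null_in_credible))
    table = pd.DataFrame(rows, columns=["block_id", "cpg_id", "panel", "z",
                                        "pip", "in_credible_set",
                                        "null_in_credible_set"])
    return table, sets
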