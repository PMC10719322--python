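import numpy as np
import pandas as pd
import pytest

import methwas as mw


@pytest.fixture(scope="session")
def cohort():
    """A small simulated cohort with two liability CpGs, shared across tests."""
    cfg = mw.SimConfig(
        n_samples=600, n_snps=120, n_cpgs=12, ld_rho=0.5, cis_h2=0.4,
        n_causal_per_cpg=2, prevalence=0.15,
        liability_effects={"cpg00001": 0.6, "cpg00005": -0.6}, seed=3,
    )
    G = mw.simulate_genotypes(cfg)
    meth, expr, truth = mw.simulate_methylation_expression(G, cfg)
    stats_df = mw.simulate_gwas(G, cfg, truth)
    return {
        "cfg": cfg, "G": G, "meth": meth, "expr": expr, "truth": truth,
        "stats": mw.GwasSummaryStats(stats_df),
        "ld": mw.LdReference.from_genotypes(G),
    }


def truth_weight_models(G, meth, truth, panel="truth"):
    """Weight models whose entries are the generative causal effects."""
    vinfo = G.variants.set_index("id")
    coords = meth.coords.set_index("id")
    models = []
    for cpg, pairs in truth.cpg_effects.items():
        if not pairs:
            continue
        entries = pd.DataFrame({
            "variant_id": [v for v, _ in pairs],
            "pos": [int(vinfo.loc[v, "pos"]) for v, _ in pairs],
            "other_allele": [vinfo.loc[v, "ref"] for v, _ in pairs],
            "effect_allele": [vinfo.loc[v, "alt"] for v, _ in pairs],
            "weight": [b for _, b in pairs],
        })
        models.append(mw.WeightModel(cpg, str(coords.loc[cpg, "chrom"]),
                                     int(coords.loc[cpg, "pos"]), panel,
                                     entries, 0.5))
    return models


def single_variant_model(cpg_id, chrom, cpg_pos, variant_id, variant_pos,
                         other, effect, weight=1.0, panel="toy", cv_r2=0.5):
    entries = pd.DataFrame({
        "variant_id": [variant_id], "pos": [variant_pos],
        "other_allele": [other], "effect_allele": [effect],
        "weight": [weight],
    })
    return mw.WeightModel(cpg_id, chrom, cpg_pos, panel, entries, cv_r2)


def toy_sumstats(rows):
    """rows: (variant_id, chrom, pos, effect, other, eaf, beta, se)."""
    df = pd.DataFrame(rows, columns=["variant_id", "chrom", "pos",
                                     "effect_allele", "other_allele", "eaf",
                                     "beta", "se"])
    from scipy.stats import norm
    df["p"] = np.clip(2 * norm.sf(np.abs(df["beta"] / df["se"])),
                      np.finfo(float).tiny, 1.0)
    df["n_cases"] = 1000
    df["n_controls"] = 9000
    return mw.GwasSummaryStats(df[["variant_id", "chrom", "pos",
                                   "effect_allele", "other_allele", "eaf",
                                   "beta", "se", "p", "n_cases",
                                   "n_controls"]])


def continuous_ld_reference(columns: dict[str, np.ndarray]) -> mw.LdReference:
    ids = list(columns)
    X = np.column_stack([columns[v] for v in ids])
    return mw.LdReference(X, ids)
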