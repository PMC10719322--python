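"""Elastic-net model training, meQTL gating and registry QC."""

import numpy as np
import pandas as pd
import pytest

import methwas as mw


def _matrix(values, ids, positions, chrom="1", kind="normalized"):
    coords = pd.DataFrame({"id": ids, "chrom": chrom, "pos": positions})
    values = values - values.mean(axis=0)
    return mw.MolecularMatrix(list(ids), coords, values, kind)


def _genotypes(dosages, positions, chrom="1"):
    n_var = dosages.shape[1]
    variants = pd.DataFrame({
        "id": [f"v{j}" for j in range(n_var)], "chrom": chrom,
        "pos": positions, "ref": "A", "alt": "C",
        "maf": np.minimum(dosages.mean(0) / 2, 1 - dosages.mean(0) / 2),
    })
    return mw.GenotypeMatrix([f"s{i}" for i in range(dosages.shape[0])],
                             variants, dosages.astype(float))


class TestMeqtlPrefilter:
    def test_window_boundary_strict(self):
        """A pair exactly at the window edge is not tested under the strict
        (BIOS-style) convention; one 2 bp closer is."""
        rng = np.random.default_rng(0)
        n = 400
        d = rng.binomial(2, 0.3, size=(n, 2)).astype(float)
        G = _genotypes(d, positions=[50_000, 550_001])  # CpG at 300,000
        cfg = mw.TrainingConfig.bios_style(seed=0)

        # CpG driven by the far SNP (distance exactly 250,001 -> untested)
        far = _matrix(d[:, [1]] + 0.01 * rng.standard_normal((n, 1)),
                      ["cpgF"], [300_000])
        assert mw.meqtl_prefilter(G, far, cfg) == {}

        # CpG driven by the near SNP (distance 250,000 under strict < fails;
        # move CpG so distance is 249,999)
        near = _matrix(d[:, [0]] + 0.01 * rng.standard_normal((n, 1)),
                       ["cpgN"], [299_999])
        got = mw.meqtl_prefilter(G, near, cfg)
        assert "cpgN" in got
        assert got["cpgN"] == ["v0"]  # only v0 is in the strict cis window

    def test_single_signal_gates_one_cpg(self):
        rng = np.random.default_rng(1)
        n = 300
        d = rng.binomial(2, 0.3, size=(n, 3)).astype(float)
        G = _genotypes(d, positions=[10_000, 20_000, 30_000])
        vals = rng.standard_normal((n, 2))
        vals[:, 0] = d[:, 0] + 0.05 * rng.standard_normal(n)  # strong meQTL
        meth = _matrix(vals, ["cpgA", "cpgB"], [15_000, 25_000])
        got = mw.meqtl_prefilter(G, meth, mw.TrainingConfig.bios_style(seed=0))
        assert set(got) == {"cpgA"}
        assert set(got["cpgA"]) == {"v0", "v1", "v2"}  # all cis variants

    def test_constant_cpg_skipped(self):
        rng = np.random.default_rng(2)
        d = rng.binomial(2, 0.3, size=(100, 2)).astype(float)
        G = _genotypes(d, positions=[10_000, 20_000])
        coords = pd.DataFrame({"id": ["cpgC"], "chrom": "1", "pos": [15_000]})
        meth = mw.MolecularMatrix(["cpgC"], coords, np.zeros((100, 1)),
                                  "expression")
        assert mw.meqtl_prefilter(G, meth,
                                  mw.TrainingConfig.bios_style(seed=0)) == {}


class TestTrainCpgModel:
    def test_planted_causal_snp_recovered(self):
        cfg = mw.SimConfig(n_samples=500, n_snps=40, n_cpgs=3, cis_h2=0.5,
                           n_causal_per_cpg=1, seed=1)
        G = mw.simulate_genotypes(cfg)
        meth, _, truth = mw.simulate_methylation_expression(G, cfg)
        # INT only: cross-sample quantile normalization needs a genome-wide
        # feature panel, not 3 CpGs
        meth_n = mw.adjust_and_normalize(meth, quantile=False)
        tcfg = mw.TrainingConfig.fhs_style(seed=1)
        model = mw.train_cpg_model(G, meth_n, "cpg00001", tcfg)
        assert isinstance(model, mw.WeightModel)
        (vid, _), = truth.cpg_effects["cpg00001"]
        assert vid in set(model.entries["variant_id"])
        assert 0.35 <= model.cv_r2 <= 0.6

    def test_noise_cpg_rarely_passes(self):
        """A heritability-free CpG is rejected or scores cv R^2 < 0.01 in
        >= 95 of 100 replicates."""
        ok = 0
        for rep in range(100):
            cfg = mw.SimConfig(n_samples=500, n_snps=20, n_cpgs=1,
                               cis_h2=0.0, seed=5000 + rep)
            G = mw.simulate_genotypes(cfg)
            meth, _, _ = mw.simulate_methylation_expression(G, cfg)
            meth_n = mw.adjust_and_normalize(meth)
            out = mw.train_cpg_model(G, meth_n, "cpg00001",
                                     mw.TrainingConfig.fhs_style(seed=rep))
            if isinstance(out, mw.ModelRejection) or out.cv_r2 < 0.01:
                ok += 1
        assert ok >= 95

    def test_lasso_drops_collinear_duplicate(self):
        rng = np.random.default_rng(3)
        n = 300
        x = rng.binomial(2, 0.4, size=n).astype(float)
        other = rng.binomial(2, 0.4, size=(n, 1)).astype(float)
        d = np.column_stack([x, x, other])  # two perfectly collinear SNPs
        G = _genotypes(d, positions=[10_000, 11_000, 12_000])
        y = x + 0.5 * rng.standard_normal(n)
        meth = _matrix(y[:, None], ["cpgL"], [10_500])
        cfg = mw.TrainingConfig(panel_label="lasso", alpha=1.0,
                                cis_window=5_000, maf_min=0.01, seed=0)
        model = mw.train_cpg_model(G, meth, "cpgL", cfg)
        assert isinstance(model, mw.WeightModel)
        dup = model.entries[model.entries["variant_id"].isin(["v0", "v1"])]
        assert (dup["weight"] != 0).sum() <= 1

    def test_constant_cpg_rejected_not_raised(self, cohort):
        G = cohort["G"]
        coords = pd.DataFrame({"id": ["flat"], "chrom": "1", "pos": [30_000]})
        meth = mw.MolecularMatrix(["flat"], coords,
                                  np.ones((G.n_samples, 1)), "expression")
        out = mw.train_cpg_model(G, meth, "flat",
                                 mw.TrainingConfig.fhs_style(seed=0))
        assert isinstance(out, mw.ModelRejection)
        assert "constant" in out.reason

    def test_window_edge_inclusive_fhs(self):
        """A variant exactly cis_window away is a candidate under the
        inclusive (FHS-style) convention."""
        rng = np.random.default_rng(4)
        n = 400
        x = rng.binomial(2, 0.4, size=(n, 2)).astype(float)
        G = _genotypes(x, positions=[10_000, 12_000])
        y = x[:, 1] + 0.3 * rng.standard_normal(n)
        meth = _matrix(y[:, None], ["cpgE"], [11_000])  # v1 at exactly 1000
        cfg = mw.TrainingConfig(panel_label="edge", cis_window=1000,
                                window_inclusive=True, maf_min=0.01, seed=0)
        model = mw.train_cpg_model(G, meth, "cpgE", cfg)
        assert isinstance(model, mw.WeightModel)
        assert "v1" in set(model.entries["variant_id"])

    def test_training_determinism(self, cohort):
        meth_n = mw.adjust_and_normalize(cohort["meth"])
        cfg = mw.TrainingConfig.fhs_style(seed=9)
        m1 = mw.train_cpg_model(cohort["G"], meth_n, "cpg00003", cfg)
        m2 = mw.train_cpg_model(cohort["G"], meth_n, "cpg00003", cfg)
        pd.testing.assert_frame_equal(m1.entries, m2.entries)
        assert m1.cv_r2 == m2.cv_r2

    def test_cv_honesty_under_permutation(self, cohort):
        """Permuting the CpG's sample labels must kill out-of-fold R^2."""
        G = cohort["G"]
        meth_n = mw.adjust_and_normalize(cohort["meth"])
        j = meth_n.feature_ids.index("cpg00002")
        rng = np.random.default_rng(17)
        r2s = []
        for rep in range(50):
            vals = meth_n.values.copy()
            vals[:, j] = rng.permutation(vals[:, j])
            shuffled = mw.MolecularMatrix(meth_n.feature_ids, meth_n.coords,
                                          vals - vals.mean(0), "normalized")
            out = mw.train_cpg_model(G, shuffled, "cpg00002",
                                     mw.TrainingConfig.fhs_style(seed=rep))
            r2s.append(0.0 if isinstance(out, mw.ModelRejection) else out.cv_r2)
        assert np.median(r2s) < 0.01


class TestRegistry:
    def _model(self, cpg, r2, panel="FHS-style", pos=5000, vpos=4000):
        entries = pd.DataFrame({"variant_id": [f"v_{cpg}"], "pos": [vpos],
                                "other_allele": ["A"],
                                "effect_allele": ["G"], "weight": [1.0]})
        return mw.WeightModel(cpg, "1", pos, panel, entries, r2)

    def test_r2_threshold_inclusive(self):
        models = [self._model("c1", 0.005), self._model("c2", 0.01),
                  self._model("c3", 0.02)]
        probes = pd.DataFrame(columns=["chrom", "start", "end", "name"])
        reg = mw.build_registry(models, probes, min_r2=0.01)
        assert {c for _, c in reg.models} == {"c2", "c3"}
        t = reg.counts["FHS-style"]
        assert t["trained"] == 3 and t["passing_r2"] == 2
        assert t["trained"] == t["passing_probe_filter"] + t["rejected"]

    def test_probe_snp_exclusion(self):
        inside = self._model("c1", 0.5, pos=5000, vpos=5010)  # within +/-24
        outside = self._model("c2", 0.5, pos=5000, vpos=4000)
        probes = pd.DataFrame({"chrom": ["1", "1"],
                               "start": [5000 - 25, 5000 - 25],
                               "end": [5000 + 24, 5000 + 24],
                               "name": ["c1", "c2"]})
        reg = mw.build_registry([inside, outside], probes, min_r2=0.01)
        assert {c for _, c in reg.models} == {"c2"}

    def test_missing_probe_interval_retains(self, caplog):
        m = self._model("orphan", 0.5)
        probes = pd.DataFrame(columns=["chrom", "start", "end", "name"])
        reg = mw.build_registry([m], probes, min_r2=0.01)
        assert ("FHS-style", "orphan") in reg.models

    def test_union_inclusion_exclusion(self):
        assert mw.union_count(72_848, 93_442, 62_188) == 104_102
        assert 72_848 - 62_188 == 10_660
        assert 93_442 - 62_188 == 31_254
        with pytest.raises(ValueError):
            mw.union_count(10, 10, 11)

    def test_duplicate_key_rejected(self):
        reg = mw.ModelRegistry()
        reg.add(self._model("c1", 0.5))
        with pytest.raises(ValueError, match="duplicate"):
            reg.add(self._model("c1", 0.9))

    def test_union_count_from_models(self):
        reg = mw.ModelRegistry()
        for c in ("c1", "c2", "c3"):
            reg.add(self._model(c, 0.5, panel="FHS-style"))
        for c in ("c2", "c3", "c4"):
            reg.add(self._model(c, 0.5, panel="BIOS-style"))
        assert reg.union_cpg_count() == 4


class TestUnstandardize:
    def _std_model(self, weights, ids=("vA", "vB")):
        entries = pd.DataFrame({"variant_id": list(ids),
                                "pos": [1000, 2000],
                                "other_allele": ["A", "T"],
                                "effect_allele": ["G", "C"],
                                "weight": list(weights)})
        return mw.WeightModel("cpgS", "1", 1500, "BIOS-style", entries, 0.3,
                              standardized=True)

    def test_unit_sd_identity(self):
        m = self._std_model([0.5, -0.25])
        out = mw.unstandardize_weights(m, {"vA": 1.0, "vB": 1.0})
        assert np.allclose(out.entries["weight"], [0.5, -0.25])
        assert not out.standardized

    def test_halving(self):
        m = self._std_model([1.0, 1.0])
        out = mw.unstandardize_weights(m, {"vA": 2.0, "vB": 4.0})
        assert np.allclose(out.entries["weight"], [0.5, 0.25])

    def test_missing_sd_drops_then_rejects(self):
        m = self._std_model([1.0, 1.0])
        out = mw.unstandardize_weights(m, {"vA": 2.0})
        assert list(out.entries["variant_id"]) == ["vA"]
        rej = mw.unstandardize_weights(m, {})
        assert isinstance(rej, mw.ModelRejection)

    def test_prediction_variance_preserved(self, cohort):
        """Var(raw-dosage prediction, unstandardized weights) equals
        Var(standardized prediction) on the same cohort."""
        G = cohort["G"]
        meth_n = mw.adjust_and_normalize(cohort["meth"])
        cfg = mw.TrainingConfig.bios_style(seed=2)
        model = mw.train_cpg_model(G, meth_n, "cpg00004", cfg)
        assert isinstance(model, mw.WeightModel) and model.standardized
        pred_std = model.predict(G)
        sds = dict(zip(G.variants["id"], G.dosages.std(axis=0, ddof=1)))
        raw = mw.unstandardize_weights(model, sds)
        pred_raw = raw.predict(G)
        v1, v2 = pred_std.var(ddof=1), pred_raw.var(ddof=1)
        assert abs(v1 - v2) / v1 <= 1e-9


def test_train_panel_counts(cohort):
    meth_n = mw.adjust_and_normalize(cohort["meth"])
    models, rejections = mw.train_panel(cohort["G"], meth_n,
                                        mw.TrainingConfig.fhs_style(seed=1))
    assert len(models) + len(rejections) == len(meth_n.feature_ids)


def test_weights_tsv_roundtrip(tmp_path, cohort):
    meth_n = mw.adjust_and_normalize(cohort["meth"])
    cfg = mw.TrainingConfig.fhs_style(seed=1)
    models, _ = mw.train_panel(cohort["G"], meth_n, cfg)
    path = tmp_path / "w.tsv"
    mw.training.write_weights_tsv(models, path)
    back = mw.training.read_weights_tsv(path)
    assert len(back) == len(models)
    orig = {m.key: m for m in models}
    for m in back:
        o = orig[m.key]
        assert np.allclose(m.entries["weight"], o.entries["weight"])
        assert list(m.entries["variant_id"]) == list(o.entries["variant_id"])
        assert (m.chrom, m.pos) == (o.chrom, o.pos)
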