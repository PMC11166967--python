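import numpy as np
import pandas as pd
import pytest

from spaceskin import dge, simdata
from spaceskin._utils import ValidationError


class TestFilterGenes:
    def test_ercc_and_low_detection_removed(self, small_counts,
                                            small_samples):
        out = dge.filter_genes(small_counts, small_samples)
        assert "ERCC-00130" not in out.index
        assert "GENE2" not in out.index          # all zeros
        assert {"GENE1", "GENE3"} <= set(out.index)

    def test_gene_nonzero_in_exactly_min_group_retained(self):
        counts = pd.DataFrame(
            {"a": [5, 9], "b": [5, 9], "c": [5, 9], "d": [0, 9],
             "e": [0, 9], "f": [0, 9]},
            index=["g_edge", "g_ref"])
        samples = pd.DataFrame({
            "sample_id": list("abcdef"), "mission": "m", "subset_id": "s1",
            "condition": ["flight"] * 3 + ["ground"] * 3})
        out = dge.filter_genes(counts, samples)
        assert "g_edge" in out.index  # nonzero in exactly 3 = smallest group

    def test_empty_result_is_error(self, small_samples):
        counts = pd.DataFrame({s: [0] for s in "abcd"}, index=["g"])
        with pytest.raises(ValidationError, match="every gene"):
            dge.filter_genes(counts, small_samples)


class TestSizeFactors:
    def test_doubled_sample_oracle(self):
        c = pd.DataFrame({"s1": [2, 4, 8], "s2": [4, 8, 16]},
                         index=list("abc"))
        f = dge.estimate_size_factors(c)
        assert f["s1"] == pytest.approx(2 ** -0.5, abs=1e-6)
        assert f["s2"] == pytest.approx(2 ** 0.5, abs=1e-6)

    def test_identical_samples(self):
        c = pd.DataFrame({"s1": [3, 7], "s2": [3, 7]}, index=["a", "b"])
        assert np.allclose(dge.estimate_size_factors(c), [1.0, 1.0])

    def test_geometric_mean_is_one(self, tiny_design):
        p = simdata.SimulationParams(n_genes=300, seed=2)
        c, _, _ = simdata.simulate_counts(tiny_design, p)
        f = dge.estimate_size_factors(c)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-9)

    def test_no_common_gene_advises_fallback(self):
        c = pd.DataFrame({"s1": [5, 0], "s2": [0, 5]}, index=["a", "b"])
        with pytest.raises(ValidationError, match="pseudo_reference"):
            dge.estimate_size_factors(c)
        f = dge.estimate_size_factors(c, pseudo_reference=True)
        assert (f > 0).all()


class TestDispersions:
    def _sim(self, alpha, n=20, n_genes=2000, seed=0):
        rng = np.random.default_rng(seed)
        mu = np.exp(rng.normal(4, 1.5, n_genes))
        if alpha == 0:
            y = rng.poisson(mu[:, None], size=(n_genes, 2 * n))
        else:
            lam = rng.gamma(1 / alpha, alpha * mu[:, None],
                            size=(n_genes, 2 * n))
            y = rng.poisson(lam)
        counts = pd.DataFrame(y, index=[f"g{i}" for i in range(n_genes)],
                              columns=[f"s{j}" for j in range(2 * n)])
        samples = pd.DataFrame({
            "sample_id": counts.columns, "mission": "m", "subset_id": "s1",
            "condition": ["flight"] * n + ["ground"] * n})
        f = dge.estimate_size_factors(counts)
        return dge.estimate_dispersions(counts, f, samples)

    def test_poisson_counts_near_zero_dispersion(self):
        disp = self._sim(alpha=0.0)
        assert disp.final.median() <= 0.01

    def test_nb_dispersion_recovered(self):
        disp = self._sim(alpha=0.2)
        assert 0.1 <= disp.final.median() <= 0.3

    def test_constant_gene_floored(self, small_samples):
        counts = pd.DataFrame({s: [7, 9] for s in "abcd"},
                              index=["flat", "flat2"])
        f = dge.estimate_size_factors(counts)
        disp = dge.estimate_dispersions(counts, f, small_samples)
        assert (disp.raw == dge.DISPERSION_FLOOR).all()

    def test_single_replicate_rejected(self, small_counts):
        samples = pd.DataFrame({
            "sample_id": list("abcd"), "mission": "m", "subset_id": "s1",
            "condition": ["flight", "ground", "ground", "ground"]})
        f = dge.estimate_size_factors(small_counts.drop("GENE2"))
        with pytest.raises(ValidationError, match="2 replicates"):
            dge.estimate_dispersions(small_counts.drop("GENE2"), f, samples)


class TestWald:
    def test_matches_statsmodels_glm(self, tiny_design):
        import statsmodels.api as sm

        p = simdata.SimulationParams(n_genes=40, seed=5)
        eff = simdata.sample_effects(tiny_design, p, n_subset_de=4,
                                     n_cross_mission=0, seed=5)
        c, s, _ = simdata.simulate_counts(tiny_design, p, eff)
        filt = dge.filter_genes(c, s)
        f = dge.estimate_size_factors(filt)
        disp = dge.estimate_dispersions(filt, f, s)
        res = dge.wald_test(filt, f, disp, s, "s1").table.set_index("gene")

        X = sm.add_constant((s["condition"] == "flight").astype(float))
        off = np.log(f.loc[s["sample_id"]].to_numpy())
        for g in filt.index[:20]:
            fam = sm.families.NegativeBinomial(alpha=disp.final[g])
            fit = sm.GLM(filt.loc[g].to_numpy(), X, family=fam,
                         offset=off).fit()
            assert res.loc[g, "log2FoldChange"] == pytest.approx(
                fit.params.iloc[1] / np.log(2), abs=1e-5)
            assert res.loc[g, "lfcSE"] == pytest.approx(
                fit.bse.iloc[1] / np.log(2), abs=1e-5)

    def test_all_genes_reported_and_t_identity(self, tiny_design):
        p = simdata.SimulationParams(n_genes=500, seed=6)
        c, s, _ = simdata.simulate_counts(tiny_design, p)
        res = dge.run_subset_dge(c, s, "s1")
        filt = dge.filter_genes(c, s)
        assert len(res.table) == len(filt)  # nothing dropped by testing
        tab = res.table
        assert np.allclose(tab["stat"],
                           tab["log2FoldChange"] / tab["lfcSE"], atol=1e-9)

    def test_planted_lfc_recovered(self):
        # 200 genes at mu~200, alpha=0.05, lfc=2, n=6/6
        rng = np.random.default_rng(7)
        n_genes, n = 200, 6
        mu = 200.0
        alpha = 0.05
        lam_g = rng.gamma(1 / alpha, alpha * mu, size=(n_genes, n))
        lam_f = rng.gamma(1 / alpha, alpha * mu * 4, size=(n_genes, n))
        y = rng.poisson(np.concatenate([lam_f, lam_g], axis=1))
        counts = pd.DataFrame(y, index=[f"g{i}" for i in range(n_genes)],
                              columns=[f"s{j}" for j in range(2 * n)])
        samples = pd.DataFrame({
            "sample_id": counts.columns, "mission": "m", "subset_id": "s1",
            "condition": ["flight"] * n + ["ground"] * n})
        f = pd.Series(1.0, index=counts.columns)
        disp = dge.DispersionEstimates(
            raw=pd.Series(alpha, index=counts.index), trend_a0=0.0,
            trend_a1=alpha, final=pd.Series(alpha, index=counts.index))
        res = dge.wald_test(counts, f, disp, samples, "s1")
        assert res.table["log2FoldChange"].mean() == pytest.approx(2.0,
                                                                   abs=0.2)

    def test_scale_equivariance_of_normalization(self, tiny_design):
        # multiplying one sample's counts by k multiplies its size factor
        # by k (relative to the others) and leaves the normalized counts
        # identical up to one global constant, so the rescaling carries no
        # differential signal into the model input
        p = simdata.SimulationParams(n_genes=300, seed=8)
        c, s, _ = simdata.simulate_counts(tiny_design, p)
        c2 = c.copy()
        c2[c.columns[0]] = c[c.columns[0]] * 2  # exact integer rescale
        f1 = dge.estimate_size_factors(c)
        f2 = dge.estimate_size_factors(c2)
        ratio = (f2 / f1) / (f2 / f1).iloc[1]
        assert ratio.iloc[0] == pytest.approx(2.0, rel=1e-6)
        norm1 = c.to_numpy() / f1.to_numpy()
        norm2 = c2.to_numpy() / f2.to_numpy()
        with np.errstate(invalid="ignore"):
            rel = norm2 / norm1
        rel = rel[np.isfinite(rel)]
        assert np.allclose(rel, rel.flat[0], rtol=1e-9)


class TestBH:
    def test_hand_computed_example(self):
        out = dge.adjust_bh([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_value_passthrough(self):
        assert dge.adjust_bh([0.3])[0] == pytest.approx(0.3)

    def test_monotone_on_sorted_input(self):
        rng = np.random.default_rng(0)
        p = np.sort(rng.random(50))
        out = dge.adjust_bh(p)
        assert (np.diff(out) >= -1e-12).all()

    def test_nan_propagates_and_out_of_range_rejected(self):
        out = dge.adjust_bh([0.01, np.nan, 0.5])
        assert np.isnan(out[1]) and not np.isnan(out[0])
        with pytest.raises(ValidationError, match="outside"):
            dge.adjust_bh([1.2])
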