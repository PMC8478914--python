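import numpy as np
import pandas as pd
import pytest

from gradmap.effects import (
    FunctionalMarkerRegression,
    code_markers,
    cross_validate,
    fit_effects,
    haplotype_table,
    relative_importance,
)
from gradmap.fixtures import simulate_core_collection
from gradmap.io import GradmapError


def _toy(n=400, seed=0, sigma=0.0):
    """Two biallelic genes with known effects (+1 for GS3-b, +0.5 for GW5-b)."""
    rng = np.random.default_rng(seed)
    alleles = pd.DataFrame(
        {
            "GS3": rng.choice(["a", "b"], n),
            "GW5": rng.choice(["a", "b"], n),
        },
        index=pd.Index([f"P{i}" for i in range(n)], name="accession"),
    )
    y = (
        5.0
        + (alleles["GS3"] == "b") * 1.0
        + (alleles["GW5"] == "b") * 0.5
        + rng.normal(0, sigma, n)
    )
    return alleles, pd.Series(y, index=alleles.index)


class TestCoding:
    def test_biallelic_gene_gives_one_column(self):
        alleles, _ = _toy(50)
        scheme, design = code_markers(alleles)
        assert design.shape[1] == 2
        assert set(scheme.reference) == {"GS3", "GW5"}

    def test_multiallelic_gene_gives_k_minus_one_columns(self):
        rng = np.random.default_rng(1)
        alleles = pd.DataFrame(
            {"GS3": rng.choice([f"GS3-{i}" for i in range(6)], 300)},
            index=[f"P{i}" for i in range(300)],
        )
        _, design = code_markers(alleles)
        assert design.shape[1] == 5

    def test_monomorphic_gene_dropped_with_warning(self):
        alleles = pd.DataFrame(
            {"GS3": ["a", "b", "a"], "DEAD": ["x", "x", "x"]}, index=["P1", "P2", "P3"]
        )
        with pytest.warns(UserWarning, match="DEAD"):
            scheme, design = code_markers(alleles)
        assert scheme.dropped_genes == ["DEAD"]

    def test_missing_rows_excluded(self):
        alleles = pd.DataFrame(
            {"GS3": ["a", "b", None, "b"]}, index=["P1", "P2", "P3", "P4"]
        )
        _, design = code_markers(alleles)
        assert list(design.index) == ["P1", "P2", "P4"]


class TestFit:
    def test_noiseless_recovery(self):
        alleles, y = _toy()
        fit = fit_effects(alleles, y)
        assert fit.r2_ == pytest.approx(1.0)
        # a biallelic gene carries its full effect on its single indicator
        # column, with sign set by which allele became the reference
        (gs3_col,) = [c for c in fit.coef_.index if c.startswith("GS3")]
        (gw5_col,) = [c for c in fit.coef_.index if c.startswith("GW5")]
        assert abs(fit.coef_[gs3_col]) == pytest.approx(1.0)
        assert abs(fit.coef_[gw5_col]) == pytest.approx(0.5)
        pred = fit.predict(alleles)
        np.testing.assert_allclose(pred, y, atol=1e-10)

    def test_permuted_phenotype_has_near_zero_r2(self):
        hits = 0
        for seed in range(20):
            alleles, y = _toy(n=500, seed=seed, sigma=0.3)
            rng = np.random.default_rng(1000 + seed)
            yp = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
            if fit_effects(alleles, yp).r2_ <= 0.05:
                hits += 1
        assert hits >= 19

    def test_synthetic_collection_recovers_target_pve(self):
        alleles, table, truth = simulate_core_collection(n=541, h2=0.67, seed=9)
        fit = fit_effects(alleles, table.means())
        assert fit.r2_ == pytest.approx(0.67, abs=0.05)

    def test_invariant_to_reference_allele_choice(self):
        # relabelling which allele is "reference" must not change fitted values
        alleles, y = _toy(200, seed=3)
        fit1 = fit_effects(alleles, y)
        swapped = alleles.replace({"GS3": {"a": "zzz"}})  # flips frequency order
        fit2 = fit_effects(swapped, y)
        np.testing.assert_allclose(
            fit1.predict(alleles), fit2.predict(swapped), atol=1e-9
        )

    def test_rank_deficient_design_reported(self):
        alleles, y = _toy(100, seed=4)
        dup = alleles.copy()
        dup["GS3copy"] = alleles["GS3"]  # aliased gene
        with pytest.warns(UserWarning, match="aliased"):
            fit = fit_effects(dup, y)
        assert fit.r2_ == pytest.approx(1.0)


class TestRelativeImportance:
    def test_single_gene_importance_equals_r2(self):
        alleles, y = _toy(seed=5, sigma=0.5)
        fit = fit_effects(alleles[["GS3"]], y)
        assert fit.importance_.sum() == pytest.approx(fit.r2_, abs=1e-9)
        assert len(fit.importance_) == 1

    def test_orthogonal_equal_genes_share_equally(self):
        # balanced factorial design: the two genes are exactly orthogonal
        idx = pd.Index([f"P{i}" for i in range(400)])
        alleles = pd.DataFrame(
            {"G1": ["a", "a", "b", "b"] * 100, "G2": ["a", "b", "a", "b"] * 100},
            index=idx,
        )
        y = pd.Series(
            (alleles["G1"] == "b") * 1.0 + (alleles["G2"] == "b") * 1.0, index=idx
        )
        fit = fit_effects(alleles, y)
        assert fit.importance_["G1"] == pytest.approx(fit.importance_["G2"], abs=1e-9)
        assert fit.importance_.sum() == pytest.approx(fit.r2_, abs=1e-9)

    def test_duplicated_predictor_splits_importance(self):
        idx = pd.Index([f"P{i}" for i in range(200)])
        rng = np.random.default_rng(6)
        g = rng.choice(["a", "b"], 200)
        design = pd.DataFrame(
            {"G1[b]": (g == "b").astype(float), "G2[b]": (g == "b").astype(float)},
            index=idx,
        )
        y = pd.Series((g == "b") * 1.0 + rng.normal(0, 0.3, 200), index=idx)
        fit = FunctionalMarkerRegression()
        imp = relative_importance(fit, design, y)
        # brute force: the duplicated column's share is split evenly and the
        # total still equals the (single-predictor) R^2
        single = np.corrcoef((g == "b").astype(float), y)[0, 1] ** 2
        assert imp["G1"] == pytest.approx(imp["G2"], abs=1e-9)
        assert imp.sum() == pytest.approx(single, abs=1e-9)

    def test_sum_matches_r2_on_core_collection(self):
        alleles, table, _ = simulate_core_collection(n=300, seed=7)
        fit = fit_effects(alleles, table.means())
        assert fit.importance_.sum() == pytest.approx(fit.r2_, abs=1e-6)
        assert (fit.importance_ >= -1e-12).all()


class TestCrossValidation:
    def test_noiseless_correlation_near_one(self):
        alleles, y = _toy(seed=8)
        assert cross_validate(alleles, y, rng=0) > 0.999

    def test_pure_noise_correlation_near_zero(self):
        rng = np.random.default_rng(9)
        alleles, _ = _toy(400, seed=9)
        y = pd.Series(rng.normal(size=400), index=alleles.index)
        assert abs(cross_validate(alleles, y, rng=0)) < 0.2

    def test_cv_correlation_tracks_sqrt_r2(self):
        alleles, table, _ = simulate_core_collection(n=541, h2=0.67, seed=10)
        cv = cross_validate(alleles, table.means(), rng=0)
        assert cv == pytest.approx(np.sqrt(0.67), abs=0.06)

    def test_cv_bounded_by_in_sample_fit(self):
        alleles, table, _ = simulate_core_collection(n=300, seed=11)
        fit = fit_effects(alleles, table.means())
        cv = cross_validate(alleles, table.means(), rng=0)
        assert cv <= np.sqrt(fit.r2_) + 0.05

    def test_needs_enough_rows(self):
        alleles, y = _toy(8)
        with pytest.raises(GradmapError):
            cross_validate(alleles, y, k=10)


class TestHaplotypes:
    def test_all_combinations_enumerated(self):
        idx = pd.Index([f"P{i}" for i in range(40)])
        alleles = pd.DataFrame(
            {"G1": ["a", "a", "b", "b"] * 10, "G2": ["a", "b", "a", "b"] * 10},
            index=idx,
        )
        y = pd.Series(np.arange(40.0), index=idx)
        tab = haplotype_table(alleles, y, min_count=1)
        assert len(tab) == 4
        # stratified means recomputed by brute force
        mask = (alleles["G1"] == "a") & (alleles["G2"] == "b")
        expect = y[mask].mean()
        assert tab.set_index("haplotype").loc["a/b", "mean"] == pytest.approx(expect)

    def test_rare_haplotypes_collapse(self):
        idx = pd.Index([f"P{i}" for i in range(5)])
        alleles = pd.DataFrame({"G1": ["a", "a", "a", "a", "b"]}, index=idx)
        y = pd.Series(np.ones(5), index=idx)
        tab = haplotype_table(alleles, y, min_count=2)
        assert "other" in set(tab["haplotype"])

    def test_group_frequencies(self):
        idx = pd.Index([f"P{i}" for i in range(6)])
        alleles = pd.DataFrame({"G1": ["a", "a", "b", "b", "b", "b"]}, index=idx)
        y = pd.Series(np.ones(6), index=idx)
        grp = pd.Series(["wild"] * 3 + ["cultivar"] * 3, index=idx)
        tab = haplotype_table(alleles, y, group_label=grp, min_count=1).set_index("haplotype")
        assert tab.loc["b", "freq_cultivar"] == pytest.approx(1.0)
        assert tab.loc["b", "freq_wild"] == pytest.approx(1 / 3)
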