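import numpy as np
import pandas as pd
import pytest

from gradmap.coseg import (
    classify_flanks,
    classify_model,
    coseg_test,
    fine_map,
    pve_f2gp,
    screen_recombinants,
    select_replacement_family,
)
from gradmap.fixtures import sigma_e_for_pve, single_locus_architecture
from gradmap.io import GenotypeCallMatrix, GradmapError
from gradmap.simulate import (
    Architecture,
    QTLocus,
    f2_from_inbreds,
    genotype_calls,
    phenotype_population,
    uniform_map,
)


def _mat(rows, markers):
    return GenotypeCallMatrix(
        pd.DataFrame(rows, index=[f"i{k}" for k in range(len(rows))], columns=markers)
    )


class TestClassifyFlanks:
    def test_joint_classes(self):
        mat = _mat([["A", "A"], ["A", "B"], ["H", "."], ["B", "B"], ["H", "H"]], ["L", "R"])
        fl = classify_flanks(mat, "L", "R")
        assert fl.classes.tolist() == ["AA", "recombinant", "missing", "BB", "HH"]

    def test_absent_marker_rejected(self):
        mat = _mat([["A", "A"]], ["L", "R"])
        with pytest.raises(GradmapError):
            classify_flanks(mat, "L", "nope")


def _flanks_and_phen(f2, left="M10", right="M12"):
    return classify_flanks(genotype_calls(f2), left, right), f2.phenotype_table().means()


class TestCosegTest:
    def test_noiseless_single_locus_verifies_with_zero_overlap(self, additive_f2):
        _, f2 = additive_f2
        fl, phen = _flanks_and_phen(f2)
        res = coseg_test(fl, phen)
        assert res.verified and res.overlap == 0.0
        assert res.pve_f2gp == pytest.approx(1.0)

    def test_small_class_gives_undetermined_not_pass(self, additive_f2):
        _, f2 = additive_f2
        fl, phen = _flanks_and_phen(f2)
        res = coseg_test(fl, phen, min_class_size=100)
        assert res.status == "undetermined" and not res.verified

    def test_permutation_null_type_one_control(self):
        # phenotype shuffled against genotype: false verification must be
        # rare (alpha = 1e-3 Welch gate plus the overlap bound)
        arch = single_locus_architecture(a=1.0, d=0.0, sigma_e=0.5)
        f2 = f2_from_inbreds(arch, 200, np.random.default_rng(40))
        fl, phen = _flanks_and_phen(f2)
        rng = np.random.default_rng(41)
        false_hits = 0
        reps = 300
        for _ in range(reps):
            perm = pd.Series(rng.permutation(phen.to_numpy()), index=phen.index)
            if coseg_test(fl, perm).verified:
                false_hits += 1
        assert false_hits <= 3  # consistent with the nominal alpha

    def test_verdict_symmetric_under_allele_relabel(self, additive_f2):
        _, f2 = additive_f2
        calls = genotype_calls(f2)
        swapped = GenotypeCallMatrix(
            calls.calls.replace({"A": "B", "B": "A"})
        )
        phen = f2.phenotype_table().means()
        r1 = coseg_test(classify_flanks(calls, "M10", "M12"), phen)
        r2 = coseg_test(classify_flanks(swapped, "M10", "M12"), phen)
        assert r1.verified == r2.verified
        assert abs(r1.statistic) == pytest.approx(abs(r2.statistic))

    def test_second_locus_with_large_noise_fails_overlap(self):
        # two unlinked equal QTL plus strong environmental noise: at one
        # locus's flanks the homozygous classes overlap too much to verify
        mmap1 = uniform_map(3, chrom="chr1")
        mmap2 = uniform_map(3, chrom="chr7", prefix="N")
        mmap = type(mmap1)(pd.concat([mmap1.df, mmap2.df], ignore_index=True))
        arch = Architecture(
            8.0,
            1.5,
            [QTLocus("chr1", 100_001, a=1.0), QTLocus("chr7", 100_001, a=1.0)],
            mmap,
        )
        f2 = f2_from_inbreds(arch, 400, np.random.default_rng(42))
        fl = classify_flanks(genotype_calls(f2), "M1", "M3")
        res = coseg_test(fl, f2.phenotype_table().means())
        assert not res.verified and res.overlap > 0.20


class TestModelClassification:
    @pytest.mark.parametrize(
        "d, expect_effect, expect_orient, counts_ratio",
        [
            (1.0, "complete-dominant", "high", (0.25, 0.75)),
            (-1.0, "complete-dominant", "low", (0.75, 0.25)),
            (0.0, "semi-dominant", "high", (0.25, 0.5, 0.25)),
            (2.0, "over-dominant", "high", (0.25, 0.25, 0.5)),
            (-2.0, "over-dominant", "low", (0.5, 0.25, 0.25)),
        ],
    )
    def test_noiseless_models_recovered(self, d, expect_effect, expect_orient, counts_ratio):
        arch = single_locus_architecture(a=1.0, d=d, sigma_e=0.0)
        f2 = f2_from_inbreds(arch, 600, np.random.default_rng(50))
        fl, phen = _flanks_and_phen(f2)
        model, diag = classify_model(fl, phen)
        effect, orient, boundary = model.split("/")
        assert (effect, orient) == (expect_effect, expect_orient)
        assert boundary == "discrete"
        assert diag["segregation_p"] > 1e-3  # consistent with the expected ratio

    def test_noise_gives_partially_overlapping_boundary(self):
        arch = single_locus_architecture(a=1.0, d=0.0, sigma_e=0.6)
        f2 = f2_from_inbreds(arch, 600, np.random.default_rng(51))
        fl, phen = _flanks_and_phen(f2)
        model, diag = classify_model(fl, phen)
        assert model.endswith("partially-overlapping")

    def test_ambiguous_dominance_returns_none(self):
        arch = single_locus_architecture(a=1.0, d=0.5, sigma_e=0.0)  # h = 0.5 gap
        f2 = f2_from_inbreds(arch, 600, np.random.default_rng(52))
        fl, phen = _flanks_and_phen(f2)
        model, diag = classify_model(fl, phen)
        assert model == "none" and "h_hat" in diag


class TestPve:
    def test_noiseless_is_one(self, additive_f2):
        _, f2 = additive_f2
        fl, phen = _flanks_and_phen(f2)
        assert pve_f2gp(fl, phen) == pytest.approx(1.0)

    def test_null_phenotype_near_zero(self):
        arch = single_locus_architecture(a=0.0, sigma_e=1.0)
        hits = 0
        for seed in range(20):
            f2 = f2_from_inbreds(arch, 200, np.random.default_rng(60 + seed))
            fl, phen = _flanks_and_phen(f2)
            if pve_f2gp(fl, phen) <= 0.05:
                hits += 1
        assert hits >= 19

    def test_recovers_target_heritability(self):
        arch = single_locus_architecture(a=1.0, d=0.0, sigma_e=sigma_e_for_pve(1.0, 0.0, 0.8))
        f2 = f2_from_inbreds(arch, 2_000, np.random.default_rng(61))
        fl, phen = _flanks_and_phen(f2)
        assert pve_f2gp(fl, phen) == pytest.approx(0.8, abs=0.05)

    def test_single_class_rejected(self):
        mat = _mat([["A", "A"], ["A", "A"]], ["L", "R"])
        fl = classify_flanks(mat, "L", "R")
        phen = pd.Series([1.0, 2.0], index=["i0", "i1"])
        with pytest.raises(GradmapError):
            pve_f2gp(fl, phen)


class TestReplacementFamily:
    def test_two_locus_line_homozygous_at_one_verifies_other(self):
        mmap1 = uniform_map(3, chrom="chr1")
        mmap2 = uniform_map(3, chrom="chr7", prefix="N")
        mmap = type(mmap1)(pd.concat([mmap1.df, mmap2.df], ignore_index=True))
        arch = Architecture(
            8.0,
            0.0,
            [QTLocus("chr1", 100_001, a=1.0), QTLocus("chr7", 100_001, a=1.0)],
            mmap,
        )
        rng = np.random.default_rng(70)
        f2 = f2_from_inbreds(arch, 300, rng)
        hit, diags = select_replacement_family(f2, arch, "M1", "M3", 150, rng)
        assert hit is not None
        fam, res = hit
        assert res.verified
        # the winning line segregates at chr1 but is homozygous at chr7
        line_id = fam.provenance["parents"][0]
        i = f2.ids.index(line_id)
        assert f2.dosage()[i, mmap.index_of("N1")] != 1 or res.verified

    def test_single_locus_heterozygote_family_verifies(self, additive_f2):
        arch, f2 = additive_f2
        rng = np.random.default_rng(71)
        hit, _ = select_replacement_family(f2, arch, "M10", "M12", 120, rng)
        assert hit is not None and hit[1].verified

    def test_homozygous_population_returns_none(self, small_map):
        from gradmap.simulate import Population

        arch = Architecture(8.0, 0.0, [], small_map)
        pop = Population("F2", small_map, np.ones((10, 2, 5), dtype=np.int8))
        pop.phenotypes = np.full(10, 8.0)
        hit, diags = select_replacement_family(pop, arch, "m1", "m2", 50, np.random.default_rng(0))
        assert hit is None


class TestRecombinantScreen:
    def test_breakpoint_localised_between_internal_markers(self):
        markers = ["L", "a", "b", "R"]
        mat = _mat([["A", "A", "B", "B"], ["A", "A", "A", "A"], ["B", "H", "H", "B"]], markers)
        mmap = uniform_map(4, spacing_bp=1000)
        mmap.df["marker"] = markers
        mmap = type(mmap)(mmap.df)
        recs = screen_recombinants(mat, mmap, "L", "R")
        assert [r.id for r in recs] == ["i0"]
        assert (recs[0].break_left, recs[0].break_right) == ("a", "b")

    def test_no_internal_markers_means_whole_interval(self):
        mat = _mat([["A", "B"]], ["L", "R"])
        mmap = uniform_map(2, spacing_bp=1000)
        mmap.df["marker"] = ["L", "R"]
        mmap = type(mmap)(mmap.df)
        recs = screen_recombinants(mat, mmap, "L", "R")
        assert (recs[0].break_left, recs[0].break_right) == ("L", "R")

    def test_count_matches_map_distance_expectation(self):
        # flanks 10 cM apart: P(discordant joint genotype) from Haldane r
        arch = single_locus_architecture(n_markers=2, spacing_bp=2_500_000, qtl_index=0)
        f2 = f2_from_inbreds(arch, 5_000, np.random.default_rng(80), phenotyped=False)
        calls = genotype_calls(f2)
        recs = screen_recombinants(calls, arch.mmap, "M1", "M2")
        r = float(0.0906298)
        # exact oracle: enumerate the 4 gamete haplotypes over the flanks
        gametes = {(0, 0): (1 - r) / 2, (1, 1): (1 - r) / 2, (0, 1): r / 2, (1, 0): r / 2}
        p_discordant = sum(
            p1 * p2
            for (x1, y1), p1 in gametes.items()
            for (x2, y2), p2 in gametes.items()
            if x1 + x2 != y1 + y2
        )
        expect = 5_000 * p_discordant
        assert abs(len(recs) - expect) < 4 * np.sqrt(expect)


class TestFineMap:
    def _nil_progeny(self, n=2000, seed=0):
        # QTL between M11 (1,000,001) and M12 (1,100,001): pseudo-marker map
        mmap = uniform_map(21, chrom="chr3", spacing_bp=100_000)
        df = mmap.df.copy()
        extra = pd.DataFrame(
            {"marker": ["Q"], "chrom": ["chr3"], "pos_bp": [1_050_001], "pos_cM": [4.2]}
        )
        full = type(mmap)(
            pd.concat([df, extra]).sort_values("pos_bp").reset_index(drop=True)
        )
        arch = Architecture(8.0, 0.0, [QTLocus("chr3", 1_050_001, a=1.0)], full)
        f2 = f2_from_inbreds(arch, n, np.random.default_rng(seed))
        calls = genotype_calls(f2, markers=[m for m in full.markers if m != "Q"])
        return arch, f2, calls, full

    def test_interval_contains_truth_and_is_one_spacing(self):
        arch, f2, calls, mmap = self._nil_progeny(seed=90)
        phen = f2.phenotype_table().means()
        recs = screen_recombinants(calls, mmap, "M1", "M21", phen)
        res = fine_map(recs, phen, 9.0, 7.0, ("chr3", 1, 2_000_001))
        assert res.start_bp < 1_050_001 < res.end_bp
        assert res.end_bp - res.start_bp <= 100_000
        assert res.n_conflicts == 0

    def test_monotone_refinement(self):
        arch, f2, calls, mmap = self._nil_progeny(seed=91)
        phen = f2.phenotype_table().means()
        recs = screen_recombinants(calls, mmap, "M1", "M21", phen)
        widths = []
        for k in (10, 30, 60, len(recs)):
            res = fine_map(recs[:k], phen, 9.0, 7.0, ("chr3", 1, 2_000_001))
            widths.append(res.end_bp - res.start_bp)
        assert widths == sorted(widths, reverse=True)

    def test_single_recombinant_bounds_one_side(self):
        mat = _mat([["A", "B"]], ["L", "R"])
        mmap = uniform_map(2, spacing_bp=1_000_000)
        mmap.df["marker"] = ["L", "R"]
        mmap = type(mmap)(mmap.df)
        phen = pd.Series([9.0], index=["i0"])
        recs = screen_recombinants(mat, mmap, "L", "R", phen)
        res = fine_map(recs, phen, 9.0, 7.0, ("chr1", 1, 1_000_001))
        # phenotype matches the left (A) flank: locus left of the breakpoint
        assert res.start_bp == 1 and res.end_bp == 1_000_001

    def test_midpoint_phenotype_excluded_as_ambiguous(self):
        mat = _mat([["A", "B"]], ["L", "R"])
        mmap = uniform_map(2, spacing_bp=1_000_000)
        mmap.df["marker"] = ["L", "R"]
        mmap = type(mmap)(mmap.df)
        phen = pd.Series([8.0], index=["i0"])  # exactly between class means
        recs = screen_recombinants(mat, mmap, "L", "R", phen)
        with pytest.raises(GradmapError, match="informative"):
            fine_map(recs, phen, 9.0, 7.0, ("chr1", 1, 1_000_001))
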