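import numpy as np
import pytest

import vqtlscan as v
from vqtlscan.epistasis import read_gff_genes


def _panel_from_design(geno_cols, y, treatment="glucose"):
    """Build aligned panels from explicit genotype columns and one phenotype."""
    n = len(y)
    geno = np.column_stack(geno_cols).astype(float)
    chrom = np.array([f"chr{j + 1}" for j in range(geno.shape[1])], dtype=object)
    g = v.GenotypePanel(
        segregant_ids=[f"s{i}" for i in range(n)],
        marker_ids=[f"m{j}" for j in range(geno.shape[1])],
        marker_chrom=chrom,
        marker_pos=np.full(geno.shape[1], 1000),
        calls=geno,
    )
    e = v.ExpressionPanel(
        segregant_ids=[f"s{i}" for i in range(n)],
        phenotype_ids=["ph1"],
        treatment=treatment,
        values=np.asarray(y, dtype=float)[:, None],
    )
    return g, e


def _and_model(n=40, effect=2.0, sigma=0.0, seed=0):
    rng = np.random.default_rng(seed)
    a = (np.arange(n) % 2).astype(float)
    b = (np.arange(n) // 2 % 2).astype(float)
    y = effect * a * b + rng.standard_normal(n) * sigma
    return a, b, y


class TestGPMap:
    def test_and_model_class_means_at_zero_noise(self):
        a, b, y = _and_model(effect=3.0, sigma=0.0)
        g, e = _panel_from_design([a, b], y)
        gpm = v.gp_map(e, g, "ph1", ["m0", "m1"])
        assert gpm.classes[(0, 0)]["mean"] == pytest.approx(0.0)
        assert gpm.classes[(0, 1)]["mean"] == pytest.approx(0.0)
        assert gpm.classes[(1, 0)]["mean"] == pytest.approx(0.0)
        assert gpm.classes[(1, 1)]["mean"] == pytest.approx(3.0)

    def test_class_sizes_sum_to_sample_count(self):
        a, b, y = _and_model(n=36, sigma=1.0)
        g, e = _panel_from_design([a, b], y)
        gpm = v.gp_map(e, g, "ph1", ["m0", "m1"])
        assert gpm.n_total() == 36

    def test_empty_class_reported_with_n_zero(self):
        # B always equals A: classes (0,1) and (1,0) are empty
        a = np.array([0.0, 0.0, 1.0, 1.0, 0.0, 1.0])
        y = np.arange(6, dtype=float)
        g, e = _panel_from_design([a, a], y)
        gpm = v.gp_map(e, g, "ph1", ["m0", "m1"])
        assert gpm.classes[(0, 1)]["n"] == 0
        assert np.isnan(gpm.classes[(0, 1)]["mean"])

    def test_up_regulation_only_with_both_alt_alleles(self):
        # pattern check: expression is raised iff both loci carry allele 1
        a, b, y = _and_model(effect=2.0, sigma=0.05, seed=4)
        g, e = _panel_from_design([a, b], y)
        gpm = v.gp_map(e, g, "ph1", ["m0", "m1"])
        up = gpm.classes[(1, 1)]["mean"]
        for combo in [(0, 0), (0, 1), (1, 0)]:
            assert gpm.classes[combo]["mean"] < up - 1.0

    def test_partition_recombines_to_overall_mean(self):
        a, b, y = _and_model(n=36, sigma=1.0, seed=9)
        g, e = _panel_from_design([a, b], y)
        gpm = v.gp_map(e, g, "ph1", ["m0", "m1"])
        weighted = sum(c["n"] * c["mean"] for c in gpm.classes.values() if c["n"])
        assert weighted / gpm.n_total() == pytest.approx(np.mean(y))


class TestInteractionContrast:
    def test_additive_map_gives_zero_delta(self):
        a = np.array([0.0, 0.0, 1.0, 1.0] * 5)
        b = np.array([0.0, 1.0, 0.0, 1.0] * 5)
        y = 1.5 * a + 0.7 * b
        g, e = _panel_from_design([a, b], y)
        summ = v.interaction_contrast(v.gp_map(e, g, "ph1", ["m0", "m1"]))
        assert summ.delta == pytest.approx(0.0, abs=1e-12)

    def test_and_model_delta_equals_effect(self):
        a, b, y = _and_model(effect=2.0, sigma=0.0)
        g, e = _panel_from_design([a, b], y)
        summ = v.interaction_contrast(v.gp_map(e, g, "ph1", ["m0", "m1"]))
        assert summ.delta == pytest.approx(2.0)

    def test_three_locus_duplicate_factor_contrast(self):
        # down-shift d only at the all-0 class: alternating sum = +d
        n = 80
        rng = np.random.default_rng(2)
        abc = [(rng.random(n) < 0.5).astype(float) for _ in range(3)]
        d = 1.8
        y = -d * np.prod([1 - x for x in abc], axis=0)
        g, e = _panel_from_design(abc, y)
        summ = v.interaction_contrast(v.gp_map(e, g, "ph1", ["m0", "m1", "m2"]))
        assert summ.delta == pytest.approx(d, abs=1e-10)

    def test_shift_invariance_and_coding_flip_algebra(self):
        a, b, y = _and_model(effect=2.0, sigma=0.3, seed=5)
        g, e = _panel_from_design([a, b], y)
        d0 = v.interaction_contrast(v.gp_map(e, g, "ph1", ["m0", "m1"])).delta
        # add a constant: delta unchanged
        g2, e2 = _panel_from_design([a, b], y + 11.0)
        assert v.interaction_contrast(v.gp_map(e2, g2, "ph1", ["m0", "m1"])).delta == pytest.approx(d0)
        # flip one locus coding: delta changes sign
        g3, e3 = _panel_from_design([1 - a, b], y)
        assert v.interaction_contrast(v.gp_map(e3, g3, "ph1", ["m0", "m1"])).delta == pytest.approx(-d0)
        # flip both codings: delta is unchanged
        g4, e4 = _panel_from_design([1 - a, 1 - b], y)
        assert v.interaction_contrast(v.gp_map(e4, g4, "ph1", ["m0", "m1"])).delta == pytest.approx(d0)

    def test_missing_class_gives_missing_delta(self):
        a = np.array([0.0, 0.0, 1.0, 1.0, 0.0, 1.0])
        g, e = _panel_from_design([a, a], np.arange(6, dtype=float))
        summ = v.interaction_contrast(v.gp_map(e, g, "ph1", ["m0", "m1"]))
        assert np.isnan(summ.delta)

    def test_delta_recovers_effect_as_noise_shrinks(self):
        errs = []
        for sigma in (0.5, 0.05, 0.005):
            a, b, y = _and_model(n=200, effect=2.0, sigma=sigma, seed=11)
            g, e = _panel_from_design([a, b], y)
            d = v.interaction_contrast(v.gp_map(e, g, "ph1", ["m0", "m1"])).delta
            errs.append(abs(d - 2.0))
        assert errs[0] > errs[2]
        assert errs[2] < 0.01

    def test_contrast_interval_coverage(self):
        # +/- 2 SE around the estimated contrast covers the true effect about
        # 95% of the time over replicates
        hits = 0
        reps = 200
        for r in range(reps):
            a, b, y = _and_model(n=120, effect=2.0, sigma=1.0, seed=1000 + r)
            g, e = _panel_from_design([a, b], y)
            s = v.interaction_contrast(v.gp_map(e, g, "ph1", ["m0", "m1"]))
            if abs(s.delta - 2.0) <= 2 * s.se_delta:
                hits += 1
        assert 0.90 <= hits / reps <= 0.99


class TestConditionalScan:
    def test_modifier_found_within_anchor_subset(self):
        cfg = v.SimConfig(
            n_segregants=109,
            chrom_lengths={"chr1": 410_000, "chr2": 410_000},
            noise_sd=1.0,
            seed=42,
            architectures=[v.Architecture("and_epistasis", [10, 150], effect=2.0)],
        )
        g = v.simulate_genotypes(cfg)
        panels, _ = v.simulate_expression(g, cfg)
        e = panels["glucose"]
        scan, thr = v.conditional_scan(
            e, g, e.phenotype_ids[0], g.marker_ids[10], 1,
            n_permutations=200, target_fdr=0.05, seed=0,
        )
        assert np.isfinite(thr)
        assert scan.p_value[0, 150] <= thr

    def test_zero_carrier_anchor_errors(self, small_panels):
        g, panels, _ = small_panels
        e = panels["glucose"]
        g.calls[:, 0] = 0.0
        with pytest.raises(ValueError, match="carry genotype"):
            v.conditional_scan(e, g, e.phenotype_ids[0], g.marker_ids[0], 1)

    def test_subset_below_minimum_errors(self, small_panels):
        g, panels, _ = small_panels
        e = panels["glucose"]
        g.calls[:, 0] = 0.0
        g.calls[0, 0] = 1.0
        with pytest.raises(ValueError):
            v.conditional_scan(e, g, e.phenotype_ids[0], g.marker_ids[0], 1)


class TestCandidateGenes:
    def _peak(self, pos, chrom="chr1"):
        return v.Peak(
            phenotype_id="ph1", treatment="glucose", test="vQTL",
            chrom=chrom, center_pos=pos, center_p=1e-8,
            member_ids=["m"], member_pos=[pos],
        )

    def test_window_intersection(self, toy_gff):
        ann = read_gff_genes(toy_gff)
        # peak at 12k: gene [5k,8k] is within 10 kb; gene [25k,30k] starts 13 kb away
        assert v.candidate_genes(self._peak(12_000), ann) == ["GENA"]

    def test_empty_annotation(self):
        assert v.candidate_genes(self._peak(12_000), {}) == []

    def test_unannotated_chromosome_warns_empty(self, toy_gff):
        ann = read_gff_genes(toy_gff)
        assert v.candidate_genes(self._peak(12_000, chrom="chr9"), ann) == []

    def test_zero_window_requires_overlap_of_center(self, toy_gff):
        ann = read_gff_genes(toy_gff)
        assert v.candidate_genes(self._peak(6_000), ann, window_bp=0) == ["GENA"]
        assert v.candidate_genes(self._peak(12_000), ann, window_bp=0) == []


class TestScreenPhenotype:
    def test_flags_planted_interaction_pair(self):
        a, b, y = _and_model(n=120, effect=2.0, sigma=0.5, seed=3)
        noise = np.random.default_rng(8).standard_normal(120)
        g, e = _panel_from_design([a, b, (noise > 0).astype(float)], y)
        summaries = v.screen_phenotype(e, g, "ph1", vqtl_markers=["m0"], other_markers=["m1", "m2"])
        by_pair = {frozenset(s.loci): s for s in summaries}
        assert by_pair[frozenset(["m0", "m1"])].flagged
        assert not by_pair[frozenset(["m0", "m2"])].flagged
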