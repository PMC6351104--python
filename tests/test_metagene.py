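"""Metagene positions, profiles, centroid shift and 5'-half statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest

import srnakit as sk
from srnakit.genome import Feature, GeneModel, GenomeBundle, revcomp
from srnakit.metagene import InsufficientDataError, rank_sum_test


def _hits_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["read_id", "chrom", "start", "strand", "length",
                 "first_nt", "n_hits", "weight", "class", "is_best"],
    )


def _hit(read_id, chrom, start, strand, length=22, weight=1.0):
    return (read_id, chrom, start, strand, length, "G", 1, weight, "22G", True)


class TestScalePosition:
    GENE = GeneModel("g", "chr1", 1000, 2000, "+")

    def test_origin(self):
        # antisense 5' end (highest coordinate of a minus-strand read) at TSS
        assert sk.scale_position(1000, 1001, "-", self.GENE) == pytest.approx(0.0)

    def test_midpoint(self):
        assert sk.scale_position(1500, 1501, "-", self.GENE) == pytest.approx(0.5)

    def test_outside_gene_is_an_error(self):
        with pytest.raises(ValueError):
            sk.scale_position(990, 1012, "-", self.GENE)

    def test_sense_read_is_an_error(self):
        with pytest.raises(ValueError):
            sk.scale_position(1100, 1122, "+", self.GENE)

    def test_minus_strand_gene_mirrors_plus(self):
        minus = GeneModel("g", "chr1", 1000, 2000, "-")
        s_plus = sk.scale_position(1200, 1222, "-", self.GENE)  # 5' end 1221
        # reflected placement on a minus-strand gene: 5' end at 1999 - 221
        s_minus = sk.scale_position(1999 - 221, 1999 - 221 + 22, "+", minus)
        assert s_minus == pytest.approx(s_plus)


def _reflect_bundle(bundle):
    """Reverse-complement every chromosome and flip all annotations."""
    L = {c: len(s) for c, s in bundle.sequences.items()}
    seqs = {c: revcomp(s) for c, s in bundle.sequences.items()}
    flip = lambda st: "-" if st == "+" else "+"

    def fgene(g):
        return GeneModel(g.id, g.chrom, L[g.chrom] - g.end, L[g.chrom] - g.start,
                         flip(g.strand))

    def ffeat(f):
        return Feature(f.id, f.chrom, L[f.chrom] - f.end, L[f.chrom] - f.start,
                       flip(f.strand), f.kind)

    return GenomeBundle(
        seqs,
        [fgene(g) for g in bundle.genes],
        [ffeat(f) for f in bundle.ncrnas],
        [ffeat(f) for f in bundle.mirnas],
        [ffeat(f) for f in bundle.pirna_loci],
        bundle.target_sets,
    ), L


class TestBuildProfile:
    def test_point_mass(self, small_bundle):
        g = next(g for g in small_bundle.genes if g.strand == "+")
        # antisense read at the very start of the gene; 5' end offset 21
        hits = _hits_frame([_hit("r1", g.chrom, g.start, "-")])
        prof = sk.build_profile(hits, small_bundle, {g.id})
        s = 21 / g.length
        assert prof.density[int(s * prof.B)] == pytest.approx(1.0)
        assert prof.per_gene_centroids[g.id] == pytest.approx(s)

    def test_two_point_masses_centroid_half(self, small_bundle):
        g = next(g for g in small_bundle.genes if g.strand == "+" and g.length >= 1000)
        o1, o2 = int(0.25 * g.length), int(0.75 * g.length)
        hits = _hits_frame(
            [_hit("r1", g.chrom, g.start + o1 - 21, "-"),
             _hit("r2", g.chrom, g.start + o2 - 21, "-")]
        )
        prof = sk.build_profile(hits, small_bundle, {g.id})
        assert prof.per_gene_centroids[g.id] == pytest.approx((o1 + o2) / 2 / g.length)
        assert abs(prof.aggregate_centroid - 0.5) < 0.01

    def test_uniform_positions_centroid_half(self):
        genome = {"chr1": "A" * 11000}
        gene = GeneModel("g", "chr1", 500, 10500, "+")
        bundle = GenomeBundle(genome, [gene])
        rng = np.random.default_rng(41)
        s = rng.random(100_000)
        offsets = np.clip((s * gene.length).astype(int), 21, gene.length - 1)
        hits = _hits_frame(
            [_hit(f"r{i}", "chr1", int(gene.start + o - 21), "-")
             for i, o in enumerate(offsets)]
        )
        prof = sk.build_profile(hits, bundle, {"g"})
        assert abs(prof.aggregate_centroid - 0.5) < 0.005
        assert prof.density.sum() == pytest.approx(1.0)

    def test_empty_gene_set_is_an_error(self, small_bundle):
        with pytest.raises(ValueError):
            sk.build_profile(_hits_frame([]), small_bundle, set())

    def test_reflection_invariance(self, small_bundle, small_index):
        cfg = sk.SimulationConfig(depth=3000, seed=42, class_mixture={"22G": 1.0})
        reads, _ = sk.simulate_small_rna_library(small_bundle, cfg, "WT")
        inserts, _ = sk.process_reads(reads, barcode=cfg.barcode)
        hits, _ = sk.classify_library(inserts, small_bundle, small_index)
        gene_set = [g.id for g in small_bundle.genes]
        prof = sk.build_profile(hits, small_bundle, gene_set)

        refl, L = _reflect_bundle(small_bundle)
        rhits = hits.copy()
        rhits["start"] = rhits["chrom"].map(L) - (rhits["start"] + rhits["length"])
        rhits["strand"] = rhits["strand"].map({"+": "-", "-": "+"})
        rprof = sk.build_profile(rhits, refl, gene_set)
        assert np.allclose(prof.density, rprof.density)
        assert prof.per_gene_centroids.equals(rprof.per_gene_centroids)


class TestCentroidShift:
    def test_identical_profiles(self, small_bundle, small_index):
        cfg = sk.SimulationConfig(depth=2000, seed=43, class_mixture={"22G": 1.0})
        reads, _ = sk.simulate_small_rna_library(small_bundle, cfg, "WT")
        inserts, _ = sk.process_reads(reads, barcode=cfg.barcode)
        hits, _ = sk.classify_library(inserts, small_bundle, small_index)
        prof = sk.build_profile(hits, small_bundle, [g.id for g in small_bundle.genes])
        res = sk.centroid_shift_test(prof, prof)
        assert res.shift == 0.0
        assert res.wilcoxon_p > 0.9

    def test_insufficient_data(self, small_bundle):
        g = small_bundle.genes[0]
        hits = _hits_frame([_hit("r1", g.chrom, g.start + 30, "-" if g.strand == "+" else "+")])
        prof = sk.build_profile(hits, small_bundle, [g.id for g in small_bundle.genes])
        with pytest.raises(InsufficientDataError):
            sk.centroid_shift_test(prof, prof)

    def test_small_sample_exact_p_matches_enumeration(self):
        rng = np.random.default_rng(44)
        for _ in range(5):
            x = rng.normal(size=5)
            y = rng.normal(size=6) + rng.uniform(0, 1)
            combined = np.concatenate([x, y])
            ranks = combined.argsort().argsort() + 1
            n1 = len(x)
            obs = ranks[:n1].sum()
            sums = [
                sum(ranks[list(c)]) for c in itertools.combinations(range(len(combined)), n1)
            ]
            sums = np.array(sums)
            upper = (sums >= obs).mean()
            lower = (sums <= obs).mean()
            expected = min(1.0, 2 * min(upper, lower))
            assert rank_sum_test(x, y) == pytest.approx(expected, abs=1e-12)


class TestFivePrimeHalf:
    def test_identical_is_zero_reduction(self):
        wt = np.array([3.0, 5.0, 2.0, 8.0])
        res = sk.five_prime_half_test(wt, wt.copy())
        assert res.percent_reduction == 0.0
        assert res.t_p == 1.0

    def test_total_loss_is_full_reduction(self):
        res = sk.five_prime_half_test(np.array([4.0, 6.0]), np.zeros(2))
        assert res.percent_reduction == 100.0

    def test_zero_wildtype_mass_is_an_error(self):
        with pytest.raises(ValueError):
            sk.five_prime_half_test(np.zeros(3), np.ones(3))

    def test_planted_two_fold_5p_depletion(self, small_bundle, small_index):
        n_genes = len(small_bundle.genes)
        depl = {g.id: 0.5 for g in small_bundle.genes[:4]}
        cfg = sk.SimulationConfig(depth=40_000, seed=45,
                                  class_mixture={"22G": 1.0}, depleted_genes=depl)
        target = sorted(depl)

        def half(genotype):
            reads, _ = sk.simulate_small_rna_library(small_bundle, cfg, genotype)
            inserts, _ = sk.process_reads(reads, barcode=cfg.barcode)
            hits, stats = sk.classify_library(inserts, small_bundle, small_index)
            return sk.five_prime_half_mass(hits, small_bundle, target, depth=stats.depth)

        res = sk.five_prime_half_test(half("WT"), half("MUT"))
        # the planted ratio, corrected for sampling-weight renormalization
        renorm = (n_genes - len(depl) + 0.5 * len(depl)) / n_genes
        expected = 100.0 * (1 - 0.5 / renorm)
        assert abs(res.percent_reduction - expected) < 5.0
        assert res.t_p < 0.05
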