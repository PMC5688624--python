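"""IR estimator, filters, FPKM, gene aggregation, and coverage QC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from irkit import quantify as Q
from irkit import simulate as sim
from irkit.annotation import Intron
from irkit.quantify import CoverageStore, IRCall, JunctionCounts


def make_intron(start=200, end=500, intron_id="t.i1", strand="+"):
    return Intron(
        id=intron_id, chrom="chr1", start=start, end=end, strand=strand,
        gene_id="g", transcript_id="t", index=1, n_introns_in_transcript=1,
    )


class TestTrimmedMean:
    def test_constant_vector_is_unchanged(self):
        assert Q.trimmed_mean([7] * 50, 0.2) == 7.0

    def test_trim_removes_one_value_per_tail(self):
        assert Q.trimmed_mean([0, 0, 0, 0, 100], 0.2) == 0.0

    def test_empty_vector_raises(self):
        with pytest.raises(ValueError):
            Q.trimmed_mean([])

    @given(
        seed=st.integers(min_value=0, max_value=300),
        trim=st.floats(min_value=0, max_value=0.49),
    )
    @settings(max_examples=40, deadline=None)
    def test_matches_sort_and_slice_oracle(self, seed, trim):
        rng = np.random.default_rng(seed)
        v = rng.integers(0, 1000, size=int(rng.integers(1, 200)))
        k = int(trim * v.size)
        expected = float(np.mean(np.sort(v)[k : v.size - k]))
        assert Q.trimmed_mean(v, trim) == pytest.approx(expected)


class TestSpliceDepth:
    def test_exact_boundary_junction_counts(self):
        jx = JunctionCounts()
        jx.add("chr1", 200, 500, "+", 12)
        d, internal = Q.splice_depth(jx, make_intron())
        assert d == 12 and internal == []

    def test_internal_junction_recorded_not_counted(self):
        jx = JunctionCounts()
        jx.add("chr1", 250, 400, "+", 5)
        d, internal = Q.splice_depth(jx, make_intron())
        assert d == 0
        assert internal == [(250, 400, 5)]


class TestIrRatio:
    def cov(self, exon_depth=50, intron_depth=0, length=700):
        depth = np.full(length, exon_depth)
        depth[200:500] = intron_depth
        return CoverageStore({"chr1": depth})

    def flanks(self):
        return ((0, 200), (500, 700))

    def test_empty_intron_gives_zero(self):
        jx = JunctionCounts()
        jx.add("chr1", 200, 500, "+", 20)
        call = Q.compute_ir_ratio(make_intron(), self.flanks(), self.cov(), jx)
        assert call.ir_ratio == 0.0

    def test_equal_depth_gives_one(self):
        jx = JunctionCounts()
        call = Q.compute_ir_ratio(
            make_intron(), self.flanks(), self.cov(intron_depth=50), jx
        )
        assert call.ir_ratio == 1.0

    def test_zero_exon_median_gives_zero(self):
        call = Q.compute_ir_ratio(
            make_intron(), self.flanks(), self.cov(exon_depth=0), JunctionCounts()
        )
        assert call.ir_ratio == 0.0

    def test_internal_splicing_flagged_at_min_reads(self):
        jx = JunctionCounts()
        jx.add("chr1", 250, 400, "+", 2)
        call = Q.compute_ir_ratio(
            make_intron(), self.flanks(), self.cov(intron_depth=25), jx
        )
        assert call.internal_splicing_detected
        jx2 = JunctionCounts()
        jx2.add("chr1", 250, 400, "+", 1)
        call2 = Q.compute_ir_ratio(
            make_intron(), self.flanks(), self.cov(intron_depth=25), jx2
        )
        assert not call2.internal_splicing_detected

    def test_missing_flank_is_structural_error(self):
        with pytest.raises(ValueError, match="flanking"):
            Q.flanking_exons([(0, 100), (150, 300)], make_intron())

    def test_monotone_in_intron_depth(self):
        jx = JunctionCounts()
        last = -1.0
        for d in (0, 5, 10, 25, 40, 50, 60):
            call = Q.compute_ir_ratio(
                make_intron(), self.flanks(), self.cov(intron_depth=d), jx
            )
            assert call.ir_ratio >= last
            last = call.ir_ratio
        assert last == 1.0  # clamped

    def test_parameter_recovery_at_depth(self):
        rng = np.random.default_rng(0)
        est = []
        for _ in range(50):
            depth = np.concatenate(
                [
                    rng.poisson(100, 200),
                    rng.poisson(20, 300),
                    rng.poisson(100, 200),
                ]
            )
            cov = CoverageStore({"chr1": depth})
            jx = JunctionCounts()
            jx.add("chr1", 200, 500, "+", int(rng.poisson(40)))
            call = Q.compute_ir_ratio(make_intron(), self.flanks(), cov, jx)
            est.append(call.ir_ratio)
        assert abs(np.mean(est) - 0.2) < 0.03


class TestFilters:
    def call(self, ratio=0.5, sdepth=10, tmean=20.0, internal=False):
        return IRCall(
            intron_id="x",
            ir_ratio=ratio,
            splice_depth=sdepth,
            intron_depth_trimmed_mean=tmean,
            flank_exon_median_depth=50.0,
            internal_splicing_detected=internal,
        )

    def test_ratio_below_threshold_is_not_retained(self):
        part = Q.filter_ir_calls([self.call(ratio=0.09)])
        assert len(part["not_retained"]) == 1

    def test_ratio_at_threshold_is_retained(self):
        part = Q.filter_ir_calls([self.call(ratio=0.1)])
        assert len(part["retained"]) == 1

    def test_splice_depth_3_is_unmeasurable(self):
        part = Q.filter_ir_calls([self.call(sdepth=3)])
        (c,) = part["unmeasurable"]
        assert "splicing depth" in c.filter_reasons

    def test_splice_depth_4_passes_depth_filter(self):
        part = Q.filter_ir_calls([self.call(sdepth=4, tmean=6.0)])
        assert len(part["retained"]) == 1

    def test_coverage_sum_boundary(self):
        part = Q.filter_ir_calls([self.call(sdepth=4, tmean=5.9)])
        (c,) = part["unmeasurable"]
        assert "coverage" in c.filter_reasons
        part2 = Q.filter_ir_calls([self.call(sdepth=4, tmean=6.0)])
        assert len(part2["retained"]) == 1

    def test_internal_splicing_voids_the_call(self):
        part = Q.filter_ir_calls([self.call(internal=True)])
        assert len(part["unmeasurable"]) == 1

    def test_filtering_is_idempotent(self):
        calls = [
            self.call(ratio=0.05),
            self.call(sdepth=2),
            self.call(),
            self.call(internal=True),
        ]
        once = Q.filter_ir_calls(calls)
        twice = {
            k: Q.filter_ir_calls(v) for k, v in once.items()
        }
        for k in once:
            assert [c.intron_id for c in twice[k][k]] == [
                c.intron_id for c in once[k]
            ]


class TestFpkm:
    def test_definition(self):
        out = Q.compute_fpkm({"g": 1000}, {"g": 1.0}, 10**6)
        assert out["g"] == 1000.0

    def test_zero_reads(self):
        assert Q.compute_fpkm({"g": 0}, {"g": 2.0}, 10**6)["g"] == 0.0

    def test_rank_correlates_with_planted_expression(self, small_sim):
        from scipy.stats import spearmanr

        truth, ann, cov = (
            small_sim["truth"],
            small_sim["ann"],
            small_sim["cov"],
        )
        est = sim.estimate_fpkm_from_coverage(
            ann, cov, small_sim["cfg"].coverage_per_fpkm
        )
        gids = sorted(est)
        rho = spearmanr(
            [est[g] for g in gids], [truth.expression[g] for g in gids]
        ).statistic
        assert rho > 0.95


class TestGeneAggregation:
    def gene_ir(self, ratios, fpkm=5.0):
        calls = [
            IRCall(
                intron_id=f"i{k}",
                ir_ratio=r,
                splice_depth=20,
                intron_depth_trimmed_mean=30.0,
                flank_exon_median_depth=50.0,
            )
            for k, r in enumerate(ratios)
        ]
        return Q.aggregate_gene_ir({"g": calls}, {"g": fpkm})["g"]

    def test_gene_ratio_is_max_over_retained(self):
        g = self.gene_ir([0.15, 0.4])
        assert g.gene_ir_ratio == 0.4 and g.n_retained == 2

    def test_expressed_gene_without_retention_is_not_ir(self):
        g = self.gene_ir([0.05, 0.0])
        assert g.is_expressed and not g.is_ir_gene and g.gene_ir_ratio == 0.0

    def test_unexpressed_gene_is_never_ir(self):
        g = self.gene_ir([0.5], fpkm=0.5)
        assert not g.is_expressed and not g.is_ir_gene

    def test_planted_ir_fraction_recovered(self, small_sim):
        frac = Q.ir_gene_fraction(small_sim["gene_irs"])
        truth = small_sim["truth"]
        planted = sum(truth.is_ir_gene.values()) / sum(
            truth.is_expressed.values()
        )
        assert abs(frac - planted) <= 0.02


class TestGeneBodyCoverage:
    def test_uniform_coverage_is_flat(self, small_sim):
        profile = Q.gene_body_coverage(
            small_sim["cov"], small_sim["ann"],
            gene_ids={g for g, gi in small_sim["gene_irs"].items()
                      if gi.is_expressed and gi.fpkm > 10},
        )
        assert profile.max() == 1.0
        assert profile.min() > 0.90

    def test_planted_three_prime_ramp_is_monotone(self):
        from tests.conftest import make_annotation, make_gene

        g = make_gene(exons=[(0, 2000)])
        ann = make_annotation(g)
        cov = CoverageStore({"chr1": np.arange(2000, dtype=np.int64)})
        profile = Q.gene_body_coverage(cov, ann, n_bins=20)
        assert (np.diff(profile) > 0).all()

    def test_minus_strand_profile_follows_transcript(self):
        from tests.conftest import make_annotation, make_gene

        g = make_gene(strand="-", exons=[(0, 2000)])
        ann = make_annotation(g)
        cov = CoverageStore({"chr1": np.arange(2000, dtype=np.int64)})
        profile = Q.gene_body_coverage(cov, ann, n_bins=20)
        # genomic ramp toward 3' on the genome = toward 5' of a minus gene
        assert (np.diff(profile) < 0).all()


class TestEvidenceIO:
    def test_coverage_tsv_round_trip(self, tmp_path, small_sim):
        cov = small_sim["cov"]
        p = tmp_path / "cov.tsv"
        cov.to_tsv(p)
        chrom = small_sim["cfg"].chrom
        cov2 = CoverageStore.from_tsv(p, small_sim["ann"].chrom_lengths)
        n = small_sim["ann"].chrom_lengths[chrom]
        assert np.array_equal(cov.get(chrom, 0, n), cov2.get(chrom, 0, n))

    def test_junction_tsv_round_trip(self, tmp_path, small_sim):
        jx = small_sim["jx"]
        p = tmp_path / "jx.tsv"
        jx.to_tsv(p)
        jx2 = JunctionCounts.from_tsv(p)
        assert jx.counts == jx2.counts

    def test_sam_ingestion_recovers_planted_retention(self, tmp_path):
        cfg = sim.SimConfig(n_genes=25, rng_seed=42)
        ann, _, truth = sim.generate_annotation_and_genome(cfg)
        sam = tmp_path / "reads.sam"
        sim.emit_sam(ann, truth, cfg, sam)
        cov, jx, n_reads = Q.evidence_from_alignments(sam, ann.chrom_lengths)
        assert n_reads > 0
        fpkm = sim.estimate_fpkm_from_coverage(ann, cov, cfg.coverage_per_fpkm)
        calls, gene_irs = Q.quantify_annotation(ann, cov, jx, fpkm=fpkm)
        errs = [
            abs(c.ir_ratio - truth.rho.get(c.intron_id, 0.0))
            for g, cl in calls.items()
            for c in cl
            if truth.expression[g] > 10
        ]
        assert np.mean(errs) < 0.05
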