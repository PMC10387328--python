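import pytest

from ecdnatk import finder
from ecdnatk.model import (
    ConsensusEcDNA,
    CircleCandidate,
    SupportRead,
    GeneModel,
    SVRecord,
)
from conftest import ai, chain
import oracles


def _junc(chains):
    out = []
    for c in chains:
        out.extend(finder.chain_to_junctions(c))
    return out


class TestRefineChain:
    def test_single_interval_unchanged(self):
        c = chain((0, 5000, "chr1", 10_000, 15_000))
        assert finder.refine_chain(c).intervals == c.intervals

    def test_lowalign_99bp_removed_100_kept(self):
        base = [(0, 2000, "chr1", 0, 2000), (2100, 4000, "chr1", 5000, 6900)]
        c99 = chain(base[0], (2000, 2099, "chr2", 0, 99), base[1])
        c100 = chain(base[0], (2000, 2100, "chr2", 0, 100), base[1])
        assert len(finder.refine_chain(c99)) == 2
        assert len(finder.refine_chain(c100)) == 3

    def test_over_read_space_containment_merged(self):
        # second alignment redundantly re-maps read bases [500,900)
        c = chain(
            (0, 2000, "chr1", 0, 2000),
            (500, 900, "chr2", 50_000, 50_400),
            (2000, 3500, "chr1", 5000, 6500),
        )
        refined = finder.refine_chain(c)
        assert len(refined) == 2
        assert {iv.ref_start for iv in refined} == {0, 5000}

    def test_genomic_containment_of_multipass_read_is_kept(self):
        # a read walking a 3-kb circle twice: the full-length middle pass
        # genomically contains both flanking pieces but must survive
        c = chain(
            (0, 1000, "chr1", 2000, 3000),
            (1000, 4000, "chr1", 0, 3000),
            (4000, 6000, "chr1", 0, 2000),
        )
        assert len(finder.refine_chain(c)) == 3

    def test_duplic_drops_shorter_near_duplicate(self):
        c = chain(
            (0, 800, "chr1", 10_000, 10_800),
            (800, 1500, "chr1", 10_100, 10_900),  # both ends within 500
        )
        refined = finder.refine_chain(c)
        assert len(refined) == 1
        assert refined.intervals[0].read_length == 800

    def test_duplic_guard_keeps_long_repeats(self):
        # near-identical 2-kb passes are multi-pass circle evidence
        c = chain(
            (0, 2000, "chr1", 10_000, 12_000),
            (2000, 4000, "chr1", 10_050, 12_050),
        )
        assert len(finder.refine_chain(c)) == 2

    def test_duplic_tolerance_strict_500(self):
        c = chain(
            (0, 800, "chr1", 10_000, 10_800),
            (800, 1600, "chr1", 10_500, 11_300),  # start offset exactly 500
        )
        assert len(finder.refine_chain(c)) == 2

    def test_five_interval_chain_matches_hand_oracle(self):
        spec = [
            (0, 1200, "chr1", 0, 1200),
            (1150, 1220, "chr2", 7000, 7070),       # LOWALIGN (70 bp)
            (1200, 2600, "chr1", 20_000, 21_400),
            (2600, 3200, "chr1", 20_100, 21_000),   # DUPLIC of previous
            (3200, 5200, "chr2", 40_000, 42_000),
        ]
        c = chain(*spec)
        refined = finder.refine_chain(c)
        dicts = [
            dict(read_start=a, read_end=b, chrom=ch, ref_start=s, ref_end=e, strand="+")
            for a, b, ch, s, e in spec
        ]
        expected = oracles.bf_refine(dicts)
        got = [
            dict(read_start=v.read_start, read_end=v.read_end, chrom=v.chrom,
                 ref_start=v.ref_start, ref_end=v.ref_end, strand=v.strand)
            for v in refined.intervals
        ]
        assert got == expected
        assert len(got) == 3

    def test_empty_chain_allowed(self):
        c = chain()
        assert len(finder.refine_chain(c)) == 0


class TestChainToJunctions:
    def test_reversal_is_circular(self):
        c = chain((0, 6000, "chr1", 100_000, 106_000), (6000, 12_000, "chr1", 50_000, 56_000))
        (j,) = finder.chain_to_junctions(c)
        assert j.kind == "circular"
        assert (j.pos_a, j.orient_a) == (50_000, "head")
        assert (j.pos_b, j.orient_b) == (106_000, "tail")

    def test_forward_jump_is_linear(self):
        c = chain((0, 1000, "chr1", 1000, 2000), (1000, 2000, "chr1", 5000, 6000))
        (j,) = finder.chain_to_junctions(c)
        assert j.kind == "linear"
        assert (j.pos_a, j.orient_a) == (2000, "tail")
        assert (j.pos_b, j.orient_b) == (5000, "head")

    def test_wrap_twice_gives_two_circular_junctions(self):
        # read wrapping a 4-kb circle [10k,14k) twice; the fragment after
        # the full middle pass restarts at the same head coordinate, which
        # still marks an origin crossing
        c = chain(
            (0, 2000, "chr1", 12_000, 14_000),
            (2000, 6000, "chr1", 10_000, 14_000),
            (6000, 8000, "chr1", 10_000, 12_000),
        )
        js = finder.chain_to_junctions(c)
        assert [j.kind for j in js] == ["circular", "circular"]
        assert {(j.pos_a, j.pos_b) for j in js} == {(10_000, 14_000)}

    def test_minus_strand_reversal(self):
        # on '-' the genomic order along the read decreases; an increase
        # of ref_start marks the circular wrap
        c = chain(
            (0, 2000, "chr1", 10_000, 12_000, "-"),
            (2000, 4000, "chr1", 12_000, 14_000, "-"),
        )
        (j,) = finder.chain_to_junctions(c)
        assert j.kind == "circular"
        assert (j.pos_a, j.pos_b) == (10_000, 14_000)

    def test_cross_chromosome_is_linear(self):
        c = chain((0, 1000, "chr1", 1000, 2000), (1000, 2000, "chr2", 5000, 6000))
        (j,) = finder.chain_to_junctions(c)
        assert j.kind == "linear"


class TestClusterBreakpoints:
    def _single(self, positions, orient="head", chrom="chr1"):
        # one circular junction per position, paired with a far-away end
        chains = []
        for k, p in enumerate(positions):
            chains.append(
                chain(
                    (0, 2000, chrom, 90_000, 92_000),
                    (2000, 4000, chrom, p, p + 2000),
                    read_id=f"r{k}",
                )
            )
        return _junc(chains)

    def test_499_apart_one_cluster(self):
        js = self._single([10_000, 10_499])
        heads = [c for c in finder.cluster_breakpoints(js) if c.orientation == "head"]
        assert len(heads) == 1
        assert heads[0].span == 499

    def test_500_apart_two_clusters(self):
        js = self._single([10_000, 10_500])
        heads = [c for c in finder.cluster_breakpoints(js) if c.orientation == "head"]
        assert len(heads) == 2

    def test_different_orientation_not_merged(self):
        c1 = chain((0, 2000, "chr1", 50_000, 52_000), (2000, 4000, "chr1", 10_000, 12_000))
        js = finder.chain_to_junctions(c1)
        # head endpoint at 10_000 and tail endpoint at 52_000; inject a
        # tail exactly at 10_000 via a second read
        c2 = chain(
            (0, 2000, "chr1", 8_000, 10_000),
            (2000, 4000, "chr1", 2_000, 4_000),
            read_id="r2",
        )
        js += finder.chain_to_junctions(c2)
        clusters = finder.cluster_breakpoints(js)
        at_10k = [c for c in clusters if c.position == 10_000]
        assert {c.orientation for c in at_10k} == {"head", "tail"}
        assert len(at_10k) == 2

    def test_median_representative(self):
        js = self._single([10_000, 10_040, 10_400])
        heads = [c for c in finder.cluster_breakpoints(js) if c.orientation == "head"]
        assert len(heads) == 1
        assert heads[0].position == 10_040

    def test_nearest_neighbour_link(self):
        js = self._single([10_000])
        clusters = finder.cluster_breakpoints(js)
        by_pos = {(c.chrom, c.orientation, c.position): c for c in clusters}
        head = by_pos[("chr1", "head", 10_000)]
        tail = by_pos[("chr1", "tail", 92_000)]
        assert head.link == tail.id
        assert tail.link == head.id


class TestDetectCircles:
    def test_no_circular_junctions_empty(self):
        c = chain((0, 1000, "chr1", 1000, 2000), (1000, 2000, "chr1", 5000, 6000))
        js = _junc([c])
        clusters = finder.cluster_breakpoints(js)
        assert finder.detect_circles(clusters, js, [c]) == []

    def test_single_fragment_circle(self):
        chains = [
            chain(
                (0, 2000, "chr1", 12_000 - 80 * k, 14_000),
                (2000, 4000, "chr1", 10_000, 12_000 + 90 * k),
                read_id=f"r{k}",
            )
            for k in range(4)
        ]
        js = _junc(chains)
        clusters = finder.cluster_breakpoints(js)
        (cand,) = finder.detect_circles(clusters, js, chains)
        assert cand.n_fragments == 1
        chrom, head, tail = cand.cyclization_site
        assert chrom == "chr1"
        assert abs(head - 10_000) <= 500 and abs(tail - 14_000) <= 500
        assert len(cand.support_reads) == 4

    def test_two_fragment_cross_chromosome_circle(self):
        # circle = chr1:[20k,26k) + chr2:[40k,44k); reads traverse
        # F1 tail -> F2 head and F2 tail -> F1 head
        chains = [
            chain(
                (0, 3000, "chr1", 23_000, 26_000),
                (3000, 7000, "chr2", 40_000, 44_000),
                (7000, 9000, "chr1", 20_000, 22_000),
                read_id=f"r{k}",
            )
            for k in range(3)
        ]
        js = _junc(chains)
        clusters = finder.cluster_breakpoints(js)
        (cand,) = finder.detect_circles(clusters, js, chains)
        assert cand.n_fragments == 2
        frags = {(c, s, e) for c, s, e, _ in cand.fragments}
        assert ("chr1", 20_000, 26_000) in frags
        assert ("chr2", 40_000, 44_000) in frags

    def test_same_chromosome_cycle_needs_circular_evidence(self):
        # two deletion-like linear junctions on one chromosome can close a
        # graph cycle but must not be reported without a circular junction
        chains = [
            chain((0, 2000, "chr1", 10_000, 12_000), (2000, 4000, "chr1", 20_000, 22_000),
                  read_id="r1"),
            chain((0, 2000, "chr1", 10_500, 12_400), (2000, 4000, "chr1", 19_800, 21_800),
                  read_id="r2"),
        ]
        js = _junc(chains)
        clusters = finder.cluster_breakpoints(js)
        assert finder.detect_circles(clusters, js, chains) == []


def _cand(chrom, head, tail, reads=3, cell="c1", jitter=0):
    return CircleCandidate(
        fragments=[(chrom, head, tail, "+")],
        cyclization_site=(chrom, head, tail),
        support_reads=[
            SupportRead(f"{cell}:r{k}", cell, head, tail,
                        head - 300 - 20 * k - jitter, tail + 250 + 30 * k + jitter)
            for k in range(reads)
        ],
        cell_id=cell,
    )


class TestFilterRepeats:
    def test_empty_track_keeps_all(self):
        cands = [_cand("chr1", 10_000, 18_000)]
        assert finder.filter_repeats(cands, {}) == cands

    def test_overlap_30_removed_29_kept(self):
        cand = _cand("chr1", 10_000, 18_000)
        # head flank is [10_000, 10_300)
        assert finder.filter_repeats([cand], {"chr1": [(10_270, 10_400)]}) == []
        assert finder.filter_repeats([cand], {"chr1": [(10_271, 10_400)]}) == [cand]

    def test_exclusive_mode(self):
        cand = _cand("chr1", 10_000, 18_000)
        track = {"chr1": [(10_270, 10_400)]}  # exactly 30 bp in the flank
        assert finder.filter_repeats([cand], track, inclusive=False) == [cand]

    def test_tail_flank_checked(self):
        cand = _cand("chr1", 10_000, 18_000)
        # tail flank is [17_700, 18_000)
        assert finder.filter_repeats([cand], {"chr1": [(17_700, 17_740)]}) == []

    def test_flanks_are_summed(self):
        cand = _cand("chr1", 10_000, 18_000)
        track = {"chr1": [(17_980, 18_020)]}  # only 20 bp inside the flank
        assert finder.filter_repeats([cand], track) == [cand]


class TestFilterSvProximity:
    def test_no_svs_unchanged(self):
        cands = [_cand("chr1", 10_000, 18_000)]
        assert finder.filter_sv_proximity(cands, []) == cands

    def test_within_500_removed(self):
        cand = _cand("chr1", 10_000, 18_000)
        sv = SVRecord("DEL", "chr1", 10_400, "chr1", 60_000, 49_600, "PRECISE", 5)
        assert finder.filter_sv_proximity([cand], [sv]) == []

    def test_exactly_500_removed_501_kept(self):
        cand = _cand("chr1", 10_000, 18_000)
        sv500 = SVRecord("INS", "chr1", 10_500, "chr1", 10_500, 300, "PRECISE", 5)
        sv501 = SVRecord("INS", "chr1", 10_501, "chr1", 10_501, 300, "PRECISE", 5)
        assert finder.filter_sv_proximity([cand], [sv500]) == []
        assert finder.filter_sv_proximity([cand], [sv501]) == [cand]

    def test_other_chromosome_ignored(self):
        cand = _cand("chr1", 10_000, 18_000)
        sv = SVRecord("TRA", "chr2", 10_000, "chr3", 18_000, 0, "PRECISE", 5)
        assert finder.filter_sv_proximity([cand], [sv]) == [cand]


class TestDedupAndSupport:
    def test_exact_duplicates_collapsed(self):
        reads = [
            SupportRead("r1", "c1", 100, 900, 50, 950),
            SupportRead("r2", "c1", 100, 900, 55, 945),   # within 10 bp both ends
            SupportRead("r3", "c1", 100, 900, 300, 700),  # distinct molecule
            SupportRead("r4", "c1", 100, 900, 52, 948),   # dup of r1/r2
        ]
        assert len(finder.dedup_support(reads)) == 2

    def test_tolerance_boundary_10_vs_11(self):
        a = SupportRead("r1", "c1", 100, 900, 50, 950)
        b10 = SupportRead("r2", "c1", 100, 900, 60, 960)
        b11 = SupportRead("r3", "c1", 100, 900, 61, 961)
        assert len(finder.dedup_support([a, b10])) == 1
        assert len(finder.dedup_support([a, b11])) == 2

    def test_different_cells_never_deduplicated(self):
        a = SupportRead("r1", "c1", 100, 900, 50, 950)
        b = SupportRead("r2", "c2", 100, 900, 50, 950)
        assert len(finder.dedup_support([a, b])) == 2

    def test_different_junction_not_deduplicated(self):
        a = SupportRead("r1", "c1", 100, 900, 50, 950)
        b = SupportRead("r2", "c1", 101, 900, 50, 950)
        assert len(finder.dedup_support([a, b])) == 2

    def test_filter_support_2_removed_3_kept(self):
        assert finder.filter_support([_cand("chr1", 1000, 9000, reads=2)]) == []
        kept = finder.filter_support([_cand("chr1", 1000, 9000, reads=3)])
        assert len(kept) == 1

    def test_filter_support_dedup_first(self):
        cand = _cand("chr1", 1000, 9000, reads=3)
        dup = SupportRead("c1:dup", "c1", 1000, 9000,
                          cand.support_reads[0].outer_start + 3,
                          cand.support_reads[0].outer_end - 2)
        cand.support_reads.append(dup)
        (kept,) = finder.filter_support([cand])
        assert len(finder.dedup_support(kept.support_reads)) == 3


class TestMergeConsensus:
    def test_within_500_both_ends_merged(self):
        a = _cand("chr1", 10_000, 18_000, cell="c1")
        b = _cand("chr1", 10_400, 18_300, cell="c2")
        (m,) = finder.merge_consensus([a, b])
        # a spans 8000 bp, b spans 7900 bp: the longer member is the rep
        assert m.cyclization_site == ("chr1", 10_000, 18_000)
        assert len(m.support_reads) == 6

    def test_head_600_apart_not_merged(self):
        a = _cand("chr1", 10_000, 18_000)
        b = _cand("chr1", 10_600, 18_000, cell="c2")
        assert len(finder.merge_consensus([a, b])) == 2

    def test_exactly_500_not_merged(self):
        a = _cand("chr1", 10_000, 18_000)
        b = _cand("chr1", 10_500, 18_000, cell="c2")
        assert len(finder.merge_consensus([a, b])) == 2

    def test_single_linkage_chain(self):
        a = _cand("chr1", 10_000, 18_000, cell="c1")
        b = _cand("chr1", 10_400, 18_400, cell="c2")
        c = _cand("chr1", 10_800, 18_800, cell="c3")  # a-c are 800 apart
        merged = finder.merge_consensus([a, b, c])
        assert len(merged) == 1

    def test_ids_deterministically_ordered(self):
        a = _cand("chr2", 10_000, 18_000)
        b = _cand("chr1", 30_000, 40_000)
        merged = finder.merge_consensus([a, b])
        assert [m.id for m in merged] == ["ecDNA_0001", "ecDNA_0002"]
        assert merged[0].cyclization_site[0] == "chr1"


class TestQuantify:
    def _setup(self):
        cand_a = _cand("chr1", 10_000, 18_000, reads=3, cell="c1")
        cand_b = _cand("chr1", 10_000, 18_000, reads=2, cell="c2")
        (cons,) = finder.merge_consensus([cand_a, cand_b])
        chains = []
        for r in cons.support_reads:
            chains.append(
                chain(
                    (0, 2000, "chr1", 16_000, 18_000),
                    (2000, 4000, "chr1", 10_000, 12_000),
                    read_id=r.read_id,
                    cell_id=r.cell_id,
                )
            )
        return cons, chains

    def test_per_cell_support(self):
        cons, chains = self._setup()
        finder.quantify([cons], chains)
        assert cons.per_cell_support == {"c1": 3, "c2": 2}

    def test_coverage_partial(self):
        cons, chains = self._setup()
        finder.quantify([cons], chains)
        # reads cover [10k,12k) and [16k,18k) of an 8-kb circle
        assert cons.per_cell_coverage["c1"] == pytest.approx(0.5)

    def test_full_coverage_one(self):
        cand = _cand("chr1", 10_000, 15_000, reads=1)
        (cons,) = finder.merge_consensus([cand])
        full = [
            chain((0, 5000, "chr1", 10_000, 15_000),
                  read_id=cons.support_reads[0].read_id, cell_id="c1")
        ]
        finder.quantify([cons], full)
        assert cons.per_cell_coverage["c1"] == pytest.approx(1.0)

    def test_idempotent(self):
        cons, chains = self._setup()
        finder.quantify([cons], chains)
        once = (dict(cons.per_cell_support), dict(cons.per_cell_coverage))
        finder.quantify([cons], chains)
        assert (cons.per_cell_support, cons.per_cell_coverage) == once


class TestAnnotateGenes:
    def _ec(self):
        return ConsensusEcDNA(
            id="e1",
            fragments=[("chr1", 10_000, 18_000, "+")],
            cyclization_site=("chr1", 10_000, 18_000),
        )

    def test_overlap_30_annotated_29_not(self):
        g30 = GeneModel("g1", "G30", "chr1", 9_000, 10_030, "+")
        g29 = GeneModel("g2", "G29", "chr1", 9_000, 10_029, "+")
        (ec,) = finder.annotate_genes([self._ec()], [g30, g29])
        assert ec.genes == ["G30"]

    def test_gene_inside_fragment(self):
        g = GeneModel("g1", "INSIDE", "chr1", 12_000, 13_000, "-")
        (ec,) = finder.annotate_genes([self._ec()], [g])
        assert ec.genes == ["INSIDE"]

    def test_cancer_catalogue(self):
        g = GeneModel("g1", "MYC", "chr1", 12_000, 13_000, "+")
        (ec,) = finder.annotate_genes([self._ec()], [g], cancer_catalogue=["MYC", "EGFR"])
        assert ec.cancer_genes == ["MYC"]


class TestCompareSets:
    def _ec(self, chrom, head, tail):
        return ConsensusEcDNA(
            id="x", fragments=[(chrom, head, tail, "+")],
            cyclization_site=(chrom, head, tail),
        )

    def test_identical_shared(self):
        a = self._ec("chr1", 0, 10_000)
        rep = finder.compare_sets([a], [self._ec("chr1", 0, 10_000)])
        assert len(rep["shared"]) == 1
        assert rep["a_only"] == [] and rep["b_only"] == []

    def test_reciprocal_boundary(self):
        small = self._ec("chr1", 0, 10_000)
        large = self._ec("chr1", 0, 100_000)
        rep = finder.compare_sets([small], [large])
        assert len(rep["shared"]) == 1  # fractions 1.0 and exactly 0.1

    def test_nine_percent_not_shared(self):
        small = self._ec("chr1", 0, 9_000)
        large = self._ec("chr1", 0, 100_000)
        rep = finder.compare_sets([small], [large])
        assert rep["shared"] == []
        assert len(rep["a_only"]) == 1 and len(rep["b_only"]) == 1


class TestMtdnaCopyNumber:
    def test_equal_depth_two_copies(self):
        lengths = {"chr1": 10_000, "chrM": 1_000}
        chains = [
            chain((0, 5000, "chr1", 0, 5000), read_id="r1"),
            chain((0, 500, "chrM", 0, 500), read_id="r2"),
        ]
        assert finder.mtdna_copy_number(chains, lengths) == pytest.approx(2.0)

    def test_fifty_fold_is_100_copies(self):
        lengths = {"chr1": 10_000, "chrM": 1_000}
        chains = [chain((0, 1000, "chr1", 0, 1000), read_id="r0")]
        for k in range(5):
            chains.append(chain((0, 1000, "chrM", 0, 1000), read_id=f"m{k}"))
        # chrM depth 5.0, autosomal 0.1 -> ratio 50 -> 100 copies
        assert finder.mtdna_copy_number(chains, lengths) == pytest.approx(100.0)

    def test_missing_chrm_errors(self):
        with pytest.raises(ValueError, match="chrM"):
            finder.mtdna_copy_number([], {"chr1": 1000})
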