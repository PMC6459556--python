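import numpy as np
import pytest

from ptmap.quantify import (
    AlignedRead,
    SiteCounts,
    apply_threshold,
    control_threshold,
    count_sites,
    icds_detect,
    load_alignments,
    pt_ratio,
    sample_control_windows,
    subsample_depths,
    write_alignments_tsv,
)
from ptmap.reference import PT_MOTIFS, Genome, MotifSite, scan_motifs


def brute_force_counts(reads, sites):
    """Independent per-read, per-site double loop."""
    out = []
    for s in sites:
        ef = sum(1 for r in reads if r.strand == "+" and r.start0 == s.cleave_fwd)
        er = sum(1 for r in reads if r.strand == "-" and r.end0 - 1 == s.cleave_rev)
        sp = sum(1 for r in reads if r.start0 <= s.start0 and r.end0 >= s.start0 + 4)
        out.append((ef, er, sp))
    return out


SITE = MotifSite("r", 1, "GAAC")  # in GGAACGTTCA..., cleave_fwd=2, cleave_rev=3


class TestCountSites:
    def test_forward_ended_read(self):
        counts = count_sites([AlignedRead("r", 2, 150, "+")], [SITE], {"r": 200})[0]
        assert (counts.ended_fwd, counts.ended_rev, counts.spanning) == (1, 0, 0)

    def test_reverse_ended_read(self):
        # reverse read [0,4): 5'-terminal base at 3 = cleave_rev
        counts = count_sites([AlignedRead("r", 0, 4, "-")], [SITE], {"r": 200})[0]
        assert (counts.ended_fwd, counts.ended_rev, counts.spanning) == (0, 1, 0)

    def test_spanning_read(self):
        counts = count_sites([AlignedRead("r", 0, 10, "+")], [SITE], {"r": 200})[0]
        assert counts.spanning == 1 and counts.ended == 0

    def test_partial_overlap_counts_as_neither(self):
        # covers only 3 of the 4 window bases and is not at a cleavage coord
        reads = [AlignedRead("r", 0, 3, "+"), AlignedRead("r", 4, 9, "+")]
        counts = count_sites(reads, [SITE], {"r": 200})[0]
        assert counts.depth == 0

    def test_matches_brute_force_on_random_reads(self):
        rng = np.random.default_rng(42)
        L = 10_000
        starts = rng.integers(0, L - 150, size=10_000)
        lens = rng.integers(30, 151, size=10_000)
        reads = [
            AlignedRead("r", int(a), int(min(a + l, L)), "+" if z else "-")
            for a, l, z in zip(starts, lens, rng.integers(0, 2, size=10_000))
        ]
        sites = [MotifSite("r", int(p), "GAAC") for p in rng.integers(0, L - 4, size=300)]
        got = [(c.ended_fwd, c.ended_rev, c.spanning) for c in count_sites(reads, sites, {"r": L})]
        assert got == brute_force_counts(reads, sites)

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        reads = [
            AlignedRead("r", int(a), int(a) + 50, "+" if z else "-")
            for a, z in zip(rng.integers(0, 500, 200), rng.integers(0, 2, 200))
        ]
        sites = [MotifSite("r", 100, "GAAC"), MotifSite("r", 300, "GTTC")]
        fwd = count_sites(reads, sites, {"r": 600})
        rev = count_sites(list(reversed(reads)), sites, {"r": 600})
        assert [(c.ended_fwd, c.ended_rev, c.spanning) for c in fwd] == [
            (c.ended_fwd, c.ended_rev, c.spanning) for c in rev
        ]

    def test_depth_conserves_counts(self):
        c = SiteCounts(SITE, 3, 4, 10)
        assert c.depth == c.ended_fwd + c.ended_rev + c.spanning == 17


class TestPtRatio:
    @pytest.mark.parametrize(
        "ef,er,sp,expected",
        [(10, 0, 90, 0.10), (0, 0, 50, 0.0), (7, 0, 0, 1.0), (5, 5, 90, 0.1)],
    )
    def test_ratio_values(self, ef, er, sp, expected):
        r = pt_ratio(SiteCounts(SITE, ef, er, sp))
        assert r.ratio == pytest.approx(expected)
        assert r.status == "ok"

    def test_no_coverage_is_undefined_not_zero(self):
        r = pt_ratio(SiteCounts(SITE, 0, 0, 0))
        assert r.ratio is None and r.status == "no_coverage"


class TestControls:
    def test_windows_are_never_motifs(self):
        g = Genome({"r": "GGAACGTTCA" * 100})
        windows = sample_control_windows(g, n_controls=20, seed=1)
        for w in windows:
            assert g["r"][w.start0 : w.start0 + 4] == w.motif
            assert w.motif not in PT_MOTIFS

    def test_threshold_is_mean_of_pseudo_ratios(self):
        g = Genome({"r": "A" * 5000})
        # two reads ending at control coords would give nonzero; with no
        # reads at any control the threshold is exactly 0
        reads = [AlignedRead("r", 0, 150, "+")]
        panel = control_threshold(reads, g, n_controls=5, seed=2)
        assert panel.threshold == pytest.approx(np.mean(panel.ratios))

    def test_no_end_reads_gives_zero_threshold(self):
        g = Genome({"r": "ATGC" * 2000})
        reads = [AlignedRead("r", 0, 8000, "+")]  # spans everything, ends at 0
        panel = control_threshold(reads, g, n_controls=10, seed=3)
        assert panel.threshold == 0.0

    def test_genome_too_small_errors(self):
        with pytest.raises(ValueError):
            sample_control_windows(Genome({"r": "ACG"}), n_controls=2, seed=0)

    def test_apply_threshold_is_strict(self):
        g = Genome({"r": "A" * 5000})
        panel = control_threshold([AlignedRead("r", 0, 150, "+")], g, seed=0)
        panel.threshold = 0.0054
        rs = [
            pt_ratio(SiteCounts(SITE, 5, 0, 95)),     # 0.05 -> pass
            pt_ratio(SiteCounts(SITE, 54, 0, 9946)),  # exactly 0.0054 -> fail
            pt_ratio(SiteCounts(SITE, 0, 0, 100)),    # 0 -> fail
            pt_ratio(SiteCounts(SITE, 0, 0, 0)),      # undefined -> fail
        ]
        apply_threshold(rs, panel)
        assert [r.passes_threshold for r in rs] == [True, False, False, False]


class TestIcdsDetect:
    @pytest.mark.parametrize("ended,expected", [(50, True), (49, False), (51, True)])
    def test_reached_fifty_rule(self, ended, expected):
        counts = [SiteCounts(SITE, ended, 0, 100)]
        assert icds_detect(counts) == [expected]

    def test_zero_never_detected_even_at_min_one(self):
        assert icds_detect([SiteCounts(SITE, 0, 0, 10)], min_ended=1) == [False]


class TestSubsampling:
    def _reads(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return [
            AlignedRead("r", int(a), int(a) + 150, "+")
            for a in rng.integers(0, 1000, size=n)
        ]

    def test_requested_read_count_arithmetic(self):
        reads = self._reads(10)
        sites = [MotifSite("r", 100, "GAAC")]
        pts = subsample_depths(reads, sites, genome_length=5_000_000,
                               read_length=150, depths=[200], lengths={"r": 1200})
        # round(200 * 5e6 / 150) exceeds available -> capped at all reads
        assert pts[0].n_reads == 10

    def test_nested_samples_give_monotone_detection(self, deep_truth):
        truth = deep_truth
        sites = truth.sites
        L = truth.genome.total_length
        pts = subsample_depths(truth.reads, sites, L, truth.config.read_length,
                               depths=[100, 200, 400, 600], seed=5,
                               min_ended=50, lengths=truth.genome.lengths)
        for shallow, deep in zip(pts, pts[1:]):
            assert shallow.detected_keys <= deep.detected_keys
        assert [p.n_detected for p in pts] == sorted(p.n_detected for p in pts)

    def test_full_depth_equals_unsubsampled_detection(self):
        reads = self._reads(100)
        sites = [MotifSite("r", 100, "GAAC")]
        full = subsample_depths(reads, sites, genome_length=100, read_length=150,
                                depths=[10_000], lengths={"r": 1200})
        counts = count_sites(reads, sites, {"r": 1200})
        assert full[0].n_detected == sum(icds_detect(counts))

    def test_nonpositive_depth_rejected(self):
        with pytest.raises(ValueError):
            subsample_depths(self._reads(5), [], 1000, 150, [0], lengths={"r": 1200})


class TestLoadAlignments:
    def test_tsv_round_trip(self, tmp_path):
        reads = [
            AlignedRead("r", 5, 100, "+", mapq=60, read_id="a"),
            AlignedRead("r", 7, 80, "-", mapq=30, read_id="b"),
        ]
        p = tmp_path / "aln.tsv"
        write_alignments_tsv(reads, p)
        assert load_alignments(p, min_mapq=0) == reads

    def test_mapq_filter_on_sam(self, tmp_path):
        sam = tmp_path / "t.sam"
        sam.write_text(
            "@HD\tVN:1.6\tSO:unsorted\n"
            "@SQ\tSN:r\tLN:1000\n"
            "a\t0\tr\t10\t60\t50M\t*\t0\t0\t" + "A" * 50 + "\t*\n"
            "b\t16\tr\t20\t60\t50M\t*\t0\t0\t" + "A" * 50 + "\t*\n"
            "c\t0\tr\t30\t0\t50M\t*\t0\t0\t" + "A" * 50 + "\t*\n"
        )
        reads = load_alignments(sam, min_mapq=1)
        assert [r.read_id for r in reads] == ["a", "b"]
        assert reads[0].start0 == 9  # SAM POS is 1-based
        assert reads[1].strand == "-"

    def test_unknown_replicon_rejected(self, tmp_path):
        p = tmp_path / "aln.tsv"
        write_alignments_tsv([AlignedRead("zzz", 0, 50, "+")], p)
        with pytest.raises(ValueError, match="zzz"):
            load_alignments(p, genome=Genome({"r": "ACGT" * 100}))
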