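"""tFP sampling and alignment-evidence decision rules."""

import numpy as np
import pysam
import pytest

from vcbench.matching import MatchResult
from vcbench.metrics import assign_size_bin
from vcbench.revalidation import (AlignmentEvidence, EvidenceParams,
                                  check_alignment_evidence,
                                  export_review_regions, sample_tfp)
from vcbench.variants import VariantCall

REF_LEN = 50_000


def V(vclass, pos, size, call_id="c", read_type="long", **kw):
    return VariantCall(call_id=call_id, chrom="chr1", pos=pos, vclass=vclass,
                       size=size, read_type=read_type, **kw)


def tfp_result(call, stratum="nonrepeat"):
    return MatchResult(call_id=call.call_id, status="tFP", stratum=stratum,
                       size_bin=assign_size_bin(call), call=call)


def write_sam(path, reads):
    """reads: list of (start0, cigar list, optional query seq)."""
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": "chr1", "LN": REF_LEN}],
    })
    reads = sorted(reads, key=lambda r: r[0])
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i, item in enumerate(reads):
            start, cigar = item[0], item[1]
            seq = item[2] if len(item) > 2 else None
            a = pysam.AlignedSegment(header)
            a.query_name = f"r{i}"
            a.reference_name = "chr1"
            a.reference_start = start
            a.mapping_quality = 60
            a.cigartuples = cigar
            qlen = sum(l for op, l in cigar if op in (0, 1, 4, 7, 8))
            a.query_sequence = seq if seq is not None else "A" * qlen
            a.flag = 0
            out.write(a)


def evidence_for(tmp_path, reads):
    path = tmp_path / "reads.sam"
    write_sam(path, reads)
    return AlignmentEvidence(str(path))


def spanning_ins_read(ins_pos0, ins_len, flank=1000):
    start = ins_pos0 - flank
    return (start, [(0, flank), (1, ins_len), (0, flank)])


def spanning_del_read(del_start0, del_len, flank=1000):
    return (del_start0 - flank, [(0, flank), (2, del_len), (0, flank)])


class TestRule1Support:
    def test_matching_ins_events_validate(self, tmp_path):
        call = V("INS", 10_001, 25)  # breakpoint at 0-based 10,000
        ev = evidence_for(tmp_path, [spanning_ins_read(10_000, 25)] * 3)
        res = check_alignment_evidence(call, ev)
        assert res.decision == "TP" and res.rule == 1 and res.n_support == 3

    def test_one_read_is_not_enough(self, tmp_path):
        call = V("INS", 10_001, 25)
        ev = evidence_for(tmp_path, [spanning_ins_read(10_000, 25),
                                     (9_000, [(0, 2000)])])
        assert check_alignment_evidence(call, ev).decision == "FP"

    def test_min_support_zero_marks_covered_loci_tp(self, tmp_path):
        call = V("INS", 10_001, 25)
        ev = evidence_for(tmp_path, [(9_000, [(0, 2000)])])  # pure match only
        res = check_alignment_evidence(call, ev,
                                       EvidenceParams(min_support_reads=0))
        assert res.decision == "TP" and res.rule == 1

    def test_del_support(self, tmp_path):
        call = V("DEL", 10_001, 300)
        ev = evidence_for(tmp_path, [spanning_del_read(10_000, 300)] * 2)
        assert check_alignment_evidence(call, ev).decision == "TP"

    def test_del_poor_overlap_rejected(self, tmp_path):
        call = V("DEL", 10_001, 300)
        # read deletion of 300 bp shifted by 200: reciprocal overlap 1/3
        ev = evidence_for(tmp_path, [spanning_del_read(10_200, 300)] * 3)
        assert check_alignment_evidence(call, ev).decision == "FP"

    def test_snv_alt_base_support(self, tmp_path):
        seq = "A" * 1000 + "G" + "A" * 999
        reads = [(9_500, [(0, 2000)], seq)] * 2
        ev = evidence_for(tmp_path, reads)
        assert check_alignment_evidence(V("SNV", 10_501, 0, alt_base="G"),
                                        ev).decision == "TP"
        assert check_alignment_evidence(V("SNV", 10_501, 0, alt_base="T"),
                                        ev).decision == "FP"

    def test_fragmented_insertions_are_summed(self, tmp_path):
        call = V("INS", 10_001, 60)
        # two 30-bp insertions 5 bp apart within each read sum to 60
        reads = [(9_000, [(0, 1000), (1, 30), (0, 5), (1, 30), (0, 1000)])] * 2
        ev = evidence_for(tmp_path, reads)
        assert check_alignment_evidence(call, ev).decision == "TP"

    def test_read_order_invariance(self, tmp_path):
        call = V("INS", 10_001, 25)
        reads = [spanning_ins_read(10_000, 25), (9_000, [(0, 2000)]),
                 spanning_ins_read(10_000, 27)]
        a = check_alignment_evidence(call, evidence_for(tmp_path, reads))
        b = check_alignment_evidence(
            call, evidence_for(tmp_path, list(reversed(reads))))
        assert (a.decision, a.rule) == (b.decision, b.rule)


class TestRule2ShortReadIns:
    def _ev(self, tmp_path, obs_len):
        return evidence_for(tmp_path, [spanning_ins_read(10_000, obs_len)] * 3)

    def test_sub10bp_observation_is_fp(self, tmp_path):
        call = V("INS", 10_001, 60, read_type="short")
        res = check_alignment_evidence(call, self._ev(tmp_path, 8))
        assert res.decision == "FP" and res.rule == 2

    def test_boundary_at_10bp(self, tmp_path):
        call = V("INS", 10_001, 60, read_type="short")
        # 9 bp: below threshold -> FP; 10 bp: acceptable support -> TP
        assert check_alignment_evidence(call, self._ev(tmp_path, 9)).rule == 2
        res = check_alignment_evidence(call, self._ev(tmp_path, 10))
        assert res.decision == "TP" and res.rule == 1

    def test_long_read_calls_use_size_ratio_instead(self, tmp_path):
        call = V("INS", 10_001, 60, read_type="long")
        # 10-bp observed insertion: ratio 6.0 outside [0.5, 2.0] -> no support
        assert check_alignment_evidence(call, self._ev(tmp_path, 10)).decision == "FP"


class TestRules34Dup:
    def _dup(self, size, read_type="short"):
        # DUP calls arrive as INS with from_dup after normalization
        return V("INS", 10_001, size, read_type=read_type, from_dup=True)

    def _ev(self, tmp_path, obs_len, n=2):
        return evidence_for(tmp_path, [spanning_ins_read(10_000, obs_len)] * n)

    def test_small_dup_observation_window(self, tmp_path):
        # size-ratio support (rule 1) would also fire for concordant
        # observations, so use a 60-bp DUP whose call/observed ratio falls
        # outside [0.5, 2.0]: only the 30-200 bp window can rescue it
        call = self._dup(60)
        assert check_alignment_evidence(call, self._ev(tmp_path, 150)).rule == 3
        assert check_alignment_evidence(call, self._ev(tmp_path, 130)).rule == 3
        assert check_alignment_evidence(call, self._ev(tmp_path, 29)).decision == "FP"
        assert check_alignment_evidence(call, self._ev(tmp_path, 201)).decision == "FP"

    def test_small_dup_boundary_size(self, tmp_path):
        # 100 bp is not "< 100 bp" (rule 3 inapplicable, observed ratio 0.4
        # fails rule 1) while a 99-bp call with the same 200-bp observation
        # (ratio 0.495) is rescued by the 30-200 bp window
        assert check_alignment_evidence(
            self._dup(100), self._ev(tmp_path, 250)).decision == "FP"
        assert check_alignment_evidence(
            self._dup(99), self._ev(tmp_path, 200)).rule == 3
        # concordant observation still validates a 100-bp DUP through rule 1
        assert check_alignment_evidence(
            self._dup(100), self._ev(tmp_path, 99)).rule == 1

    def test_large_dup_08x_threshold(self, tmp_path):
        call = self._dup(600)
        # 0.8 x 600 = 480; a modest over-threshold observation already
        # satisfies the rule-1 size ratio, so rule 1 fires first
        assert check_alignment_evidence(call, self._ev(tmp_path, 481)).rule == 1
        # a huge observed insertion (ratio 600/1300 < 0.5 fails rule 1) is
        # still valid large-DUP evidence because 1300 > 480
        assert check_alignment_evidence(call, self._ev(tmp_path, 1300)).rule == 4
        below = check_alignment_evidence(call, self._ev(tmp_path, 250))
        assert below.decision == "FP"

    def test_large_dup_boundary_size(self, tmp_path):
        # 500 bp is not "> 500 bp": rule 4 does not apply; 410-bp obs gives
        # a ratio of 500/410 = 1.2 so rule 1 fires instead
        call = self._dup(500)
        assert check_alignment_evidence(call, self._ev(tmp_path, 410)).rule == 1

    def test_rule4_needs_two_reads(self, tmp_path):
        call = self._dup(600)
        one = evidence_for(tmp_path, [spanning_ins_read(10_000, 590)])
        assert check_alignment_evidence(call, one).decision == "FP"


class TestRule5Clips:
    def _clip_reads(self, bp0, n5=2, n3=2):
        reads = []
        for _ in range(n5):
            reads.append((bp0, [(4, 400), (0, 800)]))  # 5'-clipped at bp
        for _ in range(n3):
            reads.append((bp0 - 800, [(0, 800), (4, 400)]))  # 3'-clipped at bp
        return reads

    def test_two_plus_two_clips_validate(self, tmp_path):
        call = V("INS", 10_001, 800)
        ev = evidence_for(tmp_path, self._clip_reads(10_000))
        res = check_alignment_evidence(call, ev)
        assert res.decision == "TP" and res.rule == 5

    def test_one_sided_clips_do_not(self, tmp_path):
        call = V("INS", 10_001, 800)
        ev = evidence_for(tmp_path, self._clip_reads(10_000, n5=2, n3=1))
        assert check_alignment_evidence(call, ev).decision == "FP"
        ev2 = evidence_for(tmp_path, self._clip_reads(10_000, n5=1, n3=2))
        assert check_alignment_evidence(call, ev2).decision == "FP"

    def test_dup_second_breakpoint(self, tmp_path):
        call = V("INS", 10_001, 600, from_dup=True)
        reads = [(10_000, [(4, 400), (0, 800)])] * 2  # 5' clips at first bp
        reads += [(10_600 - 800, [(0, 800), (4, 400)])] * 2  # 3' at second bp
        ev = evidence_for(tmp_path, reads)
        assert check_alignment_evidence(call, ev).rule == 5

    def test_clips_outside_window_ignored(self, tmp_path):
        call = V("INS", 10_001, 800)
        ev = evidence_for(tmp_path, self._clip_reads(10_500))  # 500 bp away
        assert check_alignment_evidence(call, ev).decision == "FP"

    def test_del_calls_never_use_clip_rule(self, tmp_path):
        call = V("DEL", 10_001, 800)
        ev = evidence_for(tmp_path, self._clip_reads(10_000))
        assert check_alignment_evidence(call, ev).decision == "FP"


class TestNoCoverage:
    def test_flagged_fp(self, tmp_path):
        ev = evidence_for(tmp_path, [(100, [(0, 500)])])
        res = check_alignment_evidence(V("INS", 40_001, 60), ev)
        assert res.decision == "FP" and res.no_coverage


class TestSampleTfp:
    def _tfps(self, n, stratum="nonrepeat", size=10):
        return [tfp_result(V("INS", 1000 + 100 * i, size, call_id=f"c{i}"),
                           stratum) for i in range(n)]

    def test_exhaustion_rule(self):
        samples = sample_tfp(self._tfps(30), n=50, seed=1)
        (key, members), = samples.items()
        assert key == ("nonrepeat", "ins", "6-50") and len(members) == 30

    def test_determinism_and_distinctness(self):
        tfps = self._tfps(200)
        a = sample_tfp(tfps, n=50, seed=9)
        b = sample_tfp(tfps, n=50, seed=9)
        ids_a = [r.call_id for r in list(a.values())[0]]
        ids_b = [r.call_id for r in list(b.values())[0]]
        assert ids_a == ids_b and len(set(ids_a)) == 50
        c = sample_tfp(tfps, n=50, seed=10)
        assert [r.call_id for r in list(c.values())[0]] != ids_a

    def test_groups_split_by_stratum_class_and_size_range(self):
        tfps = (self._tfps(5) + self._tfps(5, stratum="STR")
                + [tfp_result(V("DEL", 9000, 3, call_id="d1"))]
                + [tfp_result(V("INS", 20_000, 500, call_id="s1"))])
        samples = sample_tfp(tfps, n=50, seed=0)
        assert set(samples) == {
            ("nonrepeat", "ins", "6-50"), ("repeat", "ins", "6-50"),
            ("nonrepeat", "del", "1-5"), ("nonrepeat", "INS", "all"),
        }

    def test_sampling_is_uniform_across_quartiles(self):
        tfps = self._tfps(200)
        counts = np.zeros(4)
        for seed in range(1000):
            (members,) = sample_tfp(tfps, n=50, seed=seed).values()
            for r in members:
                counts[int(r.call_id[1:]) // 50] += 1
        freq = counts / counts.sum()
        assert np.allclose(freq, 0.25, atol=0.01)


class TestExportReviewRegions:
    def test_window_arithmetic(self, tmp_path):
        res = tfp_result(V("INS", 1000, 50, call_id="x"))
        path = tmp_path / "review.bed"
        export_review_regions([res], str(path), window=200)
        assert path.read_text() == "chr1\t800\t1250\tx\n"

    def test_clip_at_zero_and_empty(self, tmp_path):
        res = tfp_result(V("INS", 50, 10, call_id="y"))
        path = tmp_path / "review.bed"
        export_review_regions([res], str(path), window=200)
        start = int(path.read_text().split("\t")[1])
        assert start == 0
        export_review_regions([], str(path))
        assert path.read_text() == ""
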