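"""Truth matching: class-specific criteria, tie-breaking, oracle agreement."""

import numpy as np
import pytest

from vcbench.matching import (MatchParams, TruthIndex, class_label,
                              evaluate_callset, match_call, match_indel,
                              match_snv, match_sv)
from vcbench.regions import RegionSet
from vcbench.variants import CallSet, VariantCall


def V(vclass, pos, size, call_id="c", chrom="chr1", **kw):
    return VariantCall(call_id=call_id, chrom=chrom, pos=pos, vclass=vclass,
                       size=size, **kw)


def index(*variants):
    return TruthIndex(variants)


class TestMatchSnv:
    truth = index(V("SNV", 100, 0, "t1", alt_base="G"))

    def test_exact_match(self):
        res = match_snv(V("SNV", 100, 0, alt_base="G"), self.truth)
        assert res.status == "TP" and res.matched_truth_id == "t1"

    def test_wrong_alt_base(self):
        assert match_snv(V("SNV", 100, 0, alt_base="T"), self.truth).status == "tFP"

    def test_wrong_position(self):
        assert match_snv(V("SNV", 101, 0, alt_base="G"), self.truth).status == "tFP"


class TestMatchIndel:
    def test_within_half_size_and_ratio(self):
        truth = index(V("DEL", 1004, 12, "t1"))
        res = match_indel(V("DEL", 1000, 10), truth)  # dist 4 <= 5; 10/12 ok
        assert res.status == "TP"

    def test_one_bp_exception(self):
        truth = index(V("INS", 501, 1, "t1"))
        assert match_indel(V("INS", 500, 1), truth).status == "TP"
        assert match_indel(V("INS", 499, 1), truth).status == "tFP"  # 2 bp off

    def test_distance_exceeds_half_size(self):
        truth = index(V("INS", 1003, 4, "t1"))
        assert match_indel(V("INS", 1000, 4), truth).status == "tFP"  # 3 > 2

    def test_ratio_bounds_inclusive(self):
        truth = index(V("INS", 1000, 8, "t1"))
        assert match_indel(V("INS", 1000, 4), truth).status == "TP"  # ratio 0.5
        assert match_indel(V("INS", 1000, 16), truth).status == "TP"  # ratio 2.0
        assert match_indel(V("INS", 1000, 3), truth).status == "tFP"

    def test_type_must_agree(self):
        truth = index(V("DEL", 1000, 10, "t1"))
        assert match_indel(V("INS", 1000, 10), truth).status == "tFP"

    def test_nearest_candidate_wins(self):
        truth = index(V("INS", 1004, 10, "tfar"), V("INS", 1002, 10, "tnear"))
        res = match_indel(V("INS", 1000, 10), truth)
        assert res.matched_truth_id == "tnear"


class TestMatchSv:
    def test_del_reciprocal_boundary_inclusive(self):
        truth = index(V("DEL", 1051, 100, "t1"))  # spans [1050, 1150)
        # call spans [1000, 1100): overlap 50 = exactly 50% of both
        res = match_sv(V("DEL", 1001, 100), truth)
        assert res.status == "TP"
        truth49 = index(V("DEL", 1052, 100, "t1"))
        assert match_sv(V("DEL", 1001, 100), truth49).status == "tFP"

    def test_long_read_ins_needs_size_ratio(self):
        truth = index(V("INS", 5010, 200, "t1"))
        long_call = V("INS", 5000, 60, read_type="long")
        short_call = V("INS", 5000, 60, read_type="short")
        assert match_sv(long_call, truth).status == "tFP"  # ratio 0.3
        assert match_sv(short_call, truth).status == "TP"  # no ratio clause

    def test_ins_breakpoint_distance(self):
        truth = index(V("INS", 5000, 100, "t1"))
        assert match_sv(V("INS", 5200, 100, read_type="long"), truth).status == "TP"
        assert match_sv(V("INS", 5201, 100, read_type="long"), truth).status == "tFP"

    def test_dup_as_ins_needs_ratio_even_for_short_reads(self):
        truth = index(V("INS", 5000, 300, "t1"))
        good = V("INS", 5050, 250, read_type="short", from_dup=True)
        bad = V("INS", 5050, 100, read_type="short", from_dup=True)  # ratio 0.33
        assert match_sv(good, truth).status == "TP"
        assert match_sv(bad, truth).status == "tFP"

    def test_del_largest_overlap_wins(self):
        truth = index(V("DEL", 1001, 100, "tA"), V("DEL", 1041, 100, "tB"))
        res = match_sv(V("DEL", 1011, 100), truth)
        assert res.matched_truth_id == "tA"  # 90 bp overlap beats 70 bp


# ---------------------------------------------------------------------------
# brute-force oracle: an independent quadratic re-statement of the criteria


def oracle_match(call, truths, params=MatchParams()):
    """All-pairs scan applying the published criteria directly."""
    best = None
    for t in truths:
        if t.chrom != call.chrom:
            continue
        if call.vclass == "SNV":
            if t.vclass == "SNV" and t.pos == call.pos and \
                    (t.alt_base or "").upper() == (call.alt_base or "").upper():
                rank = (0, t.pos, t.call_id)
            else:
                continue
        elif call.scale == "indel":
            if t.vclass != call.vclass or t.scale != "indel":
                continue
            dist = abs(t.pos - call.pos)
            allowed = 0.5 * call.size
            if call.size == 1:
                allowed = max(allowed, 1)
            if dist > allowed:
                continue
            if not 0.5 <= call.size / t.size <= 2.0:
                continue
            rank = (dist, t.pos, t.call_id)
        elif call.vclass in ("INS", "DUP"):
            if t.vclass != "INS" or t.scale != "SV":
                continue
            dist = abs(t.pos - call.pos)
            if dist > 200:
                continue
            if (call.read_type == "long" or call.from_dup or
                    call.vclass == "DUP"):
                if not 0.5 <= call.size / t.size <= 2.0:
                    continue
            rank = (dist, t.pos, t.call_id)
        else:  # DEL SV
            if t.vclass != "DEL" or t.scale != "SV":
                continue
            cs, ce = call.pos - 1, call.pos - 1 + call.size
            ts, te = t.pos - 1, t.pos - 1 + t.size
            ov = min(ce, te) - max(cs, ts)
            if ov < 0.5 * call.size or ov < 0.5 * t.size:
                continue
            rank = (-ov, t.pos, t.call_id)
        if best is None or rank < best[0]:
            best = (rank, t.call_id)
    return best[1] if best else None


def random_instance(rng, n_calls=200, n_truth=150, span=50_000):
    def rand_var(i, prefix):
        vclass = str(rng.choice(["SNV", "INS", "DEL", "DUP"], p=[.3, .3, .3, .1]))
        if vclass == "SNV":
            size = 0
        else:
            size = int(rng.choice([rng.integers(1, 50), rng.integers(50, 500)]))
        if vclass == "DUP" and size < 50:
            size = int(rng.integers(50, 500))
        return VariantCall(
            call_id=f"{prefix}{i}", chrom="chr1",
            pos=int(rng.integers(1, span)), vclass=vclass, size=size,
            alt_base=str(rng.choice(list("ACGT"))) if vclass == "SNV" else None,
            read_type=str(rng.choice(["short", "long"])),
        )
    truths = [rand_var(i, "t") for i in range(n_truth)]
    truths = [t for t in truths if t.vclass != "DUP"]  # truth sets are DUP-free
    calls = [rand_var(i, "c") for i in range(n_calls)]
    return calls, truths


class TestOracleEquivalence:
    def test_matcher_agrees_with_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(25):
            calls, truths = random_instance(rng)
            tindex = TruthIndex(truths)
            for call in calls:
                got = match_call(call, tindex)
                expected = oracle_match(call, truths)
                assert got.matched_truth_id == expected, (
                    f"{call.vclass} size={call.size} pos={call.pos} "
                    f"read={call.read_type}"
                )

    def test_tp_truths_satisfy_predicate_when_rechecked(self):
        rng = np.random.default_rng(5)
        calls, truths = random_instance(rng)
        by_id = {t.call_id: t for t in truths}
        tindex = TruthIndex(truths)
        for call in calls:
            res = match_call(call, tindex)
            if res.status == "TP":
                assert oracle_match(call, [by_id[res.matched_truth_id]]) \
                    == res.matched_truth_id

    def test_shrinking_params_is_monotone(self):
        rng = np.random.default_rng(9)
        calls, truths = random_instance(rng)
        tindex = TruthIndex(truths)
        tight = MatchParams(ins_bp_dist=50, rec_overlap=0.8,
                            sv_size_ratio=(0.8, 1.25),
                            indel_size_ratio=(0.8, 1.25),
                            indel_dist_factor=0.25)
        for call in calls:
            loose_res = match_call(call, tindex, MatchParams())
            tight_res = match_call(call, tindex, tight)
            if tight_res.status == "TP":
                assert loose_res.status == "TP"


class TestEvaluateCallset:
    def test_identical_calls_all_tp(self):
        truths = [V("INS", 1000 + 700 * i, 60 + i, f"t{i}") for i in range(10)]
        calls = CallSet(
            calls=[V(t.vclass, t.pos, t.size, f"c{i}")
                   for i, t in enumerate(truths)],
            read_type="long", label="x",
        )
        results = evaluate_callset(calls, truths)
        assert all(r.status == "TP" for r in results) and len(results) == 10

    def test_empty_callset(self):
        assert evaluate_callset(CallSet(calls=[], label="e"), []) == []

    def test_stratum_and_bin_populated(self):
        truths = [V("INS", 1000, 60, "t0")]
        str_rs = RegionSet(intervals={"chr1": [(990, 1010)]}, label="STR")
        calls = CallSet(calls=[V("INS", 1000, 60, "c0")], read_type="long")
        res = evaluate_callset(calls, truths, str_rs, RegionSet())[0]
        assert res.stratum == "STR" and res.size_bin == "50-99"

    def test_planted_labels_reproduced(self, calls_and_labels, truth_set,
                                       toy_genome):
        calls, labels = calls_and_labels
        from vcbench.variants import dup_to_ins
        norm_calls = CallSet(calls=[dup_to_ins(c) for c in calls],
                             read_type=calls.read_type, label=calls.label)
        norm_truth = [dup_to_ins(t) for t in truth_set]
        results = evaluate_callset(norm_calls, norm_truth)
        for r in results:
            assert (r.status == "TP") == labels[r.call_id], r.call_id


def test_class_labels():
    assert class_label(V("SNV", 1, 0, alt_base="A")) == "SNV"
    assert class_label(V("INS", 1, 10)) == "ins"
    assert class_label(V("DEL", 1, 10)) == "del"
    assert class_label(V("INS", 1, 500)) == "INS"
    assert class_label(V("DUP", 1, 500)) == "ins".upper()
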