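"""Class-specific truth matching: TP versus tentative-FP decisions.

Each call is compared against a truth (reference) set with criteria that
depend on its variant class:

* SNV -- identical chromosome, position and non-reference base.
* indel (1-49 bp) -- a same-type truth indel within ``0.5 x called size`` bp
  and with called/truth size ratio in [0.5, 2.0]; 1-bp indels may sit 1 bp
  away as an exception.
* SV INS (>= 50 bp) -- a truth INS with breakpoint distance <= 200 bp; calls
  from long-read algorithms (and DUP calls converted to INS) additionally
  need a size ratio in [0.5, 2.0].
* SV DEL -- >= 50% reciprocal overlap (of *both* lengths) with a truth DEL.

Calls with no eligible truth candidate are tentative false positives (tFP):
they may still be rescued by alignment-evidence re-validation (see
:mod:`vcbench.revalidation`).
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Iterable, Optional

from .regions import RegionSet, classify_position
from .variants import CallSet, VariantCall

log = logging.getLogger(__name__)

TP = "TP"
TFP = "tFP"


@dataclass(frozen=True)
class MatchParams:
    """Tolerances for truth matching (defaults are the benchmark's values)."""

    ins_bp_dist: int = 200  # max INS breakpoint distance (SV)
    rec_overlap: float = 0.5  # min reciprocal overlap (SV DEL)
    sv_size_ratio: tuple[float, float] = (0.5, 2.0)
    indel_size_ratio: tuple[float, float] = (0.5, 2.0)
    indel_dist_factor: float = 0.5  # max distance = factor x called size
    onebp_dist: int = 1  # distance allowance for 1-bp indels

    def __post_init__(self) -> None:
        if not 0 < self.rec_overlap <= 1:
            raise ValueError("rec_overlap must be in (0, 1]")
        for low, high in (self.sv_size_ratio, self.indel_size_ratio):
            if not low < 1 < high:
                raise ValueError("size-ratio window must bracket 1")


@dataclass
class MatchResult:
    """Per-call decision with matched truth identity and stratum."""

    call_id: str
    status: str  # TP | tFP
    matched_truth_id: Optional[str] = None
    stratum: Optional[str] = None
    size_bin: Optional[str] = None
    call: Optional[VariantCall] = None

    def __post_init__(self) -> None:
        if (self.status == TP) != (self.matched_truth_id is not None):
            raise ValueError("status TP iff a matched truth id is present")


class TruthIndex:
    """Position-indexed truth set for O(log n) candidate lookup."""

    def __init__(self, variants: Iterable[VariantCall]):
        self._snv: dict[tuple[str, int], list[tuple[str, str]]] = {}
        # (chrom, vclass, scale) -> parallel (pos, size, id) sorted by pos
        self._pos: dict[tuple, list[int]] = {}
        self._meta: dict[tuple, list[tuple[int, str]]] = {}
        entries: dict[tuple, list[tuple[int, int, str]]] = {}
        for t in variants:
            if t.vclass == "SNV":
                self._snv.setdefault((t.chrom, t.pos), []).append(
                    ((t.alt_base or "").upper(), t.call_id)
                )
            else:
                key = (t.chrom, t.vclass, t.scale)
                entries.setdefault(key, []).append((t.pos, t.size, t.call_id))
        for key, items in entries.items():
            items.sort()
            self._pos[key] = [it[0] for it in items]
            self._meta[key] = [(it[1], it[2]) for it in items]

    def snv_at(self, chrom: str, pos: int) -> list[tuple[str, str]]:
        return self._snv.get((chrom, pos), [])

    def candidates(
        self, chrom: str, vclass: str, scale: str, lo: int, hi: int
    ) -> list[tuple[int, int, str]]:
        """Truth variants of (vclass, scale) with pos in [lo, hi]."""
        key = (chrom, vclass, scale)
        pos = self._pos.get(key)
        if not pos:
            return []
        i, j = bisect_left(pos, lo), bisect_right(pos, hi)
        meta = self._meta[key]
        return [(pos[k], meta[k][0], meta[k][1]) for k in range(i, j)]


def match_snv(call: VariantCall, truth_index: TruthIndex) -> MatchResult:
    """TP iff a truth SNV shares chrom, position and alternate base."""
    for alt, tid in truth_index.snv_at(call.chrom, call.pos):
        if alt == (call.alt_base or "").upper():
            return MatchResult(call.call_id, TP, tid, call=call)
    return MatchResult(call.call_id, TFP, call=call)


def _ratio_ok(call_size: int, truth_size: int, window: tuple[float, float]) -> bool:
    if truth_size == 0:
        return False
    return window[0] <= call_size / truth_size <= window[1]


def match_indel(
    call: VariantCall, truth_index: TruthIndex, params: MatchParams = MatchParams()
) -> MatchResult:
    """Match a 1-49 bp insertion or deletion against same-type truth indels.

    The nearest-position eligible candidate wins ties.
    """
    max_dist = params.indel_dist_factor * call.size
    if call.size == 1:
        max_dist = max(max_dist, params.onebp_dist)
    lo, hi = int(call.pos - max_dist), int(call.pos + max_dist)
    best: Optional[tuple[tuple, str]] = None
    for tpos, tsize, tid in truth_index.candidates(
        call.chrom, call.vclass, "indel", lo, hi
    ):
        if abs(tpos - call.pos) > max_dist:
            continue
        if not _ratio_ok(call.size, tsize, params.indel_size_ratio):
            continue
        rank = (abs(tpos - call.pos), tpos, tid)
        if best is None or rank < best[0]:
            best = (rank, tid)
    if best is None:
        return MatchResult(call.call_id, TFP, call=call)
    return MatchResult(call.call_id, TP, best[1], call=call)


def match_sv(
    call: VariantCall, truth_index: TruthIndex, params: MatchParams = MatchParams()
) -> MatchResult:
    """Match an SV call (INS, DEL, or DUP treated as INS) against the truth.

    INS ties break to the nearest breakpoint; DEL ties to the largest
    reciprocal overlap.
    """
    if call.vclass in ("INS", "DUP"):
        need_ratio = (
            call.read_type == "long" or call.from_dup or call.vclass == "DUP"
        )
        lo, hi = call.pos - params.ins_bp_dist, call.pos + params.ins_bp_dist
        best: Optional[tuple[tuple, str]] = None
        for tpos, tsize, tid in truth_index.candidates(call.chrom, "INS", "SV", lo, hi):
            if abs(tpos - call.pos) > params.ins_bp_dist:
                continue
            if need_ratio and not _ratio_ok(call.size, tsize, params.sv_size_ratio):
                continue
            rank = (abs(tpos - call.pos), tpos, tid)
            if best is None or rank < best[0]:
                best = (rank, tid)
        if best is None:
            return MatchResult(call.call_id, TFP, call=call)
        return MatchResult(call.call_id, TP, best[1], call=call)

    if call.vclass == "DEL":
        # a candidate must overlap; its size can be at most 1/rec_overlap of
        # the call size, bounding the start-position scan window
        max_tsize_factor = 1.0 / params.rec_overlap
        lo = int(call.start0 - max_tsize_factor * call.size)
        hi = call.end0
        best = None
        for tpos, tsize, tid in truth_index.candidates(
            call.chrom, "DEL", "SV", lo + 1, hi
        ):
            tstart, tend = tpos - 1, tpos - 1 + tsize
            overlap = min(call.end0, tend) - max(call.start0, tstart)
            if overlap < params.rec_overlap * call.size:
                continue
            if overlap < params.rec_overlap * tsize:
                continue
            rank = (-overlap, tpos, tid)
            if best is None or rank < best[0]:
                best = (rank, tid)
        if best is None:
            return MatchResult(call.call_id, TFP, call=call)
        return MatchResult(call.call_id, TP, best[1], call=call)

    raise ValueError(f"match_sv cannot handle class {call.vclass}")


def match_call(
    call: VariantCall, truth_index: TruthIndex, params: MatchParams = MatchParams()
) -> MatchResult:
    """Dispatch to the class-appropriate matcher."""
    if call.vclass == "SNV":
        return match_snv(call, truth_index)
    if call.scale == "indel":
        return match_indel(call, truth_index, params)
    return match_sv(call, truth_index, params)


def class_label(v: VariantCall) -> str:
    """Report label: SNV, ins/del (indel scale), INS/DEL (SV scale)."""
    if v.vclass == "SNV":
        return "SNV"
    base = "ins" if v.vclass in ("INS", "DUP") else "del"
    return base.upper() if v.scale == "SV" else base


def evaluate_callset(
    calls: CallSet,
    truth: Iterable[VariantCall],
    str_rs: Optional[RegionSet] = None,
    segdup_rs: Optional[RegionSet] = None,
    params: MatchParams = MatchParams(),
) -> list[MatchResult]:
    """Match every call and annotate results with stratum and size bin.

    Inputs are expected to be normalized (DUP converted to INS) and
    deduplicated.  Emits per stratum x class x bin TP/tFP tallies to the log.
    """
    from .metrics import assign_size_bin  # local import to avoid a cycle

    truth_index = truth if isinstance(truth, TruthIndex) else TruthIndex(truth)
    str_rs = (str_rs or RegionSet(label="STR")).coalesced()
    segdup_rs = (segdup_rs or RegionSet(label="SegDup")).coalesced()
    results: list[MatchResult] = []
    tallies: dict[tuple, int] = {}
    for call in calls:
        res = match_call(call, truth_index, params)
        res.stratum = classify_position(call, str_rs, segdup_rs)
        res.size_bin = assign_size_bin(call)
        results.append(res)
        key = (res.stratum, class_label(call), res.size_bin, res.status)
        tallies[key] = tallies.get(key, 0) + 1
    for key in sorted(tallies):
        log.debug("stratum=%s class=%s bin=%s %s: %d", *key, tallies[key])
    return results


def results_to_tsv(results: Iterable[MatchResult], path: str) -> None:
    """Export match results as TSV (call_id, status, matched_truth_id,
    stratum, size_bin)."""
    with open(path, "w") as out:
        out.write("call_id\tstatus\tmatched_truth_id\tstratum\tsize_bin\n")
        for r in results:
            out.write(
                f"{r.call_id}\t{r.status}\t{r.matched_truth_id or '.'}\t"
                f"{r.stratum or '.'}\t{r.size_bin or '.'}\n"
            )
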