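"""Sampled re-validation of tentative false positives against long reads.

Because truth sets are incomplete, calls they fail to match are only
*tentative* FPs.  A fixed-size random sample per region stratum x variant
class (x indel size range) is re-examined against long-read alignments, and
the validated fraction is scaled up into the TP2 correction
(:func:`vcbench.metrics.estimate_tp2`).

The decision rules encode what a curator would check in a genome browser,
applied automatically to CIGAR strings, evaluated in order:

1. >= ``min_support_reads`` reads carry a same-type event at the locus that
   satisfies the class TP-matching predicate against the call -> TP.
2. short-read-derived SV INS whose largest observed read-level insertion is
   < 10 bp -> FP.
3. DUP call < 100 bp with a supported read-level insertion of 30-200 bp -> TP.
4. DUP call > 500 bp with a supported read-level insertion > 0.8 x its size
   -> TP.
5. INS/DUP flanked by >= 2 reads 5'-clipped near the first breakpoint and
   >= 2 reads 3'-clipped near the second (the first again for INS) -> TP.
6. otherwise FP.

Nearby insertion events within one read (separated by <= 10 bp of
reference) are summed before size comparison, since long-read aligners
fragment large insertions.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pysam

from .matching import MatchResult, class_label
from .variants import VariantCall

log = logging.getLogger(__name__)

#: indel size ranges used when sampling tentative FPs
INDEL_SIZE_RANGES: list[tuple[int, int]] = [(1, 5), (6, 50)]

_CIGAR_CONSUMES_REF = {0, 2, 3, 7, 8}  # M, D, N, =, X
_CIGAR_CONSUMES_QUERY = {0, 1, 4, 7, 8}  # M, I, S, =, X


@dataclass(frozen=True)
class EvidenceParams:
    """Thresholds for the automated alignment-evidence rules."""

    min_support_reads: int = 2
    breakpoint_window: int = 200  # bp around a breakpoint counted as "near"
    shortread_ins_min_obs: int = 10  # rule 2
    small_dup_max: int = 100  # rule 3 applies below this call size
    small_dup_obs_range: tuple[int, int] = (30, 200)
    large_dup_min: int = 500  # rule 4 applies above this call size
    large_dup_obs_factor: float = 0.8
    ins_merge_gap: int = 10  # merge read-level insertions this close (bp)

    def __post_init__(self) -> None:
        for name in ("breakpoint_window", "shortread_ins_min_obs",
                     "small_dup_max", "large_dup_min", "ins_merge_gap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class EvidenceResult:
    decision: str  # TP | FP
    rule: Optional[int] = None  # rule number that fired, None for default FP
    n_support: int = 0
    no_coverage: bool = False


@dataclass
class SampledValidation:
    """Validation outcome for one stratum x class x size-range sample."""

    stratum: str
    vclass: str
    size_range: str
    n_initial_fp: int
    n_sampled: int
    n_validated_tp: int = 0

    def __post_init__(self) -> None:
        if not self.n_validated_tp <= self.n_sampled <= max(
            self.n_initial_fp, self.n_sampled
        ):
            raise ValueError("need n_validated_tp <= n_sampled <= n_initial_fp")


def stratum_group(stratum: Optional[str]) -> str:
    """Collapse STR/SegDup into one repetitive-region group for sampling."""
    return "nonrepeat" if stratum == "nonrepeat" else "repeat"


def size_range_label(call: VariantCall) -> str:
    if call.scale == "indel":
        for low, high in INDEL_SIZE_RANGES:
            if low <= call.size <= high:
                return f"{low}-{high}"
    return "all"


def sample_group_key(result: MatchResult) -> tuple[str, str, str]:
    call = result.call
    return (stratum_group(result.stratum), class_label(call), size_range_label(call))


def sample_tfp(
    tfp: Sequence[MatchResult],
    n: int = 50,
    seed: int = 0,
) -> dict[tuple[str, str, str], list[MatchResult]]:
    """Uniform sample (without replacement) of tentative FPs per group.

    Groups are stratum (nonrepeat/repeat) x class (SNV, ins, del, INS, DEL)
    x indel size range (1-5 / 6-50 bp; "all" otherwise).  Groups smaller
    than ``n`` are taken whole.  Each group draws from its own RNG substream
    derived deterministically from ``seed`` and the group key, so results
    are reproducible and independent of group iteration order.
    """
    groups: dict[tuple[str, str, str], list[MatchResult]] = {}
    for r in tfp:
        if r.status != "tFP":
            continue
        groups.setdefault(sample_group_key(r), []).append(r)
    sampled: dict[tuple[str, str, str], list[MatchResult]] = {}
    for key, members in groups.items():
        members = sorted(members, key=lambda r: r.call.sort_key())
        if len(members) <= n:
            sampled[key] = list(members)
            continue
        rng = np.random.default_rng([seed, zlib.crc32("/".join(key).encode())])
        idx = np.sort(rng.choice(len(members), size=n, replace=False))
        sampled[key] = [members[i] for i in idx]
    return sampled


class AlignmentEvidence:
    """Read-level evidence lookup over a SAM/BAM file.

    Indexed coordinate-sorted BAMs are fetched lazily; plain SAM (or
    unindexed BAM) files are loaded once into per-chromosome sorted lists,
    which is the intended mode for the synthetic fixtures.
    """

    def __init__(self, path: str):
        self.path = str(path)
        self._af = pysam.AlignmentFile(self.path)
        self._indexed = False
        try:
            self._indexed = self._af.has_index()
        except (AttributeError, ValueError):
            self._indexed = False
        self._by_chrom: Optional[dict[str, list]] = None
        if not self._indexed:
            self._load_all()

    def _load_all(self) -> None:
        by_chrom: dict[str, list] = {}
        for read in self._af:
            if read.is_unmapped:
                continue
            by_chrom.setdefault(read.reference_name, []).append(read)
        for reads in by_chrom.values():
            reads.sort(key=lambda r: r.reference_start)
        self._by_chrom = by_chrom

    def reads_over(self, chrom: str, start: int, end: int) -> list:
        """Mapped reads whose alignment span intersects [start, end)."""
        if self._indexed:
            if chrom not in self._af.references:
                return []
            return [
                r for r in self._af.fetch(chrom, max(0, start), end)
                if not r.is_unmapped
            ]
        reads = (self._by_chrom or {}).get(chrom, [])
        return [
            r for r in reads
            if r.reference_start < end and r.reference_end > start
        ]


def read_events(read, merge_gap: int = 10) -> dict:
    """Extract insertion/deletion events and end clips from one alignment.

    Returns ``ins`` as (ref_pos, length) pairs -- with insertions closer than
    ``merge_gap`` on the reference summed into one event -- ``del`` as
    (start, end) reference intervals, and the reference coordinates of any
    leading (5') / trailing (3') soft or hard clip.
    """
    ins: list[tuple[int, int]] = []
    dels: list[tuple[int, int]] = []
    ref = read.reference_start
    cigar = read.cigartuples or []
    for op, length in cigar:
        if op == 1:  # I
            if ins and ref - ins[-1][0] <= merge_gap:
                ins[-1] = (ins[-1][0], ins[-1][1] + length)
            else:
                ins.append((ref, length))
        elif op in (2, 3):  # D, N
            if op == 2:
                dels.append((ref, ref + length))
            ref += length
        elif op in _CIGAR_CONSUMES_REF:
            ref += length
    lclip = cigar[0][1] if cigar and cigar[0][0] in (4, 5) else 0
    rclip = cigar[-1][1] if cigar and cigar[-1][0] in (4, 5) else 0
    return {
        "ins": ins,
        "del": dels,
        "lclip_pos": read.reference_start if lclip else None,
        "lclip_len": lclip,
        "rclip_pos": read.reference_end if rclip else None,
        "rclip_len": rclip,
    }


def base_at(read, ref_pos: int) -> Optional[str]:
    """Query base aligned to a 0-based reference position, if any."""
    qpos = 0
    ref = read.reference_start
    for op, length in read.cigartuples or []:
        consumes_ref = op in _CIGAR_CONSUMES_REF
        consumes_query = op in _CIGAR_CONSUMES_QUERY
        if consumes_ref and consumes_query:
            if ref <= ref_pos < ref + length:
                seq = read.query_sequence
                return seq[qpos + (ref_pos - ref)].upper() if seq else None
        if consumes_ref:
            ref += length
            if ref > ref_pos and not consumes_query:
                return None
        if consumes_query:
            qpos += length
    return None


def _event_matches_call(call: VariantCall, ev_pos: int, ev_size: int,
                        params: EvidenceParams) -> bool:
    """Apply the class TP-matching predicate to a read-level event.

    The event plays the role of the reference variant; ``ev_pos`` is
    0-based.
    """
    from .matching import MatchParams

    mp = MatchParams()
    dist = abs(ev_pos - call.start0)
    if call.scale == "indel":
        max_dist = mp.indel_dist_factor * call.size
        if call.size == 1:
            max_dist = max(max_dist, mp.onebp_dist)
        if dist > max_dist:
            return False
        return mp.indel_size_ratio[0] <= call.size / ev_size <= mp.indel_size_ratio[1]
    # SV scale
    if call.vclass in ("INS", "DUP") or call.from_dup:
        if dist > mp.ins_bp_dist:
            return False
        if call.read_type == "short" and not (call.from_dup or call.vclass == "DUP"):
            # rule 2 floor: sub-10 bp read insertions are not valid support
            if ev_size < params.shortread_ins_min_obs:
                return False
            return True
        return mp.sv_size_ratio[0] <= call.size / ev_size <= mp.sv_size_ratio[1]
    return False


def _del_event_matches(call: VariantCall, ev: tuple[int, int]) -> bool:
    from .matching import MatchParams

    mp = MatchParams()
    ev_size = ev[1] - ev[0]
    if ev_size == 0:
        return False
    if call.scale == "indel":
        max_dist = mp.indel_dist_factor * call.size
        if call.size == 1:
            max_dist = max(max_dist, mp.onebp_dist)
        if abs(ev[0] - call.start0) > max_dist:
            return False
        return mp.indel_size_ratio[0] <= call.size / ev_size <= mp.indel_size_ratio[1]
    overlap = min(call.end0, ev[1]) - max(call.start0, ev[0])
    return overlap >= mp.rec_overlap * call.size and overlap >= mp.rec_overlap * ev_size


def check_alignment_evidence(
    call: VariantCall,
    alignments: AlignmentEvidence,
    params: EvidenceParams = EvidenceParams(),
) -> EvidenceResult:
    """Decide TP/FP for one call from long-read alignment evidence.

    See the module docstring for the rule cascade.  A locus with no reads is
    FP with the ``no_coverage`` flag set.
    """
    bw = params.breakpoint_window
    lo = call.start0 - bw
    hi = call.end0 + bw
    reads = alignments.reads_over(call.chrom, lo, hi)
    if not reads:
        return EvidenceResult("FP", no_coverage=True)

    is_dup = call.from_dup or call.vclass == "DUP"
    is_ins_like = call.vclass in ("INS", "DUP")
    bp1 = call.start0
    bp2 = call.start0 + call.size if is_dup or call.vclass == "DEL" else call.start0

    events = [read_events(r, params.ins_merge_gap) for r in reads]

    # rule 1: enough reads carrying a class-matching event
    n_support = 0
    for r, ev in zip(reads, events):
        if call.vclass == "SNV":
            ok = base_at(r, call.start0) == (call.alt_base or "").upper()
        elif call.vclass == "DEL":
            ok = any(_del_event_matches(call, d) for d in ev["del"])
        else:  # INS / DUP-as-INS
            ok = any(
                _event_matches_call(call, pos, size, params)
                for pos, size in ev["ins"]
            )
        if ok:
            n_support += 1
    if n_support >= params.min_support_reads:
        return EvidenceResult("TP", rule=1, n_support=n_support)

    near_ins = [
        (pos, size)
        for ev in events
        for pos, size in ev["ins"]
        if abs(pos - bp1) <= bw
    ]

    # rule 2: short-read SV INS with only sub-10 bp observed insertions
    if (
        call.read_type == "short" and is_ins_like and not is_dup
        and call.scale == "SV"
    ):
        largest = max((size for _, size in near_ins), default=0)
        if largest < params.shortread_ins_min_obs:
            return EvidenceResult("FP", rule=2)

    if is_dup:
        # rule 3: small DUP supported by a 30-200 bp read insertion
        if call.size < params.small_dup_max:
            lo_obs, hi_obs = params.small_dup_obs_range
            n_obs = sum(1 for _, size in near_ins if lo_obs <= size <= hi_obs)
            if n_obs >= params.min_support_reads:
                return EvidenceResult("TP", rule=3, n_support=n_obs)
        # rule 4: large DUP supported by a read insertion > 0.8 x its size
        if call.size > params.large_dup_min:
            thresh = params.large_dup_obs_factor * call.size
            n_obs = sum(1 for _, size in near_ins if size > thresh)
            if n_obs >= params.min_support_reads:
                return EvidenceResult("TP", rule=4, n_support=n_obs)

    # rule 5: clipped-read clusters flanking the breakpoints (INS/DUP)
    if is_ins_like:
        n5 = sum(
            1 for ev in events
            if ev["lclip_pos"] is not None and abs(ev["lclip_pos"] - bp1) <= bw
        )
        n3 = sum(
            1 for ev in events
            if ev["rclip_pos"] is not None and abs(ev["rclip_pos"] - bp2) <= bw
        )
        if n5 >= 2 and n3 >= 2:
            return EvidenceResult("TP", rule=5, n_support=min(n5, n3))

    return EvidenceResult("FP")


def validate_sample(
    samples: dict[tuple[str, str, str], list[MatchResult]],
    evidence: AlignmentEvidence,
    n_initial_fp: dict[tuple[str, str, str], int],
    params: EvidenceParams = EvidenceParams(),
) -> dict[tuple[str, str, str], SampledValidation]:
    """Run the evidence rules over each sampled group."""
    out: dict[tuple[str, str, str], SampledValidation] = {}
    for key, members in samples.items():
        n_tp = sum(
            1 for r in members
            if check_alignment_evidence(r.call, evidence, params).decision == "TP"
        )
        out[key] = SampledValidation(
            stratum=key[0], vclass=key[1], size_range=key[2],
            n_initial_fp=n_initial_fp.get(key, len(members)),
            n_sampled=len(members), n_validated_tp=n_tp,
        )
    return out


def validate_with_labels(
    samples: dict[tuple[str, str, str], list[MatchResult]],
    labels: dict[str, bool],
    n_initial_fp: dict[tuple[str, str, str], int],
) -> dict[tuple[str, str, str], SampledValidation]:
    """Adjudicate sampled tFPs from known ground-truth labels.

    Used with synthetic call sets whose generator recorded which calls are
    genuinely true; stands in for alignment evidence in replicated
    statistical experiments.
    """
    out: dict[tuple[str, str, str], SampledValidation] = {}
    for key, members in samples.items():
        n_tp = sum(1 for r in members if labels.get(r.call_id, False))
        out[key] = SampledValidation(
            stratum=key[0], vclass=key[1], size_range=key[2],
            n_initial_fp=n_initial_fp.get(key, len(members)),
            n_sampled=len(members), n_validated_tp=n_tp,
        )
    return out


def export_review_regions(
    samples: Iterable[MatchResult] | dict,
    path: str,
    window: int = 200,
) -> None:
    """Write a BED of sampled call loci +- ``window`` for optional manual
    review in a genome browser; coordinates are clipped at zero."""
    if isinstance(samples, dict):
        members = [r for group in samples.values() for r in group]
    else:
        members = list(samples)
    members.sort(key=lambda r: r.call.sort_key())
    with open(path, "w") as out:
        for r in members:
            call = r.call
            start = max(0, call.pos - window)
            end = call.pos + call.size + window
            out.write(f"{call.chrom}\t{start}\t{end}\t{call.call_id}\n")
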