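"""Truth (reference) variant set construction.

Two construction routes are provided:

* :func:`merge_nonredundant` -- append variants from an additional source to
  an existing truth set unless an equivalent member already exists, where
  "equivalent" is the class-specific TP-matching criterion (one consistent
  notion of "the same variant" throughout the toolkit).
* :func:`select_high_confidence` -- consensus selection of SVs detected by at
  least ``min_support`` independent call sets, clustered by single linkage
  with breakpoint distance <= 200 bp for INS and >= 50% reciprocal overlap
  for DEL.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import pysam

from .matching import MatchParams, TruthIndex, match_call
from .variants import CallSet, VariantCall, write_vcf

log = logging.getLogger(__name__)


@dataclass
class TruthVariant(VariantCall):
    """A reference-set variant carrying the provenance of its source set."""

    source_set: str = ""


def as_truth(v: VariantCall, source_set: str) -> TruthVariant:
    if isinstance(v, TruthVariant):
        return replace(v, source_set=source_set)
    return TruthVariant(source_set=source_set, **{f: getattr(v, f) for f in (
        "call_id", "chrom", "pos", "vclass", "size", "alt_base", "read_type",
        "source", "from_dup", "ref", "alt")})


def _scale_universe(variants: Iterable[VariantCall]) -> set[str]:
    return {v.scale or "SNV" for v in variants}


@dataclass
class TruthSet:
    """A sorted, non-redundant collection of reference variants."""

    variants: list[TruthVariant] = field(default_factory=list)
    label: str = "truth"

    def __post_init__(self) -> None:
        self.variants.sort(key=VariantCall.sort_key)

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self):
        return iter(self.variants)

    @property
    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for v in self.variants:
            key = f"{v.vclass}/{v.scale or 'SNV'}"
            counts[key] = counts.get(key, 0) + 1
        return counts

    @classmethod
    def from_callset(cls, callset: CallSet, label: Optional[str] = None) -> "TruthSet":
        label = label or callset.label or "truth"
        return cls(
            variants=[as_truth(c, label) for c in callset], label=label
        )


def merge_nonredundant(
    base: TruthSet, addition: CallSet, params: MatchParams = MatchParams()
) -> tuple[TruthSet, int]:
    """Append non-redundant variants from ``addition`` to ``base``.

    A candidate is redundant iff it matches an existing member (including
    members appended earlier in this merge) under the class-appropriate
    TP-matching criterion.  Both inputs should be normalized (DUP converted
    to INS for SV sets).  Returns the merged set and the number added.

    Raises ``ValueError`` when the two sets cover disjoint variant scales
    (e.g. merging an SV set into an SNV set).
    """
    if base.variants and addition.calls:
        if _scale_universe(base.variants).isdisjoint(_scale_universe(addition.calls)):
            raise ValueError(
                "class universes of base and addition are disjoint: "
                f"{_scale_universe(base.variants)} vs {_scale_universe(addition.calls)}"
            )
    members: list[TruthVariant] = list(base.variants)
    n_added = 0
    # rebuilding the index after every append would be quadratic; batch by
    # chromosome-sorted candidates and refresh the index as members grow
    index = TruthIndex(members)
    pending: list[TruthVariant] = []
    for cand in sorted(addition.calls, key=VariantCall.sort_key):
        # check against base index and against freshly appended members
        res = match_call(cand, index, params)
        if res.status == "TP":
            continue
        if pending:
            tmp_index = TruthIndex(pending)
            if match_call(cand, tmp_index, params).status == "TP":
                continue
        tv = as_truth(cand, addition.label or cand.source)
        pending.append(tv)
        n_added += 1
    members.extend(pending)
    log.info("merge_nonredundant: added %d of %d candidates", n_added, len(addition))
    return TruthSet(variants=members, label=base.label), n_added


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _cluster_link(
    a: VariantCall, b: VariantCall, params: MatchParams, enforce_ins_size_ratio: bool
) -> bool:
    if a.chrom != b.chrom or a.vclass != b.vclass:
        return False
    if a.vclass == "INS":
        if abs(a.pos - b.pos) > params.ins_bp_dist:
            return False
        if enforce_ins_size_ratio and b.size > 0:
            low, high = params.sv_size_ratio
            if not low <= a.size / b.size <= high:
                return False
        return True
    if a.vclass == "DEL":
        overlap = min(a.end0, b.end0) - max(a.start0, b.start0)
        return (
            overlap >= params.rec_overlap * a.size
            and overlap >= params.rec_overlap * b.size
        )
    return False


def select_high_confidence(
    callsets: list[CallSet],
    min_support: int = 4,
    params: MatchParams = MatchParams(),
    enforce_ins_size_ratio: bool = False,
) -> TruthSet:
    """Consensus high-confidence SVs detected by >= ``min_support`` call sets.

    All inputs must be SV-scale with DUP already converted to INS.  Calls are
    clustered across sets by single linkage (INS: breakpoint distance <= 200
    bp; DEL: >= 50% reciprocal overlap); clusters supported by at least
    ``min_support`` *distinct* call sets emit one representative: the
    median-size, median-position member, which makes the output invariant to
    the order in which call sets are given.  Size concordance is not enforced
    for INS clusters by default (``enforce_ins_size_ratio`` turns it on).
    """
    if len(callsets) < min_support:
        raise ValueError(
            f"need >= min_support={min_support} call sets, got {len(callsets)}"
        )
    items: list[tuple[VariantCall, int]] = []
    for set_idx, cs in enumerate(callsets):
        for call in cs:
            if call.scale != "SV":
                raise ValueError(
                    f"select_high_confidence expects SV-scale calls, got "
                    f"{call.vclass} of size {call.size}"
                )
            if call.vclass == "DUP":
                raise ValueError("convert DUP calls to INS before consensus selection")
            items.append((call, set_idx))
    order = sorted(range(len(items)), key=lambda i: items[i][0].sort_key())
    uf = _UnionFind(len(items))
    for oi, i in enumerate(order):
        a = items[i][0]
        # window bound: INS linking needs |dpos| <= ins_bp_dist; DEL overlap
        # needs the later start before a's end
        bound = max(params.ins_bp_dist, a.size)
        for j in order[oi + 1:]:
            b = items[j][0]
            if b.chrom != a.chrom or b.pos - a.pos > bound:
                break
            if _cluster_link(a, b, params, enforce_ins_size_ratio):
                uf.union(i, j)
    clusters: dict[int, list[int]] = {}
    for i in range(len(items)):
        clusters.setdefault(uf.find(i), []).append(i)
    selected: list[TruthVariant] = []
    for members in clusters.values():
        support = len({items[i][1] for i in members})
        if support < min_support:
            continue
        ranked = sorted(
            members,
            key=lambda i: (items[i][0].size, items[i][0].pos, items[i][0].call_id),
        )
        rep = items[ranked[(len(ranked) - 1) // 2]][0]
        selected.append(as_truth(rep, f"consensus/{support}"))
    selected.sort(key=VariantCall.sort_key)
    for k, tv in enumerate(selected):
        tv.call_id = f"hc{k}"
    log.info(
        "select_high_confidence: %d clusters -> %d with support >= %d",
        len(clusters), len(selected), min_support,
    )
    return TruthSet(variants=selected, label="high-confidence")


def write_truth_vcf(truth: TruthSet, path: str, contigs: dict[str, int]) -> None:
    """Write a truth set as VCF with a SOURCE INFO tag recording provenance."""
    extra = {v.call_id: {"SOURCE": v.source_set or "."} for v in truth}
    write_vcf(truth.variants, path, contigs, extra_info=extra)


def read_truth_vcf(path: str, read_type: str = "long") -> TruthSet:
    """Read a truth VCF written by :func:`write_truth_vcf`."""
    from .variants import read_vcf

    callset = read_vcf(path, read_type=read_type, source="truth")
    sources: dict[tuple, str] = {}
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            src = rec.info.get("SOURCE", ".")
            sources[(rec.chrom, rec.pos)] = src if isinstance(src, str) else str(src)
    variants = []
    for c in callset:
        vcf_pos = c.pos - 1 if c.vclass in ("DEL", "DUP") else c.pos
        variants.append(as_truth(c, sources.get((c.chrom, vcf_pos), "")))
    return TruthSet(variants=variants, label="truth")
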