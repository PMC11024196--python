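"""STR / segmental-duplication region sets and repeat stratification.

Region sets are per-chromosome sorted lists of 0-based half-open intervals.
STR annotations come from UCSC ``simpleRepeat`` table dumps and HipSTR-style
BED files, restricted to tandem-repeat tracts of 20-10,000 bp; segmental
duplications come from the UCSC ``genomicSuperDups`` table (not length
filtered).  Variants overlapping an STR interval are stratified as STR even
when they also overlap a SegDup; the remainder overlapping a SegDup are
SegDup; everything else is nonrepeat.
"""

from __future__ import annotations

import gzip
import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .variants import VariantCall

log = logging.getLogger(__name__)

STRATA = ("nonrepeat", "STR", "SegDup")

# column offsets (0-based, after the UCSC `bin` column is counted) of
# chrom/chromStart/chromEnd and the expected minimum column count per dialect
_UCSC_DIALECTS = {
    "simpleRepeat": {"chrom": 1, "start": 2, "end": 3, "min_cols": 16},
    "genomicSuperDups": {"chrom": 1, "start": 2, "end": 3, "min_cols": 14},
}


@dataclass
class RegionSet:
    """Per-chromosome sorted half-open intervals."""

    intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    label: str = "other"

    def add(self, chrom: str, start: int, end: int) -> None:
        if not 0 <= start < end:
            raise ValueError(f"invalid interval [{start}, {end})")
        self.intervals.setdefault(chrom, []).append((start, end))

    def coalesced(self) -> "RegionSet":
        """Return an equivalent set with sorted, non-overlapping intervals.

        Touching intervals (end == next start) are merged; total length is
        unaffected.
        """
        out = RegionSet(label=self.label)
        for chrom, ivs in self.intervals.items():
            merged: list[tuple[int, int]] = []
            for start, end in sorted(ivs):
                if merged and start <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], end))
                else:
                    merged.append((start, end))
            out.intervals[chrom] = merged
        return out

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """True if [start, end) overlaps any interval by >= 1 bp.

        Requires a coalesced set (sorted, non-overlapping intervals).
        """
        ivs = self.intervals.get(chrom)
        if not ivs:
            return False
        i = bisect_right(ivs, (start, float("inf")))
        # interval starting at or before `start` may cover it
        if i > 0 and ivs[i - 1][1] > start:
            return True
        # next interval may start inside [start, end)
        return i < len(ivs) and ivs[i][0] < end

    def __len__(self) -> int:
        return sum(len(ivs) for ivs in self.intervals.values())


def _open_text(path: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def load_ucsc_table(path: str, dialect: str) -> RegionSet:
    """Load a UCSC table dump (``simpleRepeat.txt`` or ``genomicSuperDups.txt``).

    Tables are tab-separated with a leading ``bin`` column; all rows become
    intervals, with no filtering applied here.
    """
    if dialect not in _UCSC_DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    spec = _UCSC_DIALECTS[dialect]
    label = "STR" if dialect == "simpleRepeat" else "SegDup"
    rs = RegionSet(label=label)
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < spec["min_cols"]:
                raise ValueError(
                    f"{path}:{lineno}: expected >= {spec['min_cols']} "
                    f"tab-separated columns for {dialect}, got {len(cols)}"
                )
            try:
                chrom = cols[spec["chrom"]]
                start = int(cols[spec["start"]])
                end = int(cols[spec["end"]])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row: {exc}") from exc
            rs.add(chrom, start, end)
    return rs


def load_bed(path: str, label: str = "other", one_based: bool = False) -> RegionSet:
    """Load a BED3+ file; header (track/browser/#) lines are skipped.

    ``one_based=True`` handles BED-like files whose start column is 1-based
    (as some HipSTR references are) by shifting starts down by one.  Rows with
    start >= end after conversion are rejected with a warning.
    """
    rs = RegionSet(label=label)
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                log.warning("%s:%d: fewer than 3 columns, row skipped", path, lineno)
                continue
            try:
                chrom, start, end = cols[0], int(cols[1]), int(cols[2])
            except ValueError:
                log.warning("%s:%d: non-numeric coordinates, row skipped", path, lineno)
                continue
            if one_based:
                start -= 1
            if start >= end or start < 0:
                log.warning("%s:%d: start >= end, row rejected", path, lineno)
                continue
            rs.add(chrom, start, end)
    return rs


def write_bed(rs: RegionSet, path: str) -> None:
    with open(path, "w") as out:
        for chrom in sorted(rs.intervals):
            for start, end in rs.intervals[chrom]:
                out.write(f"{chrom}\t{start}\t{end}\n")


def filter_by_length(rs: RegionSet, min_bp: int = 20, max_bp: int = 10000) -> RegionSet:
    """Keep intervals whose length is within [min_bp, max_bp], inclusive."""
    out = RegionSet(label=rs.label)
    for chrom, ivs in rs.intervals.items():
        kept = [(s, e) for s, e in ivs if min_bp <= e - s <= max_bp]
        if kept:
            out.intervals[chrom] = kept
    return out


def merge_union(a: RegionSet, b: RegionSet, label: str | None = None) -> RegionSet:
    """Coalesced union of two region sets."""
    out = RegionSet(label=label or a.label)
    for rs in (a, b):
        for chrom, ivs in rs.intervals.items():
            out.intervals.setdefault(chrom, []).extend(ivs)
    return out.coalesced()


def intersect(a: RegionSet, b: RegionSet, label: str = "other") -> RegionSet:
    """Coalesced intersection of two region sets."""
    a = a.coalesced()
    b = b.coalesced()
    out = RegionSet(label=label)
    for chrom in set(a.intervals) & set(b.intervals):
        ia, ib = a.intervals[chrom], b.intervals[chrom]
        i = j = 0
        result = []
        while i < len(ia) and j < len(ib):
            start = max(ia[i][0], ib[j][0])
            end = min(ia[i][1], ib[j][1])
            if start < end:
                result.append((start, end))
            if ia[i][1] < ib[j][1]:
                i += 1
            else:
                j += 1
        if result:
            out.intervals[chrom] = result
    return out


def total_length(rs: RegionSet) -> int:
    """Total bp covered; the input must be coalesced for this to be a measure."""
    return sum(e - s for ivs in rs.intervals.values() for s, e in ivs)


def build_str_regions(
    simple_repeat_path: str | None = None,
    hipstr_bed_path: str | None = None,
    min_bp: int = 20,
    max_bp: int = 10000,
    hipstr_one_based: bool = False,
) -> RegionSet:
    """Build the STR region set: length-filtered union of the TRF-based
    simpleRepeat table and a HipSTR reference BED (tracts of 20-10,000 bp)."""
    parts: list[RegionSet] = []
    if simple_repeat_path:
        parts.append(load_ucsc_table(simple_repeat_path, "simpleRepeat"))
    if hipstr_bed_path:
        parts.append(load_bed(hipstr_bed_path, label="STR", one_based=hipstr_one_based))
    if not parts:
        raise ValueError("need at least one STR input file")
    filtered = [filter_by_length(p, min_bp, max_bp) for p in parts]
    out = filtered[0]
    for p in filtered[1:]:
        out = merge_union(out, p, label="STR")
    return out.coalesced()


def classify_position(
    v: "VariantCall", str_rs: RegionSet, segdup_rs: RegionSet
) -> str:
    """Stratify a variant as ``STR``, ``SegDup`` or ``nonrepeat``.

    The variant footprint is its reference span for DEL/DUP and the single
    anchored base for SNV/INS (an insertion is a point event at its
    breakpoint).  A 1-bp overlap suffices; STR takes priority over SegDup.
    """
    start, end = v.start0, max(v.end0, v.start0 + 1)
    if v.vclass in ("SNV", "INS"):
        end = start + 1
    if str_rs.overlaps(v.chrom, start, end):
        return "STR"
    if segdup_rs.overlaps(v.chrom, start, end):
        return "SegDup"
    return "nonrepeat"
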