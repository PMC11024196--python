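"""Variant data model, VCF ingestion and normalization.

Variants are grouped into three classes by size: single-nucleotide variants
(SNV, size 0), short insertions/deletions (indel, 1-49 bp) and structural
variants (SV, >= 50 bp by default).  Duplications (DUP) are treated as a kind
of insertion and can be converted with :func:`dup_to_ins`.

Coordinate conventions
----------------------
``VariantCall.pos`` is the 1-based position of the first affected base: the
substituted base for an SNV, the anchored base for an insertion, and the first
deleted/duplicated base for a DEL/DUP.  All internal interval arithmetic uses
0-based half-open coordinates (``start0``/``end0``); the +-1 conversions happen
only in the VCF reader and writer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

import pysam

log = logging.getLogger(__name__)

#: size (bp) at or above which an insertion/deletion is a structural variant
SV_MIN_SIZE = 50

VCLASSES = ("SNV", "INS", "DEL", "DUP")
READ_TYPES = ("short", "long")


class ClassificationError(ValueError):
    """Raised when REF/ALT or SVTYPE/SVLEN cannot be resolved to a variant."""


@dataclass
class VariantCall:
    """One normalized variant observation from a call set."""

    call_id: str
    chrom: str
    pos: int  # 1-based, first affected base
    vclass: str  # SNV | INS | DEL | DUP
    size: int  # 0 for SNV
    alt_base: Optional[str] = None  # SNV only
    read_type: str = "short"
    source: str = ""
    from_dup: bool = False  # True when an INS originated as a DUP call
    ref: Optional[str] = None  # VCF REF allele when sequence-resolved
    alt: Optional[str] = None  # VCF ALT allele when sequence-resolved

    def __post_init__(self) -> None:
        if self.vclass not in VCLASSES:
            raise ValueError(f"unknown variant class {self.vclass!r}")
        if (self.size == 0) != (self.vclass == "SNV"):
            raise ValueError(
                f"size {self.size} inconsistent with class {self.vclass}"
            )
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.read_type not in READ_TYPES:
            raise ValueError(f"read_type must be one of {READ_TYPES}")

    @property
    def scale(self) -> Optional[str]:
        """``"indel"`` (1-49 bp), ``"SV"`` (>= 50 bp) or ``None`` for SNV."""
        if self.vclass == "SNV":
            return None
        return "SV" if self.size >= SV_MIN_SIZE else "indel"

    @property
    def start0(self) -> int:
        return self.pos - 1

    @property
    def end0(self) -> int:
        """End of the reference footprint (half-open).

        DEL/DUP span their deleted/duplicated bases; SNV/INS are point events
        at the affected/anchored base.
        """
        if self.vclass in ("DEL", "DUP"):
            return self.start0 + self.size
        return self.start0 + 1

    def sort_key(self) -> tuple:
        return (self.chrom, self.pos, self.size, self.call_id)


@dataclass
class CallSet:
    """An ordered collection of calls sharing one read technology."""

    calls: list[VariantCall] = field(default_factory=list)
    read_type: str = "short"
    label: str = ""

    def __post_init__(self) -> None:
        self.sort()

    def sort(self) -> None:
        self.calls.sort(key=VariantCall.sort_key)

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self) -> Iterator[VariantCall]:
        return iter(self.calls)


def classify_variant(
    ref_len: Optional[int],
    alt_len: Optional[int],
    svtype: Optional[str] = None,
    svlen: Optional[int] = None,
    sv_min_size: int = SV_MIN_SIZE,
) -> tuple[str, Optional[str], int]:
    """Classify an allele into ``(vclass, scale, size)``.

    Sequence-resolved alleles use ``|alt_len - ref_len|`` as the size;
    symbolic alleles use ``|svlen|``.  A size of zero is an SNV only for a
    single-base substitution.
    """
    if svtype is not None:
        if svlen is None:
            raise ClassificationError(f"symbolic {svtype} allele without a size")
        size = abs(int(svlen))
        vclass = svtype.split(":")[0].upper()
        if vclass not in ("INS", "DEL", "DUP"):
            raise ClassificationError(f"unsupported SVTYPE {svtype!r}")
        if size == 0:
            raise ClassificationError("symbolic allele with zero size")
        scale = "SV" if size >= sv_min_size else "indel"
        return vclass, scale, size

    if ref_len is None or alt_len is None:
        raise ClassificationError("neither sequence lengths nor SVTYPE/SVLEN given")
    size = abs(alt_len - ref_len)
    if size == 0:
        if ref_len == 1:
            return "SNV", None, 0
        raise ClassificationError(
            f"length-preserving multi-base allele (ref_len={ref_len}) is not "
            "a supported variant class"
        )
    vclass = "INS" if alt_len > ref_len else "DEL"
    scale = "SV" if size >= sv_min_size else "indel"
    return vclass, scale, size


def _record_passes_filter(record) -> bool:
    keys = list(record.filter.keys())
    return not keys or keys == ["PASS"]


def read_vcf(
    path: str,
    read_type: str = "short",
    source: Optional[str] = None,
    sv_min_size: int = SV_MIN_SIZE,
) -> CallSet:
    """Read a VCF 4.x file into a :class:`CallSet`.

    Multiallelic records are decomposed into one call per ALT; genotypes are
    ignored.  Records whose FILTER is neither PASS nor missing are skipped.
    Symbolic ALTs resolve their size from SVLEN, falling back to END-POS for
    DEL/DUP; a symbolic record with no resolvable size is skipped with a
    warning.
    """
    if source is None:
        source = path
    calls: list[VariantCall] = []
    n_skipped = 0
    with pysam.VariantFile(path) as vf:
        for record in vf:
            if not _record_passes_filter(record):
                continue
            alts = record.alts or ()
            for alt_i, alt in enumerate(alts):
                try:
                    call = _call_from_record(
                        record, alt, alt_i, read_type, source, sv_min_size
                    )
                except ClassificationError as exc:
                    n_skipped += 1
                    log.warning(
                        "skipping %s:%s ALT %s: %s", record.chrom, record.pos, alt, exc
                    )
                    continue
                if call is not None:
                    calls.append(call)
    for i, call in enumerate(sorted(calls, key=VariantCall.sort_key)):
        call.call_id = f"{source}:{i}"
    if n_skipped:
        log.warning("%s: skipped %d unresolvable ALT alleles", path, n_skipped)
    return CallSet(calls=calls, read_type=read_type, label=source)


def _svlen_for_alt(record, alt_i: int) -> Optional[int]:
    svlen = record.info.get("SVLEN")
    if svlen is None:
        return None
    if isinstance(svlen, (tuple, list)):
        if not svlen:
            return None
        svlen = svlen[alt_i] if alt_i < len(svlen) else svlen[0]
    return None if svlen is None else int(svlen)


def _call_from_record(
    record, alt: str, alt_i: int, read_type: str, source: str, sv_min_size: int
) -> Optional[VariantCall]:
    chrom = record.chrom
    if alt is None or alt in ("*", "."):
        raise ClassificationError("missing/overlapping-deletion ALT")
    if alt.startswith("<"):
        svtype = record.info.get("SVTYPE") or alt.strip("<>")
        svlen = _svlen_for_alt(record, alt_i)
        if svlen is None and svtype.split(":")[0].upper() in ("DEL", "DUP"):
            end = record.stop  # 0-based exclusive == 1-based END
            if end is not None and end > record.pos:
                svlen = end - record.pos
        vclass, _, size = classify_variant(None, None, str(svtype), svlen, sv_min_size)
        # VCF anchors symbolic DEL/DUP at the base before the event
        pos = record.pos + 1 if vclass in ("DEL", "DUP") else record.pos
        return VariantCall(
            call_id="", chrom=chrom, pos=pos, vclass=vclass, size=size,
            read_type=read_type, source=source,
        )
    ref = record.ref
    vclass, _, size = classify_variant(len(ref), len(alt), None, None, sv_min_size)
    if vclass == "SNV":
        return VariantCall(
            call_id="", chrom=chrom, pos=record.pos, vclass="SNV", size=0,
            alt_base=alt.upper(), read_type=read_type, source=source,
            ref=ref.upper(), alt=alt.upper(),
        )
    # sequence-resolved indel/SV: anchored base at POS, first deleted base POS+1
    pos = record.pos + 1 if vclass == "DEL" else record.pos
    return VariantCall(
        call_id="", chrom=chrom, pos=pos, vclass=vclass, size=size,
        read_type=read_type, source=source, ref=ref.upper(), alt=alt.upper(),
    )


def write_vcf(
    calls: Iterable[VariantCall],
    path: str,
    contigs: dict[str, int],
    extra_info: Optional[dict[str, dict]] = None,
) -> None:
    """Write calls as VCF 4.2.

    Sequence-resolved calls are written with their REF/ALT alleles; calls
    without stored alleles are written symbolically with SVTYPE/SVLEN/END.
    ``extra_info`` maps call_id -> {INFO key: value} (keys must be declared by
    the caller through this function's fixed header: SOURCE is supported).
    """
    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">')
    header.add_line('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">')
    header.add_line('##INFO=<ID=END,Number=1,Type=Integer,Description="End position">')
    header.add_line('##INFO=<ID=SOURCE,Number=1,Type=String,Description="Provenance">')
    for chrom, length in contigs.items():
        header.add_line(f"##contig=<ID={chrom},length={length}>")
    with pysam.VariantFile(path, "w", header=header) as out:
        for call in sorted(calls, key=VariantCall.sort_key):
            info = dict((extra_info or {}).get(call.call_id, {}))
            if call.ref is not None and call.alt is not None:
                vcf_pos = call.pos - 1 if call.vclass == "DEL" else call.pos
                rec = out.new_record(
                    contig=call.chrom, start=vcf_pos - 1, alleles=(call.ref, call.alt)
                )
            else:
                vcf_pos = call.pos - 1 if call.vclass in ("DEL", "DUP") else call.pos
                stop = (
                    vcf_pos + call.size if call.vclass in ("DEL", "DUP")
                    else vcf_pos
                )
                rec = out.new_record(
                    contig=call.chrom, start=vcf_pos - 1, stop=stop,
                    alleles=("N", f"<{call.vclass}>"),
                )
                rec.info["SVTYPE"] = call.vclass
                rec.info["SVLEN"] = -call.size if call.vclass == "DEL" else call.size
            for key, value in info.items():
                rec.info[key] = value
            rec.id = call.call_id or None
            out.write(rec)


def dup_to_ins(call: VariantCall) -> VariantCall:
    """Convert a DUP call to an INS at the DUP's first breakpoint.

    Duplications are a kind of insertion and many long-read callers emit them
    as INS, so call sets are harmonized before matching.  Non-DUP calls are
    returned unchanged; the conversion is idempotent.  The returned call keeps
    ``from_dup=True`` so DUP-specific matching and evidence rules still apply.
    """
    if call.vclass != "DUP":
        return call
    return replace(call, vclass="INS", from_dup=True, ref=None, alt=None)


def _is_duplicate_pair(a: VariantCall, b: VariantCall, ins_dist: int,
                       rec_overlap: float, ratio: tuple[float, float]) -> bool:
    if a.vclass != b.vclass or a.chrom != b.chrom:
        return False
    if a.size == 0 or b.size == 0:
        return False
    r = a.size / b.size
    if not (ratio[0] <= r <= ratio[1]):
        return False
    if a.vclass == "INS":
        return abs(a.pos - b.pos) <= ins_dist
    overlap = min(a.end0, b.end0) - max(a.start0, b.start0)
    return overlap >= rec_overlap * a.size and overlap >= rec_overlap * b.size


def deduplicate(
    callset: CallSet,
    ins_dist: int = 50,
    rec_overlap: float = 0.5,
    size_ratio: tuple[float, float] = (0.67, 1.5),
) -> CallSet:
    """Suppress likely duplicate calls within one call set.

    Two same-type calls are duplicates when they sit at (nearly) the same
    position -- INS within ``ins_dist`` bp, DEL/DUP with >= ``rec_overlap``
    reciprocal overlap -- and their size ratio lies in ``size_ratio``.  Of a
    duplicate group only the first call in (chrom, pos, size) order is kept,
    so the operation is deterministic and idempotent.  SNVs are never touched
    (they have no size).
    """
    kept: list[VariantCall] = []
    # per (chrom, vclass) sliding window over already-kept calls
    recent: dict[tuple[str, str], list[VariantCall]] = {}
    # window wide enough for both the INS distance and DEL/DUP overlap tests
    for call in sorted(callset.calls, key=VariantCall.sort_key):
        if call.vclass == "SNV":
            kept.append(call)
            continue
        key = (call.chrom, call.vclass)
        window = recent.setdefault(key, [])
        window[:] = [
            k for k in window
            if call.pos - k.pos <= max(ins_dist, k.size / rec_overlap)
        ]
        if any(
            _is_duplicate_pair(k, call, ins_dist, rec_overlap, size_ratio)
            for k in window
        ):
            continue
        window.append(call)
        kept.append(call)
    return CallSet(calls=kept, read_type=callset.read_type, label=callset.label)
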