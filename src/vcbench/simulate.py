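"""Synthetic benchmark fixtures: toy genomes, truth sets, degraded call sets
with known labels, and error-free simulated long-read alignments.

The generator emulates the statistical structure of a real benchmarking run
at desk scale: a genome with embedded tandem-repeat tracts and duplicated
segments, a planted truth set (about half of the indels inside STR tracts,
mirroring real indel distributions), call sets degraded to a chosen true
precision and recall with position/size jitter kept inside the matching
tolerances, and long reads whose CIGAR strings carry the planted events.
Every generator is fully deterministic under the configured seed; separate
RNG substreams are derived for the genome, truth, calls and reads.

The reference (known) truth set handed to an evaluation can be a subset of
the planted truth (``truth_known_fraction``): the calls matching hidden
truth variants are exactly the true positives the sampled-revalidation (TP2)
machinery is designed to recover.
"""

from __future__ import annotations

import json
import logging
from bisect import bisect_left, insort
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pysam

from .regions import RegionSet, write_bed
from .truthset import TruthSet, TruthVariant, write_truth_vcf
from .variants import CallSet, VariantCall, write_vcf

log = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic benchmark."""

    genome_length: int = 1_500_000
    chrom: str = "chr1"
    str_density: float = 0.026  # fraction of genome in STR tracts (human: ~2.6%)
    segdup_density: float = 0.03
    n_snv: int = 150
    n_indel_ins: int = 120
    n_indel_del: int = 120
    n_sv_ins: int = 40
    n_sv_del: int = 40
    n_sv_dup: int = 10
    precision_true: float = 0.8
    recall_true: float = 0.9
    truth_known_fraction: float = 0.85  # reference set completeness
    pos_jitter_sd: float = 8.0  # bp
    size_jitter_sd: float = 0.08  # fraction of size
    read_type: str = "long"  # read technology label for generated calls
    depth: int = 10  # spanning reads per variant locus
    read_length: int = 3000
    error_rate: float = 0.0  # optional substitution rate in simulated reads
    seed: int = 1

    def __post_init__(self) -> None:
        for name in ("str_density", "segdup_density", "precision_true",
                     "recall_true", "truth_known_fraction", "error_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("n_snv", "n_indel_ins", "n_indel_del", "n_sv_ins",
                     "n_sv_del", "n_sv_dup", "depth"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class ToyGenome:
    seqs: dict[str, str]
    str_regions: RegionSet
    segdup_regions: RegionSet

    @property
    def contigs(self) -> dict[str, int]:
        return {chrom: len(seq) for chrom, seq in self.seqs.items()}


class _Placer:
    """Tracks occupied intervals so planted features stay well separated."""

    def __init__(self, rng: np.random.Generator, length: int, margin: int = 1000):
        self.rng = rng
        self.length = length
        self.margin = margin
        self._starts: list[tuple[int, int]] = []  # sorted (start, end)

    def _free(self, start: int, end: int) -> bool:
        if start < self.margin or end > self.length - self.margin:
            return False
        i = bisect_left(self._starts, (start, -1))
        if i > 0 and self._starts[i - 1][1] > start:
            return False
        return not (i < len(self._starts) and self._starts[i][0] < end)

    def reserve(self, start: int, end: int) -> None:
        insort(self._starts, (start, end))

    def place(self, span: int, pad: int, max_tries: int = 200,
              within: Optional[tuple[int, int]] = None) -> Optional[int]:
        """Random free start for a footprint of ``span`` bp padded by ``pad``
        on each side; optionally restricted to a window."""
        lo = self.margin if within is None else max(self.margin, within[0])
        hi = (self.length if within is None else within[1]) - span
        if hi <= lo:
            return None
        for _ in range(max_tries):
            start = int(self.rng.integers(lo, hi))
            if self._free(start - pad, start + span + pad):
                self.reserve(start - pad, start + span + pad)
                return start
        return None


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def generate_toy_genome(cfg: SimulationConfig) -> ToyGenome:
    """Random genome with embedded STR tracts and duplicated segments.

    STR tracts have 2-6 bp units and 20-2,000 bp lengths (within the
    20-10,000 bp window the stratification uses); segmental duplications are
    literal copies of 2-10 kb segments.  Both are recorded as region sets.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    L = cfg.genome_length
    seq = _BASES[rng.integers(0, 4, size=L)]
    placer = _Placer(rng, L)
    str_rs = RegionSet(label="STR")
    covered = 0
    target = cfg.str_density * L
    while covered < target:
        unit_len = int(rng.integers(2, 7))
        unit = _random_seq(rng, unit_len)
        tract_len = min(2000, 20 + int(rng.exponential(60)))
        start = placer.place(tract_len, pad=100)
        if start is None:
            break
        tract = (unit * (tract_len // unit_len + 1))[:tract_len]
        seq[start:start + tract_len] = list(tract)
        str_rs.add(cfg.chrom, start, start + tract_len)
        covered += tract_len

    segdup_rs = RegionSet(label="SegDup")
    covered = 0
    target = cfg.segdup_density * L
    while covered < target:
        seg_len = min(10_000, 2000 + int(rng.exponential(2000)))
        src = placer.place(seg_len, pad=100)
        dst = placer.place(seg_len, pad=100)
        if src is None or dst is None:
            break
        seq[dst:dst + seg_len] = seq[src:src + seg_len]
        segdup_rs.add(cfg.chrom, src, src + seg_len)
        segdup_rs.add(cfg.chrom, dst, dst + seg_len)
        covered += 2 * seg_len

    return ToyGenome(
        seqs={cfg.chrom: "".join(seq)},
        str_regions=str_rs.coalesced(),
        segdup_regions=segdup_rs.coalesced(),
    )


def _indel_size(rng: np.random.Generator) -> int:
    if rng.random() < 0.8:
        return int(min(49, rng.geometric(0.4)))
    return int(rng.integers(2, 50))


def _sv_size(rng: np.random.Generator) -> int:
    return int(min(3000, 50 + rng.exponential(300)))


def _dup_size(rng: np.random.Generator) -> int:
    u = rng.random()
    if u < 0.4:
        return int(rng.integers(50, 100))
    if u < 0.7:
        return int(rng.integers(100, 501))
    return int(rng.integers(501, 1500))


#: exclusion padding (bp) around every planted variant; exceeds every matching
#: and deduplication tolerance so labels are unambiguous
PLACEMENT_PAD = 250


def generate_truth_set(genome: ToyGenome, cfg: SimulationConfig) -> TruthSet:
    """Plant SNVs, indels and SVs with REF/ALT consistent with the genome.

    Half of the indels are placed inside STR tracts.  Variants are separated
    by at least :data:`PLACEMENT_PAD` bp so that every call can be attributed
    to one planted variant unambiguously.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    chrom = cfg.chrom
    seq = genome.seqs[chrom]
    placer = _Placer(rng, len(seq))
    str_tracts = [
        iv for c, ivs in genome.str_regions.intervals.items() if c == chrom
        for iv in ivs if iv[1] - iv[0] >= 30
    ]
    variants: list[TruthVariant] = []

    def place(span: int, in_str: bool) -> Optional[int]:
        if in_str and str_tracts:
            for _ in range(40):
                s, e = str_tracts[int(rng.integers(0, len(str_tracts)))]
                if e - s <= span + 2:
                    continue
                start = placer.place(span, pad=PLACEMENT_PAD, max_tries=20,
                                     within=(s, e))
                if start is not None:
                    return start
            return None
        return placer.place(span, pad=PLACEMENT_PAD)

    def add(vclass: str, start0: int, size: int, ref: Optional[str],
            alt: Optional[str], alt_base: Optional[str] = None) -> None:
        pos = start0 + 1
        variants.append(TruthVariant(
            call_id=f"t{len(variants)}", chrom=chrom, pos=pos, vclass=vclass,
            size=size, alt_base=alt_base, read_type="long", source="sim",
            ref=ref, alt=alt, source_set="sim",
        ))

    for _ in range(cfg.n_snv):
        start0 = place(1, in_str=False)
        if start0 is None:
            break
        ref = seq[start0]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        add("SNV", start0, 0, ref, alt, alt_base=alt)

    for vclass, count in (("INS", cfg.n_indel_ins), ("DEL", cfg.n_indel_del)):
        for k in range(count):
            size = _indel_size(rng)
            in_str = k % 2 == 0  # half of the indels inside STR tracts
            if vclass == "INS":
                start0 = place(1, in_str)
                if start0 is None:
                    continue
                anchor = seq[start0]
                add("INS", start0, size, anchor, anchor + _random_seq(rng, size))
            else:
                start0 = place(size + 1, in_str)
                if start0 is None:
                    continue
                # pos points at the first deleted base; VCF anchors one left
                anchor = seq[start0]
                deleted = seq[start0 + 1:start0 + 1 + size]
                add("DEL", start0 + 1, size, anchor + deleted, anchor)

    for vclass, count, sizer in (
        ("INS", cfg.n_sv_ins, _sv_size),
        ("DEL", cfg.n_sv_del, _sv_size),
        ("DUP", cfg.n_sv_dup, _dup_size),
    ):
        for _ in range(count):
            size = sizer(rng)
            span = 1 if vclass == "INS" else size + 1
            start0 = placer.place(span, pad=PLACEMENT_PAD + (200 if vclass != "DEL" else 0))
            if start0 is None:
                continue
            if vclass == "INS":
                anchor = seq[start0]
                add("INS", start0, size, anchor, anchor + _random_seq(rng, size))
            elif vclass == "DEL":
                anchor = seq[start0]
                add("DEL", start0 + 1, size, anchor + seq[start0 + 1:start0 + 1 + size],
                    anchor)
            else:  # DUP: symbolic, duplicated bases start at start0+1
                add("DUP", start0 + 1, size, None, None)

    return TruthSet(variants=variants, label="sim-truth")


def _jitter_call(
    t: TruthVariant, rng: np.random.Generator, cfg: SimulationConfig
) -> tuple[str, int, int]:
    """Jittered (vclass, pos, size) for a true call, kept within the matching
    tolerance of its source variant."""
    if t.vclass == "SNV":
        return "SNV", t.pos, 0
    size = t.size
    new_size = size + int(round(rng.normal(0, cfg.size_jitter_sd * size)))
    # keep the called/truth size ratio safely inside [0.5, 2.0]
    lo = max(1, int(np.ceil(0.55 * size)))
    hi = max(lo, int(np.floor(1.8 * size)))
    if t.scale == "indel":
        hi = min(hi, 49)
    elif t.vclass == "DEL":
        lo, hi = max(50, int(np.ceil(0.87 * size))), int(np.floor(1.15 * size))
    else:
        lo = max(lo, 50)
    new_size = int(np.clip(new_size, lo, hi))

    d = int(round(rng.normal(0, cfg.pos_jitter_sd)))
    if t.vclass == "DEL" and t.scale == "SV":
        max_d = int(0.1 * min(size, new_size))
    elif t.scale == "SV":
        max_d = 200
    else:
        max_d = int(0.5 * new_size) if new_size > 1 else 1
    d = int(np.clip(d, -max_d, max_d))
    return t.vclass, t.pos + d, new_size


def generate_callset(
    truth: TruthSet,
    cfg: SimulationConfig,
    genome: Optional[ToyGenome] = None,
) -> tuple[CallSet, dict[str, bool]]:
    """Degrade a truth set into a call set with known per-call labels.

    A ``recall_true`` fraction of truth variants becomes jittered true calls;
    false calls are added to bring precision to ``precision_true``, placed so
    that they violate every matching predicate against every planted variant
    (further than any tolerance from same-class truths).  Returns the call
    set and a ground-truth label per call id (True = genuinely present).
    """
    rng = np.random.default_rng([cfg.seed, 2])
    length = genome.contigs[cfg.chrom] if genome else cfg.genome_length
    seq = genome.seqs[cfg.chrom] if genome else None
    placer = _Placer(rng, length)
    for t in truth:
        placer.reserve(t.start0 - PLACEMENT_PAD, t.end0 + PLACEMENT_PAD)

    calls: list[VariantCall] = []
    labels: dict[str, bool] = {}

    def new_call(vclass: str, pos: int, size: int, label: bool,
                 alt_base: Optional[str] = None,
                 ref: Optional[str] = None, alt: Optional[str] = None) -> None:
        cid = f"c{len(calls)}"
        calls.append(VariantCall(
            call_id=cid, chrom=cfg.chrom, pos=pos, vclass=vclass, size=size,
            alt_base=alt_base, read_type=cfg.read_type, source="simcalls",
            ref=ref, alt=alt,
        ))
        labels[cid] = label

    n_tp = 0
    for t in truth:
        if rng.random() >= cfg.recall_true:
            continue
        vclass, pos, size = _jitter_call(t, rng, cfg)
        keep_alleles = (pos, size) == (t.pos, t.size)
        new_call(vclass, pos, size, True, alt_base=t.alt_base,
                 ref=t.ref if keep_alleles else None,
                 alt=t.alt if keep_alleles else None)
        n_tp += 1

    p = cfg.precision_true
    n_fp = int(round(n_tp * (1 - p) / p)) if p > 0 else 0
    truth_classes = [
        (t.vclass, t.scale) for t in truth.variants
    ] or [("SNV", None)]
    for _ in range(n_fp):
        vclass, scale = truth_classes[int(rng.integers(0, len(truth_classes)))]
        if vclass == "SNV":
            size = 0
        elif scale == "indel":
            size = _indel_size(rng)
        elif vclass == "DUP":
            size = _dup_size(rng)
        else:
            size = _sv_size(rng)
        span = size + 1 if vclass in ("DEL", "DUP") else 1
        start0 = placer.place(span, pad=PLACEMENT_PAD)
        if start0 is None:
            log.warning("generate_callset: ran out of space for FP placement")
            break
        if vclass == "SNV":
            ref = seq[start0] if seq else "A"
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            new_call("SNV", start0 + 1, 0, False, alt_base=alt, ref=ref, alt=alt)
        elif vclass == "DEL":
            new_call("DEL", start0 + 2, size, False)
        else:
            new_call(vclass, start0 + 1, size, False)

    cs = CallSet(calls=calls, read_type=cfg.read_type, label="simcalls")
    log.info("generate_callset: %d calls (%d true, %d false)",
             len(cs), n_tp, len(cs) - n_tp)
    return cs, labels


def split_known_truth(
    truth: TruthSet, cfg: SimulationConfig
) -> tuple[TruthSet, TruthSet]:
    """Split the planted truth into (known reference set, hidden variants).

    The hidden fraction emulates true variants absent from curated reference
    sets; calls matching them are the TPs that sampled re-validation (TP2)
    must recover.
    """
    rng = np.random.default_rng([cfg.seed, 4])
    n = len(truth)
    n_known = int(round(cfg.truth_known_fraction * n))
    known_idx = set(rng.choice(n, size=n_known, replace=False).tolist())
    known = [v for i, v in enumerate(truth.variants) if i in known_idx]
    hidden = [v for i, v in enumerate(truth.variants) if i not in known_idx]
    return (
        TruthSet(variants=known, label="sim-reference"),
        TruthSet(variants=hidden, label="sim-hidden"),
    )


# ---------------------------------------------------------------------------
# simulated long-read alignments


def _apply_error(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hits = rng.random(len(arr)) < rate
    if hits.any():
        arr[hits] = _BASES[rng.integers(0, 4, size=int(hits.sum()))]
    return "".join(arr)


def generate_alignments(
    genome: ToyGenome,
    variants: TruthSet | list[VariantCall],
    cfg: SimulationConfig,
    path: str,
) -> None:
    """Simulate error-free long reads over a toy genome into SAM/BAM.

    Background reads tile the whole genome with pure-match CIGARs.  Each
    planted variant additionally receives ``cfg.depth`` spanning reads whose
    CIGARs carry the corresponding I/D event (or the alternate base for
    SNVs); large insertions and duplications also get two 5'-clipped and two
    3'-clipped reads at their breakpoints, as reads ending inside inserted
    sequence would.  Output is coordinate sorted; ``.bam`` paths are written
    as indexed BAM, everything else as SAM.
    """
    rng = np.random.default_rng([cfg.seed, 3])
    chrom = cfg.chrom
    seq = genome.seqs[chrom]
    L = len(seq)
    rl = cfg.read_length

    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": ln} for c, ln in genome.contigs.items()],
    })

    reads: list[tuple[int, pysam.AlignedSegment]] = []
    counter = 0

    def emit(name: str, start: int, cigar: list[tuple[int, int]], qseq: str) -> None:
        nonlocal counter
        a = pysam.AlignedSegment(header)
        a.query_name = f"{name}.{counter}"
        counter += 1
        a.reference_name = chrom
        a.reference_start = start
        a.mapping_quality = 60
        a.cigartuples = cigar
        a.query_sequence = _apply_error(qseq, rng, cfg.error_rate)
        a.flag = 0
        reads.append((start, a))

    # background tiling at modest depth with pure-match CIGARs
    step = max(1, rl // 3)
    for start in range(0, max(1, L - rl), step):
        emit("bg", start, [(0, rl)], seq[start:start + rl])

    ins_seqs: dict[str, str] = {}
    for v in variants:
        if v.vclass == "INS":
            ins_seqs[v.call_id] = (
                (v.alt or "")[1:] if v.alt else _random_seq(rng, v.size)
            )
        elif v.vclass == "DUP":
            ins_seqs[v.call_id] = seq[v.start0:v.start0 + v.size]

    for v in variants:
        bp1 = v.start0
        bp2 = v.end0 if v.vclass in ("DEL", "DUP") else bp1 + 1
        flank = 300
        # widen the reference window so spanning reads exist for large DELs
        win = rl if v.vclass not in ("DEL", "DUP") else max(rl, v.size + 2 * flank + 100)
        lo = max(0, bp2 + flank - win)
        hi = max(lo + 1, min(bp1 - flank, L - win))
        starts = np.linspace(lo, hi, max(cfg.depth, 1)).astype(int)
        for s in starts:
            e = min(L, s + win)
            if v.vclass == "SNV":
                qseq = seq[s:bp1] + (v.alt_base or "N") + seq[bp1 + 1:e]
                emit("snv", s, [(0, e - s)], qseq)
            elif v.vclass == "DEL":
                dstart, dend = bp1, bp1 + v.size
                if not (s + 50 < dstart and dend + 50 < e):
                    continue
                cigar = [(0, dstart - s), (2, v.size), (0, e - dend)]
                emit("del", s, cigar, seq[s:dstart] + seq[dend:e])
            else:
                # INS or DUP: insertion at the breakpoint (a tandem
                # duplication aligns as an insertion at its first breakpoint)
                ip = bp1
                if not (s + 50 < ip and ip + 50 < e):
                    continue
                inserted = ins_seqs[v.call_id]
                cigar = [(0, ip - s), (1, len(inserted)), (0, e - ip)]
                emit("ins", s, cigar, seq[s:ip] + inserted + seq[ip:e])

        if v.vclass in ("INS", "DUP") and v.scale == "SV":
            ip = bp1
            inserted = ins_seqs[v.call_id]
            clip = min(len(inserted), 500)
            m = min(1000, L - ip)
            for _ in range(2):  # reads starting inside the insertion: 5' clips
                emit("clip5", ip, [(4, clip), (0, m)],
                     inserted[-clip:] + seq[ip:ip + m])
            rend = bp2 if v.vclass == "DUP" else ip
            m2 = min(1000, rend)
            for _ in range(2):  # reads ending inside the insertion: 3' clips
                emit("clip3", rend - m2, [(0, m2), (4, clip)],
                     seq[rend - m2:rend] + inserted[:clip])

    reads.sort(key=lambda t: t[0])
    mode = "wb" if str(path).endswith(".bam") else "w"
    with pysam.AlignmentFile(path, mode, header=header) as out:
        for _, a in reads:
            out.write(a)
    if mode == "wb":
        pysam.index(str(path))


# ---------------------------------------------------------------------------
# one-call bundle


def write_fasta(genome: ToyGenome, path: str, width: int = 80) -> None:
    with open(path, "w") as out:
        for chrom, seq in genome.seqs.items():
            out.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i:i + width] + "\n")


def simulate_bundle(cfg: SimulationConfig, out_dir: str) -> dict[str, str]:
    """Generate the full fixture bundle on disk.

    Writes genome FASTA, STR/SegDup BEDs, full and known-reference truth
    VCFs, a call VCF, a JSON label sidecar, simulated alignments (SAM) and
    the configuration used.  Returns the path of every artifact.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome = generate_toy_genome(cfg)
    truth = generate_truth_set(genome, cfg)
    known, hidden = split_known_truth(truth, cfg)
    calls, labels = generate_callset(truth, cfg, genome)

    paths = {name: str(out / fname) for name, fname in {
        "genome": "genome.fa", "str_bed": "str.bed", "segdup_bed": "segdup.bed",
        "truth_full": "truth_full.vcf", "truth_known": "truth_known.vcf",
        "calls": "calls.vcf", "labels": "labels.json",
        "alignments": "alignments.sam", "config": "config.json",
    }.items()}

    write_fasta(genome, paths["genome"])
    write_bed(genome.str_regions, paths["str_bed"])
    write_bed(genome.segdup_regions, paths["segdup_bed"])
    write_truth_vcf(truth, paths["truth_full"], genome.contigs)
    write_truth_vcf(known, paths["truth_known"], genome.contigs)
    write_vcf(calls.calls, paths["calls"], genome.contigs)
    with open(paths["labels"], "w") as fh:
        json.dump(labels, fh, indent=0, sort_keys=True)
    generate_alignments(genome, truth, cfg, paths["alignments"])
    with open(paths["config"], "w") as fh:
        json.dump(asdict(cfg), fh, indent=2, sort_keys=True)
    return paths
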