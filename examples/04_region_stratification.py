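"""Build STR/SegDup region sets and stratify variants.

STR regions are the union of a TRF-style simpleRepeat table and a HipSTR
reference BED, keeping tandem-repeat tracts of 20-10,000 bp; segmental
duplications come from a genomicSuperDups table unfiltered.  A variant
overlapping both is counted as STR.
"""

import tempfile
from pathlib import Path

from vcbench.regions import (build_str_regions, classify_position, intersect,
                             load_ucsc_table, total_length)
from vcbench.variants import VariantCall


def simple_repeat_row(chrom, s, e):
    return "\t".join(map(str, [585, chrom, s, e, "trf", 2, (e - s) / 2, 2,
                               95, 0, 50, 25, 25, 25, 25, 1.9, "AC"]))


def superdup_row(chrom, s, e):
    return "\t".join(map(str, [585, chrom, s, e, "dup", 0, "+", "chr9", 1, 2,
                               e - s, 0, 99, 9000, 9000]))


with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    (tmp / "simpleRepeat.txt").write_text("\n".join([
        simple_repeat_row("chr1", 1000, 1200),
        simple_repeat_row("chr1", 5000, 5015),   # 15 bp: below the TR window
        simple_repeat_row("chr1", 8000, 30000),  # 22 kb: above it
    ]) + "\n")
    (tmp / "hipstr.bed").write_text("chr1\t1150\t1400\nchr1\t6000\t6100\n")
    (tmp / "superdups.txt").write_text(
        superdup_row("chr1", 1300, 45000) + "\n")

    str_rs = build_str_regions(str(tmp / "simpleRepeat.txt"),
                               str(tmp / "hipstr.bed"))
    segdup_rs = load_ucsc_table(str(tmp / "superdups.txt"),
                                "genomicSuperDups").coalesced()

print("STR intervals:", str_rs.intervals)
print("STR total:", total_length(str_rs), "bp")
print("SegDup total:", total_length(segdup_rs), "bp")
print("STR x SegDup overlap:", total_length(intersect(str_rs, segdup_rs)), "bp")

for pos, size, vclass in [(1100, 10, "INS"), (1350, 300, "DEL"),
                          (2000, 0, "SNV"), (46000, 0, "SNV")]:
    v = VariantCall(call_id="v", chrom="chr1", pos=pos, vclass=vclass,
                    size=size, alt_base="A" if vclass == "SNV" else None)
    print(f"{vclass} at {pos} (size {size}) ->",
          classify_position(v, str_rs, segdup_rs))

# The 1,350 DEL overlaps both an STR tract and the SegDup but is stratified
# STR: tandem-repeat context takes priority.
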