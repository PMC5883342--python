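"""Import CNV segments from a PennCNV .rawcnv file, then filter and merge.

Writes a tiny .rawcnv in the documented line dialect, reads it back, drops
segments with fewer than 10 SNPs or shorter than 10 kb, and merges
same-state segments within 1 kb of each other.
"""

import tempfile
from pathlib import Path

from cnvgeno import Region, filter_cnvs, merge_cnvs, restrict_to_region
from cnvgeno.signal_io import read_penncnv_rawcnv

raw = """\
chr7:72700000-74100000 numsnp=1500 length=1,400,001 state2,cn=1 WS01 startsnp=rs001 endsnp=rs950
chr7:74100500-74150000 numsnp=40 length=49,501 state2,cn=1 WS01 startsnp=rs951 endsnp=rs990
chr7:60000000-60005000 numsnp=6 length=5,001 state5,cn=3 WS01 startsnp=rs101 endsnp=rs106
"""
with tempfile.TemporaryDirectory() as d:
    path = Path(d) / "sample.rawcnv"
    path.write_text(raw)
    segments = read_penncnv_rawcnv(path)

print(f"parsed {len(segments)} segments")
kept = filter_cnvs(segments)                       # drops the 6-SNP 5-kb fragment
print(f"after 10-SNP / 10-kb filter: {len(kept)}")
merged = merge_cnvs(kept, max_gap=1000)            # 499-bp gap: the two cn=1 pieces fuse
for seg in merged:
    print(f"  {seg.chrom}:{seg.start}-{seg.end} cn={seg.copy_number} "
          f"n_snps={seg.n_snps} length={seg.length}")
locus = restrict_to_region(merged, Region("chr7", 72_700_000, 74_100_000))
print(f"overlapping the target locus: {len(locus)}")
# The merged deletion spans both input pieces with their SNP counts summed;
# only segments overlapping the locus are carried into genotype calling.
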