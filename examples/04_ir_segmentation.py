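"""Irreducible-region merging of a log2 fold-change signal.

Two fold-change peaks separated by a shallow dip merge into one region
when the mean area above the threshold (MAAT) stays at or above the
threshold on both sides of each crossing point; a deep, wide dip forces a
split.  This is the parameter-free alternative to distance-based merging:
only the fold-change threshold (default 0.5) is needed.
"""

from smallder import GlobalParams, IrParams, ir_segment
from smallder.rle import RunLengthTrack

wide = GlobalParams(min_size=1)
p = IrParams(min_log_fold_change=0.5)

shallow = RunLengthTrack("chr1", [2.0, 0.4, 2.0], [20, 5, 20])
deep = RunLengthTrack("chr1", [2.0, 0.0, 2.0], [20, 200, 20])
for name, lfc in (("shallow 5 nt dip", shallow), ("deep 200 nt gap", deep)):
    mask = RunLengthTrack("chr1", [1.0], [lfc.total_length])
    regions = ir_segment(lfc, mask, p, wide)
    pretty = ", ".join(f"{r.start}-{r.end}" for r in regions)
    print(f"{name}: {len(regions)} region(s): {pretty}")
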