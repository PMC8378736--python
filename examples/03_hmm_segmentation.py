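"""Two-state Viterbi segmentation of a per-nucleotide p-value track.

Constructs a run-length p-value track with two significant islands in a
p = 1 background — the shape the HMM sees after per-nucleotide testing —
and decodes the most likely state path.  The decoder binarizes
observations at pt = 0.1 and skips through the constant background in
O(1) per run, yet returns exactly the dense Viterbi path; the printed
regions are the maximal "differentially expressed"-state runs that pass
the default 18 nt size filter (so the 10 nt island is dropped).
"""

from smallder import GlobalParams, HmmParams, hmm_segment, viterbi_two_state
from smallder.rle import RunLengthTrack

pvals = RunLengthTrack(
    "chr1",
    [1.0, 1e-8, 1.0, 0.02, 1.0],
    [5000, 25, 3000, 10, 2000],
)
path = viterbi_two_state(pvals, HmmParams())
print("state path (state, run length):", path)

regions = hmm_segment(pvals, HmmParams(), GlobalParams())
for r in regions:
    print(f"detected region {r.chromosome}:{r.start}-{r.end} ({r.length} nt)")
print("the 10 nt island is below the 18 nt minimum size and is discarded")
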