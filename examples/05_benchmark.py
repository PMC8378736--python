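"""One replicate of the synthetic benchmark, scaled down for a quick run.

Simulates a 400-locus two-condition dataset, derives the truth set (loci
passing a per-locus NB test at 5% FDR), runs the detector, and reports the
ROC AUC over all loci ranked by the best matched region p-value (80%-overlap
matching) plus the recall of the truth set.  At the full default scale
(2000 loci, 6+6 replicates) the mean AUC over five seeds is the package's
headline benchmark number — see scripts/acceptance.py.
"""

from smallder import SimConfig
from smallder.simulate import benchmark_auc

cfg = SimConfig(
    n_class1_loci=200, n_class2_loci=200, n_up=40, n_down=40,
    reads_per_sample=200_000,
)
result = benchmark_auc(seed=7, cfg=cfg)
print(f"loci: {result['n_loci']}, truth set: {result['n_truth']} loci")
print(f"regions reported at 5% FDR: {result['n_regions']}")
print(f"recall of truth loci: {result['recall']:.3f}")
print(f"ROC AUC: {result['auc']:.4f}")
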