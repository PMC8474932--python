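#!/usr/bin/env python
"""Recovery of generated bipartite-Xi fractions across a differentiation
time course, and ROC of the |dLMD| classifier.

Simulates a strong-effect time course (mid-range contacts halved, long-range
quadrupled on the Xi; truth fractions 0.10-0.85), calls cells at the chr1
10%-FPR threshold, and reports per time point the raw call rate, the
FPR-corrected recovered fraction with its 95% interval, and whether the
generating truth lies inside it.
"""

from pathlib import Path

from xci_scstruct.evaluation import timecourse_recovery

res = timecourse_recovery(seed=0)
table = res["per_time_point"]

out = Path("results")
out.mkdir(exist_ok=True)
table.to_csv(out / "bipartite_recovery.tsv", sep="\t", index=False)
res["calls"].to_csv(out / "bipartite_recovery_calls.tsv", sep="\t", index=False)

print(table.to_string(index=False,
                      float_format=lambda v: f"{v:.3f}"))
print(f"\nall truths inside 95% intervals: {table['truth_in_ci'].all()}")
print(f"|dLMD| ROC AUC (bipartite chrX vs chr1 null): {res['auc']:.3f}")
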