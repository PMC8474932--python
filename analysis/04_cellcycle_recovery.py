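#!/usr/bin/env python
"""Cell-cycle archetype recovery by Spearman-distance k-means.

Simulates four archetypes (one mitotic with the 2-12 Mb band, three
interphase stages with contact enrichments at distinct distance scales),
clusters the non-allelic autosomal CDPs restricted to 50 kb-8 Mb with k=4,
and scores the recovery (adjusted Rand index) and the identification of the
mitotic cluster by band fraction.
"""

from pathlib import Path

from xci_scstruct.evaluation import cellcycle_recovery

res = cellcycle_recovery(seed=0)

out = Path("results")
out.mkdir(exist_ok=True)
res["assignments"].to_csv(out / "cellcycle_assignments.tsv", sep="\t")

print(f"adjusted Rand index vs generator archetypes: {res['ari']:.3f}")
print(f"fraction of the mitotic cluster that is truly mitotic: "
      f"{res['mitotic_recall']:.3f}")
print(res["assignments"].groupby(["archetype", "cluster"]).size()
      .unstack(fill_value=0).to_string())
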