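#!/usr/bin/env python
"""Summary figures from the pipeline and benchmark outputs.

Reads the tables written by the earlier scripts (run 01, 03 and 05 first)
and draws: the z-scaled allelic CDP heatmaps for chrX, the per-time-point
bipartite/silencing proportions, and the Xi contact-score track with its
hinge dip.  Figures are written to results/figures/.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from xci_scstruct.cdp import zscale_profiles

results = Path("results")
figdir = results / "figures"
figdir.mkdir(parents=True, exist_ok=True)

# --- allelic CDP heatmaps (chrX) -------------------------------------------
cdp = pd.read_csv(results / "pipeline" / "cdp.tsv", sep="\t")
fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
for ax, allele in zip(axes, ("hap1", "hap2")):
    sub = cdp[(cdp.chrom == "chrX") & (cdp.allele == allele)]
    bins = [c for c in sub.columns if c.startswith("bin_")]
    mat = sub[bins].to_numpy()
    mat = mat / np.maximum(mat.sum(axis=1, keepdims=True), 1)
    ax.imshow(zscale_profiles(mat), aspect="auto", cmap="RdBu_r", vmin=-3, vmax=3)
    ax.set_title(f"chrX {allele}")
    ax.set_xlabel("distance bin (log2 grid)")
axes[0].set_ylabel("cell")
fig.suptitle("z-scaled allelic contact decay profiles")
fig.tight_layout()
fig.savefig(figdir / "cdp_heatmaps_chrX.png", dpi=150)

# --- time-course proportions ------------------------------------------------
order = ["d0", "d3", "d7", "d11", "NPC"]
joint = pd.read_csv(results / "silencing_lag_timecourse.tsv", sep="\t")
joint = joint.set_index("time_point").loc[order]
fig, ax = plt.subplots(figsize=(6, 4))
ax.plot(order, joint["pct_rna_silenced"], "o-", label="RNA: chrX silenced")
ax.plot(order, joint["pct_hic_bipartite"], "s-", label="Hi-C: bipartite Xi")
ax.set_ylabel("% of callable cells")
ax.set_xlabel("time point")
ax.set_title("XCI progression: expression silencing leads structure")
ax.legend()
fig.tight_layout()
fig.savefig(figdir / "timecourse_proportions.png", dpi=150)

# --- Xi contact-score track --------------------------------------------------
bedgraph = results / "pipeline" / "contact_score_Xi.bedgraph"
if bedgraph.exists():
    track = pd.read_csv(bedgraph, sep="\t",
                        names=["chrom", "start", "end", "smoothed_log2"])
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.plot(track["start"] / 1e6, track["smoothed_log2"], lw=1)
    ax.axvline(0.44 * 171, color="red", ls="--", lw=0.8, label="hinge (44% chrX)")
    ax.set_xlabel("chrX position (Mb)")
    ax.set_ylabel("log2 contact score")
    ax.set_title("Xi pseudobulk contact score")
    ax.legend()
    fig.tight_layout()
    fig.savefig(figdir / "contact_score_Xi.png", dpi=150)

print(f"figures written to {figdir}/")
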