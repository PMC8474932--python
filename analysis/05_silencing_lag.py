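#!/usr/bin/env python
"""Joint RNA-silencing / Hi-C-bipartite time course with a structural lag.

Generates expression silencing fractions that lead the structural bipartite
fractions at intermediate time points, runs skew calling (chr1-null TAE
threshold) and bipartite calling, and tabulates the two call rates per time
point: the structural lag should appear as Hi-C % strictly below RNA %.
"""

from pathlib import Path

from xci_scstruct.evaluation import silencing_lag_timecourse

res = silencing_lag_timecourse(seed=0)

out = Path("results")
out.mkdir(exist_ok=True)
res["joint"].to_csv(out / "silencing_lag_timecourse.tsv", sep="\t", index=False)
res["rna_recovery"].to_csv(out / "rna_silencing_recovery.tsv", sep="\t", index=False)

order = ["d0", "d3", "d7", "d11", "NPC"]
joint = res["joint"].set_index("time_point").loc[order]
print(joint[["pct_rna_silenced", "pct_hic_bipartite"]].to_string(
    float_format=lambda v: f"{v:.1f}"))
lagged = [tp for tp in ("d3", "d7", "d11")
          if joint.loc[tp, "pct_hic_bipartite"] < joint.loc[tp, "pct_rna_silenced"]]
print(f"\nstructural lag visible (Hi-C < RNA) at: {', '.join(lagged)}")
print(f"RNA fractions recovered within 95% intervals: "
      f"{res['rna_recovery']['truth_in_ci'].all()}")
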