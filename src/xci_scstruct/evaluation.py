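"""Benchmark experiments on synthetic data with known ground truth.

Each function simulates a labelled population under stated conditions, runs
the corresponding pipeline stages from scratch, and returns the measured
quantities (calibration rates, recovery errors, classification AUCs).  These
drive the numbered analysis scripts and the acceptance checks.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .cdp import compute_cdp_table, coverage_select
from .cell_cycle import band_fractions, cellcycle_profiles, cluster_cellcycle
from .contacts import informative_contacts
from .simulate import (ContactGeneratorSpec, CountGeneratorSpec, simulate_allelic_counts,
                       simulate_cellcycle_population, simulate_population,
                       simulate_timecourse)
from .skew import feature_cell_filters, silencing_timecourse, skew_calls
from .structure import (classifier_roc, call_population, fpr_threshold,
                        recovered_fraction, statistics_table)


def null_fpr_calibration(seed: int, n_cells: int = 2000, n_min: int = 200,
                         n_max: int = 2000, fpr: float = 0.10) -> dict:
    """Empirical false-positive rate of the LMD bipartite classifier on
    held-out null cells.

    Simulates ``n_cells`` cells whose two alleles of both chromosomes follow
    the same decay law, derives the |ΔLMD| threshold at the nominal FPR from
    the first half's chr1 statistics, and measures the call rate on the
    second half's chrX statistics.
    """
    spec = ContactGeneratorSpec(n_min=n_min, n_max=n_max, mitotic_fraction=0.0,
                                seed=seed)
    table, truth = simulate_population(spec, n_cells, bipartite_fraction=0.0)
    cdp_table = compute_cdp_table(informative_contacts(table))
    half = n_cells // 2
    train = set(truth["cell_id"].iloc[:half])
    test = set(truth["cell_id"].iloc[half:])
    s_train = statistics_table(cdp_table[cdp_table["cell_id"].isin(train)], "chr1")
    spec_lmd = fpr_threshold(s_train["delta_lmd"], fpr=fpr)
    s_test = statistics_table(cdp_table[cdp_table["cell_id"].isin(test)], "chrX")
    k = int((s_test["delta_lmd"].abs() > spec_lmd.threshold).sum())
    n = len(s_test)
    return {"rate_pct": 100.0 * k / n, "n_test": n, "n_called": k,
            "threshold": spec_lmd.threshold, "nominal_fpr_pct": 100.0 * fpr}


def timecourse_recovery(seed: int, n_per_tp: int = 100,
                        fractions: dict[str, float] | None = None,
                        fpr: float = 0.10) -> dict:
    """Recovery of per-time-point bipartite fractions and classifier AUC.

    Simulates a strong-effect time course (mid-range halved, long-range 4x on
    the Xi), calls cells with a chr1-null LMD threshold, and reports per time
    point the raw call rate, the FPR-corrected recovered fraction with its
    95% interval, and the truth; plus the ROC AUC of |ΔLMD| for truly
    bipartite cells' chrX against the chr1 null statistics.
    """
    fractions = fractions or {"d0": 0.10, "d3": 0.35, "d7": 0.60,
                              "d11": 0.70, "NPC": 0.85}
    spec = ContactGeneratorSpec(mid_depletion=0.5, long_boost=4.0, seed=seed)
    table, truth = simulate_timecourse(spec, n_per_tp, fractions)
    cdp_table = compute_cdp_table(informative_contacts(table))
    keep = coverage_select(cdp_table, 50)
    cdp_table = cdp_table[cdp_table["cell_id"].isin(keep)]
    null = statistics_table(cdp_table, "chr1")
    spec_lmd = fpr_threshold(null["delta_lmd"], fpr=fpr)
    calls = call_population(cdp_table, spec_lmd=spec_lmd)
    calls = calls.merge(truth, on="cell_id")
    rows = []
    for tp, frac in fractions.items():
        sub = calls[calls["time_point"] == tp]
        k, n = int(sub["is_bipartite"].sum()), len(sub)
        est, lo, hi = recovered_fraction(k, n, fpr=fpr)
        rows.append({"time_point": tp, "truth_fraction": frac, "n_cells": n,
                     "raw_call_pct": 100.0 * k / n, "recovered_fraction": est,
                     "ci_low": lo, "ci_high": hi,
                     "truth_in_ci": bool(lo <= frac <= hi)})
    bip_cells = set(truth.loc[truth["bipartite"], "cell_id"]) & set(calls["cell_id"])
    chrx_stats = calls.loc[calls["cell_id"].isin(bip_cells), "delta_lmd"]
    _, auc = classifier_roc(chrx_stats, null["delta_lmd"])
    return {"per_time_point": pd.DataFrame(rows), "auc": auc, "calls": calls}


def cellcycle_recovery(seed: int, n_per_archetype: int = 25) -> dict:
    """Recovery of four cell-cycle archetypes by Spearman-distance k-means.

    QC-passing cells carry >= 1000 valid pairs, so archetype coverage is
    drawn at 250-2500 contacts per allele per chromosome.
    """
    spec = ContactGeneratorSpec(n_min=250, n_max=2500, mitotic_fraction=0.0, seed=seed)
    table, truth = simulate_cellcycle_population(spec, n_per_archetype)
    profiles = cellcycle_profiles(table)
    fracs = band_fractions(table)
    out = cluster_cellcycle(profiles, fracs, k=4, seed=seed)
    merged = out.join(truth.set_index("cell_id"))
    ari = adjusted_rand_score(merged["archetype"], merged["cluster"])
    mitotic = merged[merged["cluster"] == 1]
    return {"ari": ari,
            "mitotic_recall": float((mitotic["state"] == "mitotic").mean()),
            "assignments": merged}


def silencing_lag_timecourse(seed: int, n_hic_per_tp: int = 60, n_rna_per_tp: int = 100,
                             fpr: float = 0.10) -> dict:
    """Joint RNA-silencing / Hi-C-bipartite time course with a structural lag.

    Expression silencing fractions lead the structural (bipartite) fractions
    at intermediate time points, emulating silencing preceding the emergence
    of the Xi superdomain conformation.
    """
    silencing = {"d0": 0.0, "d3": 0.30, "d7": 0.80, "d11": 0.90, "NPC": 1.0}
    bipartite = {"d0": 0.0, "d3": 0.15, "d7": 0.60, "d11": 0.80, "NPC": 0.95}
    cspec = ContactGeneratorSpec(mid_depletion=0.5, long_boost=4.0,
                                 mitotic_fraction=0.0, seed=seed)
    table, truth = simulate_timecourse(cspec, n_hic_per_tp, bipartite)
    cdp_table = compute_cdp_table(informative_contacts(table))
    null = statistics_table(cdp_table, "chr1")
    spec_lmd = fpr_threshold(null["delta_lmd"], fpr=fpr)
    hic_calls = call_population(cdp_table, spec_lmd=spec_lmd)
    hic_calls = hic_calls.merge(truth[["cell_id", "time_point"]], on="cell_id")

    rspec = CountGeneratorSpec(seed=seed + 1)
    matrix, rna_truth = simulate_allelic_counts(rspec, n_rna_per_tp, silencing)
    filtered = feature_cell_filters(matrix, mode="combined")
    rna_calls, _ = skew_calls(filtered, fpr=fpr)

    joint = silencing_timecourse({"rna_silenced": rna_calls,
                                  "hic_bipartite": hic_calls})
    rows = []
    for tp, frac in silencing.items():
        sub = rna_calls[rna_calls["time_point"] == tp]
        k = int(sub["xci_status"].isin(["hap1_silenced", "hap2_silenced"]).sum())
        est, lo, hi = recovered_fraction(k, len(sub), fpr=fpr)
        rows.append({"time_point": tp, "truth_fraction": frac, "n_cells": len(sub),
                     "recovered_fraction": est, "ci_low": lo, "ci_high": hi,
                     "truth_in_ci": bool(lo <= frac <= hi)})
    return {"joint": joint, "rna_recovery": pd.DataFrame(rows),
            "silencing_truth": silencing, "bipartite_truth": bipartite}
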