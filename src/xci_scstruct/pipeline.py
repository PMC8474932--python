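"""End-to-end orchestration: simulate → qc → cdp → cell-cycle → bipartite calls
→ contact score → allelic skew → report, under one validated config with a
reproducibility manifest.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cdp import compute_cdp_table, coverage_select, write_cdp_table
from .cell_cycle import band_fractions, cellcycle_profiles, cluster_cellcycle
from .contacts import (ContactTable, bin_contacts, filter_cells_qc, informative_contacts,
                       qc_from_contacts, write_contacts)
from .contact_score import contact_score_track, locate_dip
from .genome import ChromSizes
from .simulate import (ContactGeneratorSpec, CountGeneratorSpec, simulate_allelic_counts,
                       simulate_timecourse)
from .skew import feature_cell_filters, silencing_timecourse, skew_calls
from .structure import fpr_threshold, call_population, proportion_bipartite, statistics_table

log = logging.getLogger("xci_scstruct")

#: every tunable of the pipeline; unknown keys in a user config are rejected
DEFAULT_CONFIG: dict = {
    "seed": 0,
    "genome": {"chr1": 195_000_000, "chrX": 171_000_000},
    "simulate": {
        "n_cells_per_time_point": 60,
        "n_rna_cells_per_time_point": 100,
        "bipartite_fractions": {"d0": 0.0, "d3": 0.15, "d7": 0.60, "d11": 0.80, "NPC": 0.95},
        "silencing_fractions": {"d0": 0.0, "d3": 0.30, "d7": 0.80, "d11": 0.90, "NPC": 1.00},
        "n_min": 50, "n_max": 5000, "alpha": 1.0,
        "mid_depletion": 0.5, "long_boost": 4.0,
        "mitotic_band_boost": 8.0, "mitotic_fraction": 0.03,
        "boundary_frac": 0.44, "xi_hap1_prob": 0.5,
        "completeness": 0.02,
    },
    "qc": {"min_pairs": 1000, "min_cis_trans": 1.0, "min_purity": 0.95},
    "coverage": {"min_per_allele": 50},
    "thresholds": {"fpr": 0.10, "null_chrom": "chr1"},
    "cell_cycle": {"k": 4, "seed": 0},
    "contact_score": {"resolution": 500_000, "arm": 20_000_000, "pseudocount": 1.0,
                      "edge_exclusion": 10_000_000, "window": 5, "polyorder": 2},
    "skew": {"fpr": 0.10, "pseudocount": 1.0, "min_cells_per_feature": 10,
             "min_umis_per_allele_per_chrom": 10},
}


def _merge_strict(defaults: dict, user: dict, path: str = "") -> dict:
    out = copy.deepcopy(defaults)
    for key, val in user.items():
        if key not in defaults:
            raise ValueError(f"unknown config key {path + key!r}")
        if isinstance(defaults[key], dict) and key not in ("genome",) \
                and not key.endswith("fractions"):
            if not isinstance(val, dict):
                raise ValueError(f"config key {path + key!r} must be a mapping")
            out[key] = _merge_strict(defaults[key], val, path + key + ".")
        else:
            out[key] = val
    return out


class PipelineConfig:
    """Validated nested pipeline configuration (see DEFAULT_CONFIG for keys)."""

    def __init__(self, overrides: dict | None = None):
        self.data = _merge_strict(DEFAULT_CONFIG, overrides or {})

    def __getitem__(self, key):
        return self.data[key]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.data, fh, sort_keys=True)

    def hash(self) -> str:
        return hashlib.sha256(json.dumps(self.data, sort_keys=True).encode()).hexdigest()[:16]

    def genome(self) -> ChromSizes:
        return ChromSizes({k: int(v) for k, v in self.data["genome"].items()})

    def contact_spec(self, seed: int | None = None) -> ContactGeneratorSpec:
        s = self.data["simulate"]
        return ContactGeneratorSpec(
            genome=self.genome(), n_min=s["n_min"], n_max=s["n_max"], alpha=s["alpha"],
            mitotic_band_boost=s["mitotic_band_boost"], boundary_frac=s["boundary_frac"],
            mid_depletion=s["mid_depletion"], long_boost=s["long_boost"],
            mitotic_fraction=s["mitotic_fraction"], xi_hap1_prob=s["xi_hap1_prob"],
            seed=self.data["seed"] if seed is None else seed)

    def count_spec(self, seed: int | None = None) -> CountGeneratorSpec:
        s = self.data["simulate"]
        return CountGeneratorSpec(completeness=s["completeness"],
                                  xi_hap1_prob=s["xi_hap1_prob"],
                                  seed=(self.data["seed"] if seed is None else seed) + 1)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, outdir, contacts: ContactTable | None = None,
                 truth: pd.DataFrame | None = None) -> dict:
    """Run every stage in dependency order; returns the run manifest.

    With no ``contacts`` input the synthetic time-course preset is generated
    first (the truth table is then written alongside for benchmarking).
    All stage outputs are TSV tables under ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    manifest = {"version": __version__, "config_hash": config.hash(),
                "seed": config["seed"], "stages": {}, "started": t0}
    genome = config.genome()
    sim = config["simulate"]

    def record(stage: str, path: Path, **info):
        manifest["stages"][stage] = {"output": str(path), "checksum": _checksum(path),
                                     "elapsed_s": round(time.time() - t0, 2), **info}
        log.info("stage %s done: %s %s", stage, path.name, info)

    # -- simulate ------------------------------------------------------------
    if contacts is None:
        spec = config.contact_spec()
        contacts, truth = simulate_timecourse(spec, sim["n_cells_per_time_point"],
                                              sim["bipartite_fractions"])
        truth.to_csv(outdir / "truth_contacts.tsv", sep="\t", index=False)
    write_contacts(contacts, outdir / "contacts.pairs.tsv")
    record("simulate", outdir / "contacts.pairs.tsv", n_records=len(contacts))

    # -- qc ------------------------------------------------------------------
    qc = qc_from_contacts(contacts)
    passing = filter_cells_qc(qc, **config["qc"])
    pd.DataFrame([vars(r) | {"pass": r.cell_id in passing} for r in qc]) \
        .to_csv(outdir / "cell_qc.tsv", sep="\t", index=False)
    contacts = informative_contacts(contacts.select(cell_ids=passing))
    record("qc", outdir / "cell_qc.tsv", cells_in=len(qc), cells_out=len(passing))

    # -- cdp -----------------------------------------------------------------
    cdp_table = compute_cdp_table(contacts)
    keep = coverage_select(cdp_table, config["coverage"]["min_per_allele"])
    cdp_table = cdp_table[cdp_table["cell_id"].isin(keep)].reset_index(drop=True)
    write_cdp_table(cdp_table, outdir / "cdp.tsv")
    record("cdp", outdir / "cdp.tsv", cells=len(keep))

    # -- cell cycle ----------------------------------------------------------
    profiles = cellcycle_profiles(contacts)
    fracs = band_fractions(contacts)
    cc = cluster_cellcycle(profiles, fracs, k=config["cell_cycle"]["k"],
                           seed=config["cell_cycle"]["seed"])
    cc.to_csv(outdir / "cell_cycle.tsv", sep="\t")
    record("cell_cycle", outdir / "cell_cycle.tsv", cells=len(cc))

    # -- bipartite calls -----------------------------------------------------
    fpr = config["thresholds"]["fpr"]
    null_chrom = config["thresholds"]["null_chrom"]
    null_stats = statistics_table(cdp_table, null_chrom)
    spec_lmd = fpr_threshold(null_stats["delta_lmd"], fpr=fpr, direction="abs_greater")
    spec_rho = fpr_threshold(null_stats["rho"], fpr=fpr, direction="less",
                             statistic="spearman_cdp")
    calls = call_population(cdp_table, spec_lmd=spec_lmd)
    calls["threshold_used"] = spec_lmd.threshold
    if truth is not None:
        calls = calls.merge(truth[["cell_id", "time_point"]], on="cell_id", how="left")
    calls.to_csv(outdir / "bipartite_calls.tsv", sep="\t", index=False)
    record("call_bipartite", outdir / "bipartite_calls.tsv",
           threshold=round(spec_lmd.threshold, 4), n_called=int(calls["is_bipartite"].sum()))

    # -- contact score on the pseudobulk Xi map ------------------------------
    cs = config["contact_score"]
    xi_cells = calls.loc[calls["xi_allele"] == "hap1", "cell_id"]
    allele = "hap1" if len(xi_cells) else "hap2"
    if not len(xi_cells):
        xi_cells = calls.loc[calls["xi_allele"] == "hap2", "cell_id"]
    score_info = {}
    if len(xi_cells):
        mat = bin_contacts(contacts, cs["resolution"], "chrX", cells=set(xi_cells),
                           allele=allele)
        track = contact_score_track(mat, genome["chrX"], arm=cs["arm"],
                                    pseudocount=cs["pseudocount"],
                                    edge_exclusion=cs["edge_exclusion"],
                                    window=cs["window"], polyorder=cs["polyorder"])
        track.to_bedgraph(outdir / "contact_score_Xi.bedgraph")
        hinge = int(config["simulate"]["boundary_frac"] * genome["chrX"])
        dip_bin, depth = locate_dip(track, hinge)
        score_info = {"dip_bin": dip_bin, "dip_depth": None if np.isnan(depth) else round(depth, 4),
                      "n_pseudobulk_cells": int(len(xi_cells))}
        record("contact_score", outdir / "contact_score_Xi.bedgraph", **score_info)
    else:
        log.warning("no Xi-called cells; contact-score stage skipped")

    # -- allelic skew (RNA) --------------------------------------------------
    sk = config["skew"]
    counts, rna_truth = simulate_allelic_counts(config.count_spec(),
                                                sim["n_rna_cells_per_time_point"],
                                                sim["silencing_fractions"])
    rna_truth.to_csv(outdir / "truth_rna.tsv", sep="\t", index=False)
    filtered = feature_cell_filters(counts, sk["min_cells_per_feature"],
                                    sk["min_umis_per_allele_per_chrom"], mode="combined")
    rna_calls, tae_spec = skew_calls(filtered, fpr=sk["fpr"], pseudocount=sk["pseudocount"])
    rna_calls.to_csv(outdir / "skew_calls_rna.tsv", sep="\t", index=False)
    record("skew", outdir / "skew_calls_rna.tsv", threshold=round(tae_spec.threshold, 4),
           cells=len(rna_calls))

    # -- report --------------------------------------------------------------
    if "time_point" in calls.columns:
        prop = proportion_bipartite(calls, "time_point")
        prop.to_csv(outdir / "report_bipartite_proportions.tsv", sep="\t", index=False)
        joint = silencing_timecourse({"rna_silenced": rna_calls, "hic_bipartite": calls})
        joint.to_csv(outdir / "report_timecourse.tsv", sep="\t", index=False)
        record("report", outdir / "report_timecourse.tsv")

    manifest["elapsed_s"] = round(time.time() - t0, 2)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
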