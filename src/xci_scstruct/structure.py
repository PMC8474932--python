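"""Bipartite-Xi structure calling from allelic contact decay profiles.

Two per-cell statistics discriminate an inactive-X (Xi) 3D conformation:

* the long-range to mid-range difference (LMD) — total contact proportion in
  6.5–87 Mb minus total in 85 kb–1.1 Mb, per homolog; the inter-homolog
  difference ΔLMD is large when one homolog carries the bipartite structure,
  and the homolog with the higher LMD is the Xi;
* the Spearman correlation ρ between the two homologs' rebinned (14-bin)
  CDPs — low when the homologs' decay laws diverge.

Thresholds are empirical quantiles of the same statistic computed on chr1,
whose homologs are structurally equivalent, at a chosen false-positive rate
(10% in the study).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cdp import CDPBinScheme, CDProfile, RebinnedCDP, cdp_bin_edges, normalize_cdp, rebin_cdp


@dataclass(frozen=True)
class LMDRanges:
    """The mid- and long-range distance windows of the LMD statistic (bp).

    The defaults are the grid edges nearest the nominal 85 kb-1.1 Mb and
    6.5-87 Mb windows (2^16.375, 2^20, 2^22.625 and 2^26.375 bp), so each
    window is an exact union of fine bins: 51..79 (mid) and 101..130 (long).
    """

    mid_lo: float = 2.0 ** 16.375    # ~85 kb
    mid_hi: float = 2.0 ** 20.0      # ~1.05 Mb ("1.1 Mb" nominal)
    long_lo: float = 2.0 ** 22.625   # ~6.5 Mb
    long_hi: float = 2.0 ** 26.375   # ~87 Mb

    def mid_bins(self, scheme: CDPBinScheme) -> np.ndarray:
        return scheme.bins_within(self.mid_lo, self.mid_hi)

    def long_bins(self, scheme: CDPBinScheme) -> np.ndarray:
        return scheme.bins_within(self.long_lo, self.long_hi)


@dataclass(frozen=True)
class ThresholdSpec:
    """A null-calibrated decision threshold for one statistic.

    ``direction`` is 'abs_greater' (call when |stat| > threshold; ΔLMD, TAE,
    TAA) or 'less' (call when stat < threshold; Spearman ρ).
    """

    statistic: str
    threshold: float
    fpr: float
    direction: str  # 'abs_greater' | 'less'
    n_null: int

    def is_called(self, stat: float) -> bool:
        if stat is None or (isinstance(stat, float) and math.isnan(stat)):
            return False
        if self.direction == "abs_greater":
            return abs(stat) > self.threshold
        return stat < self.threshold


@dataclass(frozen=True)
class BipartiteCall:
    """Per-cell Xi-structure decision with its statistics."""

    cell_id: str
    rho: float
    lmd_hap1: float
    lmd_hap2: float
    delta_lmd: float
    is_bipartite: bool
    xi_allele: str  # 'hap1' | 'hap2' | 'none'


def lmd(profile: CDProfile, ranges: LMDRanges | None = None,
        scheme: CDPBinScheme | None = None) -> float:
    """Long-range minus mid-range contact proportion of one normalized CDP.

    Computed on the scale-normalized profile so the statistic is invariant to
    per-cell coverage; NaN for zero-coverage profiles.
    """
    ranges = ranges or LMDRanges()
    scheme = scheme or cdp_bin_edges()
    if not profile.normalized:
        profile = normalize_cdp(profile)
    if profile.low_coverage or profile.counts.sum() == 0:
        return float("nan")
    c = profile.counts
    return float(c[ranges.long_bins(scheme)].sum() - c[ranges.mid_bins(scheme)].sum())


def delta_lmd(profile_hap1: CDProfile, profile_hap2: CDProfile,
              ranges: LMDRanges | None = None) -> float:
    """Signed inter-homolog LMD difference, hap1 minus hap2 (NaN if either missing)."""
    a, b = lmd(profile_hap1, ranges), lmd(profile_hap2, ranges)
    return a - b


def cdp_spearman(a: RebinnedCDP | np.ndarray, b: RebinnedCDP | np.ndarray) -> float:
    """Spearman rank correlation between two rebinned allelic CDPs.

    Ties get average ranks; a constant input has no rank ordering, so the
    coefficient is undefined and NaN is returned.
    """
    av = a.counts if isinstance(a, RebinnedCDP) else np.asarray(a, float)
    bv = b.counts if isinstance(b, RebinnedCDP) else np.asarray(b, float)
    if np.ptp(av) == 0 or np.ptp(bv) == 0:
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho, _ = stats.spearmanr(av, bv)
    return float(rho)


def fpr_threshold(null_stats, fpr: float = 0.10, direction: str = "abs_greater",
                  statistic: str = "delta_lmd") -> ThresholdSpec:
    """Empirical nearest-rank quantile threshold from a null distribution.

    For 'abs_greater' statistics the threshold is the nearest-rank (1-fpr)
    quantile of |null|; for 'less' it is the nearest-rank fpr quantile.
    With strict-inequality calls, at most floor(fpr*n) null values end up
    called positive.
    """
    if not 0 < fpr < 1:
        raise ValueError("fpr must be in (0, 1)")
    null = np.asarray(null_stats, dtype=float)
    null = null[~np.isnan(null)]
    if null.size == 0:
        raise ValueError("empty null distribution")
    if direction == "abs_greater":
        vals = np.sort(np.abs(null))
        k = math.ceil((1 - fpr) * null.size)  # nearest-rank, 1-based
    elif direction == "less":
        vals = np.sort(null)
        k = math.ceil(fpr * null.size)
    else:
        raise ValueError(f"unknown direction {direction!r}")
    threshold = float(vals[k - 1])
    return ThresholdSpec(statistic, threshold, fpr, direction, null.size)


def call_bipartite(cell_id: str, hap1: CDProfile, hap2: CDProfile,
                   spec_lmd: ThresholdSpec | None = None,
                   spec_rho: ThresholdSpec | None = None,
                   ranges: LMDRanges | None = None) -> BipartiteCall:
    """Call whether one chrX homolog carries the bipartite Xi structure.

    LMD mode (spec_lmd given): call when |ΔLMD| strictly exceeds the
    threshold; the homolog with the higher LMD is the Xi.  Spearman mode
    (spec_rho given): call when ρ between the rebinned allelic CDPs falls
    strictly below the threshold (the Xi homolog is not identified by ρ
    alone, so xi_allele stays 'none' unless LMD mode is also active).
    """
    if spec_lmd is None and spec_rho is None:
        raise ValueError("provide at least one ThresholdSpec")
    ranges = ranges or LMDRanges()
    l1, l2 = lmd(hap1, ranges), lmd(hap2, ranges)
    dl = l1 - l2
    rho = cdp_spearman(rebin_cdp(hap1), rebin_cdp(hap2))
    is_bip = False
    xi = "none"
    if spec_lmd is not None:
        if not math.isnan(dl) and spec_lmd.is_called(dl):
            is_bip = True
            xi = "hap1" if l1 > l2 else "hap2"
    if spec_rho is not None and not is_bip:
        if not math.isnan(rho) and spec_rho.is_called(rho):
            is_bip = True
            if spec_lmd is not None and not math.isnan(dl):
                xi = "hap1" if l1 > l2 else "hap2"
    return BipartiteCall(cell_id, rho, l1, l2, dl, is_bip, xi)


def classifier_roc(chrx_stats, chr1_stats) -> tuple[pd.DataFrame, float]:
    """ROC of an |stat| threshold sweep: TPR on chrX cells vs FPR on chr1 cells.

    TPR(t) = fraction of chrX cells with |stat| > t, FPR(t) the same on chr1;
    AUC by trapezoid over the step curve (equals the Mann-Whitney statistic).
    """
    x = np.abs(np.asarray(chrx_stats, float))
    y = np.abs(np.asarray(chr1_stats, float))
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if x.size == 0 or y.size == 0:
        raise ValueError("both statistic vectors must be non-empty")
    thresholds = np.concatenate(([-np.inf], np.unique(np.concatenate([x, y])), [np.inf]))
    tpr = np.array([(x > t).mean() for t in thresholds])
    fpr = np.array([(y > t).mean() for t in thresholds])
    # in descending-threshold order both rates are non-decreasing, so the
    # trapezoid over the resulting staircase is the exact Mann-Whitney AUC
    auc = float(np.trapezoid(tpr[::-1], fpr[::-1]))
    roc = pd.DataFrame({"threshold": thresholds, "tpr": tpr, "fpr": fpr})
    return roc, auc


def _binary_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC via the rank-sum (Mann-Whitney) identity with average-rank ties."""
    pos = labels.astype(bool)
    n1, n0 = pos.sum(), (~pos).sum()
    if n1 == 0 or n0 == 0:
        return float("nan")
    ranks = stats.rankdata(scores)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def embedding_timepoint_auc(embedding: np.ndarray, labels) -> float:
    """Mean per-time-point AUC of distance-based self-retrieval in a latent space.

    For each anchor point, every other point is scored by (negated) Euclidean
    distance — closer ranks higher — and labeled 1 when it shares the anchor's
    time point.  Anchor AUCs are averaged within each time point, and the
    per-time-point means are averaged.  Time points with fewer than 2 points
    are excluded with a warning.
    """
    X = np.asarray(embedding, dtype=float)
    labels = np.asarray(labels)
    if X.ndim != 2 or len(labels) != len(X):
        raise ValueError("embedding must be (n_points, n_dims) with one label per point")
    uniq, counts = np.unique(labels, return_counts=True)
    usable = uniq[counts >= 2]
    if len(usable) < 2:
        raise ValueError("need at least two time points with >= 2 points each")
    for lab in uniq[counts < 2]:
        warnings.warn(f"time point {lab!r} has a single point; excluded from AUC")
    keep = np.isin(labels, usable)
    X, labels = X[keep], labels[keep]
    d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2))
    per_tp = []
    for lab in usable:
        anchors = np.flatnonzero(labels == lab)
        aucs = []
        for i in anchors:
            others = np.arange(len(X)) != i
            aucs.append(_binary_auc(-d[i, others], (labels[others] == lab)))
        per_tp.append(np.nanmean(aucs))
    return float(np.mean(per_tp))


def proportion_bipartite(calls: pd.DataFrame, group_col: str = "time_point") -> pd.DataFrame:
    """Percent of cells carrying a bipartite X per group, split by Xi homolog.

    Expects a calls frame with columns [cell_id, is_bipartite, xi_allele] and
    a grouping column; denominators are the coverage-passing (callable) cells
    present in the frame.  Empty groups are omitted with a warning.
    """
    out = []
    for grp, sub in calls.groupby(group_col, sort=True):
        n = len(sub)
        if n == 0:
            warnings.warn(f"empty group {grp!r} omitted")
            continue
        called = int(sub["is_bipartite"].sum())
        h1 = int(((sub["is_bipartite"]) & (sub["xi_allele"] == "hap1")).sum())
        h2 = int(((sub["is_bipartite"]) & (sub["xi_allele"] == "hap2")).sum())
        out.append({group_col: grp, "n_cells": n, "n_bipartite": called,
                    "pct_bipartite": 100.0 * called / n,
                    "pct_xi_hap1": 100.0 * h1 / n, "pct_xi_hap2": 100.0 * h2 / n})
    return pd.DataFrame(out)


def statistics_table(cdp_table: pd.DataFrame, chrom: str,
                     ranges: LMDRanges | None = None) -> pd.DataFrame:
    """Per-cell ΔLMD and ρ on one chromosome from a raw CDP table.

    Returns one row per cell having both allelic profiles, with columns
    [cell_id, rho, lmd_hap1, lmd_hap2, delta_lmd].
    """
    from .cdp import profile_from_row

    sub = cdp_table[cdp_table["chrom"] == chrom]
    by_allele = {a: g.set_index("cell_id", drop=False) for a, g in sub.groupby("allele")}
    if "hap1" not in by_allele or "hap2" not in by_allele:
        return pd.DataFrame(columns=["cell_id", "rho", "lmd_hap1", "lmd_hap2", "delta_lmd"])
    cells = sorted(set(by_allele["hap1"].index) & set(by_allele["hap2"].index))
    rows = []
    for cell in cells:
        p1 = profile_from_row(by_allele["hap1"].loc[cell])
        p2 = profile_from_row(by_allele["hap2"].loc[cell])
        l1, l2 = lmd(p1, ranges), lmd(p2, ranges)
        rho = cdp_spearman(rebin_cdp(normalize_cdp(p1)), rebin_cdp(normalize_cdp(p2)))
        rows.append({"cell_id": cell, "rho": rho, "lmd_hap1": l1,
                     "lmd_hap2": l2, "delta_lmd": l1 - l2})
    return pd.DataFrame(rows)


def recovered_fraction(n_called: int, n_total: int, fpr: float = 0.0,
                       conf: float = 0.95) -> tuple[float, float, float]:
    """Classifier-corrected positive fraction with a Clopper-Pearson interval.

    A classifier calibrated to false-positive rate ``fpr`` inflates the raw
    call rate p by (1-f)·fpr; assuming near-perfect sensitivity the underlying
    positive fraction is f = (p - fpr)/(1 - fpr) (Rogan-Gladen with known
    specificity).  Returns (estimate, ci_low, ci_high), the exact binomial
    interval on the raw rate mapped through the same correction.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    a = 1.0 - conf
    lo = 0.0 if n_called == 0 else float(stats.beta.ppf(a / 2, n_called, n_total - n_called + 1))
    hi = 1.0 if n_called == n_total else float(
        stats.beta.ppf(1 - a / 2, n_called + 1, n_total - n_called))
    def corr(p: float) -> float:
        return (p - fpr) / (1.0 - fpr)
    return corr(n_called / n_total), corr(lo), corr(hi)


def call_population(cdp_table: pd.DataFrame, spec_lmd: ThresholdSpec | None = None,
                    spec_rho: ThresholdSpec | None = None, chrom: str = "chrX",
                    ranges: LMDRanges | None = None) -> pd.DataFrame:
    """Bipartite calls for every cell of a CDP table on one chromosome."""
    if spec_lmd is None and spec_rho is None:
        raise ValueError("provide at least one ThresholdSpec")
    tab = statistics_table(cdp_table, chrom, ranges)
    calls, xis = [], []
    for r in tab.itertuples(index=False):
        is_bip = False
        xi = "none"
        if spec_lmd is not None and not math.isnan(r.delta_lmd) and spec_lmd.is_called(r.delta_lmd):
            is_bip = True
            xi = "hap1" if r.lmd_hap1 > r.lmd_hap2 else "hap2"
        if not is_bip and spec_rho is not None and not math.isnan(r.rho) and spec_rho.is_called(r.rho):
            is_bip = True
            if spec_lmd is not None and not math.isnan(r.delta_lmd):
                xi = "hap1" if r.lmd_hap1 > r.lmd_hap2 else "hap2"
        calls.append(is_bip)
        xis.append(xi)
    tab = tab.copy()
    tab["is_bipartite"] = pd.Series(calls, dtype=bool)
    tab["xi_allele"] = xis
    return tab
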