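"""Per-cell XCI calling from allelic UMI counts (expression and accessibility).

Each cell's chrX silencing status is read off the log2 ratio of total allelic
UMI counts between the two homologs — total allelic expression (TAE) for
sci-RNA-seq, total allelic accessibility (TAA) for sci-ATAC-seq — thresholded
at an empirical false-positive rate derived from the chr1 ratio distribution,
where both homologs stay active.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as scipy_io
from scipy import sparse

from .structure import ThresholdSpec, fpr_threshold

ALLELES = ("hap1", "hap2")


@dataclass
class AllelicCountMatrix:
    """Feature x cell x allele UMI counts with feature and cell metadata.

    ``counts`` maps allele -> (features x cells) DataFrame with identical
    index/columns across alleles; ``feature_meta`` carries at least a
    ``chrom`` column; ``cell_meta`` carries time point / sex / line.
    """

    counts: dict[str, pd.DataFrame]
    feature_meta: pd.DataFrame
    cell_meta: pd.DataFrame

    def __post_init__(self) -> None:
        for a in ALLELES:
            if a not in self.counts:
                raise ValueError(f"missing allele matrix {a!r}")
        c1, c2 = self.counts["hap1"], self.counts["hap2"]
        if not (c1.index.equals(c2.index) and c1.columns.equals(c2.columns)):
            raise ValueError("allele matrices must share features and cells")
        if (c1.to_numpy() < 0).any() or (c2.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if "chrom" not in self.feature_meta.columns:
            raise ValueError("feature_meta must carry a 'chrom' column")

    @property
    def features(self) -> pd.Index:
        return self.counts["hap1"].index

    @property
    def cells(self) -> pd.Index:
        return self.counts["hap1"].columns

    def total(self) -> pd.DataFrame:
        """Allele-summed (non-allelic) feature x cell counts."""
        return self.counts["hap1"] + self.counts["hap2"]

    def subset(self, features=None, cells=None) -> "AllelicCountMatrix":
        f = self.features if features is None else pd.Index(features)
        c = self.cells if cells is None else pd.Index(cells)
        return AllelicCountMatrix(
            {a: m.loc[f, c] for a, m in self.counts.items()},
            self.feature_meta.loc[f], self.cell_meta.loc[c])

    def chrom_allele_totals(self, chrom: str) -> pd.DataFrame:
        """Per-cell total UMIs per allele over one chromosome's features."""
        feats = self.feature_meta.index[self.feature_meta["chrom"] == chrom]
        return pd.DataFrame({a: self.counts[a].loc[feats].sum(axis=0) for a in ALLELES})

    def write_mtx(self, prefix) -> None:
        """Per-allele MTX triplets plus feature/barcode sidecar TSVs."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        for a in ALLELES:
            scipy_io.mmwrite(f"{prefix}.{a}.mtx",
                             sparse.coo_matrix(self.counts[a].to_numpy()))
        self.feature_meta.to_csv(f"{prefix}.features.tsv", sep="\t")
        self.cell_meta.to_csv(f"{prefix}.cells.tsv", sep="\t")

    @classmethod
    def read_mtx(cls, prefix) -> "AllelicCountMatrix":
        prefix = Path(prefix)
        fm = pd.read_csv(f"{prefix}.features.tsv", sep="\t", index_col=0)
        cm = pd.read_csv(f"{prefix}.cells.tsv", sep="\t", index_col=0)
        counts = {}
        for a in ALLELES:
            m = scipy_io.mmread(f"{prefix}.{a}.mtx").toarray()
            counts[a] = pd.DataFrame(m, index=fm.index, columns=cm.index)
        return cls(counts, fm, cm)


@dataclass(frozen=True)
class SkewCall:
    """One cell's chrX allelic-ratio XCI status for one modality."""

    cell_id: str
    chrom: str
    total_hap1: float
    total_hap2: float
    log2_ratio: float
    xci_status: str  # biallelic | hap1_silenced | hap2_silenced | no_call
    xa_allele: str   # hap1 | hap2 | none


def feature_cell_filters(matrix: AllelicCountMatrix, min_cells_per_feature: int = 10,
                         min_umis_per_allele_per_chrom: int = 10,
                         chroms=("chr1", "chrX"),
                         mode: str = "per_allele") -> AllelicCountMatrix:
    """Coverage filters on features and cells before skew analysis.

    A feature is kept when at least one allele shows coverage in
    >= min_cells_per_feature cells.  A cell is kept when, for each chromosome
    in ``chroms``: per_allele mode — each allele has >= the minimum UMIs;
    combined mode — the two alleles together reach the minimum (used for
    call-time filtering, where a fully silenced allele must stay callable).
    """
    per_allele_cov = [(matrix.counts[a] > 0).sum(axis=1) for a in ALLELES]
    keep_feat = matrix.features[
        np.maximum(*[c.to_numpy() for c in per_allele_cov]) >= min_cells_per_feature]
    sub = matrix.subset(features=keep_feat)
    keep_cells = pd.Series(True, index=sub.cells)
    for chrom in chroms:
        tot = sub.chrom_allele_totals(chrom)
        if mode == "per_allele":
            keep_cells &= (tot["hap1"] >= min_umis_per_allele_per_chrom) \
                & (tot["hap2"] >= min_umis_per_allele_per_chrom)
        elif mode == "combined":
            keep_cells &= (tot["hap1"] + tot["hap2"]) >= min_umis_per_allele_per_chrom
        else:
            raise ValueError(f"unknown mode {mode!r}")
    out = sub.subset(cells=sub.cells[keep_cells.to_numpy()])
    if len(out.cells) == 0 or len(out.features) == 0:
        warnings.warn("feature/cell filters removed everything")
    return out


def allelic_log2_ratio(total_hap1: float, total_hap2: float, pseudocount: float = 1.0) -> float:
    """log2((hap1 + pc) / (hap2 + pc)); the pseudocount keeps fully silenced
    alleles (0 UMIs) finite."""
    if total_hap1 < 0 or total_hap2 < 0:
        raise ValueError("totals must be non-negative")
    return float(np.log2((total_hap1 + pseudocount) / (total_hap2 + pseudocount)))


def call_xci(cell_id: str, total_hap1: float, total_hap2: float, spec: ThresholdSpec,
             chrom: str = "chrX", pseudocount: float = 1.0) -> SkewCall:
    """XCI status from a chrX allelic log2 ratio and a chr1-derived threshold.

    A ratio skewed left (negative, hap1 low) past the threshold means the
    hap1 homolog is silenced; skewed right means hap2 silenced; the homolog
    with the higher total is the active X.  Strict inequality at the
    threshold; missing totals give no_call.
    """
    if total_hap1 is None or total_hap2 is None or \
            np.isnan(total_hap1) or np.isnan(total_hap2):
        return SkewCall(cell_id, chrom, float("nan"), float("nan"), float("nan"),
                        "no_call", "none")
    ratio = allelic_log2_ratio(total_hap1, total_hap2, pseudocount)
    if spec.is_called(ratio):
        if ratio < 0:
            return SkewCall(cell_id, chrom, total_hap1, total_hap2, ratio,
                            "hap1_silenced", "hap2")
        return SkewCall(cell_id, chrom, total_hap1, total_hap2, ratio,
                        "hap2_silenced", "hap1")
    return SkewCall(cell_id, chrom, total_hap1, total_hap2, ratio, "biallelic", "none")


def skew_calls(matrix: AllelicCountMatrix, fpr: float = 0.10, null_chrom: str = "chr1",
               test_chrom: str = "chrX", pseudocount: float = 1.0,
               statistic: str = "tae_log2") -> tuple[pd.DataFrame, ThresholdSpec]:
    """Per-cell XCI calls with the threshold recomputed from the null chromosome.

    The null is the distribution of |log2 ratio| on ``null_chrom`` (biallelic
    by assumption) across the same cells; the threshold is its nearest-rank
    (1 - fpr) quantile.
    """
    null_tot = matrix.chrom_allele_totals(null_chrom)
    null_ratios = [allelic_log2_ratio(h1, h2, pseudocount)
                   for h1, h2 in zip(null_tot["hap1"], null_tot["hap2"])]
    spec = fpr_threshold(null_ratios, fpr=fpr, direction="abs_greater", statistic=statistic)
    tot = matrix.chrom_allele_totals(test_chrom)
    calls = [call_xci(cell, tot.at[cell, "hap1"], tot.at[cell, "hap2"], spec,
                      chrom=test_chrom, pseudocount=pseudocount)
             for cell in matrix.cells]
    df = pd.DataFrame([vars(c) for c in calls]).set_index("cell_id")
    df = df.join(matrix.cell_meta, how="left")
    return df.reset_index(), spec


def atac_cell_prefilter(matrix: AllelicCountMatrix, min_umis: int = 500) -> AllelicCountMatrix:
    """Accessibility-specific pre-filter: keep cells with >= min_umis total UMIs
    (both alleles, all peaks) before the shared feature/cell filters."""
    totals = matrix.total().sum(axis=0)
    return matrix.subset(cells=matrix.cells[totals >= min_umis])


def xa_ratio(matrix: AllelicCountMatrix | pd.DataFrame, feature_chrom=None,
             min_cells: int = 10) -> pd.Series:
    """Per-cell X:A expression ratio on allele-summed counts.

    mean UMIs over qualifying chrX genes / mean over qualifying autosomal
    genes, where qualifying genes are expressed in >= min_cells cells;
    NaN where the autosomal mean is zero.
    """
    if isinstance(matrix, AllelicCountMatrix):
        counts = matrix.total()
        chroms = matrix.feature_meta["chrom"]
    else:
        counts = matrix
        chroms = pd.Series(feature_chrom, index=matrix.index)
    qualifying = (counts > 0).sum(axis=1) >= min_cells
    x_feats = counts.index[qualifying & (chroms == "chrX")]
    a_feats = counts.index[qualifying & (chroms != "chrX")]
    x_mean = counts.loc[x_feats].mean(axis=0)
    a_mean = counts.loc[a_feats].mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = x_mean / a_mean
    return r.where(a_mean > 0)


def silencing_timecourse(call_tables: dict[str, pd.DataFrame],
                         group_col: str = "time_point") -> pd.DataFrame:
    """Percent of callable cells with a silenced/structured chrX per time point
    per modality, aligned in one table for lag comparison.

    ``call_tables`` maps modality name -> calls frame.  RNA/ATAC frames carry
    ``xci_status`` (silenced = either allele silenced); Hi-C frames carry
    ``is_bipartite``.  Empty groups are omitted.
    """
    rows = {}
    for modality, tab in call_tables.items():
        if "xci_status" in tab.columns:
            callable_ = tab[tab["xci_status"] != "no_call"]
            pos = callable_["xci_status"].isin(["hap1_silenced", "hap2_silenced"])
        elif "is_bipartite" in tab.columns:
            callable_ = tab
            pos = callable_["is_bipartite"].astype(bool)
        else:
            raise ValueError(f"calls for {modality!r} lack a status column")
        for grp, sub in callable_.groupby(group_col, sort=True):
            if len(sub) == 0:
                continue
            pct = 100.0 * pos.loc[sub.index].sum() / len(sub)
            rows.setdefault(grp, {})[f"pct_{modality}"] = pct
            rows[grp][f"n_{modality}"] = len(sub)
    out = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    out.index.name = group_col
    return out.reset_index()
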