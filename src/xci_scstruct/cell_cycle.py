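"""Cell-cycle staging from non-allelic autosomal contact decay profiles.

Condensed mitotic chromosomes produce a characteristic enrichment of contacts
at ~2–12 Mb separation (the "mitotic band") and a loss of compartment-scale
structure, so the shape of the autosomal CDP within 50 kb–8 Mb tracks
progression through the cell cycle.  Cells are grouped into four k-means
clusters under a Spearman-correlation distance; the cluster with the highest
mean mitotic-band fraction is the mitotic stage, and the remaining clusters
are ordered by decreasing short-range fraction as interphase progression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .cdp import CDPBinScheme, cdp_bin_edges
from .contacts import ContactTable

#: distance window (bp) that best captures cell-cycle dynamics
CC_RANGE = (50_000.0, 8_000_000.0)

#: band definitions for the QC scatter (short-range vs mitotic band)
SHORT_RANGE = (1_000.0, 2_000_000.0)
MITOTIC_BAND = (2_000_000.0, 12_000_000.0)


def _range_bins(scheme: CDPBinScheme, lo: float, hi: float) -> np.ndarray:
    return scheme.bins_within(lo, hi)


@dataclass(frozen=True)
class CellCycleProfile:
    """Non-allelic autosome-aggregated CDP restricted to 50 kb–8 Mb, as proportions."""

    cell_id: str
    counts: np.ndarray  # 58 in-range fine bins
    low_coverage: bool = False


def cc_bins(scheme: CDPBinScheme | None = None) -> np.ndarray:
    """Indices of the fine bins fully inside the 50 kb–8 Mb window (58 bins)."""
    scheme = scheme or cdp_bin_edges()
    return _range_bins(scheme, *CC_RANGE)


def cellcycle_profile(table: ContactTable, cell_id: str,
                      scheme: CDPBinScheme | None = None) -> CellCycleProfile:
    """One cell's cell-cycle CDP: autosomes only, all alleles (ambiguous included),
    restricted to the in-range fine bins and normalized to proportions."""
    scheme = scheme or cdp_bin_edges()
    df = table.df
    autosomes = set(table.genome.autosomes)
    m = ((df["cell_id"] == cell_id) & (df["chrom_a"] == df["chrom_b"])
         & df["chrom_a"].isin(autosomes))
    sub = df.loc[m]
    d = np.abs(sub["pos_a"].to_numpy() - sub["pos_b"].to_numpy())
    hist = scheme.histogram(d)[cc_bins(scheme)]
    total = hist.sum()
    if total == 0:
        return CellCycleProfile(cell_id, hist, low_coverage=True)
    return CellCycleProfile(cell_id, hist / total)


def cellcycle_profiles(table: ContactTable, scheme: CDPBinScheme | None = None) -> pd.DataFrame:
    """Cell-cycle profiles for every cell; zero-coverage cells are excluded."""
    scheme = scheme or cdp_bin_edges()
    df = table.df
    autosomes = set(table.genome.autosomes)
    m = (df["chrom_a"] == df["chrom_b"]) & df["chrom_a"].isin(autosomes)
    sub = df.loc[m]
    cells = np.sort(df["cell_id"].unique())
    d = np.abs(sub["pos_a"].to_numpy() - sub["pos_b"].to_numpy())
    k = scheme.assign(d)
    bins = cc_bins(scheme)
    in_rng = np.isin(k, bins)
    remap = {b: i for i, b in enumerate(bins)}
    kk = np.array([remap[b] for b in k[in_rng]], dtype=int) if in_rng.any() else np.empty(0, int)
    ci = pd.Categorical(sub["cell_id"].to_numpy()[in_rng], categories=cells).codes
    hist = np.zeros((len(cells), len(bins)))
    np.add.at(hist, (ci, kk), 1.0)
    totals = hist.sum(axis=1)
    keep = totals > 0
    hist[keep] = hist[keep] / totals[keep, None]
    return pd.DataFrame(hist[keep], index=pd.Index(cells[keep], name="cell_id"),
                        columns=[f"ccbin_{i}" for i in range(len(bins))])


def band_fractions(table: ContactTable, cell_id: str | None = None) -> pd.DataFrame:
    """Short-range ([1 kb, 2 Mb)) and mitotic-band ([2, 12) Mb) contact fractions.

    Fractions are over autosomal informative cis contacts per cell; cells with
    zero such contacts get NaN.
    """
    df = table.df
    autosomes = set(table.genome.autosomes)
    m = (df["chrom_a"] == df["chrom_b"]) & df["chrom_a"].isin(autosomes)
    if cell_id is not None:
        m &= df["cell_id"] == cell_id
    sub = df.loc[m]
    d = np.abs(sub["pos_a"].to_numpy() - sub["pos_b"].to_numpy())
    informative = d > 1000
    short = informative & (d < SHORT_RANGE[1])
    band = (d >= MITOTIC_BAND[0]) & (d < MITOTIC_BAND[1])
    g = pd.DataFrame({"cell_id": sub["cell_id"].to_numpy(),
                      "informative": informative, "short": short & informative,
                      "band": band & informative}).groupby("cell_id", sort=True).sum()
    out = pd.DataFrame(index=g.index)
    with np.errstate(invalid="ignore", divide="ignore"):
        out["short_range_fraction"] = g["short"] / g["informative"]
        out["mitotic_band_fraction"] = g["band"] / g["informative"]
    return out


def _spearman_embed(profiles: np.ndarray) -> np.ndarray:
    """Rank-transform, center and unit-normalize rows.

    Squared Euclidean distance between the resulting vectors is an affine
    function of (1 - Spearman rho), so Euclidean k-means on them clusters
    under the Spearman correlation distance.
    """
    ranked = np.apply_along_axis(stats.rankdata, 1, profiles)
    ranked -= ranked.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(ranked, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("constant profile has no rank ordering; cannot cluster")
    return ranked / norms


def cluster_cellcycle(profiles: pd.DataFrame, fractions: pd.DataFrame, k: int = 4,
                      seed: int = 0) -> pd.DataFrame:
    """Group cells into k cell-cycle clusters and assign stage labels.

    Profiles (cells x in-range bins) are rank-transformed and unit-normalized
    then clustered with Euclidean k-means (k-means++ init, fixed seed); rows
    are canonically sorted first so the result is invariant to input order.
    Stage 1 is the cluster with the highest mean mitotic-band fraction;
    stages 2..k are the remaining clusters by decreasing short-range fraction.
    """
    if len(profiles) < k:
        raise ValueError(f"need at least k={k} cells, got {len(profiles)}")
    X = _spearman_embed(profiles.to_numpy(dtype=float))
    if len(np.unique(X, axis=0)) < k:
        raise ValueError("fewer than k distinct profiles; cannot separate clusters")
    # canonical order => permutation invariance for a fixed seed
    order = np.lexsort(X.T[::-1])
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X[order])
    labels = np.empty(len(X), dtype=int)
    labels[order] = km.labels_
    out = pd.DataFrame({"cluster_raw": labels}, index=profiles.index)
    out = out.join(fractions, how="left")
    means = out.groupby("cluster_raw")["mitotic_band_fraction"].mean()
    mitotic = int(means.idxmax())
    rest = out[out["cluster_raw"] != mitotic].groupby("cluster_raw")["short_range_fraction"].mean()
    stage_of = {mitotic: 1}
    for stage, cl in enumerate(rest.sort_values(ascending=False).index, start=2):
        stage_of[int(cl)] = stage
    out["cluster"] = out["cluster_raw"].map(stage_of)
    out["stage"] = np.where(out["cluster"] == 1, "mitotic",
                            "interphase_" + out["cluster"].astype(str))
    return out[["cluster", "stage", "short_range_fraction", "mitotic_band_fraction"]]
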