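"""Contact decay profiles (CDPs) on a logarithmic genomic-distance grid.

A CDP is the per-cell histogram of intrachromosomal contact counts as a
function of genomic separation, computed per chromosome and per parental
allele.  The grid has 143 half-open bins [2^x, 2^(x+0.125)) with left-edge
exponents x = 10, 10.125, ..., 27.750, i.e. distances from 1024 bp up to
(but excluding) 2^27.875 bp.  Profiles are scale-normalized to proportions
so that cells of very different sequencing depth are comparable, and can be
rebinned into 14 coarse bins (non-overlapping groups of 10 fine bins; the
trailing 3 fine bins, which lie beyond the length of any mouse chromosome,
are dropped).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .contacts import ContactTable

N_FINE_BINS = 143
N_COARSE_BINS = 14
EXP_START = 10.0
EXP_STEP = 0.125


@dataclass(frozen=True)
class CDPBinScheme:
    """The logarithmic distance grid: 143 bins [2^x, 2^(x+step))."""

    exp_start: float = EXP_START
    exp_step: float = EXP_STEP
    n_bins: int = N_FINE_BINS

    @property
    def exponents(self) -> np.ndarray:
        """Left-edge exponents x_k = exp_start + k*exp_step, k = 0..n_bins-1."""
        return self.exp_start + self.exp_step * np.arange(self.n_bins)

    @property
    def edges(self) -> np.ndarray:
        """All n_bins+1 bin edges in bp, 2^(exp_start + k*exp_step)."""
        return 2.0 ** (self.exp_start + self.exp_step * np.arange(self.n_bins + 1))

    def assign(self, distances) -> np.ndarray:
        """Fine-bin index per distance; -1 for out-of-range distances.

        Done on log2-transformed distances so the mapping is exact for
        distances that sit on bin edges (e.g. 1024 -> bin 0, 2048 -> bin 8).
        """
        d = np.asarray(distances, dtype=float)
        with np.errstate(divide="ignore"):
            k = np.floor((np.log2(d) - self.exp_start) / self.exp_step + 1e-9).astype(int)
        k[(d < self.edges[0]) | (d >= self.edges[-1])] = -1
        return k

    def histogram(self, distances) -> np.ndarray:
        k = self.assign(distances)
        return np.bincount(k[k >= 0], minlength=self.n_bins).astype(float)

    def bins_within(self, lo_bp: float, hi_bp: float) -> np.ndarray:
        """Indices of fine bins whose full extent lies inside [lo_bp, hi_bp).

        A small tolerance in exponent space makes endpoints that sit exactly
        on grid edges (e.g. 2^16.375 ~ 85 kb, 2^20 ~ 1.05 Mb) behave exactly;
        ranges defined on such edges contain no partial bins.
        """
        x = (np.log2(lo_bp) - self.exp_start) / self.exp_step
        y = (np.log2(hi_bp) - self.exp_start) / self.exp_step
        lo = max(int(np.ceil(x - 1e-9)), 0)
        hi = min(int(np.floor(y + 1e-9)), self.n_bins)
        return np.arange(lo, hi, dtype=int)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"exp_start": self.exp_start, "exp_step": self.exp_step,
                       "n_bins": self.n_bins}, fh, indent=1)


def cdp_bin_edges() -> CDPBinScheme:
    """The study's bin scheme: 143 bins, first edge 1024 bp, step 0.125 in log2."""
    return CDPBinScheme()


@dataclass(frozen=True)
class CDProfile:
    """One cell's contact-decay histogram for one chromosome and allele."""

    cell_id: str
    chrom: str
    allele: str
    counts: np.ndarray
    normalized: bool = False
    n_contacts: int = 0
    low_coverage: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=float))
        if len(self.counts) != N_FINE_BINS:
            raise ValueError(f"CDP must have {N_FINE_BINS} bins, got {len(self.counts)}")


@dataclass(frozen=True)
class RebinnedCDP:
    """Coarse 14-bin profile: group sums of 10 consecutive fine bins."""

    cell_id: str
    chrom: str
    allele: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=float))
        if len(self.counts) != N_COARSE_BINS:
            raise ValueError(f"rebinned CDP must have {N_COARSE_BINS} bins")


def compute_cdp(table: ContactTable, cell_id: str, chrom: str, allele: str,
                scheme: CDPBinScheme | None = None) -> CDProfile:
    """Raw CDP for one (cell, chromosome, allele) from informative cis contacts."""
    scheme = scheme or cdp_bin_edges()
    sub = table.select(cell_ids=[cell_id], chrom=chrom, alleles=[allele])
    counts = scheme.histogram(sub.distances)
    return CDProfile(cell_id, chrom, allele, counts, normalized=False,
                     n_contacts=int(counts.sum()))


def cdp_from_distances(distances, cell_id: str = "", chrom: str = "", allele: str = "",
                       scheme: CDPBinScheme | None = None) -> CDProfile:
    """Raw CDP directly from an array of cis contact distances."""
    scheme = scheme or cdp_bin_edges()
    counts = scheme.histogram(distances)
    return CDProfile(cell_id, chrom, allele, counts, normalized=False,
                     n_contacts=int(counts.sum()))


def normalize_cdp(profile: CDProfile) -> CDProfile:
    """Scale-normalize a raw CDP to proportions (divide by its total).

    A zero-coverage profile comes back all-zero and flagged low_coverage.
    """
    if profile.n_contacts == 0:
        return replace(profile, normalized=True, low_coverage=True)
    return replace(profile, counts=profile.counts / profile.n_contacts, normalized=True)


def rebin_cdp(profile: CDProfile) -> RebinnedCDP:
    """Aggregate fine bins into 14 non-overlapping groups of 10.

    Fine bins 140-142 (separations >= 2^27.5 bp, longer than any mouse
    chromosome) are dropped; group g sums fine bins 10g..10g+9.
    """
    grouped = profile.counts[: 10 * N_COARSE_BINS].reshape(N_COARSE_BINS, 10).sum(axis=1)
    return RebinnedCDP(profile.cell_id, profile.chrom, profile.allele, grouped)


def zscale_profiles(matrix: np.ndarray) -> np.ndarray:
    """Z-scale a cells x bins profile matrix per bin column (population SD).

    Constant columns map to 0.  Used for heatmap display of CDPs across cells.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 2:
        raise ValueError("z-scaling needs a 2-D matrix with at least 2 cells")
    mu = matrix.mean(axis=0)
    sd = matrix.std(axis=0)  # population SD
    out = np.zeros_like(matrix)
    nz = sd > 0
    out[:, nz] = (matrix[:, nz] - mu[nz]) / sd[nz]
    return out


def compute_cdp_table(table: ContactTable, chroms=("chr1", "chrX"),
                      alleles=("hap1", "hap2"),
                      scheme: CDPBinScheme | None = None) -> pd.DataFrame:
    """Raw CDPs for every (cell, chrom, allele): tidy frame with bin_0..bin_142.

    Vectorized over the whole contact table; cells absent for a combination
    get all-zero rows only if they appear elsewhere in the table.
    """
    scheme = scheme or cdp_bin_edges()
    df = table.df
    cells = np.sort(df["cell_id"].unique())
    rows = []
    for chrom in chroms:
        for allele in alleles:
            m = ((df["chrom_a"] == chrom) & (df["chrom_b"] == chrom)
                 & (df["allele"] == allele))
            sub = df.loc[m]
            d = np.abs(sub["pos_a"].to_numpy() - sub["pos_b"].to_numpy())
            k = scheme.assign(d)
            ok = k >= 0
            cell_idx = pd.Categorical(sub["cell_id"].to_numpy()[ok], categories=cells).codes
            hist = np.zeros((len(cells), scheme.n_bins))
            np.add.at(hist, (cell_idx, k[ok]), 1.0)
            for i, cell in enumerate(cells):
                rows.append({"cell_id": cell, "chrom": chrom, "allele": allele,
                             "n_contacts": int(hist[i].sum()),
                             **{f"bin_{b}": hist[i, b] for b in range(scheme.n_bins)}})
    return pd.DataFrame(rows)


def coverage_select(cdp_table: pd.DataFrame, min_per_allele: int,
                    chroms=("chr1", "chrX"), alleles=("hap1", "hap2")) -> set[str]:
    """Cells with >= min_per_allele intrachromosomal contacts for every
    requested (chromosome, allele) combination.

    The study uses 100 per allele for Patski cells and 50 for the
    differentiation time-course lines.
    """
    need = {(c, a) for c in chroms for a in alleles}
    ok_cells = set()
    if cdp_table.empty:
        return ok_cells
    piv = cdp_table.pivot_table(index="cell_id", columns=["chrom", "allele"],
                                values="n_contacts", fill_value=0)
    for cell, row in piv.iterrows():
        if all((c, a) in piv.columns and row[(c, a)] >= min_per_allele for c, a in need):
            ok_cells.add(cell)
    return ok_cells


def profile_from_row(row: pd.Series, normalized: bool = False) -> CDProfile:
    """Rebuild a CDProfile from a compute_cdp_table row."""
    counts = row[[f"bin_{b}" for b in range(N_FINE_BINS)]].to_numpy(dtype=float)
    return CDProfile(row["cell_id"], row["chrom"], row["allele"], counts,
                     normalized=normalized, n_contacts=int(row["n_contacts"]))


def write_cdp_table(cdp_table: pd.DataFrame, path, scheme: CDPBinScheme | None = None) -> None:
    cdp_table.to_csv(path, sep="\t", index=False)
    scheme = scheme or cdp_bin_edges()
    scheme.to_json(str(path) + ".scheme.json")
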