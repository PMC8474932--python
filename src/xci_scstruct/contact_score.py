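"""V-shaped contact score along the diagonal of a binned contact map.

The contact score of a genomic bin is the mean interaction count within a
V-shaped region centred on that bin — every matrix cell (i, j) with
i <= c <= j and j - i no larger than the arm span (20 Mb by default), arms
truncated at chromosome ends.  After adding a pseudocount to every cell, the
score is normalized as log2(score / chromosomal mean) and smoothed with a
five-window, degree-two Savitzky–Golay filter.  On the inactive X the track
dips sharply at the *Dxz4* hinge separating the two superdomains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import savgol_filter

from .contacts import BinnedMatrix

EDGE_EXCLUSION = 10_000_000  # bp trimmed at each chromosome end
DEFAULT_ARM = 20_000_000     # bp arm span of the V


@dataclass
class ContactScoreTrack:
    """Per-bin contact-score track for one chromosome and allele."""

    chrom: str
    allele: str
    resolution: int
    raw_score: np.ndarray
    smoothed_log2: np.ndarray  # NaN at invalid bins
    valid: np.ndarray          # bool per bin

    def to_bedgraph(self, path) -> None:
        """Write valid bins as bedGraph (chrom, start, end, smoothed_log2)."""
        with open(path, "w") as fh:
            for i in np.flatnonzero(self.valid):
                v = self.smoothed_log2[i]
                if np.isnan(v):
                    continue
                fh.write(f"{self.chrom}\t{i * self.resolution}"
                         f"\t{(i + 1) * self.resolution}\t{v:.6g}\n")


def raw_contact_score(matrix: BinnedMatrix | np.ndarray, arm: int = DEFAULT_ARM,
                      resolution: int | None = None, pseudocount: float = 1.0) -> np.ndarray:
    """Mean interaction count within the V window centred on each bin.

    ``pseudocount`` is added to every matrix cell first; truncated windows at
    chromosome ends divide by the number of cells actually included.
    """
    if isinstance(matrix, BinnedMatrix):
        if not matrix.is_cis:
            raise ValueError("contact score requires a cis (square) matrix")
        dense = matrix.dense()
        resolution = matrix.resolution
    else:
        dense = np.asarray(matrix, dtype=float)
        if resolution is None:
            raise ValueError("resolution required for a bare matrix")
    if dense.shape[0] != dense.shape[1]:
        raise ValueError("matrix must be square")
    w = arm // resolution
    if w < 1:
        raise ValueError("arm span must be at least one bin")
    n = dense.shape[0]
    m = dense + pseudocount
    scores = np.empty(n)
    for c in range(n):
        total = 0.0
        count = 0
        # cells (i, j): i <= c <= j, j - i <= w, truncated at [0, n)
        for i in range(max(0, c - w), c + 1):
            j_hi = min(n - 1, i + w)
            row = m[i, c:j_hi + 1]
            total += row.sum()
            count += row.size
        scores[c] = total / count
    return scores


def normalize_smooth_score(raw_scores: np.ndarray, chrom_length: int, resolution: int,
                           missing: np.ndarray | None = None,
                           edge_exclusion: int = EDGE_EXCLUSION,
                           window: int = 5, polyorder: int = 2,
                           chrom: str = "", allele: str = "non-allelic") -> ContactScoreTrack:
    """Normalize (log2 over chromosomal mean) and Savitzky–Golay smooth a track.

    Bins within ``edge_exclusion`` of either chromosome end are excluded;
    originally-missing bins are spline-interpolated (cubic; linear below 4
    anchors) so the filter sees a complete vector, then restored to NaN.
    """
    raw_scores = np.asarray(raw_scores, dtype=float)
    n = len(raw_scores)
    missing = np.zeros(n, dtype=bool) if missing is None else np.asarray(missing, bool)
    starts = np.arange(n) * resolution
    ends = starts + resolution
    in_edge = (starts < edge_exclusion) | (ends > chrom_length - edge_exclusion)
    valid = ~in_edge & ~missing
    out = np.full(n, np.nan)
    if valid.sum() == 0:
        return ContactScoreTrack(chrom, allele, resolution, raw_scores, out, valid)
    chrom_mean = raw_scores[valid].mean()
    with np.errstate(divide="ignore", invalid="ignore"):
        log2 = np.log2(raw_scores / chrom_mean)
    # fill missing interior bins so the filter has a complete vector
    interior = ~in_edge
    idx = np.flatnonzero(interior)
    vals = log2[idx].copy()
    miss_here = missing[idx] | ~np.isfinite(vals)
    anchors = np.flatnonzero(~miss_here)
    if miss_here.any() and anchors.size > 0:
        if anchors.size >= 4:
            cs = CubicSpline(idx[anchors], vals[anchors])
            vals[miss_here] = cs(idx[miss_here])
        else:
            vals[miss_here] = np.interp(idx[miss_here], idx[anchors], vals[anchors])
    if len(vals) < window:
        warnings.warn("fewer valid bins than the smoothing window; smoothing skipped")
        smoothed = vals
    else:
        smoothed = savgol_filter(vals, window_length=window, polyorder=polyorder)
    out[idx] = smoothed
    out[~valid] = np.nan  # restore NaN at missing + edge bins
    return ContactScoreTrack(chrom, allele, resolution, raw_scores, out, valid)


def contact_score_track(matrix: BinnedMatrix, chrom_length: int, arm: int = DEFAULT_ARM,
                        pseudocount: float = 1.0, **kwargs) -> ContactScoreTrack:
    """raw_contact_score + normalize_smooth_score for a binned cis matrix.

    Bins with zero marginal coverage in the raw matrix are treated as missing.
    """
    dense = matrix.dense()
    missing = dense.sum(axis=0) + dense.sum(axis=1) == 0
    raw = raw_contact_score(dense, arm=arm, resolution=matrix.resolution,
                            pseudocount=pseudocount)
    return normalize_smooth_score(raw, chrom_length, matrix.resolution, missing=missing,
                                  chrom=matrix.chrom_a, allele=matrix.allele, **kwargs)


def locate_dip(track: ContactScoreTrack, locus: int, window: int = 20_000_000):
    """Local minimum of the smoothed track nearest a locus, with its depth.

    Searches within ``window`` bp either side of ``locus``; depth is measured
    against the nearest flanking local maxima (mean of the two, or the single
    one at track ends).  Returns (bin index, depth) or (None, nan) when no
    local minimum exists (e.g. a constant track).
    """
    c = locus // track.resolution
    if not (0 <= c < len(track.valid)) or not track.valid[c]:
        raise ValueError("locus falls in an excluded or missing bin")
    y = track.smoothed_log2
    half = max(1, window // track.resolution)
    lo, hi = max(0, c - half), min(len(y), c + half + 1)

    def neighbor(b: int) -> float:
        # NaN / out-of-range neighbours count as -inf so track boundaries
        # are never reported as local minima
        return y[b] if 0 <= b < len(y) and np.isfinite(y[b]) else -np.inf

    # local minima with plateau handling: a run of equal values is a minimum
    # when both values flanking the run are strictly larger
    cand = []
    b = lo
    while b < hi:
        if not np.isfinite(y[b]):
            b += 1
            continue
        e = b
        while e + 1 < hi and np.isfinite(y[e + 1]) and y[e + 1] == y[b]:
            e += 1
        if neighbor(b - 1) > y[b] and neighbor(e + 1) > y[b]:
            cand.append(b if abs(b - c) <= abs(e - c) else e)
        b = e + 1
    if not cand:
        return None, float("nan")
    b = min(cand, key=lambda i: abs(i - c))
    # flanking local maxima
    def flank_max(direction: int) -> float:
        i = b + direction
        best = -np.inf
        while 0 <= i < len(y) and np.isfinite(y[i]):
            if y[i] > best:
                best = y[i]
            else:
                break
            i += direction
        return best
    lmax, rmax = flank_max(-1), flank_max(+1)
    peaks = [v for v in (lmax, rmax) if np.isfinite(v)]
    depth = float(np.mean(peaks) - y[b]) if peaks else float("nan")
    return int(b), depth
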