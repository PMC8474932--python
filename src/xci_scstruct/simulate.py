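"""Ground-truth-labelled synthetic inputs for the whole pipeline.

Two generators emulate the statistical structure of the study's inputs:

* per-cell sparse allelic contact lists with power-law distance decay
  P(d) ∝ d^(−α), an optional mitotic band (mass boost at 2–12 Mb), and an
  optional bipartite superdomain modification on the inactive-X homolog
  (mid-range depletion at 85 kb–1.1 Mb, long-range boost at 6.5–87 Mb with
  the boosted mass confined to within-superdomain pairs around a hinge at
  44% of chrX length);
* allelic UMI count matrices (genes × cells × alleles) with progressive
  mono-allelic chrX silencing across time points, a residual "escape"
  expression fraction on the silenced homolog, and gamma-Poisson
  (negative-binomial) per-cell depth variation.

Distances are sampled by inverse CDF on the decay law discretized over the
143-bin CDP grid (then placed uniformly within the bin), so generator effect
sizes are expressed on the same grid the analysis measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cdp import CDPBinScheme, cdp_bin_edges
from .contacts import COLUMNS, ContactTable
from .genome import ChromSizes
from .skew import ALLELES, AllelicCountMatrix
from .structure import LMDRanges


@dataclass(frozen=True)
class ContactGeneratorSpec:
    """Parameters of the single-cell contact generator (defaults = study conditions)."""

    genome: ChromSizes = field(default_factory=ChromSizes.default)
    n_min: int = 50           # per-allele coverage, log-uniform lower bound
    n_max: int = 5000         # and upper bound
    alpha: float = 1.0        # decay exponent of P(d) ∝ d^-alpha
    mitotic_band_boost: float = 8.0   # mass multiplier on 2-12 Mb for mitotic cells
    boundary_frac: float = 0.44       # hinge position as fraction of chrX length
    mid_depletion: float = 0.5        # Xi multiplier on 85 kb-1.1 Mb mass
    long_boost: float = 4.0           # Xi multiplier on 6.5-87 Mb mass
    mitotic_fraction: float = 0.03
    xi_hap1_prob: float = 0.5         # P(the Xi is the hap1 homolog)
    trans_fraction: float = 0.0       # fraction of contacts made interchromosomal
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.n_min <= self.n_max):
            raise ValueError("need 0 < n_min <= n_max")
        if min(self.mitotic_band_boost, self.mid_depletion, self.long_boost) <= 0:
            raise ValueError("boost/depletion factors must be positive")
        for f in (self.mitotic_fraction, self.xi_hap1_prob, self.trans_fraction,
                  self.boundary_frac):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")


MITOTIC_BAND = (2_000_000.0, 12_000_000.0)


def _base_bin_probs(scheme: CDPBinScheme, chrom_len: int, alpha: float) -> np.ndarray:
    """P(fine bin) ∝ ∫ d^-alpha over the bin, truncated at the chromosome length."""
    lo = scheme.edges[:-1].copy()
    hi = np.minimum(scheme.edges[1:], float(chrom_len))
    ok = hi > lo
    mass = np.zeros(scheme.n_bins)
    if abs(alpha - 1.0) < 1e-12:
        mass[ok] = np.log(hi[ok] / lo[ok])
    else:
        p = 1.0 - alpha
        mass[ok] = (hi[ok] ** p - lo[ok] ** p) / p
    return mass / mass.sum()


def _band_bins(scheme: CDPBinScheme, lo: float, hi: float) -> np.ndarray:
    """Bins whose geometric midpoint lies in [lo, hi)."""
    mid = np.sqrt(scheme.edges[:-1] * scheme.edges[1:])
    return np.flatnonzero((mid >= lo) & (mid < hi))


def decay_law(spec: ContactGeneratorSpec, chrom: str, mitotic: bool = False,
              bipartite: bool = False, alpha: float | None = None,
              extra_boost: tuple[float, float, float] | None = None,
              scheme: CDPBinScheme | None = None) -> np.ndarray:
    """The fine-bin distance distribution for one chromosome/state/structure.

    The bipartite modification moves mass only between the LMD mid and long
    ranges (depletion and boost, then renormalization); total probability is
    conserved exactly.  ``extra_boost`` = (lo_bp, hi_bp, factor) multiplies
    mass in an arbitrary band (used for cell-cycle archetypes).
    """
    scheme = scheme or cdp_bin_edges()
    probs = _base_bin_probs(scheme, spec.genome[chrom], spec.alpha if alpha is None else alpha)
    if mitotic:
        band = _band_bins(scheme, *MITOTIC_BAND)
        probs = probs.copy()
        probs[band] *= spec.mitotic_band_boost
        probs /= probs.sum()
    if extra_boost is not None:
        lo, hi, factor = extra_boost
        probs = probs.copy()
        probs[_band_bins(scheme, lo, hi)] *= factor
        probs /= probs.sum()
    if bipartite:
        ranges = LMDRanges()
        probs = probs.copy()
        probs[ranges.mid_bins(scheme)] *= spec.mid_depletion
        probs[ranges.long_bins(scheme)] *= spec.long_boost
        probs /= probs.sum()
    return probs


def _sample_distances(rng: np.random.Generator, probs: np.ndarray, chrom_len: int,
                      n: int, scheme: CDPBinScheme) -> tuple[np.ndarray, np.ndarray]:
    """n distances: bin by inverse CDF, then uniform placement within the bin."""
    k = rng.choice(scheme.n_bins, size=n, p=probs)
    lo = scheme.edges[k]
    hi = np.minimum(scheme.edges[k + 1], float(chrom_len))
    d = np.floor(lo + rng.random(n) * (hi - lo)).astype(np.int64)
    return d, k


def _place(rng: np.random.Generator, d: np.ndarray, chrom_len: int,
           same_side: np.ndarray | None = None, boundary: int | None = None) -> np.ndarray:
    """pos_a per contact, uniform over placements that keep pos_a + d on the
    chromosome; where same_side is set, both ends confined to one superdomain."""
    pos = rng.integers(0, np.maximum(chrom_len - d, 1))
    if same_side is not None and boundary is not None:
        for i in np.flatnonzero(same_side):
            left_room = boundary - d[i]          # pos in [0, left_room)
            right_room = chrom_len - boundary - d[i]  # pos in [boundary, ...)
            rooms = [max(left_room, 0), max(right_room, 0)]
            if sum(rooms) == 0:
                continue  # distance fits in neither superdomain; place freely
            if rng.random() < rooms[0] / sum(rooms):
                pos[i] = rng.integers(0, rooms[0])
            else:
                pos[i] = boundary + rng.integers(0, rooms[1])
    return pos


def simulate_cell_contacts(spec: ContactGeneratorSpec, cell_id: str,
                           state: str = "interphase", bipartite: bool = False,
                           xi_allele: str = "hap1", rng: np.random.Generator | None = None,
                           alpha: float | None = None,
                           extra_boost: tuple[float, float, float] | None = None
                           ) -> pd.DataFrame:
    """Contact records for one cell across both alleles of every chromosome.

    The bipartite modification applies only to the designated Xi homolog of
    chrX (and is suppressed in mitotic cells, where the condensed state
    erases the superdomain structure); the long-range boost's added mass is
    placed within a single superdomain.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    scheme = cdp_bin_edges()
    mitotic = state == "mitotic"
    frames = []
    for chrom in spec.genome.names:
        L = spec.genome[chrom]
        for allele in ("hap1", "hap2"):
            is_xi = bipartite and not mitotic and chrom == "chrX" and allele == xi_allele
            probs = decay_law(spec, chrom, mitotic=mitotic, bipartite=is_xi, alpha=alpha,
                              extra_boost=extra_boost)
            n = int(round(np.exp(rng.uniform(np.log(spec.n_min), np.log(spec.n_max)))))
            d, k = _sample_distances(rng, probs, L, n, scheme)
            same_side = None
            boundary = None
            if is_xi:
                long_bins = set(LMDRanges().long_bins(scheme).tolist())
                boundary = int(spec.boundary_frac * L)
                in_long = np.isin(k, list(long_bins))
                # the boosted share of long-range mass is within-superdomain
                same_side = in_long & (rng.random(n) < 1.0 - 1.0 / spec.long_boost)
            pos_a = _place(rng, d, L, same_side, boundary)
            pos_b = pos_a + d
            df = pd.DataFrame({"cell_id": cell_id, "chrom_a": chrom, "pos_a": pos_a,
                               "chrom_b": chrom, "pos_b": pos_b, "allele": allele})
            if spec.trans_fraction > 0:
                others = [c for c in spec.genome.names if c != chrom]
                flip = rng.random(n) < spec.trans_fraction
                for i in np.flatnonzero(flip):
                    oc = others[rng.integers(0, len(others))]
                    df.loc[i, "chrom_b"] = oc
                    df.loc[i, "pos_b"] = int(rng.integers(0, spec.genome[oc]))
            frames.append(df)
    return pd.concat(frames, ignore_index=True)[COLUMNS]


def _allocate(n: int, fraction: float) -> int:
    """Deterministic rounding allocation of a subpopulation size."""
    return int(round(n * fraction))


def simulate_population(spec: ContactGeneratorSpec, n_cells: int,
                        bipartite_fraction: float = 0.0, time_point: str = "d0",
                        rng: np.random.Generator | None = None,
                        cell_prefix: str | None = None) -> tuple[ContactTable, pd.DataFrame]:
    """A labelled population of cells for one time point.

    Composition is deterministic under the rounding allocation (counts, not
    Bernoulli draws); which cells get which truth label is randomized under
    the seed.  Returns the contact table and the per-cell truth table.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    prefix = cell_prefix if cell_prefix is not None else f"{time_point}_cell"
    n_bip = _allocate(n_cells, bipartite_fraction)
    n_mit = _allocate(n_cells, spec.mitotic_fraction)
    order = rng.permutation(n_cells)
    bip = np.zeros(n_cells, bool)
    bip[order[:n_bip]] = True
    mit = np.zeros(n_cells, bool)
    mit[rng.permutation(n_cells)[:n_mit]] = True
    xi = np.where(rng.random(n_cells) < spec.xi_hap1_prob, "hap1", "hap2")
    frames, truth = [], []
    for i in range(n_cells):
        cell = f"{prefix}{i:04d}"
        state = "mitotic" if mit[i] else "interphase"
        frames.append(simulate_cell_contacts(spec, cell, state=state,
                                             bipartite=bool(bip[i]), xi_allele=xi[i], rng=rng))
        truth.append({"cell_id": cell, "time_point": time_point, "state": state,
                      "bipartite": bool(bip[i]), "xi_allele": xi[i] if bip[i] else "none"})
    table = ContactTable(pd.concat(frames, ignore_index=True), spec.genome, validate=False)
    return table, pd.DataFrame(truth)


def simulate_timecourse(spec: ContactGeneratorSpec, n_cells_per_tp: int,
                        bipartite_fractions: dict[str, float]) -> tuple[ContactTable, pd.DataFrame]:
    """Multi-time-point population with per-time-point bipartite fractions."""
    rng = np.random.default_rng(spec.seed)
    tables, truths = [], []
    for tp, frac in bipartite_fractions.items():
        t, tr = simulate_population(spec, n_cells_per_tp, bipartite_fraction=frac,
                                    time_point=tp, rng=rng)
        tables.append(t.df)
        truths.append(tr)
    df = pd.concat(tables, ignore_index=True)
    return ContactTable(df, spec.genome, validate=False), pd.concat(truths, ignore_index=True)


#: four cell-cycle archetypes with distinct CDP shapes inside 50 kb-8 Mb:
#: (state, decay exponent, extra band boost (lo, hi, factor) or None);
#: archetype 0 is mitotic (2-12 Mb band), archetypes 1-2 carry contact
#: enrichments at successively longer ranges, archetype 3 is steeply decaying
CELLCYCLE_ARCHETYPES = (
    ("mitotic", 1.0, None),
    ("interphase", 1.0, (50_000.0, 200_000.0, 6.0)),
    ("interphase", 1.0, (400_000.0, 1_600_000.0, 6.0)),
    ("interphase", 1.3, None),
)


def simulate_cellcycle_population(spec: ContactGeneratorSpec, n_per_archetype: int = 25
                                  ) -> tuple[ContactTable, pd.DataFrame]:
    """Four cell-cycle archetypes: one mitotic (band-boosted) + three interphase
    stages whose decay laws peak at distinct distance scales."""
    rng = np.random.default_rng(spec.seed)
    frames, truth = [], []
    for arch, (state, alpha, boost) in enumerate(CELLCYCLE_ARCHETYPES):
        for i in range(n_per_archetype):
            cell = f"arch{arch}_cell{i:03d}"
            frames.append(simulate_cell_contacts(spec, cell, state=state, rng=rng,
                                                 alpha=alpha, extra_boost=boost))
            truth.append({"cell_id": cell, "archetype": arch, "state": state})
    df = pd.concat(frames, ignore_index=True)
    return ContactTable(df, spec.genome, validate=False), pd.DataFrame(truth)


@dataclass(frozen=True)
class CountGeneratorSpec:
    """Parameters of the allelic UMI count generator (expression/accessibility)."""

    n_genes: dict = field(default_factory=lambda: {"chr1": 300, "chrX": 200})
    rate_sigma: float = 1.0       # log-normal SD of per-gene baseline rates
    mean_allele_rate: float = 0.5  # mean UMIs per gene per allele per cell
    depth_shape: float = 5.0      # gamma shape of per-cell depth (gamma-Poisson = NB)
    completeness: float = 0.02    # residual Xi expression fraction (escape)
    xi_hap1_prob: float = 0.5
    sex: str = "female"           # 'male' => hap2 chrX absent
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.completeness <= 1.0:
            raise ValueError("completeness must be in [0, 1]")
        if self.sex not in ("female", "male"):
            raise ValueError("sex must be 'female' or 'male'")


def simulate_allelic_counts(spec: CountGeneratorSpec, n_cells_per_tp: int,
                            silencing_fractions: dict[str, float]
                            ) -> tuple[AllelicCountMatrix, pd.DataFrame]:
    """Allelic UMI matrix over a silencing time course, with per-cell truth.

    Counts are gamma-Poisson: count[g, c, a] ~ Poisson(rate_g · depth_c · m),
    where m is 1 for active alleles and ``completeness`` for the silenced Xi
    chrX allele; male cells have zero hap2 chrX counts throughout.
    """
    rng = np.random.default_rng(spec.seed)
    genes, chroms = [], []
    for chrom, n in spec.n_genes.items():
        genes += [f"{chrom}_g{i:04d}" for i in range(n)]
        chroms += [chrom] * n
    chrom_arr = np.array(chroms)
    rates = rng.lognormal(mean=0.0, sigma=spec.rate_sigma, size=len(genes))
    rates *= spec.mean_allele_rate / rates.mean()
    cells, truth = [], []
    mats = {a: [] for a in ALLELES}
    for tp, frac in silencing_fractions.items():
        n_sil = _allocate(n_cells_per_tp, frac)
        silenced = np.zeros(n_cells_per_tp, bool)
        silenced[rng.permutation(n_cells_per_tp)[:n_sil]] = True
        xi = np.where(rng.random(n_cells_per_tp) < spec.xi_hap1_prob, "hap1", "hap2")
        for i in range(n_cells_per_tp):
            cell = f"{tp}_rna{i:04d}"
            depth = rng.gamma(spec.depth_shape, 1.0 / spec.depth_shape)
            for a in ALLELES:
                mult = np.ones(len(genes))
                if spec.sex == "male" and a == "hap2":
                    mult[chrom_arr == "chrX"] = 0.0
                elif silenced[i] and a == xi[i]:
                    mult[chrom_arr == "chrX"] = spec.completeness
                mats[a].append(rng.poisson(rates * depth * mult))
            cells.append(cell)
            truth.append({"cell_id": cell, "time_point": tp,
                          "silenced": bool(silenced[i]) and spec.sex == "female",
                          "xi_allele": xi[i] if silenced[i] else "none",
                          "sex": spec.sex})
    counts = {a: pd.DataFrame(np.array(mats[a]).T, index=genes, columns=cells)
              for a in ALLELES}
    feature_meta = pd.DataFrame({"chrom": chroms}, index=pd.Index(genes, name="feature"))
    truth_df = pd.DataFrame(truth).set_index("cell_id")
    cell_meta = truth_df[["time_point", "sex"]].copy()
    matrix = AllelicCountMatrix(counts, feature_meta, cell_meta)
    return matrix, truth_df.reset_index()
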