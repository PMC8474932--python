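"""Single-cell chromatin contact tables: reading, QC, allelic segregation, binning.

Contacts arrive as pairs-like TSV records, one valid read pair per line, each
carrying a cell barcode and a per-pair haplotype tag (``hap1``/``hap2``/
``ambiguous``).  Ambiguous pairs (no informative SNP on either end) are kept
for non-allelic analyses only; pairs with SNP evidence for both haplotypes are
conflicts and are discarded everywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse

from .genome import ChromSizes

ALLELES = ("hap1", "hap2", "ambiguous")

#: columns of the DataFrame backing a ContactTable, in canonical order
COLUMNS = ["cell_id", "chrom_a", "pos_a", "chrom_b", "pos_b", "allele"]

#: intrachromosomal contacts at <= this separation (bp) are uninformative
MIN_INFORMATIVE_DISTANCE = 1000


class Allele(str, Enum):
    HAP1 = "hap1"
    HAP2 = "hap2"
    AMBIGUOUS = "ambiguous"
    CONFLICT = "conflict"


@dataclass(frozen=True)
class ContactRecord:
    """One valid contact pair of one cell, tagged with its parental allele."""

    cell_id: str
    chrom_a: str
    pos_a: int
    chrom_b: str
    pos_b: int
    allele: str = "ambiguous"

    def __post_init__(self) -> None:
        if self.pos_a < 0 or self.pos_b < 0:
            raise ValueError(f"negative position in record {self}")
        if self.allele not in ALLELES:
            raise ValueError(f"unknown allele tag {self.allele!r}")

    @property
    def is_cis(self) -> bool:
        return self.chrom_a == self.chrom_b

    @property
    def distance(self) -> int | None:
        """Genomic separation |pos_a - pos_b| for cis pairs, None for trans."""
        return abs(self.pos_a - self.pos_b) if self.is_cis else None


class ContactTable:
    """An ordered collection of contact records validated against a genome.

    Backed by a pandas DataFrame with columns ``cell_id, chrom_a, pos_a,
    chrom_b, pos_b, allele``; ordering is stable under write/read round trips.
    """

    def __init__(self, df: pd.DataFrame, genome: ChromSizes, validate: bool = True):
        df = df.reset_index(drop=True)[COLUMNS]
        if validate:
            _validate(df, genome)
        self.df = df
        self.genome = genome

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        return isinstance(other, ContactTable) and self.df.equals(other.df)

    @classmethod
    def from_records(cls, records: list[ContactRecord], genome: ChromSizes) -> "ContactTable":
        df = pd.DataFrame([vars(r) for r in records], columns=COLUMNS)
        df["pos_a"] = df["pos_a"].astype(np.int64)
        df["pos_b"] = df["pos_b"].astype(np.int64)
        return cls(df, genome)

    def records(self) -> list[ContactRecord]:
        return [ContactRecord(*row) for row in self.df.itertuples(index=False)]

    @property
    def cis_mask(self) -> np.ndarray:
        return (self.df["chrom_a"] == self.df["chrom_b"]).to_numpy()

    @property
    def distances(self) -> np.ndarray:
        """|pos_a - pos_b|; only meaningful where ``cis_mask`` is True."""
        return np.abs(self.df["pos_a"].to_numpy() - self.df["pos_b"].to_numpy())

    def subset(self, mask) -> "ContactTable":
        return ContactTable(self.df.loc[mask], self.genome, validate=False)

    def select(self, cell_ids=None, chrom=None, alleles=None) -> "ContactTable":
        m = np.ones(len(self.df), dtype=bool)
        if cell_ids is not None:
            m &= self.df["cell_id"].isin(set(cell_ids)).to_numpy()
        if chrom is not None:
            m &= (self.df["chrom_a"] == chrom).to_numpy() & (self.df["chrom_b"] == chrom).to_numpy()
        if alleles is not None:
            m &= self.df["allele"].isin(set(alleles)).to_numpy()
        return self.subset(m)


def _validate(df: pd.DataFrame, genome: ChromSizes) -> None:
    for col in ("chrom_a", "chrom_b"):
        unknown = set(df[col].unique()) - set(genome.names)
        if unknown:
            raise ValueError(f"unknown chromosome(s) in column {col}: {sorted(unknown)}")
    if len(df) and (df["pos_a"].lt(0).any() or df["pos_b"].lt(0).any()):
        bad = df.index[(df["pos_a"] < 0) | (df["pos_b"] < 0)][0]
        raise ValueError(f"negative position at record {bad}")
    bad_alleles = set(df["allele"].unique()) - set(ALLELES)
    if bad_alleles:
        raise ValueError(f"unknown allele tag(s): {sorted(bad_alleles)}")


def read_contacts(path, genome: ChromSizes) -> ContactTable:
    """Read a pairs-like TSV into a ContactTable.

    '#'-prefixed lines are header/comment lines; the last one (or the first
    non-'#' line if none is prefixed) names the columns.  Required columns:
    cell_id, chrom_a, pos_a, chrom_b, pos_b; an ``allele`` column is optional
    and defaults to ``ambiguous``.  Malformed lines raise with line numbers.
    """
    path = Path(path)
    header = None
    n_comment = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                header = line.lstrip("#").strip()
                n_comment += 1
            else:
                break
    if header is None:
        # plain TSV with a first-line header
        df = pd.read_csv(path, sep="\t", dtype={0: str})
    else:
        names = header.split("\t")
        df = pd.read_csv(path, sep="\t", skiprows=n_comment, header=None, names=names,
                         dtype=str)
    missing = [c for c in COLUMNS[:5] if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s) {missing} in {path}")
    if "allele" not in df.columns:
        df["allele"] = "ambiguous"
    for col in ("pos_a", "pos_b"):
        try:
            df[col] = pd.to_numeric(df[col]).astype(np.int64)
        except (ValueError, TypeError) as e:
            raise ValueError(f"non-numeric {col} in {path}: {e}") from None
    for col in ("pos_a", "pos_b"):
        neg = df.index[df[col] < 0]
        if len(neg):
            line_no = neg[0] + n_comment + (0 if header is not None else 1) + 1
            raise ValueError(f"negative {col} at line {line_no} of {path}")
    df["cell_id"] = df["cell_id"].astype(str)
    return ContactTable(df[COLUMNS], genome)


def write_contacts(table: ContactTable, path) -> None:
    """Write the pairs-like TSV dialect read_contacts consumes (round-trip safe)."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(COLUMNS) + "\n")
        table.df.to_csv(fh, sep="\t", header=False, index=False)


def segregate_allele(snp_evidence_a: tuple[int, int], snp_evidence_b: tuple[int, int]) -> Allele:
    """Assign a read pair to a parental haplotype from per-end SNP evidence.

    Each argument is (n hap1 SNP hits, n hap2 SNP hits) for one end of the
    pair.  A pair is assigned to a haplotype when either end carries at least
    one SNP particular to that haplotype and none for the other; pairs with
    evidence for both haplotypes are conflicts (discarded from every analysis),
    pairs with no SNP evidence are ambiguous (retained for non-allelic
    analysis only).
    """
    for counts in (snp_evidence_a, snp_evidence_b):
        if min(counts) < 0:
            raise ValueError(f"negative SNP evidence count: {counts}")
    h1 = snp_evidence_a[0] + snp_evidence_b[0]
    h2 = snp_evidence_a[1] + snp_evidence_b[1]
    if h1 > 0 and h2 > 0:
        return Allele.CONFLICT
    if h1 > 0:
        return Allele.HAP1
    if h2 > 0:
        return Allele.HAP2
    return Allele.AMBIGUOUS


@dataclass(frozen=True)
class CellQCRecord:
    """Per-cell library QC summary from the upstream alignment pipeline."""

    cell_id: str
    n_valid_pairs: int
    cis_count: int
    trans_count: int
    species_purity: float

    def __post_init__(self) -> None:
        if self.cis_count + self.trans_count != self.n_valid_pairs:
            raise ValueError(
                f"{self.cell_id}: cis+trans ({self.cis_count}+{self.trans_count}) "
                f"!= n_valid_pairs ({self.n_valid_pairs})")
        if not 0.0 <= self.species_purity <= 1.0:
            raise ValueError(f"{self.cell_id}: species_purity {self.species_purity} not in [0,1]")

    def cis_trans_ratio(self) -> float:
        if self.trans_count == 0:
            return np.inf
        return self.cis_count / self.trans_count


def filter_cells_qc(qc, min_pairs: int = 1000, min_cis_trans: float = 1.0,
                    min_purity: float = 0.95) -> set[str]:
    """Cells passing library QC: >=min_pairs valid pairs, cis:trans >= min_cis_trans,
    species purity >= min_purity.  trans=0 with cis>0 passes the ratio test
    (ratio treated as +inf)."""
    passing = set()
    for rec in qc:
        if (rec.n_valid_pairs >= min_pairs
                and rec.cis_trans_ratio() >= min_cis_trans
                and rec.species_purity >= min_purity):
            passing.add(rec.cell_id)
    return passing


def qc_from_contacts(table: ContactTable, species_purity: float = 1.0) -> list[CellQCRecord]:
    """Derive per-cell QC records from a contact table (purity supplied upstream)."""
    cis = table.cis_mask
    out = []
    for cell, grp in table.df.groupby("cell_id", sort=True):
        c = int((grp["chrom_a"] == grp["chrom_b"]).sum())
        t = len(grp) - c
        out.append(CellQCRecord(cell, len(grp), c, t, species_purity))
    return out


def informative_contacts(table: ContactTable) -> ContactTable:
    """Keep interchromosomal contacts and intrachromosomal contacts spanning
    more than 1 kb; short-range cis pairs are uninformative and dropped.
    Idempotent."""
    cis = table.cis_mask
    keep = ~cis | (table.distances > MIN_INFORMATIVE_DISTANCE)
    return table.subset(keep)


@dataclass
class BinnedMatrix:
    """Sparse upper-triangular binned contact matrix for one chromosome (pair).

    ``counts`` stores (i, j) with i <= j for cis matrices; the sum of entries
    equals the number of contributing records.
    """

    chrom_a: str
    chrom_b: str
    resolution: int
    counts: sparse.coo_matrix
    allele: str  # 'hap1' | 'hap2' | 'non-allelic'
    cells: frozenset[str]

    @property
    def is_cis(self) -> bool:
        return self.chrom_a == self.chrom_b

    @property
    def n_bins(self) -> tuple[int, int]:
        return self.counts.shape

    def total(self) -> int:
        return int(self.counts.sum())

    def dense(self) -> np.ndarray:
        """Dense symmetric matrix (cis) or rectangular matrix (trans)."""
        m = self.counts.toarray().astype(float)
        if self.is_cis:
            m = m + np.triu(m, 1).T
        return m

    def write_triplets(self, path) -> None:
        coo = self.counts.tocoo()
        with open(path, "w") as fh:
            fh.write(f"#chrom_a={self.chrom_a}\tchrom_b={self.chrom_b}"
                     f"\tresolution={self.resolution}\tallele={self.allele}\n")
            fh.write("#bin_i\tbin_j\tcount\n")
            for i, j, v in zip(coo.row, coo.col, coo.data):
                fh.write(f"{i}\t{j}\t{int(v)}\n")


def bin_contacts(table: ContactTable, resolution: int, chrom_a: str, chrom_b: str | None = None,
                 cells=None, allele: str | None = None) -> BinnedMatrix:
    """Sum contacts within fixed-size genomic bins for one chromosome (pair).

    ``allele`` of None selects every record regardless of tag (non-allelic);
    'hap1'/'hap2' select that haplotype only.  Pseudobulk over a cell set is
    the sum over its cells (additivity tested as an invariant).
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    chrom_b = chrom_b or chrom_a
    df = table.df
    m = (df["chrom_a"] == chrom_a).to_numpy() & (df["chrom_b"] == chrom_b).to_numpy()
    if chrom_a != chrom_b:
        m |= (df["chrom_a"] == chrom_b).to_numpy() & (df["chrom_b"] == chrom_a).to_numpy()
    if cells is not None:
        m &= df["cell_id"].isin(set(cells)).to_numpy()
    if allele is not None:
        m &= (df["allele"] == allele).to_numpy()
    sub = df.loc[m]
    na = -(-table.genome[chrom_a] // resolution)
    nb = -(-table.genome[chrom_b] // resolution)
    bi = (sub["pos_a"].to_numpy() // resolution).astype(np.int64)
    bj = (sub["pos_b"].to_numpy() // resolution).astype(np.int64)
    if chrom_a == chrom_b:
        lo, hi = np.minimum(bi, bj), np.maximum(bi, bj)
        bi, bj = lo, hi
    counts = sparse.coo_matrix((np.ones(len(sub)), (bi, bj)), shape=(na, nb)).tocsr().tocoo()
    cellset = frozenset(sub["cell_id"].unique()) if cells is None else frozenset(cells)
    return BinnedMatrix(chrom_a, chrom_b, resolution, counts,
                        allele or "non-allelic", cellset)
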