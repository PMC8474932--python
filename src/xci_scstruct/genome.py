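"""Chromosome-size tables for the mouse genome (mm10 coordinates by default)."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: Rounded mm10 lengths for the two chromosomes the analysis centres on.
DEFAULT_SIZES = {"chr1": 195_000_000, "chrX": 171_000_000}


@dataclass(frozen=True)
class ChromSizes:
    """Mapping chromosome name -> length (bp) with autosome/chrX flags.

    chrX must be present exactly once; every other name starting with "chr"
    and not in ``non_autosomes`` is treated as an autosome.
    """

    sizes: dict[str, int]
    non_autosomes: frozenset[str] = field(
        default_factory=lambda: frozenset({"chrX", "chrY", "chrM"})
    )

    def __post_init__(self) -> None:
        if "chrX" not in self.sizes:
            raise ValueError("genome table must contain chrX exactly once")
        for name, length in self.sizes.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    def __contains__(self, name: str) -> bool:
        return name in self.sizes

    def __getitem__(self, name: str) -> int:
        return self.sizes[name]

    @property
    def names(self) -> list[str]:
        return list(self.sizes)

    @property
    def autosomes(self) -> list[str]:
        return [n for n in self.sizes if n not in self.non_autosomes]

    def is_autosome(self, name: str) -> bool:
        return name in self.sizes and name not in self.non_autosomes

    @classmethod
    def default(cls) -> "ChromSizes":
        return cls(dict(DEFAULT_SIZES))

    @classmethod
    def from_file(cls, path) -> "ChromSizes":
        """Read a two-column UCSC ``chrom.sizes`` TSV (name, length)."""
        df = pd.read_csv(path, sep="\t", header=None, names=["name", "length"],
                         dtype={"name": str, "length": int})
        return cls(dict(zip(df["name"], df["length"])))

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for name, length in self.sizes.items():
                fh.write(f"{name}\t{length}\n")
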