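"""Genome coordinate system: chromosome layout, classes, and windowing.

All coordinates are 1-based inclusive (VCF convention); a window is the
closed interval [start_bp, end_bp].  The layout is a table of
(name, length, class) rows — no sequence content is modeled.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Iterable, Sequence

CHROM_CLASSES = ("AUTOSOME", "X", "Y", "MT")


@dataclass(frozen=True, slots=True)
class Chromosome:
    name: str
    length_bp: int
    chrom_class: str

    def __post_init__(self) -> None:
        if self.length_bp < 1:
            raise ValueError(f"chromosome {self.name}: length must be >= 1")
        if self.chrom_class not in CHROM_CLASSES:
            raise ValueError(
                f"chromosome {self.name}: class must be one of {CHROM_CLASSES}, "
                f"got {self.chrom_class!r}"
            )


@dataclass(frozen=True, slots=True)
class Window:
    chrom: str
    start_bp: int
    end_bp: int
    width_bp: int  # nominal tiling width; end - start + 1 may be smaller

    @property
    def span_bp(self) -> int:
        """Actual covered width (the last window of a chromosome may be short)."""
        return self.end_bp - self.start_bp + 1

    def __contains__(self, pos: int) -> bool:
        return self.start_bp <= pos <= self.end_bp


class GenomeLayout:
    """Ordered chromosome table with at most one X, Y and MT."""

    def __init__(self, chromosomes: Iterable[Chromosome]):
        self.chromosomes: tuple[Chromosome, ...] = tuple(chromosomes)
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        for cls in ("X", "Y", "MT"):
            if sum(c.chrom_class == cls for c in self.chromosomes) > 1:
                raise ValueError(f"at most one chromosome of class {cls}")
        self._by_name = {c.name: c for c in self.chromosomes}
        self._order = {c.name: i for i, c in enumerate(self.chromosomes)}

    def __iter__(self):
        return iter(self.chromosomes)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> Chromosome:
        return self._by_name[name]

    @property
    def chrom_order(self) -> dict[str, int]:
        return self._order

    def length(self, name: str) -> int:
        return self._by_name[name].length_bp

    def chrom_class(self, name: str) -> str:
        return self._by_name[name].chrom_class

    def names(self, classes: set[str] | None = None) -> list[str]:
        if classes is None:
            return [c.name for c in self.chromosomes]
        unknown = set(classes) - set(CHROM_CLASSES)
        if unknown:
            raise ValueError(f"unknown chromosome class(es): {sorted(unknown)}")
        return [c.name for c in self.chromosomes if c.chrom_class in classes]

    # ---- serialization ------------------------------------------------

    @classmethod
    def from_tsv(cls, path) -> "GenomeLayout":
        """Read a layout from a tab-separated file: name, length, class."""
        chroms = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValueError(f"layout line needs 3 columns: {line!r}")
                chroms.append(Chromosome(fields[0], int(fields[1]), fields[2]))
        return cls(chroms)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for c in self.chromosomes:
                fh.write(f"{c.name}\t{c.length_bp}\t{c.chrom_class}\n")

    def to_fai(self, path) -> None:
        """Write the name/length columns as a FASTA-index-compatible stub."""
        with open(path, "w") as fh:
            for c in self.chromosomes:
                fh.write(f"{c.name}\t{c.length_bp}\t0\t0\t0\n")


def make_windows(
    layout: GenomeLayout,
    width_bp: int,
    classes: set[str] | None = None,
) -> list[Window]:
    """Tile each selected chromosome with non-overlapping windows.

    Windows are [start, end] inclusive, in chromosome order; the last
    window of each chromosome is truncated to the chromosome end.
    """
    if width_bp < 1:
        raise ValueError("width_bp must be >= 1")
    windows: list[Window] = []
    for name in layout.names(classes):
        length = layout.length(name)
        start = 1
        while start <= length:
            end = min(start + width_bp - 1, length)
            windows.append(Window(name, start, end, width_bp))
            start = end + 1
    return windows


def assign_window(chrom: str, pos: int, layout: GenomeLayout, windows: Sequence[Window]) -> Window:
    """Return the unique window containing (chrom, pos).

    Windows must come from :func:`make_windows` (sorted, gap-free per
    chromosome).  Positions outside the chromosome raise.
    """
    if chrom not in layout:
        raise KeyError(f"chromosome {chrom!r} not in layout")
    if not 1 <= pos <= layout.length(chrom):
        raise ValueError(f"position {pos} outside chromosome {chrom} bounds")
    starts = [(layout.chrom_order[w.chrom], w.start_bp) for w in windows]
    i = bisect.bisect_right(starts, (layout.chrom_order[chrom], pos)) - 1
    if i < 0 or windows[i].chrom != chrom or pos not in windows[i]:
        raise ValueError(f"{chrom}:{pos} not covered by the supplied windows")
    return windows[i]


def default_layout() -> GenomeLayout:
    """Miniature desk-scale layout: 5 autosomes, X, Y, MT.

    Small enough that simulation and every downstream stage run in
    seconds, while exercising every chromosome class the merge rules
    distinguish.
    """
    return GenomeLayout(
        [
            Chromosome("chr1", 6_000_000, "AUTOSOME"),
            Chromosome("chr2", 5_000_000, "AUTOSOME"),
            Chromosome("chr3", 4_000_000, "AUTOSOME"),
            Chromosome("chr4", 3_000_000, "AUTOSOME"),
            Chromosome("chr5", 2_000_000, "AUTOSOME"),
            Chromosome("chrX", 4_000_000, "X"),
            Chromosome("chrY", 1_000_000, "Y"),
            Chromosome("chrMT", 16_500, "MT"),
        ]
    )
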