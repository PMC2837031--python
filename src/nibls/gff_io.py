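"""GFF-based input/output for aligned small-RNA reads, reference loci and called locales.

All coordinates follow the GFF convention: 1-based, inclusive at both ends.
Both GFF2 and GFF3 feature lines are accepted on input, since only the eight
positional columns are interpreted; comment lines (``#``) and pragmas (``##``)
are skipped.  The feature-type and source columns are ignored when reading
read alignments — every feature line is treated as one aligned read.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "AlignedRead",
    "ReferenceLocus",
    "GenomeSpec",
    "GFFParseError",
    "read_alignment_gff",
    "read_reference_gff",
    "write_alignment_gff",
    "write_reference_gff",
    "write_locales_gff",
    "read_locales_gff",
    "read_genome_tsv",
    "write_genome_tsv",
]


class GFFParseError(ValueError):
    """Raised for a malformed GFF or genome-lengths line; the message names the line number."""


_STRANDS = {"+", "-"}


@dataclass(frozen=True, slots=True)
class AlignedRead:
    """One genome-aligned sRNA read.

    ``start``/``end`` are 1-based inclusive nucleotide coordinates.  ``strand``
    is ``+``, ``-`` or ``.`` (unknown); it is carried through but never used in
    graph construction, which is strand-blind by design.  Reads mapping to
    several genomic positions appear as several ``AlignedRead`` records.
    """

    read_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"end must be >= start, got [{self.start}, {self.end}]"
            )
        if self.strand not in _STRANDS and self.strand != ".":
            object.__setattr__(self, "strand", ".")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True, slots=True)
class ReferenceLocus:
    """A positive-control locus (RFAM-style) or an annotated genomic feature.

    ``family_type`` carries the RNA family or feature type (e.g. ``miRNA``,
    ``rRNA``, ``gene``, ``transposable_element``).
    """

    locus_id: str
    chrom: str
    start: int
    end: int
    family_type: str = "unknown"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"end must be >= start, got [{self.start}, {self.end}]"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GenomeSpec:
    """Chromosome name -> length (nt).  The denominator universe for TN counting."""

    lengths: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, n in self.lengths.items():
            if not chrom:
                raise ValueError("chromosome names must be non-empty")
            if int(n) < 1:
                raise ValueError(f"chromosome {chrom!r} has non-positive length {n}")

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def __getitem__(self, chrom: str) -> int:
        return self.lengths[chrom]

    def __iter__(self) -> Iterator[str]:
        return iter(self.lengths)

    @property
    def total_length(self) -> int:
        return sum(self.lengths.values())


_ID_RE = re.compile(r"(?:^|;)\s*ID[=\s]\s*\"?([^;\"]+)\"?", re.IGNORECASE)


def _parse_attribute_id(attributes: str) -> str | None:
    m = _ID_RE.search(attributes)
    if m:
        return m.group(1).strip()
    return None


def _feature_lines(path: str | Path) -> Iterator[tuple[int, list[str]]]:
    """Yield (1-based line number, columns) for every feature line in a GFF file."""
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) not in (8, 9):
                raise GFFParseError(
                    f"line {lineno}: expected 8 or 9 tab-separated columns, got {len(cols)}"
                )
            yield lineno, cols


def _parse_coords(cols: list[str], lineno: int) -> tuple[int, int]:
    try:
        start = int(cols[3])
        end = int(cols[4])
    except ValueError as exc:
        raise GFFParseError(
            f"line {lineno}: non-integer coordinates {cols[3]!r}/{cols[4]!r}"
        ) from exc
    if start < 1:
        raise GFFParseError(f"line {lineno}: start {start} < 1")
    if end < start:
        raise GFFParseError(f"line {lineno}: end {end} < start {start}")
    return start, end


def read_alignment_gff(path: str | Path) -> list[AlignedRead]:
    """Read a GFF file of sRNA-to-genome alignments into ``AlignedRead`` records.

    One record per feature line, preserving file order.  The feature-type
    column is not filtered: all features are treated as reads.  A file with
    no feature lines yields an empty list.
    """
    reads: list[AlignedRead] = []
    for lineno, cols in _feature_lines(path):
        start, end = _parse_coords(cols, lineno)
        strand = cols[6] if cols[6] in _STRANDS else "."
        attrs = cols[8] if len(cols) == 9 else ""
        read_id = _parse_attribute_id(attrs) or f"read_{lineno}"
        reads.append(AlignedRead(read_id, cols[0], start, end, strand))
    return reads


def read_reference_gff(path: str | Path) -> list[ReferenceLocus]:
    """Read a GFF file of reference loci or genome features.

    The feature-type column (column 3) becomes ``family_type``; an ``ID``
    attribute, when present, becomes ``locus_id``.
    """
    loci: list[ReferenceLocus] = []
    for lineno, cols in _feature_lines(path):
        start, end = _parse_coords(cols, lineno)
        attrs = cols[8] if len(cols) == 9 else ""
        locus_id = _parse_attribute_id(attrs) or f"locus_{lineno}"
        loci.append(ReferenceLocus(locus_id, cols[0], start, end, cols[2]))
    return loci


def write_alignment_gff(reads: Iterable[AlignedRead], path: str | Path) -> None:
    """Write reads as GFF3 in the given order (the inverse of ``read_alignment_gff``)."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for r in reads:
            fh.write(
                f"{r.chrom}\tnibls\tsRNA_read\t{r.start}\t{r.end}\t.\t{r.strand}\t.\t"
                f"ID={r.read_id}\n"
            )


def write_reference_gff(loci: Iterable[ReferenceLocus], path: str | Path) -> None:
    """Write reference loci / features as GFF3, type column = ``family_type``."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for loc in loci:
            fh.write(
                f"{loc.chrom}\tnibls\t{loc.family_type}\t{loc.start}\t{loc.end}\t.\t.\t.\t"
                f"ID={loc.locus_id}\n"
            )


def write_locales_gff(locales: Sequence, path: str | Path) -> None:
    """Write called locales as GFF3.

    One feature line per locale, score column carrying the component
    clustering coefficient at six decimal places, sorted deterministically by
    (chrom, start, end) regardless of input order.
    """
    ordered = sorted(locales, key=lambda loc: (loc.chrom, loc.start, loc.end))
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for i, loc in enumerate(ordered, start=1):
            fh.write(
                f"{loc.chrom}\tNiBLS\tsRNA_locale\t{loc.start}\t{loc.end}\t"
                f"{loc.gamma:.6f}\t.\t.\tID=locale_{i};n_reads={loc.n_reads}\n"
            )


def read_locales_gff(path: str | Path):
    """Read a locale GFF written by ``write_locales_gff`` back into ``Locale`` objects.

    The score column supplies gamma; an ``n_reads`` attribute, when present,
    supplies the member count (defaulting to 2, the minimum a locale can have).
    """
    from .locale_caller import Locale  # local import: avoids a module cycle

    n_reads_re = re.compile(r"(?:^|;)\s*n_reads[=\s](\d+)", re.IGNORECASE)
    locales = []
    for lineno, cols in _feature_lines(path):
        start, end = _parse_coords(cols, lineno)
        try:
            gamma = float(cols[5])
        except ValueError as exc:
            raise GFFParseError(f"line {lineno}: non-numeric score {cols[5]!r}") from exc
        attrs = cols[8] if len(cols) == 9 else ""
        m = n_reads_re.search(attrs)
        n_reads = int(m.group(1)) if m else 2
        locales.append(
            Locale(chrom=cols[0], start=start, end=end, gamma=gamma, n_reads=n_reads)
        )
    return locales


def read_genome_tsv(path: str | Path) -> GenomeSpec:
    """Read a two-column TSV (chromosome, length in nt) into a ``GenomeSpec``."""
    lengths: dict[str, int] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise GFFParseError(
                    f"line {lineno}: expected 2 tab-separated columns, got {len(cols)}"
                )
            try:
                lengths[cols[0]] = int(cols[1])
            except ValueError as exc:
                raise GFFParseError(
                    f"line {lineno}: non-integer length {cols[1]!r}"
                ) from exc
    return GenomeSpec(lengths)


def write_genome_tsv(genome: GenomeSpec, path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for chrom in sorted(genome.lengths):
            fh.write(f"{chrom}\t{genome.lengths[chrom]}\n")
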