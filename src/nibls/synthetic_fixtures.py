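"""Synthetic alignment fixtures with planted ground truth.

Generates read-coordinate data that emulates the structure of genome-aligned
sRNA datasets: planted generative locales plus an isolated background, on a
genome of stated chromosome lengths.  No nucleotide sequence is simulated —
only alignment coordinates, which is all the caller consumes.

Two planted read arrangements mirror the extremes of real pile-up patterns:

``brick_wall``
    Reads stacked on a narrow window so every pair overlaps; the component is
    a clique and its clustering coefficient is exactly 1.
``fallen_domino``
    Reads of one length L overlapping serially with step L - 3, so each read
    overlaps only its chain neighbours; the component is a path (gamma = 0)
    for any minimum inclusion distance M <= L - 6 (next-but-one reads sit
    2*(L-3) - L = L - 6 nt apart).

Background reads are placed at least ``min_locale_separation`` nt from
everything else, so they never join a planted component at any tested
M below that separation.  A single integer seed drives all randomness.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np

from .gff_io import (
    AlignedRead,
    GenomeSpec,
    ReferenceLocus,
    write_alignment_gff,
    write_genome_tsv,
    write_reference_gff,
)

__all__ = ["FixtureConfig", "SimulatedData", "simulate", "generate_fixture"]

Pattern = Literal["brick_wall", "fallen_domino", "mixed"]
_PATTERNS = ("brick_wall", "fallen_domino", "mixed")


class FixtureError(ValueError):
    """Invalid fixture configuration or a genome too small for the request."""


_PROTO_CHROM = "_unplaced"  # placeholder before an item is assigned a chromosome


@dataclass(frozen=True)
class FixtureConfig:
    """Parameters of one synthetic dataset.

    ``min_locale_separation`` must exceed the largest M any downstream run
    will use, so that planted locales and background reads stay in distinct
    graph components.  Read lengths are drawn uniformly from ``read_length``
    (default 21–25 nt, typical Dicer-product sizes).
    """

    seed: int = 0
    genome: GenomeSpec = field(
        default_factory=lambda: GenomeSpec({"chr1": 100_000})
    )
    n_locales: int = 10
    locale_pattern: Pattern = "brick_wall"
    reads_per_locale: tuple[int, int] = (5, 12)
    read_length: tuple[int, int] = (21, 25)
    background_reads: int = 200
    min_locale_separation: int = 200

    def __post_init__(self) -> None:
        if self.locale_pattern not in _PATTERNS:
            raise FixtureError(f"unknown locale pattern {self.locale_pattern!r}")
        lo, hi = self.read_length
        if not (18 <= lo <= hi <= 35):
            raise FixtureError(f"read_length range {self.read_length} outside [18, 35]")
        rlo, rhi = self.reads_per_locale
        if not (2 <= rlo <= rhi):
            raise FixtureError("reads_per_locale must satisfy 2 <= lo <= hi")
        if self.n_locales < 0 or self.background_reads < 0:
            raise FixtureError("counts must be non-negative")
        if self.min_locale_separation < 1:
            raise FixtureError("min_locale_separation must be >= 1")


@dataclass(frozen=True)
class SimulatedData:
    """In-memory fixture: reads in placement order, truth loci, genome."""

    reads: tuple[AlignedRead, ...]
    truth_loci: tuple[ReferenceLocus, ...]
    genome: GenomeSpec


def _brick_wall_reads(
    rng: np.random.Generator, base: int, n: int, len_range: tuple[int, int], tag: str
) -> list[AlignedRead]:
    # jitter < min length guarantees every pair overlaps (a clique)
    jitter_max = len_range[0] - 1
    starts = base + rng.integers(0, jitter_max + 1, size=n)
    lengths = rng.integers(len_range[0], len_range[1] + 1, size=n)
    return [
        AlignedRead(f"{tag}_r{i}", _PROTO_CHROM, int(s), int(s) + int(L) - 1)
        for i, (s, L) in enumerate(zip(starts, lengths))
    ]


def _fallen_domino_reads(
    rng: np.random.Generator, base: int, n: int, len_range: tuple[int, int], tag: str
) -> list[AlignedRead]:
    # one length per chain; step L-3 => 3 nt overlap with the next read only
    L = int(rng.integers(len_range[0], len_range[1] + 1))
    step = L - 3
    return [
        AlignedRead(f"{tag}_r{i}", _PROTO_CHROM, base + i * step, base + i * step + L - 1)
        for i in range(n)
    ]


def simulate(config: FixtureConfig) -> SimulatedData:
    """Generate reads and ground-truth loci for one fixture, deterministically.

    Planted locales and background reads are laid out left to right across
    the genome's chromosomes (sorted by name) in a shuffled order, with a gap
    of ``min_locale_separation`` plus random slack between consecutive items.
    Raises ``FixtureError`` when the genome cannot hold the requested content.
    """
    rng = np.random.default_rng(config.seed)
    sep = config.min_locale_separation

    # build items first (chromosome assigned during placement)
    items: list[tuple[str, list[AlignedRead], str | None]] = []
    for k in range(config.n_locales):
        pattern = config.locale_pattern
        if pattern == "mixed":
            pattern = ("brick_wall", "fallen_domino")[int(rng.integers(0, 2))]
        n = int(rng.integers(config.reads_per_locale[0], config.reads_per_locale[1] + 1))
        tag = f"locale_{k}"
        if pattern == "brick_wall":
            reads = _brick_wall_reads(rng, 1, n, config.read_length, tag)
        else:
            reads = _fallen_domino_reads(rng, 1, n, config.read_length, tag)
        items.append((tag, reads, pattern))
    for k in range(config.background_reads):
        L = int(rng.integers(config.read_length[0], config.read_length[1] + 1))
        items.append((f"bg_{k}", [AlignedRead(f"bg_{k}", _PROTO_CHROM, 1, L)], None))

    order = rng.permutation(len(items))

    chroms = sorted(config.genome.lengths)
    chrom_idx = 0
    cursor = 1 + int(rng.integers(0, sep))
    placed_reads: list[AlignedRead] = []
    truth: list[ReferenceLocus] = []
    for oi in order:
        tag, proto_reads, pattern = items[oi]
        lo = min(r.start for r in proto_reads)
        width = max(r.end for r in proto_reads) - lo + 1
        while (
            chrom_idx < len(chroms)
            and cursor + width - 1 > config.genome[chroms[chrom_idx]]
        ):
            chrom_idx += 1
            cursor = 1 + int(rng.integers(0, sep))
        if chrom_idx >= len(chroms):
            raise FixtureError(
                "genome too small for the requested locales, background reads "
                "and separation"
            )
        chrom = chroms[chrom_idx]
        shift = cursor - lo
        shifted = [
            AlignedRead(r.read_id, chrom, r.start + shift, r.end + shift)
            for r in proto_reads
        ]
        placed_reads.extend(shifted)
        if pattern is not None:
            truth.append(
                ReferenceLocus(
                    locus_id=tag,
                    chrom=chrom,
                    start=min(r.start for r in shifted),
                    end=max(r.end for r in shifted),
                    family_type=pattern,
                )
            )
        cursor += width + sep + int(rng.integers(0, sep))

    return SimulatedData(
        reads=tuple(placed_reads),
        truth_loci=tuple(sorted(truth, key=lambda t: (t.chrom, t.start, t.end))),
        genome=config.genome,
    )


def generate_fixture(
    config: FixtureConfig, out_dir: str | Path
) -> dict[str, Path]:
    """Write the three fixture files (reads GFF, truth-loci GFF, genome TSV).

    Byte-identical across runs for a fixed seed.  Nothing is written if the
    genome is too small for the requested content.
    """
    data = simulate(config)  # raises before any file is touched
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "reads": out / "reads.gff",
        "truth": out / "truth_loci.gff",
        "genome": out / "genome.tsv",
    }
    write_alignment_gff(data.reads, paths["reads"])
    write_reference_gff(data.truth_loci, paths["truth"])
    write_genome_tsv(data.genome, paths["genome"])
    return paths
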