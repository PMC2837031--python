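"""Nucleotide-level evaluation of called locales against positive-control loci.

The evaluation treats every nucleotide of the genome as one trial: TP =
covered by both a reference locus and a called locale, FP = locale only,
FN = reference only, TN = neither.  Coverage is a set, not a multiset —
overlapping intervals within one set count a nucleotide once — so
TP + TN + FP + FN always equals the genome length exactly.  Sensitivity and
specificity are reported on a 0–100 scale.

Also provided: the positive-control filter (drop rRNA/tRNA families and loci
with fewer than ``min_hits`` overlapping reads), the (M, C) parameter scan,
pairwise locale-set overlap proportions, exact-identical locale counts over
three sets (Venn regions), and genomic-feature overlap tallies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .gff_io import AlignedRead, GenomeSpec, ReferenceLocus
from .locale_caller import CallerConfig, Locale, call_locales

__all__ = [
    "ConfusionCounts",
    "UndefinedMetricError",
    "DEFAULT_M_VALUES",
    "DEFAULT_C_VALUES",
    "filter_reference",
    "nucleotide_confusion",
    "sensitivity",
    "specificity",
    "parameter_scan",
    "overlap_proportion",
    "identical_locale_counts",
    "feature_overlap_counts",
]

#: Published scan grids for the minimum inclusion distance M (nt) and the
#: clustering-coefficient cutoff C.
DEFAULT_M_VALUES: tuple[int, ...] = (5, 10, 20, 30, 50, 75, 100)
DEFAULT_C_VALUES: tuple[float, ...] = (0.1, 0.25, 0.4, 0.5, 0.6, 0.75, 0.9)

#: RNA families removed from the positive-control set before evaluation.
EXCLUDED_FAMILIES: frozenset[str] = frozenset({"rrna", "trna"})


class UndefinedMetricError(ZeroDivisionError):
    """A ratio with an empty denominator; raised instead of silently returning 0."""


@dataclass(frozen=True, slots=True)
class ConfusionCounts:
    """Nucleotide-level confusion counts for one (locales, reference, genome) triple."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def _interval_trees(
    items: Iterable, *, closed_end_offset: int = 1
) -> dict[str, IntervalTree]:
    """Per-chromosome interval trees over half-open [start, end+1) intervals."""
    trees: dict[str, IntervalTree] = {}
    for it in items:
        trees.setdefault(it.chrom, IntervalTree()).addi(
            it.start, it.end + closed_end_offset, it
        )
    return trees


def filter_reference(
    loci: Iterable[ReferenceLocus],
    reads: Sequence[AlignedRead],
    min_hits: int = 5,
    excluded_families: Iterable[str] = EXCLUDED_FAMILIES,
) -> list[ReferenceLocus]:
    """Reduce reference loci to those detectable from the data.

    Removes rRNA/tRNA families (case-insensitive), then keeps a locus only
    when at least ``min_hits`` reads overlap it by >= 1 nt on the same
    chromosome.  With the default ``min_hits=5`` this is the "fewer than 5
    genomic matches" exclusion applied to the positive-control set.
    """
    if min_hits < 0:
        raise ValueError("min_hits must be >= 0")
    excluded = {f.lower() for f in excluded_families}
    # key by read index: identical duplicate alignments each count as a hit
    read_trees: dict[str, IntervalTree] = {}
    for i, r in enumerate(reads):
        read_trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end + 1, i)
    kept: list[ReferenceLocus] = []
    for locus in loci:
        if locus.family_type.lower() in excluded:
            continue
        tree = read_trees.get(locus.chrom)
        n_hits = len(tree.overlap(locus.start, locus.end + 1)) if tree else 0
        if n_hits >= min_hits:
            kept.append(locus)
    return kept


def _merged_intervals(items: Iterable) -> dict[str, list[tuple[int, int]]]:
    """Per-chromosome union of closed intervals, merged and sorted."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for it in items:
        by_chrom.setdefault(it.chrom, []).append((it.start, it.end))
    merged: dict[str, list[tuple[int, int]]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        out: list[tuple[int, int]] = []
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e + 1:  # overlapping or abutting closed intervals merge
                cur_e = max(cur_e, e)
            else:
                out.append((cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((cur_s, cur_e))
        merged[chrom] = out
    return merged


def _covered_length(ivs: list[tuple[int, int]]) -> int:
    return sum(e - s + 1 for s, e in ivs)


def _intersection_length(
    a: list[tuple[int, int]], b: list[tuple[int, int]]
) -> int:
    """Length of the intersection of two merged, sorted closed-interval lists."""
    total = 0
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s <= e:
            total += e - s + 1
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return total


def _intersect_lists(
    a: list[tuple[int, int]], b: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Intersection of two merged, sorted closed-interval lists."""
    out: list[tuple[int, int]] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s <= e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def nucleotide_confusion(
    locales: Iterable[Locale],
    reference: Iterable[ReferenceLocus],
    genome: GenomeSpec,
    mask: Iterable | None = None,
) -> ConfusionCounts:
    """Classify every genome nucleotide by locale and reference coverage.

    Implemented on merged interval unions (sorted sweep), which is exactly
    equivalent to literal per-nucleotide enumeration.  Raises ``ValueError``
    when a locale or locus lies on a chromosome absent from the genome or
    extends beyond its length.

    ``mask``, when given, restricts the scoring universe to a set of
    chrom/start/end intervals (e.g. the alignable part of the genome):
    nucleotides outside the mask are ignored entirely, and the counts sum to
    the mask length instead of the genome length.  Off by default — the
    whole genome is the stated universe.
    """
    locale_ivs = _merged_intervals(locales)
    ref_ivs = _merged_intervals(reference)
    mask_ivs = _merged_intervals(mask) if mask is not None else None
    checked = [("locale", locale_ivs), ("reference locus", ref_ivs)]
    if mask_ivs is not None:
        checked.append(("mask interval", mask_ivs))
    for name, ivs in checked:
        for chrom, merged in ivs.items():
            if chrom not in genome:
                raise ValueError(f"{name} on chromosome {chrom!r} absent from genome")
            if merged[-1][1] > genome[chrom]:
                raise ValueError(
                    f"{name} extends to {merged[-1][1]} beyond chromosome "
                    f"{chrom!r} length {genome[chrom]}"
                )
    if mask_ivs is not None:
        locale_ivs = {
            c: _intersect_lists(ivs, mask_ivs.get(c, []))
            for c, ivs in locale_ivs.items()
        }
        ref_ivs = {
            c: _intersect_lists(ivs, mask_ivs.get(c, []))
            for c, ivs in ref_ivs.items()
        }
        universe_length = sum(_covered_length(ivs) for ivs in mask_ivs.values())
    else:
        universe_length = genome.total_length
    tp = fp = fn = 0
    for chrom in genome:
        a = locale_ivs.get(chrom, [])
        b = ref_ivs.get(chrom, [])
        inter = _intersection_length(a, b)
        tp += inter
        fp += _covered_length(a) - inter
        fn += _covered_length(b) - inter
    tn = universe_length - tp - fp - fn
    return ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn)


def sensitivity(counts: ConfusionCounts) -> float:
    """100 * TP / (TP + FN); raises ``UndefinedMetricError`` when TP + FN = 0."""
    denom = counts.TP + counts.FN
    if denom == 0:
        raise UndefinedMetricError(
            "sensitivity undefined: no reference-covered nucleotides (TP + FN = 0)"
        )
    return 100.0 * counts.TP / denom


def specificity(counts: ConfusionCounts) -> float:
    """100 * TN / (TN + FP); raises ``UndefinedMetricError`` when TN + FP = 0."""
    denom = counts.TN + counts.FP
    if denom == 0:
        raise UndefinedMetricError(
            "specificity undefined: no reference-free nucleotides (TN + FP = 0)"
        )
    return 100.0 * counts.TN / denom


def parameter_scan(
    reads: list[AlignedRead],
    reference: Sequence[ReferenceLocus],
    genome: GenomeSpec,
    M_values: Sequence[int] = DEFAULT_M_VALUES,
    C_values: Sequence[float] = DEFAULT_C_VALUES,
    degree1: str = "zero",
) -> pd.DataFrame:
    """Run the caller over an (M, C) grid and score each cell.

    ``reference`` is used as given; apply ``filter_reference`` beforehand if
    the >= 5-hit / family filter is wanted (it depends on the read set, not on
    M or C, so it is applied once per dataset, outside the scan).  Returns a
    tidy table with one row per (M, C) cell and columns
    M, C, n_locales, sensitivity, specificity.
    """
    if not M_values or not C_values:
        raise ValueError("M_values and C_values must be non-empty")
    rows = []
    for M in M_values:
        for C in C_values:
            config = CallerConfig(
                min_inclusion_distance=M, clustering_cutoff=C, degree1=degree1
            )
            locales = call_locales(reads, config)
            counts = nucleotide_confusion(locales, reference, genome)
            rows.append(
                {
                    "M": M,
                    "C": C,
                    "n_locales": len(locales),
                    "sensitivity": sensitivity(counts),
                    "specificity": specificity(counts),
                }
            )
    return pd.DataFrame(rows)


def overlap_proportion(set_a: Sequence[Locale], set_b: Sequence[Locale]) -> float:
    """Percentage of locales in ``set_a`` that overlap any locale of ``set_b``.

    Overlap means >= 1 shared nucleotide on the same chromosome.  The measure
    is asymmetric: which set serves as the reference changes the answer when
    the sets differ in size.  Raises ``UndefinedMetricError`` on empty
    ``set_a``.
    """
    if len(set_a) == 0:
        raise UndefinedMetricError("overlap proportion undefined for an empty reference set")
    b_trees = _interval_trees(set_b)
    n_overlapping = 0
    for loc in set_a:
        tree = b_trees.get(loc.chrom)
        if tree is not None and tree.overlaps(loc.start, loc.end + 1):
            n_overlapping += 1
    return 100.0 * n_overlapping / len(set_a)


def identical_locale_counts(
    sets: Mapping[str, Sequence[Locale]],
) -> dict[tuple[str, ...], int]:
    """Count exactly-identical locales across three named sets, per Venn region.

    Locales are keyed by (chrom, start, end) exactly.  Returns a mapping from
    the sorted tuple of set names sharing a key to the number of such keys;
    all seven regions are present (zero counts included), and the region
    counts sum to the size of the union of keys.
    """
    if len(sets) != 3:
        raise ValueError(f"expected exactly 3 named locale sets, got {len(sets)}")
    names = sorted(sets)
    keysets = {
        name: {(loc.chrom, loc.start, loc.end) for loc in sets[name]}
        for name in names
    }
    regions: dict[tuple[str, ...], int] = {}
    for r in range(1, 8):
        combo = tuple(n for i, n in enumerate(names) if r >> i & 1)
        regions[combo] = 0
    union = set().union(*keysets.values())
    for key in union:
        combo = tuple(n for n in names if key in keysets[n])
        regions[combo] += 1
    return regions


def feature_overlap_counts(
    locales: Sequence[Locale],
    annotations: Sequence[ReferenceLocus],
) -> pd.DataFrame:
    """Tally locale/feature overlaps per feature type.

    For each feature type: ``n_locales`` = locales overlapping >= 1 feature of
    that type; ``n_features`` = distinct features of that type overlapped by
    >= 1 locale.  Nested features all count — a locale inside a gene that sits
    inside a transposable element increments both types.  Returns an empty
    table when there are no annotations.
    """
    if not annotations:
        return pd.DataFrame(columns=["feature_type", "n_locales", "n_features"])
    feat_trees = _interval_trees(annotations)
    locales_per_type: dict[str, set[int]] = {}
    features_per_type: dict[str, set[str]] = {}
    for feat in annotations:
        locales_per_type.setdefault(feat.family_type, set())
        features_per_type.setdefault(feat.family_type, set())
    for i, loc in enumerate(locales):
        tree = feat_trees.get(loc.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(loc.start, loc.end + 1):
            feat = hit.data
            locales_per_type[feat.family_type].add(i)
            features_per_type[feat.family_type].add(feat.locus_id)
    rows = [
        {
            "feature_type": ftype,
            "n_locales": len(locales_per_type[ftype]),
            "n_features": len(features_per_type[ftype]),
        }
        for ftype in sorted(locales_per_type)
    ]
    return pd.DataFrame(rows)
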