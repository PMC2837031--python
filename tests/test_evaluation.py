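from __future__ import annotations

import numpy as np
import pytest

from nibls import (
    AlignedRead,
    CallerConfig,
    ConfusionCounts,
    GenomeSpec,
    Locale,
    ReferenceLocus,
    UndefinedMetricError,
    call_locales,
    feature_overlap_counts,
    filter_reference,
    identical_locale_counts,
    nucleotide_confusion,
    overlap_proportion,
    parameter_scan,
    sensitivity,
    specificity,
)
from nibls.synthetic_fixtures import FixtureConfig, simulate
from tests.oracles import enumerate_confusion


def _locale(chrom, start, end, gamma=1.0, n=2):
    return Locale(chrom, start, end, gamma, n)


def _locus(chrom, start, end, family="miRNA", lid=None):
    return ReferenceLocus(lid or f"{chrom}:{start}-{end}", chrom, start, end, family)


def _random_sets(rng, n_locales, n_loci, genome):
    locales, loci = [], []
    for chrom in genome:
        span = genome[chrom]
        for _ in range(n_locales):
            s = int(rng.integers(1, span - 100))
            locales.append(_locale(chrom, s, s + int(rng.integers(20, 100))))
        for j in range(n_loci):
            s = int(rng.integers(1, span - 100))
            loci.append(_locus(chrom, s, s + int(rng.integers(20, 100)), lid=f"{chrom}_{j}"))
    return locales, loci


class TestFilterReference:
    def test_fewer_than_min_hits_excluded(self, make_read):
        locus = _locus("chr1", 100, 200)
        reads = [make_read("chr1", 100 + 10 * i, 120 + 10 * i) for i in range(4)]
        assert filter_reference([locus], reads, min_hits=5) == []
        reads.append(make_read("chr1", 180, 200))
        assert filter_reference([locus], reads, min_hits=5) == [locus]

    @pytest.mark.parametrize("family", ["rRNA", "tRNA", "rrna"])
    def test_ribosomal_and_transfer_families_always_excluded(self, make_read, family):
        locus = _locus("chr1", 100, 200, family=family)
        reads = [make_read("chr1", 100, 120)] * 100
        assert filter_reference([locus], reads) == []

    def test_overlap_must_share_a_nucleotide_on_same_chromosome(self, make_read):
        locus = _locus("chr1", 100, 200)
        touching = [make_read("chr1", 80, 100) for _ in range(5)]  # 1 nt overlap counts
        apart = [make_read("chr1", 80, 99) for _ in range(5)]  # abutting-only
        other = [make_read("chr2", 100, 200) for _ in range(5)]
        assert filter_reference([locus], touching) == [locus]
        assert filter_reference([locus], apart) == []
        assert filter_reference([locus], other) == []

    def test_identical_duplicate_alignments_each_count(self):
        # redundant sequence sets: records with the same id and coordinates
        locus = _locus("chr1", 100, 200)
        dup = AlignedRead("same", "chr1", 150, 170)
        assert filter_reference([locus], [dup] * 5, min_hits=5) == [locus]

    def test_matches_brute_force_count_oracle(self, make_read):
        rng = np.random.default_rng(12)
        reads = [
            make_read("chr1", int(s), int(s) + 24)
            for s in rng.integers(1, 5000, size=300)
        ]
        loci = [_locus("chr1", int(s), int(s) + 80, lid=f"L{i}")
                for i, s in enumerate(rng.integers(1, 5000, size=40))]
        kept = filter_reference(loci, reads, min_hits=5)
        expected = [
            loc for loc in loci
            if sum(
                r.start <= loc.end and loc.start <= r.end for r in reads
            ) >= 5
        ]
        assert kept == expected


class TestNucleotideConfusion:
    def test_half_overlapping_worked_example(self):
        genome = GenomeSpec({"chr1": 1000})
        counts = nucleotide_confusion(
            [_locale("chr1", 151, 250)], [_locus("chr1", 101, 200)], genome
        )
        assert (counts.TP, counts.FP, counts.FN, counts.TN) == (50, 50, 50, 850)
        assert sensitivity(counts) == 50.0
        assert specificity(counts) == pytest.approx(100 * 850 / 900)

    def test_empty_sets_give_all_tn(self, small_genome):
        counts = nucleotide_confusion([], [], small_genome)
        assert (counts.TP, counts.FP, counts.FN) == (0, 0, 0)
        assert counts.TN == small_genome.total_length

    def test_identical_sets_have_no_errors(self, small_genome):
        locales = [_locale("chr1", 100, 200), _locale("chr1", 400, 450)]
        loci = [_locus("chr1", 100, 200), _locus("chr1", 400, 450)]
        counts = nucleotide_confusion(locales, loci, small_genome)
        assert counts.FP == counts.FN == 0
        assert counts.TP == 152

    def test_unknown_chromosome_rejected(self, small_genome):
        with pytest.raises(ValueError, match="chr9"):
            nucleotide_confusion([_locale("chr9", 1, 10)], [], small_genome)

    def test_interval_beyond_chromosome_rejected(self, small_genome):
        with pytest.raises(ValueError):
            nucleotide_confusion([_locale("chr1", 990, 1010)], [], small_genome)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_per_nucleotide_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        genome = GenomeSpec({"chr1": 10_000, "chr2": 5_000})
        locales, loci = _random_sets(rng, 15, 10, genome)
        counts = nucleotide_confusion(locales, loci, genome)
        assert (counts.TP, counts.TN, counts.FP, counts.FN) == enumerate_confusion(
            locales, loci, genome
        )
        assert counts.total == genome.total_length

    def test_mask_restricts_scoring_universe(self):
        genome = GenomeSpec({"chr1": 1000})
        locales = [_locale("chr1", 151, 250)]
        loci = [_locus("chr1", 101, 200)]
        mask = [_locus("chr1", 101, 300, lid="alignable")]
        counts = nucleotide_confusion(locales, loci, genome, mask=mask)
        # same TP/FP/FN as unmasked (all inside the mask); TN only within it
        assert (counts.TP, counts.FP, counts.FN) == (50, 50, 50)
        assert counts.total == 200
        half_mask = [_locus("chr1", 101, 175, lid="m")]
        half = nucleotide_confusion(locales, loci, genome, mask=half_mask)
        assert (half.TP, half.FP, half.FN, half.TN) == (25, 0, 50, 0)
        assert half.total == 75

    def test_mask_beyond_chromosome_rejected(self, small_genome):
        with pytest.raises(ValueError, match="mask"):
            nucleotide_confusion([], [], small_genome,
                                 mask=[_locus("chr1", 900, 1200, lid="m")])

    def test_scale_free_metrics(self):
        rng = np.random.default_rng(77)
        genome = GenomeSpec({"chr1": 10_000})
        locales, loci = _random_sets(rng, 10, 8, genome)
        base = nucleotide_confusion(locales, loci, genome)
        doubled_genome = GenomeSpec({"chr1": 20_000})
        doubled_locales = [
            _locale(l.chrom, 2 * l.start - 1, 2 * l.end) for l in locales
        ]
        doubled_loci = [
            _locus(l.chrom, 2 * l.start - 1, 2 * l.end, lid=l.locus_id) for l in loci
        ]
        scaled = nucleotide_confusion(doubled_locales, doubled_loci, doubled_genome)
        assert sensitivity(scaled) == pytest.approx(sensitivity(base))
        assert specificity(scaled) == pytest.approx(specificity(base))


class TestMetrics:
    def test_boundary_values(self):
        assert sensitivity(ConfusionCounts(0, 10, 0, 5)) == 0.0
        assert sensitivity(ConfusionCounts(5, 10, 3, 0)) == 100.0
        assert specificity(ConfusionCounts(5, 10, 0, 3)) == 100.0

    def test_undefined_denominators_raise(self):
        with pytest.raises(UndefinedMetricError):
            sensitivity(ConfusionCounts(0, 10, 5, 0))
        with pytest.raises(UndefinedMetricError):
            specificity(ConfusionCounts(5, 0, 0, 5))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0, 0)


@pytest.fixture(scope="module")
def fixture_data():
    return simulate(FixtureConfig(seed=21, n_locales=12, background_reads=150))


class TestParameterScan:
    def test_single_cell_equals_direct_run(self, fixture_data):
        reads = list(fixture_data.reads)
        grid = parameter_scan(
            reads, fixture_data.truth_loci, fixture_data.genome, [10], [0.4]
        )
        assert len(grid) == 1
        locales = call_locales(reads, CallerConfig(10, 0.4))
        counts = nucleotide_confusion(
            locales, fixture_data.truth_loci, fixture_data.genome
        )
        row = grid.iloc[0]
        assert row["n_locales"] == len(locales)
        assert row["sensitivity"] == pytest.approx(sensitivity(counts))
        assert row["specificity"] == pytest.approx(specificity(counts))

    def test_monotone_in_c_at_fixed_m(self, fixture_data):
        grid = parameter_scan(
            list(fixture_data.reads),
            fixture_data.truth_loci,
            fixture_data.genome,
            [5, 10, 20],
            [0.1, 0.4, 0.6, 0.9],
        )
        for _, sub in grid.groupby("M"):
            sub = sub.sort_values("C")
            assert (sub["sensitivity"].diff().dropna() <= 1e-9).all()
            assert (sub["n_locales"].diff().dropna() <= 0).all()

    def test_empty_grid_rejected(self, fixture_data):
        with pytest.raises(ValueError):
            parameter_scan(
                list(fixture_data.reads), fixture_data.truth_loci,
                fixture_data.genome, [], [0.4],
            )


class TestOverlapProportion:
    def test_subset_scores_100_and_superset_scores_half(self):
        set_a = [_locale("chr1", 100 * i, 100 * i + 50) for i in range(1, 51)]
        set_b = set_a + [_locale("chr2", 100 * i, 100 * i + 50) for i in range(1, 51)]
        assert overlap_proportion(set_a, set_b) == 100.0
        assert overlap_proportion(set_b, set_a) == 50.0

    def test_disjoint_sets_score_zero(self):
        a = [_locale("chr1", 100, 200)]
        b = [_locale("chr1", 300, 400), _locale("chr2", 100, 200)]
        assert overlap_proportion(a, b) == 0.0

    def test_empty_reference_set_undefined(self):
        with pytest.raises(UndefinedMetricError):
            overlap_proportion([], [_locale("chr1", 1, 10)])

    def test_matches_brute_force_pairwise_oracle(self):
        rng = np.random.default_rng(33)
        genome = GenomeSpec({"chr1": 20_000})
        a, _ = _random_sets(rng, 30, 0, genome)
        b, _ = _random_sets(rng, 25, 0, genome)
        expected = 100.0 * sum(
            any(
                la.chrom == lb.chrom and la.start <= lb.end and lb.start <= la.end
                for lb in b
            )
            for la in a
        ) / len(a)
        assert overlap_proportion(a, b) == pytest.approx(expected)


class TestIdenticalLocaleCounts:
    def test_identical_sets_all_in_triple_region(self):
        s = [_locale("chr1", 100, 200), _locale("chr1", 300, 400)]
        regions = identical_locale_counts({"a": s, "b": list(s), "c": list(s)})
        assert regions[("a", "b", "c")] == 2
        assert sum(regions.values()) == 2

    def test_disjoint_sets_only_unique_regions(self):
        sets = {
            "a": [_locale("chr1", 1, 10)],
            "b": [_locale("chr1", 20, 30)],
            "c": [_locale("chr1", 40, 50)],
        }
        regions = identical_locale_counts(sets)
        assert regions[("a",)] == regions[("b",)] == regions[("c",)] == 1
        assert sum(regions.values()) == 3

    def test_planted_sharing_matches_set_algebra(self):
        shared_all = _locale("chr1", 1000, 1100)
        shared_ab = _locale("chr1", 2000, 2100)
        sets = {
            "a": [shared_all, shared_ab, _locale("chr1", 10, 20)],
            "b": [shared_all, shared_ab],
            "c": [shared_all, _locale("chr2", 10, 20)],
        }
        regions = identical_locale_counts(sets)
        assert regions[("a", "b", "c")] == 1
        assert regions[("a", "b")] == 1
        assert regions[("a",)] == 1
        assert regions[("c",)] == 1
        assert regions[("b",)] == regions[("a", "c")] == regions[("b", "c")] == 0
        union_size = len(
            {(l.chrom, l.start, l.end) for s in sets.values() for l in s}
        )
        assert sum(regions.values()) == union_size

    def test_requires_exactly_three_sets(self):
        with pytest.raises(ValueError):
            identical_locale_counts({"a": [], "b": []})


class TestFeatureOverlapCounts:
    def test_nested_features_all_increment(self):
        te = _locus("chr1", 100, 1000, family="transposable_element", lid="te1")
        gene = _locus("chr1", 300, 600, family="gene", lid="g1")
        table = feature_overlap_counts([_locale("chr1", 400, 450)], [te, gene])
        by_type = table.set_index("feature_type")
        assert by_type.loc["gene", "n_locales"] == 1
        assert by_type.loc["transposable_element", "n_locales"] == 1
        assert by_type.loc["gene", "n_features"] == 1

    def test_no_annotations_gives_empty_table(self):
        assert feature_overlap_counts([_locale("chr1", 1, 10)], []).empty

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(55)
        genome = GenomeSpec({"chr1": 30_000})
        locales, _ = _random_sets(rng, 40, 0, genome)
        feats = []
        for i, fam in enumerate(["gene", "mRNA", "transposon"] * 10):
            s = int(rng.integers(1, 29_000))
            feats.append(_locus("chr1", s, s + int(rng.integers(50, 500)),
                                family=fam, lid=f"f{i}"))
        table = feature_overlap_counts(locales, feats).set_index("feature_type")
        for fam in {"gene", "mRNA", "transposon"}:
            fam_feats = [f for f in feats if f.family_type == fam]
            exp_locales = sum(
                any(l.start <= f.end and f.start <= l.end for f in fam_feats)
                for l in locales
            )
            exp_feats = sum(
                any(l.start <= f.end and f.start <= l.end for l in locales)
                for f in fam_feats
            )
            assert table.loc[fam, "n_locales"] == exp_locales
            assert table.loc[fam, "n_features"] == exp_feats
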