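import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from enhancerscan.categories import (
    DEFAULT_CATEGORY_MAP,
    BindingProfile,
    CategoryMap,
    EnhancerRow,
    EnhancerTable,
    Peak,
    PeakSet,
    SOURCES,
    anchor_maxima,
    category_fractions,
    combinatorial_profiles,
    flags_bitmask,
    intersect_maxima,
    read_narrowpeak,
    remove_blacklisted,
    t_binding_summary,
    write_narrowpeak,
)
from enhancerscan.diffaccess import DifferentialRegion
from enhancerscan.fragments import CoverageTrack
from enhancerscan.intervals import GenomicInterval, RegionSet, overlaps


def _peak(chrom, start, end, summit=None, score=1.0):
    return Peak(GenomicInterval(chrom, start, end), summit, score)


def _diff(chrom, start, end, direction="A_up"):
    sign = 1 if direction == "A_up" else -1
    return DifferentialRegion(
        GenomicInterval(chrom, start, end), direction, sign * 2.0, 30.0, 1e-6, 1e-5
    )


class TestCategoryMap:
    def test_default_is_bijective_and_anchored(self):
        cm = DEFAULT_CATEGORY_MAP
        assert cm.category((True, True, True)) == 3
        assert cm.category((False, True, True)) == 5
        assert cm.category((False, False, True)) == 7
        assert cm.category((True, False, False)) == 2
        assert sorted(cm.table.values()) == list(range(1, 8))

    def test_non_bijective_map_rejected(self):
        table = dict(DEFAULT_CATEGORY_MAP.table)
        table[(True, True, True)] = 5
        with pytest.raises(ValueError):
            CategoryMap(table)


class TestRemoveBlacklisted:
    def test_peak_inside_blacklist_removed(self):
        ps = PeakSet([_peak("chr1", 100, 200)], "Foxa2")
        bl = RegionSet([GenomicInterval("chr1", 0, 500)])
        assert len(remove_blacklisted(ps, bl)) == 0

    def test_empty_blacklist_is_identity(self):
        ps = PeakSet([_peak("chr1", 100, 200)], "Foxa2")
        assert remove_blacklisted(ps, RegionSet([])).peaks == ps.peaks

    def test_matches_quadratic_filter(self, rng):
        peaks = [
            _peak("chr1", int(s), int(s) + int(rng.integers(50, 300)))
            for s in rng.integers(0, 20_000, size=30)
        ]
        bl = RegionSet(
            [
                GenomicInterval("chr1", int(s), int(s) + 500)
                for s in rng.integers(0, 20_000, size=5)
            ]
        )
        out = remove_blacklisted(PeakSet(peaks, "T_NMP"), bl)
        brute = [
            p for p in peaks if not any(overlaps(p.interval, b) for b in bl)
        ]
        assert out.peaks == brute
        assert len(out) <= len(peaks)


class TestCombinatorialProfiles:
    def test_isolated_single_source_peak(self):
        profiles = combinatorial_profiles(
            PeakSet([], "T_NMP"),
            PeakSet([], "T_NotoP"),
            PeakSet([_peak("chr1", 100, 300, 200)], "Foxa2"),
        )
        (p,) = profiles
        assert p.flags == (False, False, True)
        assert p.category == 7

    def test_all_three_overlapping_is_category_three(self):
        profiles = combinatorial_profiles(
            PeakSet([_peak("chr1", 100, 300)], "T_NMP"),
            PeakSet([_peak("chr1", 250, 450)], "T_NotoP"),
            PeakSet([_peak("chr1", 200, 400)], "Foxa2"),
        )
        (p,) = profiles
        assert p.flags == (True, True, True)
        assert p.category == 3
        assert (p.region.start, p.region.end) == (100, 450)

    def test_transitive_chain_clusters_together(self):
        # A overlaps B, B overlaps C, A does not overlap C
        profiles = combinatorial_profiles(
            PeakSet([_peak("chr1", 0, 100)], "T_NMP"),
            PeakSet([_peak("chr1", 90, 200)], "T_NotoP"),
            PeakSet([_peak("chr1", 190, 300)], "Foxa2"),
        )
        assert len(profiles) == 1
        assert profiles[0].flags == (True, True, True)

    def test_matches_union_find_oracle(self, rng):
        sets = {}
        all_peaks = []
        for source in SOURCES:
            peaks = [
                _peak("chr1", int(s), int(s) + int(rng.integers(50, 400)))
                for s in rng.integers(0, 30_000, size=25)
            ]
            sets[source] = PeakSet(peaks, source)
            all_peaks += [(source, p) for p in peaks]
        profiles = combinatorial_profiles(sets["T_NMP"], sets["T_NotoP"], sets["Foxa2"])

        # union-find over pairwise overlaps
        parent = list(range(len(all_peaks)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(all_peaks)):
            for j in range(i + 1, len(all_peaks)):
                if overlaps(all_peaks[i][1].interval, all_peaks[j][1].interval):
                    parent[find(i)] = find(j)
        clusters = {}
        for i, (source, peak) in enumerate(all_peaks):
            clusters.setdefault(find(i), set()).add(source)
        expected_flag_multiset = sorted(
            tuple(s in members for s in SOURCES) for members in clusters.values()
        )
        assert sorted(p.flags for p in profiles) == expected_flag_multiset

    def test_flags_independent_of_input_order(self, rng):
        peaks = {
            source: [
                _peak("chr1", int(s), int(s) + 200)
                for s in rng.integers(0, 10_000, size=10)
            ]
            for source in SOURCES
        }
        forward = combinatorial_profiles(
            PeakSet(peaks["T_NMP"], "T_NMP"),
            PeakSet(peaks["T_NotoP"], "T_NotoP"),
            PeakSet(peaks["Foxa2"], "Foxa2"),
        )
        reversed_ = combinatorial_profiles(
            PeakSet(peaks["T_NMP"][::-1], "T_NMP"),
            PeakSet(peaks["T_NotoP"][::-1], "T_NotoP"),
            PeakSet(peaks["Foxa2"][::-1], "Foxa2"),
        )
        key = lambda p: (p.region.start, p.region.end)
        assert [(p.flags, key(p)) for p in forward] == [
            (p.flags, key(p)) for p in reversed_
        ]


class TestAnchorMaxima:
    def _profile(self, peaks_by_source):
        start = min(p.interval.start for ps in peaks_by_source.values() for p in ps)
        end = max(p.interval.end for ps in peaks_by_source.values() for p in ps)
        flags = tuple(s in peaks_by_source for s in SOURCES)
        return BindingProfile(
            GenomicInterval("chr1", start, end),
            flags,
            DEFAULT_CATEGORY_MAP.category(flags),
            peaks_by_source,
        )

    def test_source_precedence_order(self):
        prof = self._profile(
            {
                "T_NMP": [_peak("chr1", 100, 300, summit=170)],
                "Foxa2": [_peak("chr1", 150, 350, summit=290)],
            }
        )
        assert anchor_maxima(prof) == 170  # T_NMP outranks Foxa2

    def test_single_source_uses_its_summit(self):
        prof = self._profile({"Foxa2": [_peak("chr1", 100, 300, summit=222)]})
        assert anchor_maxima(prof) == 222

    def test_multiple_same_source_peaks_highest_score_then_leftmost(self):
        prof = self._profile(
            {
                "T_NMP": [
                    _peak("chr1", 100, 300, summit=150, score=5),
                    _peak("chr1", 400, 600, summit=450, score=9),
                    _peak("chr1", 700, 900, summit=750, score=9),
                ]
            }
        )
        assert anchor_maxima(prof) == 450

    def test_missing_summit_falls_back_to_coverage(self):
        prof = self._profile({"T_NMP": [_peak("chr1", 0, 10)]})
        track = CoverageTrack({"chr1": np.array([0, 0, 5, 1, 0, 0, 0, 0, 0, 0.0])}, 1)
        assert anchor_maxima(prof, coverage=track) == 2

    def test_missing_summit_without_coverage_errors(self):
        prof = self._profile({"T_NMP": [_peak("chr1", 0, 10)]})
        with pytest.raises(ValueError, match="no summit"):
            anchor_maxima(prof)


class TestIntersectMaxima:
    def _anchored(self, chrom, pos, flags=(False, False, True)):
        prof = BindingProfile(
            GenomicInterval(chrom, pos - 50, pos + 50),
            flags,
            DEFAULT_CATEGORY_MAP.category(flags),
            {},
            anchor=pos,
        )
        return prof

    def test_anchor_containment_emits_row(self):
        table = intersect_maxima(
            [self._anchored("chr1", 1500)], [_diff("chr1", 1000, 2000)]
        )
        assert len(table) == 1
        assert table.rows[0].anchor == 1500

    def test_half_open_boundary_excluded(self):
        table = intersect_maxima(
            [self._anchored("chr1", 2000)], [_diff("chr1", 1000, 2000)]
        )
        assert len(table) == 0

    def test_flags_are_union_over_contained_anchors(self):
        profs = [
            self._anchored("chr1", 1200, (True, False, False)),
            self._anchored("chr1", 1800, (False, False, True)),
        ]
        table = intersect_maxima(profs, [_diff("chr1", 1000, 2000)])
        (row,) = table.rows
        assert row.flags == (True, False, True)
        assert row.category == DEFAULT_CATEGORY_MAP.category((True, False, True))
        assert row.anchor == 1200  # T_NMP-flagged profile outranks Foxa2

    def test_only_a_up_regions_considered(self):
        table = intersect_maxima(
            [self._anchored("chr1", 1500)],
            [_diff("chr1", 1000, 2000, direction="B_up")],
        )
        assert len(table) == 0

    def test_membership_matches_brute_force_scan(self, rng):
        regions = [
            _diff("chr1", int(s), int(s) + 800)
            for s in np.arange(0, 10) * 2000 + rng.integers(0, 500, 10)
        ]
        profs = [
            self._anchored("chr1", int(p)) for p in rng.integers(0, 22_000, size=12)
        ]
        table = intersect_maxima(profs, regions)
        expected = sorted(
            r.region
            for r in regions
            if any(r.region.contains(p.anchor) for p in profs)
        )
        assert sorted(row.region for row in table.rows) == expected


class TestCategoryArithmetic:
    def test_single_group_covering_everything_is_100(self):
        table = EnhancerTable.from_category_counts({1: 3, 5: 2})
        out = category_fractions(table, {"all": range(1, 8)})
        assert out["all"] == 100.0

    def test_empty_table_errors(self):
        with pytest.raises(ValueError):
            category_fractions(EnhancerTable([]), {"g": {1}})

    def test_invalid_group_errors(self):
        table = EnhancerTable.from_category_counts({1: 1})
        with pytest.raises(ValueError):
            category_fractions(table, {"g": {0, 9}})

    def test_partition_sums_to_table_size(self, rng):
        counts = {c: int(rng.integers(0, 40)) for c in range(1, 8)}
        counts[3] += 1  # non-empty
        table = EnhancerTable.from_category_counts(counts)
        groups = {"a": {1, 2}, "b": {3, 4, 5}, "c": {6, 7}}
        n = sum(
            sum(counts[c] for c in cats) for cats in groups.values()
        )
        assert n == len(table)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=1, max_value=7), min_size=1, max_size=200))
    def test_t_binding_ledger_identity_holds_on_any_table(self, cats):
        counts = {c: cats.count(c) for c in set(cats)}
        table = EnhancerTable.from_category_counts(counts)
        s = t_binding_summary(table)
        assert s["t_nmp"] + s["t_notop_only"] == s["total"] - s["foxa2_only"]


class TestNarrowPeakIO:
    def test_round_trip_with_summits(self, tmp_path):
        ps = PeakSet(
            [_peak("chr1", 100, 400, summit=230, score=8.5), _peak("chr2", 0, 50)],
            "T_NotoP",
        )
        path = tmp_path / "p.narrowPeak"
        write_narrowpeak(ps, path)
        back = read_narrowpeak(path, "T_NotoP")
        assert [(p.interval, p.summit) for p in back.peaks] == [
            (p.interval, p.summit) for p in ps.peaks
        ]
        assert back.peaks[0].score == pytest.approx(8.5)

    def test_flags_bitmask_order(self):
        assert flags_bitmask((True, False, False)) == 1
        assert flags_bitmask((False, True, True)) == 6
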