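"""Combinatorial transcription-factor binding categories and candidate
enhancer calling.

Three peak sets — T in neuro-mesodermal progenitors (T_NMP), T in
notochord-like cells (T_NotoP), and Foxa2 in notochord-like cells (Foxa2) —
are clustered by transitive overlap into binding profiles.  The seven
non-empty combinations of source membership define categories 1-7.  Each
profile is reduced to a single-bp anchor (the summit of its
highest-precedence peak, precedence T_NMP > T_NotoP > Foxa2) and anchors are
intersected with promoter-distal regions gaining accessibility in the
notochord condition: a differential region containing at least one anchor is
a candidate enhancer.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
from intervaltree import IntervalTree

from .diffaccess import DifferentialRegion
from .fragments import CoverageTrack, summit
from .intervals import GenomicInterval, ParseError, RegionSet

logger = logging.getLogger(__name__)

#: Source precedence order used for anchor selection.
SOURCES = ("T_NMP", "T_NotoP", "Foxa2")

Flags = Tuple[bool, bool, bool]  # (has_T_NMP, has_T_NotoP, has_Foxa2)


@dataclass(frozen=True)
class Peak:
    interval: GenomicInterval
    summit: Optional[int] = None
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.summit is not None and not self.interval.contains(self.summit):
            raise ValueError(f"summit {self.summit} outside peak {self.interval}")


@dataclass
class PeakSet:
    peaks: List[Peak]
    source: str

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise ValueError(f"unknown peak source {self.source!r}")

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass(frozen=True)
class CategoryMap:
    """Bijection between the 7 non-empty flag triples and category ids 1-7.

    The default numbering is anchored where the category analysis pins it
    (Cat 3 = all three sources, Cat 5 = T_NotoP + Foxa2, Cat 7 = Foxa2 only,
    Cat 2 = T_NMP only); the remaining assignments are a documented,
    overridable convention.
    """

    table: Mapping[Flags, int]

    def __post_init__(self) -> None:
        triples = set(self.table)
        expected = {
            (a, b, c)
            for a in (False, True)
            for b in (False, True)
            for c in (False, True)
        } - {(False, False, False)}
        if triples != expected or sorted(self.table.values()) != list(range(1, 8)):
            raise ValueError("category map must biject the 7 non-empty triples to 1-7")

    def category(self, flags: Flags) -> int:
        return self.table[flags]

    def flags(self, category: int) -> Flags:
        for fl, cat in self.table.items():
            if cat == category:
                return fl
        raise KeyError(category)


DEFAULT_CATEGORY_MAP = CategoryMap(
    {
        (True, False, True): 1,
        (True, False, False): 2,
        (True, True, True): 3,
        (True, True, False): 4,
        (False, True, True): 5,
        (False, True, False): 6,
        (False, False, True): 7,
    }
)


@dataclass
class BindingProfile:
    """A transitive-overlap cluster of peaks labeled with its sources."""

    region: GenomicInterval
    flags: Flags
    category: int
    peaks: Dict[str, List[Peak]]
    anchor: Optional[int] = None

    def __post_init__(self) -> None:
        if not any(self.flags):
            raise ValueError("profile must have at least one source flag")
        if self.anchor is not None and not self.region.contains(self.anchor):
            raise ValueError("anchor outside profile region")


@dataclass(frozen=True)
class EnhancerRow:
    region: GenomicInterval
    category: int
    anchor: int
    flags: Flags

    def __post_init__(self) -> None:
        if not self.region.contains(self.anchor):
            raise ValueError("anchor must lie inside the enhancer region")


@dataclass
class EnhancerTable:
    """Candidate enhancers: differential regions containing >=1 TF anchor."""

    rows: List[EnhancerRow]

    def __len__(self) -> int:
        return len(self.rows)

    def category_counts(self) -> Dict[int, int]:
        counts: Dict[int, int] = {}
        for row in self.rows:
            counts[row.category] = counts.get(row.category, 0) + 1
        return dict(sorted(counts.items()))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [r.region.chrom for r in self.rows],
                "start": [r.region.start for r in self.rows],
                "end": [r.region.end for r in self.rows],
                "category": [r.category for r in self.rows],
                "anchor": [r.anchor for r in self.rows],
                "has_T_NMP": [r.flags[0] for r in self.rows],
                "has_T_NotoP": [r.flags[1] for r in self.rows],
                "has_Foxa2": [r.flags[2] for r in self.rows],
            }
        )

    @classmethod
    def from_category_counts(
        cls,
        counts: Mapping[int, int],
        category_map: CategoryMap = DEFAULT_CATEGORY_MAP,
        region_length: int = 1000,
    ) -> "EnhancerTable":
        """Build a table with given per-category tallies on a dummy axis.

        Used to run the category arithmetic (fractions, binding ledgers) on
        published count tables where only the tallies, not the coordinates,
        are available.
        """
        rows: List[EnhancerRow] = []
        pos = 0
        for cat in sorted(counts):
            fl = category_map.flags(cat)
            for _ in range(counts[cat]):
                region = GenomicInterval("tally", pos, pos + region_length)
                rows.append(EnhancerRow(region, cat, pos + region_length // 2, fl))
                pos += region_length
        return cls(rows)


def remove_blacklisted(peaks: PeakSet, blacklist: RegionSet) -> PeakSet:
    """Drop peaks overlapping any blacklist interval (mapping artifacts)."""
    trees: Dict[str, IntervalTree] = {}
    for iv in blacklist:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    kept = [
        p
        for p in peaks.peaks
        if not trees.get(p.interval.chrom)
        or not trees[p.interval.chrom].overlap(p.interval.start, p.interval.end)
    ]
    return PeakSet(kept, source=peaks.source)


def combinatorial_profiles(
    t_nmp: PeakSet,
    t_notop: PeakSet,
    foxa2: PeakSet,
    category_map: CategoryMap = DEFAULT_CATEGORY_MAP,
) -> List[BindingProfile]:
    """Cluster the three peak sets by transitive overlap into profiles.

    Each cluster yields one profile whose flags record which sources
    contribute; the category comes from ``category_map``.  The result is
    independent of the order peaks are supplied in (a sorted sweep is used).
    """
    tagged: List[Tuple[GenomicInterval, str, Peak]] = []
    for ps in (t_nmp, t_notop, foxa2):
        for p in ps.peaks:
            tagged.append((p.interval, ps.source, p))
    tagged.sort(key=lambda t: (t[0].chrom, t[0].start, t[0].end, t[1]))

    profiles: List[BindingProfile] = []
    cluster: List[Tuple[GenomicInterval, str, Peak]] = []
    cluster_end = None

    def _flush() -> None:
        if not cluster:
            return
        chrom = cluster[0][0].chrom
        start = min(iv.start for iv, _, _ in cluster)
        end = max(iv.end for iv, _, _ in cluster)
        by_source: Dict[str, List[Peak]] = {}
        for _, source, peak in cluster:
            by_source.setdefault(source, []).append(peak)
        flags = tuple(s in by_source for s in SOURCES)
        profiles.append(
            BindingProfile(
                region=GenomicInterval(chrom, start, end),
                flags=flags,  # type: ignore[arg-type]
                category=category_map.category(flags),  # type: ignore[arg-type]
                peaks=by_source,
            )
        )

    for iv, source, peak in tagged:
        if cluster and (iv.chrom != cluster[0][0].chrom or iv.start >= cluster_end):
            _flush()
            cluster, cluster_end = [], None
        cluster.append((iv, source, peak))
        cluster_end = iv.end if cluster_end is None else max(cluster_end, iv.end)
    _flush()
    return profiles


def anchor_maxima(
    profile: BindingProfile, coverage: Optional[CoverageTrack] = None
) -> int:
    """Single-bp anchor of a profile: the summit of its precedence peak.

    The contributing peak comes from the highest-precedence source present
    (T_NMP > T_NotoP > Foxa2); among multiple same-source peaks the highest
    score wins, ties leftmost.  A peak without a stored summit falls back to
    the coverage maximum; with neither available an error is raised.  The
    anchor is stored on the profile and returned.
    """
    for source in SOURCES:
        candidates = profile.peaks.get(source)
        if candidates:
            best = min(candidates, key=lambda p: (-p.score, p.interval.start))
            if best.summit is not None:
                anchor = best.summit
            elif coverage is not None:
                anchor = summit(best.interval, coverage)
            else:
                raise ValueError(
                    f"peak {best.interval} has no summit and no coverage provided"
                )
            profile.anchor = int(anchor)
            return profile.anchor
    raise ValueError("profile has no contributing peaks")


def intersect_maxima(
    profiles: Sequence[BindingProfile],
    diff_regions: Sequence[DifferentialRegion],
    category_map: CategoryMap = DEFAULT_CATEGORY_MAP,
    direction: str = "A_up",
) -> EnhancerTable:
    """Intersect profile anchors with regions more accessible in condition A.

    One row per differential region containing >= 1 anchor (half-open
    containment); a region's flags are the union over contained anchors,
    re-mapped to a category.  The row anchor is taken from the contained
    profile with the highest-precedence source flags, ties leftmost.
    """
    anchors: Dict[str, List[BindingProfile]] = {}
    for prof in profiles:
        if prof.anchor is None:
            raise ValueError("profiles must be anchored (run anchor_maxima first)")
        anchors.setdefault(prof.region.chrom, []).append(prof)
    for lst in anchors.values():
        lst.sort(key=lambda p: p.anchor)

    rows: List[EnhancerRow] = []
    regions = [r for r in diff_regions if r.direction == direction]
    for dr in sorted(regions, key=lambda r: (r.region.chrom, r.region.start)):
        contained = [
            p
            for p in anchors.get(dr.region.chrom, [])
            if dr.region.contains(p.anchor)
        ]
        if not contained:
            continue
        flags = tuple(
            any(p.flags[i] for p in contained) for i in range(3)
        )  # type: Flags
        best = min(
            contained,
            key=lambda p: (_precedence_rank(p.flags), p.anchor),
        )
        rows.append(
            EnhancerRow(
                region=dr.region,
                category=category_map.category(flags),  # type: ignore[arg-type]
                anchor=best.anchor,
                flags=flags,  # type: ignore[arg-type]
            )
        )
    return EnhancerTable(rows)


def _precedence_rank(flags: Flags) -> int:
    for i, present in enumerate(flags):
        if present:
            return i
    return len(flags)


def category_fractions(
    table: EnhancerTable, groups: Mapping[str, Iterable[int]]
) -> Dict[str, float]:
    """Percentage of rows per named category group, to one decimal.

    ``percentage = 100 * |rows in group| / |rows|`` with standard
    round-half-away-from-zero at one decimal.
    """
    if len(table) == 0:
        raise ValueError("empty enhancer table")
    counts = table.category_counts()
    out: Dict[str, float] = {}
    for name, cats in groups.items():
        cats = set(cats)
        if not cats <= set(range(1, 8)):
            raise ValueError(f"group {name!r} references invalid categories")
        n = sum(counts.get(c, 0) for c in cats)
        pct = 100.0 * n / len(table)
        # round half away from zero at one decimal (matches printed tallies)
        out[name] = math.floor(pct * 10 + 0.5) / 10
    return out


def t_binding_summary(table: EnhancerTable) -> Dict[str, int]:
    """Tallies of the T/Foxa2 binding ledger.

    Returns total rows, rows T-bound in NMPs, T-bound rows occupied only in
    notochord cells (T_NotoP without T_NMP), and Foxa2-only rows.  These
    satisfy the identity ``t_nmp + t_notop_only == total - foxa2_only`` on
    any table because the seven flag triples partition into exactly those
    three groups.
    """
    total = len(table)
    t_nmp = sum(1 for r in table.rows if r.flags[0])
    t_notop_only = sum(1 for r in table.rows if r.flags[1] and not r.flags[0])
    foxa2_only = sum(1 for r in table.rows if r.flags == (False, False, True))
    return {
        "total": total,
        "t_nmp": t_nmp,
        "t_notop_only": t_notop_only,
        "foxa2_only": foxa2_only,
    }


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_narrowpeak(path, source: str) -> PeakSet:
    """narrowPeak reader; column 10 (when >= 0) gives the summit offset,
    column 7 (signalValue) the score."""
    peaks: List[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ParseError(f"{path}:{lineno}: fewer than 3 columns")
            try:
                iv = GenomicInterval(f[0], int(f[1]), int(f[2]))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            score = float(f[6]) if len(f) >= 7 else 0.0
            summit_pos = None
            if len(f) >= 10 and int(f[9]) >= 0:
                summit_pos = iv.start + int(f[9])
            peaks.append(Peak(iv, summit=summit_pos, score=score))
    return PeakSet(peaks, source=source)


def read_peaks_bed(path, source: str) -> PeakSet:
    """BED6 peak reader (no summits; column 5 as score)."""
    peaks: List[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ParseError(f"{path}:{lineno}: fewer than 3 columns")
            score = float(f[4]) if len(f) >= 5 else 0.0
            peaks.append(Peak(GenomicInterval(f[0], int(f[1]), int(f[2])), score=score))
    return PeakSet(peaks, source=source)


def write_narrowpeak(peakset: PeakSet, path) -> None:
    rows = sorted(
        peakset.peaks, key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end)
    )
    with open(path, "w") as fh:
        for i, p in enumerate(rows):
            offset = -1 if p.summit is None else p.summit - p.interval.start
            fh.write(
                "\t".join(
                    [
                        p.interval.chrom,
                        str(p.interval.start),
                        str(p.interval.end),
                        f"{peakset.source}_peak_{i + 1}",
                        "0",
                        ".",
                        format(p.score, ".6g"),
                        "-1",
                        "-1",
                        str(offset),
                    ]
                )
                + "\n"
            )


def flags_bitmask(flags: Flags) -> int:
    """bit0 = T_NMP, bit1 = T_NotoP, bit2 = Foxa2."""
    return sum(1 << i for i, present in enumerate(flags) if present)


def write_enhancer_bed(table: EnhancerTable, path) -> None:
    """BED6+ export: name=cat<k>, extra columns category, flag bitmask, anchor."""
    rows = sorted(
        table.rows, key=lambda r: (r.region.chrom, r.region.start, r.region.end)
    )
    with open(path, "w") as fh:
        for r in rows:
            fh.write(
                "\t".join(
                    [
                        r.region.chrom,
                        str(r.region.start),
                        str(r.region.end),
                        f"cat{r.category}",
                        "0",
                        ".",
                        str(r.category),
                        str(flags_bitmask(r.flags)),
                        str(r.anchor),
                    ]
                )
                + "\n"
            )


def read_enhancer_bed(path, category_map: CategoryMap = DEFAULT_CATEGORY_MAP) -> EnhancerTable:
    rows: List[EnhancerRow] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            f = line.split("\t")
            if len(f) < 9:
                raise ParseError(f"{path}:{lineno}: need 9 columns")
            mask = int(f[7])
            flags = tuple(bool(mask >> i & 1) for i in range(3))
            rows.append(
                EnhancerRow(
                    region=GenomicInterval(f[0], int(f[1]), int(f[2])),
                    category=int(f[6]),
                    anchor=int(f[8]),
                    flags=flags,  # type: ignore[arg-type]
                )
            )
    return EnhancerTable(rows)
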