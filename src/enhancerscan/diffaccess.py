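"""Sliding-window G-test detection of differential chromatin accessibility.

Two fragment libraries (condition A = treatment, condition B = control) are
compared window by window.  Each window's fragment counts form a 2x2 table
against the library totals; the G statistic

    G = 2 * sum O * ln(O / E)

over the four cells (expected values from the table margins, 0*ln 0 = 0) is
chi-square distributed with one degree of freedom under the null of equal
accessibility.  P-values are Benjamini-Hochberg adjusted across all tested
windows; significant windows passing a library-size-normalized fold-change
filter are merged (same direction, gap below one step) into differential
regions.

Counts are modeled as binomial draws from the pooled libraries, the
appropriate sampling model for a single pooled library per condition; no
replicate dispersion is modeled and no continuity correction is applied.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, NamedTuple, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .fragments import FragmentSet
from .intervals import (
    GenomeAnnotation,
    GenomicInterval,
    RegionSet,
    promoter_regions,
    subtract_overlapping,
)

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 1000
DEFAULT_STEP = 100
DEFAULT_ALPHA = 0.05
DEFAULT_MIN_FOLD = 2.0
#: Pseudocount added to window counts only for fold-change estimation,
#: never for the G statistic.
FOLD_PSEUDOCOUNT = 0.5


class WindowCount(NamedTuple):
    window: GenomicInterval
    count_a: int
    count_b: int


@dataclass(frozen=True)
class DifferentialRegion:
    """A merged run of significant windows with direction and statistics."""

    region: GenomicInterval
    direction: str  # "A_up" | "B_up"
    log2_fold: float  # library-size normalized, positive for A_up
    g_stat: float
    p_value: float
    q_value: float

    def __post_init__(self) -> None:
        if self.direction not in ("A_up", "B_up"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if (self.direction == "A_up") != (self.log2_fold > 0):
            raise ValueError("direction inconsistent with sign of log2_fold")
        if self.q_value < self.p_value:
            raise ValueError("q_value must be >= p_value")


def window_counts(
    fragset_a: FragmentSet,
    fragset_b: FragmentSet,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    chrom_sizes: Optional[Mapping[str, int]] = None,
) -> List[WindowCount]:
    """Tile windows per chromosome; a fragment counts in every window it overlaps."""
    if not (window >= step >= 1):
        raise ValueError("need window >= step >= 1")
    sizes = dict(chrom_sizes or {})
    chroms = sorted(set(fragset_a.chroms()) | set(fragset_b.chroms()) | set(sizes))
    out: List[WindowCount] = []
    for chrom in chroms:
        arr_a = fragset_a.fragments(chrom)
        arr_b = fragset_b.fragments(chrom)
        size = sizes.get(chrom)
        if size is None:
            ends = [int(a[:, 1].max()) for a in (arr_a, arr_b) if a.size]
            if not ends:
                continue
            size = max(ends)
        starts = np.arange(0, max(size - window, 0) + 1, step, dtype=np.int64)
        if len(starts) == 0:
            starts = np.array([0], dtype=np.int64)
        ends = np.minimum(starts + window, size)
        counts = []
        for arr in (arr_a, arr_b):
            if arr.size:
                s_sorted = np.sort(arr[:, 0])
                e_sorted = np.sort(arr[:, 1])
                # overlap count = #(start < win_end) - #(end <= win_start)
                c = np.searchsorted(s_sorted, ends, side="left") - np.searchsorted(
                    e_sorted, starts, side="right"
                )
            else:
                c = np.zeros(len(starts), dtype=np.int64)
            counts.append(c)
        for ws, we, ca, cb in zip(starts, ends, counts[0], counts[1]):
            out.append(
                WindowCount(GenomicInterval(chrom, int(ws), int(we)), int(ca), int(cb))
            )
    return out


def _g_stat_array(
    count_a: np.ndarray, count_b: np.ndarray, total_a: int, total_b: int
) -> np.ndarray:
    """Vectorized log-likelihood-ratio statistic for 2x2 tables."""
    obs = np.stack(
        [count_a, total_a - count_a, count_b, total_b - count_b], axis=0
    ).astype(float)
    n = float(total_a + total_b)
    row = np.stack([count_a + count_b, n - count_a - count_b]).astype(float)
    col = np.array([total_a, total_b], dtype=float)
    # expected[i, j] = row[i] * col[j] / n, laid out to match obs rows
    exp = np.stack([row[0] * col[0], row[1] * col[0], row[0] * col[1], row[1] * col[1]])
    exp /= n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / exp), 0.0)
    return 2.0 * terms.sum(axis=0)


def g_test(
    count_a: int, count_b: int, total_a: int, total_b: int
) -> Tuple[float, float]:
    """G statistic and upper-tail chi-square (1 df) p-value for one window.

    The 2x2 table is ``{count_a, total_a - count_a; count_b, total_b -
    count_b}``.  Both counts zero gives (0, 1): no signal.
    """
    if total_a <= 0 or total_b <= 0:
        raise ValueError("library totals must be > 0")
    if not (0 <= count_a <= total_a and 0 <= count_b <= total_b):
        raise ValueError("counts must lie within [0, total]")
    if count_a == 0 and count_b == 0:
        return 0.0, 1.0
    g = float(
        _g_stat_array(
            np.array([count_a]), np.array([count_b]), total_a, total_b
        )[0]
    )
    g = max(g, 0.0)
    return g, float(stats.chi2.sf(g, df=1))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order preserved)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def detect_differential(
    windows: Sequence[WindowCount],
    total_a: int,
    total_b: int,
    alpha: float = DEFAULT_ALPHA,
    min_fold: float = DEFAULT_MIN_FOLD,
    merge_gap: int = DEFAULT_STEP,
) -> List[DifferentialRegion]:
    """Per-window G-tests, BH adjustment, fold filter, and region merging.

    Windows with ``q <= alpha`` and normalized fold >= ``min_fold`` are kept;
    consecutive significant windows of the same direction whose gap is below
    ``merge_gap`` (one step) merge into a region carrying the union span, the
    smallest q (with its p), the largest G, and the largest-|.| log2 fold.
    Opposite directions never merge.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if min_fold < 1:
        raise ValueError("min_fold must be >= 1")
    if not windows:
        return []
    ca = np.array([w.count_a for w in windows], dtype=np.int64)
    cb = np.array([w.count_b for w in windows], dtype=np.int64)
    g = np.maximum(_g_stat_array(ca, cb, total_a, total_b), 0.0)
    both_zero = (ca == 0) & (cb == 0)
    p = stats.chi2.sf(g, df=1)
    p[both_zero] = 1.0
    q = bh_adjust(np.clip(p, np.finfo(float).tiny, 1.0))
    rate_a = (ca + FOLD_PSEUDOCOUNT) / total_a
    rate_b = (cb + FOLD_PSEUDOCOUNT) / total_b
    log2f = np.log2(rate_a / rate_b)
    fold = np.exp2(np.abs(log2f))
    keep = (q <= alpha) & (fold >= min_fold) & ~both_zero

    regions: List[DifferentialRegion] = []
    current: Optional[dict] = None
    order = sorted(
        np.flatnonzero(keep),
        key=lambda i: (windows[i].window.chrom, windows[i].window.start),
    )
    for i in order:
        w = windows[i].window
        direction = "A_up" if log2f[i] > 0 else "B_up"
        if (
            current is not None
            and current["chrom"] == w.chrom
            and current["direction"] == direction
            and w.start - current["end"] < merge_gap
        ):
            current["end"] = max(current["end"], w.end)
            if q[i] < current["q"]:
                current["q"], current["p"] = q[i], p[i]
            current["g"] = max(current["g"], g[i])
            if abs(log2f[i]) > abs(current["log2f"]):
                current["log2f"] = log2f[i]
        else:
            if current is not None:
                regions.append(_finalize(current))
            current = {
                "chrom": w.chrom,
                "start": w.start,
                "end": w.end,
                "direction": direction,
                "q": q[i],
                "p": p[i],
                "g": g[i],
                "log2f": log2f[i],
            }
    if current is not None:
        regions.append(_finalize(current))
    return regions


def _finalize(acc: dict) -> DifferentialRegion:
    return DifferentialRegion(
        region=GenomicInterval(acc["chrom"], acc["start"], acc["end"]),
        direction=acc["direction"],
        log2_fold=float(acc["log2f"]),
        g_stat=float(acc["g"]),
        p_value=float(acc["p"]),
        q_value=float(acc["q"]),
    )


def exclude_promoters(
    regions: Sequence[DifferentialRegion],
    annotation: GenomeAnnotation,
    flank: int = 5000,
) -> List[DifferentialRegion]:
    """Drop whole regions overlapping any +/-flank promoter interval."""
    mask = promoter_regions(annotation, flank=flank)
    keep_set = RegionSet([r.region for r in regions])
    kept_intervals = set(subtract_overlapping(keep_set, mask).intervals)
    return [r for r in regions if r.region in kept_intervals]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def write_differential_bed(regions: Sequence[DifferentialRegion], path) -> None:
    """BED6+ export: name=direction, score=-10*log10(q), then fold/G/p/q."""
    rows = sorted(regions, key=lambda r: (r.region.chrom, r.region.start, r.region.end))
    with open(path, "w") as fh:
        for r in rows:
            score = int(min(1000, round(-10 * math.log10(max(r.q_value, 1e-300)))))
            fh.write(
                "\t".join(
                    [
                        r.region.chrom,
                        str(r.region.start),
                        str(r.region.end),
                        r.direction,
                        str(score),
                        ".",
                        format(r.log2_fold, ".6g"),
                        format(r.g_stat, ".6g"),
                        format(r.p_value, ".6g"),
                        format(r.q_value, ".6g"),
                    ]
                )
                + "\n"
            )


def read_differential_bed(path) -> List[DifferentialRegion]:
    out: List[DifferentialRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            f = line.split("\t")
            if len(f) < 10:
                raise ValueError(f"{path}:{lineno}: need 10 columns")
            out.append(
                DifferentialRegion(
                    region=GenomicInterval(f[0], int(f[1]), int(f[2])),
                    direction=f[3],
                    log2_fold=float(f[6]),
                    g_stat=float(f[7]),
                    p_value=float(f[8]),
                    q_value=float(f[9]),
                )
            )
    return out
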