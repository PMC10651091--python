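"""Paired-end fragment reconstruction, deduplication, coverage, and
anchor-centered signal matrices.

Fragments are whole sequenced inserts reconstructed from mate coordinates
(outermost positions), matching pipelines that elongate reads to the original
fragment before any counting.  Coverage counts whole-fragment overlap per bin
(one fragment contributes 1 to every bin it touches), the deterministic
fragment-coverage convention of BEDTools-style genome coverage on elongated
reads.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .intervals import GenomicInterval, ParseError

logger = logging.getLogger(__name__)

#: Default maximum insert size, the ATAC-seq mapping ceiling (``-X 2000``).
DEFAULT_MAX_INSERT = 2000

#: Chromosomes removed by default from ATAC fragment sets (repetitive Y,
#: non-informative mitochondrial genome).
DEFAULT_DROP_CHROMS = frozenset({"chrY", "chrM"})


class FragmentSet:
    """Per-chromosome sorted fragments as ``(n, 2)`` integer arrays."""

    def __init__(self, per_chrom: Mapping[str, np.ndarray]):
        self.per_chrom: Dict[str, np.ndarray] = {}
        for chrom in sorted(per_chrom):
            arr = np.asarray(per_chrom[chrom], dtype=np.int64).reshape(-1, 2)
            if arr.size and np.any(arr[:, 0] >= arr[:, 1]):
                raise ValueError(f"{chrom}: fragment with start >= end")
            order = np.lexsort((arr[:, 1], arr[:, 0]))
            self.per_chrom[chrom] = arr[order]

    @classmethod
    def from_records(cls, records: Iterable[Tuple[str, int, int]]) -> "FragmentSet":
        per_chrom: Dict[str, List[Tuple[int, int]]] = {}
        for chrom, start, end in records:
            per_chrom.setdefault(chrom, []).append((start, end))
        return cls(
            {c: np.array(v, dtype=np.int64).reshape(-1, 2) for c, v in per_chrom.items()}
        )

    @property
    def library_size(self) -> int:
        return sum(arr.shape[0] for arr in self.per_chrom.values())

    def chroms(self) -> List[str]:
        return list(self.per_chrom)

    def fragments(self, chrom: str) -> np.ndarray:
        return self.per_chrom.get(chrom, np.empty((0, 2), dtype=np.int64))

    def records(self) -> Iterator[Tuple[str, int, int]]:
        for chrom, arr in self.per_chrom.items():
            for start, end in arr:
                yield chrom, int(start), int(end)

    def __len__(self) -> int:
        return self.library_size


def fragments_from_pairs(
    pairs: Iterable[Sequence], max_insert: int = DEFAULT_MAX_INSERT
) -> FragmentSet:
    """Reconstruct fragments from mate coordinate records.

    Records are ``(chrom, pos_a, pos_b)`` or ``(chrom_a, pos_a, chrom_b,
    pos_b)``; each becomes one fragment ``[min, max)``.  Pairs with mates on
    different chromosomes, zero span, or span exceeding ``max_insert`` are
    dropped (counts logged).
    """
    records: List[Tuple[str, int, int]] = []
    n_cross = n_long = n_degenerate = 0
    for rec in pairs:
        if len(rec) == 3:
            chrom, pos_a, pos_b = rec
        elif len(rec) == 4:
            chrom, pos_a, chrom_b, pos_b = rec
            if chrom != chrom_b:
                n_cross += 1
                continue
        else:
            raise ValueError(f"pair record of length {len(rec)}")
        start, end = min(pos_a, pos_b), max(pos_a, pos_b)
        if start == end:
            n_degenerate += 1
            continue
        if end - start > max_insert:
            n_long += 1
            continue
        records.append((chrom, start, end))
    if n_cross or n_long or n_degenerate:
        logger.info(
            "fragments_from_pairs: dropped %d cross-chromosome, %d over %d bp, "
            "%d zero-length pairs",
            n_cross,
            n_long,
            max_insert,
            n_degenerate,
        )
    return FragmentSet.from_records(records)


def deduplicate_fragments(fragset: FragmentSet) -> FragmentSet:
    """Collapse exact ``(chrom, start, end)`` duplicates to one fragment."""
    return FragmentSet(
        {c: np.unique(arr, axis=0) for c, arr in fragset.per_chrom.items()}
    )


def drop_chromosomes(fragset: FragmentSet, names: Iterable[str]) -> FragmentSet:
    names = set(names)
    return FragmentSet(
        {c: arr for c, arr in fragset.per_chrom.items() if c not in names}
    )


@dataclass
class CoverageTrack:
    """Per-bin fragment-overlap coverage per chromosome."""

    data: Dict[str, np.ndarray]
    bin_size: int

    def n_bins(self, chrom: str) -> int:
        return len(self.data.get(chrom, ()))

    def values(self, chrom: str) -> np.ndarray:
        return self.data.get(chrom, np.zeros(0))


def coverage(
    fragset: FragmentSet,
    bin_size: int,
    chrom_sizes: Optional[Mapping[str, int]] = None,
) -> CoverageTrack:
    """Number of fragments overlapping each bin.

    Bin count per chromosome is ``ceil(length / bin_size)``; the length comes
    from ``chrom_sizes`` when given, else from the rightmost fragment end.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    sizes = dict(chrom_sizes or {})
    chroms = sorted(set(fragset.chroms()) | set(sizes))
    data: Dict[str, np.ndarray] = {}
    for chrom in chroms:
        arr = fragset.fragments(chrom)
        size = sizes.get(chrom, int(arr[:, 1].max()) if arr.size else 0)
        n_bins = math.ceil(size / bin_size) if size else 0
        diff = np.zeros(n_bins + 1, dtype=np.int64)
        if arr.size and n_bins:
            first = arr[:, 0] // bin_size
            last = (arr[:, 1] - 1) // bin_size
            first = np.clip(first, 0, n_bins - 1)
            last = np.clip(last, 0, n_bins - 1)
            np.add.at(diff, first, 1)
            np.add.at(diff, last + 1, -1)
        data[chrom] = np.cumsum(diff[:-1]).astype(float)
    return CoverageTrack(data=data, bin_size=bin_size)


def summit(peak: GenomicInterval, track: CoverageTrack) -> int:
    """Single-bp maximum of a peak at bin resolution (leftmost on ties).

    A zero-coverage peak returns the midpoint and logs a low-confidence
    warning.
    """
    values = track.values(peak.chrom)
    bs = track.bin_size
    b0 = peak.start // bs
    b1 = min((peak.end - 1) // bs, len(values) - 1)
    if b1 < b0 or not len(values):
        logger.warning("summit: peak %s outside track; using midpoint", peak)
        return (peak.start + peak.end) // 2
    window = values[b0 : b1 + 1]
    if window.max() <= 0:
        logger.warning("summit: zero coverage in %s; low-confidence midpoint", peak)
        return (peak.start + peak.end) // 2
    pos = (b0 + int(np.argmax(window))) * bs + bs // 2
    return int(min(max(pos, peak.start), peak.end - 1))


@dataclass
class SignalMatrix:
    """Anchor-by-bin coverage matrix around anchor positions."""

    matrix: np.ndarray  # (n_anchors, 2*flank/bin)
    anchors: List[Tuple[str, int]]
    flank: int
    bin_size: int

    def __post_init__(self) -> None:
        if self.matrix.shape[0] != len(self.anchors):
            raise ValueError("row count must equal anchor count")
        if self.matrix.shape[1] != 2 * self.flank // self.bin_size:
            raise ValueError("column count must be 2*flank/bin")


def signal_matrix(
    anchors: Sequence[Tuple[str, int]],
    track: CoverageTrack,
    flank: int,
    bin_size: int,
) -> SignalMatrix:
    """Row i = coverage in ``[anchor_i - flank, anchor_i + flank)`` binned.

    Out-of-bounds positions are zero-padded so the matrix stays rectangular.
    ``flank`` must be divisible by ``bin_size`` and ``bin_size`` by the track
    bin.
    """
    if flank % bin_size != 0:
        raise ValueError("flank must be divisible by bin_size")
    if bin_size % track.bin_size != 0:
        raise ValueError("bin_size must be a multiple of the track bin")
    n_cols = 2 * flank // bin_size
    offsets = np.arange(-flank, flank)
    rows = np.zeros((len(anchors), n_cols), dtype=float)
    for i, (chrom, pos) in enumerate(anchors):
        values = track.values(chrom)
        bps = pos + offsets
        valid = (bps >= 0) & (bps // track.bin_size < len(values))
        per_bp = np.zeros(2 * flank, dtype=float)
        if valid.any():
            per_bp[valid] = values[bps[valid] // track.bin_size]
        rows[i] = per_bp.reshape(n_cols, bin_size).mean(axis=1)
    return SignalMatrix(rows, list(anchors), flank, bin_size)


def average_profile(matrix: SignalMatrix) -> np.ndarray:
    """Per-bin column means of a signal matrix."""
    if matrix.matrix.shape[0] == 0:
        raise ValueError("empty signal matrix")
    return matrix.matrix.mean(axis=0)


def order_anchors(
    anchors: Sequence,
    mode: str,
    pvalues: Optional[Sequence[float]] = None,
    categories: Optional[Sequence[int]] = None,
    seed: int = 0,
) -> List:
    """Heatmap row ordering.

    ``by_pvalue``: ascending p-value (stable).  ``by_category_then_random``:
    contiguous category blocks in ascending category order, rows shuffled
    within each block by the seeded generator.
    """
    if mode == "by_pvalue":
        if pvalues is None or len(pvalues) != len(anchors):
            raise ValueError("by_pvalue mode needs one p-value per anchor")
        order = np.argsort(np.asarray(pvalues, dtype=float), kind="stable")
        return [anchors[i] for i in order]
    if mode == "by_category_then_random":
        if categories is None or len(categories) != len(anchors):
            raise ValueError("category mode needs one category per anchor")
        rng = np.random.default_rng(seed)
        out: List = []
        cats = np.asarray(categories)
        for cat in sorted(set(categories)):
            idx = np.flatnonzero(cats == cat)
            out.extend(anchors[i] for i in rng.permutation(idx))
        return out
    raise ValueError(f"unknown ordering mode {mode!r}")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_bedpe(path) -> List[Tuple[str, int, str, int]]:
    """BEDPE mate records reduced to outermost coordinates.

    Returns ``(chrom_a, outer_start, chrom_b, outer_end)`` per line, feeding
    :func:`fragments_from_pairs`.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: BEDPE needs 6 columns")
            try:
                s1, e1 = int(fields[1]), int(fields[2])
                s2, e2 = int(fields[4]), int(fields[5])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            out.append((fields[0], min(s1, s2), fields[3], max(e1, e2)))
    return out


def fragments_from_bedpe(path, max_insert: int = DEFAULT_MAX_INSERT) -> FragmentSet:
    return fragments_from_pairs(read_bedpe(path), max_insert=max_insert)


def read_fragments_bed(path) -> FragmentSet:
    """Fragment BED3 reader (elongated, possibly deduplicated fragments)."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: fewer than 3 columns")
            try:
                records.append((fields[0], int(fields[1]), int(fields[2])))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
    return FragmentSet.from_records(records)


def write_fragments_bed(fragset: FragmentSet, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in fragset.records():
            fh.write(f"{chrom}\t{start}\t{end}\n")


def write_wiggle(track: CoverageTrack, path) -> None:
    """fixedStep wiggle (1-based starts, step = span = bin size)."""
    bs = track.bin_size
    with open(path, "w") as fh:
        for chrom in sorted(track.data):
            values = track.data[chrom]
            if len(values) == 0:
                continue
            fh.write(f"fixedStep chrom={chrom} start=1 step={bs} span={bs}\n")
            for v in values:
                fh.write(format(v, ".10g") + "\n")


def read_wiggle(path) -> CoverageTrack:
    data: Dict[str, List[float]] = {}
    bin_size = None
    chrom = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            if line.startswith("fixedStep"):
                attrs = dict(kv.split("=") for kv in line.split()[1:])
                chrom = attrs["chrom"]
                step = int(attrs.get("step", 1))
                if bin_size is None:
                    bin_size = step
                elif bin_size != step:
                    raise ParseError(f"{path}:{lineno}: mixed step sizes")
                if int(attrs.get("start", 1)) != 1:
                    raise ParseError(f"{path}:{lineno}: only start=1 supported")
                data.setdefault(chrom, [])
            else:
                if chrom is None:
                    raise ParseError(f"{path}:{lineno}: value before fixedStep header")
                data[chrom].append(float(line))
    if bin_size is None:
        raise ParseError(f"{path}: no fixedStep records")
    return CoverageTrack(
        data={c: np.asarray(v, dtype=float) for c, v in data.items()},
        bin_size=bin_size,
    )


def write_signal_matrix(matrix: SignalMatrix, path) -> None:
    """TSV export: anchor id column then one column per flank bin."""
    n_cols = matrix.matrix.shape[1]
    with open(path, "w") as fh:
        header = "anchor\t" + "\t".join(
            f"bin_{i * matrix.bin_size - matrix.flank}" for i in range(n_cols)
        )
        fh.write(header + "\n")
        for (chrom, pos), row in zip(matrix.anchors, matrix.matrix):
            fh.write(
                f"{chrom}:{pos}\t" + "\t".join(format(v, ".6g") for v in row) + "\n"
            )
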