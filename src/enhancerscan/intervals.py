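"""Genome coordinate model, annotation handling, and interval arithmetic.

Every coordinate in this package is 0-based, half-open (``[start, end)``),
the native BED convention.  GTF input (1-based, closed) is converted on read
and never stored in its original convention, so downstream arithmetic needs
no off-by-one bookkeeping.

"Upstream"/"downstream" in gene-neighbour searches means left/right in
reference coordinates, ignoring gene strand (see :data:`NEIGHBOR_DIRECTION`);
this matches the behaviour of common nearest-gene annotation tools.
"""

from __future__ import annotations

import logging
import re
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")

#: Documented convention: neighbour search is in reference-coordinate
#: direction (upstream = smaller coordinates), not gene-strand direction.
NEIGHBOR_DIRECTION = "reference"


class ParseError(ValueError):
    """Raised when a genomic text format cannot be parsed."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A chromosome-anchored half-open coordinate span."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand symbol {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        """True iff ``pos`` lies inside the half-open span."""
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return overlaps(self, other)


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """Half-open overlap test; abutting intervals do not overlap."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


@dataclass(frozen=True)
class GeneModel:
    """A gene body span with a strand-derived transcription start site.

    ``tss_sites`` optionally records per-transcript start sites (used by the
    per-transcript promoter option); it always contains at least the gene TSS.
    """

    gene_id: str
    interval: GenomicInterval
    tss_sites: Tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not self.tss_sites:
            object.__setattr__(self, "tss_sites", (self.tss,))
        for t in self.tss_sites:
            if not self.interval.contains(t):
                raise ValueError(f"gene {self.gene_id}: TSS {t} outside gene body")

    @property
    def tss(self) -> int:
        """TSS position: interval.start on +, interval.end - 1 on -."""
        if self.interval.strand == "+":
            return self.interval.start
        return self.interval.end - 1

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


@dataclass
class RegionSet:
    """A bag of intervals with a free-text role tag; duplicates permitted."""

    intervals: List[GenomicInterval]
    label: str = ""

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)


def _interval_tree(intervals: Iterable[GenomicInterval]) -> Dict[str, IntervalTree]:
    trees: Dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees


class GenomeAnnotation:
    """Per-chromosome gene models, sorted by start, plus chromosome sizes.

    Parameters
    ----------
    genes:
        Any iterable of :class:`GeneModel`; stored sorted by
        ``(chrom, start, end, gene_id)``.
    chrom_sizes:
        Chromosome length in bp.  Optional; when present every gene must fit
        inside its chromosome and promoter intervals are clipped to it.
    """

    def __init__(
        self,
        genes: Iterable[GeneModel],
        chrom_sizes: Optional[Mapping[str, int]] = None,
    ) -> None:
        self.chrom_sizes: Dict[str, int] = dict(chrom_sizes or {})
        by_chrom: Dict[str, List[GeneModel]] = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        self.by_chrom: Dict[str, List[GeneModel]] = {
            c: sorted(gs, key=lambda g: (g.start, g.end, g.gene_id))
            for c, gs in sorted(by_chrom.items())
        }
        for c, gs in self.by_chrom.items():
            size = self.chrom_sizes.get(c)
            if size is not None:
                for g in gs:
                    if g.end > size:
                        raise ValueError(
                            f"gene {g.gene_id} extends past {c} length {size}"
                        )
        # lookup indices: genes sorted by start, and by end, per chromosome
        self._starts = {c: [g.start for g in gs] for c, gs in self.by_chrom.items()}
        self._by_end = {
            c: sorted(gs, key=lambda g: (g.end, g.gene_id))
            for c, gs in self.by_chrom.items()
        }
        self._ends = {c: [g.end for g in gs] for c, gs in self._by_end.items()}
        self._gene_index = {g.gene_id: g for g in self.genes()}
        self._tree_cache: Dict[int, Dict[str, IntervalTree]] = {}

    def genes(self) -> Iterator[GeneModel]:
        for gs in self.by_chrom.values():
            yield from gs

    @property
    def n_genes(self) -> int:
        return sum(len(gs) for gs in self.by_chrom.values())

    def gene(self, gene_id: str) -> GeneModel:
        return self._gene_index[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._gene_index

    def chrom_size(self, chrom: str) -> Optional[int]:
        return self.chrom_sizes.get(chrom)

    def _extended_trees(self, flank: int) -> Dict[str, IntervalTree]:
        if flank not in self._tree_cache:
            trees: Dict[str, IntervalTree] = {}
            for c, gs in self.by_chrom.items():
                tree = IntervalTree()
                for g in gs:
                    tree.addi(max(0, g.start - flank), g.end + flank, g)
                trees[c] = tree
            self._tree_cache[flank] = trees
        return self._tree_cache[flank]

    def host_genes(self, chrom: str, pos: int, flank: int) -> List[GeneModel]:
        """Genes whose body, extended by ``flank`` on both sides, contains ``pos``."""
        trees = self._extended_trees(flank)
        hits = trees.get(chrom, IntervalTree()).at(pos)
        return sorted((h.data for h in hits), key=lambda g: (g.start, g.end, g.gene_id))


def promoter_regions(
    annotation: GenomeAnnotation, flank: int = 5000, per_transcript: bool = False
) -> RegionSet:
    """Promoter mask: one ``[tss - flank, tss + flank + 1)`` interval per TSS.

    Clipped to ``[0, chromosome length]`` where the length is known.  With
    ``per_transcript=True`` one interval is emitted per recorded transcript
    start site instead of one per gene.
    """
    if flank <= 0:
        raise ValueError("flank must be > 0")
    out: List[GenomicInterval] = []
    for g in annotation.genes():
        size = annotation.chrom_size(g.chrom)
        sites = g.tss_sites if per_transcript else (g.tss,)
        for tss in sites:
            start = max(0, tss - flank)
            end = tss + flank + 1
            if size is not None:
                end = min(end, size)
            out.append(GenomicInterval(g.chrom, start, end))
    return RegionSet(out, label="promoters")


def subtract_overlapping(regions: RegionSet, mask: RegionSet) -> RegionSet:
    """Whole-region drop: keep input regions overlapping no mask interval.

    Regions are never trimmed; input order is preserved.
    """
    trees = _interval_tree(mask)
    kept = [
        iv
        for iv in regions
        if not trees.get(iv.chrom) or not trees[iv.chrom].overlap(iv.start, iv.end)
    ]
    return RegionSet(kept, label=regions.label)


def closest_flanking_genes(
    annotation: GenomeAnnotation,
    chrom: str,
    pos: int,
    exclude: frozenset = frozenset(),
) -> Tuple[Optional[GeneModel], Optional[GeneModel]]:
    """Nearest genes entirely left of / right of ``pos`` on ``chrom``.

    Upstream = gene with greatest end <= pos; downstream = gene with least
    start >= pos.  Ties (equal boundary coordinate) break to the
    lexicographically smaller gene_id.  Returns ``None`` at chromosome ends.
    ``exclude`` removes gene_ids (e.g. host genes) from consideration.
    """
    if chrom not in annotation.by_chrom:
        raise KeyError(f"chromosome {chrom!r} not in annotation")

    upstream: Optional[GeneModel] = None
    by_end, ends = annotation._by_end[chrom], annotation._ends[chrom]
    i = bisect_right(ends, pos) - 1
    best_end = None
    while i >= 0:
        g = by_end[i]
        if best_end is not None and g.end < best_end:
            break
        if g.gene_id not in exclude:
            if best_end is None:
                best_end, upstream = g.end, g
            elif g.end == best_end and g.gene_id < upstream.gene_id:
                upstream = g
        i -= 1

    downstream: Optional[GeneModel] = None
    by_start, starts = annotation.by_chrom[chrom], annotation._starts[chrom]
    j = bisect_left(starts, pos)
    best_start = None
    while j < len(by_start):
        g = by_start[j]
        if best_start is not None and g.start > best_start:
            break
        if g.gene_id not in exclude:
            if best_start is None:
                best_start, downstream = g.start, g
            elif g.start == best_start and g.gene_id < downstream.gene_id:
                downstream = g
        j += 1

    return upstream, downstream


def classify_location(
    peak: GenomicInterval, annotation: GenomeAnnotation, flank: int = 5000
) -> str:
    """``"genic"`` iff the peak overlaps any gene body extended by ``flank``."""
    if flank <= 0:
        raise ValueError("flank must be > 0")
    trees = annotation._extended_trees(flank)
    tree = trees.get(peak.chrom)
    if tree is not None and tree.overlap(peak.start, peak.end):
        return "genic"
    return "intergenic"


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_GENE_ID_RE = re.compile(r'gene_id\s+"([^"]+)"')


def read_bed(path, label: str = "") -> RegionSet:
    """Read BED3+/BED6 (0-based half-open, taken verbatim).

    ``track``/``browser`` header lines and ``#`` comments are skipped.
    Malformed lines raise :class:`ParseError` naming the line number.
    """
    out: List[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: fewer than 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            strand = fields[5] if len(fields) >= 6 and fields[5] in STRANDS else "."
            try:
                out.append(GenomicInterval(fields[0], start, end, strand))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return RegionSet(out, label=label or str(path))


def write_bed(regions: Iterable[GenomicInterval], path) -> None:
    """Write BED3 (BED6 when any strand is set), sorted by (chrom, start, end)."""
    ivs = sorted(regions, key=lambda iv: (iv.chrom, iv.start, iv.end))
    stranded = any(iv.strand != "." for iv in ivs)
    with open(path, "w") as fh:
        for iv in ivs:
            if stranded:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_chrom_sizes(path) -> Dict[str, int]:
    """Two-column chromosome-size table (name <tab> length)."""
    sizes: Dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: need name and length")
            try:
                sizes[fields[0]] = int(fields[1])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer length") from exc
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(sizes):
            fh.write(f"{chrom}\t{sizes[chrom]}\n")


def read_annotation(
    path,
    dialect: str = "gtf",
    chrom_sizes: Optional[Mapping[str, int]] = None,
) -> GenomeAnnotation:
    """Read a gene annotation.

    ``gtf``: 1-based closed coordinates converted to 0-based half-open; one
    gene model per ``gene_id`` spanning the union of all its records;
    transcript/gene record start positions (strand-aware) are collected as
    candidate per-transcript TSS.  ``gene-bed``: BED6 with the name column as
    gene_id.
    """
    if dialect == "gtf":
        genes = _read_gtf(path)
    elif dialect == "gene-bed":
        genes = _read_gene_bed(path)
    else:
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    if not genes:
        raise ParseError(f"{path}: empty annotation")
    return GenomeAnnotation(genes, chrom_sizes=chrom_sizes)


def _read_gtf(path) -> List[GeneModel]:
    spans: Dict[str, List] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path}:{lineno}: fewer than 9 GTF columns")
            chrom, _, feature, start1, end1, _, strand = fields[:7]
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: unknown strand symbol {strand!r}")
            m = _GENE_ID_RE.search(fields[8])
            if m is None:
                raise ParseError(f"{path}:{lineno}: missing gene_id attribute")
            gene_id = m.group(1)
            try:
                start, end = int(start1) - 1, int(end1)  # GTF 1-based closed
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start >= end")
            rec = spans.setdefault(gene_id, [chrom, start, end, strand, set()])
            if rec[0] != chrom or rec[3] != strand:
                raise ParseError(
                    f"{path}:{lineno}: gene {gene_id} on conflicting chrom/strand"
                )
            rec[1] = min(rec[1], start)
            rec[2] = max(rec[2], end)
            if feature in ("gene", "transcript", "mRNA"):
                rec[4].add(start if strand == "+" else end - 1)
    genes = []
    for gene_id, (chrom, start, end, strand, tss) in spans.items():
        tss = tss or {start if strand == "+" else end - 1}
        genes.append(
            GeneModel(
                gene_id,
                GenomicInterval(chrom, start, end, strand),
                tuple(sorted(tss)),
            )
        )
    return genes


def _read_gene_bed(path) -> List[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(f"{path}:{lineno}: gene-bed needs 6 columns")
            if fields[5] not in ("+", "-"):
                raise ParseError(
                    f"{path}:{lineno}: unknown strand symbol {fields[5]!r}"
                )
            try:
                iv = GenomicInterval(
                    fields[0], int(fields[1]), int(fields[2]), fields[5]
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            genes.append(GeneModel(fields[3], iv))
    return genes


def write_gene_bed(annotation: GenomeAnnotation, path) -> None:
    with open(path, "w") as fh:
        for g in annotation.genes():
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.interval.strand}\n"
            )
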