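"""Expression-class gene calling, enhancer-to-target-gene assignment, and
gene/enhancer association summaries.

The target-gene rule: an enhancer anchor lying within a gene body extended by
a flank ("genic") is assigned to every such host gene plus the closest
up- and downstream genes flanking the host span; an intergenic anchor (beyond
the flank from every gene) is assigned to the two flanking genes only.  The
dual formulation — a gene is associated with every enhancer anchored inside
its *domain*, the span from the upstream neighbour's body through the
downstream neighbour's body — agrees with the assignment rule for interior,
non-nested genes and drives the association summaries.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .categories import EnhancerTable
from .intervals import (
    GenomeAnnotation,
    GenomicInterval,
    GeneModel,
    classify_location,
    closest_flanking_genes,
)

logger = logging.getLogger(__name__)

#: Pseudocount (FPKM) added to both sides of fold-change comparisons.
FOLD_PSEUDOCOUNT = 0.1
#: FPKM below which a gene counts as not expressed anywhere.
DEFAULT_EXPRESSION_FLOOR = 1.0
DEFAULT_SPECIFIC_FOLD = 3.0

HOST = "host"
UPSTREAM = "upstream_neighbor"
DOWNSTREAM = "downstream_neighbor"


@dataclass
class FPKMTable:
    """Gene x sample FPKM matrix with (population, stage) sample labels."""

    values: pd.DataFrame  # index = gene_id, columns = sample names
    sample_groups: Dict[str, Tuple[str, str]]  # sample -> (population, stage)

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("FPKM values must be non-negative")
        missing = set(self.values.columns) - set(self.sample_groups)
        if missing:
            raise ValueError(f"samples without group labels: {sorted(missing)}")

    def group_mean(self, population: str, stage: str) -> pd.Series:
        cols = [
            s
            for s, (p, st) in self.sample_groups.items()
            if p == population and st == stage and s in self.values.columns
        ]
        if not cols:
            raise ValueError(f"no samples for {population} at {stage}")
        return self.values[cols].mean(axis=1)

    def stages(self, population: str) -> List[str]:
        return sorted(
            {st for p, st in self.sample_groups.values() if p == population}
        )


def fpkm_from_counts(
    counts: pd.DataFrame,
    lengths: Mapping[str, int],
    totals: Mapping[str, int],
) -> pd.DataFrame:
    """FPKM = count * 1e9 / (gene length in bp * mapped fragments)."""
    lengths_s = pd.Series(lengths).reindex(counts.index)
    if lengths_s.isna().any() or (lengths_s <= 0).any():
        raise ValueError("every gene needs a positive length")
    totals_s = pd.Series(totals).reindex(counts.columns)
    if totals_s.isna().any() or (totals_s <= 0).any():
        raise ValueError("every sample needs a positive mapped-fragment total")
    return counts.mul(1e9).div(lengths_s, axis=0).div(totals_s, axis=1)


def specific_genes(
    table: FPKMTable,
    group_a: str,
    group_b: str,
    fold: float = DEFAULT_SPECIFIC_FOLD,
    pseudocount: float = FOLD_PSEUDOCOUNT,
) -> Tuple[Set[str], Set[str]]:
    """Group-specific genes: >= fold higher in one group at *every* stage.

    The criterion is inclusive (``>= fold``) and evaluated on
    pseudocount-shifted FPKM; the two returned sets are disjoint for any
    fold > 1.
    """
    if fold <= 1:
        raise ValueError("fold must be > 1")
    stages = table.stages(group_a)
    if stages != table.stages(group_b) or not stages:
        raise ValueError("both groups need FPKM at the same stages")
    a_mask = pd.Series(True, index=table.values.index)
    b_mask = pd.Series(True, index=table.values.index)
    for stage in stages:
        fa = table.group_mean(group_a, stage) + pseudocount
        fb = table.group_mean(group_b, stage) + pseudocount
        a_mask &= fa >= fold * fb
        b_mask &= fb >= fold * fa
    return set(table.values.index[a_mask]), set(table.values.index[b_mask])


def classify_expression(
    table: FPKMTable,
    a_specific: Set[str],
    b_specific: Set[str],
    expression_floor: float = DEFAULT_EXPRESSION_FLOOR,
    labels: Tuple[str, str] = ("A_specific", "B_specific"),
) -> Dict[str, str]:
    """Four-way expression class per gene.

    ``not_expressed`` when the max FPKM over all samples is below the floor;
    otherwise the specific-set label when applicable, else ``not_specific``.
    """
    if expression_floor < 0:
        raise ValueError("expression_floor must be >= 0")
    max_fpkm = table.values.max(axis=1)
    out: Dict[str, str] = {}
    for gene in table.values.index:
        if max_fpkm[gene] < expression_floor:
            out[gene] = "not_expressed"
        elif gene in a_specific:
            out[gene] = labels[0]
        elif gene in b_specific:
            out[gene] = labels[1]
        else:
            out[gene] = "not_specific"
    return out


def assign_target_genes(
    anchor: Tuple[str, int],
    annotation: GenomeAnnotation,
    flank: int = 5000,
) -> List[Tuple[GeneModel, str]]:
    """Target genes of one enhancer anchor, with relations.

    Genic anchors (inside a gene body extended by ``flank``): every host gene
    plus the closest up-/downstream genes flanking the host span (hosts
    excluded from the neighbour search).  Intergenic anchors: the two
    flanking genes (one at chromosome ends).  Duplicates are collapsed,
    keeping the first (host-first) relation.
    """
    if annotation.n_genes == 0:
        raise ValueError("empty annotation")
    chrom, pos = anchor
    hosts = annotation.host_genes(chrom, pos, flank)
    assigned: List[Tuple[GeneModel, str]] = []
    if hosts:
        assigned.extend((g, HOST) for g in hosts)
        span_lo = min(g.start for g in hosts)
        span_hi = max(g.end for g in hosts)
        exclude = frozenset(g.gene_id for g in hosts)
        up, _ = closest_flanking_genes(annotation, chrom, span_lo, exclude=exclude)
        _, down = closest_flanking_genes(annotation, chrom, span_hi, exclude=exclude)
    else:
        up, down = closest_flanking_genes(annotation, chrom, pos)
    if up is not None:
        assigned.append((up, UPSTREAM))
    if down is not None:
        assigned.append((down, DOWNSTREAM))
    seen: Set[str] = set()
    unique: List[Tuple[GeneModel, str]] = []
    for g, rel in assigned:
        if g.gene_id not in seen:
            seen.add(g.gene_id)
            unique.append((g, rel))
    return unique


def gene_domain(gene: GeneModel, annotation: GenomeAnnotation) -> GenomicInterval:
    """Association domain of a gene.

    Spans from the outer boundary (start) of the nearest gene entirely
    upstream to the outer boundary (end) of the nearest gene entirely
    downstream, clipped to the chromosome at the ends.
    """
    if gene.gene_id not in annotation:
        raise ValueError(f"gene {gene.gene_id} not in annotation")
    exclude = frozenset({gene.gene_id})
    up, _ = closest_flanking_genes(annotation, gene.chrom, gene.start, exclude=exclude)
    _, down = closest_flanking_genes(annotation, gene.chrom, gene.end, exclude=exclude)
    start = up.start if up is not None else 0
    size = annotation.chrom_size(gene.chrom)
    if down is not None:
        end = down.end
    elif size is not None:
        end = size
    else:
        end = max(g.end for g in annotation.by_chrom[gene.chrom])
    return GenomicInterval(gene.chrom, start, max(end, start + 1))


@dataclass
class EnhancerGeneMap:
    """Bidirectional gene/enhancer association bookkeeping."""

    gene_to_enhancers: Dict[str, List[int]]  # gene_id -> enhancer row indices
    enhancer_to_genes: Dict[int, List[Tuple[str, str]]]  # idx -> (gene_id, relation)
    enhancer_categories: Dict[int, int]  # idx -> category

    def categories_of(self, gene_id: str) -> Set[int]:
        return {
            self.enhancer_categories[i] for i in self.gene_to_enhancers.get(gene_id, [])
        }


def associate(
    genes: Iterable[str],
    enhancers: EnhancerTable,
    annotation: GenomeAnnotation,
    flank: int = 5000,
) -> Tuple[EnhancerGeneMap, Dict[str, object]]:
    """Associate genes with enhancers anchored inside their domains.

    Returns the map plus a summary with the count and percentage (one
    decimal) of genes having at least one associated enhancer.  Enhancer
    target assignment (the anchor-side view) is recorded alongside.
    """
    gene_ids = sorted(set(genes))
    gene_to_enh: Dict[str, List[int]] = {g: [] for g in gene_ids}
    enh_to_genes: Dict[int, List[Tuple[str, str]]] = {}
    enh_categories: Dict[int, int] = {}

    for idx, row in enumerate(enhancers.rows):
        enh_categories[idx] = row.category
        enh_to_genes[idx] = [
            (g.gene_id, rel)
            for g, rel in assign_target_genes(
                (row.region.chrom, row.anchor), annotation, flank=flank
            )
        ]

    for gene_id in gene_ids:
        if gene_id not in annotation:
            logger.info("associate: gene %s absent from annotation", gene_id)
            continue
        domain = gene_domain(annotation.gene(gene_id), annotation)
        for idx, row in enumerate(enhancers.rows):
            if row.region.chrom == domain.chrom and domain.contains(row.anchor):
                gene_to_enh[gene_id].append(idx)

    n_genes = len(gene_ids)
    n_with = sum(1 for g in gene_ids if gene_to_enh[g])
    pct = 0.0 if n_genes == 0 else math.floor(1000.0 * n_with / n_genes + 0.5) / 10
    summary = {"n_genes": n_genes, "n_with_enhancer": n_with, "percent": pct}
    return (
        EnhancerGeneMap(gene_to_enh, enh_to_genes, enh_categories),
        summary,
    )


def upset_table(emap: EnhancerGeneMap, genes: Iterable[str]) -> pd.DataFrame:
    """Exact category-combination tallies over genes (UpSet-style).

    One row per distinct set of enhancer categories observed among the
    genes' associated enhancers, counted by gene, sorted by count descending
    then by combination.  Row counts sum to the number of genes with at
    least one enhancer.
    """
    combos: Dict[Tuple[int, ...], int] = {}
    for gene_id in genes:
        cats = tuple(sorted(emap.categories_of(gene_id)))
        if cats:
            combos[cats] = combos.get(cats, 0) + 1
    rows = sorted(combos.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(
        {
            "categories": [",".join(map(str, c)) for c, _ in rows],
            "count": [n for _, n in rows],
        }
    )


def set_overlap(
    sets: Mapping[str, Iterable[str]],
    known_ids: Optional[Set[str]] = None,
) -> Dict[Tuple[str, ...], int]:
    """Counts for every non-empty region of the Venn partition of gene sets.

    Identifiers absent from ``known_ids`` (when given) are dropped with a
    logged count before tallying, mirroring comparative analyses that remove
    genes missing from the reference annotation.
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 sets")
    names = sorted(sets)
    cleaned: Dict[str, Set[str]] = {}
    n_dropped = 0
    for name in names:
        ids = set(sets[name])
        if known_ids is not None:
            kept = ids & known_ids
            n_dropped += len(ids) - len(kept)
            ids = kept
        cleaned[name] = ids
    if n_dropped:
        logger.info("set_overlap: dropped %d unmatched identifiers", n_dropped)
    out: Dict[Tuple[str, ...], int] = {}
    universe = set().union(*cleaned.values())
    for element in universe:
        member = tuple(n for n in names if element in cleaned[n])
        out[member] = out.get(member, 0) + 1
    return dict(sorted(out.items()))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_fpkm_tsv(path, sample_groups: Mapping[str, Tuple[str, str]]) -> FPKMTable:
    """TSV with header row, gene_id first column, one column per sample."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return FPKMTable(df, dict(sample_groups))


def write_fpkm_tsv(table: FPKMTable, path) -> None:
    df = table.values.sort_index()
    df.to_csv(path, sep="\t", float_format="%.6g", index_label="gene_id")


def normalize_per_gene(values: pd.DataFrame, scheme: str = "row_max") -> pd.DataFrame:
    """Per-gene normalization for heatmap export.

    ``row_max`` divides each row by its maximum (zero rows stay zero);
    ``zscore`` standardizes each row.
    """
    if scheme == "row_max":
        denom = values.max(axis=1).replace(0, 1.0)
        return values.div(denom, axis=0)
    if scheme == "zscore":
        sd = values.std(axis=1).replace(0, 1.0)
        return values.sub(values.mean(axis=1), axis=0).div(sd, axis=0)
    raise ValueError(f"unknown normalization scheme {scheme!r}")


def write_gene_map_tsv(emap: EnhancerGeneMap, path) -> None:
    """TSV export: enhancer_id, gene_id, relation, category."""
    with open(path, "w") as fh:
        fh.write("enhancer_id\tgene_id\trelation\tcategory\n")
        for idx in sorted(emap.enhancer_to_genes):
            for gene_id, rel in emap.enhancer_to_genes[idx]:
                fh.write(f"{idx}\t{gene_id}\t{rel}\t{emap.enhancer_categories[idx]}\n")


def write_upset_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_gene_set(path) -> Set[str]:
    """One identifier per line; blank lines and # comments skipped."""
    out: Set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line)
    return out


def write_gene_set(genes: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        for g in sorted(set(genes)):
            fh.write(g + "\n")
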