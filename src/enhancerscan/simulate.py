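"""Synthetic toy genomes with planted differential accessibility, TF peak
structure, and group-specific expression — with full ground-truth bookkeeping.

The generator emulates the statistical structure the pipeline assumes rather
than sequence-level data: window fragment counts are Poisson (the sampling
model for one pooled library per condition; a negative binomial with
configurable dispersion is available to probe overdispersion), fragment
lengths are lognormal around typical ATAC insert sizes, planted enhancers
carry a stated accessibility fold change in condition A only, and planted
group-specific genes carry a stated expression fold in one group at both
stages.  Every file written by :func:`emit_fixture` is linked to its ground
truth in a manifest, so each downstream stage can be scored without reading
generator internals.

A single seed is threaded to all sub-generators through
``numpy.random.SeedSequence(seed).spawn`` (one child per stage, in a fixed
order), so identical configs produce byte-identical fixtures.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
import yaml

from .categories import (
    DEFAULT_CATEGORY_MAP,
    CategoryMap,
    Peak,
    PeakSet,
    SOURCES,
    write_narrowpeak,
)
from .fragments import FragmentSet, write_fragments_bed
from .genes import FPKMTable, write_fpkm_tsv, write_gene_set
from .intervals import (
    GenomeAnnotation,
    GenomicInterval,
    GeneModel,
    RegionSet,
    promoter_regions,
    write_bed,
    write_chrom_sizes,
    write_gene_bed,
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic fixture.

    Defaults describe the tiny desk-scale fixture (2 chromosomes x 200 kb,
    20 genes, 30 enhancers) that the whole pipeline runs on in seconds.
    ``dispersion=inf`` is the Poisson limit of the negative-binomial window
    counts; finite values add overdispersion.
    """

    n_chromosomes: int = 2
    chrom_length: int = 200_000
    n_genes: int = 20
    gene_length: Tuple[int, int] = (2_000, 8_000)
    min_gap: int = 1_000
    n_enhancers: int = 30
    category_probabilities: Tuple[float, ...] = tuple([1.0 / 7] * 7)
    accessibility_fold: float = 4.0
    mean_depth: float = 50.0
    dispersion: float = math.inf
    window: int = 1_000
    fragment_length_median: float = 200.0
    fragment_length_sigma: float = 0.35
    duplicate_rate: float = 0.1
    n_specific_genes_a: int = 8
    n_specific_genes_b: int = 4
    specific_fold: float = 10.0
    fpkm_sigma: float = 0.2
    fpkm_baseline_median: float = 20.0
    fpkm_baseline_sigma: float = 1.0
    promoter_flank: int = 5_000
    peak_halfwidth: Tuple[int, int] = (150, 400)
    summit_jitter: int = 5
    boundary_jitter: int = 50
    n_blacklist: int = 5
    blacklist_length: int = 2_000
    n_decoy_peaks: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.category_probabilities) - 1.0) > 1e-9:
            raise ValueError("category probabilities must sum to 1")
        if len(self.category_probabilities) != 7:
            raise ValueError("need exactly 7 category probabilities")
        for name in ("n_chromosomes", "chrom_length", "n_genes", "n_enhancers"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.accessibility_fold < 1:
            raise ValueError("accessibility_fold must be >= 1 (1 = null)")


@dataclass(frozen=True)
class PlantedEnhancer:
    chrom: str
    pos: int
    category: int
    flags: Tuple[bool, bool, bool]


@dataclass
class GroundTruth:
    """Planted structure sufficient to score every pipeline stage."""

    enhancers: List[PlantedEnhancer]
    diff_windows: List[GenomicInterval]  # windows carrying the accessibility fold
    specific_a: Set[str]
    specific_b: Set[str]
    associations: Dict[str, List[int]]  # gene_id -> planted enhancer indices


_STAGE_NAMES = ("genome", "enhancers", "fragments", "peaks", "fpkm")


def _stage_rngs(seed: int) -> Dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STAGE_NAMES))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STAGE_NAMES, children)}


def make_genome(config: SimulationConfig) -> GenomeAnnotation:
    """Place non-overlapping genes with at least ``min_gap`` between bodies."""
    rng = _stage_rngs(config.seed)["genome"]
    per_chrom = [
        config.n_genes // config.n_chromosomes
        + (1 if i < config.n_genes % config.n_chromosomes else 0)
        for i in range(config.n_chromosomes)
    ]
    genes: List[GeneModel] = []
    sizes: Dict[str, int] = {}
    for ci, n in enumerate(per_chrom):
        chrom = f"chr{ci + 1}"
        sizes[chrom] = config.chrom_length
        lengths = rng.integers(config.gene_length[0], config.gene_length[1] + 1, size=n)
        needed = int(lengths.sum()) + (n + 1) * config.min_gap
        if needed > config.chrom_length:
            raise ValueError(
                f"{n} genes do not fit on {chrom}: need {needed} bp, have "
                f"{config.chrom_length}; reduce n_genes or gene_length, or grow "
                "chrom_length"
            )
        slack = config.chrom_length - needed
        extra = rng.multinomial(slack, [1.0 / (n + 1)] * (n + 1))
        pos = 0
        for gi in range(n):
            pos += config.min_gap + int(extra[gi])
            strand = "+" if rng.random() < 0.5 else "-"
            iv = GenomicInterval(chrom, pos, pos + int(lengths[gi]), strand)
            genes.append(GeneModel(f"gene_{chrom}_{gi + 1:03d}", iv))
            pos = iv.end
    return GenomeAnnotation(genes, chrom_sizes=sizes)


def plant_enhancers(
    annotation: GenomeAnnotation,
    config: SimulationConfig,
    category_map: CategoryMap = DEFAULT_CATEGORY_MAP,
) -> List[PlantedEnhancer]:
    """Draw enhancer positions outside promoter masks, with known categories.

    Positions keep at least two windows of separation so each planted
    enhancer occupies its own detection window, and one detection window of
    clearance from every promoter mask so the window footprint around a
    planted enhancer is unambiguously promoter-distal.
    """
    rng = _stage_rngs(config.seed)["enhancers"]
    mask = promoter_regions(annotation, flank=config.promoter_flank)
    mask_by_chrom: Dict[str, List[GenomicInterval]] = {}
    for iv in mask:
        mask_by_chrom.setdefault(iv.chrom, []).append(iv)
    chroms = sorted(annotation.chrom_sizes)
    cats = rng.choice(np.arange(1, 8), size=config.n_enhancers,
                      p=np.asarray(config.category_probabilities))
    out: List[PlantedEnhancer] = []
    taken: Dict[str, List[int]] = {c: [] for c in chroms}
    min_sep = 2 * config.window
    margin = config.window
    attempts = 0
    while len(out) < config.n_enhancers:
        attempts += 1
        if attempts > 200 * config.n_enhancers:
            raise ValueError(
                "could not place enhancers outside promoter masks; reduce "
                "n_enhancers or promoter_flank, or grow the genome"
            )
        chrom = chroms[int(rng.integers(len(chroms)))]
        size = annotation.chrom_sizes[chrom]
        pos = int(rng.integers(margin, size - margin))
        if any(
            iv.start - config.window <= pos < iv.end + config.window
            for iv in mask_by_chrom.get(chrom, [])
        ):
            continue
        if any(abs(pos - p) < min_sep for p in taken[chrom]):
            continue
        cat = int(cats[len(out)])
        out.append(PlantedEnhancer(chrom, pos, cat, category_map.flags(cat)))
        taken[chrom].append(pos)
    return sorted(out, key=lambda e: (e.chrom, e.pos))


def _window_counts_draw(
    rng: np.random.Generator, means: np.ndarray, dispersion: float
) -> np.ndarray:
    if math.isinf(dispersion):
        return rng.poisson(means)
    p = dispersion / (dispersion + means)
    return rng.negative_binomial(dispersion, p)


def simulate_fragments(
    annotation: GenomeAnnotation,
    enhancers: Sequence[PlantedEnhancer],
    config: SimulationConfig,
) -> Tuple[FragmentSet, FragmentSet, List[GenomicInterval]]:
    """Two fragment libraries with the accessibility fold planted in A only.

    Non-overlapping windows of ``config.window`` tile each chromosome; window
    counts are Poisson/NB at ``mean_depth``, multiplied by
    ``accessibility_fold`` in condition A for windows containing a planted
    enhancer.  Fragments fall uniformly inside their window with lognormal
    lengths; exact duplicates are injected at ``duplicate_rate`` to exercise
    deduplication.  Returns the libraries plus the list of planted windows.
    """
    rng = _stage_rngs(config.seed)["fragments"]
    w = config.window
    planted: Dict[str, Set[int]] = {}
    for e in enhancers:
        planted.setdefault(e.chrom, set()).add(e.pos // w)
    diff_windows: List[GenomicInterval] = []
    records = {"A": [], "B": []}  # type: Dict[str, List[Tuple[str, int, int]]]
    mu_len = math.log(config.fragment_length_median)
    for chrom in sorted(annotation.chrom_sizes):
        size = annotation.chrom_sizes[chrom]
        n_win = size // w
        planted_idx = planted.get(chrom, set())
        for cond in ("A", "B"):
            means = np.full(n_win, config.mean_depth)
            if cond == "A" and planted_idx:
                means[sorted(planted_idx)] *= config.accessibility_fold
            counts = _window_counts_draw(rng, means, config.dispersion)
            for wi in range(n_win):
                k = int(counts[wi])
                if k == 0:
                    continue
                starts = rng.integers(wi * w, (wi + 1) * w, size=k)
                lengths = np.maximum(
                    1,
                    np.rint(
                        rng.lognormal(mu_len, config.fragment_length_sigma, size=k)
                    ).astype(int),
                )
                ends = np.minimum(starts + lengths, size)
                for s, e in zip(starts, ends):
                    if e > s:
                        records[cond].append((chrom, int(s), int(e)))
        for wi in sorted(planted_idx):
            diff_windows.append(GenomicInterval(chrom, wi * w, min((wi + 1) * w, size)))
    for cond in ("A", "B"):
        recs = records[cond]
        n_dup = int(round(config.duplicate_rate * len(recs)))
        if n_dup:
            idx = rng.integers(len(recs), size=n_dup)
            recs.extend(recs[i] for i in idx)
    return (
        FragmentSet.from_records(records["A"]),
        FragmentSet.from_records(records["B"]),
        diff_windows,
    )


def simulate_peaks(
    annotation: GenomeAnnotation,
    enhancers: Sequence[PlantedEnhancer],
    config: SimulationConfig,
) -> Tuple[Dict[str, PeakSet], RegionSet]:
    """One peak per planted enhancer per true-flag source, plus a blacklist.

    Peak boundaries and summits are jittered around the planted position;
    decoy peaks are dropped inside blacklist regions (placed away from
    planted enhancers) to exercise blacklist filtering.
    """
    rng = _stage_rngs(config.seed)["peaks"]
    peaks: Dict[str, List[Peak]] = {s: [] for s in SOURCES}
    for e in enhancers:
        size = annotation.chrom_sizes[e.chrom]
        for si, source in enumerate(SOURCES):
            if not e.flags[si]:
                continue
            hw = int(rng.integers(config.peak_halfwidth[0], config.peak_halfwidth[1] + 1))
            js = int(rng.integers(-config.boundary_jitter, config.boundary_jitter + 1))
            je = int(rng.integers(-config.boundary_jitter, config.boundary_jitter + 1))
            start = max(0, e.pos - hw + js)
            end = min(size, e.pos + hw + je)
            if config.summit_jitter > 0:
                smt = e.pos + int(
                    rng.integers(-config.summit_jitter, config.summit_jitter + 1)
                )
            else:
                smt = e.pos
            smt = min(max(smt, start), end - 1)
            score = float(rng.uniform(5.0, 50.0))
            peaks[source].append(Peak(GenomicInterval(e.chrom, start, end), smt, score))

    chroms = sorted(annotation.chrom_sizes)
    blacklist: List[GenomicInterval] = []
    guard = 2 * config.window
    attempts = 0
    while len(blacklist) < config.n_blacklist and attempts < 10_000:
        attempts += 1
        chrom = chroms[int(rng.integers(len(chroms)))]
        size = annotation.chrom_sizes[chrom]
        start = int(rng.integers(0, max(1, size - config.blacklist_length)))
        iv = GenomicInterval(chrom, start, start + config.blacklist_length)
        if any(
            e.chrom == chrom and start - guard <= e.pos < iv.end + guard
            for e in enhancers
        ):
            continue
        if any(b.chrom == chrom and b.start < iv.end and start < b.end for b in blacklist):
            continue
        blacklist.append(iv)
    for di in range(config.n_decoy_peaks):
        if not blacklist:
            break
        bl = blacklist[di % len(blacklist)]
        source = SOURCES[di % len(SOURCES)]
        center = (bl.start + bl.end) // 2 + int(rng.integers(-200, 201))
        hw = int(rng.integers(config.peak_halfwidth[0], config.peak_halfwidth[1] + 1))
        start = max(bl.start, center - hw)
        end = min(bl.end, center + hw)
        peaks[source].append(
            Peak(GenomicInterval(bl.chrom, start, end), center, float(rng.uniform(5, 50)))
        )
    return (
        {s: PeakSet(sorted(ps, key=lambda p: (p.interval.chrom, p.interval.start)), s)
         for s, ps in peaks.items()},
        RegionSet(sorted(blacklist), label="blacklist"),
    )


def simulate_fpkm(
    annotation: GenomeAnnotation, config: SimulationConfig
) -> Tuple[FPKMTable, Set[str], Set[str]]:
    """FPKM table with planted group-specific genes (two groups x two stages).

    Baseline expression is lognormal; planted A-specific genes get
    ``specific_fold`` in group A at both stages (B symmetric); multiplicative
    lognormal noise with ``fpkm_sigma`` on every cell.
    """
    if config.n_specific_genes_a + config.n_specific_genes_b > config.n_genes:
        raise ValueError("more specific genes requested than genes exist")
    rng = _stage_rngs(config.seed)["fpkm"]
    gene_ids = [g.gene_id for g in annotation.genes()]
    n = len(gene_ids)
    chosen = rng.choice(n, size=config.n_specific_genes_a + config.n_specific_genes_b,
                        replace=False)
    planted_a = {gene_ids[i] for i in chosen[: config.n_specific_genes_a]}
    planted_b = {gene_ids[i] for i in chosen[config.n_specific_genes_a:]}
    baseline = rng.lognormal(
        math.log(config.fpkm_baseline_median), config.fpkm_baseline_sigma, size=n
    )
    samples = {
        "NotoP_E8.5": ("NotoP", "E8.5"),
        "NotoP_E9.5": ("NotoP", "E9.5"),
        "MP_E8.5": ("MP", "E8.5"),
        "MP_E9.5": ("MP", "E9.5"),
    }
    values = {}
    for sample, (pop, _stage) in samples.items():
        col = baseline.copy()
        for i, g in enumerate(gene_ids):
            if pop == "NotoP" and g in planted_a:
                col[i] *= config.specific_fold
            elif pop == "MP" and g in planted_b:
                col[i] *= config.specific_fold
        if config.fpkm_sigma > 0:
            col = col * np.exp(rng.normal(0.0, config.fpkm_sigma, size=n))
        values[sample] = col
    df = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"))
    return FPKMTable(df, samples), planted_a, planted_b


def _true_associations(
    annotation: GenomeAnnotation, enhancers: Sequence[PlantedEnhancer]
) -> Dict[str, List[int]]:
    """Independent linear-scan bookkeeping of enhancer-in-domain pairs."""
    out: Dict[str, List[int]] = {}
    for chrom, gs in annotation.by_chrom.items():
        size = annotation.chrom_sizes.get(chrom, max(g.end for g in gs))
        for g in gs:
            left = [o for o in gs if o.gene_id != g.gene_id and o.end <= g.start]
            right = [o for o in gs if o.gene_id != g.gene_id and o.start >= g.end]
            dom_lo = max(left, key=lambda o: (o.end, o.gene_id)).start if left else 0
            dom_hi = min(right, key=lambda o: (o.start, o.gene_id)).end if right else size
            hits = [
                ei
                for ei, e in enumerate(enhancers)
                if e.chrom == chrom and dom_lo <= e.pos < dom_hi
            ]
            out[g.gene_id] = hits
    return out


def build_ground_truth(config: SimulationConfig) -> Tuple[
    GenomeAnnotation,
    GroundTruth,
    Tuple[FragmentSet, FragmentSet],
    Dict[str, PeakSet],
    RegionSet,
    FPKMTable,
]:
    """Run all generators for one config in the fixed stage order."""
    annotation = make_genome(config)
    enhancers = plant_enhancers(annotation, config)
    frag_a, frag_b, diff_windows = simulate_fragments(annotation, enhancers, config)
    peaks, blacklist = simulate_peaks(annotation, enhancers, config)
    fpkm, planted_a, planted_b = simulate_fpkm(annotation, config)
    truth = GroundTruth(
        enhancers=list(enhancers),
        diff_windows=diff_windows,
        specific_a=planted_a,
        specific_b=planted_b,
        associations=_true_associations(annotation, enhancers),
    )
    return annotation, truth, (frag_a, frag_b), peaks, blacklist, fpkm


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def emit_fixture(config: SimulationConfig, outdir) -> Path:
    """Write the full fixture plus ground truth and a checksummed manifest.

    Returns the manifest path.  Also writes ``pipeline.yaml``, a ready-to-run
    pipeline configuration pointing at the emitted files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    annotation, truth, (frag_a, frag_b), peaks, blacklist, fpkm = build_ground_truth(
        config
    )

    files: List[Tuple[str, str, str]] = []  # (role, name, truth_ref)

    def _emit(role: str, name: str, writer, truth_ref: str = "-") -> None:
        path = outdir / name
        writer(path)
        files.append((role, name, truth_ref))

    _emit("annotation", "genes.bed", lambda p: write_gene_bed(annotation, p))
    _emit("chrom_sizes", "chrom.sizes",
          lambda p: write_chrom_sizes(annotation.chrom_sizes, p))
    _emit("fragments_a", "atac_notop.bed",
          lambda p: write_fragments_bed(frag_a, p), "truth_enhancers.tsv")
    _emit("fragments_b", "atac_mp.bed", lambda p: write_fragments_bed(frag_b, p))
    for source, fname in (
        ("T_NMP", "peaks_t_nmp.narrowPeak"),
        ("T_NotoP", "peaks_t_notop.narrowPeak"),
        ("Foxa2", "peaks_foxa2.narrowPeak"),
    ):
        _emit(f"peaks_{source}", fname,
              lambda p, s=source: write_narrowpeak(peaks[s], p), "truth_enhancers.tsv")
    _emit("blacklist", "blacklist.bed",
          lambda p: write_bed(blacklist.intervals, p))
    _emit("fpkm", "fpkm.tsv", lambda p: write_fpkm_tsv(fpkm, p),
          "truth_specific_a.txt")

    def _write_truth_enhancers(path: Path) -> None:
        with open(path, "w") as fh:
            fh.write("index\tchrom\tpos\tcategory\thas_T_NMP\thas_T_NotoP\thas_Foxa2\n")
            for i, e in enumerate(truth.enhancers):
                fh.write(
                    f"{i}\t{e.chrom}\t{e.pos}\t{e.category}\t"
                    f"{int(e.flags[0])}\t{int(e.flags[1])}\t{int(e.flags[2])}\n"
                )

    def _write_truth_associations(path: Path) -> None:
        with open(path, "w") as fh:
            fh.write("gene_id\tenhancer_indices\n")
            for gene_id in sorted(truth.associations):
                idxs = ",".join(map(str, truth.associations[gene_id]))
                fh.write(f"{gene_id}\t{idxs}\n")

    _emit("truth_enhancers", "truth_enhancers.tsv", _write_truth_enhancers)
    _emit("truth_specific_a", "truth_specific_a.txt",
          lambda p: write_gene_set(truth.specific_a, p))
    _emit("truth_specific_b", "truth_specific_b.txt",
          lambda p: write_gene_set(truth.specific_b, p))
    _emit("truth_associations", "truth_associations.tsv", _write_truth_associations)

    pipeline_cfg = {
        "annotation": "genes.bed",
        "annotation_dialect": "gene-bed",
        "chrom_sizes": "chrom.sizes",
        "fragments_a": "atac_notop.bed",
        "fragments_b": "atac_mp.bed",
        "peaks_t_nmp": "peaks_t_nmp.narrowPeak",
        "peaks_t_notop": "peaks_t_notop.narrowPeak",
        "peaks_foxa2": "peaks_foxa2.narrowPeak",
        "blacklist": "blacklist.bed",
        "fpkm": "fpkm.tsv",
        "sample_groups": {
            s: list(g) for s, g in sorted(fpkm.sample_groups.items())
        },
        "window": config.window,
        "step": 100,
        "alpha": 0.05,
        "min_fold": 2.0,
        "promoter_flank": config.promoter_flank,
        "specific_fold": 3.0,
        "expression_floor": 1.0,
        "drop_chroms": ["chrY", "chrM"],
        "seed": config.seed,
    }
    with open(outdir / "pipeline.yaml", "w") as fh:
        yaml.safe_dump(pipeline_cfg, fh, sort_keys=True)
    files.append(("pipeline_config", "pipeline.yaml", "-"))

    manifest = outdir / "manifest.tsv"
    with open(manifest, "w") as fh:
        fh.write("role\tpath\tsha256\ttruth_ref\n")
        for role, name, truth_ref in files:
            fh.write(f"{role}\t{name}\t{_sha256(outdir / name)}\t{truth_ref}\n")
    return manifest
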