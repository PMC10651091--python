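"""End-to-end pipeline runner and run reporting.

Stage order: fragment loading and deduplication -> sliding-window G-test
differential accessibility -> promoter exclusion -> blacklist filtering and
combinatorial TF categorization -> summit/differential-region intersection ->
target-gene assignment -> specific-gene calling, association, and UpSet
tabulation.  Every intermediate is written to the output directory together
with a machine-readable report of stage counts and parameters; re-running an
identical configuration reproduces identical bytes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import pandas as pd
import yaml

from . import __version__
from .categories import (
    DEFAULT_CATEGORY_MAP,
    CategoryMap,
    EnhancerTable,
    anchor_maxima,
    category_fractions,
    combinatorial_profiles,
    intersect_maxima,
    read_narrowpeak,
    remove_blacklisted,
    t_binding_summary,
    write_enhancer_bed,
)
from .diffaccess import (
    detect_differential,
    exclude_promoters,
    window_counts,
    write_differential_bed,
)
from .fragments import (
    DEFAULT_DROP_CHROMS,
    coverage,
    deduplicate_fragments,
    drop_chromosomes,
    read_fragments_bed,
)
from .genes import (
    associate,
    classify_expression,
    read_fpkm_tsv,
    specific_genes,
    upset_table,
    write_gene_map_tsv,
    write_gene_set,
    write_upset_tsv,
)
from .intervals import read_annotation, read_bed, read_chrom_sizes

logger = logging.getLogger(__name__)

#: Named category groups reported by default (T binding alone; Foxa2 alone).
DEFAULT_REPORT_GROUPS = {"t_only": (2, 4, 6), "foxa2_only": (7,)}


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    annotation: str
    fragments_a: str
    fragments_b: str
    peaks_t_nmp: str
    peaks_t_notop: str
    peaks_foxa2: str
    fpkm: str
    sample_groups: Dict[str, Tuple[str, str]]
    annotation_dialect: str = "gene-bed"
    chrom_sizes: Optional[str] = None
    blacklist: Optional[str] = None
    window: int = 1000
    step: int = 100
    alpha: float = 0.05
    min_fold: float = 2.0
    promoter_flank: int = 5000
    specific_fold: float = 3.0
    expression_floor: float = 1.0
    drop_chroms: Tuple[str, ...] = tuple(sorted(DEFAULT_DROP_CHROMS))
    category_map: Optional[Dict[str, int]] = None  # e.g. {"101": 1, ...}
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        base = path.parent

        def _resolve(value):
            return str((base / value)) if value else value

        for key in (
            "annotation",
            "chrom_sizes",
            "fragments_a",
            "fragments_b",
            "peaks_t_nmp",
            "peaks_t_notop",
            "peaks_foxa2",
            "blacklist",
            "fpkm",
        ):
            if raw.get(key):
                raw[key] = _resolve(raw[key])
        if "sample_groups" in raw:
            raw["sample_groups"] = {
                s: tuple(g) for s, g in raw["sample_groups"].items()
            }
        if "drop_chroms" in raw:
            raw["drop_chroms"] = tuple(raw["drop_chroms"])
        return cls(**raw)

    def resolved_category_map(self) -> CategoryMap:
        if self.category_map is None:
            return DEFAULT_CATEGORY_MAP
        table = {
            tuple(ch == "1" for ch in key): cat
            for key, cat in self.category_map.items()
        }
        return CategoryMap(table)  # type: ignore[arg-type]


@dataclass
class RunResult:
    outdir: Path
    stage_counts: Dict[str, int]
    fractions: Dict[str, float]
    association_summary: Dict[str, object]
    files: List[str]
    parameters: Dict[str, object]


def run_pipeline(config: PipelineConfig, outdir, overwrite: bool = False) -> RunResult:
    """Execute every stage and write all intermediates plus a run report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report_path = outdir / "report.tsv"
    if report_path.exists() and not overwrite:
        raise PipelineError(
            "setup", FileExistsError(f"{report_path} exists; pass overwrite")
        )

    counts: Dict[str, int] = {}
    files: List[str] = []

    def _stage(name: str):
        logger.info("pipeline stage: %s", name)
        return name

    stage = _stage("load_inputs")
    try:
        sizes = read_chrom_sizes(config.chrom_sizes) if config.chrom_sizes else None
        annotation = read_annotation(
            config.annotation, dialect=config.annotation_dialect, chrom_sizes=sizes
        )
        frag_a = read_fragments_bed(config.fragments_a)
        frag_b = read_fragments_bed(config.fragments_b)
    except Exception as exc:  # noqa: BLE001 - stage attribution
        raise PipelineError(stage, exc) from exc

    stage = _stage("fragment_filtering")
    try:
        counts["fragments_a_raw"] = frag_a.library_size
        counts["fragments_b_raw"] = frag_b.library_size
        frag_a = drop_chromosomes(deduplicate_fragments(frag_a), config.drop_chroms)
        frag_b = drop_chromosomes(deduplicate_fragments(frag_b), config.drop_chroms)
        counts["fragments_a_dedup"] = frag_a.library_size
        counts["fragments_b_dedup"] = frag_b.library_size
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    stage = _stage("differential_accessibility")
    try:
        wc = window_counts(
            frag_a, frag_b, window=config.window, step=config.step, chrom_sizes=sizes
        )
        counts["windows_tested"] = len(wc)
        diff_all = detect_differential(
            wc,
            frag_a.library_size,
            frag_b.library_size,
            alpha=config.alpha,
            min_fold=config.min_fold,
            merge_gap=config.step,
        )
        counts["differential_regions"] = len(diff_all)
        write_differential_bed(diff_all, outdir / "differential_all.bed")
        files.append("differential_all.bed")
        diff_distal = exclude_promoters(
            diff_all, annotation, flank=config.promoter_flank
        )
        counts["differential_distal"] = len(diff_distal)
        counts["differential_distal_a_up"] = sum(
            1 for r in diff_distal if r.direction == "A_up"
        )
        write_differential_bed(diff_distal, outdir / "differential_distal.bed")
        files.append("differential_distal.bed")
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    stage = _stage("tf_categorization")
    try:
        category_map = config.resolved_category_map()
        peak_sets = {
            "T_NMP": read_narrowpeak(config.peaks_t_nmp, "T_NMP"),
            "T_NotoP": read_narrowpeak(config.peaks_t_notop, "T_NotoP"),
            "Foxa2": read_narrowpeak(config.peaks_foxa2, "Foxa2"),
        }
        for name, ps in peak_sets.items():
            counts[f"peaks_{name}_raw"] = len(ps)
        if config.blacklist:
            blacklist = read_bed(config.blacklist, label="blacklist")
            peak_sets = {
                name: remove_blacklisted(ps, blacklist)
                for name, ps in peak_sets.items()
            }
        for name, ps in peak_sets.items():
            counts[f"peaks_{name}_filtered"] = len(ps)
        profiles = combinatorial_profiles(
            peak_sets["T_NMP"],
            peak_sets["T_NotoP"],
            peak_sets["Foxa2"],
            category_map=category_map,
        )
        counts["binding_profiles"] = len(profiles)
        cov = coverage(frag_a, bin_size=10, chrom_sizes=sizes)
        for prof in profiles:
            anchor_maxima(prof, coverage=cov)
        enhancers = intersect_maxima(profiles, diff_distal, category_map=category_map)
        counts["enhancers"] = len(enhancers)
        write_enhancer_bed(enhancers, outdir / "enhancers.bed")
        files.append("enhancers.bed")
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    stage = _stage("expression_classes")
    try:
        fpkm = read_fpkm_tsv(config.fpkm, config.sample_groups)
        pops = sorted({p for p, _ in config.sample_groups.values()})
        if len(pops) != 2:
            raise ValueError(f"need exactly two populations, got {pops}")
        pop_a = "NotoP" if "NotoP" in pops else pops[0]
        pop_b = next(p for p in pops if p != pop_a)
        spec_a, spec_b = specific_genes(
            fpkm, pop_a, pop_b, fold=config.specific_fold
        )
        counts["specific_genes_a"] = len(spec_a)
        counts["specific_genes_b"] = len(spec_b)
        classes = classify_expression(
            fpkm, spec_a, spec_b, expression_floor=config.expression_floor,
            labels=(f"{pop_a}_specific", f"{pop_b}_specific"),
        )
        write_gene_set(spec_a, outdir / "specific_genes_a.txt")
        write_gene_set(spec_b, outdir / "specific_genes_b.txt")
        files.extend(["specific_genes_a.txt", "specific_genes_b.txt"])
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    stage = _stage("gene_association")
    try:
        emap, assoc_summary = associate(
            spec_a, enhancers, annotation, flank=config.promoter_flank
        )
        counts["genes_with_enhancer"] = int(assoc_summary["n_with_enhancer"])
        write_gene_map_tsv(emap, outdir / "enhancer_gene_map.tsv")
        files.append("enhancer_gene_map.tsv")
        upset = upset_table(emap, spec_a)
        write_upset_tsv(upset, outdir / "upset.tsv")
        files.append("upset.tsv")
        class_counts = pd.Series(classes).value_counts().sort_index()
        class_counts.rename("n_genes").to_csv(
            outdir / "expression_classes.tsv", sep="\t", index_label="class"
        )
        files.append("expression_classes.tsv")
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    stage = _stage("report")
    try:
        if len(enhancers):
            fractions = category_fractions(enhancers, DEFAULT_REPORT_GROUPS)
        else:
            fractions = {name: 0.0 for name in DEFAULT_REPORT_GROUPS}
        parameters = {
            "version": __version__,
            "seed": config.seed,
            "window": config.window,
            "step": config.step,
            "alpha": config.alpha,
            "min_fold": config.min_fold,
            "promoter_flank": config.promoter_flank,
            "specific_fold": config.specific_fold,
            "expression_floor": config.expression_floor,
            "drop_chroms": ",".join(config.drop_chroms),
        }
        result = RunResult(
            outdir=outdir,
            stage_counts=counts,
            fractions=fractions,
            association_summary=assoc_summary,
            files=files,
            parameters=parameters,
        )
        write_report(result)
        result.files.extend(["report.tsv", "report.txt"])
    except Exception as exc:
        raise PipelineError(stage, exc) from exc
    return result


def write_report(result: RunResult) -> None:
    """Emit the machine-readable (TSV) and human-readable (text) summaries."""
    rows: List[Tuple[str, str, str]] = []
    for key in sorted(result.stage_counts):
        rows.append(("count", key, str(result.stage_counts[key])))
    for name in sorted(result.fractions):
        rows.append(("fraction_pct", name, format(result.fractions[name], ".1f")))
    s = result.association_summary
    rows.append(("association", "n_genes", str(s["n_genes"])))
    rows.append(("association", "n_with_enhancer", str(s["n_with_enhancer"])))
    rows.append(("association", "percent", format(float(s["percent"]), ".1f")))
    for key in sorted(result.parameters):
        rows.append(("parameter", key, str(result.parameters[key])))
    for name in sorted(result.files):
        rows.append(("output_file", name, name))
    with open(result.outdir / "report.tsv", "w") as fh:
        fh.write("section\tkey\tvalue\n")
        for section, key, value in rows:
            fh.write(f"{section}\t{key}\t{value}\n")

    with open(result.outdir / "report.txt", "w") as fh:
        fh.write("enhancer discovery pipeline run summary\n")
        fh.write("=======================================\n\n")
        fh.write("stage counts:\n")
        for key in sorted(result.stage_counts):
            fh.write(f"  {key}: {result.stage_counts[key]}\n")
        fh.write("\ncategory fractions:\n")
        for name in sorted(result.fractions):
            fh.write(f"  {name}: {result.fractions[name]:.1f}%\n")
        fh.write(
            f"\ngene association: {s['n_with_enhancer']} of {s['n_genes']} "
            f"({float(s['percent']):.1f}%) genes with >=1 enhancer\n"
        )
        fh.write("\nparameters:\n")
        for key in sorted(result.parameters):
            fh.write(f"  {key}: {result.parameters[key]}\n")
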