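import numpy as np
import pandas as pd
import pytest

from enhancerscan.categories import EnhancerRow, EnhancerTable
from enhancerscan.genes import (
    DOWNSTREAM,
    HOST,
    UPSTREAM,
    EnhancerGeneMap,
    FPKMTable,
    assign_target_genes,
    associate,
    classify_expression,
    fpkm_from_counts,
    gene_domain,
    normalize_per_gene,
    set_overlap,
    specific_genes,
    upset_table,
)
from enhancerscan.intervals import GeneModel, GenomeAnnotation, GenomicInterval

from conftest import random_annotation


def _fpkm(values: dict, genes) -> FPKMTable:
    groups = {
        "NotoP_E8.5": ("NotoP", "E8.5"),
        "NotoP_E9.5": ("NotoP", "E9.5"),
        "MP_E8.5": ("MP", "E8.5"),
        "MP_E9.5": ("MP", "E9.5"),
    }
    df = pd.DataFrame(values, index=genes)
    return FPKMTable(df, groups)


def _row(chrom, start, end, anchor, category=7, flags=(False, False, True)):
    return EnhancerRow(GenomicInterval(chrom, start, end), category, anchor, flags)


class TestFPKMFromCounts:
    def test_direct_arithmetic(self):
        counts = pd.DataFrame({"s1": [100, 0]}, index=["g1", "g2"])
        out = fpkm_from_counts(counts, {"g1": 1000, "g2": 500}, {"s1": 10**6})
        assert out.loc["g1", "s1"] == pytest.approx(100.0)
        assert out.loc["g2", "s1"] == 0.0

    def test_zero_length_or_total_rejected(self):
        counts = pd.DataFrame({"s1": [1]}, index=["g"])
        with pytest.raises(ValueError):
            fpkm_from_counts(counts, {"g": 0}, {"s1": 100})
        with pytest.raises(ValueError):
            fpkm_from_counts(counts, {"g": 100}, {"s1": 0})

    def test_matches_independent_recomputation(self, rng):
        genes = [f"g{i}" for i in range(10)]
        counts = pd.DataFrame(
            rng.integers(0, 500, size=(10, 3)), index=genes, columns=list("abc")
        )
        lengths = {g: int(rng.integers(200, 5000)) for g in genes}
        totals = {s: int(rng.integers(10**5, 10**6)) for s in "abc"}
        out = fpkm_from_counts(counts, lengths, totals)
        for g in genes:
            for s in "abc":
                exp = counts.loc[g, s] * 1e9 / (lengths[g] * totals[s])
                assert out.loc[g, s] == pytest.approx(exp)


class TestSpecificGenes:
    def test_boundary_inclusive_without_pseudocount(self):
        table = _fpkm(
            {"NotoP_E8.5": [9.0], "NotoP_E9.5": [9.0], "MP_E8.5": [3.0], "MP_E9.5": [3.0]},
            ["g"],
        )
        a, b = specific_genes(table, "NotoP", "MP", fold=3, pseudocount=0.0)
        assert a == {"g"} and b == set()

    def test_conjunction_over_stages(self):
        table = _fpkm(
            {"NotoP_E8.5": [9.0], "NotoP_E9.5": [2.0], "MP_E8.5": [3.0], "MP_E9.5": [3.0]},
            ["g"],
        )
        a, b = specific_genes(table, "NotoP", "MP", fold=3, pseudocount=0.0)
        assert a == set() and b == set()

    def test_sets_disjoint_for_any_fold(self, rng):
        genes = [f"g{i}" for i in range(50)]
        table = _fpkm(
            {
                s: rng.lognormal(2, 1, size=50)
                for s in ("NotoP_E8.5", "NotoP_E9.5", "MP_E8.5", "MP_E9.5")
            },
            genes,
        )
        for fold in (1.5, 3.0, 10.0):
            a, b = specific_genes(table, "NotoP", "MP", fold=fold)
            assert not a & b

    def test_missing_stage_errors(self):
        df = pd.DataFrame({"NotoP_E8.5": [1.0], "MP_E8.5": [1.0]}, index=["g"])
        table = FPKMTable(
            df, {"NotoP_E8.5": ("NotoP", "E8.5"), "MP_E8.5": ("MP", "E8.5")}
        )
        # only one shared stage is fine; mismatched stage sets are not
        df2 = pd.DataFrame(
            {"NotoP_E8.5": [1.0], "MP_E9.5": [1.0]}, index=["g"]
        )
        table2 = FPKMTable(
            df2, {"NotoP_E8.5": ("NotoP", "E8.5"), "MP_E9.5": ("MP", "E9.5")}
        )
        with pytest.raises(ValueError):
            specific_genes(table2, "NotoP", "MP")
        specific_genes(table, "NotoP", "MP")  # does not raise


class TestClassifyExpression:
    def test_four_way_classes(self):
        table = _fpkm(
            {
                "NotoP_E8.5": [0.0, 30.0, 5.0],
                "NotoP_E9.5": [0.2, 30.0, 5.0],
                "MP_E8.5": [0.0, 2.0, 5.0],
                "MP_E9.5": [0.1, 2.0, 5.0],
            },
            ["silent", "noto", "flat"],
        )
        a, b = specific_genes(table, "NotoP", "MP", fold=3)
        classes = classify_expression(table, a, b, expression_floor=1.0)
        assert classes == {
            "silent": "not_expressed",
            "noto": "A_specific",
            "flat": "not_specific",
        }

    def test_tally_matches_hand_count(self, rng):
        genes = [f"g{i}" for i in range(10)]
        cols = {
            s: rng.uniform(0, 10, size=10)
            for s in ("NotoP_E8.5", "NotoP_E9.5", "MP_E8.5", "MP_E9.5")
        }
        table = _fpkm(cols, genes)
        a, b = specific_genes(table, "NotoP", "MP")
        classes = classify_expression(table, a, b)
        n_not_expr = sum(
            1
            for i in range(10)
            if max(cols[s][i] for s in cols) < 1.0
        )
        assert sum(v == "not_expressed" for v in classes.values()) == n_not_expr
        assert len(classes) == 10


class TestAssignTargetGenes:
    def test_genic_anchor_gets_host_and_flanks(self, toy_annotation):
        out = assign_target_genes(("chr1", 45_000), toy_annotation, flank=5000)
        assert {(g.gene_id, rel) for g, rel in out} == {
            ("geneB", HOST),
            ("geneA", UPSTREAM),
            ("geneC", DOWNSTREAM),
        }

    def test_intergenic_anchor_gets_two_flanking_genes(self, toy_annotation):
        out = assign_target_genes(("chr1", 30_000), toy_annotation, flank=5000)
        assert {(g.gene_id, rel) for g, rel in out} == {
            ("geneA", UPSTREAM),
            ("geneB", DOWNSTREAM),
        }

    def test_overlapping_hosts_all_assigned(self):
        genes = [
            GeneModel("host1", GenomicInterval("chr1", 10_000, 30_000, "+")),
            GeneModel("host2", GenomicInterval("chr1", 20_000, 40_000, "-")),
            GeneModel("left", GenomicInterval("chr1", 1_000, 2_000, "+")),
            GeneModel("right", GenomicInterval("chr1", 60_000, 70_000, "+")),
        ]
        ann = GenomeAnnotation(genes, chrom_sizes={"chr1": 100_000})
        out = assign_target_genes(("chr1", 25_000), ann, flank=5000)
        ids = {(g.gene_id, rel) for g, rel in out}
        assert ids == {
            ("host1", HOST),
            ("host2", HOST),
            ("left", UPSTREAM),
            ("right", DOWNSTREAM),
        }

    def test_chromosome_end_yields_single_neighbor(self, toy_annotation):
        out = assign_target_genes(("chr2", 1_000), toy_annotation, flank=5000)
        assert [(g.gene_id, rel) for g, rel in out] == [("geneD", DOWNSTREAM)]

    def test_empty_annotation_errors(self):
        ann = GenomeAnnotation([], chrom_sizes={"chr1": 1000})
        with pytest.raises(ValueError):
            assign_target_genes(("chr1", 10), ann)


class TestGeneDomain:
    def test_spans_neighbor_outer_boundaries(self):
        genes = [
            GeneModel("U", GenomicInterval("chr1", 0 + 1, 100, "+")),
            GeneModel("G", GenomicInterval("chr1", 500, 600, "+")),
            GeneModel("D", GenomicInterval("chr1", 900, 1000, "+")),
        ]
        ann = GenomeAnnotation(genes, chrom_sizes={"chr1": 5000})
        dom = gene_domain(ann.gene("G"), ann)
        assert (dom.start, dom.end) == (1, 1000)

    def test_first_gene_domain_starts_at_zero(self, toy_annotation):
        dom = gene_domain(toy_annotation.gene("geneA"), toy_annotation)
        assert dom.start == 0 and dom.end == 50_000

    def test_last_gene_domain_ends_at_chromosome_length(self, toy_annotation):
        dom = gene_domain(toy_annotation.gene("geneC"), toy_annotation)
        assert dom.end == 120_000

    def test_domain_association_agrees_with_assignment_rule(self, rng):
        """Cross-check of the two target-gene formulations for interior genes."""
        ann = random_annotation(rng, n_genes=15, size=300_000, min_gap=2000)
        genes = list(ann.genes())
        anchors = [int(p) for p in rng.integers(0, 300_000, size=60)]
        for pos in anchors:
            assigned = {
                g.gene_id for g, _ in assign_target_genes(("chr1", pos), ann, flank=1)
            }
            for g in genes[1:-1]:  # interior genes only
                dom = gene_domain(g, ann)
                in_domain = dom.contains(pos)
                assert (g.gene_id in assigned) == in_domain, (pos, g.gene_id)


class TestAssociate:
    def _enhancers(self, positions, chrom="chr1"):
        rows = [
            _row(chrom, p - 100, p + 100, p, category=5, flags=(False, True, True))
            for p in positions
        ]
        return EnhancerTable(rows)

    def test_no_enhancers_is_zero_percent(self, toy_annotation):
        emap, summary = associate(["geneA", "geneB"], EnhancerTable([]), toy_annotation)
        assert summary == {"n_genes": 2, "n_with_enhancer": 0, "percent": 0.0}

    def test_counts_genes_with_anchor_in_domain(self, toy_annotation):
        # anchor between geneA and geneB: in domains of A, B and C (C's domain
        # starts at geneB.start... no: C's upstream neighbour is B, so C's
        # domain starts at 40_000) -> genes A and B only for pos 30_000.
        table = self._enhancers([30_000])
        emap, summary = associate(
            ["geneA", "geneB", "geneC", "geneD"], table, toy_annotation
        )
        assert emap.gene_to_enhancers["geneA"] == [0]
        assert emap.gene_to_enhancers["geneB"] == [0]
        assert emap.gene_to_enhancers["geneC"] == []
        assert emap.gene_to_enhancers["geneD"] == []
        assert summary["n_with_enhancer"] == 2
        assert summary["percent"] == 50.0

    def test_percentage_invariant_under_ordering(self, toy_annotation, rng):
        positions = [int(p) for p in rng.integers(500, 119_000, size=10)]
        genes = ["geneA", "geneB", "geneC"]
        table = self._enhancers(positions)
        _, s1 = associate(genes, table, toy_annotation)
        shuffled = EnhancerTable(list(reversed(table.rows)))
        _, s2 = associate(list(reversed(genes)), shuffled, toy_annotation)
        assert s1["percent"] == s2["percent"]


class TestUpsetTable:
    def _map(self, gene_cats):
        gene_to_enh = {}
        enh_cats = {}
        idx = 0
        for gene, cats in gene_cats.items():
            gene_to_enh[gene] = []
            for c in cats:
                enh_cats[idx] = c
                gene_to_enh[gene].append(idx)
                idx += 1
        return EnhancerGeneMap(gene_to_enh, {}, enh_cats)

    def test_duplicate_categories_collapse_to_set(self):
        emap = self._map({"g1": [3, 3, 5]})
        table = upset_table(emap, ["g1"])
        assert table.iloc[0]["categories"] == "3,5"
        assert table.iloc[0]["count"] == 1

    def test_row_counts_sum_to_genes_with_enhancers(self):
        emap = self._map({"g1": [1], "g2": [1, 2], "g3": [2, 1], "g4": []})
        table = upset_table(emap, ["g1", "g2", "g3", "g4"])
        assert table["count"].sum() == 3
        assert table.iloc[0]["categories"] == "1,2"  # most frequent combination

    def test_matches_brute_force_enumeration(self, rng):
        gene_cats = {
            f"g{i}": [int(c) for c in rng.integers(1, 8, size=rng.integers(0, 5))]
            for i in range(40)
        }
        emap = self._map(gene_cats)
        table = upset_table(emap, list(gene_cats))
        brute = {}
        for cats in gene_cats.values():
            key = ",".join(map(str, sorted(set(cats))))
            if key:
                brute[key] = brute.get(key, 0) + 1
        assert dict(zip(table["categories"], table["count"])) == brute


class TestSetOverlap:
    def test_small_case(self):
        out = set_overlap({"x": {"a", "b"}, "y": {"b", "c"}})
        assert out == {("x",): 1, ("x", "y"): 1, ("y",): 1}

    def test_identical_sets_concentrate_in_full_intersection(self):
        out = set_overlap({"x": {"a", "b"}, "y": {"a", "b"}, "z": {"a", "b"}})
        assert out == {("x", "y", "z"): 2}

    def test_unmatched_identifiers_dropped(self):
        out = set_overlap(
            {"x": {"a", "zz"}, "y": {"a"}}, known_ids={"a"}
        )
        assert out == {("x", "y"): 1}

    def test_matches_bitmask_enumeration(self, rng):
        universe = [f"id{i}" for i in range(60)]
        sets = {
            name: {u for u in universe if rng.random() < 0.4}
            for name in ("s1", "s2", "s3", "s4")
        }
        out = set_overlap(sets)
        names = sorted(sets)
        brute = {}
        for u in set().union(*sets.values()):
            key = tuple(n for n in names if u in sets[n])
            brute[key] = brute.get(key, 0) + 1
        assert out == brute
        with pytest.raises(ValueError):
            set_overlap({"only": {"a"}})


class TestNormalizePerGene:
    def test_row_max_scheme(self):
        df = pd.DataFrame({"a": [2.0, 0.0], "b": [4.0, 0.0]}, index=["g1", "g2"])
        out = normalize_per_gene(df)
        assert out.loc["g1"].tolist() == [0.5, 1.0]
        assert out.loc["g2"].tolist() == [0.0, 0.0]  # zero rows stay zero

    def test_zscore_scheme_centers_rows(self):
        df = pd.DataFrame({"a": [1.0], "b": [3.0], "c": [5.0]}, index=["g"])
        out = normalize_per_gene(df, scheme="zscore")
        assert out.loc["g"].mean() == pytest.approx(0.0)
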