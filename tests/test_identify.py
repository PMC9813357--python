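"""Monophyly testing, query assignment and the locus-combination sweep."""

import numpy as np
import pytest

import woodbarcode as wb
from woodbarcode.identify import GENUS, SPECIES, UNIDENTIFIED

from conftest import dendropy_splits, make_table, random_unrooted_tree


def tree_of(newick):
    return wb.PhyloTree.from_newick(newick)


class TestIsMonophyletic:
    def test_clade_detected(self):
        t = tree_of("((a1,a2),(b1,b2),c1);")
        assert wb.is_monophyletic(t, {"a1", "a2"})
        assert wb.is_monophyletic(t, {"b1", "b2"})

    def test_paraphyly_detected(self):
        t = tree_of("((a1,b1),(a2,b2),c1);")
        assert not wb.is_monophyletic(t, {"a1", "a2"})

    def test_singleton_and_whole_tree(self):
        t = tree_of("((a1,a2),(b1,b2),c1);")
        assert wb.is_monophyletic(t, {"c1"})
        assert wb.is_monophyletic(t, {"a1", "a2", "b1", "b2", "c1"})

    def test_unknown_id_errors(self):
        t = tree_of("((a1,a2),(b1,b2),c1);")
        with pytest.raises(wb.WoodBarcodeError, match="nope"):
            wb.is_monophyletic(t, {"nope"})

    def test_agrees_with_exhaustive_bipartition_scan(self, rng):
        # oracle: a leaf set is monophyletic iff it equals one side of some
        # edge's bipartition, enumerated independently via dendropy
        for _ in range(100):
            t = random_unrooted_tree(rng, 12)
            leaves = t.leaf_ids
            all_sides = dendropy_splits(t, include_trivial=True)
            full = frozenset(leaves)
            sides_both = all_sides | {full - s for s in all_sides}
            k = int(rng.integers(1, 12))
            ids = frozenset(rng.choice(leaves, size=k, replace=False))
            expected = len(ids) == 1 or ids == full or ids in sides_both
            assert wb.is_monophyletic(t, ids) == expected


class TestCountMonophyleticSpecies:
    def test_all_species_monophyletic(self):
        t = tree_of("((a1,a2),(b1,b2),c1);")
        tbl = make_table(
            {"a1": "G alpha", "a2": "G alpha", "b1": "G beta",
             "b2": "G beta", "c1": "G gamma"}
        )
        assert wb.count_monophyletic_species(t, tbl) == 3

    def test_intermixed_species_only_singleton_counts(self):
        t = tree_of("((a1,b1),(a2,b2),c1);")
        tbl = make_table(
            {"a1": "G alpha", "a2": "G alpha", "b1": "G beta",
             "b2": "G beta", "c1": "G gamma"}
        )
        assert wb.count_monophyletic_species(t, tbl) == 1

    def test_nested_query_does_not_break_monophyly(self):
        t = tree_of("((a1,(a2,q)),(b1,b2),c1);")
        tbl = make_table(
            {"a1": "G alpha", "a2": "G alpha", "b1": "G beta",
             "b2": "G beta", "c1": "G gamma"},
            queries=["q"],
        )
        assert wb.count_monophyletic_species(t, tbl) == 3
        # strict exclusivity demotes alpha
        assert wb.count_monophyletic_species(t, tbl, strict=True) == 2

    def test_matches_per_species_brute_force(self, rng):
        for _ in range(30):
            t = random_unrooted_tree(rng, 10)
            leaves = t.leaf_ids
            species = {
                sid: f"G sp{int(rng.integers(0, 4))}" for sid in leaves
            }
            tbl = make_table(species)
            by_sp = {}
            for sid, sp in species.items():
                by_sp.setdefault(sp, set()).add(sid)
            brute = sum(
                1 for ids in by_sp.values() if wb.is_monophyletic(t, ids)
            )
            assert wb.count_monophyletic_species(t, tbl) == brute


class TestAssignQuery:
    tbl = make_table(
        {"a1": "G alpha", "a2": "G alpha", "b1": "G beta", "b2": "G beta"},
        queries=["q"],
    )

    def test_query_inside_species_clade(self):
        t = tree_of("((a1,a2,q),(b1,b2));")
        r = wb.assign_query(t, self.tbl, "q")
        assert (r.level, r.assigned_species) == (SPECIES, "G alpha")
        assert r.assigned_genus == "G"

    def test_query_sister_to_species_clade(self):
        t = tree_of("((q,(a1,a2)),(b1,b2));")
        r = wb.assign_query(t, self.tbl, "q")
        assert (r.level, r.assigned_species) == (SPECIES, "G alpha")
        # with sister placements disallowed, falls back to genus
        r2 = wb.assign_query(t, self.tbl, "q", sister_ok=False)
        assert r2.level == GENUS

    def test_query_breaking_into_clade_counts_as_inside(self):
        t = tree_of("((a1,(a2,q)),(b1,b2));")
        r = wb.assign_query(t, self.tbl, "q", sister_ok=False)
        assert (r.level, r.assigned_species) == (SPECIES, "G alpha")

    def test_mixed_species_one_genus_gives_genus_level(self):
        t = tree_of("((a1,b1,q),(a2,b2));")
        r = wb.assign_query(t, self.tbl, "q")
        assert (r.level, r.assigned_species) == (GENUS, None)
        assert r.assigned_genus == "G"

    def test_mixed_genera_unidentified(self):
        tbl = make_table(
            {"a1": "Aquilaria alpha", "a2": "Aquilaria alpha",
             "b1": "Dalbergia beta", "b2": "Dalbergia beta"},
            queries=["q"],
        )
        t = tree_of("((a1,b1,q),(a2,b2));")
        r = wb.assign_query(t, tbl, "q")
        assert r.level == UNIDENTIFIED

    def test_min_support_gates_species_call(self):
        t = tree_of("((a1,a2,q)40,(b1,b2));")
        r = wb.assign_query(t, self.tbl, "q", min_support=0.7)
        assert r.level == GENUS
        r2 = wb.assign_query(t, self.tbl, "q", min_support=0.3)
        assert r2.level == SPECIES
        assert r2.support_of_clade == pytest.approx(0.40)

    def test_query_absent_errors(self):
        t = tree_of("((a1,a2),(b1,b2));")
        with pytest.raises(wb.IdentificationError, match="q"):
            wb.assign_query(t, self.tbl, "q")

    def test_simulated_queries_recover_truth(self, bench_default):
        # interspecific divergence 20x intraspecific: every query must land
        # in its true species on the full supermatrix tree
        b = bench_default
        sup = wb.concatenate(b.loci, b.samples)
        t = wb.nj(wb.distance_matrix(sup))
        for qid, true_sp in b.truth.items():
            r = wb.assign_query(t, b.samples, qid)
            assert (r.level, r.assigned_species) == (SPECIES, true_sp)


class TestEvaluateCombinations:
    def test_all_subsets_reported_sorted(self, bench_small):
        rep = wb.evaluate_combinations(bench_small.loci, bench_small.samples)
        labels = [r.combination for r in rep.rows]
        assert labels == [
            ("ITS2",), ("matK",), ("ITS2", "matK"),
        ]

    def test_rate_format_mirrors_published_style(self, bench_small):
        rep = wb.evaluate_combinations(bench_small.loci, bench_small.samples)
        full = rep.row(("ITS2", "matK"))
        assert full.rate_text == "100% (3/3)"

    def test_zero_successes_format(self):
        from woodbarcode.identify import CombinationResult

        r = CombinationResult(("ITS2",), True, 0, 4, 0)
        assert r.rate_text == "0% (0/4)"
        r2 = CombinationResult(("ITS2",), True, 2, 3, 1)
        assert r2.rate_text == "66.67% (2/3)"

    def test_rates_recomputable_from_assignment_lists(self, bench_default):
        rep = wb.evaluate_combinations(
            bench_default.loci, bench_default.samples, max_combo_size=2
        )
        for row in rep.rows:
            recount = sum(
                1 for a in row.assignments if a.level == SPECIES
            )
            assert row.successes == recount
            assert row.total == len(row.assignments)
            assert row.discrimination_rate == pytest.approx(
                recount / row.total
            )

    def test_perfect_benchmark_recovers_everything(self, bench_default):
        rep = wb.evaluate_combinations(
            bench_default.loci, bench_default.samples
        )
        full = rep.row(("ITS2", "matK", "trnL-trnF"))
        assert full.rate_text == "100% (10/10)"
        assert full.monophyletic_clades == 5

    def test_dropout_queries_excluded_with_reasons(self):
        cfg = wb.SimulationConfig(
            seed=4, n_species=3, refs_per_species=2, n_queries=6,
            loci=(("ITS2", 120), ("matK", 140)),
            dropout_prob=1.0, force_locus="ITS2",
        )
        b = wb.make_benchmark(cfg)
        rep = wb.evaluate_combinations(b.loci, b.samples)
        matk_only = rep.row(("matK",))
        assert matk_only.total == 0
        assert len(matk_only.excluded) == 6
        assert all("no locus" in reason for _, reason in matk_only.excluded)
        its2_row = rep.row(("ITS2",))
        assert its2_row.total == 6

    def test_unevaluable_combination_reported_not_fatal(self):
        # matK is saturated between species -> undefined pairs -> the row is
        # flagged not evaluable while other rows still compute
        its2 = wb.AlignedLocus(
            "ITS2",
            {"a1": "A" * 30, "a2": "A" * 30,
             "b1": "A" * 25 + "G" * 5, "b2": "A" * 25 + "G" * 5,
             "q": "A" * 30},
        )
        matk = wb.AlignedLocus(
            "matK",
            {"a1": "A" * 30, "a2": "A" * 30,
             "b1": "G" * 30, "b2": "G" * 30,
             "q": "A" * 30},
        )
        tbl = make_table(
            {"a1": "G alpha", "a2": "G alpha",
             "b1": "G beta", "b2": "G beta"},
            queries=["q"],
        )
        rep = wb.evaluate_combinations([its2, matk], tbl)
        assert not rep.row(("matK",)).evaluable
        assert "undefined" in rep.row(("matK",)).note
        assert rep.row(("ITS2",)).evaluable

    def test_report_tsv_round_trip(self, bench_small, tmp_path):
        rep = wb.evaluate_combinations(bench_small.loci, bench_small.samples)
        rep.to_tsv(tmp_path / "eval.tsv")
        rep.assignments_to_tsv(tmp_path / "assign.tsv")
        lines = (tmp_path / "eval.tsv").read_text().splitlines()
        assert len(lines) == 1 + 3
        assert lines[0].startswith("combination\trate_percent")


class TestIdentifyProduct:
    def test_uses_all_available_loci(self, bench_small):
        b = bench_small
        qid = b.samples.queries()[0]
        r = wb.identify_product(qid, b.loci, b.samples)
        assert r.combination == ("ITS2", "matK")
        assert (r.level, r.assigned_species) == (SPECIES, b.truth[qid])

    def test_single_locus_when_others_dropped(self):
        cfg = wb.SimulationConfig(
            seed=8, n_species=3, refs_per_species=2, n_queries=2,
            loci=(("ITS2", 120), ("matK", 140)),
            dropout_prob=1.0, force_locus="ITS2",
        )
        b = wb.make_benchmark(cfg)
        for qid in b.samples.queries():
            r = wb.identify_product(qid, b.loci, b.samples)
            assert r.combination == ("ITS2",)
            assert r.level == SPECIES
            assert r.assigned_species == b.truth[qid]

    def test_no_shared_locus_errors(self, bench_small):
        b = bench_small
        qid = b.samples.queries()[0]
        loci = [
            wb.AlignedLocus(
                loc.name, {s: v for s, v in loc.rows.items() if s != qid}
            )
            for loc in b.loci
        ]
        with pytest.raises(wb.IdentificationError, match=qid):
            wb.identify_product(qid, loci, b.samples)
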