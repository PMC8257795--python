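import numpy as np
import pytest
from oracles import oracle_fisher_two_sided, oracle_global_identity

from pansyn.models import GeneModel, PangenomeEntry, SimilarityHit
from pansyn.pangenome import (
    HaplotypeComparison,
    absence_runs,
    build_pangenome,
    classify_absence,
    condense_tandem_arrays,
    constrain_to_synteny,
    interval_private_enrichment,
    pav_table,
    percent_identity,
    place_orthogroups,
    project_to_alt_haplotype,
)
from pansyn.synteny import ChainParams


def entry(pan_id, chrom="p1", pos=0.0, members=None):
    members = members or {}
    return PangenomeEntry(
        pan_id=pan_id, pan_chrom=chrom, pan_position=pos,
        members={g: list(v) for g, v in members.items()},
        representative={g: v[0] for g, v in members.items() if v},
    )


class TestConstrainToSynteny:
    def _setup(self):
        genes = [
            GeneModel(f"a{i}", "A", "c1", i * 100, i * 100 + 50, "+", i)
            for i in range(30)
        ] + [
            GeneModel(f"b{i}", "B", "c1", i * 100, i * 100 + 50, "+", i)
            for i in range(30)
        ]
        hits = [SimilarityHit(f"a{i}", f"b{i}", "A", "B", 100.0) for i in range(30)]
        from pansyn.synteny import blocks_between_genomes

        blocks = blocks_between_genomes(hits, genes, ChainParams.pangenome())
        return genes, hits, blocks

    def test_hit_inside_block_retained(self):
        genes, hits, blocks = self._setup()
        kept = constrain_to_synteny(hits, genes, blocks)
        assert len(kept) == 30

    def test_isolated_translocated_hit_removed(self):
        genes, hits, blocks = self._setup()
        # a hit between unrelated far-away genes on chromosomes with no block
        genes = genes + [
            GeneModel("ax", "A", "c9", 0, 50, "+", 0),
            GeneModel("bx", "B", "c8", 0, 50, "+", 0),
        ]
        stray = SimilarityHit("ax", "bx", "A", "B", 100.0)
        kept = constrain_to_synteny(hits + [stray], genes, blocks)
        assert stray not in kept

    def test_homeologous_self_genome_hits_masked(self):
        genes, hits, blocks = self._setup()
        genes = genes + [GeneModel("a_hom", "A", "c2", 0, 50, "+", 0)]
        homeo = SimilarityHit("a0", "a_hom", "A", "A", 80.0)
        kept = constrain_to_synteny(hits + [homeo], genes, blocks)
        assert homeo not in kept

    def test_zero_noise_simulation_recovers_truth_orthogroups(self, small_pangenome):
        sim = small_pangenome
        entries, unplaced = build_pangenome(sim.hits, sim.all_genes(), "genome1")
        assert not unplaced
        truth = {frozenset(v) for v in sim.truth.orthogroups.values()}
        got = {
            frozenset((g, gid) for g in e.members for gid in e.members[g])
            for e in entries
        }
        assert got == truth


class TestCondenseTandemArrays:
    def _genes(self, ranks_chroms):
        return [
            GeneModel(f"g{i}", "A", c, r * 100, r * 100 + 50 + i, "+", r)
            for i, (r, c) in enumerate(ranks_chroms)
        ]

    def test_adjacent_genes_collapse_to_one_array(self):
        from pansyn.models import Orthogroup

        genes = self._genes([(0, "c1"), (1, "c1"), (2, "c1")])
        og = Orthogroup("og1", frozenset(("A", g.gene_id) for g in genes))
        arrays = condense_tandem_arrays([og], genes, [])
        assert [len(a) for a in arrays[("og1", "A")]] == [3]

    def test_different_chromosomes_stay_separate(self):
        from pansyn.models import Orthogroup

        genes = self._genes([(0, "c1"), (0, "c2")])
        og = Orthogroup("og1", frozenset(("A", g.gene_id) for g in genes))
        arrays = condense_tandem_arrays([og], genes, [])
        assert sorted(len(a) for a in arrays[("og1", "A")]) == [1, 1]

    def test_bitscore_tie_prefers_median_centrality(self):
        from pansyn.pangenome import _representative

        genes = self._genes([(0, "c1"), (5, "c1"), (10, "c1")])
        rep = _representative(genes, {})  # all bitscores 0: tie
        assert rep.rank == 5


class TestPlaceOrthogroups:
    def test_single_copy_reference_takes_gene_rank(self, small_pangenome):
        sim = small_pangenome
        entries, _ = build_pangenome(sim.hits, sim.all_genes(), "genome1")
        gene_rank = {
            g.gene_id: (g.chrom, g.rank) for g in sim.genes["genome1"]
        }
        for e in entries:
            if len(e.members.get("genome1", [])) == 1:
                chrom, rank = gene_rank[e.members["genome1"][0]]
                assert (e.pan_chrom, e.pan_position) == (chrom, float(rank))

    def test_reference_absent_takes_mean_syntenic_position(self):
        from pansyn.models import Orthogroup

        # reference A and two other genomes B, C collinear over 30 genes;
        # one orthogroup (og_x) lacks the A member
        genes, hits = [], []
        for g in ("A", "B", "C"):
            for i in range(30):
                genes.append(
                    GeneModel(f"{g.lower()}{i}", g, "c1", i * 100, i * 100 + 50, "+", i)
                )
        for i in range(30):
            if i != 15:
                hits.append(SimilarityHit(f"a{i}", f"b{i}", "A", "B", 100.0))
                hits.append(SimilarityHit(f"a{i}", f"c{i}", "A", "C", 100.0))
            hits.append(SimilarityHit(f"b{i}", f"c{i}", "B", "C", 100.0))
        entries, unplaced = build_pangenome(hits, genes, "A")
        absent = [e for e in entries if not e.members.get("A")]
        assert len(absent) == 1
        assert absent[0].pan_position == pytest.approx(15.0)

    def test_multi_copy_reference_uses_summed_bitscore(self):
        from pansyn.models import Orthogroup

        genes = [
            GeneModel("a1", "A", "c1", 100, 200, "+", 1),
            GeneModel("a2", "A", "c1", 9000, 9100, "+", 90),
        ]
        og = Orthogroup("og1", frozenset({("A", "a1"), ("A", "a2")}))
        within = [
            SimilarityHit("a1", "x1", "A", "A", 900.0),
            SimilarityHit("a2", "x2", "A", "A", 700.0),
        ]
        entries, _ = place_orthogroups([og], genes, [], within, "A", tandem_gap=20)
        assert entries[0].pan_position == 1.0

    def test_order_is_total_and_permutation_invariant(self, pav_pangenome):
        sim = pav_pangenome
        genes = sim.all_genes()
        entries1, _ = build_pangenome(sim.hits, genes, "genome1")
        rng = np.random.default_rng(1)
        hits = list(sim.hits)
        rng.shuffle(hits)
        genes2 = list(genes)
        rng.shuffle(genes2)
        entries2, _ = build_pangenome(hits, genes2, "genome1")
        key = lambda e: (
            e.pan_chrom, e.pan_position,
            sorted((g, tuple(sorted(v))) for g, v in e.members.items()),
        )
        assert [key(e) for e in entries1] == [key(e) for e in entries2]


class TestPavTable:
    def test_all_present_rows_have_no_incomplete(self):
        entries = [entry("og1", members={"A": ["a"], "B": ["b"]})]
        pav = pav_table(entries, ["A", "B"])
        assert pav.summary()["n_incomplete"] == 0

    def test_private_row_counted(self):
        entries = [entry("og1", members={"A": ["a"], "B": []})]
        pav = pav_table(entries, ["A", "B"])
        assert pav.summary()["private_A"] == 1

    def test_outgroup_excluded_from_accounting(self):
        entries = [entry("og1", members={"A": ["a"], "OUT": ["w"]})]
        pav = pav_table(entries, ["A", "OUT"], outgroup="OUT")
        assert list(pav.table.columns) == ["A"]

    def test_zero_noise_matrix_equals_truth(self, small_pangenome):
        sim = small_pangenome
        entries, _ = build_pangenome(sim.hits, sim.all_genes(), "genome1")
        pav = pav_table(entries, sorted(sim.genes))
        assert pav.table.to_numpy().all()  # no loss planted: everything present
        assert len(pav.table) == len(sim.truth.pav)


class TestAbsenceRuns:
    def _entries(self, presence):
        return [
            entry(f"og{i}", pos=float(i),
                  members={"A": ["x"] if p else [], "B": ["y"]})
            for i, p in enumerate(presence)
        ]

    def test_run_of_five_detected(self):
        runs = absence_runs(self._entries([1, 0, 0, 0, 0, 0, 1]), "A")
        assert [(r[0], r[3]) for r in runs] == [("p1", 5)]

    def test_run_of_four_below_threshold(self):
        assert absence_runs(self._entries([1, 0, 0, 0, 0, 1]), "A") == []

    def test_single_presence_splits_runs(self):
        runs = absence_runs(
            self._entries([0, 0, 0, 0, 0, 1, 0, 0, 0, 0, 0]), "A"
        )
        assert [r[3] for r in runs] == [5, 5]

    def test_runs_do_not_cross_chromosomes(self):
        entries = self._entries([0, 0, 0])
        for e in self._entries([0, 0]):
            e.pan_chrom = "p2"
            entries.append(e)
        assert absence_runs(entries, "A", min_run=3) != []
        assert all(r[0] == "p1" for r in absence_runs(entries, "A", min_run=3))


class TestClassifyAbsence:
    def test_identical_sequence_is_very_similar(self):
        cds = "ATGGCTGATCGTAAAGGCTGGCATCCTGAA" * 4
        region = "T" * 200 + cds + "G" * 200
        stats = classify_absence(cds, region)
        assert (stats.coverage_pct, stats.identity_pct) == (100.0, 100.0)
        assert stats.category == "very_similar"

    def test_mid_coverage_mid_identity_is_diverged(self, rng):
        cds = "".join(rng.choice(list("ACGT"), 300))
        # region keeps 260 of 300 nt with ~10% substitutions:
        # 234 matches -> coverage 78%, identity 234/260 = 90%
        kept = list(cds[:260])
        for i in range(0, 260, 10):
            kept[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[kept[i]]
        stats = classify_absence(cds, "".join(kept))
        assert stats.category == "diverged"
        assert 75 <= stats.coverage_pct <= 99
        assert 75 <= stats.identity_pct <= 95

    def test_low_coverage_is_absent_despite_high_identity(self, rng):
        cds = "".join(rng.choice(list("ACGT"), 300))
        stats = classify_absence(cds, cds[:150])
        assert stats.coverage_pct <= 75 and stats.category == "absent"

    def test_no_alignment_at_all(self):
        stats = classify_absence("ATG" * 40, "")
        assert stats.category == "absent" and stats.coverage_pct == 0.0

    def test_empty_cds_rejected(self):
        with pytest.raises(ValueError):
            classify_absence("", "ACGT")

    def test_category_monotone_in_identity_and_coverage(self):
        """Raising identity or coverage never demotes the category."""
        order = {"absent": 0, "diverged": 1, "very_similar": 2}

        def cat(cov, ident):
            if cov > 99 and ident >= 95:
                return "very_similar"
            if cov >= 75 and ident >= 75:
                return "diverged"
            return "absent"

        grid = np.linspace(0, 100, 21)
        for cov in grid:
            for ident in grid:
                assert order[cat(cov + 1, ident)] >= order[cat(cov, ident)] \
                    or cov + 1 > 100
                assert order[cat(cov, ident + 1)] >= order[cat(cov, ident)] \
                    or ident + 1 > 100


class TestIntervalPrivateEnrichment:
    def _pav(self, n_total, n_private, interval, interval_private):
        entries = []
        for i in range(n_total):
            in_iv = i < interval
            private = (i < interval_private) or (
                interval <= i < interval + (n_private - interval_private)
            )
            entries.append(entry(
                f"og{i:04d}", pos=float(i),
                members={"A": ["x"], "B": [] if private else ["y"]},
            ))
        pav = pav_table(entries, ["A", "B"])
        return pav, [f"og{i:04d}" for i in range(interval)]

    def test_private_fraction_of_46_entry_interval(self):
        """46 orthogroups with 8 private to the focal genome: 17.4%."""
        pav, interval = self._pav(1000, 58, 46, 8)
        fraction, odds, p = interval_private_enrichment(pav, interval, "A")
        assert fraction == 17.4
        assert odds > 1 and p < 0.05

    def test_no_private_in_interval_gives_zero_odds(self):
        pav, interval = self._pav(200, 10, 20, 0)
        _, odds, _ = interval_private_enrichment(pav, interval, "A")
        assert odds == 0.0

    def test_p_value_matches_hypergeometric_enumeration(self):
        pav, interval = self._pav(1096, 58, 46, 8)
        _, _, p = interval_private_enrichment(pav, interval, "A")
        assert p == pytest.approx(
            oracle_fisher_two_sided(8, 38, 50, 1000), rel=1e-9
        )

    def test_disjoint_interval_rejected(self):
        pav, _ = self._pav(10, 2, 3, 1)
        with pytest.raises(ValueError):
            interval_private_enrichment(pav, ["nope"], "A")


class TestHaplotypeProjection:
    def test_global_identity_formula_with_internal_gap(self):
        # ACDEFG vs ACDFG: 5 identical over 5 aligned + 1 internal gap
        assert percent_identity("ACDEFG", "ACDFG") == pytest.approx(83.3, abs=0.05)
        assert percent_identity("ACDEFG", "ACDFG") == pytest.approx(
            oracle_global_identity("ACDEFG", "ACDFG")
        )

    def test_identical_proteins_are_class_both_at_100(self):
        entries = [entry("og1", pos=5.0, members={"P": ["p1"]})]
        hits = [SimilarityHit("p1", "alt1", "P", "Palt", 300.0)]
        comps, mid = project_to_alt_haplotype(
            entries, "P", hits, {"alt1": "ctg1"},
            {"p1": "MKLV" * 10}, {"alt1": "MKLV" * 10},
        )
        (c,) = [c for c in comps if c.cls == "both"]
        assert c.identity_pct == 100.0
        assert mid == {"ctg1": 5.0}

    def test_uncovered_primary_only_gene_is_no_alt_contig_class(self):
        entries = [
            entry("og1", pos=5.0, members={"P": ["p1"]}),
            entry("og2", pos=50.0, members={"P": ["p2"]}),
        ]
        hits = [SimilarityHit("p1", "alt1", "P", "Palt", 300.0)]
        comps, _ = project_to_alt_haplotype(
            entries, "P", hits, {"alt1": "ctg1"},
            {"p1": "MKLV", "p2": "MKIV"}, {"alt1": "MKLV"},
        )
        cls_of = {c.pan_id: c.cls for c in comps if c.pan_id}
        assert cls_of["og2"] == "primary_only_no_alt_contig"

    def test_covered_locus_without_alt_ortholog_is_pav_class(self):
        entries = [
            entry("og1", pos=0.0, members={"P": ["p1"]}),
            entry("og2", pos=5.0, members={"P": ["p2"]}),
            entry("og3", pos=10.0, members={"P": ["p3"]}),
        ]
        hits = [
            SimilarityHit("p1", "alt1", "P", "Palt", 300.0),
            SimilarityHit("p3", "alt3", "P", "Palt", 300.0),
        ]
        comps, _ = project_to_alt_haplotype(
            entries, "P", hits, {"alt1": "ctg1", "alt3": "ctg1"},
            {"p1": "MKLV", "p2": "MKIV", "p3": "MMMV"},
            {"alt1": "MKLV", "alt3": "MMMV"},
        )
        cls_of = {c.pan_id: c.cls for c in comps if c.pan_id}
        assert cls_of["og2"] == "primary_only_with_alt_contig"

    def test_unmatched_alt_gene_reported_alt_only(self):
        comps, _ = project_to_alt_haplotype(
            [entry("og1", pos=0.0, members={"P": ["p1"]})], "P",
            [], {}, {"p1": "MKLV"}, {"alt9": "WWWW"},
        )
        assert any(c.cls == "alt_only" and c.alt_gene == "alt9" for c in comps)
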