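import numpy as np
import pytest
from oracles import oracle_bayes_interval

from pansyn import qtl as q
from pansyn.models import MISSING, CrossGenotypes, GenotypeMatrix
from pansyn.simulate import CrossSimConfig, simulate_f1_cross


def make_gm(calls, depth=None, multiallelic=None):
    calls = np.asarray(calls)
    gm = GenotypeMatrix(
        samples=[f"s{i}" for i in range(calls.shape[0])],
        sites=[("chr1", 100 * (j + 1), "A", "T") for j in range(calls.shape[1])],
        calls=calls,
        depth=None if depth is None else np.asarray(depth),
    )
    if multiallelic is not None:
        gm.multiallelic = np.asarray(multiallelic)
    return gm


class TestFilterMarkers:
    def test_low_maf_dropped(self):
        # site 0: one het in 10 samples -> MAF 0.05 kept; single copy -> dropped
        calls = np.full((10, 2), 2)
        calls[0, 0] = 1  # MAF 1/20 = 0.05 -> kept (threshold is strict <)
        gm = filter_in = make_gm(calls)
        out = q.filter_markers(filter_in)
        assert [s[1] for s in out.sites] == [100]

    def test_high_het_frequency_dropped(self):
        calls = np.ones((10, 1))  # all het
        out = q.filter_markers(make_gm(calls))
        assert out.n_sites == 0

    def test_missing_rate_threshold(self):
        calls = np.full((10, 1), 1)
        calls[:2, 0] = MISSING  # 20% missing > 10%
        out = q.filter_markers(make_gm(calls))
        assert out.n_sites == 0

    def test_multiallelic_dropped(self):
        calls = np.full((10, 1), 1)
        out = q.filter_markers(make_gm(calls, multiallelic=[True]))
        assert out.n_sites == 0

    def test_depth_tails_trimmed(self):
        calls = np.tile(np.array([[2], [2], [1], [1]]), (1, 100))
        depth = np.tile(np.arange(1, 101), (4, 1))
        out = q.filter_markers(make_gm(calls, depth=depth))
        kept_depths = out.depth[0]
        assert kept_depths.min() > 1 and kept_depths.max() < 100


class TestPhaseTestcross:
    def test_correlated_markers_share_phase(self):
        alt = np.array([[1, 1], [0, 0], [1, 1], [0, 0]])
        cg = q.phase_testcross(
            alt, ["c1", "c1"], np.array([100, 200]), ["m1", "m2"],
            ["p1", "p2", "p3", "p4"], {"m1": "gp1", "m2": "gp1"},
        )
        assert (cg.geno[:, 0] == cg.geno[:, 1]).all()

    def test_anticorrelated_markers_get_opposite_phase(self):
        alt = np.array([[1, 0], [0, 1], [1, 0], [0, 1]])
        cg = q.phase_testcross(
            alt, ["c1", "c1"], np.array([100, 200]), ["m1", "m2"],
            ["p1", "p2", "p3", "p4"], {"m1": "gp1", "m2": "gp2"},
        )
        assert (cg.geno[:, 0] == cg.geno[:, 1]).all()

    def test_single_marker_chromosome_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            q.phase_testcross(
                np.array([[1], [0]]), ["c1"], np.array([100]), ["m1"],
                ["p1", "p2"], {},
            )

    def test_recovers_truth_haplotypes_up_to_label_swap(self, f1_cross):
        c = f1_cross
        cg = q.phase_testcross(
            c.alt_presence, c.chrom, c.pos_bp, c.marker_ids,
            c.progeny, c.alt_origin,
        )
        for _, idx in cg.chrom_indices().items():
            agree = (cg.geno[:, idx] == c.truth.haplotypes[:, idx]).mean()
            assert max(agree, 1 - agree) == 1.0


class TestBinMarkers:
    def _cg(self, geno, pos_bp, phases=None):
        geno = np.asarray(geno, dtype=np.int8)
        m = geno.shape[1]
        return CrossGenotypes(
            progeny=[f"p{i}" for i in range(geno.shape[0])],
            marker_ids=[f"m{j}" for j in range(m)],
            chrom=["c1"] * m, pos_bp=np.asarray(pos_bp), geno=geno,
            phase_parent=phases or ["gp1"] * m,
        )

    def test_discordant_marker_in_bin_removed(self, rng):
        base = rng.integers(0, 2, size=(30, 1))
        geno = np.tile(base, (1, 8))
        geno[:, 3] = 1 - geno[:, 3]  # discordant with neighbors
        pos = np.array([0, 1000, 2000, 2500, 30000, 40000, 50000, 60000])
        out = q.bin_markers(self._cg(geno, pos), bin_size=25_000, local_window=3)
        assert "m3" not in out.marker_ids
        assert "m1" in out.marker_ids or "m0" in out.marker_ids

    def test_markers_in_distinct_bins_all_kept(self, rng):
        geno = np.tile(rng.integers(0, 2, size=(20, 1)), (1, 4))
        pos = np.array([0, 30_000, 60_000, 90_000])
        out = q.bin_markers(self._cg(geno, pos))
        assert out.n_markers == 4

    def test_agreement_tie_keeps_lower_coordinate(self, rng):
        geno = np.tile(rng.integers(0, 2, size=(20, 1)), (1, 4))
        pos = np.array([1000, 2000, 50_000, 60_000])
        out = q.bin_markers(self._cg(geno, pos))
        assert "m0" in out.marker_ids and "m1" not in out.marker_ids

    def test_phases_binned_independently(self, rng):
        geno = np.tile(rng.integers(0, 2, size=(20, 1)), (1, 4))
        pos = np.array([1000, 2000, 3000, 4000])
        out = q.bin_markers(
            self._cg(geno, pos, phases=["gp1", "gp1", "gp2", "gp2"])
        )
        assert out.n_markers == 2


class TestEstimateMap:
    def test_kosambi_closed_form(self):
        assert q.kosambi_cm(0.25) == pytest.approx(25 * np.log(3))
        assert q.kosambi_r(q.kosambi_cm(0.31)) == pytest.approx(0.31)

    def test_identical_markers_map_to_zero_distance(self):
        geno = np.tile(np.array([[0], [1], [0], [1]]), (1, 3))
        cg = CrossGenotypes(
            progeny=list("abcd"), marker_ids=["m0", "m1", "m2"],
            chrom=["c1"] * 3, pos_bp=np.array([0, 100, 200]), geno=geno,
        )
        out = q.estimate_map(cg, error_prob=0.0)
        assert np.allclose(out.pos_cm, 0.0)

    def test_quarter_recombination_distance(self, rng):
        n = 40_000
        g0 = rng.integers(0, 2, size=n)
        flip = rng.random(n) < 0.25
        g1 = np.where(flip, 1 - g0, g0)
        cg = CrossGenotypes(
            progeny=[f"p{i}" for i in range(n)], marker_ids=["m0", "m1"],
            chrom=["c1"] * 2, pos_bp=np.array([0, 100]),
            geno=np.stack([g0, g1], axis=1).astype(np.int8),
        )
        out = q.estimate_map(cg, error_prob=0.0)
        assert out.pos_cm[1] == pytest.approx(25 * np.log(3), rel=0.05)

    def test_total_length_recovered_on_large_cross(self):
        sim = simulate_f1_cross(
            CrossSimConfig(n_progeny=1000, n_markers=200, qtl=(0, 10.0, 0.0),
                           phenotype_noise=1.0, genotyping_error=0.0, seed=77)
        )
        cg = q.phase_testcross(
            sim.alt_presence, sim.chrom, sim.pos_bp, sim.marker_ids,
            sim.progeny, sim.alt_origin,
        )
        cg = q.estimate_map(cg, error_prob=0.0)
        total = sum(cg.pos_cm[idx].max() for _, idx in cg.chrom_indices().items())
        truth = sum(CrossSimConfig().chrom_lengths_cm)
        assert abs(total - truth) / truth < 0.10


def scanned_cross(seed=104, r2=0.5, **kw):
    sim = simulate_f1_cross(
        CrossSimConfig(n_progeny=143, n_markers=200, qtl=(0, 40.0, r2),
                       seed=seed, **kw)
    )
    cg = q.phase_testcross(
        sim.alt_presence, sim.chrom, sim.pos_bp, sim.marker_ids,
        sim.progeny, sim.alt_origin,
    )
    return q.estimate_map(cg, error_prob=0.0165), sim


class TestScanLod:
    CFG = q.ScanConfig(step=1.0, n_permutations=500, seed=3)

    def test_planted_qtl_lod_matches_closed_form_expectation(self):
        """An additive QTL explaining half the variance in 143 progeny has
        expected LOD near -(n/2) log10(1 - R^2) = 71.5 log10 2."""
        expected = 71.5 * np.log10(2)
        peaks = []
        for seed in (1, 2, 3, 4, 5):
            cg, sim = scanned_cross(seed=seed, r2=0.5)
            prof = q.scan_lod(cg, sim.phenotype, self.CFG)
            peaks.append(prof.peak_lod)
        assert abs(np.mean(peaks) - expected) / expected < 0.25

    def test_marker_orthogonal_to_phenotype_scores_near_zero(self, rng):
        cg, sim = scanned_cross(seed=9, r2=0.0)
        # phenotype orthogonalized against every marker on chr4
        prof = q.scan_lod(cg, sim.phenotype, self.CFG)
        chr4 = [i for i, c in enumerate(prof.chrom) if c == "chr4"]
        assert prof.lod[chr4].max() < 3.0

    def test_lod_invariant_to_affine_phenotype_transform(self):
        cg, sim = scanned_cross(seed=12)
        p1 = q.scan_lod(cg, sim.phenotype, self.CFG)
        p2 = q.scan_lod(cg, 3.0 * sim.phenotype - 7.0, self.CFG)
        assert np.allclose(p1.lod, p2.lod, atol=1e-8)

    def test_constant_phenotype_rejected(self):
        cg, sim = scanned_cross(seed=13)
        with pytest.raises(ValueError, match="constant"):
            q.scan_lod(cg, np.zeros(143), self.CFG)

    def test_null_phenotype_stays_below_threshold(self):
        """Without a QTL the genome-wide peak should rarely clear the 5%
        permutation threshold (allow 2 exceedances in 10 replicates)."""
        exceed = 0
        for seed in range(10):
            cg, sim = scanned_cross(seed=100 + seed, r2=0.0)
            prof = q.scan_lod(cg, sim.phenotype, self.CFG)
            thr = q.permutation_threshold(cg, sim.phenotype, self.CFG)
            exceed += prof.peak_lod > thr
        assert exceed <= 2


class TestPermutationThreshold:
    def test_seeded_threshold_reproducible(self):
        cg, sim = scanned_cross(seed=21)
        cfg = q.ScanConfig(step=1.0, n_permutations=200, seed=5)
        t1 = q.permutation_threshold(cg, sim.phenotype, cfg)
        t2 = q.permutation_threshold(cg, sim.phenotype, cfg)
        assert t1 == t2
        with pytest.warns(UserWarning, match="unstable"):
            q.permutation_threshold(
                cg, sim.phenotype, q.ScanConfig(step=1.0, n_permutations=50, seed=5)
            )

    def test_zero_permutations_rejected(self):
        cg, sim = scanned_cross(seed=22)
        with pytest.raises(ValueError):
            q.permutation_threshold(
                cg, sim.phenotype, q.ScanConfig(n_permutations=0)
            )


class TestBayesInterval:
    def _profile(self, lod, chrom="c1"):
        n = len(lod)
        prof = q.LodProfile(
            chrom=[chrom] * n, pos_cm=np.arange(n, dtype=float),
            pos_bp=np.arange(n) * 1000.0, lod=np.asarray(lod, dtype=float),
        )
        prof.peak_index = int(np.argmax(prof.lod))
        return prof

    def test_delta_profile_collapses_to_peak(self):
        prof = self._profile([0, 0, 40, 0, 0])
        c, lo, hi = q.bayes_interval(prof)
        assert (lo, hi) == (2000.0, 2000.0)

    def test_flat_profile_spans_chromosome(self):
        prof = self._profile([1.0] * 11)
        _, lo, hi = q.bayes_interval(prof)
        assert (lo, hi) == (0.0, 10_000.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_interval_oracle(self, seed):
        rng = np.random.default_rng(seed)
        lod = rng.uniform(0, 4, size=int(rng.integers(5, 21)))
        prof = self._profile(lod)
        _, lo, hi = q.bayes_interval(prof, prob=0.9)
        i, j = oracle_bayes_interval(lod, int(np.argmax(lod)), 0.9)
        assert (lo, hi) == (i * 1000.0, j * 1000.0)

    def test_interval_contains_peak_and_enough_mass(self, rng):
        lod = rng.uniform(0, 3, size=40)
        prof = self._profile(lod)
        _, lo, hi = q.bayes_interval(prof, prob=0.95)
        peak_bp = prof.pos_bp[prof.peak_index]
        assert lo <= peak_bp <= hi
        mass = np.power(10.0, lod - lod.max())
        mass /= mass.sum()
        sel = (prof.pos_bp >= lo) & (prof.pos_bp <= hi)
        assert mass[sel].sum() >= 0.95


class TestRankCandidates:
    def _comparisons(self):
        from pansyn.pangenome import HaplotypeComparison as HC

        return [
            HC("og1", "g1", "a1", 97.5, "both"),
            HC("og2", "g2", "a2", 99.5, "both"),
            HC("og3", "g3", None, None, "primary_only_with_alt_contig"),
            HC("og4", "g4", None, None, "primary_only_no_alt_contig"),
            HC("", None, "a9", None, "alt_only"),
        ]

    def _entries(self):
        from pansyn.models import PangenomeEntry

        return [
            PangenomeEntry(f"og{i}", "c1", float(i), {"P": [f"g{i}"]},
                           {"P": f"g{i}"})
            for i in range(1, 5)
        ]

    def test_divergent_pair_is_high_priority(self):
        cands = {c.gene_id: c for c in
                 q.rank_candidates(self._entries(), self._comparisons())}
        assert cands["g1"].priority == "high"

    def test_similar_pair_not_prioritized(self):
        cands = {c.gene_id: c for c in
                 q.rank_candidates(self._entries(), self._comparisons())}
        assert cands["g2"].priority == "low"

    def test_homozygous_region_gene_is_low_priority(self):
        cands = {c.gene_id: c for c in
                 q.rank_candidates(self._entries(), self._comparisons())}
        assert cands["g4"].priority == "low"
        assert cands["g3"].priority == "high"
        assert cands["a9"].priority == "high"

    def test_domain_tags_attached(self):
        cands = q.rank_candidates(
            self._entries(), self._comparisons(),
            domain_tags={"g1": ["LRR", "PF00931"]},
        )
        tagged = [c for c in cands if c.gene_id == "g1"]
        assert tagged[0].tags == ["LRR", "PF00931"]
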