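"""Synthetic data generators with the statistical structure the analyses
assume, plus ground truth for recovery tests.

Four scenarios are covered: (1) a set of annotated genomes descended from a
whole-genome-duplicated ancestor with controlled rearrangement, gene-loss
(PAV), tandem-duplication and private-gene rates; (2) a CDS pair evolved to
target Ka/Ks values; (3) a panel of source populations plus admixed test
genomes carrying planted introgression blocks; (4) an F1 pseudo-testcross
with Poisson crossovers and a planted additive QTL.

All generators are deterministic given their seed, and every scenario
returns a truth object sufficient to score downstream recovery without
re-simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import MISSING, GeneModel, GenotypeMatrix, SimilarityHit
from .molevol import BASES, CODON_TABLE, STOP_CODONS

BACKGROUND = -1  # placeholder; admixture background is source n_sources-1


@dataclass
class TruthSet:
    """Ground truth emitted alongside synthetic data."""

    orthogroups: dict[str, set[tuple[str, str]]] | None = None
    pav: pd.DataFrame | None = None
    expected_homeolog_blocks: int | None = None
    n_rearrangements: int | None = None
    ancestry_states: np.ndarray | None = None       # markers x (a, b) pairs
    donor_blocks: list[tuple[int, int, int]] | None = None  # (donor, start, end)
    haplotypes: np.ndarray | None = None            # progeny x markers in {0,1}
    qtl_marker: int | None = None
    qtl_effect: float | None = None
    target_ka: float | None = None
    target_ks: float | None = None


# ---------------------------------------------------------------------------
# Pan-genome scenario
# ---------------------------------------------------------------------------

@dataclass
class PangenomeSimConfig:
    n_chroms: int = 4               # ancestral chromosomes
    genes_per_chrom: int = 100
    n_genomes: int = 4
    wgd: bool = True
    n_rearrangements: int = 0
    pav_rate: float = 0.0
    private_rate: float = 0.0
    tandem_rate: float = 0.0
    ortholog_divergence: float = 0.01   # per-site, between genomes
    homeolog_divergence: float = 0.10   # per-site, between WGD copies
    cds_codons: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pav_rate", "private_rate", "tandem_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.pav_rate >= 1:
            raise ValueError("pav_rate = 1 leaves no shared genes")
        if min(self.n_chroms, self.genes_per_chrom, self.n_genomes) < 1:
            raise ValueError("counts must be positive")


@dataclass
class PangenomeSim:
    genes: dict[str, list[GeneModel]]          # per genome
    cds: dict[tuple[str, str], str]            # (genome, gene_id) -> CDS
    proteins: dict[tuple[str, str], str]
    hits: list[SimilarityHit]
    truth: TruthSet

    def all_genes(self) -> list[GeneModel]:
        return [g for genome in sorted(self.genes) for g in self.genes[genome]]


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    sense = sorted(set(CODON_TABLE) - STOP_CODONS)
    return "".join(rng.choice(sense) for _ in range(n_codons))


def _mutate(rng: np.random.Generator, cds: str, rate: float) -> str:
    """Per-site substitutions avoiding the creation of stop codons."""
    seq = list(cds)
    for i in range(len(seq)):
        if rng.random() >= rate:
            continue
        c0 = 3 * (i // 3)
        for base in rng.permutation([b for b in BASES if b != seq[i]]):
            codon = "".join(seq[c0:i] + [base] + seq[i + 1 : c0 + 3])
            if codon not in STOP_CODONS:
                seq[i] = base
                break
    return "".join(seq)


def _identity(a: str, b: str) -> float:
    same = sum(1 for x, y in zip(a, b) if x == y)
    return same / max(len(a), len(b))


def simulate_pangenome(cfg: PangenomeSimConfig) -> PangenomeSim:
    """Simulate annotated genomes descended from a WGD ancestor.

    The ancestral karyotype has ``n_chroms`` chromosomes of
    ``genes_per_chrom`` loci; under WGD each chromosome gains a homeolog
    copy (chromosomes ``chr{c}a`` / ``chr{c}b``).  ``n_rearrangements``
    one-way events (terminal-segment translocations or terminal inversions
    of the "b" copy) each add exactly one off-diagonal homeolog block; the
    same rearranged karyotype is shared by every genome, so orthologous
    order stays conserved.  Per genome, orthogroups are lost at
    ``pav_rate``, genes gain an adjacent tandem duplicate at
    ``tandem_rate``, and unique private genes are inserted at
    ``private_rate`` per locus.  Similarity hits connect all true homologs
    with bitscores decreasing in sequence divergence (orthologs >
    homeologs), and truth records orthogroup membership, the PAV matrix and
    the expected homeolog block count.
    """
    rng = np.random.default_rng(cfg.seed)
    copies = ["a", "b"] if cfg.wgd else ["a"]

    # ancestral karyotype: per chromosome copy, an ordered list of loci
    karyotype: dict[str, list[tuple[int, int, str]]] = {}  # (chrom locus copy)
    for c in range(cfg.n_chroms):
        for copy in copies:
            karyotype[f"chr{c + 1}{copy}"] = [
                (c, i, copy) for i in range(cfg.genes_per_chrom)
            ]

    n_rearr = 0
    if cfg.n_rearrangements and cfg.wgd:
        if cfg.n_chroms < 2:
            raise ValueError("rearrangements need >= 2 ancestral chromosomes")
        seg = max(12, cfg.genes_per_chrom // 5)
        if cfg.genes_per_chrom < 3 * seg:
            raise ValueError(
                "genes_per_chrom too small to plant non-adjacent rearrangements"
            )
        # each event uses fresh homeolog pairs so planted events stay
        # non-adjacent and each adds exactly one off-diagonal block
        available = list(range(cfg.n_chroms))
        for _ in range(cfg.n_rearrangements):
            if not available:
                break
            donor_pair = available.pop(int(rng.integers(len(available))))
            donor = f"chr{donor_pair + 1}b"
            segment = karyotype[donor][-seg:]
            karyotype[donor] = karyotype[donor][:-seg]
            if rng.random() < 0.5 or not available:  # terminal inversion
                karyotype[donor] = karyotype[donor] + segment[::-1]
            else:  # translocation to an unused pair's b copy
                recv_pair = available.pop(int(rng.integers(len(available))))
                karyotype[f"chr{recv_pair + 1}b"] = (
                    karyotype[f"chr{recv_pair + 1}b"] + segment
                )
            n_rearr += 1

    og_key = lambda c, i, copy: f"anc_{c + 1}_{i}_{copy}"
    ancestral_cds = {
        (c, i): _random_cds(rng, cfg.cds_codons)
        for c in range(cfg.n_chroms) for i in range(cfg.genes_per_chrom)
    }
    copy_cds = {}
    for (c, i), cds in ancestral_cds.items():
        copy_cds[(c, i, "a")] = cds
        if cfg.wgd:
            copy_cds[(c, i, "b")] = _mutate(rng, cds, cfg.homeolog_divergence)

    genomes = [f"genome{k + 1}" for k in range(cfg.n_genomes)]
    lost: dict[str, set[str]] = {g: set() for g in genomes}
    all_ogs = [og_key(c, i, copy) for c in range(cfg.n_chroms)
               for i in range(cfg.genes_per_chrom) for copy in copies]
    for g in genomes:
        for og in all_ogs:
            if rng.random() < cfg.pav_rate:
                lost[g].add(og)
    # never lose an orthogroup from every genome (keeps the pan-genome placeable)
    for og in all_ogs:
        if all(og in lost[g] for g in genomes):
            lost[genomes[int(rng.integers(cfg.n_genomes))]].discard(og)

    genes: dict[str, list[GeneModel]] = {g: [] for g in genomes}
    cds_of: dict[tuple[str, str], str] = {}
    truth_og: dict[str, set[tuple[str, str]]] = {og: set() for og in all_ogs}
    private_counter = 0
    for g in genomes:
        for chrom, loci in karyotype.items():
            entries: list[tuple[str, str | None]] = []  # (gene og or private, cds)
            for (c, i, copy) in loci:
                og = og_key(c, i, copy)
                if og not in lost[g]:
                    entries.append((og, copy_cds[(c, i, copy)]))
                    if rng.random() < cfg.tandem_rate:
                        entries.append((og + "|tandem", copy_cds[(c, i, copy)]))
                if rng.random() < cfg.private_rate:
                    private_counter += 1
                    entries.append(
                        (f"private_{private_counter}",
                         _random_cds(rng, cfg.cds_codons))
                    )
            pos = 0
            for rank, (tag, base_cds) in enumerate(entries):
                gid = f"{g}_{chrom}_g{rank:04d}"
                mutated = _mutate(rng, base_cds, cfg.ortholog_divergence)
                if tag.endswith("|tandem"):
                    mutated = _mutate(rng, mutated, 0.01)
                length = 3 * cfg.cds_codons
                genes[g].append(
                    GeneModel(
                        gene_id=gid, genome=g, chrom=chrom,
                        start=pos, end=pos + length, strand="+", rank=rank,
                    )
                )
                cds_of[(g, gid)] = mutated
                pos += length + 400
                og = tag.split("|")[0]
                if og in truth_og:
                    truth_og[og].add((g, gid))

    truth_og = {k: v for k, v in truth_og.items() if v}

    # similarity hits: all gene pairs sharing an ancestral locus (both
    # copies), bitscore decreasing in divergence
    locus_members: dict[tuple[int, int], list[tuple[str, str, str]]] = {}
    gene_locus: dict[tuple[str, str], tuple[int, int, str]] = {}
    for og, members in truth_og.items():
        _, c, i, copy = og.split("_")
        for g, gid in members:
            locus_members.setdefault((int(c), int(i)), []).append((g, gid, copy))
            gene_locus[(g, gid)] = (int(c), int(i), copy)
    hits: list[SimilarityHit] = []
    for locus, members in sorted(locus_members.items()):
        for ga, gida, copya in members:
            for gb, gidb, copyb in members:
                if (ga, gida) >= (gb, gidb):
                    continue
                ident = _identity(cds_of[(ga, gida)], cds_of[(gb, gidb)])
                score = round(500.0 * ident, 2)
                hits.append(SimilarityHit(gida, gidb, ga, gb, score))
                hits.append(SimilarityHit(gidb, gida, gb, ga, score))

    pav = pd.DataFrame(
        {g: [any(gg == g for gg, _ in truth_og[og]) for og in sorted(truth_og)]
         for g in genomes},
        index=sorted(truth_og), dtype=bool,
    )
    proteins = {}
    from .molevol import translate
    for key, cds in cds_of.items():
        proteins[key] = translate(cds)
    truth = TruthSet(
        orthogroups=truth_og, pav=pav,
        expected_homeolog_blocks=(cfg.n_chroms + n_rearr) if cfg.wgd else 0,
        n_rearrangements=n_rearr,
    )
    return PangenomeSim(
        genes=genes, cds=cds_of, proteins=proteins, hits=hits, truth=truth
    )


# ---------------------------------------------------------------------------
# CDS pair evolution
# ---------------------------------------------------------------------------

def simulate_cds_evolution(
    n_codons: int, target_ka: float, target_ks: float, seed: int = 0
) -> tuple[str, str, TruthSet]:
    """Evolve a CDS pair toward target NG86 Ka and Ks.

    The raw substitution proportions ``p_s`` / ``p_n`` whose Jukes–Cantor
    correction equals the targets are converted into expected substitution
    counts over the sequence's fractional synonymous / non-synonymous site
    totals; exactly those (rounded) counts are placed at positions sampled
    in proportion to each position's synonymous (resp. non-synonymous)
    opportunity, so the realized rates approximate the targets with only
    estimator-side noise.  Stop codons are never created.
    """
    if n_codons < 10:
        raise ValueError(f"n_codons must be >= 10, got {n_codons}")
    rng = np.random.default_rng(seed)
    a = _random_cds(rng, n_codons)
    # invert JC: p = 3/4 (1 - exp(-4 d / 3))
    p_s = 0.75 * (1.0 - np.exp(-4.0 * target_ks / 3.0))
    p_n = 0.75 * (1.0 - np.exp(-4.0 * target_ka / 3.0))
    b = list(a)

    def alternatives(codon: str, pos: int) -> tuple[list[str], list[str]]:
        aa = CODON_TABLE[codon]
        syn, nonsyn = [], []
        for base in BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if mutant in STOP_CODONS:
                continue
            (syn if CODON_TABLE[mutant] == aa else nonsyn).append(base)
        return syn, nonsyn

    positions = [(k, pos) for k in range(n_codons) for pos in range(3)]
    syn_w = np.empty(len(positions))
    non_w = np.empty(len(positions))
    for i, (k, pos) in enumerate(positions):
        syn, nonsyn = alternatives(a[3 * k : 3 * k + 3], pos)
        syn_w[i] = len(syn) / 3.0
        non_w[i] = len(nonsyn) / 3.0
    for weights, p_target, kind in ((syn_w, p_s, 0), (non_w, p_n, 1)):
        total_sites = weights.sum()
        count = int(round(p_target * total_sites))
        if count == 0 or total_sites == 0:
            continue
        chosen = rng.choice(
            len(positions), size=min(count, int((weights > 0).sum())),
            replace=False, p=weights / total_sites,
        )
        for i in sorted(chosen):
            k, pos = positions[i]
            # re-derive against the current codon so sequential substitutions
            # within one codon can never combine into a stop
            codon = "".join(b[3 * k : 3 * k + 3])
            syn, nonsyn = alternatives(codon, pos)
            options = syn if kind == 0 else nonsyn
            if options:
                b[3 * k + pos] = options[int(rng.integers(len(options)))]
    return a, "".join(b), TruthSet(target_ka=target_ka, target_ks=target_ks)


# ---------------------------------------------------------------------------
# Admixture panel scenario
# ---------------------------------------------------------------------------

@dataclass
class AdmixSimConfig:
    n_sources: int = 4
    n_markers: int = 2000
    fst_like_divergence: float = 0.2
    donor_blocks: list[tuple[int, tuple[int, int]]] = field(default_factory=list)
    n_relatives: int = 2
    n_per_source: int = 20
    genotyping_error: float = 1e-3
    recomb_rate: float = 1e-4   # morgans per inter-marker interval
    seed: int = 0

    def __post_init__(self) -> None:
        for donor, (s, e) in self.donor_blocks:
            if donor >= self.n_sources or donor < 0:
                raise ValueError(f"donor index {donor} >= n_sources {self.n_sources}")
            if not (0 <= s <= e < self.n_markers):
                raise ValueError(f"donor block span ({s}, {e}) out of range")

    @property
    def background(self) -> int:
        return self.n_sources - 1


@dataclass
class AdmixSim:
    genotypes: GenotypeMatrix
    population_of: dict[str, str]
    populations: list[str]
    test_sample: str
    relatives: list[str]
    positions_morgans: np.ndarray
    true_freqs: np.ndarray
    truth: TruthSet


def simulate_admixture_panel(cfg: AdmixSimConfig) -> AdmixSim:
    """Simulate source populations plus admixed test genomes.

    Source reference-allele frequencies drift from a shared ancestral
    frequency under a Balding–Nichols model with drift parameter
    ``fst_like_divergence`` (0 leaves all sources identical; >= 1 plants
    near-fixed differences).  The test genome and its relatives are
    homozygous background ancestry except inside the planted
    ``donor_blocks``, where both haplotypes copy the donor; genotypes are
    binomial draws from the ancestry's allele frequency with per-allele
    ``genotyping_error``.
    """
    rng = np.random.default_rng(cfg.seed)
    m, k = cfg.n_markers, cfg.n_sources
    f0 = rng.uniform(0.05, 0.95, size=m)
    if cfg.fst_like_divergence <= 0:
        freqs = np.tile(f0, (k, 1))
    elif cfg.fst_like_divergence >= 1:
        # fixed differences, deterministic interleaved design: even markers
        # separate every donor from the background; odd markers identify
        # which donor (round-robin), so ancestry boundaries resolve to
        # within one inter-marker spacing
        freqs = np.full((k, m), 0.001)
        j = np.arange(m)
        even = j % 2 == 0
        freqs[: k - 1, even] = 0.999
        donor_id = (j // 2) % max(k - 1, 1)
        for d in range(k - 1):
            freqs[d, (~even) & (donor_id == d)] = 0.999
    else:
        F = cfg.fst_like_divergence
        freqs = np.clip(
            rng.beta(f0 * (1 - F) / F, (1 - f0) * (1 - F) / F, size=(k, m)),
            1e-4, 1 - 1e-4,
        )

    ancestry = np.full((m, 2), cfg.background, dtype=np.int64)
    donor_runs = []
    for donor, (s, e) in cfg.donor_blocks:
        ancestry[s : e + 1, :] = donor
        donor_runs.append((donor, s, e))

    samples, cols, pops = [], [], {}
    populations = [f"pop{p}" for p in range(k)]
    for p in range(k):
        for i in range(cfg.n_per_source):
            name = f"src{p}_{i}"
            samples.append(name)
            pops[name] = populations[p]
            cols.append(rng.binomial(2, freqs[p]))

    def draw_admixed() -> np.ndarray:
        alleles = np.empty((m, 2))
        for h in range(2):
            p = freqs[ancestry[:, h], np.arange(m)]
            alleles[:, h] = rng.random(m) < p
        if cfg.genotyping_error > 0:
            flip = rng.random((m, 2)) < cfg.genotyping_error
            alleles = np.where(flip, 1 - alleles, alleles)
        return alleles.sum(axis=1).astype(np.int64)

    test_sample = "test0"
    samples.append(test_sample)
    cols.append(draw_admixed())
    relatives = []
    for r in range(cfg.n_relatives):
        name = f"rel{r}"
        relatives.append(name)
        samples.append(name)
        cols.append(draw_admixed())

    sites = [("chr1", 1000 * (j + 1), "A", "T") for j in range(m)]
    gm = GenotypeMatrix(
        samples=samples, sites=sites,
        calls=np.stack(cols, axis=0).astype(np.int16),
    )
    truth = TruthSet(
        ancestry_states=np.sort(ancestry, axis=1), donor_blocks=donor_runs
    )
    return AdmixSim(
        genotypes=gm, population_of=pops, populations=populations,
        test_sample=test_sample, relatives=relatives,
        positions_morgans=np.arange(m) * cfg.recomb_rate,
        true_freqs=freqs, truth=truth,
    )


# ---------------------------------------------------------------------------
# F1 pseudo-testcross scenario
# ---------------------------------------------------------------------------

@dataclass
class CrossSimConfig:
    n_progeny: int = 143
    n_markers: int = 200
    chrom_lengths_cm: list[float] = field(default_factory=lambda: [80.0] * 4)
    qtl: tuple[int, float, float] = (0, 40.0, 0.5)  # (chrom idx, cM, R^2)
    phenotype_noise: float = 1.0
    genotyping_error: float = 0.0165  # matches the map error.prob default
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        c, pos, r2 = self.qtl
        if not (0 <= c < len(self.chrom_lengths_cm)):
            raise ValueError(f"QTL chromosome {c} out of range")
        if not (0 <= pos <= self.chrom_lengths_cm[c]):
            raise ValueError(
                f"QTL position {pos} cM outside chromosome of "
                f"{self.chrom_lengths_cm[c]} cM"
            )
        if not (0 <= r2 < 1):
            raise ValueError("QTL effect must be a variance fraction in [0, 1)")


@dataclass
class CrossSim:
    alt_presence: np.ndarray          # progeny x markers, 0/1/-1
    chrom: list[str]
    pos_bp: np.ndarray
    pos_cm_true: np.ndarray
    marker_ids: list[str]
    progeny: list[str]
    alt_origin: dict[str, str]        # marker -> grandparent carrying alt
    phenotype: np.ndarray
    truth: TruthSet


def simulate_f1_cross(cfg: CrossSimConfig) -> CrossSim:
    """Simulate an F1 pseudo-testcross with a planted additive QTL.

    One outbred focal parent carries two phased haplotypes (labelled by the
    grandparents "gp1" and "gp2"); progeny inherit crossover mosaics with
    Poisson crossovers (1 per morgan, no interference).  The phenotype is
    ``effect x haplotype + noise`` with the effect sized so the QTL explains
    the requested fraction of variance.  Markers are emitted unphased: the
    alternate allele sits on a random haplotype per marker, as in raw
    variant calls, with calls flipped at ``genotyping_error``; the
    grandparent of origin of each alternate allele is given in
    ``alt_origin`` (the "GBS-like" parental table).
    """
    rng = np.random.default_rng(cfg.seed)
    n_chroms = len(cfg.chrom_lengths_cm)
    per_chrom = np.full(n_chroms, cfg.n_markers // n_chroms)
    per_chrom[: cfg.n_markers % n_chroms] += 1

    chrom, cm, ids = [], [], []
    for c in range(n_chroms):
        L = cfg.chrom_lengths_cm[c]
        k = int(per_chrom[c])
        pos = np.linspace(0, L, k)
        for j, p in enumerate(pos):
            chrom.append(f"chr{c + 1}")
            cm.append(p)
            ids.append(f"m_chr{c + 1}_{j:04d}")
    cm = np.array(cm)
    pos_bp = np.round(cm * 250_000).astype(np.int64)  # ~4 cM / Mb

    # inheritance mosaics
    hap = np.empty((cfg.n_progeny, len(ids)), dtype=np.int8)
    offset = 0
    for c in range(n_chroms):
        L = cfg.chrom_lengths_cm[c]
        k = int(per_chrom[c])
        marker_cm = cm[offset : offset + k]
        for i in range(cfg.n_progeny):
            n_co = rng.poisson(L / 100.0)
            breaks = np.sort(rng.uniform(0, L, size=n_co))
            start = int(rng.integers(2))
            states = (start + np.searchsorted(breaks, marker_cm)) % 2
            hap[i, offset : offset + k] = states
        offset += k

    qtl_chrom, qtl_cm, r2 = cfg.qtl
    chrom_offsets = np.concatenate([[0], np.cumsum(per_chrom)])
    lo, hi = chrom_offsets[qtl_chrom], chrom_offsets[qtl_chrom + 1]
    qtl_marker = int(lo + np.argmin(np.abs(cm[lo:hi] - qtl_cm)))
    effect = 2.0 * np.sqrt(cfg.phenotype_noise * r2 / (1.0 - r2)) if r2 > 0 else 0.0
    phenotype = (
        effect * hap[:, qtl_marker]
        + rng.normal(0, np.sqrt(cfg.phenotype_noise), size=cfg.n_progeny)
    )

    alt_on = rng.integers(0, 2, size=len(ids))
    alt_presence = (hap == alt_on[None, :]).astype(np.int8)
    if cfg.genotyping_error > 0:
        flip = rng.random(alt_presence.shape) < cfg.genotyping_error
        alt_presence = np.where(flip, 1 - alt_presence, alt_presence).astype(np.int8)
    if cfg.missing_rate > 0:
        mask = rng.random(alt_presence.shape) < cfg.missing_rate
        alt_presence = np.where(mask, MISSING, alt_presence).astype(np.int8)
    alt_origin = {
        mid: ("gp1" if alt_on[j] == 0 else "gp2") for j, mid in enumerate(ids)
    }
    progeny = [f"F1_{i:03d}" for i in range(cfg.n_progeny)]
    truth = TruthSet(
        haplotypes=hap, qtl_marker=qtl_marker, qtl_effect=effect
    )
    return CrossSim(
        alt_presence=alt_presence, chrom=chrom, pos_bp=pos_bp,
        pos_cm_true=cm, marker_ids=ids, progeny=progeny,
        alt_origin=alt_origin, phenotype=phenotype, truth=truth,
    )
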