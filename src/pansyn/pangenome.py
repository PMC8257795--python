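"""Synteny-constrained pan-genome construction and presence–absence analysis.

The pan-genome is an ordered table of orthogroups anchored to a reference
genome's gene-rank order.  Orthology is constrained to collinear blocks
(hits outside any block are discarded and homeologous self-genome pairing
is masked), tandem arrays are condensed to a single orthologous path, and
each orthogroup is placed hierarchically: by its reference gene's rank if
single-copy there, by its best within-genome bitscore member if multi-copy,
or at the mean block-interpolated syntenic position of the other genomes'
representatives when absent from the reference.
"""

from __future__ import annotations

import logging
import warnings
from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices
from scipy.stats import fisher_exact

from .models import CollinearBlock, GeneModel, Orthogroup, PangenomeEntry, SimilarityHit
from .synteny import ChainParams, PrunedHitSet, cluster_orthogroups

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Synteny constraint
# ---------------------------------------------------------------------------

def constrain_to_synteny(
    hits: list[SimilarityHit],
    genes: list[GeneModel],
    blocks: list[CollinearBlock],
) -> list[SimilarityHit]:
    """Drop hits that fall outside every collinear block.

    A cross-genome hit survives when some block between the two
    genome/chromosome pairs spans both gene ranks.  Self-genome hits
    between different chromosomes (homeologs) are masked from orthologous
    pairing; self-genome same-chromosome hits (tandem candidates) pass
    through.  Small translocations below the minimum block size are, by
    construction, not captured.
    """
    gene_by_id = {(g.genome, g.gene_id): g for g in genes}
    spans: dict[tuple[str, str, str, str], list[tuple[int, int, int, int]]] = defaultdict(list)
    for b in blocks:
        qs, qe = b.query_span
        ts, te = b.target_span
        spans[(b.query_genome, b.query_chrom, b.target_genome, b.target_chrom)].append(
            (qs, qe, ts, te)
        )
        spans[(b.target_genome, b.target_chrom, b.query_genome, b.query_chrom)].append(
            (ts, te, qs, qe)
        )
    kept = []
    for h in hits:
        q = gene_by_id.get((h.query_genome, h.query_gene))
        t = gene_by_id.get((h.target_genome, h.target_gene))
        if q is None or t is None:
            continue
        if h.query_genome == h.target_genome:
            if q.chrom == t.chrom:
                kept.append(h)  # tandem-array candidate
            continue
        for qs, qe, ts, te in spans.get((q.genome, q.chrom, t.genome, t.chrom), ()):
            if qs <= q.rank <= qe and ts <= t.rank <= te:
                kept.append(h)
                break
    return kept


def synteny_constrained_orthogroups(
    hits: list[SimilarityHit],
    genes: list[GeneModel],
    blocks: list[CollinearBlock],
) -> list[Orthogroup]:
    """Re-cluster orthogroups on the synteny-constrained hit network."""
    constrained = constrain_to_synteny(hits, genes, blocks)
    all_genes = [(g.genome, g.gene_id) for g in genes]
    return cluster_orthogroups(PrunedHitSet(hits=constrained), all_genes=all_genes)


# ---------------------------------------------------------------------------
# Tandem condensation and placement
# ---------------------------------------------------------------------------

def _summed_bitscores(hits: list[SimilarityHit]) -> dict[tuple[str, str], float]:
    """Summed within-genome bitscore per gene (query or target side)."""
    sums: dict[tuple[str, str], float] = defaultdict(float)
    for h in hits:
        if h.query_genome == h.target_genome:
            sums[(h.query_genome, h.query_gene)] += h.bitscore
            sums[(h.target_genome, h.target_gene)] += h.bitscore
    return sums


def _representative(
    candidates: list[GeneModel],
    bitscore_of: dict[tuple[str, str], float],
) -> GeneModel:
    """Pick one representative: highest summed within-genome bitscore, ties
    by physical centrality (closest to the median rank of the group), then
    gene length, then gene_id for total determinism."""
    median_rank = float(np.median([g.rank for g in candidates]))
    return min(
        candidates,
        key=lambda g: (
            -bitscore_of.get((g.genome, g.gene_id), 0.0),
            abs(g.rank - median_rank),
            -g.length,
            g.gene_id,
        ),
    )


def condense_tandem_arrays(
    orthogroups: list[Orthogroup],
    genes: list[GeneModel],
    within_genome_hits: list[SimilarityHit],
    max_gap: int = 20,
) -> dict[tuple[str, str], list[list[GeneModel]]]:
    """Group same-orthogroup genes of one genome into tandem arrays.

    Genes of one orthogroup on one chromosome whose ranks chain within
    ``max_gap`` of each other form a single array (one member list, one
    representative); copies on different chromosomes or further apart stay
    separate arrays.  Returns arrays keyed by (og_id, genome).
    """
    gene_by_id = {(g.genome, g.gene_id): g for g in genes}
    arrays: dict[tuple[str, str], list[list[GeneModel]]] = {}
    for og in orthogroups:
        per_genome: dict[str, list[GeneModel]] = defaultdict(list)
        for genome, gid in sorted(og.members):
            gm = gene_by_id.get((genome, gid))
            if gm is not None:
                per_genome[genome].append(gm)
        for genome, members in per_genome.items():
            members.sort(key=lambda g: (g.chrom, g.rank))
            groups: list[list[GeneModel]] = []
            for g in members:
                if (
                    groups
                    and groups[-1][-1].chrom == g.chrom
                    and g.rank - groups[-1][-1].rank <= max_gap
                ):
                    groups[-1].append(g)
                else:
                    groups.append([g])
            arrays[(og.og_id, genome)] = groups
    return arrays


@dataclass
class _RefInterpolator:
    """Maps (genome, chrom, rank) into reference rank space via the anchors
    of the enclosing collinear block (linear interpolation between the two
    nearest anchors)."""

    blocks_by_side: dict[tuple[str, str], list[CollinearBlock]]
    reference: str

    @classmethod
    def build(cls, blocks: list[CollinearBlock], reference: str) -> "_RefInterpolator":
        by_side: dict[tuple[str, str], list[CollinearBlock]] = defaultdict(list)
        for b in blocks:
            if b.query_genome == reference and b.target_genome != reference:
                by_side[(b.target_genome, b.target_chrom)].append(b)
            elif b.target_genome == reference and b.query_genome != reference:
                by_side[(b.query_genome, b.query_chrom)].append(b)
        return cls(blocks_by_side=by_side, reference=reference)

    def project(self, genome: str, chrom: str, rank: int) -> tuple[str, float] | None:
        """Returns (reference chrom, interpolated reference rank) or None."""
        best: tuple[int, str, float] | None = None  # (distance-to-span, chrom, pos)
        for b in self.blocks_by_side.get((genome, chrom), ()):
            if b.query_genome == self.reference:
                ref_chrom = b.query_chrom
                pairs = [(t, q) for q, t in b.anchors]
            else:
                ref_chrom = b.target_chrom
                pairs = list(b.anchors)
            pairs.sort()
            own = np.array([p[0] for p in pairs], dtype=float)
            ref = np.array([p[1] for p in pairs], dtype=float)
            dist = 0 if own[0] <= rank <= own[-1] else int(
                min(abs(rank - own[0]), abs(rank - own[-1]))
            )
            pos = float(np.interp(rank, own, ref))
            if best is None or dist < best[0]:
                best = (dist, ref_chrom, pos)
        if best is None or best[0] > 0:
            return None if best is None else (best[1], best[2])
        return best[1], best[2]


def place_orthogroups(
    orthogroups: list[Orthogroup],
    genes: list[GeneModel],
    blocks: list[CollinearBlock],
    within_genome_hits: list[SimilarityHit],
    reference_genome: str,
    tandem_gap: int = 20,
) -> tuple[list[PangenomeEntry], list[Orthogroup]]:
    """Position every orthogroup in reference rank space.

    Placement is hierarchical: single-copy-in-reference orthogroups take
    that gene's rank; multi-copy ones take the rank of the member with the
    highest summed within-genome bitscore (ties by centrality then length);
    reference-absent ones take the mean block-interpolated syntenic
    position of each other genome's representative.  Orthogroups with no
    placeable member go to the returned "unplaced" bucket.  Output is
    totally ordered by (pan_chrom, pan_position, pan_id).
    """
    gene_by_id = {(g.genome, g.gene_id): g for g in genes}
    bitscores = _summed_bitscores(within_genome_hits)
    arrays = condense_tandem_arrays(
        orthogroups, genes, within_genome_hits, max_gap=tandem_gap
    )
    interp = _RefInterpolator.build(blocks, reference_genome)

    entries: list[PangenomeEntry] = []
    unplaced: list[Orthogroup] = []
    for og in orthogroups:
        members: dict[str, list[str]] = defaultdict(list)
        for genome, gid in sorted(og.members):
            if (genome, gid) in gene_by_id:
                members[genome].append(gid)
        representative: dict[str, str] = {}
        for genome in members:
            cand = [gene_by_id[(genome, gid)] for gid in members[genome]]
            representative[genome] = _representative(cand, bitscores).gene_id

        ref_members = members.get(reference_genome, [])
        pan_chrom: str | None = None
        pan_pos: float | None = None
        if len(ref_members) == 1:
            g = gene_by_id[(reference_genome, ref_members[0])]
            pan_chrom, pan_pos = g.chrom, float(g.rank)
        elif len(ref_members) > 1:
            ref_arrays = arrays.get((og.og_id, reference_genome), [])
            # one candidate per condensed array
            cands = [
                _representative(arr, bitscores) for arr in ref_arrays
            ] or [gene_by_id[(reference_genome, gid)] for gid in ref_members]
            g = _representative(cands, bitscores)
            pan_chrom, pan_pos = g.chrom, float(g.rank)
        else:
            projected: list[tuple[str, float]] = []
            for genome in sorted(members):
                g = gene_by_id[(genome, representative[genome])]
                proj = interp.project(genome, g.chrom, g.rank)
                if proj is not None:
                    projected.append(proj)
            if projected:
                chrom_votes = defaultdict(list)
                for c, p in projected:
                    chrom_votes[c].append(p)
                pan_chrom = max(
                    chrom_votes, key=lambda c: (len(chrom_votes[c]), c)
                )
                pan_pos = float(np.mean(chrom_votes[pan_chrom]))
        if pan_chrom is None or pan_pos is None:
            unplaced.append(og)
            continue
        entries.append(
            PangenomeEntry(
                pan_id=og.og_id, pan_chrom=pan_chrom, pan_position=pan_pos,
                members=dict(members), representative=representative,
            )
        )
    entries.sort(key=lambda e: e.sort_key())
    return entries, unplaced


# ---------------------------------------------------------------------------
# PAV tables and absence runs
# ---------------------------------------------------------------------------

@dataclass
class PavMatrix:
    """Orthogroup x genome presence matrix with derived flags."""

    table: pd.DataFrame  # bool, index pan_id, columns genomes

    @property
    def complete(self) -> pd.Series:
        return self.table.all(axis=1)

    @property
    def incomplete(self) -> pd.Series:
        return ~self.table.all(axis=1)

    def private_to(self, genome: str) -> pd.Series:
        return self.table[genome] & (self.table.sum(axis=1) == 1)

    def summary(self) -> dict:
        n = len(self.table)
        out = {
            "n_orthogroups": n,
            "n_complete": int(self.complete.sum()),
            "n_incomplete": int(self.incomplete.sum()),
            "incomplete_pct": round(100.0 * self.incomplete.sum() / n, 1) if n else 0.0,
        }
        for g in self.table.columns:
            out[f"private_{g}"] = int(self.private_to(g).sum())
        return out


def pav_table(
    entries: list[PangenomeEntry],
    genomes: list[str],
    outgroup: str | None = None,
) -> PavMatrix:
    """Presence–absence matrix over the pan-genome entries.

    An optional outgroup genome is included in orthogroups but excluded
    from presence/absence accounting.
    """
    cols = [g for g in genomes if g != outgroup]
    data = {
        g: [e.presence(g) for e in entries] for g in cols
    }
    df = pd.DataFrame(data, index=[e.pan_id for e in entries], dtype=bool)
    return PavMatrix(table=df)


def absence_runs(
    entries: list[PangenomeEntry],
    focal_genome: str,
    min_run: int = 5,
) -> list[tuple[str, int, int, int]]:
    """Maximal runs of >= ``min_run`` consecutive pan entries absent in the
    focal genome, within each pan chromosome.

    Returns (pan_chrom, start entry index, end entry index inclusive,
    run length) in pan order.
    """
    ordered = sorted(entries, key=lambda e: e.sort_key())
    runs = []
    run_start = None
    prev_chrom = None
    for i, e in enumerate(ordered + [None]):
        boundary = e is None or e.pan_chrom != prev_chrom
        absent = e is not None and not e.presence(focal_genome)
        if run_start is not None and (boundary or not absent):
            length = i - run_start
            if length >= min_run:
                runs.append((prev_chrom, run_start, i - 1, length))
            run_start = None
        if e is None:
            break
        if absent and (run_start is None or boundary):
            run_start = i
        prev_chrom = e.pan_chrom
    return runs


# ---------------------------------------------------------------------------
# Absence sequence classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AbsenceAlignmentStats:
    coverage_pct: float
    identity_pct: float
    category: str  # very_similar | diverged | absent


def _dna_local_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    return aligner


def classify_absence(cds: str, syntenic_region: str) -> AbsenceAlignmentStats:
    """Classify an annotation absence by aligning the orthogroup CDS to the
    syntenic region of the absent genome.

    Coverage is 100 x matched positions / CDS length and identity is over
    aligned columns.  Categories: very_similar (coverage > 99 and identity
    >= 95), diverged (coverage >= 75 and identity >= 75, not very_similar),
    else absent.
    """
    if not cds:
        raise ValueError("empty CDS")
    cds = cds.upper()
    region = syntenic_region.upper()
    matches = mismatches = 0
    if region:
        alns = _dna_local_aligner().align(cds, region)
        if len(alns) > 0 and alns[0].score > 0:
            a, b = alns[0][0], alns[0][1]
            for ca, cb in zip(a, b):
                if ca == "-" or cb == "-":
                    continue
                if ca == cb:
                    matches += 1
                else:
                    mismatches += 1
    coverage = 100.0 * matches / len(cds)
    identity = (
        100.0 * matches / (matches + mismatches) if matches + mismatches else 0.0
    )
    if coverage > 99 and identity >= 95:
        category = "very_similar"
    elif coverage >= 75 and identity >= 75:
        category = "diverged"
    else:
        category = "absent"
    return AbsenceAlignmentStats(
        coverage_pct=coverage, identity_pct=identity, category=category
    )


# ---------------------------------------------------------------------------
# Interval private-gene enrichment
# ---------------------------------------------------------------------------

def interval_private_enrichment(
    pav: PavMatrix,
    interval_ids: list[str],
    focal_genome: str,
) -> tuple[float, float, float]:
    """Fisher's exact test for private-gene enrichment inside an interval.

    The 2x2 table crosses (interval vs rest of the pan-genome) with
    (private-to-focal vs not).  Returns (private fraction percent within
    the interval, sample odds ratio, two-sided exact p-value).
    """
    interval_ids = [i for i in interval_ids if i in pav.table.index]
    if not interval_ids:
        raise ValueError("interval is disjoint from the pan-genome")
    private = pav.private_to(focal_genome)
    in_interval = pav.table.index.isin(interval_ids)
    a = int((private & in_interval).sum())          # interval, private
    b = int(in_interval.sum()) - a                  # interval, not private
    c = int(private.sum()) - a                      # rest, private
    d = len(pav.table) - a - b - c                  # rest, not private
    _, p_value = fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if b * c == 0:
        odds = float("inf") if a * d > 0 else 0.0
    else:
        odds = (a * d) / (b * c)
    if a == 0:
        odds = 0.0
    private_fraction = round(100.0 * a / (a + b), 1)
    return private_fraction, odds, float(p_value)


# ---------------------------------------------------------------------------
# Alternative-haplotype projection
# ---------------------------------------------------------------------------

@dataclass
class HaplotypeComparison:
    """Pan entry compared between primary and alternative haplotypes."""

    pan_id: str
    primary_gene: str | None
    alt_gene: str | None
    identity_pct: float | None
    cls: str  # both | primary_only_with_alt_contig | alt_only | primary_only_no_alt_contig


def percent_identity(prot_a: str, prot_b: str) -> float:
    """Percent identity of a global protein alignment:
    100 x identical / (aligned positions + internal gap positions),
    terminal gaps excluded."""
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aligner.mode = "global"
    aln = aligner.align(prot_a.upper(), prot_b.upper())[0]
    a, b = aln[0], aln[1]
    # trim terminal gap columns (leading/trailing gaps in either row)
    start, end = 0, len(a)
    while start < end and (a[start] == "-" or b[start] == "-"):
        start += 1
    while end > start and (a[end - 1] == "-" or b[end - 1] == "-"):
        end -= 1
    identical = aligned = internal_gaps = 0
    for ca, cb in zip(a[start:end], b[start:end]):
        if ca == "-" or cb == "-":
            internal_gaps += 1
            continue
        aligned += 1
        if ca == cb:
            identical += 1
    denom = aligned + internal_gaps
    return 100.0 * identical / denom if denom else 0.0


def project_to_alt_haplotype(
    entries: list[PangenomeEntry],
    focal_genome: str,
    alt_hits: list[SimilarityHit],
    alt_gene_contig: dict[str, str],
    primary_proteins: dict[str, str],
    alt_proteins: dict[str, str],
) -> tuple[list[HaplotypeComparison], dict[str, float]]:
    """Project pan-genome representatives onto the alternative haplotype.

    ``alt_hits`` map primary genes of the focal genome to alternative-
    haplotype genes.  Each alternative contig is placed at the midpoint of
    its hit partners' pan positions; pan entries are then classified:
    ``both`` (with percent identity), ``primary_only_with_alt_contig``
    (no alt ortholog but a placed contig spans the locus),
    ``primary_only_no_alt_contig``, and ``alt_only`` entries for alt genes
    whose orthogroup has no primary member.
    """
    best_alt: dict[str, tuple[float, str]] = {}
    best_primary: dict[str, tuple[float, str]] = {}
    for h in alt_hits:
        cur = best_alt.get(h.query_gene)
        if cur is None or (h.bitscore, h.target_gene) > (cur[0], cur[1]):
            best_alt[h.query_gene] = (h.bitscore, h.target_gene)
        cur = best_primary.get(h.target_gene)
        if cur is None or (h.bitscore, h.query_gene) > (cur[0], cur[1]):
            best_primary[h.target_gene] = (h.bitscore, h.query_gene)

    pan_pos_of_primary: dict[str, tuple[str, float]] = {}
    for e in entries:
        for gid in e.members.get(focal_genome, []):
            pan_pos_of_primary[gid] = (e.pan_chrom, e.pan_position)

    # contig placement: midpoint (and span) of members' primary pan positions
    contig_positions: dict[str, list[float]] = defaultdict(list)
    contig_chrom: dict[str, str] = {}
    for alt_gene, (_, primary_gene) in best_primary.items():
        contig = alt_gene_contig.get(alt_gene)
        loc = pan_pos_of_primary.get(primary_gene)
        if contig is None or loc is None:
            continue
        contig_positions[contig].append(loc[1])
        contig_chrom.setdefault(contig, loc[0])
    contig_midpoints = {
        c: float((min(ps) + max(ps)) / 2.0) for c, ps in contig_positions.items()
    }
    contig_spans = {
        c: (contig_chrom[c], min(ps), max(ps)) for c, ps in contig_positions.items()
    }

    comparisons: list[HaplotypeComparison] = []
    matched_alt: set[str] = set()
    for e in entries:
        primary_gene = e.representative.get(focal_genome)
        if primary_gene is None:
            continue
        hit = best_alt.get(primary_gene)
        if hit is not None:
            alt_gene = hit[1]
            matched_alt.add(alt_gene)
            ident = None
            pa = primary_proteins.get(primary_gene)
            pb = alt_proteins.get(alt_gene)
            if pa and pb:
                ident = percent_identity(pa, pb)
            comparisons.append(
                HaplotypeComparison(
                    pan_id=e.pan_id, primary_gene=primary_gene,
                    alt_gene=alt_gene, identity_pct=ident, cls="both",
                )
            )
            continue
        covered = any(
            chrom == e.pan_chrom and lo <= e.pan_position <= hi
            for chrom, lo, hi in contig_spans.values()
        )
        comparisons.append(
            HaplotypeComparison(
                pan_id=e.pan_id, primary_gene=primary_gene, alt_gene=None,
                identity_pct=None,
                cls="primary_only_with_alt_contig" if covered
                else "primary_only_no_alt_contig",
            )
        )
    for alt_gene in sorted(alt_proteins):
        if alt_gene in matched_alt or alt_gene in best_primary:
            continue
        comparisons.append(
            HaplotypeComparison(
                pan_id="", primary_gene=None, alt_gene=alt_gene,
                identity_pct=None, cls="alt_only",
            )
        )
    return comparisons, contig_midpoints


def build_pangenome(
    hits: list[SimilarityHit],
    genes: list[GeneModel],
    reference_genome: str,
    params: ChainParams | None = None,
) -> tuple[list[PangenomeEntry], list[Orthogroup]]:
    """End-to-end pan-genome construction.

    Hits are pruned to one per gene per target genome (the pan-genome
    scaling), collinear blocks are computed across genome pairs with the
    pan-genome chaining parameters, orthogroups are re-clustered on the
    synteny-constrained network, and every orthogroup is placed against the
    reference gene order.  Returns (ordered entries, unplaced orthogroups).
    """
    from .synteny import blocks_between_genomes, prune_hits

    params = params or ChainParams.pangenome()
    pruned = prune_hits(hits, n_top=1)
    blocks = blocks_between_genomes(pruned.hits, genes, params)
    orthogroups = synteny_constrained_orthogroups(pruned.hits, genes, blocks)
    within = [h for h in hits if h.query_genome == h.target_genome]
    return place_orthogroups(
        orthogroups, genes, blocks, within, reference_genome,
        tandem_gap=params.max_gap,
    )


def write_pangenome_table(entries: list[PangenomeEntry], path, genomes: list[str]):
    """Tab-separated pan-genome table: pan_id, pan_chrom, pan_position, then
    per-genome representative and member columns."""
    rows = []
    for e in entries:
        row = {
            "pan_id": e.pan_id, "pan_chrom": e.pan_chrom,
            "pan_position": e.pan_position,
        }
        for g in genomes:
            row[f"{g}_representative"] = e.representative.get(g, "")
            row[f"{g}_members"] = ",".join(e.members.get(g, []))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
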