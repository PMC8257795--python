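"""Synteny detection in gene-rank space.

The unit of position here is the *rank* of a gene along its chromosome
(0-based order of gene starts), not base pairs.  Collinear blocks are
maximal monotone chains of homologous gene pairs ("anchors") in this 2-D
rank space; a whole-genome duplication shows up as off-diagonal homeolog
blocks in a genome's self-comparison, and the number of such blocks in
excess of the base chromosome count measures how many large rearrangements
have accumulated since the duplication.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import networkx as nx
import numpy as np
from sklearn.cluster import DBSCAN

from .models import CollinearBlock, GeneModel, Orthogroup, SimilarityHit

NO_REARRANGEMENTS = "no rearrangements"


@dataclass(frozen=True)
class ChainParams:
    """Collinear-chaining and density-refinement parameters.

    Defaults follow the paralog (homeolog) analysis: anchors may be up to
    ``max_gap`` ranks apart on either axis, chains need ``min_size`` anchors,
    and anchors are pre-filtered with DBSCAN (``dbscan_radius`` /
    ``dbscan_min_hits``).  Pan-genome (orthology) runs use the tighter
    ``pangenome()`` preset.
    """

    max_gap: int = 50
    min_size: int = 10
    dbscan_radius: float = 50.0
    dbscan_min_hits: int = 10

    @classmethod
    def paralog(cls) -> "ChainParams":
        return cls(max_gap=50, min_size=10, dbscan_radius=50.0, dbscan_min_hits=10)

    @classmethod
    def pangenome(cls) -> "ChainParams":
        return cls(max_gap=20, min_size=10, dbscan_radius=50.0, dbscan_min_hits=10)


@dataclass
class PrunedHitSet:
    hits: list[SimilarityHit]
    n_top: int = 2


# ---------------------------------------------------------------------------
# Hit pruning and orthogroup clustering
# ---------------------------------------------------------------------------

def prune_hits(hits: list[SimilarityHit], n_top: int = 2) -> PrunedHitSet:
    """Keep the ``n_top`` best-bitscore hits per (query gene, target genome).

    Two hits per target genome suffice to capture both the ortholog and the
    WGD homeolog of a query gene.  Ties at the cutoff keep the hit with the
    lexicographically smaller target gene id.
    """
    if n_top < 1:
        raise ValueError(f"n_top must be >= 1, got {n_top}")
    grouped: dict[tuple[str, str, str], list[SimilarityHit]] = defaultdict(list)
    for h in hits:
        grouped[(h.query_genome, h.query_gene, h.target_genome)].append(h)
    kept: list[SimilarityHit] = []
    for key in sorted(grouped):
        group = sorted(grouped[key], key=lambda h: (-h.bitscore, h.target_gene))
        kept.extend(group[:n_top])
    return PrunedHitSet(hits=kept, n_top=n_top)


def cluster_orthogroups(
    pruned: PrunedHitSet,
    all_genes: list[tuple[str, str]] | None = None,
) -> list[Orthogroup]:
    """Cluster genes into orthogroups as connected components of the
    reciprocal retained-hit graph.

    An edge joins two genes when the hit between them survives pruning in
    either direction.  ``all_genes`` (``(genome, gene_id)`` pairs) supplies
    hit-less genes, which become singleton orthogroups.  Orthogroups are
    numbered deterministically by their smallest member.
    """
    graph = nx.Graph()
    if all_genes:
        graph.add_nodes_from(all_genes)
    for h in pruned.hits:
        a = (h.query_genome, h.query_gene)
        b = (h.target_genome, h.target_gene)
        if a != b:
            graph.add_edge(a, b)
    components = sorted(
        (sorted(c) for c in nx.connected_components(graph)),
        key=lambda c: c[0],
    )
    width = max(5, len(str(len(components))))
    return [
        Orthogroup(og_id=f"OG{idx:0{width}d}", members=frozenset(comp))
        for idx, comp in enumerate(components)
    ]


def orthogroup_lookup(orthogroups: list[Orthogroup]) -> dict[tuple[str, str], str]:
    return {m: og.og_id for og in orthogroups for m in og.members}


# ---------------------------------------------------------------------------
# Collinear chaining
# ---------------------------------------------------------------------------

def _longest_chain(anchors: list[tuple[int, int]], max_gap: int, sign: int):
    """Longest monotone chain (target increasing if sign=+1, decreasing if
    sign=-1) with consecutive anchors within max_gap on both axes.  O(n^2) DP.

    Returns (chain as list of anchor indices); ties prefer the chain whose
    first anchor has the smaller query rank (then smaller target rank).
    """
    n = len(anchors)
    if n == 0:
        return []
    order = sorted(range(n), key=lambda i: (anchors[i][0], sign * anchors[i][1]))
    best_len = [1] * n
    prev = [-1] * n
    for oi in range(n):
        i = order[oi]
        qi, ti = anchors[i]
        for oj in range(oi):
            j = order[oj]
            qj, tj = anchors[j]
            if qj >= qi:
                continue
            if sign * (ti - tj) <= 0:
                continue
            if qi - qj > max_gap or abs(ti - tj) > max_gap:
                continue
            if best_len[j] + 1 > best_len[i]:
                best_len[i] = best_len[j] + 1
                prev[i] = j
    # pick the best terminal; tie-break on the chain start anchor
    def start_of(i: int) -> tuple[int, int]:
        while prev[i] != -1:
            i = prev[i]
        return anchors[i]

    best = max(range(n), key=lambda i: (best_len[i], (-start_of(i)[0], -start_of(i)[1])))
    chain = []
    i = best
    while i != -1:
        chain.append(i)
        i = prev[i]
    chain.reverse()
    return chain


def chain_collinear_blocks(
    anchors: list[tuple[int, int]],
    params: ChainParams,
    query_genome: str = "q",
    query_chrom: str = "q",
    target_genome: str = "t",
    target_chrom: str = "t",
) -> list[CollinearBlock]:
    """Chain anchors into maximal collinear blocks.

    Chains are monotone in both rank axes (same or inverted orientation)
    with consecutive anchors at most ``max_gap`` ranks apart on each axis.
    Blocks are extracted greedily by chain length (ties by smaller starting
    query rank); each anchor belongs to at most one block, and chains
    shorter than ``min_size`` are discarded.
    """
    remaining = sorted(set(anchors))
    blocks: list[CollinearBlock] = []
    while remaining:
        fwd = _longest_chain(remaining, params.max_gap, +1)
        rev = _longest_chain(remaining, params.max_gap, -1)
        cand = []
        if fwd:
            cand.append((len(fwd), remaining[fwd[0]][0], "same", fwd))
        if rev:
            cand.append((len(rev), remaining[rev[0]][0], "inverted", rev))
        if not cand:
            break
        cand.sort(key=lambda c: (-c[0], c[1], c[2]))
        length, _, orientation, idx_chain = cand[0]
        if length < params.min_size:
            break
        chain_anchors = [remaining[i] for i in idx_chain]
        blocks.append(
            CollinearBlock(
                query_genome=query_genome, query_chrom=query_chrom,
                target_genome=target_genome, target_chrom=target_chrom,
                anchors=chain_anchors, orientation=orientation,
            )
        )
        used = set(chain_anchors)
        remaining = [a for a in remaining if a not in used]
    return blocks


def density_refine(
    anchors: list[tuple[int, int]],
    radius: float = 50.0,
    min_hits: int = 10,
) -> list[list[tuple[int, int]]]:
    """DBSCAN over anchors in 2-D rank space (Euclidean metric).

    Returns dense anchor clusters; noise anchors are dropped before
    chaining.  Clusters are ordered by their smallest member.
    """
    if radius <= 0:
        raise ValueError(f"radius must be > 0, got {radius}")
    if not anchors:
        return []
    pts = np.asarray(sorted(set(anchors)), dtype=float)
    labels = DBSCAN(eps=radius, min_samples=min_hits, metric="euclidean").fit(pts).labels_
    clusters: dict[int, list[tuple[int, int]]] = defaultdict(list)
    for (q, t), lab in zip(pts.astype(int), labels):
        if lab >= 0:
            clusters[lab].append((int(q), int(t)))
    return sorted((sorted(c) for c in clusters.values()), key=lambda c: c[0])


def anchors_from_hits(
    hits: list[SimilarityHit], genes: list[GeneModel]
) -> dict[tuple[str, str, str, str], list[tuple[int, int]]]:
    """Deduplicated (query rank, target rank) anchors per
    (query genome, query chrom, target genome, target chrom).

    Cross-genome hit pairs are canonicalized to one direction
    (query genome < target genome) so reciprocal hits give one anchor.
    """
    gene_by_id = {(g.genome, g.gene_id): g for g in genes}
    out: dict[tuple[str, str, str, str], set[tuple[int, int]]] = defaultdict(set)
    for h in hits:
        q = gene_by_id.get((h.query_genome, h.query_gene))
        t = gene_by_id.get((h.target_genome, h.target_gene))
        if q is None or t is None:
            continue
        if (t.genome, t.gene_id) < (q.genome, q.gene_id):
            q, t = t, q
        out[(q.genome, q.chrom, t.genome, t.chrom)].add((q.rank, t.rank))
    return {k: sorted(v) for k, v in sorted(out.items())}


def blocks_between_genomes(
    hits: list[SimilarityHit],
    genes: list[GeneModel],
    params: ChainParams,
    refine: bool = True,
) -> list[CollinearBlock]:
    """Collinear blocks for every genome/chromosome pair in the hit set
    (cross-genome pairs only): optional DBSCAN density refinement, then
    monotone chaining within each dense cluster."""
    blocks: list[CollinearBlock] = []
    for (qg, qc, tg, tc), anchors in anchors_from_hits(hits, genes).items():
        if qg == tg:
            continue
        clusters = (
            density_refine(anchors, params.dbscan_radius, params.dbscan_min_hits)
            if refine else [anchors]
        )
        for cluster in clusters:
            blocks.extend(
                chain_collinear_blocks(
                    cluster, params,
                    query_genome=qg, query_chrom=qc,
                    target_genome=tg, target_chrom=tc,
                )
            )
    return blocks


def write_blocks(blocks: list[CollinearBlock], path) -> None:
    """Tab-separated block table: genome1, chrom1, genome2, chrom2,
    n_anchors, q_start, q_end, t_start, t_end, orientation (rank units)."""
    with open(path, "w") as fh:
        fh.write(
            "genome1\tchrom1\tgenome2\tchrom2\tn_anchors\t"
            "q_start_rank\tq_end_rank\tt_start_rank\tt_end_rank\torientation\n"
        )
        for b in blocks:
            qs, qe = b.query_span
            ts, te = b.target_span
            fh.write(
                f"{b.query_genome}\t{b.query_chrom}\t{b.target_genome}\t"
                f"{b.target_chrom}\t{b.n_anchors}\t{qs}\t{qe}\t{ts}\t{te}\t"
                f"{b.orientation}\n"
            )


# ---------------------------------------------------------------------------
# Homeolog block counting and the rearrangement interval
# ---------------------------------------------------------------------------

def count_homeolog_blocks(
    self_hits: list[SimilarityHit],
    genes: list[GeneModel],
    orthogroups: list[Orthogroup] | None,
    params: ChainParams | None = None,
    refine: bool = True,
) -> dict[tuple[str, str], int]:
    """Count homeolog collinear blocks per off-diagonal chromosome pair.

    ``self_hits`` are within-genome hits; they are restricted to pairs whose
    two genes share an orthogroup (when ``orthogroups`` given), mapped to
    rank space per unordered chromosome pair (self pairs excluded),
    optionally density-refined, then chained.  Returns block counts keyed by
    the unordered chromosome pair; ``sum(result.values())`` is the total
    block count used by :func:`rearrangement_interval`.
    """
    params = params or ChainParams.paralog()
    gene_by_id = {(g.genome, g.gene_id): g for g in genes}
    og_of = orthogroup_lookup(orthogroups) if orthogroups is not None else None

    pair_anchors: dict[tuple[str, str], set[tuple[int, int]]] = defaultdict(set)
    for h in self_hits:
        if h.query_genome != h.target_genome:
            continue
        q = gene_by_id.get((h.query_genome, h.query_gene))
        t = gene_by_id.get((h.target_genome, h.target_gene))
        if q is None or t is None or q.chrom == t.chrom:
            continue
        if og_of is not None:
            oq = og_of.get((q.genome, q.gene_id))
            ot = og_of.get((t.genome, t.gene_id))
            if oq is None or oq != ot:
                continue
        # canonical orientation for the unordered chromosome pair
        if q.chrom <= t.chrom:
            pair_anchors[(q.chrom, t.chrom)].add((q.rank, t.rank))
        else:
            pair_anchors[(t.chrom, q.chrom)].add((t.rank, q.rank))

    counts: dict[tuple[str, str], int] = {}
    for pair, anchors in sorted(pair_anchors.items()):
        anchor_list = sorted(anchors)
        if refine:
            clusters = density_refine(
                anchor_list, params.dbscan_radius, params.dbscan_min_hits
            )
        else:
            clusters = [anchor_list]
        n_blocks = 0
        for cluster in clusters:
            n_blocks += len(
                chain_collinear_blocks(
                    cluster, params,
                    query_chrom=pair[0], target_chrom=pair[1],
                )
            )
        if n_blocks:
            counts[pair] = n_blocks
    return counts


def rearrangement_interval(
    n_blocks: int, n_chroms: int, wgd_age_myr: float
) -> float | str:
    """Average time between chromosomal rearrangements since the WGD.

    The homeolog block count is corrected by the base chromosome number:
    a perfectly conserved post-WGD genome shows one block per homeolog
    pair, so only blocks in excess of ``n_chroms`` witness rearrangements.
    Returns Myr per rearrangement to one decimal, or the
    ``NO_REARRANGEMENTS`` sentinel when the block count equals the base
    chromosome number.
    """
    if n_chroms < 1:
        raise ValueError(f"n_chroms must be >= 1, got {n_chroms}")
    if wgd_age_myr <= 0:
        raise ValueError(f"wgd_age_myr must be > 0, got {wgd_age_myr}")
    if n_blocks < n_chroms:
        raise ValueError(
            f"n_blocks ({n_blocks}) must be >= n_chroms ({n_chroms})"
        )
    n_rearrangements = n_blocks - n_chroms
    if n_rearrangements == 0:
        return NO_REARRANGEMENTS
    return round(wgd_age_myr / n_rearrangements, 1)
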