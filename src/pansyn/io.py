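"""Readers and writers for the standard formats the pipeline touches.

GFF3 and VCF are 1-based inclusive on disk and converted to the internal
0-based half-open convention here; BED intervals are passed through
unchanged.  Similarity hits use the 12-column blast tabular dialect
(query id, target id, ..., bitscore in columns 1, 2 and 12).
"""

from __future__ import annotations

import logging
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .models import MISSING, AssemblySummary, GeneModel, GenotypeMatrix

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def parse_annotation(gff3_path: str | Path, genome_label: str) -> list[GeneModel]:
    """Read gene features from a GFF3 file into rank-ordered GeneModels.

    Ranks are assigned per chromosome by ascending start, ties broken by
    gene_id lexicographically, and are contiguous from 0.
    """
    gff3_path = Path(gff3_path)
    _validate_gff3_genes(gff3_path)
    db = gffutils.create_db(
        str(gff3_path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    raw: list[tuple[str, int, int, str, str]] = []
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes["ID"][0]
        # GFF3 1-based inclusive -> 0-based half-open
        raw.append((feat.seqid, feat.start - 1, feat.end, feat.strand, gene_id))

    genes: list[GeneModel] = []
    by_chrom: dict[str, list[tuple[str, int, int, str, str]]] = {}
    for rec in raw:
        by_chrom.setdefault(rec[0], []).append(rec)
    for chrom, recs in by_chrom.items():
        recs.sort(key=lambda r: (r[1], r[4]))
        for rank, (chrom_, start, end, strand, gene_id) in enumerate(recs):
            genes.append(
                GeneModel(
                    gene_id=gene_id, genome=genome_label, chrom=chrom_,
                    start=start, end=end,
                    strand=strand if strand in ("+", "-") else "+",
                    rank=rank,
                )
            )
    return genes


def _validate_gff3_genes(path: Path) -> None:
    """Pre-flight check so format violations name the offending line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GFF3 columns")
            if fields[2] != "gene":
                continue
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end < start:
                raise ParseError(f"{path}:{lineno}: end < start ({end} < {start})")
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            if "ID" not in attrs:
                raise ParseError(f"{path}:{lineno}: gene feature missing ID attribute")


def write_annotation(genes: list[GeneModel], path: str | Path) -> None:
    """Write GeneModels as a minimal GFF3 (converting back to 1-based)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            fh.write(
                f"{g.chrom}\tpansyn\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def parse_genotypes(vcf_path: str | Path) -> GenotypeMatrix:
    """Read a VCF into a matrix of reference-allele counts (0/1/2).

    Missing calls are encoded as -1; records with more than one ALT allele
    are retained but flagged multiallelic for downstream removal.
    """
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    sites: list[tuple[str, int, str, str]] = []
    calls_cols: list[np.ndarray] = []
    depth_cols: list[np.ndarray] = []
    multi: list[bool] = []
    any_depth = False
    for var in vcf:
        alts = var.ALT or ["."]
        sites.append((var.CHROM, var.POS, var.REF, ",".join(alts)))
        multi.append(len(alts) > 1)
        col = np.full(len(samples), MISSING, dtype=np.int16)
        for i, gt in enumerate(var.genotypes):
            alleles = gt[:-1]
            if len(alleles) != 2 or any(a < 0 for a in alleles):
                continue
            col[i] = sum(1 for a in alleles if a == 0)
        calls_cols.append(col)
        try:
            dp = var.format("DP")
        except KeyError:
            dp = None
        if dp is not None:
            any_depth = True
            depth_cols.append(dp.reshape(-1).astype(np.int32))
        else:
            depth_cols.append(np.full(len(samples), -1, dtype=np.int32))
    calls = (
        np.stack(calls_cols, axis=1)
        if calls_cols else np.zeros((len(samples), 0), dtype=np.int16)
    )
    depth = np.stack(depth_cols, axis=1) if (any_depth and depth_cols) else None
    return GenotypeMatrix(
        samples=samples, sites=sites, calls=calls, depth=depth,
        multiallelic=np.array(multi, dtype=bool),
    )


def write_genotypes(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a GenotypeMatrix as an uncompressed VCF.

    Reference-allele counts map back to GT: 2 -> 0/0, 1 -> 0/1, 0 -> 1/1,
    missing -> ./.
    """
    gt_map = {2: "0/0", 1: "0/1", 0: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        chroms = dict.fromkeys(s[0] for s in gm.sites)
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if gm.depth is not None:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples) + "\n"
        )
        fmt = "GT" if gm.depth is None else "GT:DP"
        for j, (chrom, pos, ref, alt) in enumerate(gm.sites):
            cells = []
            for i in range(gm.n_samples):
                gt = gt_map[int(gm.calls[i, j])]
                if gm.depth is not None:
                    gt = f"{gt}:{int(gm.depth[i, j])}"
                cells.append(gt)
            fh.write(
                f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\t{fmt}\t"
                + "\t".join(cells) + "\n"
            )


# ---------------------------------------------------------------------------
# Blast tabular hits
# ---------------------------------------------------------------------------

BLAST_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_hits(path: str | Path, query_genome: str, target_genome: str):
    """Read a 12-column blast tabular file into SimilarityHits.

    Self gene-to-same-gene hits are dropped on read.
    """
    from .models import SimilarityHit

    df = pd.read_csv(path, sep="\t", header=None, names=BLAST_COLUMNS)
    hits = []
    for row in df.itertuples(index=False):
        if query_genome == target_genome and row.qseqid == row.sseqid:
            continue
        hits.append(
            SimilarityHit(
                query_gene=str(row.qseqid), target_gene=str(row.sseqid),
                query_genome=query_genome, target_genome=target_genome,
                bitscore=float(row.bitscore),
            )
        )
    return hits


def write_hits(hits, path: str | Path) -> None:
    """Write SimilarityHits in the 12-column blast tabular dialect
    (unused middle columns zero-filled)."""
    with open(path, "w") as fh:
        for h in hits:
            fields = [h.query_gene, h.target_gene] + ["0"] * 9 + [f"{h.bitscore:g}"]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# BED intervals
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Read BED3 intervals (already 0-based half-open)."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append((f[0], int(f[1]), int(f[2])))
    return out


# ---------------------------------------------------------------------------
# Assembly summary
# ---------------------------------------------------------------------------

def assembly_summary(primary_size_mb: float, alt_size_mb: float) -> AssemblySummary:
    """Summarize the alternative-haplotype assembly relative to the primary.

    The alternative fraction (percent of the primary assembly covered by the
    alternative haplotype) is the headline diploid-completeness statistic for
    an outbred genome assembly.
    """
    if primary_size_mb <= 0:
        raise ValueError(f"primary_size_mb must be > 0, got {primary_size_mb}")
    if alt_size_mb < 0:
        raise ValueError(f"alt_size_mb must be >= 0, got {alt_size_mb}")
    return AssemblySummary(primary_size_mb=primary_size_mb, alt_size_mb=alt_size_mb)
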