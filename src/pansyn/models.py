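"""Shared in-memory containers for the pipeline.

All genomic intervals are stored 0-based half-open internally; file readers
and writers convert at the boundary (GFF3/VCF are 1-based inclusive, BED is
already 0-based half-open).  Genotypes are stored as *reference*-allele
counts (0/1/2), with -1 marking a missing call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

MISSING = -1


@dataclass(frozen=True)
class GeneModel:
    """One annotated gene with its rank-order position on its chromosome.

    ``rank`` is the 0-based order of the gene start within (genome, chrom);
    rank space, not physical space, is the coordinate system for all synteny
    computations.
    """

    gene_id: str
    genome: str
    chrom: str
    start: int  # 0-based
    end: int    # half-open
    strand: str = "+"
    rank: int = 0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"gene {self.gene_id}: start ({self.start}) must be < end ({self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SimilarityHit:
    """A directed protein-similarity hit between two genes."""

    query_gene: str
    target_gene: str
    query_genome: str
    target_genome: str
    bitscore: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.bitscore) or self.bitscore < 0:
            raise ValueError(
                f"hit {self.query_gene}->{self.target_gene}: "
                f"bitscore must be finite and >= 0, got {self.bitscore}"
            )


@dataclass
class GenotypeMatrix:
    """Sample x site matrix of reference-allele counts.

    ``calls[i, j]`` is the number of reference alleles carried by sample ``i``
    at site ``j`` (0, 1 or 2), or ``MISSING`` (-1).  ``sites`` holds
    ``(chrom, pos_1based, ref, alt)`` tuples; multi-allelic input records are
    kept but flagged so downstream filters can drop them.
    """

    samples: list[str]
    sites: list[tuple[str, int, str, str]]
    calls: np.ndarray
    depth: Optional[np.ndarray] = None
    multiallelic: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int16)
        if self.calls.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )
        if self.multiallelic is None:
            self.multiallelic = np.zeros(len(self.sites), dtype=bool)
        if self.depth is not None and self.depth.shape != self.calls.shape:
            raise ValueError("depth shape does not match calls")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def positions(self) -> np.ndarray:
        return np.array([s[1] for s in self.sites], dtype=np.int64)

    def chroms(self) -> list[str]:
        return [s[0] for s in self.sites]

    def take_sites(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index, dtype=np.int64)
        return GenotypeMatrix(
            samples=list(self.samples),
            sites=[self.sites[i] for i in index],
            calls=self.calls[:, index],
            depth=None if self.depth is None else self.depth[:, index],
            multiallelic=np.asarray(self.multiallelic)[index],
        )

    def sample_index(self, name: str) -> int:
        return self.samples.index(name)


@dataclass(frozen=True)
class AssemblySummary:
    """Primary vs alternative haplotype assembly sizes."""

    primary_size_mb: float
    alt_size_mb: float

    @property
    def alt_fraction_pct(self) -> float:
        """Alternative haplotype size as a percent of the primary assembly,
        rounded to one decimal for reporting."""
        return round(100.0 * self.alt_size_mb / self.primary_size_mb, 1)


@dataclass(frozen=True)
class Orthogroup:
    """A set of genes across genomes descended from one ancestral gene."""

    og_id: str
    members: frozenset  # of (genome, gene_id)

    def genomes(self) -> set[str]:
        return {g for g, _ in self.members}

    def genes_in(self, genome: str) -> list[str]:
        return sorted(gid for g, gid in self.members if g == genome)


@dataclass
class CollinearBlock:
    """A monotone chain of homologous gene pairs in rank space."""

    query_genome: str
    query_chrom: str
    target_genome: str
    target_chrom: str
    anchors: list[tuple[int, int]]  # (query rank, target rank)
    orientation: str  # "same" | "inverted"

    def __post_init__(self) -> None:
        if self.orientation not in ("same", "inverted"):
            raise ValueError(f"bad orientation {self.orientation!r}")

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)

    @property
    def query_span(self) -> tuple[int, int]:
        qs = [q for q, _ in self.anchors]
        return min(qs), max(qs)

    @property
    def target_span(self) -> tuple[int, int]:
        ts = [t for _, t in self.anchors]
        return min(ts), max(ts)


@dataclass
class PangenomeEntry:
    """One synteny-anchored orthogroup row of the pan-genome table."""

    pan_id: str
    pan_chrom: str
    pan_position: float
    members: dict[str, list[str]] = field(default_factory=dict)
    representative: dict[str, str] = field(default_factory=dict)

    def presence(self, genome: str) -> bool:
        return bool(self.members.get(genome))

    def sort_key(self) -> tuple:
        return (self.pan_chrom, self.pan_position, self.pan_id)


@dataclass(frozen=True)
class KaKsRecord:
    """Pairwise non-synonymous / synonymous substitution rates (NG86)."""

    og_id: str
    genome_a: str
    genome_b: str
    ka: float
    ks: float
    n_sites: float
    s_sites: float
    saturated: bool = False


@dataclass
class CrossGenotypes:
    """F1 pseudo-testcross progeny x marker phase-coded genotypes.

    ``geno[i, j]`` is 0 (phase-1 / "A" parental haplotype), 1 (phase-2 / "B")
    or ``MISSING``.  ``phase_parent`` labels, per marker, which grandparent
    contributed the alternate allele.
    """

    progeny: list[str]
    marker_ids: list[str]
    chrom: list[str]
    pos_bp: np.ndarray
    geno: np.ndarray
    pos_cm: Optional[np.ndarray] = None
    phase_parent: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.geno = np.asarray(self.geno, dtype=np.int8)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        if self.geno.shape != (len(self.progeny), len(self.marker_ids)):
            raise ValueError("geno shape inconsistent with progeny x markers")

    @property
    def n_progeny(self) -> int:
        return len(self.progeny)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def chrom_indices(self) -> dict[str, np.ndarray]:
        """Marker column indices per chromosome, in input order."""
        out: dict[str, np.ndarray] = {}
        for c in dict.fromkeys(self.chrom):
            out[c] = np.array([j for j, cc in enumerate(self.chrom) if cc == c])
        return out

    def take_markers(self, index: Sequence[int] | np.ndarray) -> "CrossGenotypes":
        index = np.asarray(index)
        return CrossGenotypes(
            progeny=list(self.progeny),
            marker_ids=[self.marker_ids[i] for i in index],
            chrom=[self.chrom[i] for i in index],
            pos_bp=self.pos_bp[index],
            geno=self.geno[:, index],
            pos_cm=None if self.pos_cm is None else self.pos_cm[index],
            phase_parent=None
            if self.phase_parent is None
            else [self.phase_parent[i] for i in index],
        )
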