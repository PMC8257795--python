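"""Pairwise molecular-evolution statistics for coding sequences.

Implements the Nei–Gojobori (1986) method: fractional synonymous /
non-synonymous site counting averaged over both sequences, substitution
counting averaged over all minimal mutational pathways between differing
codons, and Jukes–Cantor multiple-hit correction
``d = -(3/4) ln(1 - (4/3) p)``.  Proportions at or beyond the correction
domain (p >= 3/4) are flagged saturated.

Alignment is protein-guided: sequences are translated, globally aligned as
proteins, and the alignment is back-translated to codons; codon columns
containing gaps are excluded from counting.
"""

from __future__ import annotations

import logging
import warnings
from itertools import permutations

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .models import KaKsRecord

logger = logging.getLogger(__name__)

CODON_TABLE = dict(standard_dna_table.forward_table)
STOP_CODONS = set(standard_dna_table.stop_codons)
BASES = "ACGT"


class InternalStopError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Codon alignment
# ---------------------------------------------------------------------------

def _protein_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aligner.mode = "global"
    return aligner


def _prepare_cds(cds: str, label: str) -> str:
    cds = cds.upper().replace("U", "T")
    trailing = len(cds) % 3
    if trailing:
        warnings.warn(
            f"{label}: length {len(cds)} not divisible by 3; "
            f"trimming {trailing} trailing nt",
            stacklevel=3,
        )
        cds = cds[: len(cds) - trailing]
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    # a terminal stop is legitimate; an internal one is a frame error
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    for k, codon in enumerate(codons):
        if codon in STOP_CODONS:
            raise InternalStopError(f"{label}: internal stop codon at codon {k}")
    return "".join(codons)


def translate(cds: str) -> str:
    return str(Seq(cds).translate())


def align_codons(cds_a: str, cds_b: str) -> list[tuple[str, str]]:
    """Protein-guided global codon alignment of two coding sequences.

    Returns aligned codon columns as ``(codon_a, codon_b)`` pairs with
    ``---`` marking gaps.  Sequences with trailing partial codons are
    trimmed with a warning; internal stop codons raise.
    """
    a = _prepare_cds(cds_a, "cds_a")
    b = _prepare_cds(cds_b, "cds_b")
    prot_a, prot_b = translate(a), translate(b)
    aln = _protein_aligner().align(prot_a, prot_b)[0]
    cols: list[tuple[str, str]] = []
    ia = ib = 0
    sa, sb = aln[0], aln[1]
    for ca, cb in zip(sa, sb):
        codon_a = codon_b = "---"
        if ca != "-":
            codon_a = a[3 * ia : 3 * ia + 3]
            ia += 1
        if cb != "-":
            codon_b = b[3 * ib : 3 * ib + 3]
            ib += 1
        cols.append((codon_a, codon_b))
    return cols


# ---------------------------------------------------------------------------
# NG86 site and substitution counting
# ---------------------------------------------------------------------------

def _codon_site_counts(codon: str) -> tuple[float, float]:
    """Fractional (synonymous, non-synonymous) site counts for one codon.

    Each position contributes the fraction of its three possible point
    mutations that are synonymous; mutations creating a stop codon count as
    non-synonymous.
    """
    aa = CODON_TABLE[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        for base in BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if mutant not in STOP_CODONS and CODON_TABLE[mutant] == aa:
                syn += 1
        s += syn / 3.0
    return s, 3.0 - s


def _pathway_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, non-synonymous) substitution counts between two codons,
    averaged over all minimal mutational pathways with equal weight.

    Pathways passing through a stop codon are excluded; if every pathway is
    blocked (rare), all pathways are used.
    """
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return 0.0, 0.0
    totals: list[tuple[float, float]] = []
    blocked: list[tuple[float, float]] = []
    for order in permutations(diff):
        cur = codon_a
        sd = nd = 0.0
        ok = True
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
            aa_cur = CODON_TABLE.get(cur)
            aa_nxt = CODON_TABLE.get(nxt)
            if aa_cur is not None and aa_nxt is not None and aa_cur == aa_nxt:
                sd += 1
            else:
                nd += 1
            cur = nxt
        (totals if ok else blocked).append((sd, nd))
    use = totals if totals else blocked
    s = sum(x for x, _ in use) / len(use)
    n = sum(x for _, x in use) / len(use)
    return s, n


def jukes_cantor(p: float) -> float:
    """JC69 distance from a proportion of differing sites; domain p < 3/4."""
    if p >= 0.75:
        return float("nan")
    return -0.75 * np.log(1.0 - (4.0 / 3.0) * p)


def kaks_ng86(
    alignment: list[tuple[str, str]],
    og_id: str = "",
    genome_a: str = "a",
    genome_b: str = "b",
) -> KaKsRecord:
    """NG86 Ka/Ks from a gapped codon alignment.

    Gap-containing columns are excluded; at least 10 usable codon columns
    are required.  Site counts are averaged over the two sequences;
    substitution counts average over minimal mutational pathways; both
    proportions are Jukes–Cantor corrected.
    """
    cols = [
        (ca, cb) for ca, cb in alignment
        if "-" not in ca and "-" not in cb
        and ca not in STOP_CODONS and cb not in STOP_CODONS
    ]
    if len(cols) < 10:
        raise ValueError(
            f"need >= 10 gap-free codon columns, got {len(cols)}"
        )
    s_sites_a = s_sites_b = 0.0
    sd = nd = 0.0
    for ca, cb in cols:
        sa, _ = _codon_site_counts(ca)
        sb, _ = _codon_site_counts(cb)
        s_sites_a += sa
        s_sites_b += sb
        ds, dn = _pathway_counts(ca, cb)
        sd += ds
        nd += dn
    total_sites = 3.0 * len(cols)
    s_sites = 0.5 * (s_sites_a + s_sites_b)
    n_sites = total_sites - s_sites
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    saturated = ps >= 0.75 or pn >= 0.75
    ka = jukes_cantor(pn)
    ks = jukes_cantor(ps)
    return KaKsRecord(
        og_id=og_id, genome_a=genome_a, genome_b=genome_b,
        ka=ka, ks=ks, n_sites=n_sites, s_sites=s_sites, saturated=saturated,
    )


def kaks_pair(cds_a: str, cds_b: str, **kw) -> KaKsRecord:
    """Convenience: align two CDS and compute NG86 Ka/Ks."""
    return kaks_ng86(align_codons(cds_a, cds_b), **kw)


# ---------------------------------------------------------------------------
# Summaries and sliding-window quantile tracks
# ---------------------------------------------------------------------------

def mean_sem(values) -> tuple[float, float]:
    """Mean and standard error of the mean (sample sd / sqrt(n)).

    The SEM of a single value is undefined and returned as NaN.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("mean_sem of empty input")
    if arr.size == 1:
        return float(arr[0]), float("nan")
    return float(arr.mean()), float(arr.std(ddof=1) / np.sqrt(arr.size))


def _midrank_quantiles(values: np.ndarray) -> np.ndarray:
    """Empirical quantiles q = (mid-rank - 0.5) / n, tie-robust."""
    from scipy.stats import rankdata

    n = values.size
    return (rankdata(values, method="average") - 0.5) / n


def write_kaks_table(records: list[KaKsRecord], path) -> None:
    """Tab-separated Ka/Ks table: og_id, genome_a, genome_b, Ka, Ks, N, S,
    saturated."""
    with open(path, "w") as fh:
        fh.write("og_id\tgenome_a\tgenome_b\tka\tks\tn_sites\ts_sites\tsaturated\n")
        for r in records:
            fh.write(
                f"{r.og_id}\t{r.genome_a}\t{r.genome_b}\t{r.ka:.6g}\t"
                f"{r.ks:.6g}\t{r.n_sites:.2f}\t{r.s_sites:.2f}\t"
                f"{int(r.saturated)}\n"
            )


def sliding_quantile_track(
    values_by_chrom: dict[str, "np.ndarray | list[float]"],
    window: int = 100,
) -> "pd.DataFrame":
    """Windowed quantile landscape over several chromosomes.

    Values must be ordered by pan position within each chromosome; the
    quantile transform and windowing run independently per chromosome.
    Returns a bedGraph-like frame (chrom, start_rank, end_rank, value);
    chromosomes shorter than the window contribute no rows.
    """
    import pandas as pd

    rows = []
    for chrom in sorted(values_by_chrom):
        track = sliding_quantile(values_by_chrom[chrom], window=window)
        for i, v in enumerate(track):
            rows.append((chrom, i, i + window, float(v)))
    return pd.DataFrame(rows, columns=["chrom", "start_rank", "end_rank", "value"])


def sliding_quantile(values, window: int = 100) -> np.ndarray:
    """Quantile-transform values then average over sliding windows.

    Values (e.g. per-gene Ks ordered by pan position within one chromosome
    of one genome) are replaced by their mid-rank empirical quantile in
    [0, 1]; each output is the mean quantile in a ``window``-gene sliding
    window (step 1).  Fewer genes than the window yields no windows.
    """
    arr = np.asarray(list(values), dtype=float)
    n = arr.size
    if n < window:
        logger.warning("only %d genes for window %d: no windows emitted", n, window)
        return np.empty(0)
    q = _midrank_quantiles(arr)
    kernel = np.ones(window) / window
    return np.convolve(q, kernel, mode="valid")
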