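"""Pseudo-testcross F1 QTL mapping.

In a pseudo-testcross, markers heterozygous in one outbred parent and
homozygous in the other segregate like a backcross: each progeny inherits
one of the focal parent's two haplotypes at every locus.  The pipeline
phases informative markers into the two parental haplotypes, thins them to
one marker per phase and physical bin, estimates a genetic map with the
Kosambi map function allowing a symmetric genotyping-error probability,
and scans for trait associations with a one-variance-component linear
mixed model using leave-one-chromosome-out (LOCO) kinship.  Significance
comes from permutations of the phenotype and localization from a Bayes
credible interval on the LOD profile.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .models import MISSING, CrossGenotypes, GenotypeMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Marker filtering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarkerFilterConfig:
    """Site filters for mapping-population genotypes."""

    min_maf: float = 0.05
    max_het_freq: float = 0.8
    max_missing: float = 0.1
    max_alleles: int = 2
    depth_trim_fraction: float = 0.01


def filter_markers(
    gm: GenotypeMatrix, cfg: MarkerFilterConfig = MarkerFilterConfig()
) -> GenotypeMatrix:
    """Drop unreliable loci before map construction.

    Loci fail on minor allele frequency < ``min_maf``, heterozygous call
    frequency > ``max_het_freq``, missing call frequency > ``max_missing``,
    more than two observed alleles, or (when depths are available) mean
    read depth in the extreme ``depth_trim_fraction`` tails.
    """
    calls = gm.calls
    called = (calls != MISSING).sum(axis=0)
    n = gm.n_samples
    with np.errstate(invalid="ignore", divide="ignore"):
        ref = np.where(calls == MISSING, 0, calls).sum(axis=0)
        p_ref = np.where(called > 0, ref / (2.0 * called), 0.0)
        maf = np.minimum(p_ref, 1.0 - p_ref)
        het = np.where(called > 0, (calls == 1).sum(axis=0) / called, 0.0)
        missing = (calls == MISSING).sum(axis=0) / n
    keep = (
        (maf >= cfg.min_maf)
        & (het <= cfg.max_het_freq)
        & (missing <= cfg.max_missing)
        & ~np.asarray(gm.multiallelic)
    )
    if gm.depth is not None and cfg.depth_trim_fraction > 0:
        mean_depth = np.where(gm.depth < 0, np.nan, gm.depth).mean(axis=0)
        lo = np.nanquantile(mean_depth, cfg.depth_trim_fraction)
        hi = np.nanquantile(mean_depth, 1.0 - cfg.depth_trim_fraction)
        keep &= (mean_depth > lo) & (mean_depth < hi)
    return gm.take_sites(np.flatnonzero(keep))


# ---------------------------------------------------------------------------
# Phasing and binning
# ---------------------------------------------------------------------------

def phase_testcross(
    alt_presence: np.ndarray,
    chrom: list[str],
    pos_bp: np.ndarray,
    marker_ids: list[str],
    progeny: list[str],
    alt_origin: dict[str, str],
) -> CrossGenotypes:
    """Phase informative markers into the focal parent's two haplotypes.

    ``alt_presence[i, j]`` says whether progeny ``i`` inherited the
    alternate allele at marker ``j`` (0/1, -1 missing).  Per chromosome,
    markers are clustered into two phases greedily: the first marker seeds
    phase 1 and each following marker joins the phase with which its
    progeny vector agrees in sign against the running consensus.  The
    phase-coded genotype is the alternate-presence vector for phase-1
    markers and its complement for phase-2 markers, so 0/1 consistently
    index the two parental haplotypes.  ``alt_origin`` (marker ->
    grandparent label) is carried through as the per-marker phase label.
    """
    alt_presence = np.asarray(alt_presence, dtype=np.int8)
    n, m = alt_presence.shape
    geno = np.full((n, m), MISSING, dtype=np.int8)
    for c in dict.fromkeys(chrom):
        idx = [j for j, cc in enumerate(chrom) if cc == c]
        if len(idx) < 2:
            raise ValueError(f"chromosome {c}: need >= 2 informative markers")
        signed = np.where(
            alt_presence[:, idx] == MISSING, 0.0, 2.0 * alt_presence[:, idx] - 1.0
        )
        flip = np.ones(len(idx))
        consensus = signed[:, 0].astype(float).copy()
        for k in range(1, len(idx)):
            agree = float(consensus @ signed[:, k])
            if agree < 0:
                flip[k] = -1.0
            consensus += flip[k] * signed[:, k]
        for k, j in enumerate(idx):
            col = alt_presence[:, j]
            phased = np.where(
                col == MISSING, MISSING, col if flip[k] > 0 else 1 - col
            )
            geno[:, j] = phased
    return CrossGenotypes(
        progeny=list(progeny), marker_ids=list(marker_ids), chrom=list(chrom),
        pos_bp=np.asarray(pos_bp), geno=geno,
        phase_parent=[alt_origin.get(mid, "?") for mid in marker_ids],
    )


def bin_markers(
    cg: CrossGenotypes,
    bin_size: int = 25_000,
    local_window: int = 10,
) -> CrossGenotypes:
    """Thin to one marker per (phase label, ``bin_size`` bp bin).

    Within each bin the retained marker is the one whose progeny genotype
    vector best agrees with the local consensus haplotype — the per-progeny
    majority call over ``local_window`` markers up- and downstream.  Ties
    keep the lower physical coordinate.
    """
    keep: list[int] = []
    geno = cg.geno
    for c, idx in cg.chrom_indices().items():
        idx = idx[np.argsort(cg.pos_bp[idx], kind="stable")]
        bins: dict[tuple[str, int], list[int]] = {}
        for j in idx:
            phase = cg.phase_parent[j] if cg.phase_parent else "?"
            bins.setdefault((phase, int(cg.pos_bp[j] // bin_size)), []).append(j)
        pos_in_chrom = {j: k for k, j in enumerate(idx)}
        for (phase, b), members in sorted(bins.items()):
            scored = []
            for j in members:
                k = pos_in_chrom[j]
                lo = max(0, k - local_window)
                flank = [idx[x] for x in range(lo, min(len(idx), k + local_window + 1))
                         if x != k]
                if not flank:
                    agreement = 0.0
                else:
                    f = geno[:, flank].astype(float)
                    f[f == MISSING] = np.nan
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore", RuntimeWarning)
                        consensus = np.nanmean(f, axis=1)
                    consensus = np.where(np.isnan(consensus), 0.5, consensus)
                    majority = (consensus > 0.5).astype(np.int8)
                    informative = (geno[:, j] != MISSING) & (consensus != 0.5)
                    agreement = (
                        float((geno[informative, j] == majority[informative]).mean())
                        if informative.any() else 0.0
                    )
                scored.append((-agreement, int(cg.pos_bp[j]), j))
            scored.sort()
            keep.append(scored[0][2])
    keep.sort(key=lambda j: (cg.chrom[j], int(cg.pos_bp[j])))
    return cg.take_markers(keep)


# ---------------------------------------------------------------------------
# Genetic map estimation
# ---------------------------------------------------------------------------

def kosambi_cm(r: np.ndarray | float) -> np.ndarray | float:
    """Kosambi map function d = 25 ln((1+2r)/(1-2r)) (cM)."""
    return 25.0 * np.log((1.0 + 2.0 * np.asarray(r)) / (1.0 - 2.0 * np.asarray(r)))


def kosambi_r(d_cm: np.ndarray | float) -> np.ndarray | float:
    """Inverse Kosambi: recombination fraction from cM distance."""
    return 0.5 * np.tanh(np.asarray(d_cm) / 50.0)


def estimate_map(
    cg: CrossGenotypes, error_prob: float = 0.0165, max_r: float = 0.4999
) -> CrossGenotypes:
    """Estimate cM positions per chromosome from adjacent recombination
    fractions under a symmetric genotyping-error model.

    With per-call error probability ``e``, the observed discordance
    fraction between adjacent markers is
    ``p = r (1-2e)^2 + 2e(1-e)``, inverted in closed form (the EM fixed
    point for complete pairwise data) and capped at ``max_r`` before the
    Kosambi transform.  Pairs with no jointly called progeny are flagged
    unlinked (r at the cap).
    """
    e = error_prob
    geno = cg.geno
    pos_cm = np.zeros(cg.n_markers)
    for c, idx in cg.chrom_indices().items():
        cum = 0.0
        pos_cm[idx[0]] = 0.0
        for a, b in zip(idx[:-1], idx[1:]):
            ga, gb = geno[:, a], geno[:, b]
            ok = (ga != MISSING) & (gb != MISSING)
            if not ok.any():
                warnings.warn(
                    f"markers {cg.marker_ids[a]}–{cg.marker_ids[b]}: no jointly "
                    "called progeny; flagged unlinked", stacklevel=2,
                )
                r = max_r
            else:
                p_obs = float((ga[ok] != gb[ok]).mean())
                r = (p_obs - 2 * e * (1 - e)) / (1 - 2 * e) ** 2
                r = float(np.clip(r, 0.0, max_r))
            cum += float(kosambi_cm(r))
            pos_cm[b] = cum
    out = cg.take_markers(np.arange(cg.n_markers))
    out.pos_cm = pos_cm
    return out


# ---------------------------------------------------------------------------
# LOD scan with LOCO kinship
# ---------------------------------------------------------------------------

@dataclass
class ScanConfig:
    step: float = 0.1            # cM between pseudomarkers
    error_prob: float = 0.0165
    n_permutations: int = 10_000
    bayes_prob: float = 0.95
    h2_grid_step: float = 0.01
    seed: int = 0


@dataclass
class LodProfile:
    chrom: list[str]
    pos_cm: np.ndarray
    pos_bp: np.ndarray
    lod: np.ndarray
    threshold: float | None = None
    peak_index: int | None = None
    bayes_interval_bp: tuple[str, float, float] | None = None

    @property
    def peak_lod(self) -> float:
        return float(self.lod[self.peak_index])


def _genotype_probs(
    geno: np.ndarray, pos_cm: np.ndarray, grid: np.ndarray, error_prob: float
) -> np.ndarray:
    """P(haplotype 1 at each grid position | all observed markers on the
    chromosome).

    Hidden-Markov genotype reconstruction: the hidden haplotype switches
    between consecutive grid positions with the Kosambi-inverse
    recombination fraction of the cM gap, and each observed marker call is
    correct with probability 1 - error_prob (missing calls are
    uninformative).  Forward–backward over the two haplotype states gives
    error-corrected expected genotypes, shape (n_progeny, n_grid).
    """
    e = error_prob
    n, g = geno.shape[0], grid.size
    # per grid position, product of marker likelihoods located there
    lik1 = np.ones((n, g))  # P(obs at position | hap = 1)
    lik0 = np.ones((n, g))
    marker_at = np.searchsorted(grid, pos_cm)
    for j, gi in enumerate(marker_at):
        obs = geno[:, j]
        lik1[:, gi] *= np.where(obs == MISSING, 1.0,
                                np.where(obs == 1, 1 - e, e))
        lik0[:, gi] *= np.where(obs == MISSING, 1.0,
                                np.where(obs == 0, 1 - e, e))
    r = np.asarray(kosambi_r(np.diff(grid)))
    # scaled forward-backward, vectorized over progeny
    a0, a1 = 0.5 * lik0[:, 0], 0.5 * lik1[:, 0]
    alpha0, alpha1 = np.empty((n, g)), np.empty((n, g))
    s = a0 + a1
    alpha0[:, 0], alpha1[:, 0] = a0 / s, a1 / s
    for t in range(1, g):
        rt = r[t - 1]
        p0 = (1 - rt) * alpha0[:, t - 1] + rt * alpha1[:, t - 1]
        p1 = rt * alpha0[:, t - 1] + (1 - rt) * alpha1[:, t - 1]
        a0, a1 = p0 * lik0[:, t], p1 * lik1[:, t]
        s = a0 + a1
        alpha0[:, t], alpha1[:, t] = a0 / s, a1 / s
    beta0 = np.ones(n)
    beta1 = np.ones(n)
    out = np.empty((n, g))
    out[:, -1] = alpha1[:, -1]
    for t in range(g - 2, -1, -1):
        rt = r[t]
        b0 = (1 - rt) * lik0[:, t + 1] * beta0 + rt * lik1[:, t + 1] * beta1
        b1 = rt * lik0[:, t + 1] * beta0 + (1 - rt) * lik1[:, t + 1] * beta1
        s = b0 + b1
        beta0, beta1 = b0 / s, b1 / s
        num1 = alpha1[:, t] * beta1
        out[:, t] = num1 / (alpha0[:, t] * beta0 + num1)
    return out


def _loco_kinship(probs_by_chrom: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Centered genotype cross-product kinship, leaving out each chromosome."""
    centered = {
        c: x - x.mean(axis=0, keepdims=True) for c, x in probs_by_chrom.items()
    }
    out = {}
    for c in probs_by_chrom:
        others = [x for cc, x in centered.items() if cc != c]
        if not others:
            n = next(iter(probs_by_chrom.values())).shape[0]
            out[c] = np.eye(n)
            continue
        x = np.hstack(others)
        out[c] = (x @ x.T) / x.shape[1]
    return out


def _fit_h2(yr: np.ndarray, x0r: np.ndarray, s: np.ndarray, grid_step: float) -> float:
    """Restricted-likelihood grid fit of heritability for the null model in
    the eigenrotated space (s = kinship eigenvalues)."""
    n = yr.size
    best_h, best_ll = 0.0, -np.inf
    for h in np.arange(0.0, 1.0, grid_step):
        w = h * s + (1.0 - h)
        wi = 1.0 / w
        xtx = float(x0r @ (wi * x0r))
        beta = float(x0r @ (wi * yr)) / xtx
        resid = yr - beta * x0r
        rss = float(resid @ (wi * resid))
        sigma2 = rss / (n - 1)
        ll = -0.5 * (
            (n - 1) * np.log(sigma2) + np.log(w).sum() + np.log(xtx) + (n - 1)
        )
        if ll > best_ll:
            best_ll, best_h = ll, float(h)
    return best_h


def _chrom_scan(
    yr: np.ndarray, x0r: np.ndarray, gr: np.ndarray, wi: np.ndarray
) -> np.ndarray:
    """LOD at every column of the rotated genotype matrix ``gr`` via
    weighted least squares closed forms.

    ``yr`` may be one rotated phenotype (n,) or a batch (n, B) sharing the
    same weights; returns (n_positions,) or (B, n_positions).
    """
    single = yr.ndim == 1
    y = yr[:, None] if single else yr
    n = y.shape[0]
    gw = gr * wi[:, None]
    sy = np.einsum("ib,ib->b", y, y * wi[:, None])   # (B,)
    a11 = float(x0r @ (wi * x0r))
    b0 = (x0r * wi) @ y                              # (B,)
    rss0 = sy - b0 ** 2 / a11
    a12 = x0r @ gw                                   # (P,)
    a22 = np.einsum("ij,ij->j", gr, gw)              # (P,)
    c2 = y.T @ gw                                    # (B, P)
    det = a11 * a22 - a12 ** 2
    det = np.where(np.abs(det) < 1e-12, np.nan, det)
    beta1 = (b0[:, None] * a22 - c2 * a12) / det
    beta2 = (a11 * c2 - a12 * b0[:, None]) / det
    rss1 = sy[:, None] - (beta1 * b0[:, None] + beta2 * c2)
    rss1 = np.where(np.isnan(rss1), rss0[:, None], np.minimum(rss1, rss0[:, None]))
    rss1 = np.maximum(rss1, 1e-12)
    lod = (n / 2.0) * np.log10(rss0[:, None] / rss1)
    return lod[0] if single else lod


def _prepare_scan(cg: CrossGenotypes, cfg: ScanConfig):
    """Shared setup: grids, genotype probabilities, LOCO kinship
    eigendecompositions."""
    if cg.pos_cm is None:
        raise ValueError("run estimate_map first (pos_cm missing)")
    chrom_idx = cg.chrom_indices()
    grids, probs, bp_interp = {}, {}, {}
    for c, idx in chrom_idx.items():
        cm = cg.pos_cm[idx]
        grid = np.unique(np.concatenate([
            np.arange(cm.min(), cm.max() + cfg.step / 2, cfg.step), cm
        ]))
        grids[c] = grid
        probs[c] = _genotype_probs(cg.geno[:, idx], cm, grid, cfg.error_prob)
        bp_interp[c] = (cm, cg.pos_bp[idx].astype(float))
    kinship = _loco_kinship(probs)
    eig = {c: np.linalg.eigh(k) for c, k in kinship.items()}
    return chrom_idx, grids, probs, bp_interp, eig


def scan_lod(
    cg: CrossGenotypes, phenotype: np.ndarray, cfg: ScanConfig = ScanConfig()
) -> LodProfile:
    """Genome scan: LOD = (n/2) log10(RSS0/RSS1) in the GLS-rotated model.

    Pseudomarkers are inserted every ``cfg.step`` cM; the single-variance-
    component mixed model is fit once per LOCO kinship by a restricted-
    likelihood grid search over heritability, and each position is tested
    by generalized least squares in the eigenrotated space.
    """
    y = np.asarray(phenotype, dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("phenotype is constant")
    _, grids, probs, bp_interp, eig = _prepare_scan(cg, cfg)
    ones = np.ones(y.size)
    chroms_out, cm_out, bp_out, lod_out = [], [], [], []
    for c in grids:
        s, u = eig[c]
        yr, x0r, gr = u.T @ y, u.T @ ones, u.T @ probs[c]
        h = _fit_h2(yr, x0r, s, cfg.h2_grid_step)
        wi = 1.0 / (h * s + (1.0 - h))
        lod = _chrom_scan(yr, x0r, gr, wi)
        cm, bp = bp_interp[c]
        chroms_out.extend([c] * grids[c].size)
        cm_out.append(grids[c])
        bp_out.append(np.interp(grids[c], cm, bp))
        lod_out.append(lod)
    profile = LodProfile(
        chrom=chroms_out,
        pos_cm=np.concatenate(cm_out),
        pos_bp=np.concatenate(bp_out),
        lod=np.concatenate(lod_out),
    )
    profile.peak_index = int(np.argmax(profile.lod))
    return profile


def permutation_threshold(
    cg: CrossGenotypes,
    phenotype: np.ndarray,
    cfg: ScanConfig = ScanConfig(),
    quantile: float = 0.95,
) -> float:
    """Genome-wide significance threshold from phenotype permutations.

    The phenotype is permuted ``cfg.n_permutations`` times (seeded); the
    threshold is the ``quantile`` of the per-permutation genome-wide
    maximum LOD.  Heritability is refit for every permutation.
    """
    if cfg.n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if cfg.n_permutations < 100:
        warnings.warn(
            f"{cfg.n_permutations} permutations give an unstable threshold",
            stacklevel=2,
        )
    y = np.asarray(phenotype, dtype=float)
    rng = np.random.default_rng(cfg.seed)
    perms = np.stack([rng.permutation(y) for _ in range(cfg.n_permutations)], axis=1)
    _, grids, probs, _, eig = _prepare_scan(cg, cfg)
    ones = np.ones(y.size)
    max_lod = np.zeros(cfg.n_permutations)
    n = y.size
    for c in grids:
        s, u = eig[c]
        x0r, gr = u.T @ ones, u.T @ probs[c]
        yrp = u.T @ perms  # (n, B)
        # vectorized restricted-likelihood grid fit across permutations
        best_ll = np.full(cfg.n_permutations, -np.inf)
        best_h = np.zeros(cfg.n_permutations)
        for h in np.arange(0.0, 1.0, cfg.h2_grid_step):
            w = h * s + (1.0 - h)
            wi = 1.0 / w
            xtx = float(x0r @ (wi * x0r))
            beta = (x0r * wi) @ yrp / xtx              # (B,)
            resid = yrp - np.outer(x0r, beta)
            rss = np.einsum("ib,ib->b", resid, resid * wi[:, None])
            sigma2 = rss / (n - 1)
            ll = -0.5 * (
                (n - 1) * np.log(sigma2) + np.log(w).sum() + np.log(xtx) + (n - 1)
            )
            better = ll > best_ll
            best_ll[better] = ll[better]
            best_h[better] = h
        for h in np.unique(best_h):
            members = np.flatnonzero(best_h == h)
            wi = 1.0 / (h * s + (1.0 - h))
            lod = _chrom_scan(yrp[:, members], x0r, gr, wi)  # (Bg, P)
            max_lod[members] = np.maximum(max_lod[members], lod.max(axis=1))
    return float(np.quantile(max_lod, quantile))


def bayes_interval(
    profile: LodProfile, prob: float = 0.95
) -> tuple[str, float, float]:
    """Smallest contiguous peak-containing interval holding >= ``prob`` of
    the normalized 10^LOD mass on the peak chromosome, projected to bp.

    Ties in interval length prefer the leftmost interval.  The result is
    also stored on the profile.
    """
    peak = profile.peak_index
    c = profile.chrom[peak]
    idx = np.array([i for i, cc in enumerate(profile.chrom) if cc == c])
    lod = profile.lod[idx]
    mass = np.power(10.0, lod - lod.max())
    mass /= mass.sum()
    k = int(np.flatnonzero(idx == peak)[0])
    cum = np.concatenate([[0.0], np.cumsum(mass)])
    best = None  # (length, start, end)
    for i in range(k + 1):
        for j in range(k, mass.size):
            if cum[j + 1] - cum[i] >= prob - 1e-12:
                length = j - i
                if best is None or (length, i) < (best[0], best[1]):
                    best = (length, i, j)
                break
    if best is None:
        best = (mass.size - 1, 0, mass.size - 1)
    _, i, j = best
    bp_lo = float(profile.pos_bp[idx[i]])
    bp_hi = float(profile.pos_bp[idx[j]])
    profile.bayes_interval_bp = (c, bp_lo, bp_hi)
    return c, bp_lo, bp_hi


# ---------------------------------------------------------------------------
# Candidate ranking
# ---------------------------------------------------------------------------

@dataclass
class Candidate:
    gene_id: str
    pan_id: str
    cls: str
    identity_pct: float | None
    priority: str  # high | low
    tags: list[str] = field(default_factory=list)


def rank_candidates(
    interval_entries,
    comparisons,
    identity_threshold: float = 98.0,
    domain_tags: dict[str, list[str]] | None = None,
) -> list[Candidate]:
    """Prioritize interval genes by haplotype divergence.

    High priority: genes found only in the alternative assembly, genes in
    both assemblies with peptide identity below ``identity_threshold``,
    and primary-only genes under an assembled alternative contig
    (presence–absence between haplotypes).  Primary-only genes with no
    alternative contig likely sit in homozygous regions and rank low.
    Optional domain annotations (e.g. LRR/immune flags) attach as tags.
    """
    domain_tags = domain_tags or {}
    by_pan = {c.pan_id: c for c in comparisons if c.pan_id}
    alt_only = [c for c in comparisons if c.cls == "alt_only"]
    out: list[Candidate] = []
    for e in interval_entries:
        c = by_pan.get(e.pan_id)
        if c is None:
            continue
        gene = c.primary_gene or (c.alt_gene or "")
        if c.cls == "both":
            diverged = c.identity_pct is not None and c.identity_pct < identity_threshold
            priority = "high" if diverged else "low"
        elif c.cls == "primary_only_with_alt_contig":
            priority = "high"
        else:  # primary_only_no_alt_contig
            priority = "low"
        out.append(
            Candidate(
                gene_id=gene, pan_id=e.pan_id, cls=c.cls,
                identity_pct=c.identity_pct, priority=priority,
                tags=sorted(domain_tags.get(gene, [])),
            )
        )
    for c in alt_only:
        out.append(
            Candidate(
                gene_id=c.alt_gene or "", pan_id=c.pan_id, cls="alt_only",
                identity_pct=None, priority="high",
                tags=sorted(domain_tags.get(c.alt_gene or "", [])),
            )
        )
    out.sort(key=lambda cand: (cand.priority != "high", cand.gene_id))
    return out
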