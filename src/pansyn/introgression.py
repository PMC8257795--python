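"""Local-ancestry inference and introgression-block detection.

A test genome is modelled as a mosaic of ancestry tracts copied from a
small panel of source populations (three potential donor species plus the
recurrent background).  Hidden states are unordered pairs of per-haplotype
ancestries (10 states for 4 sources); emissions come from source allele
frequencies with a symmetric genotyping-error mixture, and transitions
follow a one-parameter switch-rate Markov process along the genetic map.
Posteriors are decoded to hard calls, short runs are iteratively culled up
to a minimum block size, and high-confidence introgressions are the
per-donor intersections of blocks across a genotype and all its relatives.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations_with_replacement

import numpy as np
from scipy.optimize import nnls

from .models import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Variant pruning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PruneConfig:
    """Site filters applied before ancestry inference."""

    min_minor_allele_count: int = 3
    allow_missing: bool = False
    max_r2: float = 0.999
    window: int = 100  # SNPs


def prune_variants(gm: GenotypeMatrix, cfg: PruneConfig = PruneConfig()) -> GenotypeMatrix:
    """Filter sites: biallelic, complete, minor allele count, LD.

    Filters apply in order.  LD pruning is greedy left-to-right: a site is
    dropped when its r^2 with any retained site among the trailing
    ``window`` kept sites exceeds ``max_r2`` (the earlier site wins).
    """
    keep = ~np.asarray(gm.multiallelic)
    if not cfg.allow_missing:
        keep &= ~(gm.calls == MISSING).any(axis=0)
    ref_counts = np.where(gm.calls == MISSING, 0, gm.calls).sum(axis=0)
    called = (gm.calls != MISSING).sum(axis=0)
    alt_counts = 2 * called - ref_counts
    mac = np.minimum(ref_counts, alt_counts)
    keep &= mac >= cfg.min_minor_allele_count
    idx = np.flatnonzero(keep)

    # standardize once so r^2 between sites is a dot product
    calls = gm.calls.astype(float)
    mean = calls.mean(axis=0)
    std = calls.std(axis=0)
    z = np.where(std > 0, (calls - mean) / np.where(std == 0, 1.0, std), 0.0)
    n = gm.n_samples
    kept: list[int] = []
    for j in idx:
        drop = False
        for k in kept[-(cfg.window - 1):] if cfg.window > 1 else []:
            if std[j] == 0 or std[k] == 0:
                r2 = 1.0 if (std[j] == 0 and std[k] == 0) else 0.0
            else:
                r2 = float(z[:, j] @ z[:, k] / n) ** 2
            if r2 > cfg.max_r2:
                drop = True
                break
        if not drop:
            kept.append(int(j))
    if not kept:
        warnings.warn("variant pruning removed every site", stacklevel=2)
    return gm.take_sites(kept)


def source_frequencies(
    gm: GenotypeMatrix, population_of: dict[str, str], populations: list[str]
) -> np.ndarray:
    """Reference-allele frequencies per source population.

    A pseudocount of 0.5 per allele keeps frequencies off the 0/1
    boundaries so emission probabilities never vanish.  Returns an array of
    shape (n_populations, n_sites).
    """
    freqs = np.empty((len(populations), gm.n_sites))
    for p, pop in enumerate(populations):
        rows = [i for i, s in enumerate(gm.samples) if population_of.get(s) == pop]
        if not rows:
            raise ValueError(f"no samples assigned to population {pop!r}")
        calls = gm.calls[rows, :]
        ref = np.where(calls == MISSING, 0, calls).sum(axis=0)
        n_alleles = 2 * (calls != MISSING).sum(axis=0)
        freqs[p] = (ref + 0.5) / (n_alleles + 1.0)
    return freqs


# ---------------------------------------------------------------------------
# Global ancestry
# ---------------------------------------------------------------------------

def global_ancestry(sample_calls: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Genome-wide ancestry proportions for one sample.

    Non-negative least squares of the sample's per-site allele-frequency
    vector (ref count / 2) on the source frequency vectors, normalized to
    sum to one.  Returns the uniform vector with a warning when the sources
    are indistinguishable.
    """
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape[0] < 2:
        raise ValueError("need at least 2 source populations")
    y = np.asarray(sample_calls, dtype=float) / 2.0
    if np.ptp(freqs, axis=0).max() < 1e-12:
        warnings.warn(
            "source allele frequencies are identical; ancestry is not "
            "identifiable, returning uniform proportions",
            stacklevel=2,
        )
        return np.full(freqs.shape[0], 1.0 / freqs.shape[0])
    coef, _ = nnls(freqs.T, y)
    if coef.sum() == 0:
        return np.full(freqs.shape[0], 1.0 / freqs.shape[0])
    return coef / coef.sum()


# ---------------------------------------------------------------------------
# Ancestry HMM
# ---------------------------------------------------------------------------

@dataclass
class HmmConfig:
    """Configuration of the local-ancestry HMM.

    ``switch_rate`` is the expected number of ancestry switches per morgan
    per haplotype; ``ancestry_priors`` are the stationary per-source
    proportions (e.g. the fitted global ancestry); ``genotyping_error`` is
    the per-allele misread probability mixed into the emissions;
    ``recomb_map`` gives morgans per inter-marker interval (length
    n_markers - 1; a scalar is broadcast).
    """

    n_sources: int = 4
    switch_rate: float = 5.0
    ancestry_priors: np.ndarray | None = None
    genotyping_error: float = 1e-3
    recomb_map: np.ndarray | float = 1e-4

    def __post_init__(self) -> None:
        if self.ancestry_priors is None:
            self.ancestry_priors = np.full(self.n_sources, 1.0 / self.n_sources)
        self.ancestry_priors = np.asarray(self.ancestry_priors, dtype=float)
        if abs(self.ancestry_priors.sum() - 1.0) > 1e-8:
            raise ValueError("ancestry_priors must sum to 1")
        if not (0 <= self.genotyping_error < 0.5):
            raise ValueError("genotyping_error must be in [0, 0.5)")


def hmm_states(n_sources: int) -> list[tuple[int, int]]:
    """Unordered per-haplotype ancestry pairs (a <= b)."""
    return list(combinations_with_replacement(range(n_sources), 2))


def _pair_prior(priors: np.ndarray, states: list[tuple[int, int]]) -> np.ndarray:
    out = np.empty(len(states))
    for k, (a, b) in enumerate(states):
        out[k] = priors[a] ** 2 if a == b else 2 * priors[a] * priors[b]
    return out


def emission_probs(
    genotypes: np.ndarray, freqs: np.ndarray, error: float,
    states: list[tuple[int, int]],
) -> np.ndarray:
    """P(observed ref count | state) per marker; shape (n_markers, n_states).

    Each haplotype draws a reference allele with probability f_a, misread
    with probability ``error``; alleles are independent given the state.
    Missing genotypes emit 1 (uninformative).
    """
    p = freqs * (1 - error) + (1 - freqs) * error  # (n_sources, n_markers)
    n_markers = freqs.shape[1]
    out = np.empty((n_markers, len(states)))
    g = np.asarray(genotypes)
    for k, (a, b) in enumerate(states):
        pa, pb = p[a], p[b]
        probs = np.select(
            [g == 2, g == 1, g == 0],
            [pa * pb, pa * (1 - pb) + (1 - pa) * pb, (1 - pa) * (1 - pb)],
            default=1.0,
        )
        out[:, k] = probs
    return out


def _haplotype_transition(priors: np.ndarray, switch: float) -> np.ndarray:
    n = priors.size
    return (1 - switch) * np.eye(n) + switch * np.tile(priors, (n, 1))


def pair_transition(
    priors: np.ndarray, switch: float, states: list[tuple[int, int]]
) -> np.ndarray:
    """Transition matrix over unordered ancestry pairs for one interval."""
    t = _haplotype_transition(priors, switch)
    m = np.empty((len(states), len(states)))
    for i, (a, b) in enumerate(states):
        for j, (c, d) in enumerate(states):
            if c == d:
                m[i, j] = t[a, c] * t[b, c]
            else:
                m[i, j] = t[a, c] * t[b, d] + t[a, d] * t[b, c]
    return m


def forward_backward(
    init: np.ndarray, transitions: list[np.ndarray], emissions: np.ndarray
) -> tuple[np.ndarray, float]:
    """Scaled forward–backward.

    ``transitions[t]`` moves from marker t to t+1; ``emissions`` has shape
    (n_markers, n_states).  Returns (posterior with unit row sums,
    log-likelihood).
    """
    n, k = emissions.shape
    alpha = np.empty((n, k))
    scale = np.empty(n)
    alpha[0] = init * emissions[0]
    scale[0] = alpha[0].sum()
    alpha[0] /= scale[0]
    for t in range(1, n):
        alpha[t] = (alpha[t - 1] @ transitions[t - 1]) * emissions[t]
        scale[t] = alpha[t].sum()
        alpha[t] /= scale[t]
    beta = np.empty((n, k))
    beta[-1] = 1.0
    for t in range(n - 2, -1, -1):
        beta[t] = (transitions[t] @ (emissions[t + 1] * beta[t + 1])) / scale[t + 1]
    post = alpha * beta
    post /= post.sum(axis=1, keepdims=True)
    return post, float(np.log(scale).sum())


def ancestry_posteriors(
    genotypes: np.ndarray,
    freqs: np.ndarray,
    cfg: HmmConfig,
    positions_morgans: np.ndarray | None = None,
) -> np.ndarray:
    """Posterior over ancestry-pair states at every marker.

    ``genotypes`` are one sample's reference-allele counts at markers
    ordered by position; ``freqs`` is (n_sources, n_markers).  Inter-marker
    genetic distances come from ``positions_morgans`` when given, else from
    ``cfg.recomb_map``.
    """
    genotypes = np.asarray(genotypes)
    freqs = np.asarray(freqs, dtype=float)
    n_markers = freqs.shape[1]
    if genotypes.shape[-1] != n_markers:
        raise ValueError("genotypes and freqs disagree on marker count")
    if positions_morgans is not None:
        positions_morgans = np.asarray(positions_morgans, dtype=float)
        if np.any(np.diff(positions_morgans) < 0):
            raise ValueError("marker positions must be non-decreasing")
        dists = np.diff(positions_morgans)
    else:
        dists = np.broadcast_to(
            np.asarray(cfg.recomb_map, dtype=float), (max(n_markers - 1, 0),)
        )
    states = hmm_states(cfg.n_sources)
    init = _pair_prior(cfg.ancestry_priors, states)
    emit = emission_probs(genotypes, freqs, cfg.genotyping_error, states)
    switches = 1.0 - np.exp(-cfg.switch_rate * np.asarray(dists))
    transitions = [
        pair_transition(cfg.ancestry_priors, s, states) for s in switches
    ]
    post, _ = forward_backward(init, transitions, emit)
    return post


# ---------------------------------------------------------------------------
# Hard-call decoding and block culling
# ---------------------------------------------------------------------------

@dataclass
class AncestryBlock:
    """A culled run of identical ancestry hard calls."""

    state: tuple[int, int]
    start: int  # marker index, inclusive
    end: int    # marker index, inclusive
    n_markers: int
    bp_start: int | None = None
    bp_end: int | None = None

    @property
    def span_bp(self) -> int | None:
        if self.bp_start is None or self.bp_end is None:
            return None
        return self.bp_end - self.bp_start


def hard_calls(posterior: np.ndarray, cfg: HmmConfig) -> np.ndarray:
    """Most-likely state per marker; posterior ties go to the state with the
    larger prior, then the lower state index."""
    states = hmm_states(cfg.n_sources)
    prior = _pair_prior(cfg.ancestry_priors, states)
    # lexicographic argmax on (posterior, prior, -index)
    n, k = posterior.shape
    calls = np.empty(n, dtype=np.int64)
    for t in range(n):
        row = posterior[t]
        best = max(range(k), key=lambda s: (row[s], prior[s], -s))
        calls[t] = best
    return calls


def _runs(calls: np.ndarray) -> list[list[int]]:
    """Run-length encoding as mutable [state, length] pairs."""
    runs: list[list[int]] = []
    for c in calls:
        if runs and runs[-1][0] == c:
            runs[-1][1] += 1
        else:
            runs.append([int(c), 1])
    return runs


def _merge_adjacent(runs: list[list[int]]) -> list[list[int]]:
    out: list[list[int]] = []
    for st, ln in runs:
        if out and out[-1][0] == st:
            out[-1][1] += ln
        else:
            out.append([st, ln])
    return out


def cull_runs(calls: np.ndarray, min_block: int = 500) -> np.ndarray:
    """Iteratively absorb short runs into their larger flank.

    For L = 2 .. min_block, any maximal run shorter than L is reassigned to
    the flanking run with more markers (ties and edges go left when a left
    flank exists); this repeats until no run shorter than L remains, then L
    increases.  The result has no run shorter than min_block unless the
    whole sequence is one run.
    """
    if min_block < 2:
        raise ValueError(f"min_block must be >= 2, got {min_block}")
    runs = _runs(np.asarray(calls))
    for L in range(2, min_block + 1):
        changed = True
        while changed:
            changed = False
            if len(runs) <= 1:
                return _expand(runs)
            for i, (st, ln) in enumerate(runs):
                if ln >= L:
                    continue
                left = runs[i - 1] if i > 0 else None
                right = runs[i + 1] if i < len(runs) - 1 else None
                if left is None and right is None:
                    continue
                if left is None:
                    target = right
                elif right is None:
                    target = left
                else:
                    target = right if right[1] > left[1] else left
                runs[i][0] = target[0]
                runs = _merge_adjacent(runs)
                changed = True
                break
    return _expand(runs)


def _expand(runs: list[list[int]]) -> np.ndarray:
    return np.concatenate([np.full(ln, st, dtype=np.int64) for st, ln in runs]) \
        if runs else np.empty(0, dtype=np.int64)


def decode_and_cull(
    posterior: np.ndarray,
    cfg: HmmConfig,
    min_block: int = 500,
    positions_bp: np.ndarray | None = None,
) -> list[AncestryBlock]:
    """Hard-call the posterior, cull short runs, emit ancestry blocks.

    Blocks tile the markers without overlap; physical spans are attached
    when ``positions_bp`` is given.
    """
    calls = hard_calls(posterior, cfg)
    culled = cull_runs(calls, min_block=min_block)
    states = hmm_states(cfg.n_sources)
    blocks: list[AncestryBlock] = []
    start = 0
    for st, ln in _runs(culled):
        end = start + ln - 1
        blk = AncestryBlock(
            state=states[st], start=start, end=end, n_markers=ln,
        )
        if positions_bp is not None:
            blk.bp_start = int(positions_bp[start])
            blk.bp_end = int(positions_bp[end])
        blocks.append(blk)
        start = end + 1
    return blocks


# ---------------------------------------------------------------------------
# High-confidence introgressions
# ---------------------------------------------------------------------------

def _donor_intervals(
    blocks: list[AncestryBlock], donor: int
) -> list[tuple[int, int]]:
    ivs = [
        (b.bp_start, b.bp_end) for b in blocks
        if donor in b.state and b.bp_start is not None
    ]
    return _merge_intervals(ivs)


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _intersect(a: list[tuple[int, int]], b: list[tuple[int, int]]):
    out, i, j = [], 0, 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def high_confidence_introgressions(
    blocks_by_sample: dict[str, list[AncestryBlock]],
    background: int,
    n_sources: int,
) -> dict[int, list[tuple[int, int]]]:
    """Per-donor intervals with non-background ancestry in *all* samples.

    ``blocks_by_sample`` holds the reference genotype plus at least one
    relative; an introgression is high-confidence only where the donor
    ancestry is shared by every sample.
    """
    if len(blocks_by_sample) < 2:
        raise ValueError("need the reference genotype plus >= 1 relative")
    donors = [d for d in range(n_sources) if d != background]
    out: dict[int, list[tuple[int, int]]] = {}
    for donor in donors:
        per_sample = [
            _donor_intervals(blocks, donor)
            for blocks in blocks_by_sample.values()
        ]
        acc = per_sample[0]
        for ivs in per_sample[1:]:
            acc = _intersect(acc, ivs)
        out[donor] = acc
    return out


def introgression_summary(
    intervals_by_donor: dict[int, list[tuple[int, int]]],
    genome_size_mb: float,
) -> dict[int, tuple[float, float]]:
    """Total introgressed Mb and percent of genome per donor."""
    out = {}
    for donor, ivs in intervals_by_donor.items():
        mb = sum(e - s for s, e in ivs) / 1e6
        out[donor] = (mb, 100.0 * mb / genome_size_mb if genome_size_mb else 0.0)
    return out
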