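"""Independent brute-force oracles used to validate pipeline operations.

Every function here is deliberately written from first principles, without
touching the implementation under test: exhaustive enumeration, direct
recursion, or closed forms at tiny problem sizes.
"""

from __future__ import annotations

from itertools import permutations
from math import comb, exp, log

import numpy as np
from Bio.Seq import Seq

# ---------------------------------------------------------------------------
# Longest monotone chain / greedy block extraction
# ---------------------------------------------------------------------------

def _chains_from(anchors, max_gap, sign):
    """All maximal-length monotone chains by depth-first extension."""
    best = {"len": 0, "chains": []}

    def extend(chain, remaining):
        extended = False
        last = chain[-1]
        for a in remaining:
            if a[0] > last[0] and sign * (a[1] - last[1]) > 0 \
                    and a[0] - last[0] <= max_gap and abs(a[1] - last[1]) <= max_gap:
                extend(chain + [a], [r for r in remaining if r[0] > a[0]])
                extended = True
        if not extended:
            if len(chain) > best["len"]:
                best["len"] = len(chain)
                best["chains"] = [list(chain)]
            elif len(chain) == best["len"]:
                best["chains"].append(list(chain))

    for i, a in enumerate(anchors):
        extend([a], [r for r in anchors if r[0] > a[0]])
    return best["len"], best["chains"]


def oracle_chain_blocks(anchors, max_gap, min_size):
    """Greedy block extraction identical in policy to the pipeline but via
    exhaustive chain search: longest chain first (ties: smaller starting
    query rank, then 'inverted' sorts after 'same'), anchors removed,
    repeat until the longest chain is below min_size."""
    remaining = sorted(set(anchors))
    blocks = []
    while remaining:
        cands = []
        for sign, name in ((+1, "same"), (-1, "inverted")):
            ln, chains = _chains_from(remaining, max_gap, sign)
            if ln:
                chain = min(chains, key=lambda ch: (ch[0][0], ch[0][1]))
                cands.append((-ln, chain[0][0], name, chain))
        if not cands:
            break
        cands.sort()
        neg_ln, _, name, chain = cands[0]
        if -neg_ln < min_size:
            break
        blocks.append((name, chain))
        used = set(map(tuple, chain))
        remaining = [a for a in remaining if a not in used]
    return blocks


# ---------------------------------------------------------------------------
# NG86 by direct enumeration
# ---------------------------------------------------------------------------

_STOPS = {"TAA", "TAG", "TGA"}


_AA_CACHE: dict[str, str] = {}


def _aa(codon):
    if codon not in _AA_CACHE:
        _AA_CACHE[codon] = str(Seq(codon).translate())
    return _AA_CACHE[codon]


def _syn_sites(codon):
    s = 0.0
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mut = codon[:pos] + base + codon[pos + 1:]
            if mut not in _STOPS and _aa(mut) == _aa(codon):
                s += 1 / 3
    return s


def _path_subs(ca, cb):
    diff = [i for i in range(3) if ca[i] != cb[i]]
    if not diff:
        return 0.0, 0.0
    valid, invalid = [], []
    for order in permutations(diff):
        cur, s, n, ok = ca, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
            if nxt in _STOPS:
                ok = False
                n += 1
            elif cur not in _STOPS and _aa(nxt) == _aa(cur):
                s += 1
            else:
                n += 1
            cur = nxt
        (valid if ok else invalid).append((s, n))
    use = valid or invalid
    return (sum(x for x, _ in use) / len(use), sum(x for _, x in use) / len(use))


def oracle_ng86(codons_a, codons_b):
    """(ka, ks, n_sites, s_sites) from first principles."""
    assert len(codons_a) == len(codons_b)
    s_sites = sum(_syn_sites(c) for c in codons_a) / 2 \
        + sum(_syn_sites(c) for c in codons_b) / 2
    n_sites = 3 * len(codons_a) - s_sites
    sd = nd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        s, n = _path_subs(ca, cb)
        sd += s
        nd += n
    ps, pn = sd / s_sites, nd / n_sites

    def jc(p):
        return float("nan") if p >= 0.75 else -0.75 * log(1 - 4 * p / 3)

    return jc(pn), jc(ps), n_sites, s_sites


# ---------------------------------------------------------------------------
# HMM posterior by path enumeration
# ---------------------------------------------------------------------------

def oracle_posterior(init, transitions, emissions):
    """Posterior state probabilities by summing over every hidden path."""
    n, k = emissions.shape
    post = np.zeros((n, k))
    paths = []

    def walk2(t, path, prob):
        for state in range(k):
            p = prob * emissions[t, state] * (
                init[state] if t == 0 else transitions[t - 1][path[-1], state]
            )
            if t == n - 1:
                paths.append((path + [state], p))
            else:
                walk2(t + 1, path + [state], p)

    walk2(0, [], 1.0)
    total = sum(p for _, p in paths)
    for path, p in paths:
        for t, state in enumerate(path):
            post[t, state] += p
    return post / total


# ---------------------------------------------------------------------------
# Fisher / hypergeometric two-sided p by tail enumeration
# ---------------------------------------------------------------------------

def oracle_fisher_two_sided(a, b, c, d):
    """Sum of hypergeometric probabilities <= that of the observed table."""
    row1, col1, n = a + b, a + c, a + b + c + d

    def pmf(x):
        if x < 0 or x > row1 or col1 - x < 0 or col1 - x > c + d:
            return 0.0
        return comb(row1, x) * comb(n - row1, col1 - x) / comb(n, col1)

    p_obs = pmf(a)
    return sum(pmf(x) for x in range(col1 + 1) if pmf(x) <= p_obs * (1 + 1e-9))


# ---------------------------------------------------------------------------
# Misc small oracles
# ---------------------------------------------------------------------------

def oracle_dbscan_clusters(points, radius, min_hits):
    """Density clustering by brute-force pairwise distances: core points
    have >= min_hits neighbors (incl. self) within radius; clusters are the
    connected components of core points plus their border points."""
    pts = sorted(set(points))
    n = len(pts)
    d = np.array([
        [np.hypot(p[0] - q[0], p[1] - q[1]) for q in pts] for p in pts
    ])
    core = [(d[i] <= radius).sum() >= min_hits for i in range(n)]
    label = [-1] * n
    cur = 0
    for i in range(n):
        if not core[i] or label[i] != -1:
            continue
        stack, label[i] = [i], cur
        while stack:
            j = stack.pop()
            for m in range(n):
                if d[j, m] <= radius and label[m] == -1:
                    if core[m]:
                        label[m] = cur
                        stack.append(m)
        cur += 1
    # border points: first core cluster by scan order
    for i in range(n):
        if label[i] == -1:
            for j in range(n):
                if core[j] and d[i, j] <= radius:
                    label[i] = label[j]
                    break
    clusters = {}
    for i, lab in enumerate(label):
        if lab >= 0:
            clusters.setdefault(lab, set()).add(pts[i])
    return sorted((frozenset(c) for c in clusters.values()),
                  key=lambda c: sorted(c)[0])


def oracle_cull(calls, min_block):
    """Direct simulation of the run-culling recurrence."""
    seq = list(calls)
    for L in range(2, min_block + 1):
        while True:
            runs = []
            i = 0
            while i < len(seq):
                j = i
                while j < len(seq) and seq[j] == seq[i]:
                    j += 1
                runs.append((i, j - i, seq[i]))
                i = j
            short = [
                (i, ln, v) for (i, ln, v) in runs if ln < L
            ]
            if len(runs) <= 1 or not short:
                break
            idx = runs.index(short[0])
            start, ln, v = runs[idx]
            left = runs[idx - 1] if idx > 0 else None
            right = runs[idx + 1] if idx < len(runs) - 1 else None
            if left is None and right is None:
                break
            if left is None:
                newv = right[2]
            elif right is None:
                newv = left[2]
            else:
                newv = right[2] if right[1] > left[1] else left[2]
            for p in range(start, start + ln):
                seq[p] = newv
    return np.array(seq)


def oracle_bayes_interval(lod, peak, prob):
    """Smallest contiguous peak-containing index interval with >= prob of
    the normalized 10^LOD mass; ties prefer the leftmost."""
    mass = np.power(10.0, np.asarray(lod) - max(lod))
    mass = mass / mass.sum()
    best = None
    for i in range(peak + 1):
        for j in range(peak, len(mass)):
            if mass[i:j + 1].sum() >= prob - 1e-12:
                cand = (j - i, i, j)
                if best is None or cand < best:
                    best = cand
                break
    return best[1], best[2]


def oracle_sliding_quantile(values, window):
    """Mean of mid-rank quantiles per window, computed directly."""
    v = list(values)
    n = len(v)
    qs = []
    for x in v:
        below = sum(1 for y in v if y < x)
        ties = sum(1 for y in v if y == x)
        midrank = below + (ties + 1) / 2
        qs.append((midrank - 0.5) / n)
    return [
        float(np.mean(qs[i:i + window])) for i in range(n - window + 1)
    ]


def oracle_global_identity(a, b):
    """Needleman–Wunsch (match 1, mismatch/gap scored like the pipeline's
    BLOSUM62 setup is unnecessary here: used only on sequences with one
    unambiguous optimal alignment); returns the identity formula
    100 * identical / (aligned + internal gaps) with terminal gaps excluded."""
    # simple NW with match=1, mismatch=-1, gap=-2
    la, lb = len(a), len(b)
    score = np.zeros((la + 1, lb + 1))
    ptr = np.zeros((la + 1, lb + 1), dtype=int)  # 0 diag, 1 up, 2 left
    for i in range(1, la + 1):
        score[i, 0], ptr[i, 0] = -2 * i, 1
    for j in range(1, lb + 1):
        score[0, j], ptr[0, j] = -2 * j, 2
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            opts = [
                (score[i - 1, j - 1] + (1 if a[i - 1] == b[j - 1] else -1), 0),
                (score[i - 1, j] - 2, 1),
                (score[i, j - 1] - 2, 2),
            ]
            score[i, j], ptr[i, j] = max(opts)
    i, j, cols = la, lb, []
    while i > 0 or j > 0:
        p = ptr[i, j]
        if p == 0 and i > 0 and j > 0:
            cols.append((a[i - 1], b[j - 1]))
            i, j = i - 1, j - 1
        elif p == 1 and i > 0:
            cols.append((a[i - 1], "-"))
            i -= 1
        else:
            cols.append(("-", b[j - 1]))
            j -= 1
    cols.reverse()
    while cols and ("-" in cols[0]):
        cols.pop(0)
    while cols and ("-" in cols[-1]):
        cols.pop()
    ident = sum(1 for x, y in cols if x == y)
    aligned = sum(1 for x, y in cols if "-" not in (x, y))
    gaps = len(cols) - aligned
    return 100.0 * ident / (aligned + gaps)
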