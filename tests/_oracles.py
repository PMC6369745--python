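"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's algorithms: segmentations are
enumerated exhaustively, Wright-Fisher fixation is simulated directly with
binomial draws, and NG86 site counts are enumerated codon by codon.
"""

from __future__ import annotations

import itertools

import numpy as np


# ---------------------------------------------------------------------------
# exhaustive minimal segmentation
# ---------------------------------------------------------------------------
# Canonical objective (shared with the implementation under test):
# lexicographically minimize (total discordant sites, number of blocks,
# switch positions left-to-right, block-label sequence), subject to every
# block containing >= min_support sites matching its own label.

def brute_force_segmentation(labels, n_labels, min_support):
    """Enumerate every block partition + labeling of a small sequence.

    Returns (disc, blocks, switches, labelseq) of the canonical optimum, or
    None when no valid segmentation exists.  ``switches`` are the indices
    of the first site of each new block.
    """
    n = len(labels)
    best = None
    for k in range(n):  # number of switches
        for cuts in itertools.combinations(range(1, n), k):
            bounds = [0, *cuts, n]
            segs = [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]
            for labseq in itertools.product(range(n_labels), repeat=len(segs)):
                if any(a == b for a, b in zip(labseq, labseq[1:])):
                    continue
                ok = True
                disc = 0
                for (s, e), lab in zip(segs, labseq):
                    sup = sum(1 for i in range(s, e) if labels[i] == lab)
                    if sup < min_support:
                        ok = False
                        break
                    disc += (e - s) - sup
                if not ok:
                    continue
                cand = (disc, len(segs), cuts, labseq)
                if best is None or cand < best:
                    best = cand
    return best


def _popcount(arr):
    try:
        return np.bitwise_count(arr)
    except AttributeError:  # pragma: no cover
        table = np.array([bin(i).count("1") for i in range(1 << 16)],
                         dtype=np.uint8)
        return table[arr]


def exhaustive_scores(n, min_support):
    """Canonical-optimum score for EVERY 2-parent sequence of length n.

    Sequences are encoded as integers (bit i = label of site i).  The score
    packs (disc, blocks, bit-reversed switch mask, first label) so that the
    integer order equals the canonical lexicographic order; -1 marks
    sequences with no valid segmentation.  Evaluates all 2^(n-1) boundary
    masks x 2 labelings against all 2^n sequences at once.
    """
    X = np.arange(1 << n, dtype=np.uint64)
    INF = np.iinfo(np.int64).max
    best = np.full(1 << n, INF, dtype=np.int64)
    for b in range(1 << (n - 1)) if n > 1 else [0]:
        # boundary bit s set => a new block starts at site s+1
        cuts = [s + 1 for s in range(n - 1) if b >> s & 1]
        bounds = [0, *cuts, n]
        runmasks = [(((1 << (e - s)) - 1) << s, e - s)
                    for s, e in zip(bounds, bounds[1:])]
        blocks = len(runmasks)
        rev = 0
        for s in range(n - 1):
            if b >> s & 1:
                rev |= 1 << (n - 2 - s)
        # v0: labels alternate starting from label 0; v1 is its complement,
        # so per-run mismatch counts for v1 are (run length - counts for v0)
        v0 = 0
        for bi, (m, _) in enumerate(runmasks):
            if bi % 2 == 1:
                v0 |= m
        diff = X ^ np.uint64(v0)
        disc0 = np.zeros(1 << n, dtype=np.int64)
        ok0 = np.ones(1 << n, dtype=bool)
        ok1 = np.ones(1 << n, dtype=bool)
        for m, rl in runmasks:
            c = _popcount(diff & np.uint64(m)).astype(np.int64)
            disc0 += c
            ok0 &= (rl - c) >= min_support
            ok1 &= c >= min_support
        for l0, ok, disc in ((0, ok0, disc0), (1, ok1, n - disc0)):
            tie = (((1 << (n - 1)) - 1 - rev) << 1) | l0
            score = (((disc << 5) | blocks) << (n + 1)) | tie
            np.minimum(best, np.where(ok, score, INF), out=best)
    best[best == INF] = -1
    return best


def encode_solution(n, disc, blocks, switch_sites, first_label):
    """Encode a segmentation in the same packed order as exhaustive_scores.

    ``switch_sites`` are indices of the first site of each non-initial
    block.
    """
    rev = 0
    for s in switch_sites:
        rev |= 1 << (n - 2 - (s - 1))
    tie = (((1 << (n - 1)) - 1 - rev) << 1) | first_label
    return (((disc << 5) | blocks) << (n + 1)) | tie


# ---------------------------------------------------------------------------
# Wright-Fisher fixation by direct binomial simulation
# ---------------------------------------------------------------------------

def wf_fixation_fraction(p0, n_eff, n_gen, n_reps, rng):
    """Fraction of two-type Wright-Fisher lineages fixed after n_gen."""
    p = np.full(n_reps, p0)
    for _ in range(n_gen):
        p = rng.binomial(n_eff, p) / n_eff
    return float(np.mean((p == 0.0) | (p == 1.0)))


# ---------------------------------------------------------------------------
# naive G+C counting
# ---------------------------------------------------------------------------

def naive_gc(seq: bytes) -> float:
    s = seq.decode().upper()
    valid = [c for c in s if c != "N"]
    if not valid:
        return float("nan")
    return sum(c in "GC" for c in valid) / len(valid)
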