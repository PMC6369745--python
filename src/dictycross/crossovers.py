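"""Parental haplotype segmentation and crossover calling.

A progeny chromosome is a sequence of parental-origin calls at ordered
informative sites.  Segmentation partitions that sequence into parental
blocks (adjacent blocks from different parents, each block supported by at
least ``min_support`` sites matching its own parent) so as to minimize,
lexicographically, (total discordant sites, number of blocks).  Among
equally good segmentations the canonical one has its switch positions
leftmost (compared lexicographically), then the lexicographically smallest
block-label sequence in sorted-label order.  Short runs of discordant calls
therefore never nucleate a block: they are treated as the read-assignment
noise they almost always are in haploid progeny.

A crossover event is the interval between the last supporting site of one
block and the first supporting site of the next; crossovers outside the
first/last informative site of a chromosome are undetectable by design.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AMBIGUOUS = "ambiguous"

__all__ = ["HaplotypeBlock", "CrossoverEvent", "segment_haplotypes",
           "call_crossovers", "events_to_frame", "check_macrocyst_identity"]


@dataclass
class HaplotypeBlock:
    chrom: str
    parent: str
    first_support_pos: int
    last_support_pos: int
    n_support: int
    n_discordant: int
    low_support: bool = False


@dataclass
class CrossoverEvent:
    chrom: str
    left_flank_pos: int
    right_flank_pos: int
    parent_from: str
    parent_to: str
    gc_fraction: float = float("nan")

    @property
    def interval_len(self) -> int:
        return self.right_flank_pos - self.left_flank_pos

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.left_flank_pos + self.right_flank_pos)


# ---------------------------------------------------------------------------
# canonical minimal segmentation (dynamic program over call runs)
# ---------------------------------------------------------------------------

def _compress_runs(labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal runs of equal labels as (label, start, end) half-open."""
    runs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append((int(labels[start]), start, i))
            start = i
    return runs


def canonical_segmentation(labels: np.ndarray, n_labels: int, min_support: int,
                           ) -> list[tuple[int, int, int]] | None:
    """Optimal block partition of an integer label sequence.

    Returns blocks as (start, end, label) over site indices (half-open), or
    None when no label reaches ``min_support`` in the whole sequence (the
    caller then falls back to a flagged single majority block).

    Optimal block boundaries always coincide with run boundaries: moving a
    boundary within a run strictly changes the discordant count when the
    run's label matches exactly one adjacent block, and the leftmost
    tie-break resolves the remaining (matches-neither) case to the run
    start.  The program therefore works on the run-compressed sequence.
    """
    n = len(labels)
    if n == 0:
        return []
    counts = np.bincount(labels, minlength=n_labels)
    if counts.max() < min_support:
        return None
    runs = _compress_runs(labels)
    R = len(runs)
    run_label = [r[0] for r in runs]
    run_len = [r[2] - r[1] for r in runs]
    run_start = [r[1] for r in runs]
    # cumulative per-label site counts over runs
    cum = np.zeros((R + 1, n_labels), dtype=np.int64)
    for i, (lab, s, e) in enumerate(runs):
        cum[i + 1] = cum[i]
        cum[i + 1, lab] += e - s
    tot = np.concatenate([[0], np.cumsum(run_len)])

    def match(i: int, j: int, lab: int) -> int:
        """Sites matching lab within runs i..j inclusive."""
        return int(cum[j + 1, lab] - cum[i, lab])

    def size(i: int, j: int) -> int:
        return int(tot[j + 1] - tot[i])

    INF = (float("inf"), float("inf"))
    # g[i][lab] = minimal (disc, blocks) for runs i..R-1, first block labeled
    # lab and starting at run i
    g = [[INF] * n_labels for _ in range(R + 1)]
    for i in range(R - 1, -1, -1):
        for lab in range(n_labels):
            best = INF
            for j in range(i, R):
                sup = match(i, j, lab)
                if sup < min_support:
                    continue
                disc = size(i, j) - sup
                if j == R - 1:
                    cand = (disc, 1)
                else:
                    cont = min(g[j + 1][l2] for l2 in range(n_labels)
                               if l2 != lab)
                    if cont == INF:
                        continue
                    cand = (disc + cont[0], 1 + cont[1])
                if cand < best:
                    best = cand
            g[i][lab] = best
    opt = min(g[0])
    opt_disc, opt_blocks = opt

    # --- fix switch boundaries, leftmost-first --------------------------
    # states: (current block label, discordants accumulated before it)
    boundaries: list[int] = []  # run indices where a new block starts
    states = {(lab, 0) for lab in range(n_labels) if g[0][lab] == opt}
    i0 = 0
    for t in range(1, int(opt_blocks)):
        remaining = opt_blocks - t
        found = None
        for j in range(i0 + 1, R - int(remaining) + 2):
            new_states = set()
            for lab, acc in states:
                sup = match(i0, j - 1, lab)
                if sup < min_support:
                    continue
                d = acc + size(i0, j - 1) - sup
                for l2 in range(n_labels):
                    if l2 == lab:
                        continue
                    gd, gb = g[j][l2]
                    if gb == remaining and d + gd == opt_disc:
                        new_states.add((l2, d))
            if new_states:
                found = (j, new_states)
                break
        assert found is not None, "canonical segmentation reconstruction failed"
        boundaries.append(found[0])
        states = found[1]
        i0 = found[0]

    # --- fix labels, lexicographically smallest -------------------------
    seg_runs = list(zip([0] + boundaries, boundaries + [R]))

    def seg_stats(k: int, lab: int) -> tuple[int, int]:
        a, b = seg_runs[k]
        sup = match(a, b - 1, lab)
        return sup, size(a, b - 1) - sup

    memo: dict[tuple[int, int, int], bool] = {}

    def feasible(k: int, prev: int, disc_left: int) -> bool:
        if k == len(seg_runs):
            return disc_left == 0
        key = (k, prev, disc_left)
        if key not in memo:
            ok = False
            for lab in range(n_labels):
                if lab == prev:
                    continue
                sup, d = seg_stats(k, lab)
                if sup >= min_support and d <= disc_left and \
                        feasible(k + 1, lab, disc_left - d):
                    ok = True
                    break
            memo[key] = ok
        return memo[key]

    chosen: list[int] = []
    disc_left = int(opt_disc)
    prev = -1
    for k in range(len(seg_runs)):
        for lab in range(n_labels):
            if lab == prev:
                continue
            sup, d = seg_stats(k, lab)
            if sup >= min_support and d <= disc_left and \
                    feasible(k + 1, lab, disc_left - d):
                chosen.append(lab)
                disc_left -= d
                prev = lab
                break
        else:
            raise AssertionError("label reconstruction failed")

    return [(run_start[a], run_start[b - 1] + run_len[b - 1], lab)
            for (a, b), lab in zip(seg_runs, chosen)]


def segment_haplotypes(positions: np.ndarray, calls: np.ndarray,
                       chrom: str = "", min_support: int = 2,
                       parents: list[str] | None = None,
                       ) -> list[HaplotypeBlock]:
    """Segment one chromosome's origin calls into parental haplotype blocks.

    Ambiguous calls are dropped first.  With fewer informative sites than
    ``min_support`` (or no parent reaching it), a single majority block is
    returned with ``low_support=True``.
    """
    positions = np.asarray(positions)
    calls = np.asarray(calls, dtype=object)
    keep = calls != AMBIGUOUS
    positions, calls = positions[keep], calls[keep]
    if parents is None:
        parents = sorted(set(calls))
    if len(positions) == 0:
        return []
    lab2idx = {p: i for i, p in enumerate(parents)}
    labels = np.array([lab2idx[c] for c in calls], dtype=np.int64)

    segs = canonical_segmentation(labels, len(parents), min_support)
    if segs is None:  # no parent reaches min_support: flagged majority block
        counts = np.bincount(labels, minlength=len(parents))
        lab = int(counts.argmax())
        segs = [(0, len(labels), lab)]
        low = True
    else:
        low = False

    blocks = []
    for s, e, lab in segs:
        in_blk = labels[s:e]
        sup_idx = np.nonzero(in_blk == lab)[0] + s
        if len(sup_idx) == 0:  # only in the flagged fallback
            sup_idx = np.arange(s, e)
        blocks.append(HaplotypeBlock(
            chrom=chrom, parent=parents[lab],
            first_support_pos=int(positions[sup_idx[0]]),
            last_support_pos=int(positions[sup_idx[-1]]),
            n_support=int((in_blk == lab).sum()),
            n_discordant=int((in_blk != lab).sum()),
            low_support=low,
        ))
    return blocks


# ---------------------------------------------------------------------------
# crossover events
# ---------------------------------------------------------------------------

def call_crossovers(blocks: list[HaplotypeBlock]) -> list[CrossoverEvent]:
    """One event per adjacent block pair, localized between the last
    supporting site of the left block and the first of the right."""
    events = []
    for left, right in zip(blocks, blocks[1:]):
        events.append(CrossoverEvent(
            chrom=left.chrom,
            left_flank_pos=left.last_support_pos,
            right_flank_pos=right.first_support_pos,
            parent_from=left.parent,
            parent_to=right.parent,
        ))
    return events


def events_to_frame(events: list[CrossoverEvent],
                    progeny: str | None = None) -> pd.DataFrame:
    rows = [{
        "progeny": progeny, "chrom": e.chrom, "left": e.left_flank_pos,
        "right": e.right_flank_pos, "parent_from": e.parent_from,
        "parent_to": e.parent_to, "interval_len": e.interval_len,
        "midpoint": e.midpoint, "gc_fraction": e.gc_fraction,
    } for e in events]
    return pd.DataFrame(rows, columns=["progeny", "chrom", "left", "right",
                                       "parent_from", "parent_to",
                                       "interval_len", "midpoint",
                                       "gc_fraction"])


def segment_progeny(obs: pd.DataFrame, nuclear_parents: tuple[str, str],
                    min_support: int = 2) -> tuple[pd.DataFrame, dict]:
    """Segment every (progeny, chromosome) of an observation table.

    Returns the combined crossover-event table and a dict of block lists
    keyed by (progeny, chrom).  Only nuclear sites whose origin call is one
    of the two nuclear parents participate.
    """
    nuc = obs[(obs["contig_type"] == "nuclear")
              & obs["origin_call"].isin(nuclear_parents)]
    parents = sorted(nuclear_parents)
    frames, block_map = [], {}
    for (pid, chrom), sub in nuc.groupby(["progeny", "chrom"], sort=True):
        sub = sub.sort_values("pos")
        blocks = segment_haplotypes(sub["pos"].to_numpy(),
                                    sub["origin_call"].to_numpy(),
                                    chrom=chrom, min_support=min_support,
                                    parents=parents)
        block_map[(pid, chrom)] = blocks
        frame = events_to_frame(call_crossovers(blocks), progeny=pid)
        if len(frame):
            frames.append(frame)
    events = (pd.concat(frames, ignore_index=True) if frames
              else events_to_frame([]))
    return events, block_map


# ---------------------------------------------------------------------------
# macrocyst clonality
# ---------------------------------------------------------------------------

def check_macrocyst_identity(obs: pd.DataFrame, progeny_ids: list[str],
                             threshold: float = 0.995) -> dict:
    """Pairwise origin-call concordance within a putative clonal group.

    Only unambiguous nuclear calls shared by both clones are compared.
    Verdict: 'identical' if every pairwise concordance >= threshold,
    'distinct' otherwise, 'indeterminate' if any pair shares no sites.
    """
    if len(progeny_ids) < 2:
        raise ValueError("need at least two progeny to compare")
    nuc = obs[(obs["contig_type"] == "nuclear")
              & (obs["origin_call"] != AMBIGUOUS)
              & obs["progeny"].isin(progeny_ids)]
    pairs = []
    indeterminate = False
    for a, b in itertools.combinations(progeny_ids, 2):
        oa = nuc[nuc["progeny"] == a][["chrom", "pos", "origin_call"]]
        ob = nuc[nuc["progeny"] == b][["chrom", "pos", "origin_call"]]
        merged = oa.merge(ob, on=["chrom", "pos"], suffixes=("_a", "_b"))
        if len(merged) == 0:
            pairs.append({"a": a, "b": b, "n_shared": 0,
                          "concordance": float("nan")})
            indeterminate = True
            continue
        conc = float((merged["origin_call_a"] == merged["origin_call_b"]).mean())
        pairs.append({"a": a, "b": b, "n_shared": len(merged),
                      "concordance": conc})
    if indeterminate:
        verdict = "indeterminate"
    elif all(p["concordance"] >= threshold for p in pairs):
        verdict = "identical"
    else:
        verdict = "distinct"
    return {"verdict": verdict, "pairs": pd.DataFrame(pairs),
            "threshold": threshold}
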