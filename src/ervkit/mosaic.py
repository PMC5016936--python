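"""Mosaic assignment of transcripts to one locus or a recombinant of loci.

A transcript is compared against candidate loci on a common reference
coordinate grid; a Viterbi-style dynamic program over grid columns (states =
candidate loci, per-column cost = discordant bases with indel runs counted
once, transition cost = a configurable switch penalty) yields the minimum-
cost segmentation.  The switch penalty makes a breakpoint worthwhile only
when it saves at least that many discordant bases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import AlignedPair, AlignmentParams, global_align, project_to_reference
from .errors import InputError
from .reference import ReferenceModel

__all__ = [
    "MosaicConfig",
    "MosaicSegment",
    "MosaicAssignment",
    "count_discordant",
    "best_matching_locus",
    "segment_query",
]


@dataclass(frozen=True)
class MosaicConfig:
    switch_penalty: float = 4.0  # mismatch-equivalents per breakpoint
    max_candidates: int = 10
    min_identity: float = 0.8  # best-hit search floor


@dataclass
class MosaicSegment:
    query_interval: tuple  # 1-based inclusive query positions
    locus_id: str
    mismatches: int


@dataclass
class MosaicAssignment:
    segments: list
    breakpoints: list  # query positions where the locus changes
    total_mismatches: int
    single_locus_mismatches: int
    single_locus_id: str
    identity_best: float


def count_discordant(aln: AlignedPair) -> int:
    """Discordant bases: mismatched columns plus one per contiguous gap run."""
    n = 0
    in_gap = False
    for cr, cq in aln.columns():
        if cr == "-" or cq == "-":
            if not in_gap:
                n += 1
                in_gap = True
        else:
            in_gap = False
            if cr != cq and "N" not in (cr, cq):
                n += 1
    return n


def best_matching_locus(
    query: str,
    locus_db: dict,
    model: ReferenceModel | None = None,
    params: AlignmentParams | None = None,
    min_identity: float = 0.8,
) -> list:
    """Rank loci by identity to the query (ties: fewer discordant, then id).

    When a reference model is given, each locus is first projected onto the
    reference and the comparison is restricted to the query's reference
    span; otherwise the query is globally aligned to each full locus.
    Returns a list of (locus_id, identity, discordant); empty (with the
    caller expected to warn) when nothing reaches ``min_identity``.
    """
    if not locus_db:
        raise InputError("empty locus database")
    if params is None:
        params = AlignmentParams(free_end_gaps=True)
    results = []
    qry_span = None
    if model is not None:
        q_pair = project_to_reference(model, query)
        mapped = [p for p in range(1, model.length + 1) if q_pair.ref_map[p] is not None]
        if mapped:
            qry_span = (mapped[0], mapped[-1])
    for locus_id, locus_seq in sorted(locus_db.items()):
        target = locus_seq
        if qry_span is not None:
            l_pair = project_to_reference(model, locus_seq)
            lo, hi = qry_span
            idx = [l_pair.ref_map[p] for p in range(lo, hi + 1)]
            idx = [q for q in idx if q is not None]
            if idx:
                target = l_pair.qry_seq[idx[0] - 1 : idx[-1]]
        if not target:
            continue
        aln = global_align(target, query, params)
        matches = sum(1 for r, q in aln.columns() if r == q and r != "-")
        if matches / len(query) < min_identity:  # coverage guard
            continue
        results.append((locus_id, aln.identity, count_discordant(aln)))
    results = [r for r in results if r[1] >= min_identity]
    results.sort(key=lambda r: (-r[1], r[2], r[0]))
    return results


def _column_costs(
    model: ReferenceModel, query_pair: AlignedPair, locus_pair: AlignedPair,
    grid: list,
) -> np.ndarray:
    """Per-grid-column discordance of one locus against the query.

    Grid columns are reference positions covered by the query; a locus gap
    run over consecutive grid columns costs 1 at its first column.
    """
    qseq = query_pair.qry_seq
    lseq = locus_pair.qry_seq
    costs = np.zeros(len(grid))
    in_gap = False
    for k, p in enumerate(grid):
        qb = query_pair.ref_map[p]
        lb = locus_pair.ref_map[p]
        if lb is None:
            if not in_gap:
                costs[k] = 1.0
                in_gap = True
            continue
        in_gap = False
        cq, cl = qseq[qb - 1], lseq[lb - 1]
        if cq != cl and "N" not in (cq, cl):
            costs[k] = 1.0
    return costs


def segment_query(
    query: str,
    candidates: dict,
    model: ReferenceModel,
    config: MosaicConfig = MosaicConfig(),
) -> MosaicAssignment:
    """Minimum-cost segmentation of a transcript over candidate loci.

    ``candidates`` maps locus id to locus sequence; all sequences (query and
    loci) are projected onto the reference to share a coordinate grid.  With
    switch_penalty = 0 this degenerates to the per-column best locus; with a
    very large penalty, to the single best locus.
    """
    if not candidates:
        raise InputError("at least one candidate locus required")
    ids = sorted(candidates)
    q_pair = project_to_reference(model, query)
    grid = [p for p in range(1, model.length + 1) if q_pair.ref_map[p] is not None]
    if not grid:
        raise InputError("query does not project onto the reference")
    cost = np.vstack([
        _column_costs(model, q_pair, project_to_reference(model, candidates[i]), grid)
        for i in ids
    ])  # shape (k, n_cols)
    k, n = cost.shape
    lam = config.switch_penalty

    dp = cost[:, 0].copy()
    back = np.zeros((n, k), dtype=np.int32)
    back[0] = np.arange(k)
    for t in range(1, n):
        best_prev = float(dp.min())
        stay = dp
        switch = best_prev + lam
        take_switch = switch < stay
        argbest = int(dp.argmin())
        back[t] = np.where(take_switch, argbest, np.arange(k))
        dp = np.where(take_switch, switch, stay) + cost[:, t]

    state = int(dp.argmin())
    total = float(dp[state])
    path = np.zeros(n, dtype=np.int32)
    path[-1] = state
    for t in range(n - 1, 0, -1):
        path[t - 1] = back[t, path[t]]

    # switch columns; refine each to the midpoint of its cost-tie window
    # (between informative columns the cut position is cost-equivalent)
    cuts = [t for t in range(1, n) if path[t] != path[t - 1]]
    refined = []
    prev_cut = 0
    for idx, t in enumerate(cuts):
        a, b = path[t - 1], path[t]
        lo = t
        while lo - 1 > prev_cut and cost[a, lo - 1] == cost[b, lo - 1]:
            lo -= 1
        hi = t
        upper = cuts[idx + 1] if idx + 1 < len(cuts) else n
        while hi < upper - 1 and cost[a, hi] == cost[b, hi]:
            hi += 1
        mid = (lo + hi) // 2
        refined.append(max(prev_cut + 1, min(mid, upper - 1)))
        prev_cut = refined[-1]

    qpos = [q_pair.ref_map[p] for p in grid]
    seg_states = [int(path[b]) for b in [0] + cuts]
    segments = []
    breakpoints = []
    bounds = [0] + refined + [n]
    for st, (s, e) in zip(seg_states, zip(bounds[:-1], bounds[1:])):
        mism = int(cost[st, s:e].sum())
        segments.append(MosaicSegment((qpos[s], qpos[e - 1]), ids[st], mism))
        if e < n:
            breakpoints.append(qpos[e])

    single = cost.sum(axis=1)
    best_single = int(single.argmin())
    n_switches = len(segments) - 1
    return MosaicAssignment(
        segments=segments,
        breakpoints=breakpoints,
        total_mismatches=int(round(total - lam * n_switches)),
        single_locus_mismatches=int(single[best_single]),
        single_locus_id=ids[best_single],
        identity_best=1.0 - single[best_single] / n,
    )
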