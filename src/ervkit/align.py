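"""Global affine-gap pairwise alignment and reference projection.

Every downstream module addresses element bases by reference coordinate, so
each element is anchored to the group consensus with a single pairwise
alignment (:func:`project_to_reference`).  Optimal global alignment is
delegated to Biopython's :class:`Bio.Align.PairwiseAligner`; projection of
near-full-length elements is accelerated by exact k-mer anchor chaining with
optimal alignment of the inter-anchor blocks, which is exact whenever the
anchors themselves lie on the optimal path (they are unique exact matches)
and falls back to a full dynamic program otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .errors import InputError
from .reference import ReferenceModel

__all__ = ["AlignmentParams", "AlignedPair", "global_align", "project_to_reference"]

_ALPHABET = "ACGTN"


@dataclass(frozen=True)
class AlignmentParams:
    """Scores for global alignment.

    A gap of length k costs ``gap_open + (k - 1) * gap_extend``.  ``N``
    matches any base at score 0.  Defaults are long-indel tolerant because
    most group members carry kilobase-scale deletions.
    """

    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -5.0
    gap_extend: float = -1.0
    free_end_gaps: bool = False


DEFAULT_PARAMS = AlignmentParams()


@lru_cache(maxsize=16)
def _make_aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    matrix = substitution_matrices.Array(alphabet=_ALPHABET, dims=2)
    for a in _ALPHABET:
        for b in _ALPHABET:
            if "N" in (a, b):
                matrix[a, b] = 0.0
            else:
                matrix[a, b] = params.match if a == b else params.mismatch
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    if params.free_end_gaps:
        try:  # Biopython >= 1.86 naming
            aligner.end_insertion_score = 0.0
            aligner.end_deletion_score = 0.0
        except AttributeError:  # pragma: no cover - older releases
            aligner.target_end_gap_score = 0.0
            aligner.query_end_gap_score = 0.0
    return aligner


@dataclass
class AlignedPair:
    """A global alignment of a query against a reference sequence.

    ``ref_aligned`` and ``qry_aligned`` are equal-length gapped strings;
    removing gaps recovers the inputs exactly.  ``ref_map[p]`` gives the
    1-based query position aligned to 1-based reference position ``p`` (or
    ``None`` on a gap); it is monotone non-decreasing over mapped positions.
    """

    ref_aligned: str
    qry_aligned: str
    score: float
    not_group_member: bool = False
    _ref_map: list | None = field(default=None, repr=False)
    _qry_map: list | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if len(self.ref_aligned) != len(self.qry_aligned):
            raise InputError("aligned strings must have equal length")

    @property
    def ref_seq(self) -> str:
        return self.ref_aligned.replace("-", "")

    @property
    def qry_seq(self) -> str:
        return self.qry_aligned.replace("-", "")

    def _build_maps(self) -> None:
        ref_map: list = [None] * (len(self.ref_seq) + 1)
        qry_map: list = [None] * (len(self.qry_seq) + 1)
        r = q = 0
        for cr, cq in zip(self.ref_aligned, self.qry_aligned):
            if cr != "-":
                r += 1
            if cq != "-":
                q += 1
            if cr != "-" and cq != "-":
                ref_map[r] = q
                qry_map[q] = r
        self._ref_map = ref_map
        self._qry_map = qry_map

    @property
    def ref_map(self) -> list:
        if self._ref_map is None:
            self._build_maps()
        return self._ref_map

    @property
    def qry_map(self) -> list:
        if self._qry_map is None:
            self._build_maps()
        return self._qry_map

    def query_base_at(self, ref_pos: int) -> str | None:
        """Query base aligned to 1-based reference position, or None on gap."""
        q = self.ref_map[ref_pos]
        return None if q is None else self.qry_seq[q - 1]

    def columns(self) -> zip:
        """Iterate (ref_char, qry_char) over alignment columns."""
        return zip(self.ref_aligned, self.qry_aligned)

    @property
    def identity(self) -> float:
        """Fraction of identical bases over columns aligned in both sequences."""
        aligned = matches = 0
        for cr, cq in self.columns():
            if cr != "-" and cq != "-":
                aligned += 1
                if cr == cq:
                    matches += 1
        return matches / aligned if aligned else 0.0


def _check_seq(seq: str, name: str) -> str:
    if not seq:
        raise InputError(f"empty sequence: {name}")
    seq = seq.upper()
    bad = set(seq) - set(_ALPHABET)
    if bad:
        raise InputError(f"{name} contains invalid symbols: {sorted(bad)}")
    return seq


def _score_alignment(ra: str, qa: str, params: AlignmentParams) -> float:
    """Re-score an alignment from its gapped strings (for stitched paths)."""
    score = 0.0
    in_gap = None
    for cr, cq in zip(ra, qa):
        if cr == "-" or cq == "-":
            which = "r" if cr == "-" else "q"
            score += params.gap_extend if in_gap == which else params.gap_open
            in_gap = which
        else:
            in_gap = None
            if cr == "N" or cq == "N":
                pass
            else:
                score += params.match if cr == cq else params.mismatch
    return score


def global_align(ref: str, qry: str, params: AlignmentParams = DEFAULT_PARAMS) -> AlignedPair:
    """Optimal global alignment of two DNA sequences.

    Ties between co-optimal alignments are broken deterministically by the
    underlying dynamic program (first reported traceback).
    """
    ref = _check_seq(ref, "ref")
    qry = _check_seq(qry, "qry")
    aligner = _make_aligner(params)
    aln = aligner.align(ref, qry)[0]
    return AlignedPair(str(aln[0]), str(aln[1]), float(aln.score))


# ---------------------------------------------------------------------------
# Anchored projection
# ---------------------------------------------------------------------------

_ANCHOR_K = 24


def _unique_kmers(seq: str, k: int) -> dict:
    """Map k-mer -> 0-based position, for k-mers occurring exactly once."""
    pos: dict = {}
    dup = set()
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        if km in dup:
            continue
        if km in pos:
            del pos[km]
            dup.add(km)
        else:
            pos[km] = i
    return pos


def _chain_anchors(ref: str, qry: str, k: int = _ANCHOR_K) -> list[tuple[int, int]]:
    """Longest consistent chain of unique exact k-mer matches (0-based)."""
    ref_idx = _unique_kmers(ref, k)
    qry_idx = _unique_kmers(qry, k)
    hits = sorted(
        (r, qry_idx[km]) for km, r in ref_idx.items() if km in qry_idx
    )
    if not hits:
        return []
    # longest strictly-increasing subsequence in query coordinate
    qpos = [q for _, q in hits]
    import bisect

    tails: list[int] = []
    tails_idx: list[int] = []
    prev = [-1] * len(hits)
    for i, q in enumerate(qpos):
        j = bisect.bisect_left(tails, q)
        if j == len(tails):
            tails.append(q)
            tails_idx.append(i)
        else:
            tails[j] = q
            tails_idx[j] = i
        prev[i] = tails_idx[j - 1] if j > 0 else -1
    chain = []
    i = tails_idx[-1]
    while i >= 0:
        chain.append(hits[i])
        i = prev[i]
    chain.reverse()
    # drop anchors overlapping their predecessor in either coordinate
    spaced = [chain[0]]
    for r, q in chain[1:]:
        pr, pq = spaced[-1]
        if r >= pr + k and q >= pq + k:
            spaced.append((r, q))
    return spaced


def _align_block(
    ref: str, qry: str, params: AlignmentParams, free_side: str | None = None
) -> tuple[str, str]:
    """Globally align one inter-anchor block.

    ``free_side`` ('left'/'right') waives the penalty for reference overhang
    on the outer side of a terminal block, keeping the block anchored at the
    inner edge while the query stays fully consumed.
    """
    if not ref and not qry:
        return "", ""
    if not ref:
        return "-" * len(qry), qry
    if not qry:
        return ref, "-" * len(ref)
    aligner = _make_aligner(
        AlignmentParams(params.match, params.mismatch, params.gap_open, params.gap_extend)
    )
    if free_side is not None:
        import copy

        aligner = copy.deepcopy(aligner)
        setattr(aligner, f"open_{free_side}_deletion_score", 0.0)
        setattr(aligner, f"extend_{free_side}_deletion_score", 0.0)
    aln = aligner.align(ref, qry)[0]
    return str(aln[0]), str(aln[1])


def anchored_global_align(
    ref: str, qry: str, params: AlignmentParams = DEFAULT_PARAMS
) -> AlignedPair | None:
    """Heuristic global alignment via unique k-mer anchor chaining.

    Returns None when anchoring is too sparse to be trusted (caller should
    fall back to the full dynamic program).
    """
    chain = _chain_anchors(ref, qry)
    if len(chain) < 3:
        return None
    span = chain[-1][0] - chain[0][0] + _ANCHOR_K
    if span < 0.3 * min(len(ref), len(qry)):
        return None
    parts_r: list[str] = []
    parts_q: list[str] = []
    pr = pq = 0
    first = True
    for r, q in chain:
        if first:
            # head block: keep the query adjacent to the first anchor; the
            # reference overhang beyond a bounded window is pure gap
            window = min(r, 2 * q + 100)
            br, bq = _align_block(ref[r - window : r], qry[:q], params,
                                  free_side="left")
            parts_r.append(ref[: r - window] + br)
            parts_q.append("-" * (r - window) + bq)
            first = False
        else:
            br, bq = _align_block(ref[pr:r], qry[pq:q], params)
            parts_r.append(br)
            parts_q.append(bq)
        parts_r.append(ref[r : r + _ANCHOR_K])
        parts_q.append(qry[q : q + _ANCHOR_K])
        pr, pq = r + _ANCHOR_K, q + _ANCHOR_K
    # tail block: same bounded window after the last anchor
    q_tail = len(qry) - pq
    window = min(len(ref) - pr, 2 * q_tail + 100)
    br, bq = _align_block(ref[pr : pr + window], qry[pq:], params,
                          free_side="right")
    parts_r.append(br + ref[pr + window :])
    parts_q.append(bq + "-" * (len(ref) - pr - window))
    ra, qa = "".join(parts_r), "".join(parts_q)
    return AlignedPair(ra, qa, _score_alignment(ra, qa, params))


def project_to_reference(
    model: ReferenceModel,
    element_seq: str,
    params: AlignmentParams = DEFAULT_PARAMS,
) -> AlignedPair:
    """Anchor an element sequence to the reference frame.

    Inputs shorter than 200 nt are rejected as unalignable fragments.  A
    result with identity below 0.5 over aligned columns is returned with the
    ``not_group_member`` flag set (not an exception).
    """
    element_seq = _check_seq(element_seq, "element_seq")
    if len(element_seq) < 200:
        raise InputError(
            f"element too short to project ({len(element_seq)} nt < 200)"
        )
    pair = anchored_global_align(model.sequence, element_seq, params)
    if pair is None:
        free = AlignmentParams(
            params.match, params.mismatch, params.gap_open, params.gap_extend,
            free_end_gaps=True,
        )
        pair = global_align(model.sequence, element_seq, free)
    # membership requires both per-column identity and query coverage, since
    # free end gaps let unrelated sequence align over a handful of columns
    matches = sum(1 for r, q in pair.columns() if r == q and r != "-")
    if pair.identity < 0.5 or matches / len(element_seq) < 0.5:
        pair.not_group_member = True
    return pair


def slice_alignment(pair: AlignedPair, ref_start: int, ref_end: int) -> AlignedPair:
    """Restrict an alignment to a 1-based inclusive reference interval.

    Columns where the reference is gapped (query insertions) inside the
    window are retained; flanking insertion columns are excluded.
    """
    cols_start = cols_end = None
    r = 0
    for i, cr in enumerate(pair.ref_aligned):
        if cr != "-":
            r += 1
            if r == ref_start and cols_start is None:
                cols_start = i
            if r == ref_end:
                cols_end = i
                break
    if cols_start is None or cols_end is None:
        raise InputError(f"reference window {ref_start}-{ref_end} outside alignment")
    ra = pair.ref_aligned[cols_start : cols_end + 1]
    qa = pair.qry_aligned[cols_start : cols_end + 1]
    return AlignedPair(ra, qa, _score_alignment(ra, qa, DEFAULT_PARAMS))


def pair_from_column_strings(seq_a: str, seq_b: str) -> AlignedPair:
    """Build an AlignedPair from two equal-length gapped column strings,
    dropping columns gapped in both."""
    if len(seq_a) != len(seq_b):
        raise InputError("column strings must have equal length")
    ra = []
    qa = []
    for ca, cb in zip(seq_a, seq_b):
        if ca == "-" and cb == "-":
            continue
        ra.append(ca)
        qa.append(cb)
    ra_s, qa_s = "".join(ra), "".join(qa)
    return AlignedPair(ra_s, qa_s, _score_alignment(ra_s, qa_s, DEFAULT_PARAMS))


def ref_frame_string(model: ReferenceModel, pair: AlignedPair) -> str:
    """Gapped query string over reference coordinates 1..L (insertions dropped).

    Position p of the result is the query base aligned to reference position
    p, or '-' when the query has no base there.
    """
    out = ["-"] * model.length
    qseq = pair.qry_seq
    rm = pair.ref_map
    for p in range(1, model.length + 1):
        q = rm[p]
        if q is not None:
            out[p - 1] = qseq[q - 1]
    return "".join(out)
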