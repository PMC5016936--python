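"""Primer-binding-site assignment and gammaretroviral motif features.

The PBS is an 18-nt window a few nucleotides downstream of the 5' LTR,
complementary to the 3' end of a host tRNA; it is assigned to the library
entry with the fewest mismatches when that best hit is unique and has at
most 4 mismatches.  Protein features are scanned with literal patterns:
nucleocapsid zinc fingers CX2CX4HX4C and CX2CX3HX4C, and the integrase
C-terminal GPY/F motif WXnGPYXV.
"""

from __future__ import annotations

import importlib.resources
import math
import re
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import reverse_complement

from .align import AlignedPair
from .errors import InputError
from .reference import ReferenceModel

__all__ = [
    "PBSCall",
    "MotifHit",
    "load_trna_library",
    "find_pbs",
    "scan_protein_motifs",
    "composition_stats",
    "position_frequency_matrix",
    "ag_rich_leader",
]

PBS_LENGTH = 18
PBS_SLACK = 3
PBS_MAX_MISMATCHES = 4

MOTIF_PATTERNS = {
    "zinc_finger_cx2cx4hx4c": r"C.{2}C.{4}H.{4}C",
    "zinc_finger_cx2cx3hx4c": r"C.{2}C.{3}H.{4}C",
    "gpy_f": r"W.{3,30}?GP[YF].V",
}


@dataclass
class PBSCall:
    sequence: str | None
    ref_offset: int | None  # offset applied to the canonical window (nt)
    assignment: str  # one-letter tRNA code | "ambiguous" | "absent"
    mismatches_best: int | None = None
    runner_up_gap: int | None = None


@dataclass
class MotifHit:
    motif_name: str
    start: int  # 1-based in the scanned protein
    end: int
    matched: str


def load_trna_library(path=None) -> dict:
    """tRNA 3'-end library: one-letter code -> expected 18-nt PBS sequence.

    FASTA records hold the tRNA 3' ends; the PBS is their reverse
    complement.
    """
    if path is None:
        path = importlib.resources.files("ervkit") / "data" / "trna_3p_library.fasta"
    lib = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        lib[rec.id] = reverse_complement(str(rec.seq).upper())
    if not lib:
        raise InputError("empty tRNA library")
    return lib


def find_pbs(
    aln: AlignedPair,
    model: ReferenceModel,
    trna_lib: dict | None = None,
) -> PBSCall:
    """Extract the PBS window from a projected element and assign its tRNA.

    The window at the reference PBS coordinates is tried at offsets within
    +-3 nt and the best-scoring (offset, library entry) pair wins.  The
    assignment is ambiguous when the best entry is tied or exceeds 4
    mismatches, and absent when the element does not cover the window.
    """
    if trna_lib is None:
        trna_lib = load_trna_library()
    window = model.pbs_reference_window()
    qseq = aln.qry_seq
    rm = aln.ref_map

    candidates = []
    for off in range(-PBS_SLACK, PBS_SLACK + 1):
        start = window.start + off
        q = rm[start] if 1 <= start <= model.length else None
        if q is None or q + PBS_LENGTH - 1 > len(qseq):
            continue
        candidates.append((off, qseq[q - 1 : q - 1 + PBS_LENGTH]))
    if not candidates:
        return PBSCall(None, None, "absent")

    best = None  # (mismatches, off, code, seq)
    scores = []
    for off, seq in candidates:
        for code, pbs in trna_lib.items():
            mm = sum(a != b for a, b in zip(seq, pbs))
            scores.append((mm, code))
            if best is None or mm < best[0]:
                best = (mm, off, code, seq)
    mm_best, off, code, seq = best
    per_code = {}
    for mm, c in scores:
        per_code[c] = min(mm, per_code.get(c, PBS_LENGTH + 1))
    runner = min((m for c, m in per_code.items() if c != code), default=PBS_LENGTH)
    gap = runner - mm_best
    if mm_best > PBS_MAX_MISMATCHES or gap < 1:
        return PBSCall(seq, off, "ambiguous", mm_best, gap)
    return PBSCall(seq, off, code, mm_best, gap)


def scan_protein_motifs(protein: str, which=None) -> list:
    """Non-overlapping literal-pattern motif hits with 1-based coordinates."""
    if not protein:
        raise InputError("empty protein")
    names = list(MOTIF_PATTERNS) if which is None else list(which)
    hits = []
    for name in names:
        try:
            pattern = MOTIF_PATTERNS[name]
        except KeyError:
            raise InputError(f"unknown motif {name!r}") from None
        for m in re.finditer(pattern, protein):
            hits.append(MotifHit(name, m.start() + 1, m.end(), m.group()))
    return hits


def composition_stats(seq: str, a_rich: float = 0.28, g_poor: float = 0.24) -> dict:
    """Base fractions plus purine-bias flags (A-rich, G-poor)."""
    if len(seq) < 100:
        raise InputError("sequence too short for composition stats (< 100 nt)")
    n = len(seq)
    fractions = {b: seq.count(b) / n for b in "ACGT"}
    return {
        "fractions": fractions,
        "a_rich": fractions["A"] > a_rich,
        "g_poor": fractions["G"] < g_poor,
    }


def position_frequency_matrix(strings: list, alphabet: str = "ACGT"):
    """Column-wise relative frequencies and information content in bits.

    Returns (freq, ic) where freq has shape (L, |alphabet|) and ic[L] is
    log2(|alphabet|) minus the column entropy; symbols outside the alphabet
    (gaps) are ignored in the counts.
    """
    if len(strings) < 2:
        raise InputError("need at least 2 strings")
    L = len(strings[0])
    if any(len(s) != L for s in strings):
        raise InputError("strings must have equal length")
    k = len(alphabet)
    idx = {c: i for i, c in enumerate(alphabet)}
    freq = np.zeros((L, k))
    for s in strings:
        for j, c in enumerate(s):
            if c in idx:
                freq[j, idx[c]] += 1
    totals = freq.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1
    freq = freq / totals
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freq > 0, freq * np.log2(freq), 0.0)
    ic = math.log2(k) + plogp.sum(axis=1)
    return freq, ic


def ag_rich_leader(
    seq: str, min_length: int = 100, purine_fraction: float = 0.7
) -> tuple | None:
    """Longest window >= min_length with purine fraction >= threshold.

    Returns (start, end, fraction) 1-based inclusive, or None.  Intended for
    the leader region between the 5' LTR and the first gene.
    """
    n = len(seq)
    if n < min_length:
        return None
    purine = np.fromiter((c in "AG" for c in seq), dtype=int, count=n)
    cum = np.concatenate([[0], np.cumsum(purine)])
    best = None
    for length in range(n, min_length - 1, -1):
        counts = cum[length:] - cum[:-length]
        ok = np.flatnonzero(counts >= purine_fraction * length)
        if ok.size:
            s = int(ok[0])
            frac = counts[s] / length
            best = (s + 1, s + length, float(frac))
            break
    return best
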