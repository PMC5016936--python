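"""Integration dating from neutral divergence.

Three divergence measurements feed a single age: (1) 5' vs 3' LTR of the
same element, (2) each LTR vs the subgroup consensus, (3) sub-gene windows
vs the subgroup consensus.  Divergence is the Kimura 2-parameter distance
over comparable columns, excluding gap columns and (optionally) any column
inside a CpG dinucleotide of either sequence.  Age in million years is
T = D% / rate, halved for the LTR-vs-LTR method because each LTR accumulates
substitutions independently; per-element ages are averaged and flagged when
the standard deviation exceeds 20 % of the mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .align import AlignedPair, pair_from_column_strings, ref_frame_string
from .errors import InputError, InsufficientSitesError, SaturatedDivergenceError
from .reference import ReferenceModel

__all__ = [
    "K2PResult",
    "AgeEstimate",
    "k2p_distance",
    "estimate_age",
    "aggregate_ages",
    "date_element",
]

DEFAULT_RATE = 0.13  # percent per nucleotide per million years
SD_FLAG_RATIO = 0.20
MIN_SITES = 50

_PURINES = frozenset("AG")
_BASES = frozenset("ACGT")


@dataclass
class K2PResult:
    P: float  # transition fraction
    Q: float  # transversion fraction
    sites_used: int
    d: float  # substitutions per site
    excluded_cpg_columns: int = 0


@dataclass
class AgeEstimate:
    per_method: list = field(default_factory=list)  # {method, D_percent, T_my}
    mean_my: float = 0.0
    sd_my: float = 0.0
    flagged: bool = False
    rate: float = DEFAULT_RATE


def _cpg_positions(seq: str) -> set:
    """0-based positions participating in a CG dinucleotide."""
    out = set()
    idx = seq.find("CG")
    while idx != -1:
        out.add(idx)
        out.add(idx + 1)
        idx = seq.find("CG", idx + 1)
    return out


def k2p_distance(
    aln: AlignedPair, exclude_cpg: bool = True, min_sites: int = MIN_SITES
) -> K2PResult:
    """Kimura 2-parameter distance over the alignment's comparable columns.

    Columns with a gap (or N) in either sequence are excluded; with
    ``exclude_cpg``, so is any column that is part of a CG dinucleotide in
    either ungapped sequence.  d = -1/2 ln(1-2P-Q) - 1/4 ln(1-2Q).
    """
    ra, qa = aln.ref_aligned, aln.qry_aligned
    cpg_r = _cpg_positions(aln.ref_seq) if exclude_cpg else set()
    cpg_q = _cpg_positions(aln.qry_seq) if exclude_cpg else set()

    sites = transitions = transversions = cpg_excluded = 0
    r = q = 0
    for cr, cq in zip(ra, qa):
        ri, qi = r, q
        if cr != "-":
            r += 1
        if cq != "-":
            q += 1
        if cr in ("-",) or cq in ("-",) or cr not in _BASES or cq not in _BASES:
            continue
        if exclude_cpg and (ri in cpg_r or qi in cpg_q):
            cpg_excluded += 1
            continue
        sites += 1
        if cr != cq:
            if (cr in _PURINES) == (cq in _PURINES):
                transitions += 1
            else:
                transversions += 1
    if sites < min_sites:
        raise InsufficientSitesError(
            f"insufficient sites: {sites} comparable columns < {min_sites}"
        )
    P = transitions / sites
    Q = transversions / sites
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturatedDivergenceError(
            f"saturated divergence: P={P:.4f} Q={Q:.4f} outside the K2P domain"
        )
    d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return K2PResult(P, Q, sites, d, cpg_excluded)


def estimate_age(d: float, method: str, rate: float = DEFAULT_RATE) -> float:
    """T(My) = D% / rate, halved for the LTR-vs-LTR method."""
    if rate <= 0:
        raise InputError("rate must be positive")
    if d < 0:
        raise InputError("distance must be non-negative")
    D_percent = 100.0 * d
    T = D_percent / rate
    if method == "ltr_vs_ltr":
        T /= 2.0
    return T


def aggregate_ages(estimates: list) -> AgeEstimate:
    """Mean and sample SD over per-method ages; flag when sd/mean > 0.20."""
    if not estimates:
        raise InputError("no age estimates to aggregate")
    arr = np.asarray(estimates, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    flagged = mean > 0 and sd / mean > SD_FLAG_RATIO
    return AgeEstimate(mean_my=mean, sd_my=sd, flagged=flagged)


def _window_columns(cols: str, consensus: str, start: int, end: int,
                    length: int = 300) -> tuple[str, str]:
    """Central <=300-nt slice of the retained portion of a gene window."""
    mapped = [p for p in range(start, end + 1) if cols[p - 1] != "-"]
    if not mapped:
        return "", ""
    if len(mapped) > length:
        mid = len(mapped) // 2
        half = length // 2
        mapped = mapped[mid - half : mid - half + length]
    lo, hi = mapped[0], mapped[-1]
    return cols[lo - 1 : hi], consensus[lo - 1 : hi]


def date_element(
    model: ReferenceModel,
    aln: AlignedPair,
    consensus_columns: str | None = None,
    rate: float = DEFAULT_RATE,
    exclude_cpg: bool = True,
    window_length: int = 300,
) -> AgeEstimate:
    """All applicable dating methods for one projected element.

    ``consensus_columns`` is the subgroup consensus as a reference-frame
    column string (from :func:`ervkit.subgroup.consensus_columns`); it
    defaults to the reference itself when no cohort consensus is available.
    Methods whose windows lack sufficient comparable sites are skipped.
    """
    cols = ref_frame_string(model, aln)
    if consensus_columns is None:
        consensus_columns = model.sequence
    per_method = []

    def try_method(name: str, s_a: str, s_b: str, method_kind: str) -> None:
        try:
            pair = pair_from_column_strings(s_a, s_b)
            res = k2p_distance(pair, exclude_cpg=exclude_cpg)
        except (InsufficientSitesError, SaturatedDivergenceError, InputError):
            return
        T = estimate_age(res.d, method_kind, rate)
        per_method.append(
            {"method": name, "D_percent": 100.0 * res.d, "T_my": T}
        )

    l5, l3 = model.ltr5, model.ltr3
    s5 = cols[l5.start - 1 : l5.end]
    s3 = cols[l3.start - 1 : l3.end]
    try_method("ltr_vs_ltr", s5, s3, "ltr_vs_ltr")

    c5 = consensus_columns[l5.start - 1 : l5.end]
    c3 = consensus_columns[l3.start - 1 : l3.end]
    try_method("5ltr_vs_consensus", s5, c5, "ltr_vs_consensus")
    try_method("3ltr_vs_consensus", s3, c3, "ltr_vs_consensus")

    for gene, iv in model.gene_windows.items():
        wq, wc = _window_columns(cols, consensus_columns, iv.start, iv.end,
                                 window_length)
        if wq:
            try_method(f"{gene}_vs_consensus", wq, wc, "gene_vs_consensus")

    if not per_method:
        raise InsufficientSitesError("no dating method applicable to element")
    summary = aggregate_ages([m["T_my"] for m in per_method])
    summary.per_method = per_method
    summary.rate = rate
    return summary
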