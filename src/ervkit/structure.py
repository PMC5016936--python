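"""Structural annotation: retention, indels, retroposition signatures, class.

An element is called a provirus when at least one LTR shows the full-length
U3-R-U5 form; a processed pseudogene when both LTRs are truncated at the
retroposition anchors (R-U5 from the 5' anchor, U3-R to the 3' anchor) and
at least one L1 hallmark (poly(A) tail, target-site duplication, TT/AAAA
junction) is present; undefined otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import AlignedPair
from .element import ERVElement
from .errors import InputError
from .reference import Interval, ReferenceModel

__all__ = [
    "Signatures",
    "Indel",
    "LTRForms",
    "StructuralAnnotation",
    "compute_retention",
    "detect_retro_signatures",
    "annotate_indels",
    "ltr_forms",
    "classify_structure",
    "annotate_element",
]

THETA_DEFAULT = 0.20
ANCHOR_TOLERANCE = 25  # nt around the truncation anchors
FORM_COVERAGE = 0.50  # coverage of U3 / U5 required to call a segment present
ABSENT_COVERAGE = 0.05


@dataclass
class Signatures:
    """L1-retroposition hallmarks; None means undeterminable (no flanks)."""

    polyA: bool = False
    polyA_length: int = 0
    tsd: str | None = None
    tt_aaaa: bool | None = None
    tsd_determinable: bool = True


@dataclass
class Indel:
    ref_interval: Interval
    kind: str  # insertion | deletion
    length: int


@dataclass
class LTRForms:
    ltr5_form: str  # U3-R-U5 | R-U5 | absent | partial
    ltr3_form: str  # U3-R-U5 | U3-R | absent | partial
    ltr5_start: int | None  # first mapped LTR-frame position of the 5' LTR
    ltr3_end: int | None  # last mapped LTR-frame position of the 3' LTR


@dataclass
class StructuralAnnotation:
    retention: dict  # landmark -> (fraction, retained)
    indels: list
    signatures: Signatures
    forms: LTRForms
    label: str  # provirus | processed_pseudogene | undefined


def compute_retention(
    aln: AlignedPair, model: ReferenceModel, theta: float = THETA_DEFAULT
) -> dict:
    """Fraction of each landmark covered by query bases; retained iff >= theta.

    Ties (fraction == theta) count as retained.
    """
    rm = aln.ref_map
    out = {}
    for name, iv in model.landmarks.items():
        covered = sum(1 for p in range(iv.start, iv.end + 1) if rm[p] is not None)
        frac = covered / iv.length
        out[name] = (frac, frac >= theta)
    return out


def _longest_tolerant_run(s: str, char: str, max_other: int = 1) -> int:
    """Longest substring containing at most ``max_other`` non-``char`` symbols,
    required to start and end on ``char``."""
    best = 0
    n = len(s)
    left = 0
    others = 0
    for right in range(n):
        if s[right] != char:
            others += 1
        while others > max_other:
            if s[left] != char:
                others -= 1
            left += 1
        lo, hi = left, right
        while lo <= hi and s[lo] != char:
            lo += 1
        while hi >= lo and s[hi] != char:
            hi -= 1
        if hi >= lo:
            best = max(best, hi - lo + 1)
    return best


def detect_retro_signatures(
    element_seq: str, flank5: str = "", flank3: str = ""
) -> Signatures:
    """Scan for poly(A) tail, target-site duplication and TT/AAAA junction.

    poly(A): a run of >= 8 A's (one interruption tolerated) within the last
    30 nt of the element or the first 30 nt of the 3' flank.  TSD: longest
    exact 5-15 nt string that both ends the 5' flank and starts the 3'
    flank.  TT/AAAA: "TT" immediately 5' of the duplication and "AAAA"
    starting it.  With empty flanks, tsd and tt_aaaa are undeterminable.
    """
    sig = Signatures()
    tail_zone = element_seq[-30:] + flank3[:30]
    run = _longest_tolerant_run(tail_zone, "A")
    if run >= 8:
        sig.polyA = True
        sig.polyA_length = run

    if not flank5 or not flank3:
        sig.tsd = None
        sig.tt_aaaa = None
        sig.tsd_determinable = False
        return sig

    for k in range(min(15, len(flank5), len(flank3)), 4, -1):
        if flank5[-k:] == flank3[:k]:
            sig.tsd = flank5[-k:]
            break

    if sig.tsd is not None:
        upstream = flank5[: -len(sig.tsd)]
        sig.tt_aaaa = upstream.endswith("TT") and sig.tsd.startswith("AAAA")
    else:
        sig.tt_aaaa = flank5.endswith("TT") and (
            flank3.startswith("AAAA") or element_seq.startswith("AAAA")
        )
    return sig


def annotate_indels(aln: AlignedPair, min_len: int = 1) -> list:
    """Maximal gap runs as deletions (gap in query) and insertions (gap in
    reference, anchored to the preceding reference position)."""
    if min_len < 1:
        raise InputError("min_len must be >= 1")
    out = []
    ref_pos = 0
    run_kind = None
    run_start_ref = 0
    run_len = 0

    def flush():
        if run_kind is None or run_len < min_len:
            return
        if run_kind == "deletion":
            iv = Interval(run_start_ref, run_start_ref + run_len - 1)
        else:
            anchor = max(run_start_ref, 1)
            iv = Interval(anchor, anchor)
        out.append(Indel(iv, run_kind, run_len))

    for cr, cq in aln.columns():
        if cr != "-" and cq == "-":
            kind = "deletion"
        elif cr == "-" and cq != "-":
            kind = "insertion"
        else:
            kind = None
        if kind != run_kind:
            flush()
            run_kind = kind
            run_len = 0
            run_start_ref = ref_pos + 1 if kind == "deletion" else ref_pos
        if kind is not None:
            run_len += 1
        if cr != "-":
            ref_pos += 1
    flush()
    return out


def _coverage(rm: list, start: int, end: int) -> float:
    n = end - start + 1
    if n <= 0:
        return 0.0
    return sum(1 for p in range(start, end + 1) if rm[p] is not None) / n


def ltr_forms(aln: AlignedPair, model: ReferenceModel) -> LTRForms:
    """Classify the form of each LTR from reference-frame coverage."""
    rm = aln.ref_map
    a5 = model.pseudo_5p_anchor
    a3 = model.pseudo_3p_anchor
    l5, l3 = model.ltr5, model.ltr3

    u3_cov = _coverage(rm, l5.start, l5.start + a5 - 2)  # LTR 1..255
    ru5_cov = _coverage(rm, l5.start + a5 - 1, l5.end)  # LTR 256..780
    tot5 = _coverage(rm, l5.start, l5.end)
    u3r_cov = _coverage(rm, l3.start, l3.start + a3 - 1)  # LTR 1..326
    u5_cov = _coverage(rm, l3.start + a3, l3.end)  # LTR 327..780
    tot3 = _coverage(rm, l3.start, l3.end)

    if tot5 < ABSENT_COVERAGE:
        f5 = "absent"
    elif u3_cov >= FORM_COVERAGE and ru5_cov >= FORM_COVERAGE:
        f5 = "U3-R-U5"
    elif u3_cov < FORM_COVERAGE and ru5_cov >= FORM_COVERAGE:
        f5 = "R-U5"
    else:
        f5 = "partial"

    if tot3 < ABSENT_COVERAGE:
        f3 = "absent"
    elif u3r_cov >= FORM_COVERAGE and u5_cov >= FORM_COVERAGE:
        f3 = "U3-R-U5"
    elif u5_cov < FORM_COVERAGE and u3r_cov >= FORM_COVERAGE:
        f3 = "U3-R"
    else:
        f3 = "partial"

    # Truncation points as coverage changepoints: stray matches (e.g. a
    # poly(A) tail forced into the reference by global alignment) must not
    # drag the estimate across the LTR.
    mapped5 = [rm[p] is not None for p in range(l5.start, l5.end + 1)]
    mapped3 = [rm[p] is not None for p in range(l3.start, l3.end + 1)]
    ltr5_start = _changepoint_start(mapped5) if tot5 >= ABSENT_COVERAGE else None
    ltr3_end = _changepoint_end(mapped3) if tot3 >= ABSENT_COVERAGE else None
    return LTRForms(f5, f3, ltr5_start, ltr3_end)


def _changepoint_start(mapped: list) -> int:
    """1-based position p maximizing unmapped-before-p plus mapped-from-p."""
    n = len(mapped)
    total_mapped = sum(mapped)
    best_p, best_score = 1, total_mapped
    unmapped_before = mapped_from = 0
    for p in range(2, n + 1):
        unmapped_before += 0 if mapped[p - 2] else 1
        mapped_from += 1 if mapped[p - 2] else 0
        score = unmapped_before + (total_mapped - mapped_from)
        if score > best_score:
            best_p, best_score = p, score
    return best_p


def _changepoint_end(mapped: list) -> int:
    """1-based position p maximizing mapped-through-p plus unmapped-after-p."""
    n = len(mapped)
    total_unmapped = n - sum(mapped)
    best_p, best_score = n, sum(mapped)
    mapped_through = sum(mapped)
    unmapped_after = 0
    for p in range(n - 1, 0, -1):
        mapped_through -= 1 if mapped[p] else 0
        unmapped_after += 0 if mapped[p] else 1
        score = mapped_through + unmapped_after
        if score > best_score:
            best_p, best_score = p, score
    return best_p


def classify_structure(
    forms: LTRForms,
    signatures: Signatures,
    model: ReferenceModel,
    strict_signatures: bool = False,
) -> str:
    """Provirus / processed pseudogene / undefined decision rule.

    With ``strict_signatures`` the TSD is required for a pseudogene call
    whenever flanks were available; by default any one hallmark suffices.
    """
    if forms.ltr5_form == "U3-R-U5" or forms.ltr3_form == "U3-R-U5":
        return "provirus"

    pseudo_forms = forms.ltr5_form in ("R-U5", "absent") and forms.ltr3_form in (
        "U3-R",
        "absent",
    )
    any_ltr = not (forms.ltr5_form == "absent" and forms.ltr3_form == "absent")
    anchors_ok = True
    if forms.ltr5_form == "R-U5":
        anchors_ok &= (
            forms.ltr5_start is not None
            and abs(forms.ltr5_start - model.pseudo_5p_anchor) <= ANCHOR_TOLERANCE
        )
    if forms.ltr3_form == "U3-R":
        anchors_ok &= (
            forms.ltr3_end is not None
            and abs(forms.ltr3_end - model.pseudo_3p_anchor) <= ANCHOR_TOLERANCE
        )
    if strict_signatures:
        evidence = bool(signatures.tsd) or not signatures.tsd_determinable
    else:
        evidence = bool(
            signatures.polyA or signatures.tsd or signatures.tt_aaaa
        )
    if pseudo_forms and any_ltr and anchors_ok and evidence:
        return "processed_pseudogene"
    return "undefined"


def annotate_element(
    model: ReferenceModel,
    element: ERVElement,
    aln: AlignedPair,
    theta: float = THETA_DEFAULT,
    min_indel_len: int = 1,
    strict_signatures: bool = False,
) -> StructuralAnnotation:
    """Full structural annotation of one projected element."""
    retention = compute_retention(aln, model, theta)
    signatures = detect_retro_signatures(element.sequence, element.flank5, element.flank3)
    indels = annotate_indels(aln, min_indel_len)
    forms = ltr_forms(aln, model)
    label = classify_structure(forms, signatures, model, strict_signatures)
    return StructuralAnnotation(retention, indels, signatures, forms, label)
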