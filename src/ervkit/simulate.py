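"""Synthetic element generator with known ground truth.

Inverts the group's descriptive structure into a simulator: proviral
insertions (full U3-R-U5 LTRs, short target-site duplication), L1-processed
pseudogenes (5' LTR truncated to R-U5 at the 5' anchor, 3' LTR truncated to
U3-R at the 3' anchor, poly(A) tail, TT/AAAA junction, 5-15 bp TSD), solo
LTRs, subgroup key mutations installed in both LTRs, age-proportional
neutral substitution at a configurable rate (default 0.13 %/nt/My), and
explicit deletions.  Everything is bit-reproducible from the seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .element import ERVElement
from .errors import InputError
from .reference import ReferenceModel
from .subgroup import load_key_positions

__all__ = [
    "SimulationSpec",
    "SimulatedElement",
    "mutate_sequence",
    "simulate_element",
    "simulate_cohort",
    "simulate_recombinant_transcript",
]

DEFAULT_RATE = 0.13  # percent substitutions per nucleotide per million years

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}


@dataclass
class SimulationSpec:
    """Ground-truth recipe for one simulated element."""

    class_label: str = "provirus"  # provirus | processed_pseudogene | solo_ltr
    subgroup: str = "1"  # 1 | 2 | 2A | 2B
    age_my: float = 0.0
    rate: float = DEFAULT_RATE
    kappa: float = 2.0
    deletions: list = field(default_factory=list)  # list of reference Intervals
    tsd_length: int = 8
    polyA_length: int = 12
    flank_length: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_label not in ("provirus", "processed_pseudogene", "solo_ltr"):
            raise InputError(f"unknown class_label {self.class_label!r}")
        if self.subgroup not in ("1", "2", "2A", "2B"):
            raise InputError(f"unknown subgroup {self.subgroup!r}")
        if self.age_my < 0 or self.rate <= 0 or self.kappa < 0:
            raise InputError("age_my must be >= 0, rate > 0, kappa >= 0")
        if not 5 <= self.tsd_length <= 15:
            raise InputError("tsd_length must be in [5, 15]")
        if self.class_label == "processed_pseudogene" and self.polyA_length < 8:
            raise InputError("polyA_length must be >= 8")

    @property
    def expected_divergence(self) -> float:
        """Per-branch expected substitution fraction."""
        return self.rate * self.age_my / 100.0


@dataclass
class SimulatedElement:
    element: ERVElement
    spec: SimulationSpec
    realized_mutations: int
    realized_ltr_divergence: float | None
    tsd: str


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def mutate_sequence(seq: str, expected_divergence: float, kappa: float = 2.0,
                    seed=0) -> str:
    """Substitute each site independently with the given probability.

    Conditional on substitution, a transition is chosen with probability
    kappa / (kappa + 2), otherwise one of the two transversions uniformly.
    Length-preserving and deterministic for a fixed seed.
    """
    if not 0 <= expected_divergence < 0.75:
        raise InputError("expected_divergence must be in [0, 0.75)")
    if expected_divergence == 0 or not seq:
        return seq
    rng = _as_rng(seed)
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = rng.random(len(arr)) < expected_divergence
    ts = rng.random(len(arr)) < kappa / (kappa + 2.0)
    tv_pick = rng.integers(0, 2, size=len(arr))
    out = list(seq)
    for i in np.flatnonzero(hit):
        base = out[i]
        if base not in _TRANSITION:  # leave N untouched
            continue
        out[i] = _TRANSITION[base] if ts[i] else _TRANSVERSIONS[base][tv_pick[i]]
    return "".join(out)


def _rand_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def _install_variants(model: ReferenceModel, subgroup: str) -> str:
    """Reference copy with the subgroup key variants installed in both LTRs."""
    table = load_key_positions()
    tiers = {"1": (), "2": ("main",), "2A": ("main", "2A"), "2B": ("main", "2B")}
    seq = list(model.sequence)
    for entry in table.entries:
        if entry.tier not in tiers[subgroup]:
            continue
        for which in ("5ltr", "3ltr"):
            p = model.ltr_frame_to_reference(entry.ltr_position, which)
            seq[p - 1] = entry.alt_base
    return "".join(seq)


def simulate_element(model: ReferenceModel, spec: SimulationSpec) -> SimulatedElement:
    """Generate one element with fully recorded ground truth."""
    ss = np.random.SeedSequence(spec.seed)
    rng_body, rng_l5, rng_l3, rng_pa, rng_fl = (
        np.random.default_rng(c) for c in ss.spawn(5)
    )
    div = spec.expected_divergence
    if div >= 0.75:
        raise InputError("age/rate imply divergence beyond model validity")

    base = _install_variants(model, spec.subgroup)
    l5 = base[model.ltr5.start - 1 : model.ltr5.end]
    l3 = base[model.ltr3.start - 1 : model.ltr3.end]
    internal = base[model.ltr5.end : model.ltr3.start - 1]

    m_l5 = mutate_sequence(l5, div, spec.kappa, rng_l5)
    m_l3 = mutate_sequence(l3, div, spec.kappa, rng_l3)
    m_internal = mutate_sequence(internal, div, spec.kappa, rng_body)
    full = m_l5 + m_internal + m_l3
    realized_mut = sum(a != b for a, b in zip(full, base))
    realized_ltr_div = sum(a != b for a, b in zip(m_l5, m_l3)) / len(l5)

    keep = np.ones(model.length + 1, dtype=bool)  # 1-based mask
    keep[0] = False
    for iv in spec.deletions:
        keep[iv.start : iv.end + 1] = False

    if spec.class_label == "provirus":
        diag5 = keep[1 : model.pseudo_5p_anchor]  # U3 of the 5' LTR
        u5_start = model.ltr3.start + model.pseudo_3p_anchor
        diag3 = keep[u5_start : model.ltr3.end + 1]  # U5 of the 3' LTR
        if not diag5.any() and not diag3.any():
            warnings.warn("deletions remove both LTR diagnostic regions; "
                          "element will be unclassifiable")
    elif spec.class_label == "processed_pseudogene":
        keep[1 : model.pseudo_5p_anchor] = False
        keep[model.ltr3.start + model.pseudo_3p_anchor :] = False
    elif spec.class_label == "solo_ltr":
        keep[model.ltr5.end + 1 :] = False

    seq = "".join(c for p, c in enumerate(full, start=1) if keep[p])
    realized_ltr = realized_ltr_div if spec.class_label != "solo_ltr" else None

    if spec.class_label == "processed_pseudogene":
        seq += mutate_sequence("A" * spec.polyA_length, div, spec.kappa, rng_pa)
        tsd = "AAAA" + _rand_dna(rng_fl, spec.tsd_length - 4)
        flank5 = _rand_dna(rng_fl, spec.flank_length) + "TT" + tsd
        flank3 = tsd + _rand_dna(rng_fl, spec.flank_length)
    else:
        tsd = _rand_dna(rng_fl, spec.tsd_length)
        flank5 = _rand_dna(rng_fl, spec.flank_length) + tsd
        flank3 = tsd + _rand_dna(rng_fl, spec.flank_length)

    element = ERVElement(
        id=f"sim_{spec.class_label}_{spec.subgroup}_{spec.seed}",
        sequence=seq,
        flank5=flank5,
        flank3=flank3,
    )
    return SimulatedElement(element, spec, realized_mut, realized_ltr, tsd)


def simulate_cohort(model: ReferenceModel, specs: list[SimulationSpec]) -> list[SimulatedElement]:
    return [simulate_element(model, s) for s in specs]


def truth_table(sims: list[SimulatedElement]):
    """Ground-truth table (pandas DataFrame) for a simulated cohort."""
    import pandas as pd

    rows = []
    for s in sims:
        rows.append({
            "id": s.element.id,
            "class": s.spec.class_label,
            "subgroup": s.spec.subgroup,
            "age_my": s.spec.age_my,
            "seed": s.spec.seed,
            "tsd": s.tsd,
            "deletions": ";".join(f"{iv.start}-{iv.end}" for iv in s.spec.deletions),
            "realized_mutations": s.realized_mutations,
            "realized_ltr_divergence": s.realized_ltr_divergence,
        })
    return pd.DataFrame(rows)


def simulate_recombinant_transcript(locusA: str, locusB: str,
                                    breakpoints: list[int], seed: int = 0) -> str:
    """Chimeric transcript alternating A/B segments at the breakpoints.

    ``locusA`` and ``locusB`` must be pre-aligned to a common reference frame
    (equal-length strings, '-' for absent positions); breakpoints are
    strictly increasing 1-based frame positions.  The segment before the
    first breakpoint comes from A.  Gap characters are stripped from the
    output.
    """
    if len(locusA) != len(locusB):
        raise InputError("loci must share a common aligned frame")
    n = len(locusA)
    prev = 0
    for b in breakpoints:
        if not 1 <= b <= n:
            raise InputError(f"breakpoint {b} outside shared aligned span 1..{n}")
        if b <= prev:
            raise InputError("breakpoints must be strictly increasing")
        prev = b
    pieces = []
    cuts = [0] + [b - 1 for b in breakpoints] + [n]
    for i in range(len(cuts) - 1):
        src = locusA if i % 2 == 0 else locusB
        pieces.append(src[cuts[i] : cuts[i + 1]])
    return "".join(pieces).replace("-", "")
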