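"""Key-position genotyping, subgroup classification and consensus building.

Subgroup membership is decided from diagnostic single-nucleotide positions
in the LTR frame: seven "main" positions separate subgroup 2 from subgroup 1
(alt alleles present in 95-100 % of subgroup-2 members and 0-3.5 % of
subgroup-1 members), with additional position tiers refining subgroup 2
into types 2A and 2B.  Classification pools the observable positions of
both LTRs and uses an explicit abstention band instead of guessing.
"""

from __future__ import annotations

import csv
import importlib.resources
from dataclasses import dataclass, field
from functools import lru_cache

from .align import AlignedPair, slice_alignment
from .errors import ConfigurationError, InputError
from .reference import ReferenceModel

__all__ = [
    "KeyPosition",
    "KeyPositionTable",
    "load_key_positions",
    "GenotypeSet",
    "SubgroupCall",
    "genotype_key_positions",
    "classify_subgroup",
    "build_consensus",
    "consensus_columns",
    "ltr_frame_alignment",
]

LTR_KINDS = ("5p_full", "3p_full", "5p_RU5", "3p_U3R", "solo")


@dataclass(frozen=True)
class KeyPosition:
    ltr_position: int
    ref_base: str
    alt_base: str
    tier: str  # main | 2A | 2B


@dataclass
class KeyPositionTable:
    entries: list[KeyPosition]

    def tier(self, name: str) -> list[KeyPosition]:
        return [e for e in self.entries if e.tier == name]

    @classmethod
    def from_tsv(cls, path) -> "KeyPositionTable":
        entries = []
        with open(path) as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                try:
                    entries.append(
                        KeyPosition(
                            int(row["ltr_position"]),
                            row["ref_base"].upper(),
                            row["alt_base"].upper(),
                            row["tier"],
                        )
                    )
                except (KeyError, ValueError) as exc:
                    raise ConfigurationError(f"malformed key-position row {row!r}") from exc
        if not entries:
            raise ConfigurationError("empty key-position table")
        return cls(entries)


@lru_cache(maxsize=1)
def load_key_positions() -> KeyPositionTable:
    """The packaged canonical key-position table."""
    path = importlib.resources.files("ervkit") / "data" / "key_positions.tsv"
    return KeyPositionTable.from_tsv(path)


@dataclass
class GenotypeSet:
    """Observed bases at key positions for one LTR copy.

    ``calls[pos]`` is the observed base, '-' when the position is deleted
    in the aligned LTR, or None when it lies outside the truncated form.
    """

    ltr_kind: str
    calls: dict = field(default_factory=dict)


@dataclass
class SubgroupCall:
    genotypes: list  # GenotypeSet per LTR used
    n_available: int
    n_alt: int
    label: str  # 1 | 2 | 2A | 2B | unclassifiable


def genotype_key_positions(
    aln: AlignedPair,
    table: KeyPositionTable | None = None,
    ltr_kind: str = "5p_full",
    pseudo_5p_anchor: int = 256,
    pseudo_3p_anchor: int = 326,
) -> GenotypeSet:
    """Read the key positions from an LTR aligned against the LTR frame.

    ``aln`` must have the full-length LTR consensus as its reference.  The
    truncated pseudogenic forms restrict which positions are observable:
    R-U5 observes only positions >= the 5' anchor, U3-R only positions <=
    the 3' anchor.
    """
    if table is None:
        table = load_key_positions()
    if ltr_kind not in LTR_KINDS:
        raise InputError(f"unknown ltr_kind {ltr_kind!r}")
    gset = GenotypeSet(ltr_kind=ltr_kind)
    n_ref = len(aln.ref_seq)
    for entry in table.entries:
        pos = entry.ltr_position
        if ltr_kind == "5p_RU5" and pos < pseudo_5p_anchor:
            gset.calls[pos] = None
            continue
        if ltr_kind == "3p_U3R" and pos > pseudo_3p_anchor:
            gset.calls[pos] = None
            continue
        if pos > n_ref:
            gset.calls[pos] = None
            continue
        base = aln.query_base_at(pos)
        gset.calls[pos] = "-" if base is None else base
    return gset


def _pooled_counts(gsets: list, entries: list) -> tuple[int, int]:
    n_av = n_alt = 0
    for entry in entries:
        for gset in gsets:
            obs = gset.calls.get(entry.ltr_position)
            if obs in (None, "-", "N"):
                continue
            n_av += 1
            if obs == entry.alt_base:
                n_alt += 1
    return n_av, n_alt


def _tier_position_status(gsets: list, entries: list) -> tuple[int, int]:
    """(observable positions, positions carrying alt in at least one LTR)."""
    n_obs = n_alt = 0
    for entry in entries:
        obs = [g.calls.get(entry.ltr_position) for g in gsets]
        bases = [o for o in obs if o not in (None, "-", "N")]
        if not bases:
            continue
        n_obs += 1
        if entry.alt_base in bases:
            n_alt += 1
    return n_obs, n_alt


def classify_subgroup(
    call_5p: GenotypeSet | None,
    call_3p: GenotypeSet | None,
    table: KeyPositionTable | None = None,
    lower: float = 0.4,
    upper: float = 0.6,
    min_available: int = 3,
) -> SubgroupCall:
    """Label an element 1 / 2 / 2A / 2B from its LTR genotypes.

    Pools the observable main-tier positions of both LTRs; the alt-allele
    fraction decides the subgroup with an abstention band in
    (``lower``, ``upper``).  Subgroup 2 is refined to 2A (both 2A positions
    alt) or 2B (>= 2 of 3 2B positions alt) only when the competing tier
    does not also qualify.
    """
    if table is None:
        table = load_key_positions()
    gsets = [g for g in (call_5p, call_3p) if g is not None]
    if not gsets:
        raise InputError("at least one LTR genotype is required")
    n_av, n_alt = _pooled_counts(gsets, table.tier("main"))
    if n_av < min_available:
        return SubgroupCall(gsets, n_av, n_alt, "unclassifiable")
    ratio = n_alt / n_av
    if ratio >= upper:
        label = "2"
    elif ratio <= lower:
        label = "1"
    else:
        return SubgroupCall(gsets, n_av, n_alt, "unclassifiable")
    if label == "2":
        obs_a, alt_a = _tier_position_status(gsets, table.tier("2A"))
        obs_b, alt_b = _tier_position_status(gsets, table.tier("2B"))
        is_2a = obs_a >= 2 and alt_a == obs_a
        is_2b = obs_b >= 2 and alt_b >= 2
        if is_2a and not is_2b:
            label = "2A"
        elif is_2b and not is_2a:
            label = "2B"
    return SubgroupCall(gsets, n_av, n_alt, label)


def ltr_frame_alignment(model: ReferenceModel, pair: AlignedPair, which: str) -> AlignedPair:
    """Rebase a reference projection to the 780-nt LTR frame of one LTR."""
    iv = model.ltr5 if which == "5ltr" else model.ltr3
    return slice_alignment(pair, iv.start, iv.end)


def consensus_columns(column_strings: list, reference: str) -> str:
    """Per-column majority consensus in the reference frame.

    Each input is a gapped string over reference coordinates (one character
    per reference position).  Ties break toward the reference base; columns
    gapped in more than half of the sequences emit '-' (consensus deletion).
    """
    if len(column_strings) < 2:
        raise InputError("consensus requires at least 2 sequences")
    n = len(reference)
    for s in column_strings:
        if len(s) != n:
            raise InputError("column strings must match reference length")
    out = []
    for i in range(n):
        col = [s[i] for s in column_strings]
        bases = [c for c in col if c not in ("-", "N")]
        if len(bases) * 2 < len(col):
            out.append("-")
            continue
        counts: dict = {}
        for b in bases:
            counts[b] = counts.get(b, 0) + 1
        best = max(counts.values())
        winners = sorted(b for b, c in counts.items() if c == best)
        ref_base = reference[i]
        out.append(ref_base if ref_base in winners else winners[0])
    return "".join(out)


def build_consensus(column_strings: list, reference: str) -> str:
    """Majority-rule consensus as a plain (gapless) DNA string."""
    return consensus_columns(column_strings, reference).replace("-", "")
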