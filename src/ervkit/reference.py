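"""Reference model: the group consensus sequence plus every fixed coordinate.

All public coordinates are 1-based and inclusive on both ends, matching the
consensus numbering used throughout the annotation tables.  The canonical
model (a 10,186-nt LTR-internal-LTR consensus with 780-nt LTRs) ships with
the package as a FASTA plus a YAML landmark config and is loaded with
:func:`load_canonical`.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import yaml
from Bio import SeqIO

from .errors import ConfigurationError, InputError

__all__ = [
    "Interval",
    "ReferenceModel",
    "load_reference",
    "load_canonical",
    "landmark_slice",
]

_VALID_BASES = set("ACGTN")


@dataclass(frozen=True, order=True)
class Interval:
    """1-based inclusive interval on the reference."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ConfigurationError(f"invalid interval {self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def to_dict(self) -> dict:
        return {"start": self.start, "end": self.end}


@dataclass
class ReferenceModel:
    """Consensus sequence with named landmark intervals.

    Attributes
    ----------
    sequence:
        Uppercase DNA string of length ``length``.
    landmarks:
        Map of landmark name to :class:`Interval` (1-based inclusive).
    ltr_length:
        Length of each LTR; the 5' and 3' LTR landmarks must both have
        exactly this length.
    pseudo_5p_anchor:
        LTR-frame position where retroposed (L1-processed) copies begin:
        their 5' LTR is truncated to an R-U5 form starting here.
    pseudo_3p_anchor:
        LTR-frame position where the 3' LTR of retroposed copies ends
        (U3-R form).
    recurrent_deletions:
        Intervals recurrently deleted across the group.
    pbs_window:
        Primer-binding-site window in *internal-region* coordinates
        (position 1 = first base after the 5' LTR).
    gene_windows:
        Optional sub-gene windows used for the gene-versus-consensus
        dating method.
    """

    sequence: str
    landmarks: dict[str, Interval]
    ltr_length: int
    pseudo_5p_anchor: int
    pseudo_3p_anchor: int
    recurrent_deletions: list[Interval] = field(default_factory=list)
    pbs_window: Interval | None = None
    gene_windows: dict[str, Interval] = field(default_factory=dict)

    REQUIRED_LANDMARKS = ("5ltr", "gag", "propol", "env", "3ltr")

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ConfigurationError(f"reference contains invalid symbols: {sorted(bad)}")
        self.validate()

    # -- derived coordinates -------------------------------------------------

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def ltr5(self) -> Interval:
        return self.landmarks["5ltr"]

    @property
    def ltr3(self) -> Interval:
        return self.landmarks["3ltr"]

    @property
    def internal(self) -> Interval:
        """The internal region between the LTRs."""
        return Interval(self.ltr5.end + 1, self.ltr3.start - 1)

    def pbs_reference_window(self) -> Interval:
        """PBS window translated from internal-region to reference coordinates."""
        if self.pbs_window is None:
            raise ConfigurationError("model has no pbs_window configured")
        off = self.internal.start - 1
        return Interval(self.pbs_window.start + off, self.pbs_window.end + off)

    def ltr_frame_to_reference(self, pos: int, which: str) -> int:
        """Map an LTR-frame position (1..ltr_length) to a reference position."""
        if not 1 <= pos <= self.ltr_length:
            raise InputError(f"LTR position {pos} outside 1..{self.ltr_length}")
        base = self.ltr5.start if which == "5ltr" else self.ltr3.start
        return base + pos - 1

    # -- validation ----------------------------------------------------------

    def validate(self) -> None:
        for name in self.REQUIRED_LANDMARKS:
            if name not in self.landmarks:
                raise ConfigurationError(f"missing landmark: {name}")
        for name, iv in self.landmarks.items():
            if iv.end > self.length:
                raise ConfigurationError(
                    f"interval out of bounds: landmark {name} "
                    f"({iv.start}-{iv.end}) exceeds reference length {self.length}"
                )
        if self.ltr5.length != self.ltr_length or self.ltr3.length != self.ltr_length:
            raise ConfigurationError(
                "LTR length mismatch: 5ltr=%d 3ltr=%d expected ltr_length=%d"
                % (self.ltr5.length, self.ltr3.length, self.ltr_length)
            )
        # the R repeat is shared by both truncated forms, so the R-U5 start
        # must precede the U3-R end
        if not (1 <= self.pseudo_5p_anchor <= self.pseudo_3p_anchor <= self.ltr_length):
            raise ConfigurationError(
                "truncation anchors must satisfy 1 <= pseudo_5p_anchor <= "
                f"pseudo_3p_anchor <= ltr_length, got {self.pseudo_5p_anchor} "
                f"/ {self.pseudo_3p_anchor} / {self.ltr_length}"
            )
        for iv in self.recurrent_deletions:
            if iv.end > self.length:
                raise ConfigurationError(
                    f"interval out of bounds: recurrent deletion {iv.start}-{iv.end}"
                )
        if self.pbs_window is not None and self.pbs_window.end > self.internal.length:
            raise ConfigurationError("interval out of bounds: pbs_window")

    # -- serialization -------------------------------------------------------

    def landmarks_config(self) -> dict:
        """Round-trippable dict in the on-disk YAML layout."""
        return {
            "ltr_length": self.ltr_length,
            "pseudo_5p_anchor": self.pseudo_5p_anchor,
            "pseudo_3p_anchor": self.pseudo_3p_anchor,
            "landmarks": {
                name: {"name": name, **iv.to_dict()}
                for name, iv in self.landmarks.items()
            },
            "recurrent_deletions": [iv.to_dict() for iv in self.recurrent_deletions],
            "pbs_window": self.pbs_window.to_dict() if self.pbs_window else None,
            "gene_windows": {
                name: {"name": name, **iv.to_dict()}
                for name, iv in self.gene_windows.items()
            },
        }


def _interval_from_config(obj: dict, what: str) -> Interval:
    try:
        return Interval(int(obj["start"]), int(obj["end"]))
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigurationError(f"malformed interval for {what}: {obj!r}") from exc


def model_from_config(sequence: str, config: dict) -> ReferenceModel:
    """Build and validate a :class:`ReferenceModel` from a parsed config dict."""
    try:
        ltr_length = int(config["ltr_length"])
        p5 = int(config["pseudo_5p_anchor"])
        p3 = int(config["pseudo_3p_anchor"])
        raw_landmarks = config["landmarks"]
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigurationError(f"landmark config missing field: {exc}") from exc
    landmarks = {
        name: _interval_from_config(iv, f"landmark {name}")
        for name, iv in raw_landmarks.items()
    }
    dels = [
        _interval_from_config(iv, "recurrent deletion")
        for iv in config.get("recurrent_deletions", [])
    ]
    pbs = config.get("pbs_window")
    gene_windows = {
        name: _interval_from_config(iv, f"gene window {name}")
        for name, iv in (config.get("gene_windows") or {}).items()
    }
    return ReferenceModel(
        sequence=sequence,
        landmarks=landmarks,
        ltr_length=ltr_length,
        pseudo_5p_anchor=p5,
        pseudo_3p_anchor=p3,
        recurrent_deletions=dels,
        pbs_window=_interval_from_config(pbs, "pbs_window") if pbs else None,
        gene_windows=gene_windows,
    )


def load_reference(consensus_fasta, landmarks_config) -> ReferenceModel:
    """Load a reference model from a single-record FASTA and a YAML config.

    Raises :class:`ConfigurationError` naming the offending field on any
    invariant violation (missing landmark, out-of-bounds interval, LTR
    length mismatch) and :class:`InputError` for a multi-record FASTA.
    """
    records = list(SeqIO.parse(str(consensus_fasta), "fasta"))
    if len(records) != 1:
        raise InputError(f"single record required, found {len(records)}")
    with open(landmarks_config) as fh:
        config = yaml.safe_load(fh)
    return model_from_config(str(records[0].seq).upper(), config)


def load_canonical() -> ReferenceModel:
    """Load the packaged canonical reference model."""
    root = importlib.resources.files("ervkit") / "data"
    return load_reference(root / "reference.fasta", root / "landmarks.yaml")


def landmark_slice(model: ReferenceModel, name: str) -> str:
    """Return the reference subsequence at a named landmark."""
    try:
        iv = model.landmarks[name]
    except KeyError:
        raise KeyError(f"unknown landmark: {name!r}") from None
    return model.sequence[iv.start - 1 : iv.end]
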