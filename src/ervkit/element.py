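"""Candidate ERV element records and their FASTA round trip.

Flanking genomic sequence is carried in the FASTA description line as
``flank5=<seq> flank3=<seq>`` so that a cohort remains a single plain-text
file; absent flanks are simply omitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass
class ERVElement:
    """One candidate locus: element sequence plus optional genomic flanks."""

    id: str
    sequence: str
    flank5: str = ""
    flank3: str = ""
    strand: str = "+"
    chrom: str | None = None
    start: int | None = None
    end: int | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        self.flank5 = self.flank5.upper()
        self.flank3 = self.flank3.upper()

    @property
    def with_flanks(self) -> str:
        return self.flank5 + self.sequence + self.flank3


def _to_record(el: ERVElement) -> SeqRecord:
    desc = []
    if el.flank5:
        desc.append(f"flank5={el.flank5}")
    if el.flank3:
        desc.append(f"flank3={el.flank3}")
    if el.strand != "+":
        desc.append(f"strand={el.strand}")
    return SeqRecord(Seq(el.sequence), id=el.id, description=" ".join(desc))


def write_elements(path, elements: list[ERVElement]) -> None:
    SeqIO.write([_to_record(e) for e in elements], str(path), "fasta")


def read_elements(path) -> list[ERVElement]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        kv = {}
        for token in rec.description.split()[1:]:
            if "=" in token:
                k, v = token.split("=", 1)
                kv[k] = v
        out.append(
            ERVElement(
                id=rec.id,
                sequence=str(rec.seq),
                flank5=kv.get("flank5", ""),
                flank3=kv.get("flank3", ""),
                strand=kv.get("strand", "+"),
            )
        )
    return out
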