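"""Genomic-context annotation: locus vs gene/exon interval intersection.

Interval arithmetic is 0-based half-open internally (BED convention) and
converted at the 1-based inclusive public boundary.  Only local annotation
files are consulted; there is no network access.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .errors import InputError

__all__ = ["GeneFeature", "ContextCall", "annotate_context", "read_gff3", "read_bed"]


@dataclass
class GeneFeature:
    """A gene with optional exon structure (1-based inclusive coordinates)."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    exons: list = field(default_factory=list)  # [(start, end)] 1-based inclusive


@dataclass
class ContextCall:
    locus_id: str
    relation: str  # intergenic | intronic | exonic | mixed
    gene_id: str | None = None
    orientation: str = "n/a"  # sense | antisense | n/a
    overlapped_features: list = field(default_factory=list)


def _half_open(start_1: int, end_1: int) -> tuple:
    return start_1 - 1, end_1


def _overlap(a: tuple, b: tuple) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def annotate_context(loci: list, features: list) -> list:
    """Classify each locus against gene/exon intervals.

    ``loci`` is a list of dicts with keys id, chrom, start, end, strand
    (1-based inclusive).  Relation is exonic when every overlapped gene base
    lies in exons, intronic when none does, mixed otherwise; the gene with
    the largest overlap wins.  Orientation is sense iff locus and gene
    strands agree.
    """
    by_chrom: dict = {}
    for g in features:
        by_chrom.setdefault(g.chrom, []).append(g)
    known_chroms = set(by_chrom)
    out = []
    for locus in loci:
        lid = locus["id"]
        chrom = locus["chrom"]
        interval = _half_open(locus["start"], locus["end"])
        if chrom not in known_chroms:
            warnings.warn(f"chromosome {chrom!r} absent from feature set")
            out.append(ContextCall(lid, "intergenic"))
            continue
        best = None  # (overlap, gene)
        for g in by_chrom[chrom]:
            ov = _overlap(interval, _half_open(g.start, g.end))
            if ov and (best is None or ov > best[0]):
                best = (ov, g)
        if best is None:
            out.append(ContextCall(lid, "intergenic"))
            continue
        ov_total, gene = best
        exon_ov = sum(
            _overlap(interval, _half_open(s, e)) for s, e in gene.exons
        )
        if not gene.exons:
            relation = "exonic"  # featureless gene body treated as exonic span
        elif exon_ov == 0:
            relation = "intronic"
        elif exon_ov >= ov_total:
            relation = "exonic"
        else:
            relation = "mixed"
        orientation = "sense" if locus.get("strand", "+") == gene.strand else "antisense"
        overlapped = [
            {"feature_kind": "exon", "interval": (s, e)}
            for s, e in gene.exons
            if _overlap(interval, _half_open(s, e))
        ]
        out.append(ContextCall(lid, relation, gene.gene_id, orientation, overlapped))
    return out


def read_gff3(path) -> list:
    """Minimal GFF3 reader collecting gene and exon features."""
    genes: dict = {}
    exons: list = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise InputError(f"malformed GFF3 line: {line!r}")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = parts[:9]
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype == "gene":
                gid = attr.get("ID") or attr.get("gene_id") or f"gene_{len(genes)}"
                genes[gid] = GeneFeature(gid, chrom, int(start), int(end), strand)
            elif ftype == "exon":
                parent = attr.get("Parent") or attr.get("gene_id")
                exons.append((parent, chrom, int(start), int(end)))
    for parent, chrom, s, e in exons:
        target = None
        if parent in genes:
            target = genes[parent]
        else:
            for g in genes.values():
                if g.chrom == chrom and g.start <= s and e <= g.end:
                    target = g
                    break
        if target is not None:
            target.exons.append((s, e))
    for g in genes.values():
        g.exons.sort()
    return list(genes.values())


def read_bed(path) -> list:
    """BED (0-based half-open) gene intervals, converted to 1-based inclusive."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise InputError(f"malformed BED line: {line!r}")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else f"feature_{i}"
            strand = parts[5] if len(parts) > 5 else "+"
            out.append(GeneFeature(name, chrom, start + 1, end, strand))
    return out
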