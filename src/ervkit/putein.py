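"""Envelope putative-protein ("putein") reconstruction and domain checks.

Damaged env genes are translated in all three frames and stitched into a
single protein by a dynamic program that aligns the nucleotide sequence
directly against the envelope reference protein: codon moves consume 3 nt
and one reference residue, 1- or 2-nt moves change reading frame at a
penalty calibrated so a frame switch must be supported by roughly ten
residues of improved identity.  Stop codons are rendered '*'; stops within
the final 5 % of the aligned reference span count as terminal, not internal.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable

from .errors import InputError

__all__ = [
    "Putein",
    "reconstruct_putein",
    "annotate_env_domains",
    "load_env_reference",
    "load_env_cds",
]

MATCH = 2.0
MISMATCH = -1.0
STOP_SCORE = -3.0
INSERTION = -4.0  # whole-codon insertion relative to the reference
DELETION = -3.0  # reference residue with no codon
FRAMESHIFT = -12.0
MIN_IDENTITY = 0.30
TERMINAL_FRACTION = 0.05

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
_CODON_AA = dict(_STANDARD.forward_table)
for stop in _STANDARD.stop_codons:
    _CODON_AA[stop] = "*"


def _translate_codon(codon: str) -> str:
    return _CODON_AA.get(codon, "X")


@dataclass
class Putein:
    """Reconstructed protein with frame and stop annotation."""

    sequence: str  # '*' for stops
    frame_segments: list  # {"nt_interval": (s, e), "frame": 0|1|2}
    n_internal_stops: int
    n_frameshifts: int
    length_aa: int  # residues excluding stops
    identity: float  # vs the reference over codon-aligned positions
    aligned_span: tuple  # (first, last) aligned reference residue (1-based)
    ref_map: dict = field(default_factory=dict)  # ref residue -> putein index
    insertions: list = field(default_factory=list)  # (after_ref_residue, aa)
    stop_positions: list = field(default_factory=list)  # putein indices of '*'


def reconstruct_putein(env_nt: str, reference_protein: str) -> Putein:
    """Stitch a single putein from all three frames of a damaged env gene.

    Raises :class:`InputError` when no frame aligns with identity >= 0.3
    ("not Env-homologous") or the input is shorter than 150 nt.
    """
    env_nt = env_nt.upper().replace("U", "T")
    if len(env_nt) < 150:
        raise InputError(f"env sequence too short ({len(env_nt)} nt < 150)")
    if not reference_protein:
        raise InputError("empty reference protein")
    ref = reference_protein.upper()
    N, M = len(env_nt), len(ref)
    ref_arr = np.frombuffer(ref.encode(), dtype="S1")

    aa_at = [""] * (N + 1)  # aa of codon ending at nt position i (1-based)
    for i in range(3, N + 1):
        aa_at[i] = _translate_codon(env_nt[i - 3 : i])

    NEG = -1e12
    S = np.full((N + 1, M + 1), NEG)
    S[0, :] = 0.0  # free leading reference deletions
    S[:, 0] = 0.0  # free leading query skips (frame selection)
    jarange = np.arange(M + 1, dtype=float)

    icost = np.full(M + 1, INSERTION)
    icost[M] = 0.0  # free trailing query codons
    fcost = np.full(M + 1, FRAMESHIFT)
    fcost[M] = 0.0

    for i in range(1, N + 1):
        base = np.full(M + 1, NEG)
        if i >= 3:
            aa = aa_at[i]
            sm = np.where(ref_arr == aa.encode(), MATCH, MISMATCH)
            if aa == "*":
                sm = np.full(M, STOP_SCORE)
            base[1:] = S[i - 3, :M] + sm  # codon match/mismatch
            np.maximum(base, S[i - 3] + icost, out=base)  # codon insertion
        fs = np.maximum(S[i - 1], S[i - 2] if i >= 2 else NEG)
        np.maximum(base, fs + fcost, out=base)  # frameshift
        base[0] = 0.0
        dc = 0.0 if i == N else -DELETION
        if dc == 0.0:
            S[i] = np.maximum.accumulate(base)
        else:
            # m[j] = max(base[j], m[j-1] - dc) via the affine-scan identity
            S[i] = np.maximum.accumulate(base + dc * jarange) - dc * jarange

    # traceback (deterministic move priority: codon > insertion > deletion > shift)
    moves = []
    i, j = N, M
    while i > 0 or j > 0:
        s = S[i, j]
        dcost = 0.0 if i in (0, N) else DELETION
        if i >= 3 and j >= 1:
            aa = aa_at[i]
            ms = STOP_SCORE if aa == "*" else (MATCH if aa == ref[j - 1] else MISMATCH)
            if s == S[i - 3, j - 1] + ms:
                moves.append(("M", i, j))
                i, j = i - 3, j - 1
                continue
        if i >= 3 and s == S[i - 3, j] + (0.0 if j in (0, M) else INSERTION):
            moves.append(("I", i, j))
            i -= 3
            continue
        if j >= 1 and s == S[i, j - 1] + dcost:
            moves.append(("D", i, j))
            j -= 1
            continue
        if i >= 1 and s == S[i - 1, j] + (0.0 if j in (0, M) else FRAMESHIFT):
            moves.append(("F1", i, j))
            i -= 1
            continue
        if i >= 2 and s == S[i - 2, j] + (0.0 if j in (0, M) else FRAMESHIFT):
            moves.append(("F2", i, j))
            i -= 2
            continue
        raise AssertionError("traceback failed")  # pragma: no cover
    moves.reverse()

    m_moves = [(i, j) for kind, i, j in moves if kind == "M"]
    if not m_moves:
        raise InputError("not Env-homologous: no codon aligns to the reference")
    jmin, jmax = m_moves[0][1], m_moves[-1][1]
    matches = sum(1 for i, j in m_moves if aa_at[i] == ref[j - 1])
    identity = matches / len(m_moves)
    if identity < MIN_IDENTITY:
        raise InputError(
            f"not Env-homologous: identity {identity:.2f} below {MIN_IDENTITY}"
        )

    seq_chars: list = []
    ref_map: dict = {}
    insertions: list = []
    segments: list = []
    stop_positions: list = []
    n_shifts = 0
    cur_ins: list | None = None
    first_m = moves.index(("M", *m_moves[0]))
    last_m = len(moves) - 1 - moves[::-1].index(("M", *m_moves[-1]))
    terminal_cut = jmin + (1.0 - TERMINAL_FRACTION) * (jmax - jmin)
    n_internal_stops = 0

    for k, (kind, i, j) in enumerate(moves):
        inside = first_m <= k <= last_m
        if kind in ("F1", "F2") and inside:
            n_shifts += 1
        if kind == "M":
            aa = aa_at[i]
            seq_chars.append(aa)
            idx = len(seq_chars)
            ref_map[j] = idx
            if aa == "*":
                stop_positions.append(idx)
                if j <= terminal_cut:
                    n_internal_stops += 1
            frame = (i - 3) % 3
            if segments and segments[-1]["frame"] == frame and not segments[-1]["closed"]:
                segments[-1]["nt_interval"] = (segments[-1]["nt_interval"][0], i)
            else:
                for s in segments:
                    s["closed"] = True
                segments.append({"nt_interval": (i - 2, i), "frame": frame,
                                 "closed": False})
            cur_ins = None
        elif kind == "I" and inside:
            aa = aa_at[i]
            seq_chars.append(aa)
            idx = len(seq_chars)
            if aa == "*":
                stop_positions.append(idx)
                if j <= terminal_cut:
                    n_internal_stops += 1
            if cur_ins is None:
                cur_ins = [j, ""]
                insertions.append(cur_ins)
            cur_ins[1] += aa
        else:
            cur_ins = None

    for s in segments:
        s.pop("closed", None)
    sequence = "".join(seq_chars)
    return Putein(
        sequence=sequence,
        frame_segments=segments,
        n_internal_stops=n_internal_stops,
        n_frameshifts=n_shifts,
        length_aa=sum(1 for c in sequence if c != "*"),
        identity=identity,
        aligned_span=(jmin, jmax),
        ref_map=ref_map,
        insertions=[(j, aa) for j, aa in insertions],
        stop_positions=stop_positions,
    )


# ---------------------------------------------------------------------------
# Domain report against the envelope reference protein
# ---------------------------------------------------------------------------


def load_env_reference() -> tuple:
    """Packaged envelope reference protein and its domain annotation."""
    root = importlib.resources.files("ervkit") / "data"
    rec = next(SeqIO.parse(str(root / "syncytin1.fasta"), "fasta"))
    with open(root / "syncytin1_domains.json") as fh:
        domains = json.load(fh)
    return str(rec.seq), domains


def load_env_cds() -> str:
    root = importlib.resources.files("ervkit") / "data"
    rec = next(SeqIO.parse(str(root / "syncytin1_cds.fasta"), "fasta"))
    return str(rec.seq)


def _range_status(putein: Putein, reference: str, start: int, end: int) -> dict:
    obs = []
    for pos in range(start, end + 1):
        idx = putein.ref_map.get(pos)
        obs.append(None if idx is None else putein.sequence[idx - 1])
    if all(o is None for o in obs):
        return {"status": "absent"}
    if any(o is None for o in obs):
        return {"status": "truncated"}
    subs = [
        f"{reference[pos - 1]}{pos}{o}"
        for pos, o in zip(range(start, end + 1), obs)
        if o != reference[pos - 1]
    ]
    if subs:
        return {"status": "substituted", "substitutions": subs}
    return {"status": "conserved"}


def annotate_env_domains(putein: Putein, reference: str | None = None,
                         domains: dict | None = None) -> dict:
    """Classify each functional envelope domain of a reconstructed putein.

    Domain coordinates are fixed on the packaged reference-protein residue
    numbering.  The R-peptide cleavage motif is reported as "deleted" when
    no insertion carrying it is present at the cleavage position (the state
    of the reference protein itself).
    """
    if reference is None or domains is None:
        ref, dom = load_env_reference()
        reference = reference or ref
        domains = domains or dom
    report = {}
    for name, spec in domains.items():
        if "position" in spec:
            pos = spec["position"]
            idx = putein.ref_map.get(pos)
            if idx is None:
                report[name] = {"status": "absent"}
            else:
                obs = putein.sequence[idx - 1]
                exp = spec.get("expected", reference[pos - 1])
                if obs == exp:
                    report[name] = {"status": "conserved", "observed": obs}
                else:
                    report[name] = {
                        "status": "substituted",
                        "substitutions": [f"{exp}{pos}{obs}"],
                    }
        elif "after" in spec:
            anchor = spec["after"]
            motif = spec["motif"]
            # the aligner may split one biological insertion across adjacent
            # reference columns; join everything inserted near the anchor
            nearby = "".join(
                aa for j, aa in sorted(putein.insertions) if abs(j - anchor) <= 5
            )
            report[name] = {"status": "present" if motif in nearby else "deleted"}
        else:
            report[name] = _range_status(putein, reference, spec["start"], spec["end"])
    return report
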