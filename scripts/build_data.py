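#!/usr/bin/env python
"""Regenerate the packaged data files under src/ervkit/data/.

The canonical reference consensus is a synthetic 10,186-nt LTR-internal-LTR
model: it reproduces every published landmark coordinate (gene intervals,
truncation anchors, key LTR positions, motif-coding windows, PBS window)
with deterministic pseudo-random filler elsewhere.  All files are plain
text and bit-reproducible (fixed seed).

Run from the repository root:  python scripts/build_data.py
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

OUT = Path(__file__).resolve().parent.parent / "src" / "ervkit" / "data"

SEED = 20160601
L_REF = 10186
LTR_LEN = 780

# LTR-frame reference bases at the diagnostic key positions (ref_base of the
# key-position table); alt bases define subgroup 2 / 2A / 2B.
KEY_POSITIONS = [
    # (ltr_position, ref, alt, tier)
    (43, "C", "T", "main"),
    (95, "C", "T", "main"),
    (100, "T", "C", "main"),
    (180, "C", "T", "main"),
    (254, "A", "G", "main"),
    (706, "A", "G", "main"),
    (765, "G", "A", "main"),
    (456, "C", "T", "2A"),
    (498, "A", "G", "2A"),
    (133, "A", "G", "2B"),
    (188, "C", "A", "2B"),
    (252, "C", "G", "2B"),
]

CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "N": ["AAT", "AAC"],
    "D": ["GAT", "GAC"],
    "C": ["TGT", "TGC"],
    "Q": ["CAA", "CAG"],
    "E": ["GAA", "GAG"],
    "G": ["GGT", "GGC", "GGA", "GGG"],
    "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "K": ["AAA", "AAG"],
    "M": ["ATG"],
    "F": ["TTT", "TTC"],
    "P": ["CCT", "CCC", "CCA", "CCG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"],
    "W": ["TGG"],
    "Y": ["TAT", "TAC"],
    "V": ["GTT", "GTC", "GTA", "GTG"],
}
AA20 = sorted(CODONS)
COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(s: str) -> str:
    return s.translate(COMPLEMENT)[::-1]


def rand_dna(rng, n, probs=None, max_run=5) -> str:
    """Random DNA with homopolymer runs capped at max_run."""
    bases = np.array(list("ACGT"))
    if probs is None:
        probs = [0.25, 0.25, 0.25, 0.25]
    out = []
    run = 0
    while len(out) < n:
        b = rng.choice(bases, p=probs)
        if out and b == out[-1]:
            if run >= max_run:
                continue
            run += 1
        else:
            run = 1
        out.append(b)
    return "".join(out)


def rand_protein(rng, n) -> str:
    return "".join(rng.choice(AA20) for _ in range(n))


def _suffix_run(s: str) -> int:
    if not s:
        return 0
    n = 1
    while n < len(s) and s[-n - 1] == s[-1]:
        n += 1
    return n


def reverse_translate(rng, protein: str, max_run=5) -> str:
    """Deterministic reverse translation keeping homopolymer runs short."""
    out = ""
    for aa in protein:
        choices = list(CODONS[aa])
        rng.shuffle(choices)
        best = None
        best_run = 10**9
        for codon in choices:
            run = max(_suffix_run(out + codon[: i + 1]) for i in range(3))
            if run <= max_run:
                best = codon
                break
            if run < best_run:
                best, best_run = codon, run
        out += best
    return out


def plant(seq: list, start_1based: int, insert: str) -> None:
    i = start_1based - 1
    seq[i : i + len(insert)] = list(insert)


def build_syncytin(rng) -> tuple[str, dict]:
    """538-aa envelope reference protein with annotated functional domains."""
    prot = list(rand_protein(rng, 538))
    prot[0] = "M"
    plant(prot, 100, "SDGGGWKDYTR")     # receptor binding, SDGGGX2DX2R
    plant(prot, 186, "CWIC")            # SU disulfide motif
    plant(prot, 314, "RKNR")            # furin cleavage site
    prot[332 - 1] = "A"                 # fusion peptide check residue
    plant(prot, 388, "CLDKGRACC")       # TM CX6CC
    plant(prot, 400, "LQNRRALDLLFAERGGT")  # immunosuppressive domain
    prot[433 - 1] = "R"                 # C-terminal heptad check residue
    domains = {
        "receptor_binding": {"start": 100, "end": 110, "pattern": "SDGGGX2DX2R"},
        "su_cwic": {"start": 186, "end": 189, "motif": "CWIC"},
        "furin_site": {"start": 314, "end": 317, "motif": "RKNR"},
        "fusion_peptide_332": {"position": 332, "expected": "A"},
        "tm_cx6cc": {"start": 388, "end": 396, "pattern": "CX6CC"},
        "immunosuppressive": {"start": 400, "end": 416},
        "heptad_433": {"position": 433, "expected": "R"},
        "r_peptide_cleavage": {"after": 500, "motif": "LQMV",
                               "state_in_reference": "deleted"},
    }
    return "".join(prot), domains


def build_trna_library(rng) -> dict:
    """One-letter-coded tRNA 3'-end 18-mers; the PBS is their revcomp.

    Every PBS starts with TGG (so each 3'-end terminates in the CCA tail)
    and the variable 15-mers are pairwise >= 6 mismatches apart so that a
    4-mismatch assignment cap stays unambiguous.
    """
    codes = ["W", "R", "F", "I", "S", "P", "L", "N", "E", "G", "K", "Q"]
    pbs = {}
    tails = []
    while len(tails) < len(codes):
        cand = rand_dna(rng, 15)
        if all(sum(a != b for a, b in zip(cand, t)) >= 6 for t in tails):
            tails.append(cand)
    for code, tail in zip(codes, tails):
        pbs[code] = "TGG" + tail
    return {code: revcomp(p) for code, p in pbs.items()}


def build_reference(rng, syncytin_cds: str, pbs_w: str) -> str:
    ltr = list(rand_dna(rng, LTR_LEN))
    for pos, ref, _alt, _tier in KEY_POSITIONS:
        ltr[pos - 1] = ref
    ltr = "".join(ltr)

    internal = list(rand_dna(rng, 8626))  # ref 781..9406

    def plant_ref(start_ref: int, insert: str) -> None:
        i = start_ref - 781
        internal[i : i + len(insert)] = list(insert)

    plant_ref(784, pbs_w)                                   # PBS window 784-801
    plant_ref(1000, rand_dna(rng, 300, probs=[0.45, 0.10, 0.35, 0.10]))  # AG-rich leader
    plant_ref(4021, reverse_translate(rng, "CQTCKELGHTAKQC"))  # NC zinc finger 1
    plant_ref(4093, reverse_translate(rng, "CAECRKGHWLSDC"))   # NC zinc finger 2
    plant_ref(7501, reverse_translate(rng, "WKELGPYRV"))       # IN GPY/F
    plant_ref(7720, syncytin_cds)                              # env CDS

    # repair homopolymer runs created at plant junctions, touching only
    # unprotected (filler) positions
    protected = [(784, 801), (4021, 4062), (4093, 4131), (7501, 7527),
                 (7720, 7720 + len(syncytin_cds) - 1)]

    def is_protected(ref_pos: int) -> bool:
        return any(s <= ref_pos <= e for s, e in protected)

    import re

    text = "".join(internal)
    for m in re.finditer(r"(A{7,}|C{7,}|G{7,}|T{7,})", text):
        base = m.group()[0]
        for off in range(m.start(), m.end()):
            if not is_protected(off + 781):
                repl = {"A": "C", "C": "A", "G": "T", "T": "G"}[base]
                internal[off] = repl
                break
    seq = ltr + "".join(internal) + ltr
    assert len(seq) == L_REF
    for base in "ACGT":
        assert base * 9 not in seq, f"homopolymer run of {base} in reference"
    return seq


def write_fasta(path: Path, records: list[tuple[str, str]], width=70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)

    protein, domains = build_syncytin(rng)
    cds = reverse_translate(rng, protein) + "TAA"
    assert len(cds) == 1617
    trna = build_trna_library(rng)
    pbs_w = revcomp(trna["W"])
    ref = build_reference(rng, cds, pbs_w)

    assert ref[783:801] == pbs_w  # reference positions 784..801
    assert ref[:LTR_LEN] == ref[-LTR_LEN:]

    write_fasta(OUT / "reference.fasta", [("group_consensus", ref)])
    write_fasta(OUT / "syncytin1.fasta", [("env_reference_protein", protein)])
    write_fasta(OUT / "syncytin1_cds.fasta", [("env_reference_cds", cds)])
    write_fasta(
        OUT / "trna_3p_library.fasta",
        [(code, seq) for code, seq in trna.items()],
    )
    with open(OUT / "syncytin1_domains.json", "w") as fh:
        json.dump(domains, fh, indent=2)
        fh.write("\n")

    with open(OUT / "key_positions.tsv", "w") as fh:
        fh.write("ltr_position\tref_base\talt_base\ttier\n")
        for pos, r, a, tier in KEY_POSITIONS:
            fh.write(f"{pos}\t{r}\t{a}\t{tier}\n")

    landmarks = {
        "ltr_length": LTR_LEN,
        "pseudo_5p_anchor": 256,
        "pseudo_3p_anchor": 326,
        "landmarks": {
            "5ltr": {"start": 1, "end": 780},
            "leader": {"start": 781, "end": 2717},
            "gag": {"start": 2718, "end": 4191},
            "propol": {"start": 4195, "end": 7692},
            "env": {"start": 7720, "end": 9348},
            "3ltr": {"start": 9407, "end": 10186},
            "nc_zinc_finger_1": {"start": 4021, "end": 4062},
            "nc_zinc_finger_2": {"start": 4093, "end": 4131},
            "gpy_f": {"start": 7501, "end": 7527},
            "env_island": {"start": 8289, "end": 8318},
        },
        "recurrent_deletions": [
            {"start": 2780, "end": 3209},
            {"start": 4513, "end": 6184},
            {"start": 6797, "end": 7692},
            {"start": 7928, "end": 9114},
        ],
        "pbs_window": {"start": 4, "end": 21},
        "gene_windows": {
            "gag": {"start": 2718, "end": 4191},
            "pro": {"start": 4195, "end": 5187},
            "pol_rt": {"start": 5188, "end": 6700},
            "pol_in": {"start": 6701, "end": 7692},
            "env": {"start": 7720, "end": 9348},
        },
    }
    import yaml

    with open(OUT / "landmarks.yaml", "w") as fh:
        yaml.safe_dump(landmarks, fh, sort_keys=False)

    print(f"wrote data files to {OUT}")


if __name__ == "__main__":
    main()
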