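import math
import re

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ervkit.align import project_to_reference
from ervkit.errors import InputError
from ervkit.motifs import (
    ag_rich_leader,
    composition_stats,
    find_pbs,
    load_trna_library,
    position_frequency_matrix,
    scan_protein_motifs,
)
from ervkit.reference import Interval
from ervkit.simulate import SimulationSpec, simulate_element

AA = "ACDEFGHIKLMNPQRSTVWY"


def translate(nt):
    from Bio.Seq import Seq

    return str(Seq(nt).translate())


@pytest.fixture(scope="module")
def trna_lib():
    return load_trna_library()


class TestFindPBS:
    def test_reference_carries_w_pbs(self, model, trna_lib):
        pair = project_to_reference(model, model.sequence)
        call = find_pbs(pair, model, trna_lib)
        assert call.assignment == "W"
        assert call.mismatches_best == 0
        assert call.runner_up_gap >= 1

    def test_planted_two_mismatches_recovered(self, model, trna_lib):
        window = model.pbs_reference_window()
        seq = list(model.sequence)
        for off in (5, 11):
            p = window.start + off
            seq[p - 1] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[p - 1]]
        pair = project_to_reference(model, "".join(seq))
        call = find_pbs(pair, model, trna_lib)
        assert call.assignment == "W"
        assert call.mismatches_best == 2

    def test_tie_is_ambiguous(self, model):
        # toy library engineered so the window is equidistant from two entries
        pair = project_to_reference(model, model.sequence)
        window_seq = model.sequence[783:801]
        lib = {"X": window_seq[:-2] + "XX".replace("X", "A" if window_seq[-1] != "A" else "C"),
               "Y": window_seq[:-2] + "XX".replace("X", "A" if window_seq[-1] != "A" else "C")}
        # both entries differ from the window at the same 2 positions
        alt = "A" if window_seq[-1] != "A" else "C"
        lib = {"X": window_seq[:-2] + alt * 2, "Y": window_seq[:-2] + alt * 2}
        call = find_pbs(pair, model, lib)
        assert call.assignment == "ambiguous"
        assert call.runner_up_gap == 0

    def test_too_many_mismatches_ambiguous(self, model, trna_lib):
        window = model.pbs_reference_window()
        seq = list(model.sequence)
        for off in (1, 4, 7, 10, 13):
            p = window.start + off
            seq[p - 1] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[p - 1]]
        pair = project_to_reference(model, "".join(seq))
        call = find_pbs(pair, model, trna_lib)
        assert call.assignment == "ambiguous"

    def test_deleted_pbs_absent(self, model, trna_lib):
        sim = simulate_element(
            model,
            SimulationSpec(age_my=0, seed=1, deletions=[Interval(781, 900)]),
        )
        pair = project_to_reference(model, sim.element.sequence)
        call = find_pbs(pair, model, trna_lib)
        assert call.assignment == "absent"

    @pytest.mark.parametrize("code", ["W", "R", "F", "I"])
    def test_planted_library_codes_recovered(self, model, trna_lib, code):
        window = model.pbs_reference_window()
        seq = (
            model.sequence[: window.start - 1]
            + trna_lib[code]
            + model.sequence[window.end :]
        )
        pair = project_to_reference(model, seq)
        call = find_pbs(pair, model, trna_lib)
        assert call.assignment == code
        assert call.mismatches_best == 0


class TestProteinMotifs:
    def test_reference_zinc_finger_1(self, model):
        # NC zinc finger coding region translates to one CX2CX4HX4C hit
        prot = translate(model.sequence[4020:4062])
        hits = scan_protein_motifs(prot, ["zinc_finger_cx2cx4hx4c"])
        assert len(hits) == 1
        assert re.fullmatch(r"C.{2}C.{4}H.{4}C", hits[0].matched)

    def test_reference_zinc_finger_2(self, model):
        prot = translate(model.sequence[4092:4131])
        hits = scan_protein_motifs(prot, ["zinc_finger_cx2cx3hx4c"])
        assert len(hits) == 1
        assert re.fullmatch(r"C.{2}C.{3}H.{4}C", hits[0].matched)

    def test_reference_gpy_f(self, model):
        prot = translate(model.sequence[7500:7527])
        hits = scan_protein_motifs(prot, ["gpy_f"])
        assert len(hits) == 1
        assert hits[0].matched.startswith("W")
        assert hits[0].matched.endswith("V")

    def test_poly_alanine_no_hits(self):
        assert scan_protein_motifs("A" * 100) == []

    def test_empty_protein_rejected(self):
        with pytest.raises(InputError):
            scan_protein_motifs("")

    def test_coordinates_are_1_based(self):
        prot = "MM" + "CAACKLMGHWXYZC".replace("X", "A").replace("Z", "A")
        hits = scan_protein_motifs(prot, ["zinc_finger_cx2cx4hx4c"])
        assert hits and hits[0].start == 3

    @settings(max_examples=50, deadline=None)
    @given(st.text(alphabet=AA, min_size=10, max_size=500))
    def test_zinc_finger_scan_matches_bruteforce(self, protein):
        hits = scan_protein_motifs(protein, ["zinc_finger_cx2cx4hx4c"])
        found = {(h.start, h.end) for h in hits}
        # brute-force sliding window, honoring non-overlap greedily
        expected = set()
        i = 0
        L = 14  # C X2 C X4 H X4 C
        while i + L <= len(protein):
            w = protein[i : i + L]
            if w[0] == "C" and w[3] == "C" and w[8] == "H" and w[13] == "C":
                expected.add((i + 1, i + L))
                i += L
            else:
                i += 1
        assert found == expected

    @settings(max_examples=50, deadline=None)
    @given(st.text(alphabet=AA, min_size=10, max_size=300))
    def test_gpy_f_scan_matches_bruteforce(self, protein):
        hits = scan_protein_motifs(protein, ["gpy_f"])
        # oracle: earliest-ending match starting at each W, non-overlapping
        expected = []
        i = 0
        while i < len(protein):
            hit = None
            if protein[i] == "W":
                for n in range(3, 31):
                    j = i + 1 + n
                    if j + 5 > len(protein):
                        break
                    tail = protein[j : j + 5]
                    if (tail[0] == "G" and tail[1] == "P" and tail[2] in "YF"
                            and tail[4] == "V"):
                        hit = (i + 1, j + 5)
                        break
            if hit:
                expected.append(hit)
                i = hit[1]
            else:
                i += 1
        assert [(h.start, h.end) for h in hits] == expected


class TestComposition:
    def test_uniform(self):
        stats = composition_stats("ACGT" * 100)
        assert all(v == 0.25 for v in stats["fractions"].values())
        assert not stats["a_rich"] and not stats["g_poor"]

    def test_purine_bias_flags(self):
        seq = "A" * 30 + "G" * 22 + "C" * 24 + "T" * 24
        stats = composition_stats(seq)
        assert stats["fractions"]["A"] == pytest.approx(0.30)
        assert stats["fractions"]["G"] == pytest.approx(0.22)
        assert stats["a_rich"] and stats["g_poor"]

    def test_too_short(self):
        with pytest.raises(InputError):
            composition_stats("ACGT")


class TestPFM:
    def test_identical_strings(self):
        freq, ic = position_frequency_matrix(["ACGT", "ACGT", "ACGT"])
        assert np.allclose(freq.max(axis=1), 1.0)
        assert np.allclose(ic, 2.0)

    def test_half_split_column(self):
        freq, ic = position_frequency_matrix(["A", "T"])
        assert ic[0] == pytest.approx(1.0)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(InputError):
            position_frequency_matrix(["ACG", "AC"])

    def test_pbs_tgg_start_conserved(self, model, trna_lib):
        rng = np.random.default_rng(0)
        windows = []
        for code, pbs in trna_lib.items():
            w = list(pbs)
            for i in rng.integers(3, 18, size=2):
                w[i] = "ACGT"[rng.integers(0, 4)]
            windows.append("".join(w))
        freq, ic = position_frequency_matrix(windows)
        assert np.all(ic[:3] == pytest.approx(2.0))  # TGG start shared by all
        assert ic[3:].mean() < 1.9


class TestAGRichLeader:
    def test_reference_leader_detected(self, model):
        leader = model.sequence[780:2717]
        hit = ag_rich_leader(leader)
        assert hit is not None
        start, end, frac = hit
        assert end - start + 1 >= 100
        assert frac >= 0.7
        # planted AG-rich stretch sits at reference 1000-1299 = leader 220-519;
        # the maximal window may extend into flanking filler but must cover it
        assert start <= 220 + 100 and end >= 519 - 100

    def test_absent_in_uniform(self):
        rng = np.random.default_rng(3)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 1000)])
        hit = ag_rich_leader(seq)
        assert hit is None or hit[2] >= 0.7
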