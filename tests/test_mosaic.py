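import itertools

import numpy as np
import pytest

from ervkit.align import AlignedPair, global_align
from ervkit.errors import InputError
from ervkit.mosaic import (
    MosaicConfig,
    best_matching_locus,
    count_discordant,
    segment_query,
)
from ervkit.simulate import mutate_sequence, simulate_recombinant_transcript


class TestCountDiscordant:
    def test_identical(self):
        assert count_discordant(global_align("ACGT" * 20, "ACGT" * 20)) == 0

    def test_three_substitutions(self):
        ref = ("ACGT" * 81)[:324]
        qry = list(ref)
        for i in (10, 100, 200):
            qry[i] = {"A": "G", "C": "T", "G": "A", "T": "C"}[qry[i]]
        aln = global_align(ref, "".join(qry))
        assert count_discordant(aln) == 3
        assert aln.identity == pytest.approx(321 / 324)

    def test_gap_run_counts_once(self):
        aln = AlignedPair("ACGTACGTAC", "ACG-----AC", 0.0)
        assert count_discordant(aln) == 1

    def test_two_gap_runs(self):
        aln = AlignedPair("ACGTACGTAC", "A-GTAC--AC", 0.0)
        assert count_discordant(aln) == 2


class TestBestMatchingLocus:
    def test_verbatim_copy_wins(self, model):
        rng = np.random.default_rng(0)
        X = mutate_sequence(model.sequence, 0.02, seed=1)
        Y = mutate_sequence(model.sequence, 0.05, seed=2)
        query = X[3000:4000]
        ranked = best_matching_locus(query, {"X": X, "Y": Y}, model)
        assert ranked[0][0] == "X"
        assert ranked[0][1] == 1.0
        assert ranked[0][2] == 0

    def test_two_substitutions_still_wins(self, model):
        X = mutate_sequence(model.sequence, 0.01, seed=3)
        Y = mutate_sequence(model.sequence, 0.05, seed=4)
        q = list(X[3000:4000])
        q[100] = {"A": "G", "C": "T", "G": "A", "T": "C"}[q[100]]
        q[500] = {"A": "G", "C": "T", "G": "A", "T": "C"}[q[500]]
        ranked = best_matching_locus("".join(q), {"X": X, "Y": Y}, model)
        assert ranked[0][0] == "X"
        assert ranked[0][2] == 2

    def test_empty_db_is_error(self, model):
        with pytest.raises(InputError):
            best_matching_locus("ACGT" * 100, {}, model)

    def test_unrelated_query_empty_result(self, model):
        rng = np.random.default_rng(9)
        junk = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 400)])
        ranked = best_matching_locus(junk, {"X": model.sequence}, model)
        assert ranked == []


class TestSegmentQuery:
    def test_identical_query_single_segment(self, model):
        A = mutate_sequence(model.sequence, 0.02, seed=5)
        B = mutate_sequence(model.sequence, 0.02, seed=6)
        q = A[4000:5000]
        asg = segment_query(q, {"A": A, "B": B}, model)
        assert len(asg.segments) == 1
        assert asg.segments[0].locus_id == "A"
        assert asg.total_mismatches == 0
        assert asg.breakpoints == []

    def test_chimera_two_segments(self, model):
        A = mutate_sequence(model.sequence, 0.05, seed=7)
        B = mutate_sequence(model.sequence, 0.05, seed=8)
        chim = simulate_recombinant_transcript(A, B, [5001])
        q = chim[3499:6500]
        asg = segment_query(q, {"A": A, "B": B}, model)
        assert [s.locus_id for s in asg.segments] == ["A", "B"]
        assert len(asg.breakpoints) == 1
        # true breakpoint at query position 5001 - 3499 = 1502
        assert abs(asg.breakpoints[0] - 1502) <= 20
        assert asg.total_mismatches < asg.single_locus_mismatches

    def test_huge_penalty_degenerates_to_single_locus(self, model):
        A = mutate_sequence(model.sequence, 0.05, seed=9)
        B = mutate_sequence(model.sequence, 0.05, seed=10)
        chim = simulate_recombinant_transcript(A, B, [5001])
        q = chim[3999:6000]
        asg = segment_query(q, {"A": A, "B": B}, model,
                            MosaicConfig(switch_penalty=1e9))
        assert len(asg.segments) == 1
        assert asg.segments[0].locus_id == asg.single_locus_id
        assert asg.total_mismatches == asg.single_locus_mismatches

    def test_zero_penalty_per_column_best(self, model):
        A = mutate_sequence(model.sequence, 0.05, seed=11)
        B = mutate_sequence(model.sequence, 0.05, seed=12)
        q = A[4000:4500] + B[4500:5000]
        asg = segment_query(q, {"A": A, "B": B}, model,
                            MosaicConfig(switch_penalty=0.0))
        assert asg.total_mismatches == 0  # every column can pick its own locus

    def test_no_candidates_is_error(self, model):
        with pytest.raises(InputError):
            segment_query("ACGT" * 100, {}, model)

    def test_monotone_in_breakpoints(self, model):
        A = mutate_sequence(model.sequence, 0.05, seed=13)
        B = mutate_sequence(model.sequence, 0.05, seed=14)
        chim = simulate_recombinant_transcript(A, B, [4500, 5500])
        q = chim[3999:6000]
        prev = None
        for lam in (1e9, 50.0, 4.0, 0.0):
            asg = segment_query(q, {"A": A, "B": B}, model,
                                MosaicConfig(switch_penalty=lam))
            if prev is not None:
                assert asg.total_mismatches <= prev
            prev = asg.total_mismatches


def oracle_min_cost(qcols, locus_cols, lam, max_breaks=2):
    """Brute-force minimum segmentation cost with <= max_breaks breakpoints.

    Sequences are plain strings on a shared coordinate grid (no gaps), so the
    per-column cost is a direct character comparison.
    """
    n = len(qcols)
    k = len(locus_cols)
    cost = np.array([
        [1.0 if locus[t] != qcols[t] else 0.0 for t in range(n)]
        for locus in locus_cols
    ])
    prefix = np.concatenate([np.zeros((k, 1)), np.cumsum(cost, axis=1)], axis=1)

    def seg_cost(state, s, e):
        return prefix[state, e] - prefix[state, s]

    best = min(seg_cost(s, 0, n) for s in range(k))
    for b1 in range(1, n):
        for s1 in range(k):
            c1 = seg_cost(s1, 0, b1)
            for s2 in range(k):
                if s2 == s1:
                    continue
                best = min(best, c1 + seg_cost(s2, b1, n) + lam)
                if max_breaks >= 2:
                    for b2 in range(b1 + 1, n):
                        for s3 in range(k):
                            if s3 == s2:
                                continue
                            best = min(
                                best,
                                c1 + seg_cost(s2, b1, b2)
                                + seg_cost(s3, b2, n) + 2 * lam,
                            )
    return best


@pytest.mark.parametrize("seed", range(4))
def test_dp_cost_optimal_vs_bruteforce(model, seed):
    rng = np.random.default_rng(seed)
    lo = 4000
    span = 260
    loci_full = [mutate_sequence(model.sequence, 0.06, seed=100 + i) for i in range(3)]
    cuts = sorted(rng.choice(np.arange(40, span - 40), size=2, replace=False))
    src = rng.integers(0, 3, size=3)
    qcols = (
        loci_full[src[0]][lo : lo + cuts[0]]
        + loci_full[src[1]][lo + cuts[0] : lo + cuts[1]]
        + loci_full[src[2]][lo + cuts[1] : lo + span]
    )
    lam = 4.0
    # embed the query in enough reference context to satisfy projection
    asg = segment_query(
        qcols, {f"L{i}": loci_full[i] for i in range(3)}, model,
        MosaicConfig(switch_penalty=lam),
    )
    dp_cost = asg.total_mismatches + lam * len(asg.breakpoints)
    oracle = oracle_min_cost(
        qcols, [s[lo : lo + span] for s in loci_full], lam
    )
    assert dp_cost == pytest.approx(oracle)


def test_breakpoint_recall(model):
    hits = 0
    n = 25
    for seed in range(n):
        rng = np.random.default_rng(1000 + seed)
        A = mutate_sequence(model.sequence, 0.05, seed=3000 + seed)
        B = mutate_sequence(model.sequence, 0.05, seed=4000 + seed)
        bp = int(rng.integers(4200, 5800))
        chim = simulate_recombinant_transcript(A, B, [bp])
        q = chim[2999:7000]
        asg = segment_query(q, {"A": A, "B": B}, model)
        if len(asg.breakpoints) == 1 and abs(asg.breakpoints[0] + 2999 - bp) <= 20:
            hits += 1
    assert hits / n >= 0.9
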