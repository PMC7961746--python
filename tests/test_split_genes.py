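"""Protein alignment, TM profiling, and the four-criterion split test."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from linearmito.split_genes import (
    CohortEntry,
    ProteinRecord,
    blosum62_score,
    detect_split,
    global_align,
    tm_profile,
)

AAS = "ACDEFGHIKLMNPQRSTVWY"


def brute_force_align(a, b, gap_open=11, gap_extend=1, semi_global=False):
    """Exhaustive enumeration of alignment paths (op strings over M/X/Y).

    X consumes a residue of ``a`` (gap in b), Y consumes a residue of
    ``b`` (gap in a).  Affine cost: each maximal gap run costs
    open + (len-1) * extend; semi-global waives leading/trailing Y runs.
    """
    best = [None]

    def score(ops):
        s = 0
        i = j = 0
        runs = []
        for op in ops:
            if op == "M":
                s += blosum62_score(a[i], b[j])
                i += 1
                j += 1
                runs.append(None)
            else:
                if runs and runs[-1] and runs[-1][0] == op:
                    runs[-1][1] += 1
                else:
                    runs.append([op, 1])
                if op == "X":
                    i += 1
                else:
                    j += 1
        gap_runs = [r for r in runs if r]
        if semi_global and gap_runs:
            if ops and ops[0] == "Y":
                gap_runs = gap_runs[1:]
            if ops and ops[-1] == "Y" and gap_runs and gap_runs[-1][0] == "Y" and ops[-1] == "Y":
                # trailing Y run is the last run only if ops end with Y
                gap_runs = gap_runs[:-1]
        for op, ln in gap_runs:
            s -= gap_open + (ln - 1) * gap_extend
        return s

    def rec(i, j, ops):
        if i == len(a) and j == len(b):
            sc = score(ops)
            if best[0] is None or sc > best[0]:
                best[0] = sc
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, ops + "M")
        if i < len(a):
            rec(i + 1, j, ops + "X")
        if j < len(b):
            rec(i, j + 1, ops + "Y")

    rec(0, 0, "")
    return best[0]


class TestGlobalAlign:
    def test_self_alignment_diagonal_score(self, rng):
        s = "".join(np.array(list(AAS))[rng.integers(0, 20, 10)])
        res = global_align(s, s)
        assert res.score == sum(blosum62_score(c, c) for c in s)
        assert res.ref_coverage == 1.0
        assert res.ref_span == (1, 10)

    def test_prefix_fragment_semi_global(self, rng):
        ref = "".join(np.array(list(AAS))[rng.integers(0, 20, 400)])
        res = global_align(ref[:120], ref, semi_global=True)
        assert res.ref_span == (1, 120)
        assert res.ref_coverage == pytest.approx(0.3)

    def test_internal_fragment_semi_global(self, rng):
        ref = "".join(np.array(list(AAS))[rng.integers(0, 20, 300)])
        res = global_align(ref[100:200], ref, semi_global=True)
        assert res.ref_span == (101, 200)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            global_align("", "ACD")

    def test_score_symmetric(self, rng):
        for _ in range(10):
            x = "".join(np.array(list(AAS))[rng.integers(0, 20, 15)])
            y = "".join(np.array(list(AAS))[rng.integers(0, 20, 12)])
            assert global_align(x, y).score == global_align(y, x).score

    def test_degapped_rows_equal_inputs(self, rng):
        x = "".join(np.array(list(AAS))[rng.integers(0, 20, 30)])
        y = "".join(np.array(list(AAS))[rng.integers(0, 20, 25)])
        for sg in (False, True):
            res = global_align(x, y, semi_global=sg)
            assert res.aligned_a.replace("-", "") == x
            assert res.aligned_b.replace("-", "") == y

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        st.text(alphabet=AAS, min_size=1, max_size=6),
        st.text(alphabet=AAS, min_size=1, max_size=6),
    )
    def test_score_equals_exhaustive_enumeration_global(self, x, y):
        assert global_align(x, y).score == brute_force_align(x, y)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        st.text(alphabet=AAS, min_size=1, max_size=6),
        st.text(alphabet=AAS, min_size=1, max_size=6),
    )
    def test_score_equals_exhaustive_enumeration_semiglobal(self, x, y):
        got = global_align(x, y, semi_global=True).score
        assert got == brute_force_align(x, y, semi_global=True)

    def test_score_matches_biopython_global(self, rng):
        from Bio.Align import PairwiseAligner, substitution_matrices

        aligner = PairwiseAligner()
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.mode = "global"
        aligner.open_gap_score = -11
        aligner.extend_gap_score = -1
        for _ in range(25):
            la, lb = int(rng.integers(3, 13)), int(rng.integers(3, 13))
            x = "".join(np.array(list(AAS))[rng.integers(0, 20, la)])
            y = "".join(np.array(list(AAS))[rng.integers(0, 20, lb)])
            assert global_align(x, y).score == int(aligner.score(x, y))


class TestTMProfile:
    def test_single_hydrophobic_stretch(self):
        seq = "K" * 20 + "IL" * 15 + "K" * 20
        prof = tm_profile(seq)
        assert prof.n_segments == 1
        s, e = prof.segments[0]
        assert 20 < s < 35 and 35 < e < 55

    def test_hydrophilic_protein_no_segments(self):
        assert tm_profile("R" * 60).n_segments == 0

    def test_two_separated_stretches(self):
        seq = "K" * 20 + "I" * 25 + "K" * 30 + "L" * 25 + "K" * 20
        assert tm_profile(seq).n_segments == 2

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="19"):
            tm_profile("ILILIL")

    def test_invariant_under_hydrophilic_flanks(self):
        core = "K" * 20 + "IL" * 15 + "K" * 20
        n0 = tm_profile(core).n_segments
        assert tm_profile("R" * 40 + core + "E" * 40).n_segments == n0

    def test_segments_disjoint_and_long_enough(self, rng):
        seq = "".join(np.array(list(AAS))[rng.integers(0, 20, 500)])
        prof = tm_profile(seq)
        prev_end = 0
        for s, e in prof.segments:
            assert s > prev_end
            assert e - s + 1 >= 15
            prev_end = e


def _random_protein(rng, n):
    return "".join(np.array(list(AAS))[rng.integers(0, 20, n)])


def _mutate(s, rate, rng):
    out = list(s)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = AAS[rng.integers(0, 20)]
    return "".join(out)


@pytest.fixture(scope="module")
def reference():
    rng = np.random.default_rng(88)
    return ProteinRecord("ccmf_ref", _random_protein(rng, 600))


@pytest.fixture(scope="module")
def cohort():
    return [
        CohortEntry("taxon1", (300, 300), 300, (3, 1)),
        CohortEntry("taxon2", (310, 290), 305, (3, 1)),
        CohortEntry("taxon3", (295, 305), 298, (3, 1)),
    ]


class TestDetectSplit:
    def test_clean_bipartition_is_split(self, reference, cohort):
        R = reference.sequence
        orfs = [ProteinRecord("o1", R[:300]), ProteinRecord("o2", R[300:])]
        call = detect_split(orfs, reference, cohort)
        assert call.verdict == "split"
        assert call.criteria["adjacent_orf_coverage"]
        assert abs(call.split_site - 300) <= 5

    def test_single_full_orf_is_non_split(self, reference, cohort):
        call = detect_split([ProteinRecord("o", reference.sequence)], reference, cohort)
        assert call.verdict == "non_split"

    def test_mutated_parts_still_split(self, reference, cohort):
        rng = np.random.default_rng(99)
        R = reference.sequence
        # 50-aa deletion in the middle of part i, 10% substitutions on both
        p1 = _mutate(R[:125] + R[175:300], 0.10, rng)
        p2 = _mutate(R[300:], 0.10, rng)
        call = detect_split(
            [ProteinRecord("o1", p1), ProteinRecord("o2", p2)], reference, cohort
        )
        assert call.verdict == "split"
        assert abs(call.split_site - 300) <= 30

    def test_split_sites_across_bipartitions(self, reference):
        R = reference.sequence
        for s in (150, 300, 450):
            cohort = [CohortEntry(f"t{i}", (s, 600 - s), s, None) for i in range(3)]
            orfs = [ProteinRecord("o1", R[:s]), ProteinRecord("o2", R[s:])]
            call = detect_split(orfs, reference, cohort)
            assert call.verdict == "split"
            assert abs(call.split_site - s) <= 5

    def test_unrelated_orfs_undetermined(self, reference, cohort):
        rng = np.random.default_rng(123)
        orfs = [
            ProteinRecord("o1", _random_protein(rng, 250)),
            ProteinRecord("o2", _random_protein(rng, 250)),
        ]
        call = detect_split(orfs, reference, cohort)
        assert call.verdict in ("undetermined", "non_split")
        assert not call.criteria["adjacent_orf_coverage"]

    def test_inconsistent_cohort_blocks_split_verdict(self, reference):
        R = reference.sequence
        # cohort says the split belongs near column 100 with short part i
        cohort = [CohortEntry(f"t{i}", (100, 500), 100, (1, 3)) for i in range(3)]
        orfs = [ProteinRecord("o1", R[:300]), ProteinRecord("o2", R[300:])]
        call = detect_split(orfs, reference, cohort)
        assert call.criteria["adjacent_orf_coverage"]
        assert call.verdict == "undetermined"

    def test_empty_orf_list_rejected(self, reference, cohort):
        with pytest.raises(ValueError):
            detect_split([], reference, cohort)
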