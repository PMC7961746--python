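"""Repeat detectors: tandem arrays, telomeres, TIRs, central repeat."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_dna
from linearmito.catalog import TELOMERE_UNITS, reconstruct_central_region
from linearmito.genome_io import GeneFeature, LinearMitogenome
from linearmito.repeats import (
    classify_repeats,
    divergence_fraction,
    find_tandem_repeats,
    find_telomeres,
    find_tir,
    locate_central_repeat,
    revcomp,
)
from linearmito.synthetic import SimParams, generate_mitogenome


def brute_force_tandem(seq, min_unit=2, max_unit=40, min_copies=2):
    """Independent enumeration of maximal tandem arrays.

    For every substring, compute its minimal period from first principles;
    keep substrings that are maximal for that period, contain enough full
    copies, and are not strictly contained in a kept longer array.
    """

    def min_period(s):
        for p in range(1, len(s) + 1):
            if all(s[i] == s[i - p] for i in range(p, len(s))):
                return p
        return len(s)

    n = len(seq)
    raw = []
    for i in range(n):
        for j in range(i + 1, n + 1):
            sub = seq[i:j]
            p = min_period(sub)
            if p < min_unit or p > max_unit:
                continue
            if len(sub) // p < min_copies:
                continue
            # maximality: extending one base in either direction breaks period p
            if i > 0 and seq[i - 1] == seq[i - 1 + p]:
                continue
            if j < n and seq[j] == seq[j - p]:
                continue
            raw.append((i + 1, j, sub[:p], len(sub) // p, len(sub) % p))
    # drop arrays strictly inside another array
    kept = []
    for c in raw:
        if not any(
            o is not c and o[0] <= c[0] and c[1] <= o[1] and (o[1] - o[0]) > (c[1] - c[0])
            for o in raw
        ):
            kept.append(c)
    return sorted(set(kept))


class TestRevcomp:
    def test_printed_telomere_unit(self):
        assert revcomp("CTCCCTTATCTAGTCTTT") == "AAAGACTAGATAAGGGAG"

    def test_single_base(self):
        assert revcomp("A") == "T"

    @given(st.text(alphabet="ACGTN", min_size=1, max_size=80))
    def test_involution(self, s):
        assert revcomp(revcomp(s)) == s

    def test_invalid_character(self):
        with pytest.raises(ValueError):
            revcomp("ACGU")


class TestFindTandemRepeats:
    def test_printed_central_region_single_call(self):
        region = reconstruct_central_region("Strombidium_sp")
        assert len(region) == 170
        calls = find_tandem_repeats(region, min_unit=2, max_unit=30)
        assert len(calls) == 1
        c = calls[0]
        assert (len(c.unit), c.full_copies, c.partial_tail_bp) == (15, 11, 5)
        assert c.at_content_pct == 100.00

    def test_no_call_below_min_copies(self):
        assert find_tandem_repeats("ACGT") == []

    def test_primitive_unit_reduction(self):
        calls = find_tandem_repeats("GATATATATC")
        assert len(calls) == 1
        assert calls[0].unit == "AT" and calls[0].full_copies == 4

    def test_parameter_error(self):
        with pytest.raises(ValueError):
            find_tandem_repeats("ACGT", min_unit=10, max_unit=5)

    def test_calls_reconstruct_their_substring(self, rng):
        for _ in range(30):
            s = random_dna(rng, 200, at_bias=0.8)
            for c in find_tandem_repeats(s):
                assert c.reconstruct() == s[c.start - 1 : c.end]
                assert len(c.unit) * c.full_copies + c.partial_tail_bp == c.length
                assert c.full_copies >= 2

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.text(alphabet="AT", min_size=4, max_size=60))
    def test_matches_exhaustive_enumeration_at_alphabet(self, s):
        got = sorted(
            (c.start, c.end, c.unit, c.full_copies, c.partial_tail_bp)
            for c in find_tandem_repeats(s)
        )
        assert got == brute_force_tandem(s)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=4, max_size=60))
    def test_matches_exhaustive_enumeration_acgt(self, s):
        got = sorted(
            (c.start, c.end, c.unit, c.full_copies, c.partial_tail_bp)
            for c in find_tandem_repeats(s)
        )
        assert got == brute_force_tandem(s)


def _capped_genome(unit, core, copies=4):
    return unit * copies + core + revcomp(unit * copies)


class TestFindTelomeres:
    def test_printed_halteria_unit_recovered(self, rng):
        unit = TELOMERE_UNITS["Halteria_grandinella"]
        g = _capped_genome(unit, random_dna(rng, 2000, at_bias=0.8))
        call = find_telomeres(g)
        assert call is not None and call.symmetric
        assert len(call.unit_5p) == 31
        assert call.unit_5p == unit

    def test_uniform_random_genome_absent(self, rng):
        g = random_dna(rng, 3000, at_bias=0.5)
        call = find_telomeres(g)
        assert call is None or not call.symmetric

    def test_rotation_invariance_of_symmetry(self, rng):
        unit = TELOMERE_UNITS["Strombidium_sp"]
        core = random_dna(rng, 1500, at_bias=0.8)
        g = _capped_genome(unit, core)
        grc = revcomp(g)
        c1, c2 = find_telomeres(g), find_telomeres(grc)
        assert c1.symmetric and c2.symmetric
        assert len(c1.unit_5p) == len(c2.unit_5p)

    def test_planted_unit_recovered_up_to_rotation_cohort(self):
        recovered = 0
        n = 40
        for i in range(n):
            rng = np.random.default_rng([555, i])
            ulen = int(rng.integers(10, 41))
            while True:
                unit = random_dna(rng, ulen, at_bias=0.6)
                # primitive check from first principles
                if all(
                    any(unit[k] != unit[k - p] for k in range(p, ulen))
                    for p in range(1, ulen)
                ):
                    break
            g = _capped_genome(unit, random_dna(rng, 1800, at_bias=0.7))
            call = find_telomeres(g)
            if (
                call is not None
                and call.symmetric
                and len(call.unit_5p) == ulen
                and call.unit_5p in unit + unit
            ):
                recovered += 1
        assert recovered == n

    def test_too_short_genome_rejected(self):
        with pytest.raises(ValueError):
            find_telomeres("ACGT" * 100, window=500)


class TestFindTir:
    def test_planted_perfect_tir(self, rng):
        P = random_dna(rng, 1500, at_bias=0.5)
        g = P + random_dna(rng, 9000, at_bias=0.5) + revcomp(P)
        call = find_tir(g)
        assert call is not None
        assert call.length_bp >= 1500  # may extend by chance matches
        assert call.length_bp <= 1510
        assert call.identity_pct >= 99.0
        assert call.span_5p[0] <= 5

    def test_no_planted_tir_absent(self, rng):
        g = random_dna(rng, 12000, at_bias=0.5)
        assert find_tir(g) is None

    def test_mutated_tir_recovered_within_10pct(self):
        rng = np.random.default_rng(404)
        P = random_dna(rng, 1500, at_bias=0.5)
        P3 = list(revcomp(P))
        bases = "ACGT"
        for i in range(len(P3)):
            if rng.random() < 0.05:
                P3[i] = bases[(bases.index(P3[i]) + int(rng.integers(1, 4))) % 4]
        g = P + random_dna(rng, 9000, at_bias=0.5) + "".join(P3)
        call = find_tir(g)
        assert call is not None
        assert abs(call.length_bp - 1500) <= 150
        assert call.identity_pct >= 90.0


class TestLocateCentralRepeat:
    def test_between_trnF_trnY_true(self, small_genome):
        genome, manifest = small_genome
        call, between = locate_central_repeat(genome)
        assert between is True
        assert [call.start, call.end] == manifest.central["span"]
        assert call.unit == manifest.central["unit"]

    def test_between_flag_false_without_flanking_trnas(self, small_genome):
        genome, manifest = small_genome
        # strip the tRNA annotations: context is lost, AT-rich fallback fires
        stripped = genome.with_features(
            [f for f in genome.features if f.category != "tRNA"]
        )
        call, between = locate_central_repeat(stripped)
        assert between is False
        assert call is not None
        assert [call.start, call.end] == manifest.central["span"]

    def test_cohort_recovery(self):
        hits = 0
        n = 25
        for i in range(n):
            params = SimParams(seed=700 + i, genome_len=20_000, n_genes=14)
            genome, manifest = generate_mitogenome(params)
            call, between = locate_central_repeat(genome)
            if between and [call.start, call.end] == manifest.central["span"]:
                hits += 1
        assert hits == n


class TestDivergenceFraction:
    def _genome(self, strands_left, strands_right):
        feats = []
        pos = 10
        for i, s in enumerate(strands_left):
            feats.append(GeneFeature(f"l{i}", "protein", pos, pos + 50, s))
            pos += 60
        center = (pos, pos + 100)
        pos += 110
        for i, s in enumerate(strands_right):
            feats.append(GeneFeature(f"r{i}", "protein", pos, pos + 50, s))
            pos += 60
        g = LinearMitogenome(id="g", sequence="A" * (pos + 50), features=feats)
        return g, center

    def test_fully_divergent(self):
        g, center = self._genome([-1, -1, -1], [1, 1, 1])
        assert divergence_fraction(g, center) == 1.0

    def test_all_plus_half_and_half(self):
        g, center = self._genome([1, 1], [1, 1])
        assert divergence_fraction(g, center) == 0.5

    def test_random_strands_binomial(self, rng):
        strands = [int(x) for x in rng.choice([1, -1], size=1000)]
        g, center = self._genome(strands[:500], strands[500:])
        frac = divergence_fraction(g, center)
        assert abs(frac - 0.5) <= 3 * 0.5 / (1000 ** 0.5)

    def test_no_features_error(self):
        g = LinearMitogenome(id="g", sequence="A" * 100)
        with pytest.raises(ValueError):
            divergence_fraction(g, (40, 60))


class TestClassifyRepeats:
    def test_telomere_and_central_no_tir(self, small_genome):
        genome, _ = small_genome
        rep = classify_repeats(genome)
        assert sorted(rep.repeat_kinds_present) == ["central", "telomeric"]

    def test_all_three_kinds(self):
        params = SimParams(seed=21, genome_len=30_000, n_genes=16, tir_len=1200)
        genome, _ = generate_mitogenome(params)
        rep = classify_repeats(genome)
        assert sorted(rep.repeat_kinds_present) == ["TIR", "central", "telomeric"]

    def test_fields_equal_standalone_components(self, small_genome):
        genome, _ = small_genome
        rep = classify_repeats(genome)
        assert rep.telomeres == find_telomeres(genome)
        standalone_central, between = locate_central_repeat(genome)
        assert rep.central_repeat == standalone_central
        assert rep.between_trnF_trnY == between
        assert rep.divergence_fraction == divergence_fraction(
            genome, (standalone_central.start, standalone_central.end)
        )
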