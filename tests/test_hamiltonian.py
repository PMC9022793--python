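"""BQM construction and energy evaluation."""

from __future__ import annotations

import itertools
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stemfold.hamiltonian import (
    EmptyStemSetError,
    HamiltonianParams,
    build_bqm,
    decode_structure,
    evaluate_energy,
    linear_coefficient,
    objective_direct,
    quadratic_coefficient,
)
from stemfold.stems import Stem, StemSet, enumerate_stems, is_overlap, is_pseudoknot

from conftest import full_scan_minimum


def make_stemset(stems: list[Stem], n: int | None = None) -> StemSet:
    """A StemSet over a dummy all-A sequence long enough for the stems."""
    if n is None:
        n = max(s.j for s in stems) + 1
    return StemSet(sequence="A" * n, stems=tuple(sorted(stems)), min_stem=1, min_loop=0)


def params_for(stems: list[Stem], **kw) -> HamiltonianParams:
    return HamiltonianParams.for_stems(make_stemset(stems), **kw)


def random_stemset(rng: random.Random, n_stems: int) -> StemSet:
    stems = set()
    while len(stems) < n_stems:
        i = rng.randrange(0, 30)
        k = rng.randint(1, 4)
        j = i + 2 * k + rng.randint(3, 12)
        try:
            stems.add(Stem(i, j, k))
        except ValueError:
            continue
    return make_stemset(list(stems), n=60)


class TestCoefficients:
    @pytest.mark.parametrize(
        "k,mu,expected",
        [(3, 3, -9.0), (3, 6, 81.0), (6, 6, -36.0)],
    )
    def test_linear(self, k, mu, expected):
        p = HamiltonianParams(c_B=1.0, c_L=10.0, mu=mu)
        assert linear_coefficient(Stem(0, 2 * k + 3, k), p) == expected

    def test_quadratic_compatible(self):
        a, b = Stem(0, 8, 3), Stem(9, 17, 3)
        p = params_for([a, b], c_B=1.0)
        assert quadratic_coefficient(a, b, p) == -18.0

    def test_quadratic_pseudoknot_scaled(self):
        a, b = Stem(0, 12, 3), Stem(6, 20, 3)
        assert is_pseudoknot(a, b)
        p = params_for([a, b], c_B=1.0, c_P=0.5)
        assert quadratic_coefficient(a, b, p) == -9.0

    def test_quadratic_overlap_penalized(self):
        a, b = Stem(0, 9, 3), Stem(1, 8, 2)
        assert is_overlap(a, b)
        p = params_for([a, b])
        assert quadratic_coefficient(a, b, p) == p.overlap_penalty > 0

    def test_param_validation(self):
        with pytest.raises(ValueError):
            HamiltonianParams(c_B=0.0)
        with pytest.raises(ValueError):
            HamiltonianParams(c_P=1.5)
        with pytest.raises(ValueError):
            HamiltonianParams(c_P=-0.5)
        # explicit override admits out-of-range pseudoknot factors
        HamiltonianParams(c_P=-0.5, allow_c_p_out_of_range=True)

    def test_mu_recomputed_from_stems(self):
        stems = [Stem(0, 8, 3), Stem(10, 24, 5)]
        p = params_for(stems)
        assert p.mu == 5


class TestBuildAndEvaluate:
    def test_two_compatible_stems_table(self):
        stems = [Stem(0, 8, 3), Stem(9, 17, 3)]
        p = params_for(stems, c_B=1.0, c_L=10.0)
        bqm = build_bqm(make_stemset(stems), p)
        assert bqm.linear == {0: -9.0, 1: -9.0}
        assert bqm.quadratic == {(0, 1): -18.0}

    def test_single_stem_no_quadratic(self):
        stems = [Stem(0, 14, 4)]
        bqm = build_bqm(make_stemset(stems), params_for(stems))
        assert bqm.quadratic == {}

    def test_empty_stemset_signalled(self):
        empty = StemSet(sequence="AAAA", stems=(), min_stem=3, min_loop=3)
        with pytest.raises(EmptyStemSetError):
            HamiltonianParams.for_stems(empty)
        with pytest.raises(EmptyStemSetError):
            build_bqm(empty, HamiltonianParams(mu=1))

    def test_all_zero_configuration_has_zero_energy(self):
        stems = [Stem(0, 8, 3), Stem(9, 17, 3)]
        bqm = build_bqm(make_stemset(stems), params_for(stems))
        assert evaluate_energy(bqm, [0, 0]) == 0.0

    def test_two_length_three_stems_score_36(self):
        # (3+3)^2 = 36: both selected, length term neutral at mu = 3
        stems = [Stem(0, 8, 3), Stem(9, 17, 3)]
        p = params_for(stems, c_B=1.0, c_L=10.0)
        assert p.mu == 3
        bqm = build_bqm(make_stemset(stems), p)
        assert evaluate_energy(bqm, [1, 1]) == -36.0

    def test_single_length_six_stem_score_36(self):
        # 6^2 = 36
        stems = [Stem(0, 14, 6)]
        p = params_for(stems, c_B=1.0, c_L=10.0)
        bqm = build_bqm(make_stemset(stems), p)
        assert evaluate_energy(bqm, [1]) == -36.0

    def test_length_mismatch_rejected(self):
        stems = [Stem(0, 8, 3)]
        bqm = build_bqm(make_stemset(stems), params_for(stems))
        with pytest.raises(ValueError):
            evaluate_energy(bqm, [1, 0])

    def test_json_export_round_trips(self):
        import json

        stems = [Stem(0, 8, 3), Stem(9, 17, 3)]
        bqm = build_bqm(make_stemset(stems), params_for(stems))
        doc = json.loads(bqm.to_json())
        assert doc["linear"]["0"] == -9.0
        assert doc["quadratic"] == [[0, 1, -18.0]]
        assert doc["offset"] == 0.0


class TestDirectObjectiveEquivalence:
    @pytest.mark.parametrize("seed", range(5))
    def test_all_configurations_match(self, seed):
        """BQM energy == direct objective on every configuration."""
        rng = random.Random(seed)
        stemset = random_stemset(rng, 8)
        p = HamiltonianParams.for_stems(stemset, c_P=rng.choice([0.0, 0.5, 1.0]))
        bqm = build_bqm(stemset, p)
        for bits in itertools.product((0, 1), repeat=len(stemset)):
            selected = [stemset[i] for i, b in enumerate(bits) if b]
            assert evaluate_energy(bqm, bits) == pytest.approx(
                objective_direct(selected, p)
            )

    def test_direct_examples(self):
        p = HamiltonianParams(c_B=1.0, c_L=10.0, mu=5)
        assert objective_direct([], p) == 0.0
        assert objective_direct([Stem(0, 12, 5)], p) == -25.0


class TestModelProperties:
    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_squared_sum_identity(self, seed):
        """With c_L = 0, no crossings, no overlaps: H = -c_B (sum k)^2."""
        rng = random.Random(seed)
        stemset = random_stemset(rng, 10)
        p = HamiltonianParams.for_stems(stemset, c_L=0.0, c_P=0.5)
        # grow a random compatible, non-crossing selection
        chosen: list[Stem] = []
        for s in stemset:
            if rng.random() < 0.5 and not any(
                is_overlap(s, c) or is_pseudoknot(s, c) for c in chosen
            ):
                chosen.append(s)
        total_k = sum(s.k for s in chosen)
        assert objective_direct(chosen, p) == pytest.approx(-1.0 * total_k**2)

    def test_cp_one_makes_crossing_indistinguishable(self):
        crossing = [Stem(0, 12, 3), Stem(6, 20, 3)]
        nested = [Stem(0, 20, 3), Stem(5, 15, 3)]
        assert is_pseudoknot(*crossing) and not is_pseudoknot(*nested)
        for pair in (crossing, nested):
            p = params_for(pair, c_P=1.0)
            assert quadratic_coefficient(pair[0], pair[1], p) == -18.0

    @pytest.mark.parametrize("seed", range(3))
    def test_overlap_configs_above_all_valid_configs(self, seed):
        rng = random.Random(seed)
        stemset = random_stemset(rng, 8)
        p = HamiltonianParams.for_stems(stemset)
        bqm = build_bqm(stemset, p)
        valid_energies, invalid_energies = [], []
        for bits in itertools.product((0, 1), repeat=len(stemset)):
            sel = [stemset[i] for i, b in enumerate(bits) if b]
            has_overlap = any(
                is_overlap(sel[a], sel[b])
                for a in range(len(sel))
                for b in range(a + 1, len(sel))
            )
            (invalid_energies if has_overlap else valid_energies).append(
                evaluate_energy(bqm, bits)
            )
        if invalid_energies:
            assert min(invalid_energies) > max(valid_energies)


class TestDecode:
    def test_zero_vector_decodes_empty(self):
        ss = enumerate_stems("GGGAAACCC")
        structure = decode_structure([0], ss)
        assert structure.pairs == frozenset()

    def test_single_stem_decodes_pairs(self):
        ss = enumerate_stems("GGGAAACCC")
        structure = decode_structure([1], ss)
        assert structure.pairs == {(0, 8), (1, 7), (2, 6)}

    def test_overlapping_selection_rejected(self):
        stems = [Stem(0, 9, 3), Stem(1, 8, 2)]
        stemset = make_stemset(stems)
        with pytest.raises(ValueError, match="overlap"):
            decode_structure([1, 1], stemset)

    def test_exact_optimum_of_full_scan(self, fig_sequence):
        """The decoded ground state matches the independent full scan."""
        ss = enumerate_stems(fig_sequence, 3, 3)
        p = HamiltonianParams.for_stems(ss)
        bqm = build_bqm(ss, p)
        bits, energy = full_scan_minimum(bqm)
        structure = decode_structure(bits, ss)
        # every selected stem's pairs appear in the decoded structure
        expected = frozenset(
            pair for i, b in enumerate(bits) if b for pair in ss[i].pairs()
        )
        assert structure.pairs == expected
        assert energy == evaluate_energy(bqm, bits)
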