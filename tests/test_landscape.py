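"""Landscape generation, scoring, enumeration and serialization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import helpers
from nkmix import (
    NKLandscape,
    bits_to_index,
    bits_to_string,
    enumerate_global_max,
    export_enumeration,
    generate_landscape,
    index_to_bits,
    read_landscape,
    string_to_bits,
    write_landscape,
)
from nkmix.landscape import CapacityError, LandscapeFormatError, ParameterError


class TestEncodings:
    def test_round_trip(self):
        for s in (0, 1, 37, 63):
            assert bits_to_index(index_to_bits(s, 6)) == s

    def test_string_convention_locus0_leftmost(self):
        bits = string_to_bits("100110")
        assert bits.tolist() == [1, 0, 0, 1, 1, 0]
        assert bits_to_string(bits) == "100110"
        # integer encoding: LSB = locus 0
        assert bits_to_index(bits) == 0b011001

    def test_rejects_non_binary(self):
        with pytest.raises(ParameterError):
            string_to_bits("10x1")


class TestStructure:
    def test_paper_scale_tables(self):
        land = generate_landscape(20, 5, seed=3)
        assert land.payoff_tables.shape == (20, 64)
        assert land.partners.shape == (20, 5)
        land.free_tables()

    def test_partner_invariants(self, small_landscape):
        n, k = small_landscape.n_loci, small_landscape.k_epistasis
        for i in range(n):
            row = small_landscape.partners[i]
            assert len(set(row.tolist())) == k
            assert i not in row
            assert row.min() >= 0 and row.max() < n

    def test_payoffs_in_unit_interval(self, small_landscape):
        t = small_landscape.payoff_tables
        assert t.shape == (6, 8)
        assert (t >= 0).all() and (t < 1).all()

    def test_single_locus_degenerate(self):
        land = generate_landscape(1, 0, seed=5)
        assert land.payoff_tables.shape == (1, 2)
        assert land.raw_global_max == pytest.approx(land.payoff_tables.max())

    def test_parameter_errors(self):
        with pytest.raises(ParameterError):
            generate_landscape(4, 4, seed=0)  # K > N-1
        with pytest.raises(ParameterError):
            generate_landscape(0, 0, seed=0)

    def test_enumeration_cap(self):
        with pytest.raises(CapacityError):
            generate_landscape(12, 2, seed=0, enumeration_cap=10)


class TestScoringOracle:
    @pytest.mark.parametrize("seed", range(5))
    def test_raw_score_matches_naive_loop(self, seed):
        land = generate_landscape(6, 2, seed=seed)
        for s in range(64):
            bits = index_to_bits(s, 6)
            assert land.raw_score(bits) == pytest.approx(
                helpers.naive_raw_score(land, bits), abs=1e-12
            )
            assert land.raw_table()[s] == pytest.approx(
                helpers.naive_raw_score(land, bits), abs=1e-12
            )

    @pytest.mark.parametrize("seed", range(5))
    def test_global_max_matches_naive_enumeration(self, seed):
        land = generate_landscape(6, 2, seed=seed)
        idx, val = helpers.naive_global_max(land)
        opt_bits, opt_val = enumerate_global_max(land)
        assert bits_to_index(opt_bits) == idx
        assert opt_val == pytest.approx(val, abs=1e-12)
        assert land.raw_global_max == pytest.approx(val, abs=1e-12)

    def test_hand_arithmetic_two_locus_additive(self):
        # N=2, K=0, tables [[0.2, 0.8], [0.4, 0.6]]: solution 11 -> (0.8+0.6)/2
        land = NKLandscape(
            n_loci=2,
            k_epistasis=0,
            partners=np.empty((2, 0), dtype=np.int64),
            payoff_tables=np.array([[0.2, 0.8], [0.4, 0.6]]),
        )
        assert land.raw_score([1, 1]) == pytest.approx(0.7)
        _, mx = enumerate_global_max(land)
        assert mx == pytest.approx(0.7)
        assert land.normalized_score([1, 1]) == pytest.approx(1.0)

    def test_component_score_worked_example(self):
        # locus 5 (1-indexed) depends on loci 2 and 16; the all-zero
        # configuration reads the hypothetical table value 0.15
        n, k = 16, 2
        rng = np.random.default_rng(0)
        partners = np.array([
            [(i + 1) % n, (i + 2) % n] for i in range(n)
        ], dtype=np.int64)
        partners[4] = [1, 15]  # 0-indexed locus 5's dependencies
        tables = rng.random((n, 8))
        tables[4, 0] = 0.15  # all-zero combination
        land = NKLandscape(n_loci=n, k_epistasis=k, partners=partners,
                           payoff_tables=tables)
        bits = np.zeros(n, dtype=np.uint8)
        assert land.component_score(bits, 4) == pytest.approx(0.15)

    def test_k0_component_depends_only_on_own_bit(self):
        land = generate_landscape(5, 0, seed=1)
        bits = np.zeros(5, dtype=np.uint8)
        other = bits.copy()
        other[1:] = 1
        assert land.component_score(bits, 0) == land.component_score(other, 0)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(data=st.data())
    def test_component_locality(self, small_landscape, data):
        """Flipping a bit outside locus+partners leaves the component unchanged."""
        land = small_landscape
        s = data.draw(st.integers(0, 63))
        locus = data.draw(st.integers(0, 5))
        dependent = {locus, *land.partners[locus].tolist()}
        free = sorted(set(range(6)) - dependent)
        if not free:
            return
        j = data.draw(st.sampled_from(free))
        bits = index_to_bits(s, 6)
        flipped = bits.copy()
        flipped[j] ^= 1
        assert land.component_score(bits, locus) == land.component_score(flipped, locus)

    def test_k0_optimum_is_concatenated_argmaxes(self):
        land = generate_landscape(6, 0, seed=9)
        opt_bits, _ = enumerate_global_max(land)
        expected = [int(np.argmax(land.payoff_tables[i])) for i in range(6)]
        assert opt_bits.tolist() == expected

    def test_length_mismatch_rejected(self, small_landscape):
        with pytest.raises(ParameterError):
            small_landscape.raw_score([0, 1])


class TestNormalization:
    def test_optimum_maps_to_one(self, small_landscape):
        opt_bits, _ = enumerate_global_max(small_landscape)
        assert small_landscape.normalized_score(opt_bits) == pytest.approx(1.0)
        norm = small_landscape.normalized_table()
        assert norm.max() == pytest.approx(1.0)
        assert ((norm >= 0) & (norm <= 1)).all()

    def test_tenth_power_closed_form(self, small_landscape):
        land = small_landscape
        for s in (3, 17, 40):
            ratio = land.raw_table()[s] / land.raw_global_max
            assert land.normalized_table()[s] == pytest.approx(ratio**10)

    def test_unset_global_max_raises(self):
        land = NKLandscape(
            n_loci=2,
            k_epistasis=0,
            partners=np.empty((2, 0), dtype=np.int64),
            payoff_tables=np.array([[0.2, 0.8], [0.4, 0.6]]),
        )
        with pytest.raises(RuntimeError):
            land.normalized_score([0, 1])

    def test_random_solutions_score_near_zero(self):
        """The 10th power makes the typical random solution far worse than 0.5."""
        land = generate_landscape(12, 3, seed=11)
        rng = np.random.default_rng(0)
        sample = rng.integers(1 << 12, size=500)
        median = float(np.median(land.normalized_table()[sample]))
        assert median < 0.1


class TestDeterminism:
    def test_same_seed_reconstructs_bit_identical(self):
        a = generate_landscape(6, 2, seed=77)
        b = generate_landscape(6, 2, seed=77)
        assert np.array_equal(a.partners, b.partners)
        assert np.array_equal(a.payoff_tables, b.payoff_tables)
        assert a.raw_global_max == b.raw_global_max

    def test_different_seed_differs(self):
        a = generate_landscape(6, 2, seed=77)
        b = generate_landscape(6, 2, seed=78)
        assert not np.array_equal(a.payoff_tables, b.payoff_tables)


class TestSerialization:
    def test_write_read_round_trip(self, tmp_path, small_landscape):
        path = tmp_path / "land.nk"
        write_landscape(small_landscape, path)
        back = read_landscape(path)
        assert back.n_loci == small_landscape.n_loci
        assert back.k_epistasis == small_landscape.k_epistasis
        assert back.exponent == small_landscape.exponent
        assert back.seed == small_landscape.seed
        assert back.raw_global_max == small_landscape.raw_global_max
        assert np.array_equal(back.partners, small_landscape.partners)
        assert np.array_equal(back.payoff_tables, small_landscape.payoff_tables)

    def test_full_dump_has_2_to_n_lines(self, tmp_path):
        land = generate_landscape(4, 1, seed=2)
        path = tmp_path / "dump.txt"
        export_enumeration(land, path)
        lines = path.read_text().splitlines()
        assert len(lines) == 16

    def test_dump_scores_match_native_file(self, tmp_path):
        land = generate_landscape(4, 1, seed=2)
        native = tmp_path / "land.nk"
        dump = tmp_path / "dump.txt"
        write_landscape(land, native)
        export_enumeration(land, dump)
        reread = read_landscape(native)
        for line in dump.read_text().splitlines():
            bit_str, score_str = line.split()
            assert float(score_str) == pytest.approx(
                reread.normalized_score(string_to_bits(bit_str)), abs=1e-12
            )

    def test_malformed_file_reports_line(self, tmp_path):
        path = tmp_path / "bad.nk"
        path.write_text("nkmix-landscape-v1\nn_loci 4\nwrong 2\n")
        with pytest.raises(LandscapeFormatError, match="line 3"):
            read_landscape(path)

    def test_bad_magic_rejected(self, tmp_path):
        path = tmp_path / "bad.nk"
        path.write_text("not-a-landscape\n")
        with pytest.raises(LandscapeFormatError, match="line 1"):
            read_landscape(path)
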