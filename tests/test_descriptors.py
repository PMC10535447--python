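import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import acps_assf as aa
from acps_assf.descriptors import _discretize_equal_frequency
import helpers

SEQUENCES = st.text(alphabet=aa.ALPHABET, min_size=1, max_size=60)


class TestBPF:
    @pytest.mark.parametrize(
        "sequence,expected_ones",
        [
            ("ACDEFGH", {0, 21, 42, 63, 84, 105, 126}),
            ("AAAAAAAA", {0, 20, 40, 60, 80, 100, 120}),  # 8th residue ignored
            ("KR", {8, 34}),
        ],
    )
    def test_one_hot_positions(self, sequence, expected_ones):
        v = aa.encode_bpf(sequence)
        assert v.shape == (140,)
        assert set(np.flatnonzero(v)) == expected_ones
        assert set(np.unique(v)) <= {0.0, 1.0}

    @settings(max_examples=50, derandomize=True)
    @given(SEQUENCES)
    def test_exactly_min7_L_ones(self, sequence):
        v = aa.encode_bpf(sequence)
        assert v.sum() == min(7, len(sequence))
        # at most one 1 per consecutive 20-wide block
        assert (v.reshape(7, 20).sum(axis=1) <= 1).all()


class TestOPE:
    def test_rank_times_40_plus_position(self):
        # D (rank 2) at position 5 -> 2*40+5 = 85
        v = aa.encode_ope("AAAAAD")
        assert v[5] == 85

    def test_padding_coded_minus_one(self):
        v = aa.encode_ope("A")
        assert v[0] == 0
        assert (v[1:] == -1).all()

    def test_truncation_beyond_40(self):
        v = aa.encode_ope("K" * 45)
        assert v.shape == (40,)
        assert (v >= 0).all()  # no padding entries

    @settings(max_examples=50, derandomize=True)
    @given(SEQUENCES)
    def test_value_range(self, sequence):
        v = aa.encode_ope(sequence)
        assert ((v == -1) | ((v >= 0) & (v <= 799))).all()
        # 799 occurs iff Y (rank 19) sits at position 39
        has_799 = 799 in v
        assert has_799 == (len(sequence) >= 40 and sequence[39] == "Y")


class TestCKSAAGP:
    def test_single_pair_k0(self):
        v = aa.encode_cksaagp("GF")  # G->G1, F->G2, one 0-spaced pair
        block0 = v[:25]
        assert block0[0 * 5 + 1] == 1.0  # (G1, G2)
        assert block0.sum() == 1.0
        assert (v[25:] == 0).all()  # L <= k+1 for k >= 1

    def test_two_spaced_pair(self):
        v = aa.encode_cksaagp("GGGG")
        k2 = v[2 * 25 : 3 * 25]
        assert k2[0] == 1.0 / (4 - 3)  # (G1,G1) count 1 over L-(k+1)=1

    @settings(max_examples=50, derandomize=True)
    @given(st.text(alphabet=aa.ALPHABET, min_size=7, max_size=60))
    def test_block_sums_to_one_when_defined(self, sequence):
        v = aa.encode_cksaagp(sequence)
        for bi in range(6):
            assert v[bi * 25 : (bi + 1) * 25].sum() == pytest.approx(1.0)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(500):
            seq = helpers.random_sequence(rng, int(rng.integers(2, 61)))
            np.testing.assert_allclose(
                aa.encode_cksaagp(seq), helpers.cksaagp_oracle(seq), atol=1e-12
            )


class TestAAC:
    def test_single_residue(self):
        v = aa.encode_aac("KK")
        assert v[aa.ALPHABET.index("K")] == 1.0
        assert v.sum() == 1.0

    def test_even_split(self):
        v = aa.encode_aac("ACACACAC")
        assert v[0] == 0.5 and v[1] == 0.5

    @settings(max_examples=50, derandomize=True)
    @given(SEQUENCES)
    def test_sums_to_one(self, sequence):
        assert aa.encode_aac(sequence).sum() == pytest.approx(1.0)

    def test_concatenation_is_count_weighted_mean(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(3, 30))
            s1 = helpers.random_sequence(rng, n)
            s2 = helpers.random_sequence(rng, n)
            np.testing.assert_allclose(
                aa.encode_aac(s1 + s2),
                (aa.encode_aac(s1) + aa.encode_aac(s2)) / 2,
                atol=1e-12,
            )


class TestIndexTable:
    def test_bundled_table_covers_all_residues(self, bundled_table):
        assert bundled_table.count >= 20
        assert bundled_table.values.shape == (bundled_table.count, 20)

    def test_too_few_scales_rejected(self):
        with pytest.raises(ValueError):
            aa.IndexTable(["only"], np.ones((1, 20)))

    def test_aaindex_flat_reader(self, tmp_path):
        flat = (
            "H TEST001\n"
            "D A test scale\n"
            "I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V\n"
            "     1.0     2.0     3.0     4.0     5.0     6.0     7.0     8.0     9.0    10.0\n"
            "    11.0    12.0    13.0    14.0    15.0    16.0    17.0    18.0    19.0    20.0\n"
            "//\n"
            "H TEST002\n"
            "I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V\n"
            "     0.0     0.0     0.0     0.0     0.0     0.0     0.0     0.0     0.0     0.0\n"
            "     1.0     1.0     1.0     1.0     1.0     1.0     1.0     1.0     1.0     1.0\n"
            "//\n"
        )
        p = tmp_path / "aaindex1"
        p.write_text(flat)
        table = aa.IndexTable.from_aaindex_flat(p)
        assert table.names == ["TEST001", "TEST002"]
        # A is first in the AAindex order, L first in the lower row
        assert table.values[0, aa.ALPHABET.index("A")] == 1.0
        assert table.values[0, aa.ALPHABET.index("L")] == 11.0
        assert table.values[0, aa.ALPHABET.index("V")] == 20.0


class TestAAIndexPositional:
    def test_printed_531_by_40_dimension(self):
        rng = np.random.default_rng(0)
        big = aa.IndexTable(
            [f"s{i}" for i in range(531)], rng.normal(size=(531, 20))
        )
        assert aa.encode_aaindex_positional("KLAK", big).shape == (21240,)

    def test_padding_positions_are_zero(self):
        table = aa.IndexTable(["a", "b"], np.ones((2, 20)))
        v = aa.encode_aaindex_positional("A", table)
        assert v.shape == (80,)
        grid = v.reshape(2, 40)
        assert (grid[:, 0] == 1.0).all()
        assert (grid[:, 1:] == 0.0).all()

    def test_constant_scale_maps_to_constant_row(self):
        table = aa.IndexTable(["c", "z"], np.vstack([np.full(20, 3.5), np.zeros(20)]))
        v = aa.encode_aaindex_positional("K" * 40, table).reshape(2, 40)
        assert (v[0] == 3.5).all()


class TestMRMR:
    def test_label_copy_selected_first(self):
        rng = np.random.default_rng(1)
        y = np.array([0, 1] * 50)
        X = rng.normal(size=(100, 5))
        X[:, 3] = y
        assert aa.mrmr_select(X, y, n_select=1) == [3]

    def test_redundancy_penalty_excludes_duplicate(self):
        """Two identical strong columns plus one weaker independent column:
        the second pick must be the weaker column, confirmed by brute-force
        evaluation of the MID score for every candidate."""
        rng = np.random.default_rng(2)
        n = 200
        y = np.array([0, 1] * (n // 2))
        strong = y * 2.0 + rng.normal(0, 0.05, n)
        weak = np.where(rng.random(n) < 0.25, 1 - y, y) + rng.normal(0, 0.05, n)
        X = np.column_stack([strong, strong.copy(), weak])
        picked = aa.mrmr_select(X, y, n_select=2, n_bins=5)
        assert picked[0] == 0  # tie between duplicates -> lowest index
        assert picked[1] == 2

        # independent brute force: discretize, then pick argmax MID
        codes = [
            np.searchsorted(np.quantile(X[:, j], np.arange(1, 5) / 5), X[:, j], side="left")
            for j in range(3)
        ]
        rel = [helpers.discrete_mi(c, y) for c in codes]
        first = int(np.argmax(rel))
        scores = {
            j: rel[j] - helpers.discrete_mi(codes[j], codes[first])
            for j in range(3)
            if j != first
        }
        second = max(scores, key=lambda j: (scores[j], -j))
        assert picked == [first, second]

    def test_select_all_returns_all(self):
        rng = np.random.default_rng(3)
        y = np.array([0, 1] * 20)
        X = rng.normal(size=(40, 4))
        assert sorted(aa.mrmr_select(X, y, n_select=4)) == [0, 1, 2, 3]

    def test_constant_labels_rejected(self):
        X = np.random.default_rng(0).normal(size=(20, 3))
        with pytest.raises(aa.descriptors.SelectionError):
            aa.mrmr_select(X, np.ones(20, dtype=int), n_select=1)

    def test_n_select_too_large(self):
        X = np.zeros((10, 2))
        with pytest.raises(ValueError):
            aa.mrmr_select(X, np.array([0, 1] * 5), n_select=3)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        n = 150
        y = rng.integers(0, 2, n)
        X = rng.normal(size=(n, 6))
        X[:, 0] += y * 2.0
        X[:, 2] += y * 1.0
        X[:, 4] -= y * 1.5
        base = aa.mrmr_select(X, y, n_select=3)
        perm = np.array([5, 3, 1, 0, 4, 2])  # new column j holds old column perm[j]
        Xp = X[:, perm]
        permuted = aa.mrmr_select(Xp, y, n_select=3)
        assert {perm[j] for j in permuted} == set(base)

    def test_binning_is_equal_frequency(self):
        col = np.arange(100, dtype=float)
        codes = _discretize_equal_frequency(col, 5)
        assert (np.bincount(codes) == 20).all()


class TestFittedEncoder:
    def test_total_width_400(self, fitted_state):
        assert fitted_state.layout.total_width == 400
        assert fitted_state.layout.widths == {
            "BPF": 140, "OPE": 40, "CKSAAGP": 150, "AAC": 20, "AAIF": 50
        }

    def test_encoding_deterministic(self, fitted_state):
        a = fitted_state.encode_sequence("KLAKLAKKLAKLAK")
        b = fitted_state.encode_sequence("KLAKLAKKLAKLAK")
        np.testing.assert_array_equal(a.values, b.values)

    def test_refit_is_deterministic(self, small_dataset, bundled_table):
        s1 = aa.fit_encoder(small_dataset, table=bundled_table)
        s2 = aa.fit_encoder(small_dataset, table=bundled_table)
        assert s1.aaif_columns == s2.aaif_columns

    def test_too_few_candidates_rejected(self, small_dataset):
        tiny = aa.IndexTable(["a", "b"], np.random.default_rng(0).normal(size=(2, 20)))
        with pytest.raises(ValueError):
            aa.fit_encoder(small_dataset, table=tiny, n_aaif=81)

    def test_encode_dataset_preserves_order_and_invariants(
        self, small_dataset, encoded_vectors
    ):
        assert len(encoded_vectors) == len(small_dataset)
        for record, vec in zip(small_dataset, encoded_vectors):
            assert vec.source_id == record.id
            aac = vec.segment("AAC")
            assert aac.sum() == pytest.approx(1.0)
            assert (aac >= 0).all() and (aac <= 1).all()
            bpf = vec.segment("BPF")
            assert set(np.unique(bpf)) <= {0.0, 1.0}
            assert (bpf.reshape(7, 20).sum(axis=1) <= 1).all()
            cks = vec.segment("CKSAAGP")
            L = len(record.sequence)
            for bi, k in enumerate(range(6)):
                if L > k + 1:
                    assert cks[bi * 25 : (bi + 1) * 25].sum() == pytest.approx(1.0)

    def test_segment_matches_standalone_encoder(self, fitted_state):
        vec = fitted_state.encode_sequence("GFKLAK")
        np.testing.assert_array_equal(
            vec.segment("CKSAAGP"), aa.encode_cksaagp("GFKLAK")
        )

    def test_state_roundtrip(self, fitted_state, tmp_path):
        p = tmp_path / "state.json"
        fitted_state.save(p)
        loaded = aa.EncoderState.load(p)
        a = fitted_state.encode_sequence("KLAKKLAK").values
        b = loaded.encode_sequence("KLAKKLAK").values
        np.testing.assert_array_equal(a, b)

    def test_unfitted_state_rejected(self, small_dataset):
        with pytest.raises(TypeError):
            aa.encode_dataset(small_dataset, state=None)
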