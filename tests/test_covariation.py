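import numpy as np
import pytest

from bridgescan import covariation as cov
from bridgescan.seqio import AlignmentBlock, SeqRecord
from bridgescan.simulate import FamilyTruth, gen_orthologue_family

from conftest import concordance_bruteforce, random_dna


def _block(rows):
    return AlignmentBlock([SeqRecord(f"r{i}", s) for i, s in enumerate(rows)])


def _paired(bridge_rows, partner_rows):
    return _block(bridge_rows), _block(partner_rows)


class TestProjectToReference:
    def test_gap_columns_dropped(self):
        block = _block(["A-CG", "TTTT", "GG-G"])
        out = cov.project_to_reference(block, "r0")
        assert out.width == 3
        assert [r.seq for r in out.rows] == ["ACG", "TTT", "G-G"]

    def test_gapfree_reference_is_identity(self):
        block = _block(["ACGT", "TGCA"])
        out = cov.project_to_reference(block, "r0")
        assert [r.seq for r in out.rows] == ["ACGT", "TGCA"]

    def test_all_gap_reference_warns_empty(self):
        block = _block(["----", "ACGT"])
        with pytest.warns(UserWarning):
            out = cov.project_to_reference(block, "r0")
        assert out.width == 0

    def test_missing_reference_raises(self):
        with pytest.raises(KeyError):
            cov.project_to_reference(_block(["AC"]), "nope")


class TestConcordance:
    def _single_column(self, pairs):
        """Build a 1x1-column paired alignment from (rna, dna) tuples,
        padded to the 10-row minimum with gap rows."""
        pad = 10 - len(pairs)
        bridge = [a for a, _ in pairs] + ["-"] * pad
        partner = [b for _, b in pairs] + ["-"] * pad
        return _paired(bridge, partner)

    def test_all_equal_gives_plus_one(self):
        b, t = self._single_column([("A", "A"), ("G", "G"), ("C", "C")])
        assert cov.concordance_matrix(b, t).C[0, 0] == pytest.approx(1.0)

    def test_all_complementary_gives_minus_one(self):
        b, t = self._single_column([("A", "T"), ("C", "G"), ("G", "C")])
        assert cov.concordance_matrix(b, t).C[0, 0] == pytest.approx(-1.0)

    def test_hand_enumerated_mixed_column(self):
        # match sum 1, complement sum -3 -> C = -0.75
        b, t = self._single_column([("A", "A"), ("A", "T"), ("C", "G"),
                                    ("G", "C")])
        cm = cov.concordance_matrix(b, t)
        assert cm.C[0, 0] == pytest.approx(-0.75)
        assert cm.n_eff[0, 0] == 4

    def test_gap_rows_discounted_from_n(self):
        b, t = self._single_column([("A", "A"), ("A", "-"), ("-", "T")])
        cm = cov.concordance_matrix(b, t)
        assert cm.n_eff[0, 0] == 1 and cm.C[0, 0] == pytest.approx(1.0)

    def test_ambiguity_codes_excluded(self):
        b, t = self._single_column([("A", "A"), ("N", "A"), ("A", "N")])
        assert cov.concordance_matrix(b, t).n_eff[0, 0] == 1

    def test_absmax_tie_returns_positive_and_flags(self):
        b, t = self._single_column([("A", "A"), ("A", "T")])
        cm = cov.concordance_matrix(b, t)
        assert cm.C[0, 0] == pytest.approx(0.5)
        assert cm.tie[0, 0]

    def test_matches_bruteforce_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(5)
        for _ in range(3):
            bridge = [random_dna(rng, 12) for _ in range(25)]
            partner = [random_dna(rng, 9) for _ in range(25)]
            b, t = _paired(bridge, partner)
            expected = concordance_bruteforce(bridge, partner)
            np.testing.assert_allclose(cov.concordance_matrix(b, t).C,
                                       expected, atol=1e-6)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(6)
        bridge = [random_dna(rng, 8) for _ in range(20)]
        partner = [random_dna(rng, 8) for _ in range(20)]
        b, t = _paired(bridge, partner)
        C1 = cov.concordance_matrix(b, t).C
        b2 = _block(list(reversed(bridge)))
        t2 = _block(list(reversed(partner)))
        # re-id so row ids still match pairwise
        C2 = cov.concordance_matrix(b2, t2).C
        np.testing.assert_allclose(C1, C2)

    def test_row_id_mismatch_rejected(self):
        b = _block(["A"] * 10)
        t = AlignmentBlock([SeqRecord(f"x{i}", "A") for i in range(10)])
        with pytest.raises(ValueError, match="row ids"):
            cov.concordance_matrix(b, t)

    def test_wobble_option_counts_gu_pairs(self):
        b, t = self._single_column([("G", "T"), ("G", "T"), ("T", "G")])
        strict = cov.concordance_matrix(b, t).C[0, 0]
        loose = cov.concordance_matrix(b, t, wobble=True).C[0, 0]
        assert strict == pytest.approx(0.0) or np.isnan(strict)
        assert loose == pytest.approx(-1.0)


class TestPermutationNull:
    def test_invalid_mode_and_small_nperm_rejected(self, small_family):
        _, b, t, _ = small_family
        with pytest.raises(ValueError):
            cov.permutation_null_z(b, t, mode="diagonal")
        with pytest.raises(ValueError):
            cov.permutation_null_z(b, t, n_perm=0)

    def test_deterministic_under_seed(self, small_family):
        _, b, t, _ = small_family
        z1 = cov.permutation_null_z(b, t, mode="rows", n_perm=120, seed=3).z
        z2 = cov.permutation_null_z(b, t, mode="rows", n_perm=120, seed=3).z
        np.testing.assert_array_equal(np.nan_to_num(z1), np.nan_to_num(z2))

    def test_planted_cells_stand_out_of_row_null(self, small_family):
        truth, b, t, _ = small_family
        cm = cov.permutation_null_z(b, t, mode="rows", n_perm=300, seed=0)
        for m in range(truth.geometry.ltg_len):
            assert cm.z[truth.ltg_start + m, truth.site_start + m] > 5

    def test_null_family_z_is_calibrated(self):
        truth = FamilyTruth.random(3, n_orthologues=300, coupling=0.0)
        b, t, _ = gen_orthologue_family(truth)
        cm = cov.permutation_null_z(b, t, mode="rows", n_perm=1000, seed=1)
        z = cm.z[np.isfinite(cm.z)]
        assert abs(z.mean()) < 0.1
        assert abs(z.std() - 1) < 0.15


class TestSignedMinmax:
    def test_positive_scaling(self):
        np.testing.assert_allclose(cov.signed_minmax(np.array([2.0, 4.0])),
                                   [0.5, 1.0])

    def test_mixed_signs(self):
        np.testing.assert_allclose(
            cov.signed_minmax(np.array([-1.0, -4.0, 2.0])),
            [-0.25, -1.0, 1.0])

    def test_single_value_maps_to_one(self):
        np.testing.assert_allclose(cov.signed_minmax(np.array([7.0])), [1.0])

    def test_zeros_preserved_and_idempotent(self):
        v = np.array([-2.0, 0.0, 1.0, 3.0])
        out = cov.signed_minmax(v)
        assert out[1] == 0.0
        np.testing.assert_allclose(cov.signed_minmax(out), out)

    def test_monotone_and_sign_preserving(self, rng):
        v = rng.normal(size=50)
        out = cov.signed_minmax(v)
        assert np.all(np.sign(out) == np.sign(v))
        order = np.argsort(v)
        assert np.all(np.diff(out[order]) >= -1e-12)

    def test_all_masked_rejected(self):
        with pytest.raises(ValueError):
            cov.signed_minmax(np.array([np.nan, np.nan]))


class TestCovariationMatrix:
    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(8)
        bridge = [random_dna(rng, 4) for _ in range(1000)]
        partner = [random_dna(rng, 4) for _ in range(1000)]
        b, t = _paired(bridge, partner)
        raw = cov.covariation_matrix(b, t)
        assert raw.max() < 0.02          # nats

    def test_perfect_copy_is_matrix_maximum(self):
        rng = np.random.default_rng(9)
        bridge = [random_dna(rng, 6) for _ in range(400)]
        partner = [row[2] + random_dna(rng, 5) for row in bridge]
        b, t = _paired(bridge, partner)
        raw = cov.covariation_matrix(b, t)
        assert np.unravel_index(raw.argmax(), raw.shape) == (2, 0)

    def test_external_matrix_shape_checked(self, tmp_path, small_family):
        _, b, t, _ = small_family
        bad = tmp_path / "m.txt"
        np.savetxt(bad, np.zeros((3, 3)))
        with pytest.raises(ValueError, match="shape"):
            cov.covariation_matrix(b, t, method="external", external_path=bad)

    def test_external_zero_matrix_loads(self, tmp_path, small_family):
        _, b, t, _ = small_family
        path = tmp_path / "m.txt"
        np.savetxt(path, np.zeros((b.width, t.width)))
        raw = cov.covariation_matrix(b, t, method="external",
                                     external_path=path)
        assert raw.shape == (b.width, t.width) and not raw.any()


class TestSignedMapAndSegments:
    def test_sign_projection(self):
        raw = np.array([[4.0, 1.0], [0.0, 2.0]])
        conc = cov.ConcordanceMatrix(
            C=np.zeros((2, 2)), n_eff=np.full((2, 2), 10),
            match_sum=np.zeros((2, 2)), comp_sum=np.zeros((2, 2)),
            tie=np.zeros((2, 2), bool),
            z=np.array([[-1.0, 2.0], [np.nan, 3.0]]))
        sm = cov.signed_covariation_map(raw, conc)
        assert sm.signed[0, 0] == pytest.approx(-1.0)   # max cell, z < 0
        assert sm.sign_source[1, 0] == 0 and sm.signed[1, 0] == 0

    def test_all_masked_z_gives_zero_map(self):
        raw = np.ones((2, 2))
        conc = cov.ConcordanceMatrix(
            C=np.zeros((2, 2)), n_eff=np.zeros((2, 2)),
            match_sum=np.zeros((2, 2)), comp_sum=np.zeros((2, 2)),
            tie=np.zeros((2, 2), bool), z=np.full((2, 2), np.nan))
        sm = cov.signed_covariation_map(raw, conc)
        assert not sm.signed.any() and not sm.sign_source.any()

    def test_shape_mismatch_rejected(self):
        conc = cov.ConcordanceMatrix(
            C=np.zeros((2, 2)), n_eff=np.zeros((2, 2)),
            match_sum=np.zeros((2, 2)), comp_sum=np.zeros((2, 2)),
            tie=np.zeros((2, 2), bool), z=np.zeros((2, 2)))
        with pytest.raises(ValueError):
            cov.signed_covariation_map(np.zeros((3, 2)), conc)

    def test_all_zero_matrix_yields_no_segments(self):
        assert cov.detect_guide_segments(np.zeros((20, 20))) == []

    def test_unsatisfiable_threshold_yields_no_segments(self):
        m = np.ones((20, 20))
        assert cov.detect_guide_segments(m, threshold=1.01) == []

    def test_diagonal_run_detected_with_strand(self):
        m = np.zeros((20, 20))
        for k in range(6):
            m[3 + k, 8 + k] = 0.9          # bottom strand diagonal
            m[12 + k, 15 - k] = -0.8       # top strand anti-diagonal
        segs = cov.detect_guide_segments(m, min_run=4, threshold=0.5)
        assert len(segs) == 2
        bottom = next(s for s in segs if s.strand == "bottom")
        top = next(s for s in segs if s.strand == "top")
        assert (bottom.rna_start, bottom.rna_end) == (3, 9)
        assert (bottom.dna_start, bottom.dna_end) == (8, 14)
        assert (top.rna_start, top.rna_end) == (12, 18)
        assert (top.dna_start, top.dna_end) == (10, 16)

    def test_structure_restricts_to_loop_positions(self):
        m = np.zeros((10, 10))
        for k in range(6):
            m[2 + k, 2 + k] = 1.0
        structure = "((......))"
        segs = cov.detect_guide_segments(m, min_run=4, threshold=0.5,
                                         structure=structure)
        assert len(segs) == 1
        assert segs[0].rna_start >= 2 and segs[0].rna_end <= 8

    def test_min_run_precondition(self):
        with pytest.raises(ValueError):
            cov.detect_guide_segments(np.zeros((4, 4)), min_run=1)
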