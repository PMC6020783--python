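import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import erptopo as et
from erptopo.core import (FormatError, average_reference, gfp, grand_mean,
                          normalize_by_gfp, read_erp_matrix, read_montage,
                          window_to_samples)

maps_strategy = arrays(np.float64, st.tuples(st.integers(2, 12)),
                       elements=st.floats(-50, 50, allow_nan=False,
                                          width=32))


class TestReadErpMatrix:
    def test_identity_read(self, tmp_path):
        p = tmp_path / "m.asc"
        p.write_text("1 2\n3 4\n")
        m = read_erp_matrix(p)
        np.testing.assert_array_equal(m.samples, [[1, 2], [3, 4]])

    def test_transpose(self, tmp_path):
        p = tmp_path / "m.asc"
        p.write_text("1 2\n3 4\n")
        m = read_erp_matrix(p, transpose=True)
        np.testing.assert_array_equal(m.samples, [[1, 3], [2, 4]])

    def test_ragged_rows_name_the_line(self, tmp_path):
        p = tmp_path / "m.asc"
        p.write_text("1 2\n3 4 5\n")
        with pytest.raises(FormatError, match="line 2"):
            read_erp_matrix(p)

    def test_non_numeric_names_location(self, tmp_path):
        p = tmp_path / "m.asc"
        p.write_text("1 2\n3 oops\n")
        with pytest.raises(FormatError, match="line 2, column 2"):
            read_erp_matrix(p)


class TestMontage:
    def test_header_dialect(self, tmp_path):
        p = tmp_path / "m.xyz"
        p.write_text("2\n0 0 1 Cz\n1 0 0 T8\n")
        m = read_montage(p)
        assert m.labels == ("Cz", "T8")
        np.testing.assert_array_equal(m.positions,
                                      [[0, 0, 1], [1, 0, 0]])

    def test_headerless_dialect_autogenerates_labels(self, tmp_path):
        p = tmp_path / "m.xyz"
        p.write_text("0 0 1\n1 0 0\n")
        m = read_montage(p)
        assert m.labels == ("Ch1", "Ch2")

    def test_channel_count_mismatch_with_data(self, tmp_path, rng):
        p = tmp_path / "m.xyz"
        p.write_text("0 0 1\n1 0 0\n0 1 0\n")
        montage = read_montage(p)
        with pytest.raises(ValueError, match="montage has 3"):
            et.ErpDataset(rng.standard_normal((2, 1, 4, 2)), ("a", "b"),
                          ("X",), montage=montage)


class TestImportDataset:
    def _write(self, folder, name, text="1 2\n3 4\n"):
        (folder / name).write_text(text)

    def test_full_grid(self, tmp_path):
        for s in ("S01", "S02"):
            for c in ("C1", "F1"):
                self._write(tmp_path, f"{s}_{c}.asc")
        ds = et.import_dataset(tmp_path, "*_C1.asc", ["C1", "F1"],
                               do_average_reference=False)
        assert ds.subject_ids == ("S01", "S02")
        assert ds.n_conditions == 2 and ds.n_timepoints == 2

    def test_missing_cell_is_named(self, tmp_path):
        for s in ("S01", "S02"):
            for c in ("C1", "F1"):
                self._write(tmp_path, f"{s}_{c}.asc")
        (tmp_path / "S02_F1.asc").unlink()
        with pytest.raises(FileNotFoundError, match=r"\(S02, F1\)"):
            et.import_dataset(tmp_path, "*_C1.asc", ["C1", "F1"])

    def test_inconsistent_dimensions(self, tmp_path):
        self._write(tmp_path, "S01_C1.asc")
        self._write(tmp_path, "S01_F1.asc", "1 2 3\n4 5 6\n")
        with pytest.raises(FormatError, match="matrix is"):
            et.import_dataset(tmp_path, "*_C1.asc", ["C1", "F1"])

    def test_import_average_references(self, tmp_path):
        self._write(tmp_path, "S01_C1.asc", "3 1\n5 1\n")
        ds = et.import_dataset(tmp_path, "*_C1.asc", ["C1"])
        assert np.allclose(ds.data.mean(axis=-1), 0)


class TestGfp:
    @pytest.mark.parametrize("values, expected", [
        ([1, -1], 1.0),
        ([5, 5, 5], 0.0),
        ([2, 0, -2, 0], np.sqrt(2)),
    ])
    def test_closed_forms(self, values, expected):
        assert gfp(np.asarray(values, float)) == pytest.approx(expected,
                                                               abs=1e-12)

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            gfp(np.array([1.0]))

    @given(maps_strategy)
    @settings(deadline=None, max_examples=50)
    def test_equals_population_standard_deviation(self, v):
        manual = np.sqrt(((v - v.mean()) ** 2).sum() / v.size)
        assert gfp(v) == pytest.approx(manual, abs=1e-12)


class TestAverageReference:
    def test_examples(self):
        np.testing.assert_allclose(average_reference(np.array([3.0, 1.0])),
                                   [1, -1])
        np.testing.assert_allclose(
            average_reference(np.array([5.0, 5.0, 5.0])), [0, 0, 0])

    @given(maps_strategy)
    @settings(deadline=None, max_examples=50)
    def test_idempotent_and_difference_preserving(self, v):
        once = average_reference(v)
        np.testing.assert_allclose(average_reference(once), once,
                                   atol=1e-10)
        # all pairwise channel differences survive re-referencing
        np.testing.assert_allclose(np.subtract.outer(once, once),
                                   np.subtract.outer(v, v), atol=1e-9)


class TestNormalizeByGfp:
    def test_examples(self):
        out, n = normalize_by_gfp(np.array([[2.0, -2.0]]))
        np.testing.assert_allclose(out, [[1, -1]])
        assert n == 0

    def test_degenerate_map_becomes_zero_with_warning(self):
        with pytest.warns(RuntimeWarning, match="1 map"):
            out, n = normalize_by_gfp(np.array([[0.0, 0.0], [1.0, -1.0]]))
        assert n == 1
        np.testing.assert_array_equal(out[0], [0, 0])

    def test_unit_gfp_after_normalization(self, rng):
        maps = rng.standard_normal((20, 8))
        out, _ = normalize_by_gfp(average_reference(maps))
        np.testing.assert_allclose(gfp(out), 1.0, atol=1e-12)


class TestGrandMean:
    def test_two_subject_mean(self):
        data = np.array([[[[1.0, -1.0]]], [[[3.0, -3.0]]]])
        ds = et.ErpDataset(data, ("a", "b"), ("X",))
        np.testing.assert_allclose(grand_mean(ds).samples, [[2, -2]])

    def test_single_subject_identity(self, small_dataset):
        gm = grand_mean(small_dataset, subjects=["s2"],
                        condition_weights=[1.0, 0.0])
        np.testing.assert_allclose(gm.samples, small_dataset.data[1, 0])

    def test_condition_weighting(self, small_dataset):
        gm = grand_mean(small_dataset, condition_weights=[0.5, 0.5])
        np.testing.assert_allclose(
            gm.samples, small_dataset.data.mean(axis=0).mean(axis=0))

    def test_linearity_over_disjoint_subject_sets(self, small_dataset):
        ga = grand_mean(small_dataset, subjects=["s1", "s2"]).samples
        gb = grand_mean(small_dataset, subjects=["s3", "s4"]).samples
        gall = grand_mean(small_dataset).samples
        np.testing.assert_allclose((ga + gb) / 2, gall, atol=1e-12)

    def test_empty_subset_rejected(self, small_dataset):
        with pytest.raises(ValueError, match="empty"):
            grand_mean(small_dataset, subjects=[])


class TestArchive:
    def test_round_trip_bit_exact(self, tmp_path, rng):
        ds, _ = et.generate_dataset(et.SyntheticSpec(
            n_subjects=3, n_channels=8, n_timepoints=10, n_templates=2,
            seed=5))
        et.export_dataset(ds, tmp_path / "arc")
        back = et.load_dataset(tmp_path / "arc")
        assert np.array_equal(back.data, ds.data)
        assert back.subject_ids == ds.subject_ids
        assert back.dt == ds.dt
        assert back.montage.labels == ds.montage.labels


def test_window_to_samples_inclusive_nearest():
    assert window_to_samples((0, 12), 4.0, 0.0, 10) == (0, 3)
    assert window_to_samples((7, 9), 4.0, 0.0, 10) == (2, 2)
    with pytest.raises(ValueError):
        window_to_samples((100, 200), 4.0, 0.0, 10)
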