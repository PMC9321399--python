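import numpy as np
import pandas as pd
import pytest

from npxpred import ingest
from npxpred.ingest import (
    ReferenceStats,
    apply_qc,
    impute_knn,
    mask_below_lod,
    read_npx,
    standardize,
    standardize_new,
    write_npx,
)

from conftest import make_dataset


class TestReadNpx:
    def test_wide_shape(self, tmp_path):
        path = tmp_path / "npx.csv"
        path.write_text(
            "sample_id,p1:A,p2:A\ns1,1.0,2.0\ns2,1.5,2.5\ns3,2.0,3.0\n"
        )
        ds = read_npx(path, layout="wide")
        assert ds.shape == (3, 2)
        assert ds.sample_ids == ["s1", "s2", "s3"]

    def test_long_matches_wide(self, tmp_path):
        wide = tmp_path / "wide.csv"
        wide.write_text("sample_id,p1:A,p2:B\ns1,1.0,2.0\ns2,1.5,2.5\n")
        rows = ["sample_id,protein,panel,npx,lod,qc_warning"]
        for s, (v1, v2) in [("s1", (1.0, 2.0)), ("s2", (1.5, 2.5))]:
            rows.append(f"{s},p1,A,{v1},0.1,0")
            rows.append(f"{s},p2,B,{v2},0.2,0")
        long = tmp_path / "long.csv"
        long.write_text("\n".join(rows) + "\n")
        ds_w = read_npx(wide, layout="wide")
        ds_l = read_npx(long, layout="long")
        assert ds_l.protein_ids == ds_w.protein_ids
        np.testing.assert_array_equal(ds_l.values, ds_w.values)

    def test_duplicate_sample_id_errors(self, tmp_path):
        path = tmp_path / "npx.csv"
        path.write_text("sample_id,p1:A\ns1,1.0\ns1,2.0\n")
        with pytest.raises(ValueError, match="repeated sample"):
            read_npx(path, layout="wide")

    def test_duplicate_long_row_errors(self, tmp_path):
        path = tmp_path / "long.csv"
        path.write_text(
            "sample_id,protein,panel,npx,lod,qc_warning\n"
            "s1,p1,A,1.0,0.1,0\ns1,p1,A,1.1,0.1,0\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            read_npx(path, layout="long")

    def test_tsv_autodetected(self, tmp_path):
        path = tmp_path / "npx.tsv"
        path.write_text("sample_id\tp1:A\ns1\t1.0\ns2\t2.0\n")
        assert read_npx(path, layout="wide").shape == (2, 1)

    def test_roundtrip_write_read(self, tmp_path):
        ds = make_dataset([[1.0, 2.0], [3.0, 4.0]], lod=[0.5, 0.5])
        write_npx(ds, tmp_path / "n.csv", tmp_path / "l.csv", tmp_path / "q.csv")
        back = read_npx(
            tmp_path / "n.csv",
            layout="wide",
            lod_path=tmp_path / "l.csv",
            qc_path=tmp_path / "q.csv",
        )
        np.testing.assert_allclose(back.values, ds.values)
        np.testing.assert_allclose(back.lod, ds.lod)


class TestApplyQc:
    def test_no_flags_identity(self):
        ds = make_dataset([[1.0, 2.0], [3.0, 4.0]])
        out = apply_qc(ds)
        assert not out.missing_mask.any()

    def test_flag_masks_panel_cells(self):
        # s1 flagged on panel A; 2 proteins on A, 1 on B
        ds = make_dataset(
            [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]],
            panels=["A", "A", "B"],
            qc=[("s1", "A")],
        )
        out = apply_qc(ds)
        assert out.missing_mask.sum() == 2
        assert out.missing_mask[0, 0] and out.missing_mask[0, 1]
        assert not out.missing_mask[0, 2]
        np.testing.assert_array_equal(out.values, ds.values)

    def test_all_flagged_saturates(self):
        ds = make_dataset(
            [[1.0, 2.0], [3.0, 4.0]],
            panels=["A", "B"],
            qc=[(s, p) for s in ("s1", "s2") for p in ("A", "B")],
        )
        assert apply_qc(ds).missing_mask.all()


class TestMaskBelowLod:
    def test_identity_when_above(self):
        ds = make_dataset([[1.0, 2.0], [3.0, 4.0]], lod=[0.5, 0.5])
        out = mask_below_lod(ds)
        assert out.missing_fraction == 0.0

    def test_fraction_counts(self, rng):
        values = rng.uniform(5, 10, size=(20, 10))  # 200 cells
        values[0, 0] = values[3, 4] = values[7, 9] = 0.0  # 3 below LoD
        ds = make_dataset(values, lod=np.full(10, 1.0))
        out = mask_below_lod(ds)
        assert out.missing_mask.sum() == 3
        assert out.missing_fraction == pytest.approx(0.015)

    def test_equal_to_lod_retained(self):
        ds = make_dataset([[1.0], [2.0]], lod=[1.0])
        assert not mask_below_lod(ds).missing_mask.any()

    def test_missing_lod_errors(self):
        ds = make_dataset([[1.0], [2.0]], lod=[np.nan])
        with pytest.raises(ValueError, match="LoD"):
            mask_below_lod(ds)


class TestImputeKnn:
    def test_constant_column(self):
        values = np.full((5, 2), 1.7)
        values[2, 1] = np.nan
        ds = make_dataset(values)
        for k in (1, 2, 4):
            out = impute_knn(ds, k=k)
            assert out.values[2, 1] == pytest.approx(1.7)

    def test_matches_bruteforce_oracle(self):
        # 4-sample toy, one missing cell, k = 2
        values = np.array(
            [
                [1.0, 2.0, 3.0],
                [2.0, 2.5, 4.0],
                [9.0, 9.0, 9.0],
                [1.2, 2.2, np.nan],
            ]
        )
        ds = make_dataset(values)
        out = impute_knn(ds, k=2)
        # oracle: Euclidean distance over the two observed columns
        dists = [
            np.sqrt(((values[i, :2] - values[3, :2]) ** 2).sum())
            for i in range(3)
        ]
        nearest = np.argsort(dists)[:2]
        expected = values[nearest, 2].mean()
        assert out.values[3, 2] == pytest.approx(expected)

    def test_complete_matrix_identity(self, rng):
        ds = make_dataset(rng.normal(size=(6, 4)))
        out = impute_knn(ds, k=3)
        np.testing.assert_array_equal(out.values, ds.values)

    def test_all_missing_sample_errors(self, rng):
        values = rng.normal(size=(12, 2))
        values[3, :] = np.nan  # 2/24 cells missing, below the ceiling
        with pytest.raises(ValueError, match="all proteins missing"):
            impute_knn(make_dataset(values), k=1)

    def test_missing_ceiling(self, rng):
        values = rng.normal(size=(4, 4))
        values[:2, :2] = np.nan  # 25% missing
        with pytest.raises(ValueError, match="ceiling"):
            impute_knn(make_dataset(values), k=2)

    def test_observed_cells_untouched_and_bounded(self, rng):
        values = rng.normal(size=(10, 5))
        mask = rng.random((10, 5)) < 0.08
        mask[0] = False  # keep one full row
        vals = values.copy()
        vals[mask] = np.nan
        ds = make_dataset(vals)
        out = impute_knn(ds, k=3)
        np.testing.assert_array_equal(out.values[~mask], values[~mask])
        for i, j in zip(*np.nonzero(mask)):
            col = vals[:, j][~np.isnan(vals[:, j])]
            assert col.min() <= out.values[i, j] <= col.max()


class TestStandardize:
    def test_symmetric_column(self):
        ds = make_dataset([[1.0], [2.0], [3.0]])
        z, ref = standardize(ds)
        np.testing.assert_allclose(z.to_numpy().ravel(), [-1.0, 0.0, 1.0])
        assert ref.mean[0] == pytest.approx(2.0)

    def test_columns_normalised(self, rng):
        ds = make_dataset(rng.normal(3, 2, size=(20, 5)))
        z, _ = standardize(ds)
        assert np.abs(z.mean(axis=0)).max() < 1e-10
        assert np.abs(z.std(axis=0, ddof=1) - 1).max() < 1e-10

    def test_round_trip(self, rng):
        ds = make_dataset(rng.normal(3, 2, size=(15, 4)))
        z, ref = standardize(ds)
        back = z.to_numpy() * ref.sd + ref.mean
        np.testing.assert_allclose(back, ds.values, atol=1e-12)

    def test_zero_variance_errors(self):
        ds = make_dataset([[1.0, 5.0], [2.0, 5.0]])
        with pytest.raises(ValueError, match="prot2"):
            standardize(ds)

    def test_incomplete_errors(self):
        ds = make_dataset([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError, match="complete"):
            standardize(ds)

    def test_restandardize_is_identity(self, rng):
        ds = make_dataset(rng.normal(size=(12, 3)))
        z1, _ = standardize(ds)
        ds2 = make_dataset(z1.to_numpy())
        z2, _ = standardize(ds2)
        np.testing.assert_allclose(z2.to_numpy(), z1.to_numpy(), atol=1e-10)


class TestStandardizeNew:
    @pytest.fixture()
    def ref(self):
        return ReferenceStats(
            feature_ids=("a", "b", "c"),
            mean=np.array([1.0, 2.0, 3.0]),
            sd=np.array([0.5, 1.0, 2.0]),
            n_cohort=10,
        )

    def test_means_give_zero(self, ref):
        z = standardize_new({"a": 1.0, "b": 2.0, "c": 3.0}, ref)
        np.testing.assert_allclose(z, 0.0)

    def test_one_sd_above(self, ref):
        z = standardize_new({"a": 1.5, "b": 3.0, "c": 5.0}, ref)
        np.testing.assert_allclose(z, 1.0)

    def test_formula(self, ref, rng):
        record = {f: float(rng.normal()) for f in ("a", "b", "c")}
        z = standardize_new(record, ref)
        expected = (np.array([record["a"], record["b"], record["c"]]) - ref.mean) / ref.sd
        np.testing.assert_allclose(z, expected)

    def test_missing_feature_errors(self, ref):
        with pytest.raises(ValueError, match="'c'"):
            standardize_new({"a": 1.0, "b": 2.0}, ref)

    def test_extra_feature_warns(self, ref):
        with pytest.warns(UserWarning, match="unknown"):
            standardize_new({"a": 1.0, "b": 2.0, "c": 3.0, "d": 9.0}, ref)


class TestProperties:
    def test_qc_lod_idempotent_and_commute(self, rng):
        values = rng.normal(5, 1, size=(6, 4))
        values[1, 2] = -10.0
        ds = make_dataset(
            values, panels=["A", "A", "B", "B"], lod=np.zeros(4), qc=[("s3", "A")]
        )
        ab = mask_below_lod(apply_qc(ds))
        ba = apply_qc(mask_below_lod(ds))
        np.testing.assert_array_equal(ab.missing_mask, ba.missing_mask)
        np.testing.assert_array_equal(
            apply_qc(apply_qc(ds)).missing_mask, apply_qc(ds).missing_mask
        )
        np.testing.assert_array_equal(
            mask_below_lod(mask_below_lod(ds)).missing_mask,
            mask_below_lod(ds).missing_mask,
        )

    def test_pipeline_preserves_dims(self, paper_cohort):
        ds, _, _ = paper_cohort
        out = ingest.standardize(
            ingest.impute_knn(ingest.mask_below_lod(ingest.apply_qc(ds)))
        )[0]
        assert out.shape == ds.shape
        assert np.isfinite(out.to_numpy()).all()
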