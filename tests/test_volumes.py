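"""Data model, rasterization, resampling, margins, and I/O round trips."""

import numpy as np
import pytest

from contourdose import (
    ContourSet,
    ContourSlice,
    DoseGrid,
    GridSpec,
    StructureMask,
    expand_margin,
    rasterize_contours,
    read_dose,
    read_structures,
    resample_dose,
    write_dose,
    write_structures,
)
from contourdose.errors import (
    ConfigurationError,
    DegenerateContourError,
    InvalidArgumentError,
    InvalidGridError,
    OutOfExtentError,
    ParseError,
)

from conftest import make_mask


class TestGridSpec:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(shape=(0, 4, 4), spacing=(1, 1, 1)),
            dict(shape=(4, 4, 4), spacing=(0, 1, 1)),
            dict(shape=(4, 4, 4), spacing=(1, -2, 1)),
        ],
    )
    def test_invalid_grid_rejected(self, kwargs):
        with pytest.raises(InvalidGridError):
            GridSpec(**kwargs)

    def test_voxel_volume_cc(self):
        g = GridSpec(shape=(2, 2, 2), spacing=(2.0, 2.5, 5.0))
        assert g.voxel_volume_cc == pytest.approx(2 * 2.5 * 5 / 1000)

    def test_dose_rejects_negative_and_shape_mismatch(self, unit_grid):
        with pytest.raises(InvalidArgumentError):
            DoseGrid(grid=unit_grid, values=-np.ones(unit_grid.shape))
        with pytest.raises(InvalidGridError):
            DoseGrid(grid=unit_grid, values=np.zeros((2, 2, 2)))


class TestRasterize:
    def test_empty_contour_set(self, unit_grid):
        mask = rasterize_contours(ContourSet(name="e"), unit_grid)
        assert mask.is_empty and mask.volume_cc == 0.0

    def test_square_enclosing_four_centers(self, unit_grid):
        # voxel centers at integer mm; square (1.5..3.5)² encloses centers 2,3
        square = [[1.5, 1.5], [3.5, 1.5], [3.5, 3.5], [1.5, 3.5]]
        mask = rasterize_contours(
            ContourSet(name="sq", slices=[ContourSlice(z=2.0, polygons=[square])]), unit_grid
        )
        assert mask.voxel_count == 4
        assert mask.voxels[2:4, 2:4, 2].all()

    def test_shrunk_square_encloses_no_center(self, unit_grid):
        square = [[2.2, 2.2], [2.8, 2.2], [2.8, 2.8], [2.2, 2.8]]
        mask = rasterize_contours(
            ContourSet(name="sq", slices=[ContourSlice(z=2.0, polygons=[square])]), unit_grid
        )
        assert mask.is_empty

    def test_even_odd_hole(self, unit_grid):
        outer = [[0.5, 0.5], [6.5, 0.5], [6.5, 6.5], [0.5, 6.5]]
        inner = [[2.5, 2.5], [4.5, 2.5], [4.5, 4.5], [2.5, 4.5]]
        mask = rasterize_contours(
            ContourSet(name="ring", slices=[ContourSlice(z=0.0, polygons=[outer, inner])]),
            unit_grid,
        )
        assert mask.voxels[1, 1, 0] and not mask.voxels[3, 3, 0]

    def test_degenerate_polygon(self, unit_grid):
        cs = ContourSet(name="bad", slices=[ContourSlice(z=0.0, polygons=[[[0, 0], [1, 1]]])])
        with pytest.raises(DegenerateContourError):
            rasterize_contours(cs, unit_grid)

    def test_z_out_of_extent(self, unit_grid):
        cs = ContourSet(
            name="far", slices=[ContourSlice(z=50.0, polygons=[[[0, 0], [2, 0], [1, 2]]])]
        )
        with pytest.raises(OutOfExtentError):
            rasterize_contours(cs, unit_grid)

    def test_matches_point_in_polygon_oracle(self):
        """Random polygons vs a shapely point-in-polygon oracle on small grids."""
        from shapely.geometry import Point, Polygon

        rng = np.random.default_rng(7)
        grid = GridSpec(shape=(16, 16, 3), spacing=(1.0, 1.0, 2.0), origin=(0.0, 0.0, 0.0))
        for _ in range(20):
            # star-convex random polygon around a random center
            c = 2 + 12 * rng.random(2)
            angles = np.sort(rng.uniform(0, 2 * np.pi, rng.integers(3, 9)))
            radii = 1 + 5 * rng.random(angles.size)
            verts = np.c_[c[0] + radii * np.cos(angles), c[1] + radii * np.sin(angles)]
            mask = rasterize_contours(
                ContourSet(name="p", slices=[ContourSlice(z=2.0, polygons=[verts])]), grid
            )
            poly = Polygon(verts)
            for i in range(16):
                for j in range(16):
                    assert mask.voxels[i, j, 1] == poly.contains(Point(i, j)), (i, j)

    def test_box_volume_converges_with_spacing(self):
        """Rasterized axial box volume approaches the analytic volume as spacing shrinks."""
        a, b = 2.26, 13.54  # edges chosen off-lattice so no spacing is exact
        box = [[a, a], [b, a], [b, b], [a, b]]
        analytic_cc = (b - a) ** 2 * 2.0 / 1000
        errs = []
        for sp in (2.0, 1.0, 0.5):
            n = int(16 / sp)
            grid = GridSpec(shape=(n, n, 2), spacing=(sp, sp, 2.0))
            cs = ContourSet(name="box", slices=[ContourSlice(z=0.0, polygons=[box])])
            vol = rasterize_contours(cs, grid).volume_cc
            errs.append(abs(vol - analytic_cc))
        assert errs[0] > errs[1] > errs[2]


class TestResample:
    def test_identity(self, aniso_grid):
        rng = np.random.default_rng(1)
        dose = DoseGrid(grid=aniso_grid, values=rng.random(aniso_grid.shape))
        out = resample_dose(dose, aniso_grid)
        np.testing.assert_array_equal(out.values, dose.values)

    def test_constant_field(self, unit_grid):
        dose = DoseGrid(grid=unit_grid, values=np.full(unit_grid.shape, 3.5))
        target = GridSpec(shape=(5, 5, 5), spacing=(1.2, 1.1, 1.3), origin=(0.5, 0.5, 0.5))
        out = resample_dose(dose, target)
        np.testing.assert_allclose(out.values, 3.5)

    def test_linear_field_at_midpoints(self, unit_grid):
        x = np.arange(8, dtype=float)
        dose = DoseGrid(grid=unit_grid, values=np.broadcast_to(x[:, None, None], (8, 8, 8)).copy())
        target = GridSpec(shape=(7, 8, 8), spacing=(1.0, 1.0, 1.0), origin=(0.5, 0.0, 0.0))
        out = resample_dose(dose, target)
        np.testing.assert_allclose(out.values[:, 0, 0], x[:-1] + 0.5, atol=1e-12)

    def test_outside_extent_zero_with_warning(self, unit_grid, caplog):
        dose = DoseGrid(grid=unit_grid, values=np.full(unit_grid.shape, 10.0))
        target = GridSpec(shape=(8, 8, 8), spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 20.0))
        with caplog.at_level("WARNING", logger="contourdose"):
            out = resample_dose(dose, target)
        assert np.all(out.values == 0.0)
        assert any("outside source extent" in r.message for r in caplog.records)


class TestExpandMargin:
    def test_zero_margin_identity(self, aniso_grid):
        mask = make_mask(aniso_grid, (slice(2, 5), slice(2, 5), slice(1, 3)))
        out = expand_margin(mask, 0.0)
        np.testing.assert_array_equal(out.voxels, mask.voxels)

    def test_single_voxel_plus_shape(self, unit_grid):
        mask = make_mask(unit_grid, (4, 4, 4))
        out = expand_margin(mask, 1.0)
        assert out.voxel_count == 7
        for di, dj, dk in ((0, 0, 0), (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
            assert out.voxels[4 + di, 4 + dj, 4 + dk]

    def test_negative_margin(self, unit_grid):
        with pytest.raises(InvalidArgumentError):
            expand_margin(make_mask(unit_grid, (4, 4, 4)), -1.0)

    def test_monotone_superset(self, aniso_grid):
        mask = make_mask(aniso_grid, (slice(4, 7), slice(4, 6), slice(2, 4)))
        out = expand_margin(mask, 3.0)
        assert np.all(out.voxels[mask.voxels])

    def test_composition_on_convex_shape(self):
        """Dilating by a then b is contained in dilating by a+b, and the two
        differ only within one voxel diagonal of the outer boundary (digital
        dilation chains through voxel centers, so exact continuum equality
        does not hold)."""
        grid = GridSpec(shape=(20, 20, 20), spacing=(1.0, 1.0, 1.0))
        mask = make_mask(grid, (slice(8, 12), slice(8, 12), slice(8, 12)))
        ab = expand_margin(expand_margin(mask, 2.0), 3.0)
        once = expand_margin(mask, 5.0)
        assert np.all(once.voxels[ab.voxels])  # ab ⊆ once
        diff = once.voxels & ~ab.voxels
        if diff.any():
            from scipy import ndimage

            dist = ndimage.distance_transform_edt(~mask.voxels, sampling=grid.spacing)
            diagonal = np.linalg.norm(grid.spacing)
            assert dist[diff].min() > 5.0 - diagonal

    def test_brute_force_distance_oracle(self, aniso_grid):
        rng = np.random.default_rng(3)
        vox = rng.random(aniso_grid.shape) < 0.05
        vox[3, 3, 2] = True
        mask = StructureMask(grid=aniso_grid, voxels=vox, name="r")
        margin = 4.0
        out = expand_margin(mask, margin)
        centers = aniso_grid.centers_mm()
        true_pts = centers[vox]
        d = np.sqrt(((centers[..., None, :] - true_pts[None, None, None, :, :]) ** 2).sum(-1))
        expected = d.min(axis=-1) <= margin + 1e-9
        np.testing.assert_array_equal(out.voxels, expected)


class TestIO:
    def test_contour_json_round_trip(self, tmp_path):
        cs = ContourSet(
            name="eso",
            slices=[
                ContourSlice(z=0.0, polygons=[[[0.1, 0.2], [3.3, 0.2], [1.7, 2.9]]]),
                ContourSlice(z=5.0, polygons=[[[0, 0], [2, 0], [2, 2], [0, 2]]]),
            ],
        )
        path = tmp_path / "c.json"
        write_structures(cs, path, "json-contours")
        (back,) = read_structures(path, "json-contours")
        assert back.name == "eso"
        for s_in, s_out in zip(cs.slices, back.slices):
            assert s_out.z == s_in.z
            for p_in, p_out in zip(s_in.polygons, s_out.polygons):
                np.testing.assert_allclose(p_out, p_in, atol=1e-6)

    def test_mask_nifti_round_trip(self, tmp_path, aniso_grid):
        mask = make_mask(aniso_grid, (slice(1, 5), slice(2, 6), slice(1, 4)), name="heart")
        mask.source = "automatic"
        path = tmp_path / "m.nii.gz"
        write_structures(mask, path, "mask-volume")
        (back,) = read_structures(path, "mask-volume")
        np.testing.assert_array_equal(back.voxels, mask.voxels)
        assert back.grid.compatible(mask.grid, atol=1e-6)
        assert back.name == "heart" and back.source == "automatic"

    def test_dose_nifti_round_trip(self, tmp_path, aniso_grid):
        rng = np.random.default_rng(5)
        dose = DoseGrid(grid=aniso_grid, values=60 * rng.random(aniso_grid.shape))
        path = tmp_path / "d.nii.gz"
        write_dose(dose, path)
        back = read_dose(path)
        assert np.abs(back.values - dose.values).max() <= 1e-6
        assert back.grid.compatible(dose.grid, atol=1e-6)

    def test_unknown_dialect(self, tmp_path, unit_grid):
        with pytest.raises(ConfigurationError):
            write_structures(make_mask(unit_grid, (0, 0, 0)), tmp_path / "x", "hdf5")
        with pytest.raises(ConfigurationError):
            read_structures(tmp_path / "x", "hdf5")

    def test_malformed_json(self, tmp_path):
        bad = tmp_path / "bad.json"
        bad.write_text('{"name": "x", "slices": [{"z": "not closed"')
        with pytest.raises(ParseError):
            read_structures(bad, "json-contours")
        bad2 = tmp_path / "bad2.json"
        bad2.write_text('{"name": "x"}')
        with pytest.raises(ParseError, match="bad2.json"):
            read_structures(bad2, "json-contours")


class TestDicomRT:
    """Readers checked against files synthesized with pydicom."""

    def _rtstruct(self, path):
        import pydicom
        from pydicom.dataset import Dataset, FileMetaDataset
        from pydicom.uid import ExplicitVRLittleEndian, generate_uid

        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.RTStructureSetStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = Dataset()
        ds.file_meta = meta
        ds.Modality = "RTSTRUCT"
        roi = Dataset()
        roi.ROINumber = 1
        roi.ROIName = "cord"
        ds.StructureSetROISequence = [roi]
        contour = Dataset()
        contour.ContourGeometricType = "CLOSED_PLANAR"
        contour.ContourData = [0.0, 0.0, 5.0, 10.0, 0.0, 5.0, 10.0, 10.0, 5.0]
        rc = Dataset()
        rc.ReferencedROINumber = 1
        rc.ContourSequence = [contour]
        ds.ROIContourSequence = [rc]
        ds.save_as(str(path), enforce_file_format=True)

    def test_read_rtstruct(self, tmp_path):
        path = tmp_path / "rs.dcm"
        self._rtstruct(path)
        (cs,) = read_structures(path, "dicom-rt")
        assert cs.name == "cord"
        assert cs.slices[0].z == 5.0
        np.testing.assert_allclose(
            cs.slices[0].polygons[0], [[0, 0], [10, 0], [10, 10]], atol=1e-9
        )

    def test_read_rtdose(self, tmp_path):
        import pydicom
        from pydicom.dataset import Dataset, FileMetaDataset
        from pydicom.uid import ExplicitVRLittleEndian, generate_uid

        rng = np.random.default_rng(2)
        raw = rng.integers(0, 5000, size=(4, 6, 5), dtype=np.uint16)  # (z, y, x)
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.RTDoseStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = Dataset()
        ds.file_meta = meta
        ds.Modality = "RTDOSE"
        ds.DoseGridScaling = 0.01
        ds.Rows, ds.Columns, ds.NumberOfFrames = 6, 5, 4
        ds.PixelSpacing = [2.0, 2.5]  # row (y), col (x)
        ds.ImagePositionPatient = [-10.0, -12.0, 30.0]
        ds.GridFrameOffsetVector = [0.0, 5.0, 10.0, 15.0]
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.PixelData = raw.tobytes()
        ds.save_as(str(tmp_path / "rd.dcm"), enforce_file_format=True)

        dose = read_dose(tmp_path / "rd.dcm", dialect="dicom-rt")
        assert dose.grid.shape == (5, 6, 4)
        assert dose.grid.spacing == (2.5, 2.0, 5.0)
        np.testing.assert_allclose(dose.values, raw.transpose(2, 1, 0) * 0.01, atol=1e-12)
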