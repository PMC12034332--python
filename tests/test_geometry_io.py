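"""Grid validation, contour rasterization, and structure-set round trips."""

import numpy as np
import pydicom
import pytest
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid
from scipy import ndimage
from shapely.geometry import Point, Polygon

from segqa import (
    BinaryMask,
    Contour,
    ImageGeometry,
    StructureSet,
    rasterize,
    read_structure_set,
    write_structure_set,
)
from segqa.io import MissingGeometryError

from conftest import ball_mask


def ring(xy, z):
    return np.column_stack([np.asarray(xy, float), np.full(len(xy), float(z))])


class TestImageGeometry:
    def test_rejects_nonpositive_spacing(self):
        with pytest.raises(ValueError):
            ImageGeometry((8, 8, 8), (1.0, 0.0, 1.0))
        with pytest.raises(ValueError):
            ImageGeometry((8, 8, 8), (1.0, 1.0, -2.0))

    def test_z_index_ties_go_to_lower_slice(self):
        g = ImageGeometry((4, 4, 4), (1, 1, 2))
        assert g.z_index(3.0) == 1  # exactly between planes 2 and 4
        assert g.z_index(3.1) == 2
        assert g.z_index(2.9) == 1

    def test_z_outside_extent_errors(self):
        g = ImageGeometry((4, 4, 4), (1, 1, 2))
        with pytest.raises(ValueError, match="half a slice spacing"):
            g.z_index(-1.5)
        with pytest.raises(ValueError):
            g.z_index(7.5)

    def test_json_round_trip(self, tmp_path):
        g = ImageGeometry((10, 12, 14), (0.5, 0.5, 2.5), (-3.0, 1.0, 2.0))
        g.save_json(tmp_path / "g.json")
        assert ImageGeometry.load_json(tmp_path / "g.json") == g


class TestRasterize:
    def test_axis_aligned_square_covers_exact_voxel_count(self):
        # 20x20 mm square with edges on voxel-center lines: half-open
        # convention keeps the left/bottom edges and drops right/top.
        g = ImageGeometry((32, 32, 4), (1, 1, 1))
        c = Contour("sq", [ring([(5, 5), (25, 5), (25, 25), (5, 25)], 2)])
        m = rasterize(c, g)
        assert m.count() == 400
        sl = m.voxels[:, :, 2]
        assert sl[5, 5] and sl[24, 24]
        assert not sl[25, 5] and not sl[5, 25]

    def test_matches_point_in_polygon_oracle_on_random_polygons(self):
        # star-shaped random polygons, vertices off-lattice so the oracle has
        # no boundary ambiguity
        rng = np.random.default_rng(42)
        g = ImageGeometry((40, 40, 3), (1, 1, 1))
        for _ in range(20):
            k = int(rng.integers(5, 12))
            ang = np.sort(rng.uniform(0, 2 * np.pi, k))
            rad = rng.uniform(4, 17, k)
            cx, cy = rng.uniform(15, 25, 2)
            xy = np.column_stack([cx + rad * np.cos(ang) + rng.uniform(0.01, 0.09),
                                  cy + rad * np.sin(ang) + rng.uniform(0.01, 0.09)])
            m = rasterize(Contour("p", [ring(xy, 1)]), g)
            poly = Polygon(xy)
            for i in range(40):
                for j in range(40):
                    assert m.voxels[i, j, 1] == poly.contains(Point(i, j)), (i, j)

    def test_disjoint_rings_stay_disjoint(self):
        g = ImageGeometry((40, 40, 3), (1, 1, 1))
        c = Contour("two", [
            ring([(2.5, 2.5), (12.5, 2.5), (12.5, 12.5), (2.5, 12.5)], 1),
            ring([(22.5, 22.5), (32.5, 22.5), (32.5, 32.5), (22.5, 32.5)], 1),
        ])
        m = rasterize(c, g)
        _, ncomp = ndimage.label(m.voxels[:, :, 1])
        assert ncomp == 2

    def test_nested_rings_carve_a_hole(self):
        g = ImageGeometry((30, 30, 3), (1, 1, 1))
        c = Contour("donut", [
            ring([(2.5, 2.5), (22.5, 2.5), (22.5, 22.5), (2.5, 22.5)], 1),
            ring([(8.5, 8.5), (16.5, 8.5), (16.5, 16.5), (8.5, 16.5)], 1),
        ])
        m = rasterize(c, g)
        assert not m.voxels[12, 12, 1] and m.voxels[5, 5, 1]

    def test_half_spacing_ring_assigned_to_lower_slice(self):
        g = ImageGeometry((16, 16, 4), (1, 1, 2))
        c = Contour("t", [ring([(2.5, 2.5), (9.5, 2.5), (9.5, 9.5), (2.5, 9.5)], 3.0)])
        m = rasterize(c, g)
        assert m.voxels[:, :, 1].any() and not m.voxels[:, :, 2].any()

    def test_ring_outside_z_extent_errors(self):
        g = ImageGeometry((16, 16, 4), (1, 1, 2))
        c = Contour("t", [ring([(2.5, 2.5), (9.5, 2.5), (9.5, 9.5)], 9.0)])
        with pytest.raises(ValueError):
            rasterize(c, g)

    def test_rasterized_volume_converges_to_analytic(self):
        # 20.5 x 13.3 mm rectangle on one slice (edges off every grid line):
        # voxel volume error must shrink monotonically as spacing halves
        verts = [(3.3, 4.2), (23.8, 4.2), (23.8, 17.5), (3.3, 17.5)]
        errors = []
        for sp in (1.0, 0.5):
            n = int(32 / sp)
            g = ImageGeometry((n, n, 3), (sp, sp, 1.0))
            m = rasterize(Contour("r", [ring(verts, 1.0)]), g)
            errors.append(abs(m.volume_mm3() - 20.5 * 13.3 * 1.0))
        assert errors[1] < errors[0]


class TestMaskVolumeRoundTrip:
    def _sample_set(self, geom):
        ss = StructureSet("pat7", "old", geom)
        ss.add("Bladder", ball_mask(geom, (12, 12, 12), 6))
        ss.add("Rectum", ball_mask(geom, (6, 18, 10), 4))
        ss.add("Ghost", BinaryMask(geom, np.zeros(geom.shape, bool)))  # empty kept
        return ss

    def test_round_trip_preserves_every_voxel(self, iso_geom, tmp_path):
        ss = self._sample_set(iso_geom)
        write_structure_set(ss, tmp_path / "p.nii")
        back = read_structure_set(tmp_path / "p.nii")
        assert back.patient_id == "pat7" and back.version_label == "old"
        assert back.organ_names() == ss.organ_names()
        for name in ss.organ_names():
            assert np.array_equal(back.get_mask(name).voxels, ss.get_mask(name).voxels)
        assert back.get_mask("Ghost").is_empty

    def test_overlapping_organs_survive_round_trip(self, iso_geom, tmp_path):
        ss = StructureSet("p", "gt", iso_geom)
        ss.add("big", ball_mask(iso_geom, (12, 12, 12), 8))
        ss.add("inner", ball_mask(iso_geom, (12, 12, 12), 4))  # fully inside big
        write_structure_set(ss, tmp_path / "o.nii")
        back = read_structure_set(tmp_path / "o.nii")
        assert np.array_equal(back.get_mask("inner").voxels, ss.get_mask("inner").voxels)

    def test_case_colliding_names_rejected_before_writing(self, iso_geom, tmp_path):
        ss = StructureSet("p", "v", iso_geom)
        ss.structures = {"Bladder": ball_mask(iso_geom, (12, 12, 12), 5),
                         "bladder": ball_mask(iso_geom, (12, 12, 12), 4)}
        with pytest.raises(ValueError, match="duplicate"):
            write_structure_set(ss, tmp_path / "d.nii")
        assert not (tmp_path / "d.nii").exists()

    def test_label_map_read(self, iso_geom, tmp_path):
        import json
        import nibabel as nib

        lab = np.zeros(iso_geom.shape, dtype=np.int16)
        lab[2:6, 2:6, 2:6] = 1
        lab[10:14, 10:14, 10:14] = 2
        nib.save(nib.Nifti1Image(lab, np.eye(4)), str(tmp_path / "lm.nii"))
        meta = {"labels": {"1": "Bladder", "2": "Rectum"},
                "geometry": iso_geom.to_json_dict(), "patient_id": "x"}
        (tmp_path / "lm.json").write_text(json.dumps(meta))
        ss = read_structure_set(tmp_path / "lm.nii")
        assert ss.organ_names() == ["Bladder", "Rectum"]
        assert ss.get_mask("Bladder").count() == 64

    def test_missing_sidecar_is_missing_geometry(self, iso_geom, tmp_path):
        import nibabel as nib

        nib.save(nib.Nifti1Image(np.zeros((4, 4, 4), np.uint8), np.eye(4)),
                 str(tmp_path / "x.nii"))
        with pytest.raises(MissingGeometryError):
            read_structure_set(tmp_path / "x.nii")


def _make_rtstruct(path, rois):
    """Minimal RT Structure Set written with pydicom; rois: name -> list of rings."""
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = "1.2.840.10008.5.1.4.1.1.481.3"
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\x00" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTSTRUCT"
    ds.PatientID = "rtpat"
    ds.StructureSetLabel = "VA30"
    ds.StructureSetROISequence = []
    ds.ROIContourSequence = []
    for num, (name, rings) in enumerate(rois.items(), start=1):
        roi = Dataset()
        roi.ROINumber = num
        roi.ROIName = name
        roi.ReferencedFrameOfReferenceUID = generate_uid()
        ds.StructureSetROISequence.append(roi)
        rc = Dataset()
        rc.ReferencedROINumber = num
        rc.ContourSequence = []
        for r in rings:
            item = Dataset()
            item.ContourGeometricType = "CLOSED_PLANAR"
            item.NumberOfContourPoints = len(r)
            item.ContourData = [float(x) for x in np.asarray(r).ravel()]
            rc.ContourSequence.append(item)
        ds.ROIContourSequence.append(rc)
    ds.save_as(str(path), enforce_file_format=True)


class TestRTStructRead:
    def test_two_rois_parse_and_rasterize(self, tmp_path):
        geom = ImageGeometry((64, 64, 64), (1, 1, 1))
        sq1 = ring([(10.5, 10.5), (20.5, 10.5), (20.5, 20.5), (10.5, 20.5)], 30)
        sq2 = ring([(30.5, 30.5), (40.5, 30.5), (40.5, 40.5), (30.5, 40.5)], 32)
        _make_rtstruct(tmp_path / "rs.dcm", {"Bladder": [sq1], "Rectum": [sq2]})
        ss = read_structure_set(tmp_path / "rs.dcm", geometry_source=geom)
        assert ss.patient_id == "rtpat" and ss.version_label == "VA30"
        assert sorted(ss.organ_names()) == ["Bladder", "Rectum"]
        assert ss.get_mask("Bladder").count() == 100
        # reading the same contour directly gives the identical mask
        direct = rasterize(Contour("Bladder", [sq1]), geom)
        assert np.array_equal(ss.get_mask("Bladder").voxels, direct.voxels)

    def test_missing_geometry_is_a_hard_error(self, tmp_path):
        _make_rtstruct(tmp_path / "rs.dcm", {"A": [ring([(1, 1), (5, 1), (5, 5)], 2)]})
        with pytest.raises(MissingGeometryError, match="missing geometry"):
            read_structure_set(tmp_path / "rs.dcm")

    def test_zero_point_structure_kept_empty_with_warning(self, tmp_path):
        geom = ImageGeometry((16, 16, 16), (1, 1, 1))
        _make_rtstruct(tmp_path / "rs.dcm", {"Empty": []})
        ss = read_structure_set(tmp_path / "rs.dcm", geometry_source=geom)
        assert "Empty" in ss.organ_names()
        assert ss.get_mask("Empty").is_empty
        assert any("Empty" in w for w in ss.warnings)
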