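"""Mesh/landmark file round trips, exact vertex merging, and format errors."""

import struct

import numpy as np
import pytest

from shapeforge.geometry import (
    HM12_NAMES,
    LandmarkSchemeError,
    LandmarkSet,
    MeshInvariantError,
    Scheme,
    TM20_NAMES,
    TriangleMesh,
)
from shapeforge.mesh_io import (
    MeshFormatError,
    read_landmarks,
    read_mesh,
    write_landmarks,
    write_mesh,
    write_mesh_binary_stl,
)


def _single_triangle():
    return TriangleMesh([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0]], [[0, 1, 2]])


def _random_mesh(rng, n_tri=20, scale=5.0):
    # a fan of triangles sharing vertex 0 (valid, duplicate-free)
    verts = rng.uniform(-scale, scale, size=(n_tri + 2, 3))
    faces = [[0, i + 1, i + 2] for i in range(n_tri)]
    return TriangleMesh(verts, faces)


class TestMeshRoundTrip:
    def test_ascii_stl_single_triangle_identity(self, tmp_path):
        mesh = _single_triangle()
        path = tmp_path / "tri.stl"
        write_mesh(mesh, path)
        back = read_mesh(path)
        assert back.n_faces == 1
        assert back.n_vertices == 3
        # same vertex set (STL reorders via per-facet storage + merge)
        assert sorted(map(tuple, back.vertices)) == sorted(map(tuple, mesh.vertices))

    @pytest.mark.parametrize("fmt", ["stl", "obj", "ply"])
    def test_round_trip_geometry_within_tolerance(self, tmp_path, rng, fmt):
        mesh = _random_mesh(rng)
        path = tmp_path / f"m.{fmt}"
        write_mesh(mesh, path)
        back = read_mesh(path)
        assert back.n_faces == mesh.n_faces
        # compare vertex sets via nearest matching
        from scipy.spatial import cKDTree

        d, _ = cKDTree(mesh.vertices).query(back.vertices)
        assert d.max() <= 1e-6

    def test_obj_ply_preserve_vertex_order(self, tmp_path, rng):
        mesh = _random_mesh(rng)
        for fmt in ("obj", "ply"):
            path = tmp_path / f"m.{fmt}"
            write_mesh(mesh, path)
            back = read_mesh(path)
            assert np.allclose(back.vertices, mesh.vertices, atol=1e-6)
            assert np.array_equal(back.faces, mesh.faces)

    def test_binary_stl_cube_merges_to_8_vertices(self, tmp_path):
        # 12 facets, 36 per-facet vertices -> 8 unique vertices after merging
        corners = np.array(
            [[x, y, z] for x in (0.0, 1.0) for y in (0.0, 1.0) for z in (0.0, 1.0)]
        )
        quads = [
            (0, 1, 3, 2), (4, 6, 7, 5), (0, 4, 5, 1),
            (2, 3, 7, 6), (0, 2, 6, 4), (1, 5, 7, 3),
        ]
        tris = []
        for a, b, c, d in quads:
            tris.append((a, b, c))
            tris.append((a, c, d))
        blob = b"\0" * 80 + struct.pack("<I", len(tris))
        for tri in tris:
            blob += struct.pack("<3f", 0, 0, 0)
            for vid in tri:
                blob += struct.pack("<3f", *corners[vid])
            blob += struct.pack("<H", 0)
        path = tmp_path / "cube.stl"
        path.write_bytes(blob)
        mesh = read_mesh(path)
        assert mesh.n_vertices == 8
        assert mesh.n_faces == 12

    def test_binary_stl_writer_round_trip(self, tmp_path, rng):
        mesh = _random_mesh(rng, scale=2.0)
        path = tmp_path / "b.stl"
        write_mesh_binary_stl(mesh, path)
        back = read_mesh(path)
        from scipy.spatial import cKDTree

        d, _ = cKDTree(mesh.vertices).query(back.vertices)
        assert d.max() <= 1e-6  # float32 quantization at unit scale


class TestMeshErrors:
    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.stl"
        path.touch()
        with pytest.raises(MeshFormatError, match="empty"):
            read_mesh(path)

    def test_garbage_file_rejected(self, tmp_path):
        path = tmp_path / "bad.obj"
        path.write_text("not a mesh\nat all")
        with pytest.raises(MeshFormatError):
            read_mesh(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_mesh(tmp_path / "nope.stl")

    def test_out_of_range_face_rejected_before_writing(self, tmp_path):
        mesh = TriangleMesh([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [[0, 1, 5]])
        path = tmp_path / "bad.stl"
        with pytest.raises(MeshInvariantError, match="out of range"):
            write_mesh(mesh, path)
        assert not path.exists()

    def test_degenerate_face_rejected(self):
        with pytest.raises(MeshInvariantError, match="degenerate"):
            TriangleMesh([[0, 0, 0], [1, 0, 0], [0, 1, 0]], [[0, 1, 1]]).validate()


class TestLandmarkIO:
    def _tm20(self, rng):
        return LandmarkSet(list(TM20_NAMES), rng.normal(size=(20, 3)), Scheme.TM20)

    def test_csv_round_trip_and_canonical_order(self, tmp_path, rng):
        lms = self._tm20(rng)
        path = tmp_path / "lm.csv"
        write_landmarks(lms, path)
        back = read_landmarks(path, Scheme.TM20)
        assert back.names == list(TM20_NAMES)
        assert np.allclose(back.points, lms.points)

    def test_json_round_trip(self, tmp_path, rng):
        lms = self._tm20(rng)
        path = tmp_path / "lm.json"
        write_landmarks(lms, path)
        back = read_landmarks(path, "TM20")
        assert np.allclose(back.points, lms.points)

    def test_shuffled_order_is_canonicalized(self, tmp_path, rng):
        lms = self._tm20(rng)
        perm = rng.permutation(20)
        shuffled = LandmarkSet(
            [lms.names[i] for i in perm], lms.points[perm], Scheme.TM20
        )
        assert shuffled.names == lms.names
        assert np.allclose(shuffled.points, lms.points)

    def test_missing_landmark_named_in_error(self, rng):
        names = list(HM12_NAMES[:11])
        with pytest.raises(LandmarkSchemeError, match="Left lower central"):
            LandmarkSet(names, rng.normal(size=(11, 3)), Scheme.HM12)

    def test_unknown_name_rejected(self, rng):
        names = list(TM20_NAMES[:19]) + ["Mystery point"]
        with pytest.raises(LandmarkSchemeError, match="Mystery point"):
            LandmarkSet(names, rng.normal(size=(20, 3)), Scheme.TM20)

    def test_csv_without_header_rejected(self, tmp_path):
        path = tmp_path / "raw.csv"
        path.write_text("a,1,2,3\n")
        with pytest.raises(LandmarkSchemeError, match="header"):
            read_landmarks(path, Scheme.TM20)


class TestShapeSpaceSerialization:
    def test_directory_round_trip(self, tmp_path, rng, reference0):
        from shapeforge.mesh_io import load_shape_space, save_shape_space
        from shapeforge.geometry import HomologousModel, TriangleMesh
        from shapeforge.shape_space import ShapeSpacePCA, build_shape_matrix

        mesh, tm, _ = reference0
        models = [
            HomologousModel(
                TriangleMesh(mesh.vertices + rng.normal(0, 0.5, mesh.vertices.shape),
                             mesh.faces),
                "ref",
            )
            for _ in range(6)
        ]
        space = ShapeSpacePCA(n_components=3).fit(build_shape_matrix(models))
        save_shape_space(space, tmp_path / "space")
        back = load_shape_space(tmp_path / "space")
        assert np.allclose(back.components_, space.components_)
        assert np.allclose(back.eigenvalues_, space.eigenvalues_)
        x = models[0].flatten()
        assert np.allclose(back.transform(x[None]), space.transform(x[None]))
        rec = back.reconstruct(np.zeros(3))
        assert np.allclose(rec.flatten(), space.mean_)
        assert (tmp_path / "space" / "variance_report.csv").exists()
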