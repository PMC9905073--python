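"""Coarse-to-fine scanning, map output, site extraction, MRC I/O."""

import numpy as np
import pytest

import hydrosite as hs
from hydrosite.predict import (
    CoarseScan,
    MRCFormatError,
    read_sites_pdb,
    scan_lattice_points,
)


class _StubModel:
    """Duck-typed classifier stub: constant or grid-dependent output."""

    def __init__(self, box, value=None, fn=None, resolution_tag=None):
        self.box = box
        self.resolution_tag = resolution_tag
        self._value = value
        self._fn = fn

    def predict_water_probability(self, X):
        if self._fn is not None:
            return np.array([self._fn(g) for g in X])
        return np.full(len(X), self._value)


def _single_atom_structure():
    st = hs.ProteinStructure(
        protein_atoms=[hs.Atom(position=np.zeros(3), element_class="C")],
        water_sites=[], id="one-atom")
    return hs.compute_asa(st)


class TestScanCoarse:
    def test_lattice_count_matches_sphere_oracle(self):
        st = _single_atom_structure()
        pts = scan_lattice_points(st, spacing=0.5)
        # brute-force: same snapped grid, points within 4 A of the atom
        lo = np.floor((st.protein_coords.min(axis=0) - 4.0) / 0.5) * 0.5
        n = np.ceil((st.protein_coords.max(axis=0) + 4.0 - lo) / 0.5).astype(int)
        count = 0
        for i in range(n[0]):
            for j in range(n[1]):
                for k in range(n[2]):
                    c = lo + (np.array([i, j, k]) + 0.5) * 0.5
                    if np.linalg.norm(c) <= 4.0:
                        count += 1
        assert len(pts) == count
        assert np.all(np.linalg.norm(pts, axis=1) <= 4.0)

    def test_far_points_never_evaluated(self, toy_structure):
        pts = scan_lattice_points(toy_structure, spacing=0.5)
        surf = toy_structure.nonzero_asa_coords()
        from scipy.spatial import cKDTree
        d, _ = cKDTree(surf).query(pts)
        assert d.max() <= 4.0 + 1e-9

    def test_constant_zero_model_yields_no_candidates(self, toy_structure):
        stub = _StubModel(hs.BoxSpec(13, 0.5), value=0.0, resolution_tag="coarse")
        scan = hs.scan_coarse(toy_structure, stub)
        assert len(scan.points) == 0
        assert scan.n_evaluated > 0

    def test_no_surface_atoms_is_error(self):
        st = _single_atom_structure()
        st.asa = np.zeros(1)
        stub = _StubModel(hs.BoxSpec(13, 0.5), value=1.0)
        with pytest.raises(ValueError, match="non-zero ASA"):
            hs.scan_coarse(st, stub)

    def test_wrong_resolution_tag_rejected(self, toy_structure):
        stub = _StubModel(hs.BoxSpec(13, 0.5), value=1.0, resolution_tag="fine")
        with pytest.raises(ValueError, match="coarse"):
            hs.scan_coarse(toy_structure, stub)


class TestPredictMap:
    def test_constant_one_model_fills_mask_only(self):
        st = _single_atom_structure()
        stub = _StubModel(hs.BoxSpec(9, 0.25), value=1.0, resolution_tag="fine")
        cands = CoarseScan(points=np.zeros((1, 3)), probabilities=np.ones(1),
                           n_evaluated=1)
        pmap = hs.predict_map(st, stub, cands, refine_radius=1.0)
        assert pmap.voxel_size == 0.25
        assert np.all(pmap.values[pmap.evaluated_mask] == 1.0)
        assert np.all(pmap.values[~pmap.evaluated_mask] == 0.0)
        assert pmap.evaluated_mask.sum() > 0

    def test_map_values_equal_pattern_prediction_at_voxel_centers(self, rng):
        st = _single_atom_structure()
        model = hs.HydrationCNN(n_conv_units=2, conv_layers_per_unit=1, channels=4,
                                fcb_nodes=8, input_edge=9, random_state=0,
                                box=hs.BoxSpec(9, 0.25),
                                resolution_tag="fine").initialize()
        cands = CoarseScan(points=np.array([[0.5, 0.0, -0.5]]),
                           probabilities=np.ones(1), n_evaluated=1)
        pmap = hs.predict_map(st, model, cands, refine_radius=0.6)
        idx = np.argwhere(pmap.evaluated_mask)
        pick = idx[rng.choice(len(idx), size=min(20, len(idx)), replace=False)]
        for ijk in pick:
            center = pmap.voxel_centers(ijk)
            pat = hs.voxelize(st, center, model.box)
            expected = hs.predict_pattern(model, pat)
            assert pmap.values[tuple(ijk)] == pytest.approx(expected, abs=1e-6)

    def test_empty_candidates_rejected(self):
        st = _single_atom_structure()
        stub = _StubModel(hs.BoxSpec(9, 0.25), value=1.0)
        with pytest.raises(ValueError, match="candidate"):
            hs.predict_map(st, stub, np.empty((0, 3)))


def _blob_map(origin=(0.0, 0.0, 0.0), peak=0.95, shape=(15, 15, 15),
              center=(7, 7, 7), width=2.0, voxel_size=0.25):
    ijk = np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1)
    d2 = ((ijk - np.array(center)) ** 2).sum(axis=-1)
    values = peak * np.exp(-d2 / (2 * width ** 2))
    return hs.ProbabilityMap(values=values.astype(np.float32),
                             origin=np.array(origin, dtype=float),
                             voxel_size=voxel_size,
                             evaluated_mask=np.ones(shape, dtype=bool))


class TestExtractSites:
    def test_uniform_map_has_no_sites(self):
        pmap = hs.ProbabilityMap(values=np.full((9, 9, 9), 0.5, np.float32),
                                 origin=np.zeros(3), voxel_size=0.25,
                                 evaluated_mask=np.ones((9, 9, 9), bool))
        assert hs.extract_sites(pmap, threshold=0.8) == []

    def test_gaussian_blob_gives_single_site_at_argmax(self):
        pmap = _blob_map()
        sites = hs.extract_sites(pmap, threshold=0.8)
        assert len(sites) == 1
        np.testing.assert_allclose(sites[0].position,
                                   pmap.voxel_centers(np.array([7, 7, 7])))
        assert sites[0].probability == pytest.approx(0.95)

    def test_two_blobs_sorted_by_probability(self):
        a = _blob_map(peak=0.9, center=(3, 3, 3), width=1.0)
        b = _blob_map(peak=0.95, center=(11, 11, 11), width=1.0)
        merged = hs.ProbabilityMap(values=np.maximum(a.values, b.values),
                                   origin=a.origin, voxel_size=a.voxel_size,
                                   evaluated_mask=np.ones(a.shape, bool))
        sites = hs.extract_sites(merged, threshold=0.5, nms_radius=0.6)
        assert len(sites) == 2
        assert sites[0].probability >= sites[1].probability

    def test_origin_shift_shifts_sites_rigidly(self):
        base = _blob_map()
        shifted = hs.ProbabilityMap(values=base.values.copy(),
                                    origin=base.origin + np.array([3.0, -1.0, 2.0]),
                                    voxel_size=base.voxel_size,
                                    evaluated_mask=base.evaluated_mask.copy())
        s0 = hs.extract_sites(base, threshold=0.8)
        s1 = hs.extract_sites(shifted, threshold=0.8)
        np.testing.assert_allclose(s1[0].position - s0[0].position,
                                   [3.0, -1.0, 2.0])
        assert s0[0].probability == s1[0].probability

    def test_plateau_keeps_lexicographically_smallest(self):
        values = np.zeros((7, 7, 7), np.float32)
        values[3, 3, 3] = values[3, 3, 4] = 0.9
        pmap = hs.ProbabilityMap(values=values, origin=np.zeros(3), voxel_size=0.5,
                                 evaluated_mask=np.ones((7, 7, 7), bool))
        sites = hs.extract_sites(pmap, threshold=0.5, nms_radius=1.2)
        assert len(sites) == 1
        np.testing.assert_allclose(sites[0].position,
                                   pmap.voxel_centers(np.array([3, 3, 3])))

    def test_threshold_bounds_enforced(self):
        pmap = _blob_map()
        with pytest.raises(ValueError):
            hs.extract_sites(pmap, threshold=0.0)


class TestProbabilityMapInvariants:
    def test_values_outside_mask_must_be_zero(self):
        values = np.full((5, 5, 5), 0.3, np.float32)
        with pytest.raises(ValueError, match="mask"):
            hs.ProbabilityMap(values=values, origin=np.zeros(3), voxel_size=0.25,
                              evaluated_mask=np.zeros((5, 5, 5), bool))

    def test_values_out_of_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            hs.ProbabilityMap(values=np.full((3, 3, 3), 1.5, np.float32),
                              origin=np.zeros(3), voxel_size=0.25)


class TestMrcRoundTrip:
    def test_bit_exact_values(self, rng, tmp_path):
        values = rng.random((6, 7, 8)).astype(np.float32)
        pmap = hs.ProbabilityMap(values=values, origin=np.array([1.5, -2.0, 3.25]),
                                 voxel_size=0.25,
                                 evaluated_mask=np.ones((6, 7, 8), bool))
        path = tmp_path / "map.mrc"
        hs.write_mrc(pmap, path)
        back = hs.read_mrc(path)
        np.testing.assert_array_equal(back.values, values)
        np.testing.assert_allclose(back.origin, pmap.origin)
        assert back.voxel_size == pytest.approx(0.25)

    def test_header_cell_dimensions(self, tmp_path):
        import gemmi
        pmap = _blob_map()
        path = tmp_path / "map.mrc"
        hs.write_mrc(pmap, path)
        m = gemmi.read_ccp4_map(str(path))
        assert m.header_i32(4) == 2  # mode 2, 32-bit float
        assert m.grid.unit_cell.a == pytest.approx(15 * 0.25)
        # MRC2014 default axis mapping: columns/rows/sections = x/y/z
        assert (m.header_i32(17), m.header_i32(18), m.header_i32(19)) == (1, 2, 3)

    def test_malformed_file_raises_format_error(self, tmp_path):
        bad = tmp_path / "bad.mrc"
        bad.write_bytes(b"not an mrc map")
        with pytest.raises(MRCFormatError):
            hs.read_mrc(bad)


class TestSiteSerialization:
    def test_pdb_round_trip(self, tmp_path):
        sites = [hs.HydrationSite(position=np.array([1.0, 2.0, 3.0]), probability=0.91),
                 hs.HydrationSite(position=np.array([-4.5, 0.25, 9.0]), probability=0.55)]
        path = tmp_path / "sites.pdb"
        hs.write_sites_pdb(sites, path)
        back = read_sites_pdb(path)
        assert len(back) == 2
        np.testing.assert_allclose(back[0].position, sites[0].position, atol=1e-3)
        assert back[0].probability == pytest.approx(0.91, abs=1e-3)

    def test_tsv_contents(self, tmp_path):
        sites = [hs.HydrationSite(position=np.array([1.0, 2.0, 3.0]), probability=0.91)]
        text = hs.write_sites_tsv(sites, tmp_path / "sites.tsv")
        lines = text.strip().splitlines()
        assert lines[0].split("\t") == ["x", "y", "z", "probability"]
        assert lines[1].split("\t") == ["1.000", "2.000", "3.000", "0.9100"]
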