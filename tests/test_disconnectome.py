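import numpy as np
import pytest

from oracles import polyline_box_chord, supersampled_voxels
from sdcmap import (
    DisconnectionMapper,
    ReferenceGrid,
    binarize_severity,
    disconnection_severity_map,
    find_disconnected,
    lesion_volume,
    streamline_voxels,
    tract_disconnection,
)
from sdcmap.atlas import TractAtlas


def make_atlas(streamlines, labels):
    return TractAtlas(streamlines=streamlines, tract_labels=labels)


class TestStreamlineVoxels:
    def test_axis_aligned_segment(self, small_grid):
        # from the center of voxel (2,3,3) to the center of voxel (4,3,3)
        sl = np.array([[10.0, 14.0, 14.0], [18.0, 14.0, 14.0]])
        vox = streamline_voxels(sl, small_grid)
        assert {tuple(v) for v in vox} == {(2, 3, 3), (3, 3, 3), (4, 3, 3)}

    def test_point_on_face_goes_to_higher_voxel(self, small_grid):
        # endpoint exactly on the face between voxels 4 and 5 along x
        sl = np.array([[18.0, 14.0, 14.0], [20.0, 14.0, 14.0]])
        vox = {tuple(v) for v in streamline_voxels(sl, small_grid)}
        assert (5, 3, 3) in vox

    def test_degenerate_streamline_single_voxel(self, small_grid):
        sl = np.array([[10.0, 10.0, 10.0], [10.0, 10.0, 10.0]])
        with pytest.warns(UserWarning, match="degenerate"):
            vox = streamline_voxels(sl, small_grid)
        assert vox.shape == (1, 3)

    def test_nonfinite_rejected(self, small_grid):
        with pytest.raises(ValueError):
            streamline_voxels(np.array([[0.0, 0, 0], [np.nan, 1, 1]]), small_grid)

    @pytest.mark.parametrize("trial", range(8))
    def test_matches_supersampling_oracle(self, small_grid, trial):
        rng = np.random.default_rng(100 + trial)
        lo, hi = small_grid.world_bounds()
        pts = rng.uniform(lo + 1, hi - 1, size=(50, 3))
        got = {tuple(int(x) for x in v) for v in streamline_voxels(pts, small_grid)}
        expected = supersampled_voxels(pts, small_grid)
        # everything dense sampling finds must be found exactly
        assert expected <= got
        # voxels beyond the sampling resolution must be genuine
        # intersections: adjudicated by an independent slab-clip chord
        u = small_grid.world_to_voxel(pts)
        for voxel in got - expected:
            assert polyline_box_chord(u, voxel) > 0.0


class TestFindDisconnected:
    def test_lesion_covering_bundle(self, small_grid, tiny_study):
        atlas = tiny_study.atlas
        lesion = np.zeros(small_grid.shape, bool)
        for sl, lab in zip(atlas.streamlines, atlas.tract_labels):
            if lab == 1:
                vox = streamline_voxels(sl, small_grid)
                lesion[tuple(vox.T)] = True
        hit = find_disconnected(lesion, atlas, small_grid)
        tract1 = np.flatnonzero(atlas.tract_labels == 1)
        assert set(tract1).issubset(set(hit))

    def test_empty_lesion_empty_set(self, small_grid, tiny_study):
        lesion = np.zeros(small_grid.shape, bool)
        assert find_disconnected(lesion, tiny_study.atlas, small_grid).size == 0

    def test_matches_brute_force(self, small_grid, tiny_study, rng):
        lesion = rng.random(small_grid.shape) < 0.02
        atlas = tiny_study.atlas
        got = set(find_disconnected(lesion, atlas, small_grid))
        lesion_vox = {tuple(v) for v in np.argwhere(lesion)}
        expected = {
            i
            for i, sl in enumerate(atlas.streamlines)
            if supersampled_voxels(sl, small_grid) & lesion_vox
        }
        assert got == expected


class TestSeverityMap:
    def test_half_disconnected_voxel(self):
        grid = ReferenceGrid(shape=(8, 8, 8), voxel_size=(1, 1, 1))
        # two streamlines share voxel (4,4,4); only the first passes (1,4,4)
        s1 = np.array([[1.5, 4.5, 4.5], [6.5, 4.5, 4.5]])
        s2 = np.array([[4.5, 1.5, 4.5], [4.5, 6.5, 4.5]])
        atlas = make_atlas([s1, s2], [1, 2])
        lesion = np.zeros(grid.shape, bool)
        lesion[1, 4, 4] = True
        sev = disconnection_severity_map(lesion, atlas, grid)
        assert sev.severity.data[4, 4, 4] == 50.0
        assert sev.denominator.data[4, 4, 4] == 2

    def test_empty_lesion_zero_map(self, small_grid, tiny_study):
        sev = disconnection_severity_map(
            np.zeros(small_grid.shape, bool), tiny_study.atlas, small_grid
        )
        assert np.all(sev.severity.data == 0.0)

    def test_recount_oracle(self, small_grid, tiny_study, rng):
        lesion = rng.random(small_grid.shape) < 0.02
        atlas = tiny_study.atlas
        sev = disconnection_severity_map(lesion, atlas, small_grid)
        # independent recount from per-streamline voxel sets
        traversing = {}
        for i, sl in enumerate(atlas.streamlines):
            for v in map(tuple, streamline_voxels(sl, small_grid)):
                traversing.setdefault(v, []).append(i)
        hit = set(find_disconnected(lesion, atlas, small_grid))
        for v, ids in traversing.items():
            expected = 100.0 * len([i for i in ids if i in hit]) / len(ids)
            assert sev.severity.data[v] == pytest.approx(expected)

    def test_severity_bounds_and_zero_denominator(self, small_grid, tiny_study):
        sev = disconnection_severity_map(
            tiny_study.lesions[0], tiny_study.atlas, small_grid
        )
        s, d = sev.severity.data, sev.denominator.data
        assert np.all((s >= 0) & (s <= 100))
        assert np.all(s[d == 0] == 0)

    def test_monotone_in_lesion(self, small_grid, tiny_study):
        small = tiny_study.lesions[0].copy()
        bigger = small.copy()
        bigger[3:6, 3:6, 3:6] = True
        atlas = tiny_study.atlas
        s1 = disconnection_severity_map(small, atlas, small_grid).severity.data
        s2 = disconnection_severity_map(bigger, atlas, small_grid).severity.data
        assert np.all(s2 >= s1)

    def test_disconnected_sets_additive(self, small_grid, tiny_study):
        a, b = tiny_study.lesions[0], tiny_study.lesions[1]
        atlas = tiny_study.atlas
        union = set(find_disconnected(a | b, atlas, small_grid))
        parts = set(find_disconnected(a, atlas, small_grid)) | set(
            find_disconnected(b, atlas, small_grid)
        )
        assert union == parts


class TestBinarize:
    def test_inclusive_threshold(self):
        m = np.array([[[10.0, 9.99], [20.0, 0.0]]])
        out = binarize_severity(m, 10.0)
        np.testing.assert_array_equal(out, [[[1, 0], [1, 0]]])

    def test_threshold_nesting(self, small_grid, tiny_study):
        sev = tiny_study.severity[0]
        b1 = binarize_severity(sev, 1.0)
        b10 = binarize_severity(sev, 10.0)
        b20 = binarize_severity(sev, 20.0)
        assert np.all(b1 >= b10) and np.all(b10 >= b20)

    @pytest.mark.parametrize("bad", [0.0, -5.0, 101.0])
    def test_invalid_threshold(self, bad):
        with pytest.raises(ValueError):
            binarize_severity(np.zeros((2, 2, 2)), bad)


class TestTractDisconnection:
    def test_single_tract_fully_hit(self, small_grid, tiny_study):
        atlas = tiny_study.atlas
        lesion = np.zeros(small_grid.shape, bool)
        for sl, lab in zip(atlas.streamlines, atlas.tract_labels):
            if lab == 3:
                vox = streamline_voxels(sl, small_grid)
                lesion[tuple(vox.T)] = True
        sev = tract_disconnection(lesion, atlas, small_grid)
        assert sev[2] == 100.0

    def test_empty_lesion_all_zero(self, small_grid, tiny_study):
        sev = tract_disconnection(
            np.zeros(small_grid.shape, bool), tiny_study.atlas, small_grid
        )
        assert np.all(sev == 0.0)

    def test_recount_from_find_disconnected(self, small_grid, tiny_study, rng):
        lesion = rng.random(small_grid.shape) < 0.03
        atlas = tiny_study.atlas
        sev = tract_disconnection(lesion, atlas, small_grid)
        hit = set(find_disconnected(lesion, atlas, small_grid))
        for t in range(1, atlas.n_tracts + 1):
            members = np.flatnonzero(atlas.tract_labels == t)
            expected = 100.0 * len(set(members) & hit) / len(members)
            assert sev[t - 1] == pytest.approx(expected)


class TestLesionVolume:
    def test_volume_arithmetic(self):
        grid = ReferenceGrid(shape=(10, 10, 10), voxel_size=(2, 2, 2))
        lesion = np.zeros(grid.shape, bool)
        lesion[:5, :5, :5] = True  # 125 voxels at 8 mm^3 each
        vol, frac = lesion_volume(lesion, grid=grid)
        assert vol == pytest.approx(1.0)
        assert frac == pytest.approx(125 / 1000)

    def test_lesion_equals_brain_mask(self, small_grid):
        mask = np.ones(small_grid.shape, bool)
        _, frac = lesion_volume(mask, brain_mask=mask, grid=small_grid)
        assert frac == 1.0

    def test_outside_brain_warns_but_counts(self, small_grid):
        lesion = np.zeros(small_grid.shape, bool)
        lesion[0, 0, 0] = True
        brain = np.zeros(small_grid.shape, bool)
        brain[5:10, 5:10, 5:10] = True
        with pytest.warns(UserWarning, match="outside"):
            vol, _ = lesion_volume(lesion, brain_mask=brain, grid=small_grid)
        assert vol > 0


class TestDisconnectionMapper:
    def test_transform_matches_single_map_path(self, small_grid, tiny_study):
        mapper = DisconnectionMapper(
            atlas=tiny_study.atlas, grid=small_grid
        ).fit()
        stack = mapper.transform(tiny_study.lesions[:5])
        for i in range(5):
            single = disconnection_severity_map(
                tiny_study.lesions[i], tiny_study.atlas, small_grid
            )
            np.testing.assert_allclose(stack[i], single.severity.data)

    def test_tract_severities_match(self, small_grid, tiny_study):
        mapper = DisconnectionMapper(
            atlas=tiny_study.atlas, grid=small_grid
        ).fit()
        got = mapper.tract_severities(tiny_study.lesions[:5])
        for i in range(5):
            expected = tract_disconnection(
                tiny_study.lesions[i], tiny_study.atlas, small_grid
            )
            np.testing.assert_allclose(got[i], expected)

    def test_sklearn_params_roundtrip(self, small_grid, tiny_study):
        mapper = DisconnectionMapper(atlas=tiny_study.atlas, grid=small_grid)
        params = mapper.get_params()
        assert set(params) == {"atlas", "grid"}
        mapper.set_params(grid=small_grid)
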