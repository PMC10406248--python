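"""Volume/mask substrate: I/O round trips, geometry, morphology oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strokewmh.volumes import (
    AffineTransform,
    GridError,
    LabelMask,
    Volume3D,
    check_same_grid,
    connected_components,
    dilate_mask,
    distance_to_mask,
    read_affine_matrix,
    read_mask,
    read_volume,
    resample_affine,
    write_affine_matrix,
    write_volume,
)

from .conftest import random_mask


# ---------------------------------------------------------------------------
# containers


def test_volume_invariants_enforced():
    with pytest.raises(ValueError):
        Volume3D(np.zeros((4, 4)))  # not 3D
    with pytest.raises(ValueError):
        Volume3D(np.zeros((4, 4, 4)), np.zeros((4, 4)))  # singular affine
    with pytest.raises(ValueError):
        Volume3D(np.zeros((4, 4, 4)), modality="BOLD")


def test_mask_rejects_nonbinary_values():
    with pytest.raises(ValueError):
        LabelMask(np.arange(8).reshape(2, 2, 2))
    m = LabelMask(np.ones((2, 2, 2), dtype=np.uint8), role="BRAIN")
    assert m.data.dtype == bool and m.n_voxels == 8


def test_voxel_size_and_volume_from_affine():
    aff = np.diag([0.5, 1.0, 3.0, 1.0])
    v = Volume3D(np.zeros((4, 4, 4)), aff)
    assert v.voxel_size == (0.5, 1.0, 3.0)
    assert v.voxel_volume_mm3 == pytest.approx(1.5)


def test_world_coordinates_apply_affine():
    aff = np.eye(4)
    aff[:3, 3] = (10.0, 20.0, 30.0)
    v = Volume3D(np.zeros((4, 4, 4)), aff)
    np.testing.assert_allclose(v.world_coordinates([[1, 2, 3]]), [[11.0, 22.0, 33.0]])


# ---------------------------------------------------------------------------
# I/O


def test_nifti_round_trip_is_lossless(tmp_path, rng):
    aff = np.eye(4)
    aff[:3, 3] = (-3.0, 1.5, 2.0)
    vol = Volume3D(rng.random((8, 8, 8)), aff, "FLAIR")
    path = tmp_path / "vol.nii.gz"
    write_volume(vol, path)
    back = read_volume(path, "FLAIR")
    np.testing.assert_array_equal(back.data, vol.data)
    np.testing.assert_allclose(back.affine, vol.affine)


def test_mask_round_trip_stays_binary(tmp_path, rng):
    mask = random_mask(rng, (8, 8, 8))
    path = tmp_path / "mask.nii.gz"
    write_volume(mask, path)
    back = read_mask(path, "BRAIN")
    np.testing.assert_array_equal(back.data, mask.data)


def test_reading_4d_image_is_a_dimension_error(tmp_path):
    import nibabel as nib

    path = tmp_path / "4d.nii.gz"
    nib.Nifti1Image(np.zeros((4, 4, 4, 3)), np.eye(4)).to_filename(str(path))
    with pytest.raises(ValueError, match="3D"):
        read_volume(path)


def test_affine_matrix_text_round_trip(tmp_path):
    mat = np.array(
        [[1.0, 0, 0, 2.5], [0, 0.9, 0.1, -1], [0, -0.1, 0.9, 0], [0, 0, 0, 1.0]]
    )
    path = tmp_path / "xfm.mat"
    write_affine_matrix(mat, path)
    np.testing.assert_allclose(read_affine_matrix(path), mat)


# ---------------------------------------------------------------------------
# resampling


def test_identity_resample_is_exact(rng):
    vol = Volume3D(rng.random((6, 6, 6)))
    out = resample_affine(vol, AffineTransform.identity(), vol.shape, vol.affine)
    np.testing.assert_allclose(out.data, vol.data, atol=1e-12)


def test_integer_translation_equals_index_shift():
    data = np.zeros((6, 6, 6), dtype=np.uint8)
    data[2, 3, 3] = 1
    mask = LabelMask(data)
    t = np.eye(4)
    t[0, 3] = 1.0  # +1 voxel along axis 0 in world mm (1 mm voxels)
    out = resample_affine(mask, AffineTransform(t, "nearest"), mask.shape, mask.affine)
    expected = np.zeros_like(data, dtype=bool)
    expected[3, 3, 3] = True
    np.testing.assert_array_equal(out.data, expected)


def test_trilinear_preserves_constant_images():
    vol = Volume3D(np.full((6, 6, 6), 3.25))
    t = np.eye(4)
    t[:3, 3] = (0.4, -0.3, 0.2)
    out = resample_affine(vol, AffineTransform(t), vol.shape, vol.affine)
    interior = out.data[1:-1, 1:-1, 1:-1]
    np.testing.assert_allclose(interior, 3.25, atol=1e-12)


def test_singular_transform_rejected():
    with pytest.raises(ValueError, match="singular"):
        AffineTransform(np.zeros((4, 4)))


def test_grid_compatibility_check():
    a = Volume3D(np.zeros((4, 4, 4)))
    b = Volume3D(np.zeros((4, 4, 5)))
    with pytest.raises(GridError):
        check_same_grid(a, b)
    aff = np.eye(4)
    aff[0, 3] = 1.0
    c = Volume3D(np.zeros((4, 4, 4)), aff)
    with pytest.raises(GridError):
        check_same_grid(a, c)


# ---------------------------------------------------------------------------
# dilation


def test_dilation_radius_zero_is_identity(rng):
    m = random_mask(rng)
    out = dilate_mask(m, 0.0)
    np.testing.assert_array_equal(out.data, m.data)


def test_dilation_1mm_isotropic_gives_face_neighbours():
    data = np.zeros((5, 5, 5), dtype=bool)
    data[2, 2, 2] = True
    out = dilate_mask(LabelMask(data), 1.0)
    assert out.n_voxels == 7  # centre + 6 face neighbours


def test_dilation_honours_anisotropic_voxels():
    # 2 mm slices along z: a 1.5 mm ball must not reach the z neighbours
    aff = np.diag([1.0, 1.0, 2.0, 1.0])
    data = np.zeros((5, 5, 5), dtype=bool)
    data[2, 2, 2] = True
    out = dilate_mask(LabelMask(data, aff), 1.5)
    assert out.data[2, 2, 1] == out.data[2, 2, 3] == False  # noqa: E712
    assert out.data[1, 2, 2] and out.data[2, 1, 2]


def test_dilation_of_full_mask_unchanged():
    m = LabelMask(np.ones((4, 4, 4), dtype=bool))
    assert dilate_mask(m, 2.0).n_voxels == 64


def test_negative_radius_rejected(rng):
    with pytest.raises(ValueError):
        dilate_mask(random_mask(rng), -0.1)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1), st.floats(0.0, 3.0), st.floats(0.0, 3.0))
def test_dilation_monotone_in_radius(seed, r1, r2):
    rng = np.random.default_rng(seed)
    m = random_mask(rng, (8, 8, 8))
    a, b = sorted((r1, r2))
    small, big = dilate_mask(m, a), dilate_mask(m, b)
    assert np.all(small.data <= big.data)


# ---------------------------------------------------------------------------
# connected components


def _flood_fill_count(mask: np.ndarray, connectivity: int) -> int:
    """BFS flood-fill oracle."""
    if connectivity == 6:
        offsets = [o for o in itertools.product((-1, 0, 1), repeat=3)
                   if sum(map(abs, o)) == 1]
    else:
        offsets = [o for o in itertools.product((-1, 0, 1), repeat=3)
                   if any(o)]
        if connectivity == 18:
            offsets = [o for o in offsets if sum(map(abs, o)) <= 2]
    seen = np.zeros_like(mask, dtype=bool)
    count = 0
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        count += 1
        stack = [start]
        seen[start] = True
        while stack:
            x, y, z = stack.pop()
            for dx, dy, dz in offsets:
                n = (x + dx, y + dy, z + dz)
                if all(0 <= n[i] < mask.shape[i] for i in range(3)) and mask[n] and not seen[n]:
                    seen[n] = True
                    stack.append(n)
    return count


def test_empty_mask_has_zero_components():
    _, n = connected_components(LabelMask(np.zeros((4, 4, 4), dtype=bool)))
    assert n == 0


def test_corner_adjacency_depends_on_connectivity():
    data = np.zeros((3, 3, 3), dtype=bool)
    data[0, 0, 0] = data[1, 1, 1] = True  # share only a corner
    m = LabelMask(data)
    assert connected_components(m, 26)[1] == 1
    assert connected_components(m, 6)[1] == 2


@pytest.mark.parametrize("connectivity", [6, 26])
def test_components_match_flood_fill_on_all_3x3x1_grids(connectivity):
    for bits in range(2**9):
        arr = np.array([(bits >> i) & 1 for i in range(9)], dtype=bool)
        mask = LabelMask(arr.reshape(3, 3, 1))
        _, n = connected_components(mask, connectivity)
        assert n == _flood_fill_count(mask.data, connectivity), bits


def test_components_match_flood_fill_on_random_grids(rng):
    for _ in range(10):
        m = random_mask(rng, (16, 16, 16), p=0.3)
        for connectivity in (6, 18, 26):
            _, n = connected_components(m, connectivity)
            assert n == _flood_fill_count(m.data, connectivity)


def test_every_masked_voxel_is_labelled(rng):
    m = random_mask(rng, (10, 10, 10), p=0.4)
    labels, n = connected_components(m)
    assert set(np.unique(labels[m.data])) == set(range(1, n + 1))
    assert np.all(labels[~m.data] == 0)


# ---------------------------------------------------------------------------
# distance transform


def test_distance_simple_neighbours():
    data = np.zeros((5, 5, 5), dtype=bool)
    data[2, 2, 2] = True
    d = distance_to_mask(LabelMask(data)).data
    assert d[2, 2, 2] == 0.0
    assert d[3, 2, 2] == pytest.approx(1.0)
    assert d[3, 3, 3] == pytest.approx(np.sqrt(3.0))


def test_distance_zero_on_mask(rng):
    m = random_mask(rng, (8, 8, 8), p=0.3)
    d = distance_to_mask(m).data
    assert np.all(d[m.data] == 0)


def test_empty_mask_distance_is_error():
    with pytest.raises(ValueError):
        distance_to_mask(LabelMask(np.zeros((3, 3, 3), dtype=bool)))


def test_distance_matches_brute_force_with_anisotropy(rng):
    aff = np.diag([1.0, 1.5, 2.0, 1.0])
    for _ in range(5):
        data = rng.random((12, 12, 12)) < 0.05
        if not data.any():
            data[0, 0, 0] = True
        m = LabelMask(data, aff)
        d = distance_to_mask(m).data
        pts = np.argwhere(data) * np.array([1.0, 1.5, 2.0])
        grid = np.indices(data.shape).reshape(3, -1).T * np.array([1.0, 1.5, 2.0])
        brute = np.sqrt(
            ((grid[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
        ).min(1).reshape(data.shape)
        np.testing.assert_allclose(d, brute, atol=1e-9)
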