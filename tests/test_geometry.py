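import numpy as np
import pytest

from perirad.errors import EmptyMaskError, GridMismatchError
from perirad.geometry import (
    ball_element,
    build_tst,
    dilate_mm,
    erode_mm,
    resample_isotropic,
    ring_qc,
)
from perirad.grids import BinaryMask, Volume

from .conftest import sphere_mask


# ------------------------------------------------------------ ball_element

def test_ball_radius_zero_is_single_center():
    elem = ball_element(0.0, (1.0, 1.0, 1.0))
    assert elem.shape == (1, 1, 1)
    assert elem.sum() == 1


def test_ball_isotropic_count_matches_enumeration():
    # independent enumeration of integer offsets with x^2+y^2+z^2 <= 4
    count = sum(
        1
        for x in range(-2, 3)
        for y in range(-2, 3)
        for z in range(-2, 3)
        if x * x + y * y + z * z <= 4
    )
    assert count == 33
    elem = ball_element(2.0, (1.0, 1.0, 1.0))
    assert elem.sum() == count


def test_ball_anisotropic_limits_z_extent():
    elem = ball_element(2.0, (1.0, 1.0, 2.0))
    assert elem.shape[2] == 3  # |z| <= 1 voxel at 2 mm spacing
    expected = sum(
        1
        for x in range(-2, 3)
        for y in range(-2, 3)
        for z in range(-1, 2)
        if x * x + y * y + (2 * z) ** 2 <= 4
    )
    assert elem.sum() == expected


def test_ball_negative_radius_raises():
    with pytest.raises(ValueError):
        ball_element(-1.0, (1.0, 1.0, 1.0))


def test_ball_reflection_symmetric():
    elem = ball_element(3.0, (1.0, 1.2, 2.0))
    for axis in range(3):
        assert np.array_equal(elem, np.flip(elem, axis=axis))


# ------------------------------------------------------------ build_tst

def test_tst_sphere_is_4mm_thick_along_axes():
    mask = sphere_mask(10)
    ring = build_tst(mask)
    c = mask.shape[0] // 2
    line = ring.values[:, c, c]
    # two runs of exactly 4 voxels (4 mm) on either side of the center
    runs = np.flatnonzero(line)
    assert len(runs) == 8
    left, right = runs[:4], runs[4:]
    assert np.array_equal(np.diff(left), [1, 1, 1])
    assert np.array_equal(np.diff(right), [1, 1, 1])


def test_tst_disjoint_union_with_erosion():
    mask = sphere_mask(8)
    ring = build_tst(mask)
    ero = erode_mm(mask, 2.0)
    dil = dilate_mm(mask, 2.0)
    assert not (ring.bool() & ero.bool()).any()
    assert np.array_equal(ring.bool() | ero.bool(), dil.bool())


def test_tst_single_voxel_equals_dilation_ball():
    # brute-force oracle on the 5^3 neighborhood: erosion of a single voxel
    # is empty, so the ring is the dilation ball itself
    vals = np.zeros((5, 5, 5), dtype=np.uint8)
    vals[2, 2, 2] = 1
    mask = BinaryMask(values=vals, spacing=(1.0, 1.0, 1.0))
    ring = build_tst(mask)
    expected = np.zeros((5, 5, 5), dtype=bool)
    for x in range(5):
        for y in range(5):
            for z in range(5):
                if (x - 2) ** 2 + (y - 2) ** 2 + (z - 2) ** 2 <= 4:
                    expected[x, y, z] = True
    assert np.array_equal(ring.bool(), expected)


def test_tst_empty_input_raises():
    empty = BinaryMask(values=np.zeros((4, 4, 4), dtype=np.uint8), spacing=(1, 1, 1))
    with pytest.raises(EmptyMaskError):
        build_tst(empty)


def test_tst_zero_radii_raises():
    with pytest.raises(EmptyMaskError):
        build_tst(sphere_mask(5), dilate_radius_mm=0.0, erode_radius_mm=0.0)


# ------------------------------------------------------------ morphology oracles

def _oracle_morph(mask: np.ndarray, offsets: np.ndarray, dilate: bool) -> np.ndarray:
    out = np.zeros_like(mask, dtype=bool)
    shape = mask.shape
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                hits = []
                for dx, dy, dz in offsets:
                    u, v, w = x + dx, y + dy, z + dz
                    inside = (
                        0 <= u < shape[0] and 0 <= v < shape[1] and 0 <= w < shape[2]
                    )
                    hits.append(bool(mask[u, v, w]) if inside else False)
                out[x, y, z] = any(hits) if dilate else all(hits)
    return out


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_dilation_erosion_match_bruteforce_oracle(seed):
    rng = np.random.default_rng(seed)
    vals = (rng.random((16, 16, 16)) < 0.4).astype(np.uint8)
    vals[0, 0, 0] = 1  # ensure nonempty
    mask = BinaryMask(values=vals, spacing=(1.0, 1.0, 1.0))
    elem = ball_element(2.0, mask.spacing)
    offsets = np.argwhere(elem) - np.array(elem.shape) // 2

    assert np.array_equal(dilate_mm(mask, 2.0).bool(), _oracle_morph(vals.astype(bool), offsets, True))
    assert np.array_equal(erode_mm(mask, 2.0).bool(), _oracle_morph(vals.astype(bool), offsets, False))


def test_erosion_is_dual_of_dilation_on_padded_grid():
    rng = np.random.default_rng(7)
    vals = np.zeros((20, 20, 20), dtype=np.uint8)
    vals[4:16, 4:16, 4:16] = (rng.random((12, 12, 12)) < 0.5).astype(np.uint8)
    vals[10, 10, 10] = 1
    mask = BinaryMask(values=vals, spacing=(1.0, 1.0, 1.0))
    complement = BinaryMask(values=1 - vals, spacing=(1.0, 1.0, 1.0))
    ero = erode_mm(mask, 2.0).bool()
    dual = ~dilate_mm(complement, 2.0).bool()
    assert np.array_equal(ero, dual)


# ------------------------------------------------------------ resampling

def test_resample_identity_when_already_isotropic():
    mask = sphere_mask(5)
    vol = Volume(values=np.arange(np.prod(mask.shape), dtype=float).reshape(mask.shape),
                 spacing=mask.spacing)
    out_vol, out_mask = resample_isotropic(vol, mask, 1.0)
    assert out_vol is vol
    assert np.array_equal(out_mask.values, mask.values)


def test_resample_preserves_sphere_volume():
    mask = sphere_mask(10)
    vol = Volume(values=np.ones(mask.shape), spacing=mask.spacing)
    _, coarse = resample_isotropic(vol, mask, 2.0)
    analytic = 4 / 3 * np.pi * 10**3
    measured = coarse.n_voxels * 8.0
    assert abs(measured - analytic) / analytic < 0.10


def test_resample_rejects_bad_target_and_mismatched_grids():
    mask = sphere_mask(4)
    vol = Volume(values=np.ones(mask.shape), spacing=mask.spacing)
    with pytest.raises(ValueError):
        resample_isotropic(vol, mask, 0.0)
    other = Volume(values=np.ones((4, 4, 4)), spacing=(1, 1, 1))
    with pytest.raises(GridMismatchError):
        resample_isotropic(other, mask, 1.0)


def test_resample_mask_binary_output():
    mask = sphere_mask(6, spacing=(1.0, 1.0, 2.0))
    vol = Volume(values=np.random.default_rng(0).random(mask.shape), spacing=mask.spacing)
    _, out = resample_isotropic(vol, mask, 3.0)
    assert set(np.unique(out.values)) <= {0, 1}


def test_ring_qc_reports_counts():
    mask = sphere_mask(6)
    ring = build_tst(mask)
    qc = ring_qc(ring, mask)
    assert qc["ring_voxels"] == ring.n_voxels
    assert qc["touches_image_boundary"] is False
    assert qc["tumor_voxels"] == mask.n_voxels
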