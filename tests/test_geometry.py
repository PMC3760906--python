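"""Morphometry and the equal-volume shell partition."""

import numpy as np
import pytest
from scipy import stats

from nucshell import (
    DegenerateGeometryError,
    SimulationConfig,
    Spot,
    assign_spots,
    equal_volume_shells,
    fit_ellipsoid,
    morphometry_table,
    radial_coordinate,
    sample_spots,
    simulate_nucleus,
)
from nucshell.config import stage_rng
from nucshell.imaging import NucleusMask
from tests.conftest import make_sphere_mask


# --- ellipsoid fit -------------------------------------------------------

def test_sphere_fit_recovers_radius_and_unity_flattening(sphere_mask):
    fit = fit_ellipsoid(sphere_mask)
    assert np.all(np.abs(fit.semi_axes - 5.0) / 5.0 < 0.03)
    assert 1.0 <= fit.flattening < 1.05


def test_rotated_ellipsoid_fit_recovers_axes():
    cfg = SimulationConfig(
        seed=5, semi_axes_mean=(8.0, 6.0, 2.4), semi_axes_cv=0.0,
        condition_scale={"myoblast": (1.0, 1.0, 1.0)},
    )
    for s in range(3):
        mask, truth = simulate_nucleus(cfg, "myoblast", stage_rng(s, "fit"))
        fit = fit_ellipsoid(mask)
        assert np.all(np.abs(fit.semi_axes - truth.semi_axes) / truth.semi_axes < 0.05)
        assert abs(fit.flattening - 8.0 / 2.4) / (8.0 / 2.4) < 0.05


def test_volume_is_count_times_voxel_volume(sphere_mask):
    fit = fit_ellipsoid(sphere_mask)
    assert fit.volume == sphere_mask.mask.sum() * 0.2**3


def test_planar_mask_raises_degenerate():
    mask = np.zeros((5, 20, 20), bool)
    mask[2] = True
    with pytest.raises(DegenerateGeometryError):
        fit_ellipsoid(NucleusMask(1, mask, (0.3, 0.2, 0.2)))


# --- radial coordinate ---------------------------------------------------

def test_radial_modes_agree_on_sphere(sphere_mask):
    edt = radial_coordinate(sphere_mask, "edt")[sphere_mask.mask]
    ell = radial_coordinate(sphere_mask, "ellipsoid")[sphere_mask.mask]
    assert stats.spearmanr(edt, ell).statistic > 0.99


def test_center_voxel_near_zero_border_voxel_maximal(sphere_mask):
    coord = radial_coordinate(sphere_mask, "edt")
    center = tuple((np.array(sphere_mask.mask.shape) - 1) // 2)
    # one-voxel tolerance at the center of a digital sphere
    assert coord[center] <= 0.2 / 5.0 + 1e-9
    inside = coord[sphere_mask.mask]
    # border voxels (one voxel from background) carry the maximal coordinate
    assert inside.max() == pytest.approx(1.0 - 0.2 / 5.0, abs=1e-9)
    from scipy import ndimage

    border = sphere_mask.mask & ~ndimage.binary_erosion(sphere_mask.mask)
    assert np.isclose(coord[border].max(), inside.max())


def test_unknown_mode_rejected(sphere_mask):
    with pytest.raises(ValueError):
        radial_coordinate(sphere_mask, "spiral")


# --- equal-volume shells -------------------------------------------------

def test_k1_is_identity(sphere_mask):
    part = equal_volume_shells(sphere_mask, k=1)
    assert part.boundaries.size == 0
    assert np.array_equal(part.labels > 0, sphere_mask.mask)


def test_k_exceeding_voxels_raises():
    tiny = np.zeros((3, 3, 3), bool)
    tiny[1, 1, 1] = True
    tiny[1, 1, 2] = True
    with pytest.raises(ValueError):
        equal_volume_shells(NucleusMask(1, tiny, (0.2, 0.2, 0.2)), k=5)


@pytest.mark.parametrize("k", [2, 5, 7])
def test_equal_volume_contract(myoblast_nucleus, k):
    """Every shell's volume deviates from total/K by at most one voxel."""
    mask, _ = myoblast_nucleus
    part = equal_volume_shells(mask, k=k)
    target = mask.volume / k
    assert np.max(np.abs(part.shell_volumes - target)) <= k * mask.voxel_volume
    assert np.all(np.diff(part.boundaries) > 0) or k <= 2
    covered = part.labels[mask.mask]
    assert covered.min() >= 1 and covered.max() == k
    assert np.all(part.labels[~mask.mask] == 0)


def test_sphere_shell_boundary_matches_analytic_radius():
    """Innermost equal-volume boundary of a sphere sits at (1/5)^(1/3) R."""
    mask = make_sphere_mask(10.0, (0.2, 0.2, 0.2))
    fit = fit_ellipsoid(mask)
    part = equal_volume_shells(mask, k=5, mode="ellipsoid")
    r1 = part.boundaries[0] * fit.semi_axes[0]
    expected = (1.0 / 5.0) ** (1.0 / 3.0) * 10.0
    assert abs(r1 - expected) / expected < 0.02


def test_mode_agreement_on_sphere(sphere_mask):
    edt = equal_volume_shells(sphere_mask, k=5, mode="edt")
    ell = equal_volume_shells(sphere_mask, k=5, mode="ellipsoid")
    inside = sphere_mask.mask
    agreement = np.mean(edt.labels[inside] == ell.labels[inside])
    assert agreement >= 0.95


def test_mode_disagreement_is_adjacent_shells(myoblast_nucleus):
    """On a flattened ellipsoid the EDT (offset) and ellipsoid (scaled)
    partitions diverge, but almost always by a single shell index."""
    mask, _ = myoblast_nucleus
    edt = equal_volume_shells(mask, k=5, mode="edt")
    ell = equal_volume_shells(mask, k=5, mode="ellipsoid")
    inside = mask.mask
    diff = np.abs(edt.labels[inside].astype(int) - ell.labels[inside].astype(int))
    assert diff.max() <= 2
    assert np.mean(diff <= 1) >= 0.995


def test_shell_index_nested_along_rays(sphere_partition, sphere_mask):
    """Shell index never decreases walking outward from the deepest voxel."""
    coord = radial_coordinate(sphere_mask, "edt")
    start = np.unravel_index(
        np.argmin(np.where(sphere_mask.mask, coord, np.inf)), coord.shape
    )
    labels = sphere_partition.labels
    for direction in ([1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 0], [1, 1, 1]):
        pos = np.array(start)
        seen = [labels[tuple(pos)]]
        while True:
            pos = pos + direction
            if np.any(pos >= labels.shape) or labels[tuple(pos)] == 0:
                break
            seen.append(labels[tuple(pos)])
        assert np.all(np.diff(seen) >= 0)


def test_rotation_by_90_degrees_permutes_nothing(default_config):
    """Rotating an isotropically sampled nucleus by 90° leaves its shell
    partition unchanged, except for voxels sitting exactly on a quantile
    boundary, whose deterministic raster tie-break may move them one
    shell."""
    cfg = SimulationConfig(
        seed=17, voxel_spacing=(0.3, 0.3, 0.3), semi_axes_mean=(6.0, 5.0, 3.0),
        semi_axes_cv=0.0, condition_scale={"myoblast": (1.0, 1.0, 1.0)},
    )
    rng = stage_rng(17, "rot")
    mask, truth = simulate_nucleus(cfg, "myoblast", rng)
    spots, part = sample_spots(mask, truth, (0.2,) * 5, 40, rng)
    coord = radial_coordinate(mask, "edt")
    boundary_values = set(np.round(part.boundaries, 12))
    for axes in ((0, 1), (1, 2), (0, 2)):
        rot_mask = NucleusMask(1, np.rot90(mask.mask, axes=axes), cfg.voxel_spacing)
        rot_part = equal_volume_shells(rot_mask, k=5)
        assert np.array_equal(part.shell_volumes, rot_part.shell_volumes)
        n = mask.mask.shape[axes[1]]
        for s in spots:
            vox = np.round(s.position / mask.spacing).astype(int)
            rv = vox.copy()
            rv[axes[0]], rv[axes[1]] = n - 1 - vox[axes[1]], vox[axes[0]]
            rotated_shell = rot_part.labels[tuple(rv)]
            if rotated_shell != s.shell:
                assert abs(int(rotated_shell) - s.shell) == 1
                assert round(float(coord[tuple(vox)]), 12) in boundary_values


# --- spot assignment -----------------------------------------------------

def test_spot_at_sphere_center_lands_in_shell_one(sphere_mask, sphere_partition):
    center = (np.array(sphere_mask.mask.shape) - 1) / 2 * sphere_mask.spacing
    spot = Spot(tuple(center), nucleus_label=1, probe="HSA1")
    dists, audit = assign_spots([spot], {1: sphere_partition}, condition="c")
    assert audit.shell.tolist() == [1]


def test_spot_just_outside_mask_is_snapped_far_spot_discarded(
    sphere_mask, sphere_partition
):
    shape = np.array(sphere_mask.mask.shape)
    center = (shape - 1) / 2
    # first voxel outside the sphere surface along +z, within 1 voxel of mask
    z = int(center[0] + np.ceil(5.0 / 0.2)) + 1
    near = Spot(tuple(np.array([z, center[1], center[2]]) * 0.2),
                nucleus_label=1, probe="p")
    far = Spot((0.0, 0.0, 0.0), nucleus_label=1, probe="p")
    dists, audit = assign_spots([near, far], {1: sphere_partition}, condition="c")
    assert len(audit) == 1
    assert audit.shell.tolist() == [5]


def test_uniform_spots_match_uniform_null(myoblast_nucleus):
    """Uniformly placed spots are consistent with 1/K per shell."""
    mask, _ = myoblast_nucleus
    part = equal_volume_shells(mask, k=5)
    rng = stage_rng(23, "unif")
    voxels = np.argwhere(mask.mask)
    rejections = 0
    for _ in range(40):
        chosen = voxels[rng.integers(len(voxels), size=300)]
        counts = np.bincount(part.labels[tuple(chosen.T)], minlength=6)[1:]
        p = stats.chisquare(counts).pvalue
        rejections += p <= 0.01
    assert rejections <= 2  # >=95% of replicates keep p > 0.01


def test_morphometry_table_orders_conditions(default_config):
    rng = stage_rng(31, "morphtab")
    masks = []
    for i in range(6):
        cond = "myoblast" if i % 2 == 0 else "myocyte"
        mask, _ = simulate_nucleus(default_config, cond, rng, nucleus_id=i + 1)
        masks.append(mask)
    table = morphometry_table(masks)
    assert len(table) == 6
    med = table.groupby("condition").median()
    assert med.loc["myocyte", "volume_um3"] < med.loc["myoblast", "volume_um3"]
    assert med.loc["myocyte", "flattening"] > med.loc["myoblast", "flattening"]


def test_morphometry_table_empty_input():
    table = morphometry_table([])
    assert table.empty
    assert list(table.columns) == ["nucleus", "condition", "volume_um3", "flattening"]
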