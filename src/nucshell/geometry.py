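"""Nucleus morphometry and the equal-volume concentric shell partition.

The radial position of a voxel can be measured two ways:

``edt``
    1 − d/d_max, where d is the Euclidean distance (µm) from the voxel to
    the nearest background voxel.  0 at the deepest interior point, → 1
    at the border.  Works for arbitrary mask shapes and is the default.
``ellipsoid``
    The scale s at which the voxel lies on the s-scaled fitted ellipsoid
    surface (a Mahalanobis-type radius in the principal frame).

Equal-volume shells are cut at the empirical K-quantiles of the radial
coordinate over mask voxels, with ties broken deterministically in raster
order, which bounds every shell's volume deviation by one voxel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from nucshell.errors import DegenerateGeometryError
from nucshell.imaging import NucleusMask, Spot

log = logging.getLogger(__name__)


@dataclass
class EllipsoidFit:
    """Inertia-equivalent ellipsoid of a voxel mask.

    Semi-axes are √(5 λᵢ) for the eigenvalues λᵢ of the voxel-coordinate
    covariance, which makes a uniformly filled ellipsoid map onto itself.
    Flattening is the dimensionless ratio a/c of longest to shortest
    semi-axis (≥ 1; 1 for a sphere).
    """

    center: np.ndarray  # µm (z, y, x)
    semi_axes: np.ndarray  # µm, descending (a, b, c)
    axes: np.ndarray  # rows = principal directions, orthonormal
    volume: float  # µm³, voxel count × voxel volume
    flattening: float  # a / c


@dataclass
class ShellPartition:
    """K equal-volume co-centric shells of one nucleus (1 = innermost)."""

    k: int
    labels: np.ndarray  # int16 (Z, Y, X); 0 outside the mask
    boundaries: np.ndarray  # K-1 increasing radial-coordinate cutoffs
    shell_volumes: np.ndarray  # µm³, length K
    mode: str
    voxel_spacing: tuple[float, float, float]

    def shell_of_voxel(self, voxel: Sequence[int]) -> int:
        """Shell index of a voxel (0 if outside the mask)."""
        return int(self.labels[tuple(int(v) for v in voxel)])


@dataclass
class ShellDistribution:
    """Shell counts for one probe in one condition."""

    probe: str
    condition: str
    counts: np.ndarray  # K non-negative ints

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, int)
        if np.any(self.counts < 0):
            raise ValueError("shell counts must be non-negative")

    @property
    def k(self) -> int:
        return len(self.counts)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def percentages(self) -> np.ndarray:
        """Counts as percentages, half-up rounded to 2 decimals."""
        from nucshell.shell_stats import round_half_up

        return round_half_up(100.0 * self.counts / self.n, 2)


def fit_ellipsoid(mask: NucleusMask) -> EllipsoidFit:
    """Fit the inertia-equivalent ellipsoid of a nucleus mask.

    Raises
    ------
    DegenerateGeometryError
        If the voxel set is planar/linear (a vanishing principal moment).
    """
    coords = np.argwhere(mask.mask) * mask.spacing
    center = coords.mean(axis=0)
    centered = coords - center
    cov = centered.T @ centered / len(coords)
    eigval, eigvec = np.linalg.eigh(cov)  # ascending
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    voxel_scale = float(np.min(mask.spacing))
    if eigval[-1] <= (0.05 * voxel_scale) ** 2:
        raise DegenerateGeometryError(
            "voxel set is degenerate (planar or linear); cannot fit ellipsoid"
        )
    semi_axes = np.sqrt(5.0 * eigval)
    return EllipsoidFit(
        center=center,
        semi_axes=semi_axes,
        axes=eigvec.T,
        volume=mask.volume,
        flattening=float(semi_axes[0] / semi_axes[2]),
    )


def radial_coordinate(
    mask: NucleusMask, mode: str = "edt", fit: EllipsoidFit | None = None
) -> np.ndarray:
    """Per-voxel radial coordinate, increasing from center to periphery.

    Returns a float grid; values are meaningful inside the mask only
    (0 outside).  ``edt`` mode is normalised to [0, 1]; ``ellipsoid``
    mode returns the Mahalanobis-type ellipsoid radius (≈1 at the
    surface of the fitted ellipsoid).
    """
    if mode == "edt":
        padded = np.pad(mask.mask, 1)
        dist = ndimage.distance_transform_edt(padded, sampling=mask.spacing)
        dist = dist[1:-1, 1:-1, 1:-1]
        dmax = dist[mask.mask].max()
        if dmax <= 0:
            raise DegenerateGeometryError("mask has no interior")
        coord = np.where(mask.mask, 1.0 - dist / dmax, 0.0)
        return coord
    if mode == "ellipsoid":
        fit = fit or fit_ellipsoid(mask)
        coords = np.argwhere(mask.mask) * mask.spacing
        body = (coords - fit.center) @ fit.axes.T
        s = np.sqrt(((body / fit.semi_axes) ** 2).sum(axis=1))
        out = np.zeros(mask.mask.shape)
        out[mask.mask] = s
        return out
    raise ValueError(f"unknown radial mode {mode!r}")


def equal_volume_shells(
    mask: NucleusMask,
    k: int = 5,
    mode: str = "edt",
    coord: np.ndarray | None = None,
) -> ShellPartition:
    """Partition a nucleus into K co-centric shells of equal volume.

    Voxels are ranked by radial coordinate (stable sort, so boundary ties
    resolve in raster order) and split into K consecutive blocks of
    near-equal size; shell volumes therefore differ by at most one voxel.
    Shell 1 is innermost.
    """
    n_voxels = int(mask.mask.sum())
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n_voxels:
        raise ValueError(f"k={k} exceeds mask voxel count {n_voxels}")
    if coord is None:
        coord = radial_coordinate(mask, mode=mode)
    flat_idx = np.flatnonzero(mask.mask.ravel())
    values = coord.ravel()[flat_idx]
    order = np.argsort(values, kind="stable")
    edges = np.round(np.linspace(0, n_voxels, k + 1)).astype(int)
    labels = np.zeros(mask.mask.size, np.int16)
    for shell in range(k):
        labels[flat_idx[order[edges[shell] : edges[shell + 1]]]] = shell + 1
    labels = labels.reshape(mask.mask.shape)
    boundaries = np.array(
        [values[order[edges[shell] - 1]] for shell in range(1, k)]
    )
    shell_volumes = np.diff(edges) * mask.voxel_volume
    return ShellPartition(
        k=k,
        labels=labels,
        boundaries=boundaries,
        shell_volumes=shell_volumes.astype(float),
        mode=mode,
        voxel_spacing=mask.voxel_spacing,
    )


def assign_spots(
    spots: Iterable[Spot],
    partitions: Mapping[int, ShellPartition],
    condition: str = "",
    snap_radius_vox: float = 1.0,
) -> tuple[dict[tuple[str, str], ShellDistribution], pd.DataFrame]:
    """Assign each spot to the shell containing its centroid.

    A centroid that rounds to a voxel just outside its nucleus mask
    (possible after sub-voxel refinement) is snapped to the nearest mask
    voxel within ``snap_radius_vox`` voxels, else discarded and logged.

    Returns the per (probe, condition) aggregated :class:`ShellDistribution`
    and a per-spot audit table (probe, nucleus, shell).
    """
    rows = []
    n_discarded = 0
    for spot in spots:
        part = partitions.get(spot.nucleus_label)
        if part is None:
            raise KeyError(f"no shell partition for nucleus {spot.nucleus_label}")
        spacing = np.asarray(part.voxel_spacing, float)
        vox = np.round(spot.position / spacing).astype(int)
        vox = np.clip(vox, 0, np.array(part.labels.shape) - 1)
        shell = part.shell_of_voxel(vox)
        if shell == 0:
            shell = _snap_to_mask(part, vox, snap_radius_vox)
        if shell == 0:
            n_discarded += 1
            continue
        rows.append(
            {"probe": spot.probe, "condition": condition,
             "nucleus": spot.nucleus_label, "shell": shell}
        )
    if n_discarded:
        log.info("assign_spots: %d spot(s) outside mask discarded", n_discarded)
    audit = pd.DataFrame(rows, columns=["probe", "condition", "nucleus", "shell"])
    k = max(p.k for p in partitions.values())
    distributions: dict[tuple[str, str], ShellDistribution] = {}
    if len(audit):
        for (probe, cond), grp in audit.groupby(["probe", "condition"]):
            counts = np.bincount(grp["shell"], minlength=k + 1)[1:]
            distributions[(probe, cond)] = ShellDistribution(probe, cond, counts)
    return distributions, audit


def _snap_to_mask(part: ShellPartition, vox: np.ndarray, radius: float) -> int:
    """Nearest in-mask shell label within `radius` voxels (0 if none)."""
    r = int(np.ceil(radius))
    lo = np.maximum(vox - r, 0)
    hi = np.minimum(vox + r + 1, part.labels.shape)
    best, best_d2 = 0, np.inf
    for z in range(lo[0], hi[0]):
        for y in range(lo[1], hi[1]):
            for x in range(lo[2], hi[2]):
                lab = part.labels[z, y, x]
                if lab == 0:
                    continue
                d2 = float((z - vox[0]) ** 2 + (y - vox[1]) ** 2 + (x - vox[2]) ** 2)
                if d2 <= radius**2 + 1e-9 and d2 < best_d2:
                    best, best_d2 = int(lab), d2
    return best


def morphometry_table(masks: Sequence[NucleusMask]) -> pd.DataFrame:
    """Per-nucleus volume (µm³) and flattening for non-flagged masks."""
    rows = []
    for m in masks:
        if m.flagged:
            continue
        fit = fit_ellipsoid(m)
        rows.append(
            {
                "nucleus": m.label,
                "condition": m.condition,
                "volume_um3": fit.volume,
                "flattening": fit.flattening,
            }
        )
    return pd.DataFrame(rows, columns=["nucleus", "condition", "volume_um3", "flattening"])
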