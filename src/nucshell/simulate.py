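"""Synthetic 3-D FISH experiment generator with exact ground truth.

Emulates the study conditions end to end: ellipsoidal nuclei whose size
and flattening depend on differentiation state (myocyte nuclei smaller
and flatter), centromere spots placed according to per-shell probability
vectors (e.g. the rows of the published distribution table), rendering to
two-channel confocal-like stacks (anisotropic Gaussian PSF, Poisson
photon noise, additive Gaussian background), and two-group triplicate
log2 expression matrices with spiked ≥2-fold effects.

Every stochastic quantity is recorded as ground truth so downstream
stages (segmentation, morphometry, shell assignment, differential
expression) can be scored by parameter recovery.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.transform import Rotation

from nucshell.config import SimulationConfig, stage_rng, validate_shell_probs
from nucshell.errors import DegenerateGeometryError, SizingError
from nucshell.geometry import ShellPartition, equal_volume_shells
from nucshell.imaging import ImageStack, NucleusMask


@dataclass
class NucleusTruth:
    """True parameters of one simulated nucleus."""

    nucleus_id: int
    condition: str
    center: np.ndarray  # µm (z, y, x)
    semi_axes: np.ndarray  # µm, descending
    rotation: np.ndarray  # quaternion (x, y, z, w)

    @property
    def volume(self) -> float:
        """Analytic ellipsoid volume, µm³."""
        return float(4.0 / 3.0 * np.pi * np.prod(self.semi_axes))

    @property
    def flattening(self) -> float:
        return float(self.semi_axes[0] / self.semi_axes[2])


@dataclass
class SpotTruth:
    """True position and shell index of one simulated FISH signal."""

    nucleus_id: int
    probe: str
    position: np.ndarray  # µm (z, y, x)
    shell: int  # 1 = innermost


@dataclass
class GroundTruth:
    """Bundle of all truths for a simulated dataset."""

    nuclei: list[NucleusTruth] = field(default_factory=list)
    spots: list[SpotTruth] = field(default_factory=list)
    genes: pd.DataFrame | None = None

    def nuclei_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "nucleus": t.nucleus_id,
                    "condition": t.condition,
                    "center_z_um": t.center[0],
                    "center_y_um": t.center[1],
                    "center_x_um": t.center[2],
                    "a_um": t.semi_axes[0],
                    "b_um": t.semi_axes[1],
                    "c_um": t.semi_axes[2],
                    "qx": t.rotation[0],
                    "qy": t.rotation[1],
                    "qz": t.rotation[2],
                    "qw": t.rotation[3],
                    "volume_um3": t.volume,
                    "flattening": t.flattening,
                }
                for t in self.nuclei
            ]
        )

    def spots_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "nucleus": s.nucleus_id,
                    "probe": s.probe,
                    "z_um": s.position[0],
                    "y_um": s.position[1],
                    "x_um": s.position[2],
                    "shell": s.shell,
                }
                for s in self.spots
            ]
        )


def sample_nucleus_params(
    config: SimulationConfig,
    condition: str,
    rng: np.random.Generator,
    nucleus_id: int = 1,
) -> NucleusTruth:
    """Draw semi-axes (log-scale CV per axis) and a uniform random rotation.

    Separated from voxelization so that population-level morphometry
    (e.g. Mann-Whitney power over many nuclei) can be studied cheaply on
    the analytic parameters.
    """
    mean_axes = config.scaled_axes(condition)
    factors = np.exp(rng.normal(0.0, config.semi_axes_cv, 3))
    semi_axes = np.sort(mean_axes * factors)[::-1]
    quat = Rotation.random(rng=rng).as_quat()
    return NucleusTruth(
        nucleus_id=nucleus_id,
        condition=condition,
        center=np.zeros(3),
        semi_axes=semi_axes,
        rotation=np.asarray(quat, float),
    )


def simulate_nucleus(
    config: SimulationConfig,
    condition: str,
    rng: np.random.Generator,
    nucleus_id: int = 1,
    grid_shape: tuple[int, int, int] | None = None,
) -> tuple[NucleusMask, NucleusTruth]:
    """Voxelize one randomly oriented ellipsoidal nucleus.

    A voxel belongs to the mask iff its center satisfies the ellipsoid
    inequality.  The grid is sized to hold the ellipsoid plus a PSF
    margin unless ``grid_shape`` is given, in which case an ellipsoid
    exceeding the grid raises :class:`SizingError` naming the axis.
    """
    truth = sample_nucleus_params(config, condition, rng, nucleus_id)
    spacing = np.asarray(config.voxel_spacing, float)
    margin = 3.0 * np.asarray(config.psf_sigma, float) + 2.0 * spacing
    extent = 2.0 * truth.semi_axes[0] + 2.0 * margin  # orientation-safe bound
    if grid_shape is None:
        shape = tuple(int(np.ceil(e / s)) | 1 for e, s in zip(extent, spacing))
    else:
        shape = tuple(int(s) for s in grid_shape)
        for axis, (n, s) in enumerate(zip(shape, spacing)):
            if 2.0 * truth.semi_axes[0] > n * s:
                raise SizingError(
                    f"ellipsoid (a={truth.semi_axes[0]:.2f} µm) exceeds grid "
                    f"along axis {'zyx'[axis]} ({n} voxels × {s} µm)"
                )
    center = (np.asarray(shape) - 1) / 2.0 * spacing
    truth.center = center
    rot = Rotation.from_quat(truth.rotation).as_matrix()
    idx = np.indices(shape)
    rel = np.stack(idx, axis=-1) * spacing - center
    body = rel @ rot  # rotate world coords into the principal frame
    s2 = ((body / truth.semi_axes) ** 2).sum(axis=-1)
    mask_arr = s2 <= 1.0
    if not mask_arr.any():
        raise SizingError("ellipsoid contains no voxel centers; grid too coarse")
    mask = NucleusMask(
        label=nucleus_id,
        mask=mask_arr,
        voxel_spacing=config.voxel_spacing,
        condition=condition,
    )
    return mask, truth


def sample_spots(
    mask: NucleusMask,
    truth: NucleusTruth,
    shell_probs: Sequence[float],
    n_spots: int,
    rng: np.random.Generator,
    probe: str = "",
    mode: str = "edt",
    partition: ShellPartition | None = None,
) -> tuple[list[SpotTruth], ShellPartition]:
    """Place spots with a known radial structure inside one nucleus.

    For each spot a shell is drawn from ``shell_probs`` (1 = innermost),
    then a voxel uniformly from that shell of the true partition; the
    spot sits at the voxel center plus a sub-voxel jitter confined to the
    same voxel, so its true shell index is exact and it lies strictly
    inside the mask.
    """
    k = len(shell_probs)
    probs = validate_shell_probs(shell_probs, k)
    if n_spots < 1:
        raise ValueError("n_spots must be >= 1")
    if partition is None:
        partition = equal_volume_shells(mask, k=k, mode=mode)
    spacing = mask.spacing
    shell_voxels = {
        shell: np.argwhere(partition.labels == shell) for shell in range(1, k + 1)
    }
    for shell in range(1, k + 1):
        if probs[shell - 1] > 0 and len(shell_voxels[shell]) == 0:
            raise DegenerateGeometryError(
                f"shell {shell} has probability {probs[shell-1]} but no voxels"
            )
    spots = []
    for _ in range(n_spots):
        shell = int(rng.choice(k, p=probs)) + 1
        voxels = shell_voxels[shell]
        vox = voxels[rng.integers(len(voxels))]
        jitter = rng.uniform(-0.25, 0.25, 3)
        position = (vox + jitter) * spacing
        spots.append(
            SpotTruth(
                nucleus_id=truth.nucleus_id,
                probe=probe,
                position=position,
                shell=shell,
            )
        )
    return spots, partition


def render_stack(
    masks: Sequence[NucleusMask],
    spots: Sequence[SpotTruth],
    config: SimulationConfig,
    rng: np.random.Generator,
    noise: bool = True,
) -> ImageStack:
    """Render nuclei and spots into a two-channel stack.

    Channel ``dna`` is the mask intensity, channel ``fish`` the point
    emitters (trilinear sub-voxel splat), both convolved with the
    anisotropic Gaussian PSF; Poisson photon noise is applied first, then
    the additive Gaussian background.  ``noise=False`` renders the clean
    expectation.
    """
    shape = masks[0].mask.shape
    spacing = np.asarray(config.voxel_spacing, float)
    dna = np.zeros(shape)
    for m in masks:
        dna[m.mask] = config.nuclear_amplitude
    fish = np.zeros(shape)
    for s in spots:
        _splat_trilinear(fish, s.position / spacing, config.spot_photons)
    sigma_vox = np.asarray(config.psf_sigma, float) / spacing
    if np.any(sigma_vox > 0):
        dna = ndimage.gaussian_filter(dna, sigma_vox)
        fish = ndimage.gaussian_filter(fish, sigma_vox)
    channels = []
    for clean in (dna, fish):
        if noise:
            img = rng.poisson(np.clip(clean, 0, None)).astype(float)
            img += config.background
            if config.read_noise_sd > 0:
                img += rng.normal(0.0, config.read_noise_sd, shape)
            img = np.clip(img, 0, None)
        else:
            img = clean
        channels.append(img)
    return ImageStack(
        np.stack(channels), config.voxel_spacing, channel_names=("dna", "fish")
    )


def _splat_trilinear(img: np.ndarray, pos_vox: np.ndarray, mass: float) -> None:
    """Deposit `mass` at a sub-voxel position with trilinear weights."""
    base = np.floor(pos_vox).astype(int)
    frac = pos_vox - base
    for dz in (0, 1):
        for dy in (0, 1):
            for dx in (0, 1):
                w = (
                    (frac[0] if dz else 1 - frac[0])
                    * (frac[1] if dy else 1 - frac[1])
                    * (frac[2] if dx else 1 - frac[2])
                )
                v = base + (dz, dy, dx)
                if np.all(v >= 0) and np.all(v < img.shape):
                    img[tuple(v)] += mass * w


def simulate_fov(
    config: SimulationConfig,
    condition: str,
    probe: str,
    shell_probs: Sequence[float],
    rng: np.random.Generator,
    nucleus_id: int = 1,
    noise: bool = True,
) -> tuple[ImageStack, NucleusMask, list[SpotTruth], NucleusTruth, ShellPartition]:
    """One field of view: a single nucleus with its spots, rendered."""
    mask, truth = simulate_nucleus(config, condition, rng, nucleus_id)
    spots, partition = sample_spots(
        mask, truth, shell_probs, config.spots_per_nucleus, rng,
        probe=probe, mode=config.shell_mode,
    )
    stack = render_stack([mask], spots, config, rng, noise=noise)
    return stack, mask, spots, truth, partition


def simulate_expression(
    n_genes: int,
    n_per_group: int = 3,
    spike_fraction: float = 0.05,
    effect_log2fc: float = 3.0,
    rng: np.random.Generator | None = None,
    noise_sd: float = 0.25,
    group_names: tuple[str, str] = ("myoblast", "myocyte"),
) -> tuple[pd.DataFrame, dict[str, str], pd.DataFrame]:
    """Two-group log2 expression matrix with spiked fold changes.

    Genes carry i.i.d. Gaussian noise around a per-gene baseline; a
    ``spike_fraction`` of genes is shifted by ±``effect_log2fc`` in the
    second group (sign random).  Returns (matrix, sample→group map,
    per-gene truth with columns gene, true_log2fc, is_de).
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    rng = rng if rng is not None else np.random.default_rng(0)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    samples = [f"{g}_{i+1}" for g in group_names for i in range(n_per_group)]
    groups = {s: group_names[0] if s.startswith(group_names[0]) else group_names[1]
              for s in samples}
    baseline = rng.uniform(4.0, 12.0, n_genes)
    values = baseline[:, None] + rng.normal(0.0, noise_sd, (n_genes, 2 * n_per_group))
    n_spike = int(round(spike_fraction * n_genes))
    spiked = rng.choice(n_genes, size=n_spike, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_spike)
    true_lfc = np.zeros(n_genes)
    true_lfc[spiked] = signs * effect_log2fc
    values[:, n_per_group:] += true_lfc[:, None]
    matrix = pd.DataFrame(values, index=genes, columns=samples)
    truth = pd.DataFrame(
        {"gene": genes, "true_log2fc": true_lfc, "is_de": true_lfc != 0.0}
    )
    return matrix, groups, truth


def simulate_dataset(
    config: SimulationConfig,
    out_dir: str | Path,
    probes: Sequence[str] | None = None,
    noise: bool = True,
) -> GroundTruth:
    """Render a full two-condition dataset to disk with ground truth TSVs.

    One TIFF per field of view (one nucleus each) under ``out_dir``, a
    sidecar ``spacing.tsv``, and ``truth_nuclei.tsv`` / ``truth_spots.tsv``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    probes = list(probes) if probes is not None else list(config.shell_probs)
    truth = GroundTruth()
    nucleus_id = 0
    for condition in config.condition_scale:
        for probe in probes:
            probs = config.shell_probs[probe][condition]
            rng = stage_rng(config.seed, f"simulate/{condition}/{probe}")
            for _ in range(config.n_nuclei_per_condition):
                nucleus_id += 1
                stack, mask, spots, ntruth, _ = simulate_fov(
                    config, condition, probe, probs, rng, nucleus_id, noise=noise
                )
                stack.save(out / f"fov_{nucleus_id:04d}_{condition}_{probe}.tiff")
                truth.nuclei.append(ntruth)
                truth.spots.extend(spots)
    dz, dy, dx = config.voxel_spacing
    pd.DataFrame(
        [{"dz_um": dz, "dy_um": dy, "dx_um": dx}]
    ).to_csv(out / "spacing.tsv", sep="\t", index=False)
    truth.nuclei_frame().to_csv(out / "truth_nuclei.tsv", sep="\t", index=False)
    truth.spots_frame().to_csv(out / "truth_spots.tsv", sep="\t", index=False)
    return truth
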