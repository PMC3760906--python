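"""Simulation configuration and the single-seed randomness policy.

All stochastic stages draw from substreams derived from one integer seed,
keyed by a stage name, so that adding or reordering stages never perturbs
the draws of other stages.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

#: Conditions used throughout: proliferating myoblasts 24 h after plating
#: versus differentiated myocytes after 7 d in low-serum medium.
CONDITIONS = ("myoblast", "myocyte")


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Return a reproducible per-stage random generator.

    The substream is keyed by ``(seed, crc32(stage))`` so every stage of a
    run has an independent stream derived from the one configured seed.
    """
    key = zlib.crc32(stage.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions for the synthetic 3-D FISH experiment.

    Parameters
    ----------
    seed
        Master seed; every stochastic stage derives its stream from it.
    n_nuclei_per_condition
        Nuclei imaged per condition (the study scored 50 ± 8 per population).
    voxel_spacing
        Physical voxel size in µm, order (z, y, x); confocal stacks are
        coarser axially than laterally.
    semi_axes_mean
        Mean ellipsoid semi-axes (a ≥ b ≥ c) of a myoblast nucleus, µm.
    semi_axes_cv
        Coefficient of variation applied per axis per nucleus.
    condition_scale
        Per-condition multiplier on the semi-axes.  The myocyte default
        scales anisotropically (z most) so differentiated nuclei are
        smaller and more flattened, as observed after myotube formation.
    shell_probs
        Per-probe, per-condition shell probability vector (length K,
        shell 1 = innermost) used to place spots.
    spots_per_nucleus
        FISH signals per nucleus; 2 for a diploid autosome pair.
    psf_sigma
        Gaussian point-spread-function σ in µm (z, y, x).
    nuclear_amplitude, spot_photons, background, read_noise_sd
        Photon-budget model: counterstain plateau intensity, integrated
        photons per spot, additive background offset, Gaussian read noise.
    """

    seed: int = 0
    n_nuclei_per_condition: int = 50
    voxel_spacing: tuple[float, float, float] = (0.5, 0.2, 0.2)
    semi_axes_mean: tuple[float, float, float] = (8.0, 6.0, 3.0)
    semi_axes_cv: float = 0.08
    condition_scale: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "myoblast": (1.0, 1.0, 1.0),
            "myocyte": (7.0 / 8.0, 1.0, 2.0 / 3.0),
        }
    )
    shell_probs: Mapping[str, Mapping[str, tuple[float, ...]]] = field(
        default_factory=dict
    )
    spots_per_nucleus: int = 2
    psf_sigma: tuple[float, float, float] = (0.6, 0.25, 0.25)
    nuclear_amplitude: float = 100.0
    spot_photons: float = 500.0
    background: float = 10.0
    read_noise_sd: float = 2.0
    shell_k: int = 5
    shell_mode: str = "edt"

    def __post_init__(self) -> None:
        spacing = np.asarray(self.voxel_spacing, float)
        axes = np.asarray(self.semi_axes_mean, float)
        if spacing.shape != (3,) or np.any(spacing <= 0):
            raise ValueError("voxel_spacing must be 3 strictly positive lengths")
        if axes.shape != (3,) or np.any(axes <= 0):
            raise ValueError("semi_axes_mean must be 3 strictly positive lengths")
        if np.any(np.diff(axes) > 0):
            raise ValueError("semi_axes_mean must be sorted descending (a >= b >= c)")
        if self.spots_per_nucleus < 1:
            raise ValueError("spots_per_nucleus must be >= 1")
        if self.shell_k < 1:
            raise ValueError("shell_k must be >= 1")
        if self.shell_mode not in ("edt", "ellipsoid"):
            raise ValueError("shell_mode must be 'edt' or 'ellipsoid'")
        for probe, per_cond in self.shell_probs.items():
            for cond, probs in per_cond.items():
                validate_shell_probs(probs, self.shell_k, f"{probe}/{cond}")

    def scaled_axes(self, condition: str) -> np.ndarray:
        """Mean semi-axes for a condition, µm."""
        try:
            scale = np.asarray(self.condition_scale[condition], float)
        except KeyError:
            raise KeyError(f"unknown condition {condition!r}") from None
        return np.asarray(self.semi_axes_mean, float) * scale


def validate_shell_probs(
    probs: Sequence[float], k: int, label: str = "shell_probs"
) -> np.ndarray:
    """Check a shell probability vector: length K, non-negative, sums to 1."""
    p = np.asarray(probs, float)
    if p.shape != (k,):
        raise ValueError(f"{label}: expected length {k}, got shape {p.shape}")
    if np.any(p < 0):
        raise ValueError(f"{label}: probabilities must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"{label}: probabilities must sum to 1 (got {p.sum()!r})")
    return p
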