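"""End-to-end validation computations on the packaged study conditions.

Each function recomputes a headline quantity from scratch by running the
package: reconstructing counts from the packaged percentage table and
testing them, measuring shell geometry on analytic solids, calibrating
the uniformity null, and recovering generating shell distributions
through the full imaging pipeline.  Used by the test suite and the
reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from nucshell.config import SimulationConfig, stage_rng
from nucshell.geometry import assign_spots, equal_volume_shells, fit_ellipsoid
from nucshell.imaging import detect_spots, segment_nuclei
from nucshell.shell_stats import chi_square_homogeneity, reconstruct_counts
from nucshell.simulate import simulate_fov
from nucshell.table_io import load_packaged_table1

#: chromosomes reported as repositioning (p < 0.05) vs stable (p > 0.05)
MOVING = ("HSA1", "HSA3", "HSA12", "HSA17", "HSAX")
STABLE = ("HSA7", "HSA11")


def table1_reconstructions() -> pd.DataFrame:
    """Reconstruct integer counts for every packaged percentage row."""
    table = load_packaged_table1()
    pct_cols = [f"shell_{k}_pct" for k in range(1, 6)]
    rows = []
    for _, row in table.iterrows():
        rec = reconstruct_counts([row[c] for c in pct_cols])
        rows.append(
            {
                "probe": row["probe"],
                "condition": row["condition"],
                "n": rec.n,
                "exact": rec.exact,
                **{f"count_{k+1}": int(c) for k, c in enumerate(rec.counts)},
            }
        )
    return pd.DataFrame(rows)


def table1_chi_square() -> pd.DataFrame:
    """Per-chromosome 2×5 chi-square on the reconstructed counts."""
    recs = table1_reconstructions().set_index(["probe", "condition"])
    count_cols = [f"count_{k}" for k in range(1, 6)]
    rows = []
    for probe in recs.index.get_level_values(0).unique():
        a = recs.loc[(probe, "24h"), count_cols].to_numpy(int)
        b = recs.loc[(probe, "7d"), count_cols].to_numpy(int)
        res = chi_square_homogeneity(a, b)
        rows.append({"probe": probe, "chi2": res.statistic, "df": res.df,
                     "p": res.p_value})
    return pd.DataFrame(rows)


def sphere_shell_geometry(
    radius_um: float = 10.0, spacing: float = 0.2, k: int = 5
) -> dict[str, float]:
    """Equal-volume shell geometry of a digital sphere.

    Returns the worst shell-volume deviation (in voxel volumes) from
    total/K and the innermost boundary radius in µm, to compare with the
    analytic (1/K)^(1/3)·R.
    """
    from nucshell.imaging import NucleusMask

    sp = np.array([spacing] * 3)
    shape = tuple(int(np.ceil(2 * radius_um / spacing)) + 5 for _ in range(3))
    center = (np.array(shape) - 1) / 2 * sp
    idx = np.indices(shape)
    r = np.linalg.norm(np.stack(idx, -1) * sp - center, axis=-1)
    mask = NucleusMask(1, r <= radius_um, tuple(sp))
    part = equal_volume_shells(mask, k=k, mode="ellipsoid")
    fit = fit_ellipsoid(mask)
    target = mask.volume / k
    deviation_voxels = float(
        np.max(np.abs(part.shell_volumes - target)) / mask.voxel_volume
    )
    inner_radius = float(part.boundaries[0] * fit.semi_axes[0])
    return {
        "max_shell_volume_deviation_voxels": deviation_voxels,
        "inner_boundary_radius_um": inner_radius,
        "analytic_radius_um": (1.0 / k) ** (1.0 / 3.0) * radius_um,
    }


def uniformity_null_rejection_rate(
    seed: int, n_replicates: int = 1000, spots_per_replicate: int = 200,
    n_nuclei: int = 5, alpha: float = 0.05,
) -> float:
    """Chi-square GOF rejection rate for uniformly placed spots.

    Spots are placed uniformly over mask voxels of synthetic nuclei, so
    the per-shell expectation is proportional to shell voxel counts
    (equal up to one voxel); a calibrated test rejects ≈ alpha.
    """
    from nucshell.simulate import simulate_nucleus

    cfg = SimulationConfig(seed=seed)
    rng = stage_rng(seed, "uniformity-null")
    partitions = []
    for i in range(n_nuclei):
        cond = "myoblast" if i % 2 == 0 else "myocyte"
        mask, _ = simulate_nucleus(cfg, cond, rng)
        part = equal_volume_shells(mask, k=cfg.shell_k)
        voxels = np.argwhere(mask.mask)
        labels = part.labels[tuple(voxels.T)]
        expected = np.bincount(labels, minlength=cfg.shell_k + 1)[1:]
        partitions.append((labels, expected / expected.sum()))
    rejections = 0
    for rep in range(n_replicates):
        labels, p_exp = partitions[rep % n_nuclei]
        chosen = labels[rng.integers(len(labels), size=spots_per_replicate)]
        counts = np.bincount(chosen, minlength=6)[1:]
        p = stats.chisquare(counts, f_exp=spots_per_replicate * p_exp).pvalue
        rejections += p < alpha
    return rejections / n_replicates


def pipeline_parameter_recovery(
    seed: int, probe: str = "HSA3", n_nuclei: int = 50
) -> dict[str, object]:
    """Full imaging→assignment recovery of generating shell distributions.

    Generates ``n_nuclei`` nuclei per condition with the packaged rows of
    ``probe`` as generating probabilities, renders with default noise,
    runs segmentation, shell partitioning, spot detection and assignment,
    and compares the recovered distributions with the generators.
    """
    table = load_packaged_table1().set_index(["probe", "condition"])
    pct_cols = [f"shell_{k}_pct" for k in range(1, 6)]
    gen_probs = {}
    for cond_label, cond in (("24h", "myoblast"), ("7d", "myocyte")):
        p = table.loc[(probe, cond_label), pct_cols].to_numpy(float) / 100.0
        gen_probs[cond] = p / p.sum()
    cfg = SimulationConfig(seed=seed, n_nuclei_per_condition=n_nuclei)
    out: dict[str, object] = {"probe": probe}
    recovered = {}
    truth_counts = {}
    n_true = n_matched = n_shell_correct = 0
    nucleus_id = 0
    for cond, probs in gen_probs.items():
        rng = stage_rng(seed, f"recovery/{cond}")
        partitions = {}
        detections = []
        t_counts = np.zeros(5, int)
        for _ in range(n_nuclei):
            nucleus_id += 1
            stack, true_mask, true_spots, _truth, true_part = simulate_fov(
                cfg, cond, probe, probs, rng, nucleus_id
            )
            seg = segment_nuclei(stack, "dna", condition=cond)
            if not seg:
                continue
            mask = seg[0]
            mask.label = nucleus_id
            partitions[nucleus_id] = equal_volume_shells(mask, k=5)
            found = detect_spots(stack, "fish", [mask], probe=probe)
            for s in found:
                s.nucleus_label = nucleus_id
            detections.extend(found)
            n_true += len(true_spots)
            for ts in true_spots:
                t_counts[ts.shell - 1] += 1
                match = None
                for f in found:
                    if np.max(np.abs(f.position - ts.position) / mask.spacing) <= 1.0:
                        match = f
                        break
                if match is None:
                    continue
                n_matched += 1
                vox = tuple(
                    np.clip(np.round(match.position / mask.spacing).astype(int),
                            0, np.array(mask.mask.shape) - 1)
                )
                if partitions[nucleus_id].labels[vox] == ts.shell:
                    n_shell_correct += 1
        dists, _ = assign_spots(detections, partitions, condition=cond)
        recovered[cond] = dists[(probe, cond)]
        truth_counts[cond] = t_counts
    within_band = True
    max_sigma = 0.0
    for cond, dist in recovered.items():
        p = gen_probs[cond]
        freq = dist.counts / dist.n
        sigma = np.sqrt(np.clip(p * (1 - p), 1e-12, None) / dist.n)
        z = np.abs(freq - p) / sigma
        max_sigma = max(max_sigma, float(z.max()))
        within_band &= bool(np.all(z <= 3.0))
    res = chi_square_homogeneity(
        recovered["myoblast"].counts, recovered["myocyte"].counts
    )
    out.update(
        {
            "recovered": recovered,
            "truth_counts": truth_counts,
            "within_3sigma": within_band,
            "max_band_sigma": max_sigma,
            "chi2_p": res.p_value,
            "spot_recall": n_matched / n_true if n_true else 0.0,
            "shell_accuracy": n_shell_correct / n_matched if n_matched else 0.0,
        }
    )
    return out
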