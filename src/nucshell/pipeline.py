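"""Pipeline orchestration: configuration, staging, manifests.

A run goes simulate/ingest → segment → morphometry → shells → spots →
assign → compare, writing every stage table as TSV tagged with the
config hash.  All randomness flows from the single config seed through
stage-keyed substreams, so reruns are byte-identical and adding a stage
never perturbs earlier stages' draws.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

import nucshell
from nucshell.config import SimulationConfig, stage_rng
from nucshell.errors import NucshellError
from nucshell.geometry import (
    assign_spots,
    equal_volume_shells,
    fit_ellipsoid,
    morphometry_table,
)
from nucshell.imaging import DetectionParams, SegmentationParams, detect_spots, segment_nuclei
from nucshell.shell_stats import chi_square_homogeneity, mann_whitney_u, shapiro_wilk
from nucshell.simulate import simulate_fov
from nucshell.table_io import read_table1, table_to_distributions, write_table1

log = logging.getLogger(__name__)

SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """One structured document holding every stage's parameters."""

    schema_version: int = SCHEMA_VERSION
    seed: int = 0
    k: int = 5
    mode: str = "edt"
    alpha: float = 0.05
    simulate: dict[str, Any] = field(default_factory=dict)
    segmentation: dict[str, Any] = field(default_factory=dict)
    detection: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.schema_version != SCHEMA_VERSION:
            raise NucshellError(
                f"unsupported config schema_version {self.schema_version}"
            )
        _check_keys(self.simulate, SimulationConfig, "simulate")
        _check_keys(self.segmentation, SegmentationParams, "segmentation")
        _check_keys(self.detection, DetectionParams, "detection")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise NucshellError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def simulation_config(self) -> SimulationConfig:
        params = dict(self.simulate)
        params.setdefault("seed", self.seed)
        params.setdefault("shell_k", self.k)
        params.setdefault("shell_mode", self.mode)
        return SimulationConfig(**params)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @property
    def hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _check_keys(params: Mapping[str, Any], klass: type, section: str) -> None:
    known = {f.name for f in dataclasses.fields(klass)}
    unknown = set(params) - known
    if unknown:
        raise NucshellError(f"unknown keys in '{section}': {sorted(unknown)}")


@dataclass
class RunManifest:
    """Provenance and bookkeeping of one pipeline run."""

    tool_version: str
    config_hash: str
    started: str
    finished: str = ""
    input_hashes: dict[str, str] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        """Atomic write (tmp file + rename)."""
        path = Path(path)
        tmp = path.with_suffix(".tmp")
        with open(tmp, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
        os.replace(tmp, path)


def _file_hash(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _now() -> str:
    return time.strftime("%Y-%m-%dT%H:%M:%S")


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> RunManifest:
    """Full synthetic run: simulate, recover, compare, write all tables.

    For every probe in ``config.simulate['shell_probs']`` and every
    condition, nuclei are simulated one per field of view, rendered with
    noise, segmented back, partitioned into K equal-volume shells, spots
    detected and assigned, and the two conditions compared (chi-square on
    shell distributions; Mann-Whitney with a Shapiro-Wilk gate on
    morphometry).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        tool_version=nucshell.__version__,
        config_hash=config.hash,
        started=_now(),
    )
    sim = config.simulation_config()
    if not sim.shell_probs:
        raise NucshellError(
            "stage simulate: config.simulate.shell_probs is empty; nothing to run"
        )
    seg_params = SegmentationParams(**config.segmentation)
    det_params = DetectionParams(**config.detection)

    masks_all = []
    distributions = {}
    n_spots_true = n_spots_detected = n_spots_assigned = 0
    nucleus_id = 0
    for probe, per_cond in sim.shell_probs.items():
        for condition, probs in per_cond.items():
            rng = stage_rng(sim.seed, f"simulate/{condition}/{probe}")
            partitions = {}
            spots_cond = []
            for _ in range(sim.n_nuclei_per_condition):
                nucleus_id += 1
                try:
                    stack, true_mask, true_spots, truth, _ = simulate_fov(
                        sim, condition, probe, probs, rng, nucleus_id
                    )
                except NucshellError as exc:
                    raise NucshellError(
                        f"stage simulate: nucleus {nucleus_id}: {exc}"
                    ) from exc
                n_spots_true += len(true_spots)
                seg = segment_nuclei(stack, "dna", seg_params, condition=condition)
                if not seg:
                    log.warning("stage segment: nucleus %d lost", nucleus_id)
                    continue
                mask = seg[0]  # one nucleus per field of view
                mask.label = nucleus_id
                masks_all.append(mask)
                partitions[nucleus_id] = equal_volume_shells(
                    mask, k=config.k, mode=config.mode
                )
                found = detect_spots(stack, "fish", [mask], det_params, probe=probe)
                for s in found:
                    s.nucleus_label = nucleus_id
                n_spots_detected += len(found)
                spots_cond.extend(found)
            dist, _audit = assign_spots(spots_cond, partitions, condition=condition)
            n_spots_assigned += sum(d.n for d in dist.values())
            distributions.update(dist)

    morph = morphometry_table(masks_all)
    morph.to_csv(out / "morphometry.tsv", sep="\t", index=False)
    write_table1(distributions, out / "distributions.tsv", config_hash=config.hash)
    report = compare_distributions(distributions, alpha=config.alpha)
    morph_report = compare_morphometry(morph)
    _write_report(report, out / "shell_stats.tsv", config.hash)
    _write_report(morph_report, out / "morphometry_stats.tsv", config.hash)

    manifest.counts = {
        "nuclei_simulated": nucleus_id,
        "nuclei_segmented": len(masks_all),
        "spots_true": n_spots_true,
        "spots_detected": n_spots_detected,
        "spots_assigned": n_spots_assigned,
    }
    manifest.finished = _now()
    manifest.write(out / "manifest.json")
    return manifest


def run_compare(table_path: str | Path, out_dir: str | Path,
                alpha: float = 0.05) -> RunManifest:
    """Compare-only mode: statistics on an existing distribution table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = PipelineConfig(alpha=alpha)
    manifest = RunManifest(
        tool_version=nucshell.__version__,
        config_hash=config.hash,
        started=_now(),
        input_hashes={str(table_path): _file_hash(table_path)},
    )
    dists = table_to_distributions(read_table1(table_path))
    report = compare_distributions(dists, alpha=alpha)
    _write_report(report, out / "shell_stats.tsv", config.hash)
    manifest.counts = {"probes_compared": int(len(report))}
    manifest.finished = _now()
    manifest.write(out / "manifest.json")
    return manifest


def compare_distributions(
    distributions: Mapping[tuple[str, str], Any], alpha: float = 0.05
) -> pd.DataFrame:
    """Chi-square homogeneity per probe between its two conditions."""
    probes = sorted({p for p, _ in distributions})
    rows = []
    for probe in probes:
        conds = sorted(c for p, c in distributions if p == probe)
        if len(conds) != 2:
            log.warning("probe %s has %d condition(s); skipped", probe, len(conds))
            continue
        a = distributions[(probe, conds[0])]
        b = distributions[(probe, conds[1])]
        res = chi_square_homogeneity(a.counts, b.counts)
        rows.append(
            {
                "probe": probe,
                "condition_a": conds[0],
                "condition_b": conds[1],
                "n_a": a.n,
                "n_b": b.n,
                "chi2": res.statistic,
                "df": res.df,
                "p": res.p_value,
                "significant": res.p_value < alpha,
                "low_expected_warning": res.warning_low_expected,
            }
        )
    return pd.DataFrame(rows)


def compare_morphometry(morph: pd.DataFrame) -> pd.DataFrame:
    """Mann-Whitney on volume and flattening between the two conditions,
    with Shapiro-Wilk normality documentation per sample."""
    conds = sorted(morph["condition"].unique()) if len(morph) else []
    if len(conds) != 2:
        return pd.DataFrame()
    rows = []
    for metric in ("volume_um3", "flattening"):
        x = morph.loc[morph["condition"] == conds[0], metric].to_numpy()
        y = morph.loc[morph["condition"] == conds[1], metric].to_numpy()
        res = mann_whitney_u(x, y)
        row = {
            "metric": metric,
            "condition_a": conds[0],
            "condition_b": conds[1],
            "median_a": float(np.median(x)),
            "median_b": float(np.median(y)),
            "U": res.u,
            "p": res.p_value,
        }
        for label, sample in (("a", x), ("b", y)):
            try:
                _, sw_p = shapiro_wilk(sample)
            except (ValueError, NucshellError):
                sw_p = float("nan")
            row[f"shapiro_p_{label}"] = sw_p
        rows.append(row)
    return pd.DataFrame(rows)


def _write_report(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index=False)
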