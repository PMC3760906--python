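"""Readers/writers for the canonical TSV artifacts.

The central layout is the published-style shell distribution table: one
row per probe × condition with K shell columns, interior first.  Tables
are tab-delimited UTF-8 with '.' decimals; lines starting with '#' are
metadata comments (e.g. the run's config hash) and are skipped on read.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from nucshell.geometry import ShellDistribution
from nucshell.shell_stats import round_half_up

_SHELL_COL = "shell_{}_pct"
_COUNT_COL = "count_{}"


def read_table1(path: str | Path) -> pd.DataFrame:
    """Read a shell-distribution table (percentages and/or counts).

    Requires ``probe`` and ``condition`` columns plus K ``shell_k_pct``
    and/or ``count_k`` columns.  Every percentage row must sum to
    100 ± 0.05; violations raise with the offending line number.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"probe", "condition"} <= set(df.columns):
        raise ValueError(f"{path}: 'probe' and 'condition' columns required")
    pct_cols = [c for c in df.columns if c.startswith("shell_") and c.endswith("_pct")]
    count_cols = [c for c in df.columns if c.startswith("count_")]
    if not pct_cols and not count_cols:
        raise ValueError(f"{path}: no shell percentage or count columns found")
    if pct_cols:
        sums = df[pct_cols].sum(axis=1)
        bad = np.flatnonzero(np.abs(sums - 100.0) > 0.05)
        if len(bad):
            row = int(bad[0])
            raise ValueError(
                f"{path}: line {row + 2}: percentages sum to "
                f"{sums.iloc[row]:.2f}, expected 100 ± 0.05"
            )
    return df


def write_table1(
    distributions: Mapping[tuple[str, str], ShellDistribution] | list[ShellDistribution],
    path: str | Path,
    config_hash: str | None = None,
) -> pd.DataFrame:
    """Write distributions as a table-1-layout TSV (counts + percentages).

    Percentages are re-derived from the counts (half-up, 2 decimals) so
    read ∘ write is lossless on counts.
    """
    if isinstance(distributions, Mapping):
        dists = list(distributions.values())
    else:
        dists = list(distributions)
    rows = []
    for d in dists:
        row: dict[str, object] = {"probe": d.probe, "condition": d.condition}
        pct = round_half_up(100.0 * d.counts / d.n, 2)
        for k in range(d.k):
            row[_COUNT_COL.format(k + 1)] = int(d.counts[k])
        for k in range(d.k):
            row[_SHELL_COL.format(k + 1)] = pct[k]
        rows.append(row)
    df = pd.DataFrame(rows)
    with open(path, "w", encoding="utf-8") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index=False)
    return df


def table_to_distributions(df: pd.DataFrame) -> dict[tuple[str, str], ShellDistribution]:
    """Build ShellDistributions from a table read by :func:`read_table1`.

    Prefers count columns; otherwise reconstructs integer counts from the
    percentages by exhaustive search (see
    :func:`nucshell.shell_stats.reconstruct_counts`).
    """
    from nucshell.shell_stats import reconstruct_counts

    count_cols = sorted(
        (c for c in df.columns if c.startswith("count_")),
        key=lambda c: int(c.split("_")[1]),
    )
    pct_cols = sorted(
        (c for c in df.columns if c.startswith("shell_") and c.endswith("_pct")),
        key=lambda c: int(c.split("_")[1]),
    )
    out: dict[tuple[str, str], ShellDistribution] = {}
    for _, row in df.iterrows():
        key = (str(row["probe"]), str(row["condition"]))
        if count_cols:
            counts = np.array([int(row[c]) for c in count_cols])
        else:
            rec = reconstruct_counts([float(row[c]) for c in pct_cols])
            counts = rec.counts
        out[key] = ShellDistribution(key[0], key[1], counts)
    return out


def load_packaged_table1() -> pd.DataFrame:
    """The packaged centromere shell-distribution percentage table.

    Seven centromeric probes (HSA1, 3, 7, 11, 12, 17, X) in proliferating
    myoblasts (``24h``) and differentiated myocytes (``7d``), percentages
    over five equal-volume shells, interior first.
    """
    ref = importlib.resources.files("nucshell.data").joinpath("table1.tsv")
    with importlib.resources.as_file(ref) as p:
        return read_table1(p)


def load_packaged_de_fixture() -> pd.DataFrame:
    """Synthetic regulated-gene fixture with chromosome positions.

    A small synthetic stand-in for a supplementary regulated-transcript
    list: gene ids with chromosome, cytoband and direction whose
    per-chromosome up/down tallies mirror the reported ideogram pattern.
    """
    ref = importlib.resources.files("nucshell.data").joinpath(
        "de_genes_synthetic.tsv"
    )
    with importlib.resources.as_file(ref) as p:
        return pd.read_csv(p, sep="\t", comment="#")
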