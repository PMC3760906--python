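"""Microarray layer: quantile normalisation, differential expression,
and chromosome mapping of regulated genes.

The pipeline starts from a gene-level log2 matrix (probe-level
summarisation is upstream of this package).  Differential calls use a
per-gene two-sample t-test with Benjamini-Hochberg adjustment over all
tested genes, and a ≥2-fold change requirement:

    up   iff  log2FC ≥ +1 and q < alpha
    down iff  log2FC ≤ −1 and q < alpha

with log2FC = mean(group 2) − mean(group 1).  The default t-test pools
variances (df = n1+n2−2): with triplicate microarray samples the
Satterthwaite degrees of freedom of Welch's test are estimated from two
variances of 2 df each and collapse toward 2, costing most of the power;
``welch=True`` is available where group variances genuinely differ.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Genes × samples log2 expression values with a two-group design."""

    values: pd.DataFrame  # index = genes, columns = sample ids
    groups: Mapping[str, str]  # sample id -> group label

    def __post_init__(self) -> None:
        missing = [s for s in self.values.columns if s not in self.groups]
        if missing:
            raise ValueError(f"samples without a group: {missing}")
        labels = pd.Series({s: self.groups[s] for s in self.values.columns})
        counts = labels.value_counts()
        if len(counts) != 2:
            raise ValueError("exactly two groups are required")
        if counts.min() < 2:
            raise ValueError("each group needs at least 2 samples")
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValueError("expression values must be finite")

    @property
    def group_names(self) -> tuple[str, str]:
        seen: list[str] = []
        for s in self.values.columns:
            g = self.groups[s]
            if g not in seen:
                seen.append(g)
        return seen[0], seen[1]

    def group_columns(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]


def quantile_normalize(
    matrix: ExpressionMatrix | pd.DataFrame,
) -> ExpressionMatrix | pd.DataFrame:
    """Force every sample onto the common reference distribution.

    The reference is the row-wise mean of the sorted columns; tied values
    within a column receive the mean of the reference values their
    positions span.  Idempotent, and a fixed point for matrices whose
    columns are already identically distributed.  Accepts a bare
    DataFrame (normalisation is design-agnostic) or an
    :class:`ExpressionMatrix`, returning the same kind.
    """
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    arr = values.to_numpy(float)
    n, m = arr.shape
    reference = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(m):
        col = arr[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty(n)
        assigned[order] = reference
        # average the reference over tied input values
        s = pd.Series(assigned).groupby(pd.Series(col)).transform("mean")
        out[:, j] = s.to_numpy()
    frame = pd.DataFrame(out, index=values.index, columns=values.columns)
    if isinstance(matrix, ExpressionMatrix):
        return ExpressionMatrix(frame, dict(matrix.groups))
    return frame


def differential_expression(
    matrix: ExpressionMatrix,
    fc_threshold: float = 1.0,
    alpha: float = 0.01,
    welch: bool = False,
    adjust: bool = True,
) -> pd.DataFrame:
    """Per-gene t-test, BH adjustment, and ≥2-fold classification.

    Returns a DataFrame with columns gene, log2_fc, p, q, direction
    (up/down/ns).  ``adjust=False`` applies the alpha to raw p-values
    instead of BH-adjusted q-values.  Genes with zero variance in both
    groups get p = 0 if the means differ, else 1 (logged).
    """
    g1, g2 = matrix.group_names
    a = matrix.values[matrix.group_columns(g1)].to_numpy(float)
    b = matrix.values[matrix.group_columns(g2)].to_numpy(float)
    log2_fc = b.mean(axis=1) - a.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = stats.ttest_ind(b, a, axis=1, equal_var=not welch)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        log.info(
            "differential_expression: %d gene(s) with zero variance in both groups",
            int(degenerate.sum()),
        )
        p = np.where(degenerate, np.where(log2_fc != 0, 0.0, 1.0), p)
    q = multipletests(p, method="fdr_bh")[1] if adjust else p.copy()
    significant = q < alpha
    direction = np.where(
        significant & (log2_fc >= fc_threshold),
        "up",
        np.where(significant & (log2_fc <= -fc_threshold), "down", "ns"),
    )
    return pd.DataFrame(
        {
            "gene": matrix.values.index,
            "log2_fc": log2_fc,
            "p": p,
            "q": q,
            "direction": direction,
        }
    ).reset_index(drop=True)


def map_to_chromosomes(
    records: pd.DataFrame, positions: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Attach chromosome (and cytoband) to DE records and tally per chromosome.

    ``positions`` needs unique ``gene`` ids plus ``chromosome`` (optional
    ``cytoband``).  Unmapped genes are counted under chromosome
    ``"unmapped"`` in the tally and logged.  Returns (annotated records,
    per-chromosome tally with columns chromosome, up, down).
    """
    if positions["gene"].duplicated().any():
        raise ValueError("gene ids in the position table must be unique")
    cols = ["gene", "chromosome"] + (
        ["cytoband"] if "cytoband" in positions.columns else []
    )
    merged = records.merge(positions[cols], on="gene", how="left")
    unmapped = merged["chromosome"].isna()
    if unmapped.any():
        log.info("map_to_chromosomes: %d gene(s) unmapped", int(unmapped.sum()))
    merged["chromosome"] = merged["chromosome"].fillna("unmapped")
    de = merged[merged["direction"].isin(["up", "down"])]
    tally = (
        de.pivot_table(
            index="chromosome",
            columns="direction",
            values="gene",
            aggfunc="count",
            fill_value=0,
        )
        .reindex(columns=["up", "down"], fill_value=0)
        .reset_index()
    )
    tally.columns.name = None
    return merged, tally
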