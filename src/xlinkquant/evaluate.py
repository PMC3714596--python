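"""Evaluation of quantitation output: per-run medians, replicate
agreement, and accuracy against a simulation truth table."""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .aggregate import ReplicateStats, SiteRatio, compare_replicates, read_site_table


def load_results(path: str | Path) -> pd.DataFrame:
    """Read a per-PSM result TSV written by ``write_results``."""
    df = pd.read_csv(path, sep="\t", comment=None)
    for col in ("light_area", "heavy_area", "ratio_hl", "log2_ratio_hl"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def load_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def median_log2(results: pd.DataFrame) -> tuple[float, int]:
    """Median log2(H/L) over the quantified PSMs; returns (median, n)."""
    values = results["log2_ratio_hl"].dropna()
    if values.empty:
        return math.nan, 0
    return float(values.median()), int(values.size)


@dataclass(frozen=True)
class TruthComparison:
    """Per-PSM accuracy of measured ratios against simulation truth."""

    bias_log2: float  # median of (measured - true) log2 ratios
    rmse_log2: float
    n: int


def compare_to_truth(results: pd.DataFrame, truth: pd.DataFrame) -> TruthComparison:
    """Join measured PSM ratios to the truth table and score them."""
    merged = results.merge(truth[["psm_id", "true_ratio_hl"]], on="psm_id", how="inner")
    merged = merged.dropna(subset=["log2_ratio_hl"])
    if merged.empty:
        return TruthComparison(math.nan, math.nan, 0)
    err = merged["log2_ratio_hl"].to_numpy() - np.log2(
        merged["true_ratio_hl"].to_numpy()
    )
    return TruthComparison(
        bias_log2=float(np.median(err)),
        rmse_log2=float(np.sqrt(np.mean(err**2))),
        n=int(err.size),
    )


def replicate_pair_stats(path_a: str | Path, path_b: str | Path) -> ReplicateStats:
    """Replicate agreement between two site-level TSV files."""
    return compare_replicates(read_site_table(path_a), read_site_table(path_b))


def all_pair_stats(paths: list[str | Path]) -> list[tuple[str, str, ReplicateStats]]:
    """All pairwise replicate comparisons (run 1 vs 2, 1 vs 3, 2 vs 3, ...)."""
    tables: list[tuple[str, list[SiteRatio]]] = [
        (str(p), read_site_table(p)) for p in paths
    ]
    out = []
    for i in range(len(tables)):
        for j in range(i + 1, len(tables)):
            out.append(
                (tables[i][0], tables[j][0], compare_replicates(tables[i][1], tables[j][1]))
            )
    return out
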