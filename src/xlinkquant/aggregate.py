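"""Collapse per-PSM ratios to per-cross-link-site ratios.

A cross-link site's ratio is the median of all defined PSM ratios that
support it; sites backed by fewer than ``min_evidence`` ratios (default:
at least two) are reported separately, never silently dropped.  Flagged
PSMs without a defined ratio never count as evidence.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as _scipy_stats

from .quant import DoubletQuant


@dataclass(frozen=True)
class SiteRatio:
    """Median heavy/light ratio of one cross-link site."""

    site_key: str
    median_ratio_hl: float
    log2_median: float
    n_evidence: int
    psm_ids: tuple[str, ...]


@dataclass(frozen=True)
class ReplicateStats:
    """Agreement statistics between two site-ratio lists (log2 scale)."""

    pearson_r: float | None
    rmse: float | None
    r_squared: float | None
    n_common: int


def site_ratios(
    quants: Iterable[DoubletQuant],
    sites: Mapping[str, str],
    min_evidence: int = 2,
) -> tuple[list[SiteRatio], list[SiteRatio]]:
    """Aggregate PSM ratios per site.

    ``sites`` maps psm_id to the cross-link site key (normally taken from
    the ID list).  The median is taken on the ratio scale; for even
    evidence counts it is the arithmetic mean of the two central values.
    Returns ``(accepted, insufficient)`` where ``insufficient`` lists the
    sites with fewer than ``min_evidence`` defined ratios.
    """
    if min_evidence < 1:
        raise ValueError("min_evidence must be >= 1")
    by_site: dict[str, list[tuple[str, float]]] = {}
    for quant in quants:
        ratio = quant.ratio_hl
        if ratio is None:
            continue  # flagged / one-sided doublets are not evidence
        site = sites.get(quant.psm_id)
        if site is None:
            raise KeyError(f"no site key for psm_id {quant.psm_id!r}")
        by_site.setdefault(site, []).append((quant.psm_id, ratio))

    accepted: list[SiteRatio] = []
    insufficient: list[SiteRatio] = []
    for site in sorted(by_site):
        evidence = by_site[site]
        ratios = [r for _, r in evidence]
        median = float(statistics.median(ratios))
        entry = SiteRatio(
            site_key=site,
            median_ratio_hl=median,
            log2_median=math.log2(median),
            n_evidence=len(evidence),
            psm_ids=tuple(pid for pid, _ in evidence),
        )
        (accepted if len(evidence) >= min_evidence else insufficient).append(entry)
    return accepted, insufficient


def compare_replicates(
    a: Sequence[SiteRatio], b: Sequence[SiteRatio]
) -> ReplicateStats:
    """Agreement between two replicate site-ratio lists.

    Statistics are computed on the log2 medians of the sites observed in
    both lists; a site missing from either replicate is excluded from the
    comparison.  With no common sites the statistics are absent; the
    Pearson r (and r^2, its square) additionally needs at least two
    common sites with variance on both axes.
    """
    a_map = {s.site_key: s.log2_median for s in a}
    b_map = {s.site_key: s.log2_median for s in b}
    common = sorted(a_map.keys() & b_map.keys())
    if not common:
        return ReplicateStats(None, None, None, 0)
    x = np.array([a_map[k] for k in common])
    y = np.array([b_map[k] for k in common])
    rmse = float(np.sqrt(np.mean((x - y) ** 2)))
    pearson: float | None = None
    if len(common) >= 2 and np.std(x) > 0 and np.std(y) > 0:
        pearson = float(_scipy_stats.pearsonr(x, y).statistic)
    r2 = None if pearson is None else pearson**2
    return ReplicateStats(pearson, rmse, r2, len(common))


def write_site_tables(
    accepted: Sequence[SiteRatio],
    insufficient: Sequence[SiteRatio],
    path_accepted: str | Path,
    path_insufficient: str | Path,
) -> None:
    """Write the site-level TSV plus the insufficient-evidence listing."""
    header = "site_key\tn_evidence\tmedian_ratio_hl\tlog2_median\tpsm_ids"

    def _rows(entries: Sequence[SiteRatio]) -> str:
        lines = [header]
        for s in entries:
            lines.append(
                f"{s.site_key}\t{s.n_evidence}\t{s.median_ratio_hl!r}\t"
                f"{s.log2_median!r}\t{';'.join(s.psm_ids)}"
            )
        return "\n".join(lines) + "\n"

    Path(path_accepted).write_text(_rows(accepted), encoding="utf-8")
    Path(path_insufficient).write_text(_rows(insufficient), encoding="utf-8")


def read_site_table(path: str | Path) -> list[SiteRatio]:
    """Read a site-level TSV written by :func:`write_site_tables`."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    out: list[SiteRatio] = []
    for line in lines[1:]:
        if not line.strip():
            continue
        site, n, median, log2m, psm_ids = line.split("\t")
        out.append(
            SiteRatio(site, float(median), float(log2m), int(n),
                      tuple(p for p in psm_ids.split(";") if p))
        )
    return out
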