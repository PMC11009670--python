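"""Sliding-window genome scan for regions violating MSC expectations.

Under the multispecies coalescent, per-locus quartet support for any
fixed branch fluctuates locus to locus, but its mean over a window of
consecutive loci concentrates around the genome-wide mean. The scan
standardizes each window mean,

    Z_i = (Q_i - mu_Q) / sigma_Q,

and assigns the one-sided-minimum p-value min(F(Z_i), 1 - F(Z_i))
with F the standard normal CDF (a two-tailed test of size 2*alpha at
threshold alpha), followed by Benjamini-Hochberg correction across
all windows of the branch. Runs of significant windows are merged
into outlier regions -- candidate recombination-suppressed blocks.

By default mu_Q is the genome-wide mean of the per-locus statistic
and sigma_Q the standard deviation of the window means, which makes
Z approximately standard normal by construction; the per-locus
standard deviation is available via ``sigma_mode="locus"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .model import (
    CladeModel,
    GenomeTable,
    LocusTree,
    OutlierRegion,
    SupportTrack,
)
from .support import qqs_track

logger = logging.getLogger(__name__)

__all__ = [
    "ScanParams",
    "moving_average",
    "window_means",
    "msc_window_test",
    "bh_adjust",
    "call_outlier_regions",
    "genome_scan",
]


@dataclass
class ScanParams:
    """Parameters of the genome scan (defaults follow the windowed
    quartet-support test: 20-locus windows, BH threshold 0.01)."""

    w: int = 20
    alpha: float = 0.01
    max_gap_loci: int = 0
    sigma_mode: str = "window"  # or "locus"
    sex_chromosomes: tuple[str, ...] = ("chrZ", "chrW")
    ma_k: int = 200


def moving_average(track: SupportTrack, k: int) -> SupportTrack:
    """Trailing average of the k most recent qualifying loci.

    At each qualifying locus the value is the mean of the k preceding
    qualifying values up to and including it, computed within its
    chromosome; positions with fewer than k qualifying predecessors,
    and non-qualifying positions, are missing.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    out = np.full(len(track.values), np.nan)
    any_defined = False
    for chrom, sl in track.table.chromosome_slices():
        vals = track.values[sl]
        idx = np.flatnonzero(~np.isnan(vals))
        if len(idx) < k:
            continue
        any_defined = True
        v = vals[idx]
        csum = np.concatenate([[0.0], np.cumsum(v)])
        means = (csum[k:] - csum[:-k]) / k
        out[sl.start + idx[k - 1 :]] = means
    if not any_defined:
        logger.warning(
            "moving_average: window k=%d exceeds every chromosome's "
            "qualifying locus count; all values missing",
            k,
        )
    return SupportTrack(
        table=track.table, values=out, name=f"{track.name}_ma{k}"
    )


def window_means(track: SupportTrack, w: int = 20) -> pd.DataFrame:
    """Sliding windows of exactly ``w`` consecutive qualifying loci.

    Loci with missing values are dropped before windowing, so every
    window averages exactly w defined values; windows never span
    chromosomes and slide one qualifying locus at a time. Returns one
    row per window with the mean ``q`` plus locus/bp bookkeeping.
    """
    rows = []
    starts = track.table.starts
    ends = track.table.ends
    for chrom, sl in track.table.chromosome_slices():
        vals = track.values[sl]
        idx = np.flatnonzero(~np.isnan(vals)) + sl.start  # global rows
        if len(idx) < w:
            logger.info(
                "window_means: chromosome %s has %d qualifying loci "
                "(< w=%d); no windows",
                chrom,
                len(idx),
                w,
            )
            continue
        v = track.values[idx]
        csum = np.concatenate([[0.0], np.cumsum(v)])
        q = (csum[w:] - csum[:-w]) / w
        for i in range(len(q)):
            first, last = idx[i], idx[i + w - 1]
            rows.append(
                {
                    "chrom": chrom,
                    "first_qi": i,
                    "last_qi": i + w - 1,
                    "first_row": int(first),
                    "last_row": int(last),
                    "start": int(starts[first]),
                    "end": int(ends[last]),
                    "q": q[i],
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "first_qi",
            "last_qi",
            "first_row",
            "last_row",
            "start",
            "end",
            "q",
        ],
    )


def msc_window_test(
    windows: pd.DataFrame, mu: float, sigma: float
) -> pd.DataFrame:
    """Standardize window means and attach the min-form p-value.

    p = min(F(Z), 1 - F(Z)) is at most 0.5 and is two-tailed at size
    2*alpha when thresholded at alpha.
    """
    if sigma <= 0:
        raise ValueError(
            "sigma must be > 0 (degenerate genome: no variation in "
            "window means)"
        )
    out = windows.copy()
    z = (out["q"].to_numpy() - mu) / sigma
    cdf = norm.cdf(z)
    out["z"] = z
    out["p"] = np.minimum(cdf, 1.0 - cdf)
    return out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def call_outlier_regions(
    windows: pd.DataFrame,
    alpha: float = 0.01,
    max_gap_loci: int = 0,
) -> list[OutlierRegion]:
    """Merge runs of significant windows (p_adj < alpha) into regions.

    Two significant windows on the same chromosome join the same
    region when the number of qualifying loci strictly between their
    spans is at most ``max_gap_loci`` (overlapping windows always
    merge). Region bp span runs from the start of the first locus to
    the end of the last locus covered.
    """
    regions: list[OutlierRegion] = []
    if len(windows) == 0:
        return regions
    sig = windows[windows["p_adj"] < alpha]
    for chrom, grp in sig.groupby("chrom", sort=False):
        grp = grp.sort_values("first_qi")
        run: list[pd.Series] = []
        for _, row in grp.iterrows():
            if run and row["first_qi"] - run[-1]["last_qi"] - 1 > max_gap_loci:
                regions.append(_close_region(chrom, run))
                run = []
            run.append(row)
        if run:
            regions.append(_close_region(chrom, run))
    regions.sort(key=lambda r: (r.chrom, r.start))
    return regions


def _close_region(chrom, run) -> OutlierRegion:
    start = int(min(r["start"] for r in run))
    end = int(max(r["end"] for r in run))
    n_loci = int(max(r["last_qi"] for r in run) - min(r["first_qi"] for r in run) + 1)
    return OutlierRegion(
        chrom=str(chrom),
        start=start,
        end=end,
        n_windows=len(run),
        n_loci=n_loci,
        min_p_adj=float(min(r["p_adj"] for r in run)),
    )


@dataclass
class BranchScan:
    """Scan output for one quadripartition."""

    name: str
    track: SupportTrack
    windows: pd.DataFrame
    regions: list[OutlierRegion]
    mu: float
    sigma: float
    alpha: float = 0.01

    @property
    def n_significant(self) -> int:
        if len(self.windows) == 0:
            return 0
        return int((self.windows["p_adj"].to_numpy() < self.alpha).sum())


def scan_track(
    track: SupportTrack, params: ScanParams
) -> tuple[pd.DataFrame, list[OutlierRegion], float, float]:
    """Windowed MSC-conformity test of one support track.

    Sex chromosomes (``params.sex_chromosomes``) are excluded before
    estimating the null moments and testing. Returns the window table
    (with z, p, p_adj), called regions, and the (mu, sigma) used.
    """
    mask = ~np.isin(track.table.chroms, params.sex_chromosomes)
    values = np.where(mask, track.values, np.nan)
    autosomal = SupportTrack(
        table=track.table, values=values, name=track.name
    )
    windows = window_means(autosomal, params.w)
    if len(windows) == 0:
        windows["z"] = windows["p"] = windows["p_adj"] = []
        return windows, [], np.nan, np.nan
    mu = float(np.nanmean(values))
    if params.sigma_mode == "window":
        sigma = float(windows["q"].std(ddof=1))
    elif params.sigma_mode == "locus":
        sigma = float(np.nanstd(values, ddof=1))
    else:
        raise ValueError(f"unknown sigma_mode {params.sigma_mode!r}")
    windows = msc_window_test(windows, mu, sigma)
    windows["p_adj"] = bh_adjust(windows["p"].to_numpy())
    regions = call_outlier_regions(
        windows, alpha=params.alpha, max_gap_loci=params.max_gap_loci
    )
    return windows, regions, mu, sigma


def genome_scan(
    trees: Sequence[LocusTree],
    table: GenomeTable,
    clade_model: CladeModel,
    params: ScanParams | None = None,
) -> dict[str, BranchScan]:
    """Full scan: per configured quadripartition, the QQS track, the
    windowed test with BH correction, and merged outlier regions."""
    params = params or ScanParams()
    results: dict[str, BranchScan] = {}
    for quad in clade_model.quadripartitions:
        track = qqs_track(trees, table, quad)
        windows, regions, mu, sigma = scan_track(track, params)
        results[quad.name] = BranchScan(
            name=quad.name,
            track=track,
            windows=windows,
            regions=regions,
            mu=mu,
            sigma=sigma,
            alpha=params.alpha,
        )
    return results


def rejection_summary(results: dict[str, BranchScan], alpha: float) -> pd.DataFrame:
    """Per-branch counts of windows rejecting the MSC null."""
    rows = []
    for name, bs in results.items():
        n = len(bs.windows)
        n_sig = (
            int((bs.windows["p_adj"].to_numpy() < alpha).sum()) if n else 0
        )
        rows.append(
            {
                "branch": name,
                "n_windows": n,
                "n_rejected": n_sig,
                "pct_rejected": 100.0 * n_sig / n if n else np.nan,
                "n_regions": len(bs.regions),
            }
        )
    return pd.DataFrame(rows)
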