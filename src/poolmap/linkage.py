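"""Genome-wide homozygosity scan for linkage mapping.

For each retained marker the mutant-pool alt-read fraction ``f`` is computed
and folded to ``max(f, 1-f)``, an allele-orientation-free homozygosity
score: near 0.5 where the mutant pool segregates freely, near 1.0 where all
pooled mutants share one haplotype. The folded values are averaged over a
sliding window of a fixed number of neighbouring loci (not a fixed physical
distance) within each chromosome, and the linked region is called as the
contiguous run of markers around the genome-wide peak whose window value
stays above a threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)


def mutant_allele_frequency(mut_ref, mut_alt):
    """Alt-read fraction ``alt / (ref + alt)`` in the mutant pool.

    Vectorised; zero total depth yields NaN (the marker is flagged
    ``no_data`` and excluded from windows rather than raising).
    """
    mut_ref = np.asarray(mut_ref, dtype=float)
    mut_alt = np.asarray(mut_alt, dtype=float)
    depth = mut_ref + mut_alt
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(depth > 0, mut_alt / depth, np.nan)
    return f if f.ndim else float(f)


def fold_frequency(raw_freq):
    """Fold an allele frequency to ``max(f, 1-f)`` (homozygosity score)."""
    f = np.asarray(raw_freq, dtype=float)
    out = np.maximum(f, 1.0 - f)
    return out if out.ndim else float(out)


def sliding_window_profile(
    table: pd.DataFrame,
    window_size: int = 50,
    *,
    statistic: str = "folded",
    alignment: str = "centered",
) -> pd.DataFrame:
    """Per-marker allele-frequency profile with sliding-window smoothing.

    Parameters
    ----------
    table : DataFrame
        Marker count table (``chrom, pos, mut_ref, mut_alt`` required),
        sorted by (chrom, pos).
    window_size : int
        Number of neighbouring loci averaged per window. Windows never span
        chromosome boundaries; markers too close to a chromosome end (or on
        chromosomes with fewer usable markers than the window) get NaN.
    statistic : "folded" or "raw"
        Which per-marker value is averaged.
    alignment : "centered" or "trailing"
        Centered windows place the mean at the middle marker (for even
        sizes, ``(w-1)//2`` markers to the left and ``w//2`` to the right);
        trailing windows at the last marker of the window.

    Returns a copy of the table with columns ``raw_freq, folded_freq,
    window_freq, no_data`` appended. Zero-depth markers (``no_data``) are
    skipped by the windows: windows run over consecutive *usable* markers.
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    if statistic not in ("folded", "raw"):
        raise ValueError("statistic must be 'folded' or 'raw'")
    if alignment not in ("centered", "trailing"):
        raise ValueError("alignment must be 'centered' or 'trailing'")
    out = table.reset_index(drop=True).copy()
    raw = mutant_allele_frequency(out["mut_ref"], out["mut_alt"])
    folded = fold_frequency(raw)
    out["raw_freq"] = raw
    out["folded_freq"] = folded
    out["no_data"] = np.isnan(raw)
    window = np.full(len(out), np.nan)
    n_no_data = int(out["no_data"].sum())
    if n_no_data:
        logger.info("%d markers with zero mutant-pool depth excluded from windows",
                    n_no_data)
    vals_col = folded if statistic == "folded" else raw
    w = window_size
    for chrom, grp in out.groupby("chrom", sort=False):
        usable = grp.index[~grp["no_data"]]
        vals = np.asarray(vals_col)[usable]
        if vals.size < w:
            logger.info("chromosome %s: %d usable markers < window %d; no window values",
                        chrom, vals.size, w)
            continue
        means = sliding_window_view(vals, w).mean(axis=1)
        if alignment == "centered":
            lo = (w - 1) // 2
            window[usable[lo : lo + means.size]] = means
        else:
            window[usable[w - 1 :]] = means
    out["window_freq"] = window
    return out


@dataclass
class LinkageInterval:
    """Genomic span called as the homozygosity peak."""

    chrom: str
    start_bp: int  # 1-based inclusive
    end_bp: int
    peak_window_freq: float
    n_markers_in_interval: int

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("interval start after end")

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    def to_bed_fields(self) -> tuple[str, int, int]:
        """(chrom, start, end) in BED 0-based half-open convention."""
        return self.chrom, self.start_bp - 1, self.end_bp

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start_bp <= pos <= self.end_bp


@dataclass
class LinkageResult:
    """Interval call plus per-chromosome summary and a status flag."""

    interval: LinkageInterval | None
    status: str  # "ok" or "no_linkage"
    chrom_summary: pd.DataFrame  # chrom, max_window_freq, pos_at_max, ranked


def find_linkage_region(
    profile: pd.DataFrame,
    peak_threshold: float = 0.98,
    threshold_mode: str = "relative",
    flat_tolerance: float = 0.01,
) -> LinkageResult:
    """Call the linked region from a windowed profile.

    The peak is the global maximum of ``window_freq``; ties are broken by the
    longest contiguous run of tied markers, then by lowest genomic
    coordinate. The interval is the maximal contiguous run of windowed
    markers around the peak whose window value stays at or above the
    threshold — by default a fraction (0.98) of the peak height;
    ``threshold_mode="absolute"`` treats ``peak_threshold`` as an absolute
    window frequency instead (the run always includes the peak marker).

    A flat profile (max - min < ``flat_tolerance``) yields status
    ``"no_linkage"`` with no interval.
    """
    if not 0.5 < peak_threshold <= 1:
        raise ValueError("peak_threshold must be in (0.5, 1]")
    if threshold_mode not in ("relative", "absolute"):
        raise ValueError("threshold_mode must be 'relative' or 'absolute'")
    prof = profile.reset_index(drop=True)
    defined = prof[~prof["window_freq"].isna()]
    if defined.empty:
        raise ValueError("no defined window values in profile")

    summary = (
        defined.loc[defined.groupby("chrom", sort=False)["window_freq"].idxmax(),
                    ["chrom", "pos", "window_freq"]]
        .rename(columns={"pos": "pos_at_max", "window_freq": "max_window_freq"})
        .sort_values("max_window_freq", ascending=False, kind="stable")
        .reset_index(drop=True)
    )

    wmax = float(defined["window_freq"].max())
    wmin = float(defined["window_freq"].min())
    if wmax - wmin < flat_tolerance:
        logger.warning("flat profile (max-min=%.4f): no linkage detected", wmax - wmin)
        return LinkageResult(None, "no_linkage", summary)

    # peak selection with tie-breaking over contiguous runs of tied maxima
    at_max = defined.index[defined["window_freq"] == wmax]
    runs: list[list[int]] = []
    chrom_arr = prof["chrom"]
    for i in at_max:
        if runs and _adjacent(defined.index, runs[-1][-1], i) and \
                chrom_arr[runs[-1][-1]] == chrom_arr[i]:
            runs[-1].append(i)
        else:
            runs.append([i])
    best = max(runs, key=len)  # ties: max() keeps the first (lowest coordinate)
    if sum(len(r) == len(best) for r in runs) > 1:
        logger.info("tied peaks: choosing longest run then lowest coordinate")
    peak_idx = best[len(best) // 2]
    peak_chrom = prof.at[peak_idx, "chrom"]

    thr = peak_threshold * wmax if threshold_mode == "relative" else peak_threshold
    thr = min(thr, wmax)  # run always contains the peak

    chrom_defined = defined.index[defined["chrom"] == peak_chrom].to_numpy()
    k = int(np.flatnonzero(chrom_defined == peak_idx)[0])
    lo = k
    while lo > 0 and prof.at[chrom_defined[lo - 1], "window_freq"] >= thr:
        lo -= 1
    hi = k
    while hi < chrom_defined.size - 1 and prof.at[chrom_defined[hi + 1], "window_freq"] >= thr:
        hi += 1
    run = chrom_defined[lo : hi + 1]
    interval = LinkageInterval(
        chrom=str(peak_chrom),
        start_bp=int(prof.at[run[0], "pos"]),
        end_bp=int(prof.at[run[-1], "pos"]),
        peak_window_freq=wmax,
        n_markers_in_interval=int(run.size),
    )
    logger.info("linkage interval %s:%d-%d (%.1f kb, peak %.4f, %d markers)",
                interval.chrom, interval.start_bp, interval.end_bp,
                interval.length_bp / 1e3, wmax, interval.n_markers_in_interval)
    return LinkageResult(interval, "ok", summary)


def _adjacent(index: pd.Index, a: int, b: int) -> bool:
    arr = index.to_numpy()
    ka = np.flatnonzero(arr == a)
    kb = np.flatnonzero(arr == b)
    return bool(ka.size and kb.size and kb[0] == ka[0] + 1)


class LinkageScanner(BaseEstimator):
    """Sliding-window homozygosity scan as a scikit-learn style estimator.

    ``fit(X)`` takes a marker count table and exposes the fitted profile and
    interval call:

    Attributes
    ----------
    profile_ : DataFrame
        Per-marker raw, folded and windowed frequencies.
    result_ : LinkageResult
    interval_ : LinkageInterval or None
    status_ : str
    chrom_summary_ : DataFrame
    """

    def __init__(self, window_size: int = 50, peak_threshold: float = 0.98,
                 threshold_mode: str = "relative", statistic: str = "folded",
                 alignment: str = "centered", flat_tolerance: float = 0.01):
        self.window_size = window_size
        self.peak_threshold = peak_threshold
        self.threshold_mode = threshold_mode
        self.statistic = statistic
        self.alignment = alignment
        self.flat_tolerance = flat_tolerance

    def fit(self, X: pd.DataFrame, y=None) -> "LinkageScanner":
        self.profile_ = sliding_window_profile(
            X, self.window_size, statistic=self.statistic, alignment=self.alignment
        )
        self.result_ = find_linkage_region(
            self.profile_, peak_threshold=self.peak_threshold,
            threshold_mode=self.threshold_mode, flat_tolerance=self.flat_tolerance,
        )
        self.interval_ = self.result_.interval
        self.status_ = self.result_.status
        self.chrom_summary_ = self.result_.chrom_summary
        return self
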