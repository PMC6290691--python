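"""Read-depth CNV calling and interval-set comparison.

Pipeline: 1-kb coverage bins are GC-corrected (depth divided by the median
of its 2 %-wide GC stratum), normalized against an identically corrected
reference coverage profile and rescaled to a genome-wide median ratio of 1.
Per-bin ploidy is 2 x corrected ratio; bins are classified loss / neutral /
gain by half-integer thresholds (<= 1.5, >= 2.5), merged into segments, and
segments longer than 1 kb whose mean ploidy departs from 2 significantly
are emitted as CNV calls.  Calls matching a common-CNV database at >= 50 %
overlap are filtered out; cross-sample comparison uses reciprocal overlap.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .vardata import (CNV_TYPES, SV_TYPES, CoverageProfile, IntervalCall)


@dataclass
class SegmentationConfig:
    bin_size: int = 1000
    gain_threshold: float = 2.5      # ploidy >= value -> gain bin
    loss_threshold: float = 1.5      # ploidy <= value -> loss bin
    min_cnv_length: int = 1000       # strictly-greater rule
    min_sv_length: int = 1000
    max_sv_length: int = 3_000_000
    overlap_fraction: float = 0.5    # common-DB filter threshold (inclusive)
    reciprocal: bool = True          # cross-sample matching mode
    bridge_gap: int = 1              # neutral bins a run may bridge
    merge_gap: int = 5               # max gap when merging same-type segments
    min_seg_z: float = 6.0           # robust z of |mean ploidy - 2| to emit
    smooth_window: int = 5           # moving-average bins for bin labelling
    refine_window: int = 6           # bins searched per side for the boundary
    gc_stratum_width: float = 0.02

    def validate(self) -> "SegmentationConfig":
        if not self.loss_threshold < 2 < self.gain_threshold:
            raise ValueError("need loss_threshold < 2 < gain_threshold")
        if not 0 < self.overlap_fraction <= 1:
            raise ValueError("overlap_fraction outside (0,1]")
        if self.bridge_gap < 0 or self.merge_gap < 0 or self.refine_window < 0:
            raise ValueError("negative gap/window")
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ValueError("smooth_window must be a positive odd number")
        return self


@dataclass(frozen=True)
class CoverageStats:
    mean_coverage: float
    frac_above_20x: float

    def __post_init__(self):
        if not 0.0 <= self.frac_above_20x <= 1.0:
            raise ValueError("fraction outside [0,1]")


def coverage_stats(profile: CoverageProfile) -> CoverageStats:
    """Genome-wide mean depth and the fraction of bins covered > 20x."""
    depth = profile.bins["raw_depth"].to_numpy()
    if len(depth) == 0:
        raise ValueError("empty coverage profile")
    return CoverageStats(mean_coverage=float(depth.mean()),
                         frac_above_20x=float((depth > 20).mean()))


# ---------------------------------------------------------------------------
# GC correction + normalization
# ---------------------------------------------------------------------------

def _gc_correct(depth: np.ndarray, gc: np.ndarray, width: float) -> np.ndarray:
    """Divide each bin by the median depth of its GC stratum."""
    out = np.full_like(depth, np.nan, dtype=float)
    ok = np.isfinite(gc) & np.isfinite(depth)
    strata = np.floor(gc[ok] / width).astype(int)
    corrected = np.empty(ok.sum())
    values = depth[ok]
    for s in np.unique(strata):
        sel = strata == s
        med = np.median(values[sel])
        corrected[sel] = values[sel] / med if med > 0 else np.nan
    out[ok] = corrected
    return out


def gc_correct_and_normalize(profile: CoverageProfile,
                             reference_profile: CoverageProfile,
                             config: SegmentationConfig | None = None
                             ) -> CoverageProfile:
    """GC-correct both profiles, take their ratio, rescale to median 1.

    Bins where the reference profile has zero (or masked) corrected depth
    are masked (corrected_ratio = NaN).
    """
    config = (config or SegmentationConfig()).validate()
    if not profile.same_binning(reference_profile):
        raise ValueError("sample and reference profiles are binned differently")
    gc = profile.bins["gc_fraction"].to_numpy()
    if not np.isfinite(gc).any():
        raise ValueError("profile has no GC fractions; attach a reference first")
    samp = _gc_correct(profile.bins["raw_depth"].to_numpy(), gc,
                       config.gc_stratum_width)
    ref = _gc_correct(reference_profile.bins["raw_depth"].to_numpy(), gc,
                      config.gc_stratum_width)
    if not (np.nan_to_num(ref) > 0).any():
        raise ValueError("reference profile is all zero")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(ref > 0, samp / ref, np.nan)
    med = np.nanmedian(ratio)
    if not np.isfinite(med) or med <= 0:
        raise ValueError("cannot normalize: non-positive median ratio")
    ratio = ratio / med
    bins = profile.bins.copy()
    bins["corrected_ratio"] = ratio
    return CoverageProfile(bins, profile.bin_size)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def _runs_with_bridging(labels: np.ndarray, bridge_gap: int):
    """Maximal same-label runs of non-neutral bins, bridging short neutral gaps."""
    runs = []
    i, n = 0, len(labels)
    while i < n:
        if labels[i] == 0:
            i += 1
            continue
        lab, j, last_hit = labels[i], i, i
        while j + 1 < n:
            nxt = j + 1
            if labels[nxt] == lab:
                j = nxt
                last_hit = nxt
            elif labels[nxt] == 0 and nxt - last_hit <= bridge_gap:
                j = nxt
            else:
                break
        runs.append((i, last_hit, int(lab)))
        i = last_hit + 1
    return runs


def _refine_boundary(ploidy: np.ndarray, lo: int, hi: int, side: str,
                     seg_mean: float, window: int) -> int:
    """Least-squares changepoint search within +/- window bins of one edge."""
    n = len(ploidy)
    if side == "left":
        candidates = range(max(0, lo - window), min(hi, lo + window) + 1)
        best, best_sse = lo, np.inf
        for t in candidates:
            out = ploidy[max(0, lo - window):t]
            ins = ploidy[t:hi + 1]
            sse = np.nansum((out - 2.0) ** 2) + np.nansum((ins - seg_mean) ** 2)
            if sse < best_sse - 1e-12:
                best, best_sse = t, sse
        return best
    candidates = range(max(lo, hi - window), min(n - 1, hi + window) + 1)
    best, best_sse = hi, np.inf
    for t in candidates:
        ins = ploidy[lo:t + 1]
        out = ploidy[t + 1:min(n, hi + window + 1)]
        sse = np.nansum((ins - seg_mean) ** 2) + np.nansum((out - 2.0) ** 2)
        if sse < best_sse - 1e-12:
            best, best_sse = t, sse
    return best


def _moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average ignoring NaNs, shrinking at the edges."""
    if window == 1:
        return values.copy()
    finite = np.isfinite(values)
    kernel = np.ones(window)
    total = np.convolve(np.where(finite, values, 0.0), kernel, mode="same")
    count = np.convolve(finite.astype(float), kernel, mode="same")
    with np.errstate(invalid="ignore"):
        return np.where(count > 0, total / count, np.nan)


def segment_and_call(profile: CoverageProfile,
                     config: SegmentationConfig | None = None
                     ) -> list[IntervalCall]:
    """Merge non-neutral bins into CNV calls with refined boundaries.

    Bins are labelled on a ``smooth_window`` moving average of per-bin
    ploidy (raw 1-kb bins at ~30x are too noisy to threshold individually);
    boundaries are then re-located on the raw bins by a least-squares
    changepoint search, which uses the full diploid-vs-segment contrast.  A
    segment is emitted when its raw mean ploidy passes the calling
    threshold, its robust z-score |mean - 2| * sqrt(n_bins) / sigma reaches
    ``min_seg_z`` (sigma = scaled MAD of per-bin ploidy, so a handful of
    Poisson outlier bins cannot fake a call), and it is longer than
    ``min_cnv_length`` (strict).
    """
    config = (config or SegmentationConfig()).validate()
    if not profile.has_corrected:
        raise ValueError("profile lacks corrected_ratio; normalize first")
    calls: list[IntervalCall] = []
    for chrom, sub in profile.bins.groupby("chrom", sort=False):
        ploidy = 2.0 * sub["corrected_ratio"].to_numpy()
        starts = sub["bin_start"].to_numpy()
        ends = sub["bin_end"].to_numpy()
        finite = ploidy[np.isfinite(ploidy)]
        if len(finite) == 0:
            continue
        sigma = 1.4826 * np.median(np.abs(finite - np.median(finite)))
        sigma = max(float(sigma), 1e-9)
        smoothed = _moving_average(ploidy, config.smooth_window)
        labels = np.zeros(len(ploidy), dtype=int)
        with np.errstate(invalid="ignore"):
            labels[smoothed >= config.gain_threshold] = 1
            labels[smoothed <= config.loss_threshold] = -1

        segs = _runs_with_bridging(labels, config.bridge_gap)

        def seg_mean(lo, hi):
            return float(np.nanmean(ploidy[lo:hi + 1]))

        def passes(mean, lab):
            return (mean >= config.gain_threshold if lab > 0
                    else mean <= config.loss_threshold)

        # merge same-type segments across short neutral gaps when the
        # merged mean still supports the call
        merged = []
        for seg in segs:
            if merged and merged[-1][2] == seg[2] \
                    and seg[0] - merged[-1][1] - 1 <= config.merge_gap:
                cand = (merged[-1][0], seg[1], seg[2])
                if passes(seg_mean(cand[0], cand[1]), cand[2]):
                    merged[-1] = cand
                    continue
            merged.append(seg)

        for lo, hi, lab in merged:
            mean = seg_mean(lo, hi)
            lo = _refine_boundary(ploidy, lo, hi, "left", mean,
                                  config.refine_window)
            hi = _refine_boundary(ploidy, lo, hi, "right", mean,
                                  config.refine_window)
            mean = seg_mean(lo, hi)
            if not passes(mean, lab):
                continue
            nbins = hi - lo + 1
            z = abs(mean - 2.0) * np.sqrt(nbins) / sigma
            if z < config.min_seg_z:
                continue
            length = int(ends[hi] - starts[lo])
            if length <= config.min_cnv_length:
                continue
            calls.append(IntervalCall(
                chrom=chrom, start=int(starts[lo]), end=int(ends[hi]),
                call_type="cnv_gain" if lab > 0 else "cnv_loss",
                ploidy=mean, source_label="cnvseg"))
    calls.sort(key=IntervalCall.sort_key)
    return calls


# ---------------------------------------------------------------------------
# interval-set operations
# ---------------------------------------------------------------------------

def _overlap(a: IntervalCall, b: IntervalCall) -> int:
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def filter_common(calls: Sequence[IntervalCall],
                  common_db: Sequence[IntervalCall],
                  config: SegmentationConfig | None = None
                  ) -> tuple[list[IntervalCall], list[IntervalCall]]:
    """Partition calls into (retained, removed) against a common-CNV database.

    A call is removed iff some database interval covers at least
    ``overlap_fraction`` of the *call's* length (inclusive >= rule; one-way,
    because database records are heterogeneous in size).
    """
    config = (config or SegmentationConfig()).validate()
    trees: dict[str, IntervalTree] = {}
    for db in common_db:
        trees.setdefault(db.chrom, IntervalTree()).addi(db.start, db.end)
    retained, removed = [], []
    for call in calls:
        hits = trees.get(call.chrom, IntervalTree()).overlap(call.start, call.end)
        frac = max((min(call.end, h.end) - max(call.start, h.begin)) / len(call)
                   for h in hits) if hits else 0.0
        (removed if frac >= config.overlap_fraction else retained).append(call)
    return retained, removed


def _compatible(a: IntervalCall, b: IntervalCall) -> bool:
    if a.call_type in CNV_TYPES and b.call_type in CNV_TYPES:
        return a.call_type == b.call_type
    if a.call_type in SV_TYPES and b.call_type in SV_TYPES:
        return a.call_type == b.call_type
    return False


def compare_interval_sets(calls_a: Sequence[IntervalCall],
                          calls_b: Sequence[IntervalCall],
                          config: SegmentationConfig | None = None):
    """Match calls across samples by type and (reciprocal) overlap.

    Two calls match iff they have the same direction/type and their overlap
    reaches ``overlap_fraction`` of both intervals (of the A call only, if
    ``reciprocal`` is off).  Matching is greedy by descending overlap and
    one-to-one.  Returns (shared pairs, a_only, b_only).
    """
    config = (config or SegmentationConfig()).validate()
    candidates = []
    for i, a in enumerate(calls_a):
        for j, b in enumerate(calls_b):
            if not _compatible(a, b):
                continue
            ov = _overlap(a, b)
            if ov <= 0:
                continue
            ok = (ov >= config.overlap_fraction * len(a)
                  and (not config.reciprocal
                       or ov >= config.overlap_fraction * len(b)))
            if ok:
                candidates.append((ov, i, j))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a, used_b, shared = set(), set(), []
    for ov, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        shared.append((calls_a[i], calls_b[j]))
    a_only = [c for i, c in enumerate(calls_a) if i not in used_a]
    b_only = [c for j, c in enumerate(calls_b) if j not in used_b]
    return shared, a_only, b_only
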