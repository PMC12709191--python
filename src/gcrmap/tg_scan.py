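"""Sliding-window telomere-likeness scan.

Computes, along the caller-supplied 3'->5' strand (for a left arm, the
reverse complement of the reference top strand), the percentage of
nucleotides that are T or G and the G:T ratio in each window, then
merges and ranks super-threshold windows into candidate telomere-like
intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from gcrmap.errors import DataError

#: sentinel G:T ratio for windows without any T; ranks above any finite ratio
GT_SENTINEL = math.inf


@dataclass(frozen=True)
class TGWindow:
    start: int
    end: int
    tg_percent: float
    gt_ratio: float  # GT_SENTINEL when the window has G but no T

    @property
    def length(self) -> int:
        return self.end - self.start


def tg_windows(seq: str, window: int = 50, step: int = 10) -> list[TGWindow]:
    """Exact T+G composition over tiled windows of the given strand."""
    if window > len(seq):
        raise DataError(f"window {window} exceeds sequence length {len(seq)}")
    if step < 1:
        raise DataError("step must be >= 1")
    seq = seq.upper()
    out = []
    for start in range(0, len(seq) - window + 1, step):
        sub = seq[start : start + window]
        g = sub.count("G")
        t = sub.count("T")
        if t > 0:
            ratio = g / t
        elif g > 0:
            ratio = GT_SENTINEL
        else:
            ratio = 0.0
        out.append(
            TGWindow(
                start=start,
                end=start + window,
                tg_percent=100.0 * (g + t) / window,
                gt_ratio=ratio,
            )
        )
    return out


@dataclass(frozen=True)
class TGPeak:
    start: int
    end: int
    peak_gt_ratio: float
    peak_tg_percent: float
    n_windows: int


def rank_tg_peaks(
    windows: Iterable[TGWindow],
    min_tg_percent: float = 70.0,
    min_gt_ratio: float = 1.0,
) -> list[TGPeak]:
    """Merge overlapping super-threshold windows and rank the intervals by
    peak G:T ratio, then peak T+G percent, breaking ties leftmost-first."""
    passing = sorted(
        (
            w
            for w in windows
            if w.tg_percent >= min_tg_percent and w.gt_ratio >= min_gt_ratio
        ),
        key=lambda w: w.start,
    )
    peaks: list[TGPeak] = []
    group: list[TGWindow] = []
    for w in passing:
        if group and w.start <= group[-1].end:
            group.append(w)
            continue
        if group:
            peaks.append(_to_peak(group))
        group = [w]
    if group:
        peaks.append(_to_peak(group))
    peaks.sort(key=lambda p: (-p.peak_gt_ratio, -p.peak_tg_percent, p.start))
    return peaks


def _to_peak(group: list[TGWindow]) -> TGPeak:
    return TGPeak(
        start=group[0].start,
        end=max(w.end for w in group),
        peak_gt_ratio=max(w.gt_ratio for w in group),
        peak_tg_percent=max(w.tg_percent for w in group),
        n_windows=len(group),
    )


def write_window_table(windows: list[TGWindow], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("start\tend\ttg_percent\tgt_ratio\n")
        for w in windows:
            ratio = "inf" if math.isinf(w.gt_ratio) else f"{w.gt_ratio:.4f}"
            fh.write(f"{w.start}\t{w.end}\t{w.tg_percent:.2f}\t{ratio}\n")


def write_peak_table(peaks: list[TGPeak], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("start\tend\tpeak_gt_ratio\tpeak_tg_percent\tn_windows\n")
        for p in peaks:
            ratio = "inf" if math.isinf(p.peak_gt_ratio) else f"{p.peak_gt_ratio:.4f}"
            fh.write(
                f"{p.start}\t{p.end}\t{ratio}\t{p.peak_tg_percent:.2f}\t{p.n_windows}\n"
            )
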