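"""Genomic interval arithmetic on (chrom, start, end) DataFrames.

All coordinates are 0-based half-open.  Intervals are held in plain pandas
DataFrames with at least ``chrom``, ``start`` and ``end`` columns; every
function here returns intervals sorted by (chrom, start).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

BED_COLS = ["chrom", "start", "end"]


def as_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and sort an interval frame."""
    if not set(BED_COLS) <= set(df.columns):
        raise ValueError(f"interval frame needs columns {BED_COLS}")
    if len(df) and (df["end"] < df["start"]).any():
        raise ValueError("interval with end < start")
    return df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)


def merge(df: pd.DataFrame) -> pd.DataFrame:
    """Union of intervals: overlapping or book-ended intervals are fused."""
    df = as_intervals(df)
    out = []
    for chrom, sub in df.groupby("chrom", sort=True):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        # running maximum of ends; a new block starts where start > max(end so far)
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s > cur_e:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=BED_COLS)


def total_bp(df: pd.DataFrame) -> int:
    """Total base pairs covered (after merging)."""
    if len(df) == 0:
        return 0
    m = merge(df)
    return int((m["end"] - m["start"]).sum())


def intersect(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Pairwise intersection of two (merged) interval sets."""
    if len(a) == 0 or len(b) == 0:
        return pd.DataFrame(columns=BED_COLS)
    a, b = merge(a), merge(b)
    out = []
    for chrom, sub_a in a.groupby("chrom", sort=True):
        sub_b = b[b["chrom"] == chrom]
        if len(sub_b) == 0:
            continue
        bs = sub_b["start"].to_numpy()
        be = sub_b["end"].to_numpy()
        for s, e in zip(sub_a["start"].to_numpy(), sub_a["end"].to_numpy()):
            lo = np.searchsorted(be, s, side="right")
            hi = np.searchsorted(bs, e, side="left")
            for j in range(lo, hi):
                out.append((chrom, max(s, bs[j]), min(e, be[j])))
    res = pd.DataFrame(out, columns=BED_COLS)
    return res[res["end"] > res["start"]].reset_index(drop=True)


def intersect_bp(a: pd.DataFrame, b: pd.DataFrame) -> int:
    return total_bp(intersect(a, b))


def complement(df: pd.DataFrame, chrom_lengths: dict[str, int]) -> pd.DataFrame:
    """Gaps between intervals, within declared chromosome bounds."""
    m = merge(df) if len(df) else pd.DataFrame(columns=BED_COLS)
    out = []
    for chrom, length in chrom_lengths.items():
        sub = m[m["chrom"] == chrom]
        pos = 0
        for s, e in zip(sub["start"], sub["end"]):
            if s > pos:
                out.append((chrom, pos, s))
            pos = max(pos, e)
        if pos < length:
            out.append((chrom, pos, length))
    return pd.DataFrame(out, columns=BED_COLS)


def jaccard(a: pd.DataFrame, b: pd.DataFrame) -> float:
    """bp-level Jaccard index |A∩B| / |A∪B| (NaN when both empty)."""
    inter = intersect_bp(a, b)
    union = total_bp(a) + total_bp(b) - inter
    return float("nan") if union == 0 else inter / union


class GenomeCoords:
    """Concatenated single-axis coordinate system over a set of chromosomes.

    Collapsing chromosomes onto one axis lets overlap queries against a
    fixed interval set run as two searchsorted calls, which is what the
    Monte Carlo shuffle machinery needs to stay fast.
    """

    def __init__(self, chrom_lengths: dict[str, int]):
        self.chroms = list(chrom_lengths)
        lens = np.array([chrom_lengths[c] for c in self.chroms], dtype=np.int64)
        self.offsets = dict(zip(self.chroms, np.concatenate([[0], np.cumsum(lens)[:-1]])))
        self.total = int(lens.sum())

    def globalize(self, df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        off = df["chrom"].map(self.offsets).to_numpy(dtype=np.int64)
        return df["start"].to_numpy() + off, df["end"].to_numpy() + off


class CoverageIndex:
    """Prefix-sum index answering 'how many covered bp in [a, b)' in O(log n)."""

    def __init__(self, intervals: pd.DataFrame, coords: GenomeCoords):
        m = merge(intervals) if len(intervals) else pd.DataFrame(columns=BED_COLS)
        if len(m):
            s, e = coords.globalize(m)
        else:
            s = e = np.empty(0, dtype=np.int64)
        self.starts, self.ends = s, e
        self.cum = np.concatenate([[0], np.cumsum(e - s)])

    def _cov_before(self, x: np.ndarray) -> np.ndarray:
        """Covered bp in [0, x)."""
        if len(self.starts) == 0:
            return np.zeros(np.shape(x), dtype=np.int64)
        i = np.searchsorted(self.starts, x, side="right")
        full = self.cum[i]
        # subtract the part of interval i-1 extending past x
        over = np.where(i > 0, np.maximum(self.ends[np.maximum(i - 1, 0)] - x, 0), 0)
        return full - over

    def overlap_bp(self, gstart: np.ndarray, gend: np.ndarray) -> np.ndarray:
        """Covered bp within each query [gstart, gend) (global coordinates)."""
        gstart = np.asarray(gstart, dtype=np.int64)
        gend = np.asarray(gend, dtype=np.int64)
        return self._cov_before(gend) - self._cov_before(gstart)
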