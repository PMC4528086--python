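"""Methylome QC and quantification from per-cytosine bisulfite call tables.

The unit of analysis is the CpG dyad: plus- and minus-strand calls of one CpG
are summed into a single record at the position of the plus-strand C.  QC
follows standard low-coverage WGBS practice: the bisulfite conversion rate is
estimated from non-CpG (CHG/CHH) cytosines, and CpG sites with coverage below
4x or above the sample's 99.9th coverage percentile are discarded before any
regional quantification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


class EmptyInputError(ValueError):
    """Raised when a statistic is undefined on the given (empty) input."""


def combine_strands(records: pd.DataFrame) -> pd.DataFrame:
    """Merge plus/minus strand CpG calls of each dyad into CpG-unit records.

    A ``+`` record at position p and a ``-`` record at p+1 are summed into one
    record at p.  Unpaired records pass through unchanged (a ``-``-only dyad is
    reported at the C of the minus strand read, i.e. p+1 maps back to p).
    Count totals are conserved exactly.
    """
    cg = records[records["context"] == "CG"]
    non_cg = len(records) - len(cg)
    if non_cg:
        # non-CpG records carry no dyad structure; they are simply not merged
        pass
    if len(cg) == 0:
        return cg.copy()
    key = np.where(cg["strand"] == "-", cg["pos0"] - 1, cg["pos0"])
    g = (
        cg.assign(dyad=key)
        .groupby(["chrom", "dyad"], sort=True, as_index=False)[["meth_count", "total_count"]]
        .sum()
    )
    out = pd.DataFrame({
        "chrom": g["chrom"],
        "pos0": g["dyad"],
        "strand": "+",
        "context": "CG",
        "meth_count": g["meth_count"],
        "total_count": g["total_count"],
    })
    return out.sort_values(["chrom", "pos0"], kind="stable").reset_index(drop=True)


def conversion_rate(records: pd.DataFrame) -> float:
    """Bisulfite conversion rate from CHG+CHH cytosines: converted C / total C."""
    nc = records[records["context"].isin(["CHG", "CHH"])]
    tot = int(nc["total_count"].sum())
    if tot == 0:
        raise EmptyInputError("no CHG/CHH coverage; conversion rate undefined")
    return float((tot - int(nc["meth_count"].sum())) / tot)


def cpg_coverage(records: pd.DataFrame) -> float:
    """Mean reads per covered CpG (CpG-unit records)."""
    cg = records[records["context"] == "CG"]
    if len(cg) == 0:
        raise EmptyInputError("no CpG records; coverage undefined")
    return float(cg["total_count"].mean())


def coverage_filter(
    records: pd.DataFrame,
    min_cov: int = 4,
    upper_pct: float = 99.9,
    upper_value: float | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Discard CpG records with coverage < min_cov or above the upper percentile.

    The high cut is the ``upper_pct`` percentile (linear interpolation) of the
    input records' own coverage distribution; records strictly above it are
    dropped.  Pass ``upper_value`` to reuse a previously computed cut, which
    makes repeated application a no-op.
    """
    if min_cov < 1:
        raise ValueError("min_cov must be >= 1")
    totals = records["total_count"].to_numpy()
    if upper_value is None:
        upper_value = float(np.percentile(totals, upper_pct)) if len(totals) else np.inf
    low = totals < min_cov
    high = totals > upper_value
    report = {
        "n_input": int(len(records)),
        "dropped_low": int(low.sum()),
        "dropped_high": int(high.sum()),
        "min_cov": min_cov,
        "upper_pct": upper_pct,
        "upper_value": float(upper_value),
    }
    return records[~(low | high)].reset_index(drop=True), report


@dataclass
class MethylomeSample:
    """A QC'd, strand-combined, coverage-filtered CpG methylome."""

    sample_id: str
    records: pd.DataFrame
    conversion_rate: float | None = None
    mean_cpg_coverage: float | None = None
    filter_report: dict | None = None

    @classmethod
    def from_calls(cls, sample_id: str, calls: pd.DataFrame, min_cov: int = 4, upper_pct: float = 99.9) -> "MethylomeSample":
        """Full QC path: conversion rate, strand combining, coverage filter."""
        try:
            conv = conversion_rate(calls)
        except EmptyInputError:
            conv = None
        units = combine_strands(calls)
        filtered, report = coverage_filter(units, min_cov=min_cov, upper_pct=upper_pct)
        cov = cpg_coverage(units) if len(units) else None
        return cls(sample_id, filtered, conv, cov, report)

    def global_methylation(self) -> float:
        return weighted_pct(self.records)


def weighted_pct(records: pd.DataFrame) -> float:
    tot = records["total_count"].sum()
    return float("nan") if tot == 0 else 100.0 * float(records["meth_count"].sum()) / float(tot)


def region_methylation(
    records: pd.DataFrame,
    intervals: pd.DataFrame,
    mode: str = "weighted",
) -> pd.DataFrame:
    """Percent methylation per interval.

    ``weighted``: 100 * sum(meth) / sum(total) over CpGs in the interval.
    ``sitemean``: unweighted mean of per-site percentages.
    Intervals without a covered CpG get NaN and n_sites=0.
    """
    if mode not in ("weighted", "sitemean"):
        raise ValueError("mode must be 'weighted' or 'sitemean'")
    if len(intervals) and (intervals["end"] < intervals["start"]).any():
        raise ValueError("malformed interval (end < start)")
    out = intervals.reset_index(drop=True).copy()
    pct = np.full(len(out), np.nan)
    nsite = np.zeros(len(out), dtype=int)
    msum = np.zeros(len(out), dtype=np.int64)
    tsum = np.zeros(len(out), dtype=np.int64)
    for chrom, sub in records.groupby("chrom"):
        sel = out.index[out["chrom"] == chrom]
        if len(sel) == 0:
            continue
        pos = sub["pos0"].to_numpy()
        order = np.argsort(pos, kind="stable")
        pos = pos[order]
        meth = sub["meth_count"].to_numpy()[order]
        tot = sub["total_count"].to_numpy()[order]
        cm = np.concatenate([[0], np.cumsum(meth)])
        ct = np.concatenate([[0], np.cumsum(tot)])
        lo = np.searchsorted(pos, out.loc[sel, "start"].to_numpy(), side="left")
        hi = np.searchsorted(pos, out.loc[sel, "end"].to_numpy(), side="left")
        nsite[sel] = hi - lo
        msum[sel] = cm[hi] - cm[lo]
        tsum[sel] = ct[hi] - ct[lo]
        if mode == "sitemean":
            site_pct = 100.0 * meth / np.maximum(tot, 1)
            cs = np.concatenate([[0], np.cumsum(site_pct)])
            with np.errstate(invalid="ignore"):
                pct[sel] = np.where(hi > lo, (cs[hi] - cs[lo]) / np.maximum(hi - lo, 1), np.nan)
    if mode == "weighted":
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(tsum > 0, 100.0 * msum / np.where(tsum > 0, tsum, 1), np.nan)
    out["pct_methylation"] = pct
    out["n_sites"] = nsite
    out["meth_sum"] = msum
    out["total_sum"] = tsum
    return out


def binned_track(
    records: pd.DataFrame,
    chrom_lengths: dict[str, int],
    bin_size: int = 2_000_000,
) -> pd.DataFrame:
    """Fixed-bin weighted percent-methylation track (bedGraph-style frame)."""
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    bins = []
    for chrom, L in chrom_lengths.items():
        edges = np.arange(0, L, bin_size)
        bins.append(pd.DataFrame({
            "chrom": chrom, "start": edges, "end": np.minimum(edges + bin_size, L)}))
    frame = pd.concat(bins, ignore_index=True)
    return region_methylation(records, frame, mode="weighted")


def metaplot(
    records: pd.DataFrame,
    anchors: pd.DataFrame,
    flank_bp: int = 10_000,
    n_bins: int = 20,
) -> pd.DataFrame:
    """Average methylation around oriented anchors (TSS/TTS metaplot).

    ``anchors`` needs chrom, start (anchor position) and strand.  Sites within
    +-flank_bp are pooled across anchors into 2*n_bins bins of width
    flank_bp/n_bins, minus-strand anchors mirrored so bin offsets are in
    transcriptional orientation.  Bin 0 is the first downstream bin [0, width).
    """
    if len(anchors) == 0:
        raise ValueError("no anchors")
    if flank_bp % n_bins != 0:
        raise ValueError("flank_bp must be divisible by n_bins")
    width = flank_bp // n_bins
    msum = np.zeros(2 * n_bins, dtype=np.int64)
    tsum = np.zeros(2 * n_bins, dtype=np.int64)
    nsit = np.zeros(2 * n_bins, dtype=np.int64)
    for chrom, sub in records.groupby("chrom"):
        anc = anchors[anchors["chrom"] == chrom]
        if len(anc) == 0:
            continue
        pos = sub["pos0"].to_numpy()
        order = np.argsort(pos, kind="stable")
        pos = pos[order]
        meth = sub["meth_count"].to_numpy()[order]
        tot = sub["total_count"].to_numpy()[order]
        for apos, strand in zip(anc["start"].to_numpy(), anc["strand"].to_numpy()):
            lo = np.searchsorted(pos, apos - flank_bp, side="left")
            hi = np.searchsorted(pos, apos + flank_bp, side="left")
            if hi == lo:
                continue
            rel = pos[lo:hi] - apos
            if strand == "-":
                rel = -rel  # mirror into transcriptional orientation
            b = rel // width + n_bins
            ok = (b >= 0) & (b < 2 * n_bins)
            np.add.at(msum, b[ok], meth[lo:hi][ok])
            np.add.at(tsum, b[ok], tot[lo:hi][ok])
            np.add.at(nsit, b[ok], 1)
    offsets = (np.arange(2 * n_bins) - n_bins) * width
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(tsum > 0, 100.0 * msum / np.where(tsum > 0, tsum, 1), np.nan)
    return pd.DataFrame({
        "bin": np.arange(2 * n_bins) - n_bins,
        "offset_bp": offsets,
        "pct_methylation": mean,
        "n_sites": nsit,
    })


def paired_wilcoxon_less(values_a, values_b) -> float:
    """One-sided paired Wilcoxon signed-rank p-value for H1: a < b.

    Zero differences are dropped (Wilcoxon convention); the exact null
    distribution is used for n <= 25 untied pairs, the normal approximation
    with continuity correction otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    d = a - b
    d = d[d != 0]
    if len(d) < 2:
        raise EmptyInputError("fewer than 2 non-tied pairs; test undefined")
    method = "exact" if len(d) <= 25 else "approx"
    try:
        res = sps.wilcoxon(d, alternative="less", zero_method="wilcox", method=method, correction=True)
    except ValueError:
        res = sps.wilcoxon(d, alternative="less", zero_method="wilcox", method="approx", correction=True)
    return float(res.pvalue)
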