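"""Feature-overlap statistics and Monte Carlo empirical p-values.

The central null model follows the resampling design of the peak analysis:
each query (AGS-unique) peak is replaced by a length-matched interval drawn
from inside the *common* peak set, repeated ``n_shuffles`` (default 500)
times, and the empirical p-value is (1 + #{null >= observed, in the observed
direction}) / (n_shuffles + 1).  Drawing from the common set rather than from
the genome controls for the base composition of peaks; genome-wide placement
is available separately for domain location analysis.  A call is flagged
significant under the joint rule p < alpha (default 0.002, the floor of a
500-shuffle test) and fold change vs common deviating more than 20% from 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import intervals as iv
from .methylome import EmptyInputError, paired_wilcoxon_less, region_methylation


def percent_length_overlap(query: pd.DataFrame, feature: pd.DataFrame) -> float:
    """100 * (bp of query overlapping feature) / (bp of query)."""
    qbp = iv.total_bp(query)
    if qbp == 0:
        raise EmptyInputError("empty query set; percent overlap undefined")
    return 100.0 * iv.intersect_bp(query, feature) / qbp


def fold_change_vs_common(unique_set: pd.DataFrame, common_set: pd.DataFrame, feature: pd.DataFrame) -> float:
    """Fold change of % length overlap of the unique set relative to the common set.

    Returns inf when the common set has zero overlap with the feature.
    """
    u = percent_length_overlap(unique_set, feature)
    c = percent_length_overlap(common_set, feature)
    return float("inf") if c == 0 else u / c


def _coords_from(*frames: pd.DataFrame) -> iv.GenomeCoords:
    lengths: dict[str, int] = {}
    for f in frames:
        if len(f) == 0:
            continue
        for chrom, sub in f.groupby("chrom"):
            lengths[chrom] = max(lengths.get(chrom, 0), int(sub["end"].max()) + 1)
    return iv.GenomeCoords(lengths)


def shuffle_from_common(length_bp: int, common_set: pd.DataFrame, rng: np.random.Generator) -> tuple[str, int, int]:
    """One length-matched interval drawn from inside the common peak set.

    A common peak with length >= length_bp is chosen with probability
    proportional to its number of valid start positions; the start is uniform
    within it.  If no common peak is long enough, the longest common peak is
    returned whole.
    """
    if len(common_set) == 0:
        raise ValueError("empty common set")
    lens = (common_set["end"] - common_set["start"]).to_numpy()
    valid = lens - length_bp + 1
    if (valid <= 0).all():
        i = int(np.argmax(lens))
        row = common_set.iloc[i]
        return str(row["chrom"]), int(row["start"]), int(row["end"])
    w = np.clip(valid, 0, None).astype(float)
    i = int(rng.choice(len(common_set), p=w / w.sum()))
    row = common_set.iloc[i]
    start = int(row["start"]) + int(rng.integers(0, valid[i]))
    return str(row["chrom"]), start, start + length_bp


def _shuffle_matrix(
    lengths: np.ndarray,
    common_gs: np.ndarray,
    common_ge: np.ndarray,
    n_shuffles: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Global-coordinate (start, end) arrays of shape (n_peaks, n_shuffles)."""
    clens = common_ge - common_gs
    n = len(lengths)
    gs = np.empty((n, n_shuffles), dtype=np.int64)
    ge = np.empty((n, n_shuffles), dtype=np.int64)
    for i, L in enumerate(lengths):
        valid = clens - L + 1
        if (valid <= 0).all():
            j = int(np.argmax(clens))
            gs[i] = common_gs[j]
            ge[i] = common_ge[j]
            continue
        w = np.clip(valid, 0, None).astype(float)
        js = rng.choice(len(clens), size=n_shuffles, p=w / w.sum())
        offs = rng.integers(0, valid[js])
        gs[i] = common_gs[js] + offs
        ge[i] = gs[i] + L
    return gs, ge


@dataclass
class EnrichmentResult:
    feature: str
    observed_pct: float
    null_pcts: np.ndarray
    fold_change_vs_common: float
    empirical_p: float
    direction: str                    # enriched / depleted
    significant: bool
    n_shuffles: int

    def summary(self) -> dict:
        return {
            "feature": self.feature,
            "observed_pct": self.observed_pct,
            "null_mean": float(np.mean(self.null_pcts)),
            "null_sd": float(np.std(self.null_pcts)),
            "fold_change_vs_common": self.fold_change_vs_common,
            "empirical_p": self.empirical_p,
            "direction": self.direction,
            "significant": bool(self.significant),
        }


def monte_carlo_enrichment(
    unique_set: pd.DataFrame,
    common_set: pd.DataFrame,
    feature: pd.DataFrame,
    feature_name: str = "feature",
    n_shuffles: int = 500,
    seed: int | np.random.Generator = 0,
    alpha: float = 0.002,
    min_fold_dev: float = 0.20,
    alternative: str = "auto",
) -> EnrichmentResult:
    """Monte Carlo empirical p for feature overlap of a peak set.

    Each null replicate replaces every unique peak with one length-matched
    interval drawn from the common set and records the pooled % length
    overlap.  ``alternative``: 'auto' tests in the direction of the observed
    deviation from the null median; 'enriched'/'depleted' fix the direction.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    if len(unique_set) == 0 or len(common_set) == 0:
        raise ValueError("unique and common sets must be non-empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    coords = _coords_from(unique_set, common_set, feature)
    cov = iv.CoverageIndex(feature, coords)

    u = unique_set.reset_index(drop=True)
    ugs, uge = coords.globalize(u)
    lengths = uge - ugs
    observed = 100.0 * cov.overlap_bp(ugs, uge).sum() / lengths.sum()

    cgs, cge = coords.globalize(common_set.reset_index(drop=True))
    gs, ge = _shuffle_matrix(lengths, cgs, cge, n_shuffles, rng)
    ov = cov.overlap_bp(gs.ravel(), ge.ravel()).reshape(gs.shape)
    null = 100.0 * ov.sum(axis=0) / (ge - gs).sum(axis=0)

    med = float(np.median(null))
    if alternative == "auto":
        direction = "enriched" if observed >= med else "depleted"
    elif alternative in ("enriched", "depleted"):
        direction = alternative
    else:
        raise ValueError("alternative must be auto/enriched/depleted")
    if direction == "enriched":
        k = int((null >= observed).sum())
    else:
        k = int((null <= observed).sum())
    p = (1 + k) / (n_shuffles + 1)

    fold = fold_change_vs_common(u, common_set, feature)
    significant = (p < alpha) and np.isfinite(fold) and (abs(fold - 1.0) > min_fold_dev)
    return EnrichmentResult(feature_name, float(observed), null, float(fold), float(p),
                            direction, significant, n_shuffles)


# ---------------------------------------------------------------------------
# GC skew
# ---------------------------------------------------------------------------

def gc_skew_blocks(
    sequences: dict[str, str],
    window: int = 500,
    step: int = 100,
    min_abs_skew: float = 0.1,
    min_block: int = 300,
    min_consistent_windows: int = 7,
) -> pd.DataFrame:
    """Windowed GC-skew caller: blocks of consistent (G-C)/(G+C) sign.

    A block is a run of at least ``min_consistent_windows`` consecutive
    sliding windows whose skew all passes ``min_abs_skew`` with the same
    sign; blocks shorter than ``min_block`` bp are dropped.  Requiring a
    sustained run keeps calls on skew-free sequence to a few percent of the
    genome while still recovering planted skew blocks essentially whole.
    This is a deliberately simple stand-in for HMM-based skew annotation,
    parameterized as a low-stringency caller.
    """
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    rows = []
    for chrom, seq in sequences.items():
        b = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
        isg = np.concatenate([[0], np.cumsum(b == ord("G"))])
        isc = np.concatenate([[0], np.cumsum(b == ord("C"))])
        starts = np.arange(0, max(len(b) - window + 1, 1), step)
        ends = np.minimum(starts + window, len(b))
        g = isg[ends] - isg[starts]
        c = isc[ends] - isc[starts]
        tot = g + c
        with np.errstate(invalid="ignore", divide="ignore"):
            skew = np.where(tot > 0, (g - c) / np.where(tot > 0, tot, 1), np.nan)
        for sign in (1, -1):
            qual = np.nonzero((tot > 0) & (sign * skew >= min_abs_skew))[0]
            if len(qual) == 0:
                continue
            breaks = np.nonzero(np.diff(qual) > 1)[0]
            seg_starts = np.concatenate([[0], breaks + 1])
            seg_ends = np.concatenate([breaks + 1, [len(qual)]])
            for a, z in zip(seg_starts, seg_ends):
                if z - a < min_consistent_windows:
                    continue
                s = int(starts[qual[a]])
                e = int(ends[qual[z - 1]])
                if e - s >= min_block:
                    rows.append((chrom, s, e, float(np.mean(skew[qual[a:z]])), "+" if sign > 0 else "-"))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "skew", "strand"]).sort_values(
        ["chrom", "start"]).reset_index(drop=True)


def overlap_with_skew(peak_sets_by_category: dict[str, pd.DataFrame], skew_blocks: pd.DataFrame) -> pd.Series:
    """Per category: % of peaks overlapping any skew block by >= 1 bp."""
    out = {}
    coords = _coords_from(skew_blocks, *peak_sets_by_category.values())
    cov = iv.CoverageIndex(skew_blocks, coords)
    for cat, peaks in peak_sets_by_category.items():
        if len(peaks) == 0:
            out[cat] = np.nan
            continue
        gs, ge = coords.globalize(peaks.reset_index(drop=True))
        out[cat] = 100.0 * float((cov.overlap_bp(gs, ge) > 0).mean())
    return pd.Series(out, name="pct_peaks_overlapping_skew")


def domain_occupancy(
    peak_sets_by_category: dict[str, pd.DataFrame],
    segmentation: pd.DataFrame,
    pmd_sublabels: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """% of peaks (by midpoint) falling in HMD vs PMD per category.

    Midpoints use the half-open rule: a midpoint at a domain boundary belongs
    to the right-hand (starting) domain.  ``pmd_sublabels`` (chrom, start,
    end, sublabel) optionally splits PMD hits into e.g. common vs unique PMDs.
    """
    rows = []
    for cat, peaks in peak_sets_by_category.items():
        counts = {"HMD": 0, "PMD": 0, "unassigned": 0}
        sub_counts: dict[str, int] = {}
        for chrom, sub in peaks.groupby("chrom"):
            seg = segmentation[segmentation["chrom"] == chrom]
            mids = ((sub["start"] + sub["end"]) // 2).to_numpy()
            ss = seg["start"].to_numpy()
            se = seg["end"].to_numpy()
            lab = seg["label"].to_numpy()
            j = np.searchsorted(ss, mids, side="right") - 1
            ok = (j >= 0) & (mids < se[np.clip(j, 0, None)])
            for m, jj, good in zip(mids, j, ok):
                if not good:
                    counts["unassigned"] += 1
                    continue
                counts[lab[jj]] = counts.get(lab[jj], 0) + 1
                if lab[jj] == "PMD" and pmd_sublabels is not None:
                    ps = pmd_sublabels[pmd_sublabels["chrom"] == chrom]
                    k = np.searchsorted(ps["start"].to_numpy(), m, side="right") - 1
                    if k >= 0 and m < ps["end"].to_numpy()[k]:
                        sl = ps["sublabel"].to_numpy()[k]
                        sub_counts[sl] = sub_counts.get(sl, 0) + 1
        n = max(sum(v for k, v in counts.items()), 1)
        row = {"category": cat, "n_peaks": n}
        for k in ("HMD", "PMD", "unassigned"):
            row[f"pct_{k}"] = 100.0 * counts.get(k, 0) / n
        for k, v in sub_counts.items():
            row[f"pct_PMD_{k}"] = 100.0 * v / n
        rows.append(row)
    return pd.DataFrame(rows)


def fold_change_vs_genome(
    query: pd.DataFrame,
    mark: pd.DataFrame,
    chrom_lengths: dict[str, int],
    n_shuffles: int = 500,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Overlap fold change relative to the genome average, with an empirical p
    from genome-wide length-matched random placement."""
    mark_bp = iv.total_bp(mark)
    if mark_bp == 0:
        raise EmptyInputError("mark covers 0 bp")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    coords = iv.GenomeCoords(chrom_lengths)
    cov = iv.CoverageIndex(mark, coords)
    qgs, qge = coords.globalize(iv.merge(query))
    qlens = qge - qgs
    q_frac = cov.overlap_bp(qgs, qge).sum() / qlens.sum()
    g_frac = mark_bp / coords.total
    fold = float(q_frac / g_frac)

    # null: place each query interval uniformly on the genome (same chromosome
    # choice probability proportional to the number of valid starts)
    chrom_names = coords.chroms
    clen = np.array([chrom_lengths[c] for c in chrom_names], dtype=np.int64)
    coff = np.array([coords.offsets[c] for c in chrom_names], dtype=np.int64)
    null = np.empty(n_shuffles)
    for s in range(n_shuffles):
        tot_ov = 0
        tot_len = 0
        for L in qlens:
            valid = clen - L + 1
            w = np.clip(valid, 1, None).astype(float)
            j = rng.choice(len(clen), p=w / w.sum())
            start = coff[j] + rng.integers(0, max(valid[j], 1))
            tot_ov += int(cov.overlap_bp(np.array([start]), np.array([start + L]))[0])
            tot_len += L
        null[s] = (tot_ov / tot_len) / g_frac
    if fold >= np.median(null):
        k = int((null >= fold).sum())
        direction = "enriched"
    else:
        k = int((null <= fold).sum())
        direction = "depleted"
    return {"fold_change": fold, "empirical_p": (1 + k) / (n_shuffles + 1),
            "direction": direction, "null_mean": float(null.mean())}


def peak_methylation_by_sample(
    peak_category_sets: dict[str, pd.DataFrame],
    methylome_samples: dict[str, pd.DataFrame],
    control_id: str,
) -> pd.DataFrame:
    """Per-category, per-sample weighted % methylation over peaks, with a
    one-sided paired Wilcoxon (pairs = peaks) for H1: sample < control."""
    rows = []
    ctrl = methylome_samples[control_id]
    for cat, peaks in peak_category_sets.items():
        ctrl_meth = region_methylation(ctrl, peaks, mode="weighted")
        for sid, recs in methylome_samples.items():
            rm = region_methylation(recs, peaks, mode="weighted")
            both = (~rm["pct_methylation"].isna()) & (~ctrl_meth["pct_methylation"].isna())
            row = {
                "category": cat,
                "sample": sid,
                "pct_methylation": float(100.0 * rm["meth_sum"].sum() / max(rm["total_sum"].sum(), 1)),
                "n_peaks_paired": int(both.sum()),
                "n_peaks_dropped": int((~both).sum()),
            }
            if sid != control_id and both.sum() >= 2:
                try:
                    row["p_less_than_control"] = paired_wilcoxon_less(
                        rm.loc[both, "pct_methylation"], ctrl_meth.loc[both, "pct_methylation"])
                except EmptyInputError:
                    row["p_less_than_control"] = np.nan
            else:
                row["p_less_than_control"] = np.nan
            rows.append(row)
    return pd.DataFrame(rows)
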