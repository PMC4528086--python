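"""Two-state HMM segmentation of a methylome into HMDs and PMDs.

The genome is tiled with fixed windows (default 1 kb); each window's
coverage-weighted methylation is the observation.  Emissions are discrete
(K equal bins over [0, 1] plus a missing symbol shared equally by both
states) and are trained from randomly sampled 25-kb regions stratified by
their methylation level: 25-55% regions train the PMD state, 60-100% regions
the HMD state, regions in between are left unlabeled.  Transitions are fixed
from an expected domain length rather than re-estimated; decoding is Viterbi
in log space with ties broken toward HMD, followed by absorption of domains
shorter than a minimum length into the more similar flanking domain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import intervals as iv
from .simulate import substream

MISSING = -1  # observation symbol for windows with no covered CpG


@dataclass
class WindowedMethylome:
    """Per-chromosome fixed-window observation arrays."""

    window_bp: int
    values: dict[str, np.ndarray]     # weighted methylation in [0,1], NaN = missing
    meth: dict[str, np.ndarray]       # per-window summed methylated counts
    total: dict[str, np.ndarray]      # per-window summed total counts
    chrom_lengths: dict[str, int]


def windowize(records: pd.DataFrame, chrom_lengths: dict[str, int], window_bp: int = 1000) -> WindowedMethylome:
    """Tile each chromosome with fixed windows and pool CpG counts per window."""
    if window_bp < 100:
        raise ValueError("window_bp < 100 is too sparse for low-coverage data")
    values, meths, tots = {}, {}, {}
    for chrom, L in chrom_lengths.items():
        n_win = (L + window_bp - 1) // window_bp
        m = np.zeros(n_win, dtype=np.int64)
        t = np.zeros(n_win, dtype=np.int64)
        sub = records[records["chrom"] == chrom]
        if len(sub):
            w = sub["pos0"].to_numpy() // window_bp
            np.add.at(m, w, sub["meth_count"].to_numpy())
            np.add.at(t, w, sub["total_count"].to_numpy())
        with np.errstate(invalid="ignore", divide="ignore"):
            v = np.where(t > 0, m / np.where(t > 0, t, 1), np.nan)
        values[chrom], meths[chrom], tots[chrom] = v, m, t
    return WindowedMethylome(window_bp, values, meths, tots, dict(chrom_lengths))


@dataclass
class TrainingPools:
    """Stratified 25-kb training regions per state, with their window values."""

    regions: dict[str, pd.DataFrame]        # state -> (chrom, start, end, pct)
    window_values: dict[str, np.ndarray]    # state -> pooled window methylation values
    n_drawn: int = 0
    n_discarded: int = 0


class StratumError(RuntimeError):
    """A training stratum could not be filled from the methylome."""


def sample_training_windows(
    wm: WindowedMethylome,
    region_bp: int = 25_000,
    n_regions: int = 1000,
    strata: dict[str, tuple[float, float]] | None = None,
    min_pool: int = 200,
    max_draw_factor: int = 50,
    seed: int = 0,
) -> TrainingPools:
    """Draw random fixed-length regions and stratify them by methylation level.

    Regions are drawn uniformly over the genome (snapped to the window grid);
    a region joins the pool of the stratum containing its weighted methylation
    and is discarded otherwise.  Sampling stops when every pool holds at least
    ``min_pool`` regions, or fails loudly naming the empty stratum after
    ``max_draw_factor * n_regions`` draws.
    """
    strata = strata or {"PMD": (0.25, 0.55), "HMD": (0.60, 1.00)}
    rng = substream(seed, "training")
    win = wm.window_bp
    r_win = max(region_bp // win, 1)
    chroms = [c for c, L in wm.chrom_lengths.items() if L >= region_bp]
    if not chroms:
        raise ValueError("no chromosome long enough for a training region")
    weights = np.array([wm.chrom_lengths[c] - region_bp + 1 for c in chroms], dtype=float)
    weights /= weights.sum()

    pools: dict[str, list] = {s: [] for s in strata}
    win_vals: dict[str, list] = {s: [] for s in strata}
    n_drawn = n_discarded = 0
    max_draws = max_draw_factor * n_regions
    while n_drawn < max_draws and any(len(pools[s]) < min_pool for s in strata):
        n_drawn += 1
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        max_start = (wm.chrom_lengths[chrom] - region_bp) // win
        w0 = int(rng.integers(0, max_start + 1))
        m = wm.meth[chrom][w0:w0 + r_win].sum()
        t = wm.total[chrom][w0:w0 + r_win].sum()
        if t == 0:
            n_discarded += 1
            continue
        frac = m / t
        for state, (lo, hi) in strata.items():
            if lo <= frac <= hi:
                if len(pools[state]) < min_pool:
                    pools[state].append((chrom, w0 * win, w0 * win + region_bp, 100.0 * frac))
                    vals = wm.values[chrom][w0:w0 + r_win]
                    win_vals[state].append(vals[~np.isnan(vals)])
                break
        else:
            n_discarded += 1
    for state in strata:
        if len(pools[state]) < min_pool:
            raise StratumError(
                f"stratum '{state}' could not be filled ({len(pools[state])}/{min_pool} "
                f"regions after {n_drawn} draws)")
    regions = {s: pd.DataFrame(pools[s], columns=["chrom", "start", "end", "pct"]) for s in strata}
    wvals = {s: (np.concatenate(win_vals[s]) if win_vals[s] else np.empty(0)) for s in strata}
    return TrainingPools(regions, wvals, n_drawn, n_discarded)


@dataclass
class EmissionModel:
    state: str
    pmf: np.ndarray          # over K methylation bins, sums to 1
    pseudocount: float

    @property
    def k(self) -> int:
        return len(self.pmf)

    def mean(self) -> float:
        centers = (np.arange(self.k) + 0.5) / self.k
        return float(np.dot(self.pmf, centers))


def discretize(values: np.ndarray, k: int) -> np.ndarray:
    """Map methylation values in [0,1] to bin symbols 0..K-1 (NaN -> MISSING)."""
    sym = np.full(len(values), MISSING, dtype=np.int64)
    ok = ~np.isnan(values)
    if ((values[ok] < 0) | (values[ok] > 1)).any():
        raise ValueError("observations must lie in [0, 1]")
    sym[ok] = np.minimum((values[ok] * k).astype(np.int64), k - 1)
    return sym


def fit_emissions(pools: TrainingPools, k: int = 20, pseudocount: float = 1.0) -> dict[str, EmissionModel]:
    """Smoothed empirical window-methylation pmf per state."""
    if k < 2:
        raise ValueError("K must be >= 2")
    models = {}
    for state, vals in pools.window_values.items():
        if len(vals) == 0:
            raise StratumError(f"no window values for state '{state}'")
        sym = discretize(vals, k)
        counts = np.bincount(sym[sym >= 0], minlength=k).astype(float)
        pmf = (counts + pseudocount) / (counts.sum() + pseudocount * k)
        models[state] = EmissionModel(state, pmf, pseudocount)
    return models


@dataclass
class DomainHMM:
    """Two-state discrete HMM; state order fixed as (HMD, PMD)."""

    emissions: dict[str, EmissionModel]
    window_bp: int = 1000
    expected_domain_bp: int = 100_000
    states: tuple[str, str] = ("HMD", "PMD")
    transition: np.ndarray = field(init=False)
    initial: np.ndarray = field(init=False)

    def __post_init__(self):
        p_self = 1.0 - self.window_bp / self.expected_domain_bp
        if p_self < 0.5:
            raise ValueError("self-transition < 0.5; increase expected_domain_bp")
        self.transition = np.array([[p_self, 1 - p_self], [1 - p_self, p_self]])
        self.initial = np.array([0.5, 0.5])

    def log_emission_matrix(self) -> np.ndarray:
        return np.log(np.vstack([self.emissions[s].pmf for s in self.states]))


def viterbi_path(symbols: np.ndarray, hmm: DomainHMM) -> np.ndarray:
    """Most probable state path (0=HMD, 1=PMD); ties break toward HMD.

    The missing symbol contributes equal (zero) log-likelihood to both states,
    so decoding through gaps is driven by the transition structure alone.
    """
    log_e = hmm.log_emission_matrix()
    log_t = np.log(hmm.transition)
    log_pi = np.log(hmm.initial)
    n = len(symbols)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    delta = np.zeros((n, 2))
    back = np.zeros((n, 2), dtype=np.int64)

    def emis(sym):
        return np.zeros(2) if sym == MISSING else log_e[:, sym]

    delta[0] = log_pi + emis(symbols[0])
    for t in range(1, n):
        cand = delta[t - 1][:, None] + log_t  # cand[i, j]: from i to j
        back[t] = np.argmax(cand, axis=0)
        delta[t] = cand[back[t], np.arange(2)] + emis(symbols[t])
    path = np.zeros(n, dtype=np.int64)
    path[-1] = int(np.argmax(delta[-1]))
    for t in range(n - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path


def viterbi_segment(wm: WindowedMethylome, hmm: DomainHMM) -> pd.DataFrame:
    """Decode every chromosome and merge same-state runs into domains.

    Returns intervals with label, mean methylation (over covered windows;
    missing windows inherit the decoded state but contribute no counts),
    window and count sums.
    """
    k = hmm.emissions[hmm.states[0]].k
    rows = []
    for chrom in wm.chrom_lengths:
        vals = wm.values[chrom]
        sym = discretize(vals, k)
        path = viterbi_path(sym, hmm)
        if len(path) == 0:
            continue
        change = np.nonzero(np.diff(path))[0]
        starts = np.concatenate([[0], change + 1])
        ends = np.concatenate([change + 1, [len(path)]])
        for s, e in zip(starts, ends):
            m = int(wm.meth[chrom][s:e].sum())
            t = int(wm.total[chrom][s:e].sum())
            rows.append((
                chrom, s * wm.window_bp, min(e * wm.window_bp, wm.chrom_lengths[chrom]),
                hmm.states[path[s]], (100.0 * m / t) if t else np.nan, e - s, m, t,
            ))
    return pd.DataFrame(rows, columns=[
        "chrom", "start", "end", "label", "pct_methylation", "n_windows", "meth_sum", "total_sum"])


def postprocess(segmentation: pd.DataFrame, min_domain_bp: int = 10_000) -> pd.DataFrame:
    """Absorb sub-minimum domains into the flanking domain with the closer mean.

    Adjacent same-label domains are merged (count sums recombined) so the
    output strictly alternates labels per chromosome.
    """
    out_frames = []
    for chrom, sub in segmentation.groupby("chrom", sort=True):
        doms = [list(r) for r in sub.sort_values("start")[
            ["start", "end", "label", "n_windows", "meth_sum", "total_sum"]].itertuples(index=False)]

        def merge_adjacent(ds):
            merged = []
            for d in ds:
                if merged and merged[-1][2] == d[2]:
                    prev = merged[-1]
                    prev[1] = d[1]
                    prev[3] += d[3]
                    prev[4] += d[4]
                    prev[5] += d[5]
                else:
                    merged.append(d)
            return merged

        doms = merge_adjacent(doms)
        while True:
            short = [i for i, d in enumerate(doms) if d[1] - d[0] < min_domain_bp]
            if not short or len(doms) == 1:
                break
            # absorb the shortest first for stability
            i = min(short, key=lambda j: doms[j][1] - doms[j][0])
            d = doms[i]
            d_mean = d[4] / d[5] if d[5] else np.nan

            def flank_dist(j):
                f = doms[j]
                f_mean = f[4] / f[5] if f[5] else np.nan
                if np.isnan(d_mean) or np.isnan(f_mean):
                    return 1.0
                return abs(d_mean - f_mean)

            neighbors = [j for j in (i - 1, i + 1) if 0 <= j < len(doms)]
            tgt = min(neighbors, key=flank_dist)
            doms[tgt][3] += d[3]
            doms[tgt][4] += d[4]
            doms[tgt][5] += d[5]
            doms[tgt][0] = min(doms[tgt][0], d[0])
            doms[tgt][1] = max(doms[tgt][1], d[1])
            del doms[i]
            doms = merge_adjacent(doms)
        for d in doms:
            out_frames.append((chrom, d[0], d[1], d[2],
                               (100.0 * d[4] / d[5]) if d[5] else np.nan, d[3], d[4], d[5]))
    return pd.DataFrame(out_frames, columns=[
        "chrom", "start", "end", "label", "pct_methylation", "n_windows", "meth_sum", "total_sum"])


def segment_methylome(
    records: pd.DataFrame,
    chrom_lengths: dict[str, int],
    window_bp: int = 1000,
    region_bp: int = 25_000,
    strata: dict[str, tuple[float, float]] | None = None,
    k: int = 20,
    expected_domain_bp: int = 100_000,
    min_domain_bp: int = 10_000,
    min_pool: int = 200,
    seed: int = 0,
) -> tuple[pd.DataFrame, DomainHMM, TrainingPools]:
    """Full segmentation path: windowize, train by strata, decode, post-process."""
    wm = windowize(records, chrom_lengths, window_bp)
    pools = sample_training_windows(wm, region_bp=region_bp, strata=strata, min_pool=min_pool, seed=seed)
    emis = fit_emissions(pools, k=k)
    hmm = DomainHMM(emis, window_bp=window_bp, expected_domain_bp=expected_domain_bp)
    seg = postprocess(viterbi_segment(wm, hmm), min_domain_bp=min_domain_bp)
    return seg, hmm, pools


def compare_pmds(segmentations: dict[str, pd.DataFrame], label: str = "PMD") -> pd.DataFrame:
    """Pairwise bp-level overlap table (shared bp, unique bp, Jaccard) for a label."""
    sets = {name: seg[seg["label"] == label] for name, seg in segmentations.items()}
    names = list(sets)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            inter = iv.intersect_bp(sets[a], sets[b])
            bp_a, bp_b = iv.total_bp(sets[a]), iv.total_bp(sets[b])
            union = bp_a + bp_b - inter
            rows.append((a, b, bp_a, bp_b, inter, bp_a - inter, bp_b - inter,
                         inter / union if union else np.nan))
    return pd.DataFrame(rows, columns=[
        "set_a", "set_b", "bp_a", "bp_b", "shared_bp", "unique_a_bp", "unique_b_bp", "jaccard"])
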