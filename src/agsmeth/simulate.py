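"""Synthetic genomes, annotations, methylomes, DRIP peak sets and bisulfite clones.

Every generator is deterministic given (config, seed).  A single master seed
feeds named substreams (``genome``, ``methylome``, ``peaks``, ``clones``, ...)
so individual stages can be re-run reproducibly.  Each generator also returns
the ground truth it planted, so downstream estimators can be scored exactly.

The methylome generator emulates low-coverage whole-genome bisulfite data:
megabase-scale blocks of high (HMD-like, ~60-100%) or intermediate (PMD-like,
~25-55%) CpG methylation, per-site levels drawn from a Beta around the block
mean, per-site read depth Poisson at a few-fold coverage, and a small bisulfite
conversion-failure rate that leaves unmethylated cytosines reading as C.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import intervals as iv

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def substream(seed: int, name: str) -> np.random.Generator:
    """Named child RNG derived from the master seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())]))


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

@dataclass
class SyntheticGenome:
    chrom_lengths: dict[str, int]
    sequences: dict[str, str]
    seed: int

    def __post_init__(self):
        for c, L in self.chrom_lengths.items():
            if len(self.sequences[c]) != L:
                raise ValueError(f"{c}: sequence length != declared length")


def make_genome(
    chrom_lengths: dict[str, int],
    gc_fraction: float = 0.42,
    skew_blocks: list[tuple[str, int, int, float]] | None = None,
    seed: int = 0,
) -> SyntheticGenome:
    """i.i.d. random genome with controllable GC content and planted GC-skew blocks.

    Within a skew block (chrom, start, end, skew) the forward strand obeys
    P(G) - P(C) = skew * gc_fraction while P(G) + P(C) stays at gc_fraction.
    """
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must be in [0, 1]")
    skew_blocks = skew_blocks or []
    by_chrom: dict[str, list[tuple[int, int, float]]] = {}
    for chrom, start, end, skew in skew_blocks:
        if not -1.0 <= skew <= 1.0:
            raise ValueError("skew must be in [-1, 1]")
        if chrom not in chrom_lengths or start < 0 or end > chrom_lengths[chrom] or start >= end:
            raise ValueError(f"skew block outside genome bounds: {(chrom, start, end)}")
        by_chrom.setdefault(chrom, []).append((start, end, skew))
    for blocks in by_chrom.values():
        blocks.sort()
        for (s1, e1, _), (s2, _, _) in zip(blocks, blocks[1:]):
            if s2 < e1:
                raise ValueError("overlapping skew blocks")

    rng = substream(seed, "genome")
    at = (1.0 - gc_fraction) / 2.0

    def probs(skew: float) -> np.ndarray:
        return np.array([at, gc_fraction * (1 - skew) / 2, gc_fraction * (1 + skew) / 2, at])

    sequences = {}
    for chrom, L in chrom_lengths.items():
        idx = rng.choice(4, size=L, p=probs(0.0))
        for s, e, skew in by_chrom.get(chrom, []):
            idx[s:e] = rng.choice(4, size=e - s, p=probs(skew))
        sequences[chrom] = _BASES[idx].tobytes().decode()
    return SyntheticGenome(dict(chrom_lengths), sequences, seed)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

_REPEAT_LENGTHS = {"LINE": 1000, "LTR": 600, "SINE": 300, "satellite": 2000}


def make_annotation(
    genome: SyntheticGenome,
    n_genes: int,
    repeat_density_by_class: dict[str, float] | None = None,
    gene_length_range: tuple[int, int] = (2_000, 20_000),
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Random gene models plus repeats placed in the intergenic space.

    Returns a dict of interval frames: ``gene`` (stranded bodies, TSS..TTS),
    ``tss``/``tts`` (1-bp stranded anchors), ``intergenic`` (exact complement
    of gene bodies) and one frame per repeat class.  Repeats are placed by
    Bernoulli occupancy of fixed-length slots tiling the intergenic intervals,
    so the realized density is Binomial around the requested one.
    """
    rng = substream(seed, "annotation")
    repeat_density_by_class = repeat_density_by_class or {}
    genes = []
    for chrom, L in genome.chrom_lengths.items():
        n_c = int(round(n_genes * L / sum(genome.chrom_lengths.values())))
        if n_c == 0:
            continue
        lengths = rng.integers(gene_length_range[0], gene_length_range[1] + 1, size=n_c)
        free = L - int(lengths.sum())
        if free < 0:
            raise ValueError(f"{n_c} genes do not fit on {chrom} ({L} bp)")
        gaps = np.sort(rng.integers(0, free + 1, size=n_c))
        starts = gaps + np.concatenate([[0], np.cumsum(lengths)[:-1]])
        strands = rng.choice(["+", "-"], size=n_c)
        for s, ln, st in zip(starts, lengths, strands):
            genes.append((chrom, int(s), int(s + ln), st))
    gene_df = pd.DataFrame(genes, columns=["chrom", "start", "end", "strand"])
    gene_df = gene_df.sort_values(["chrom", "start"]).reset_index(drop=True)
    gene_df["name"] = [f"gene{i}" for i in range(len(gene_df))]

    plus = gene_df["strand"] == "+"
    tss_pos = np.where(plus, gene_df["start"], gene_df["end"] - 1)
    tts_pos = np.where(plus, gene_df["end"] - 1, gene_df["start"])
    tss = pd.DataFrame({"chrom": gene_df["chrom"], "start": tss_pos, "end": tss_pos + 1, "strand": gene_df["strand"]})
    tts = pd.DataFrame({"chrom": gene_df["chrom"], "start": tts_pos, "end": tts_pos + 1, "strand": gene_df["strand"]})

    intergenic = iv.complement(gene_df, genome.chrom_lengths)
    ann = {"gene": gene_df, "tss": tss, "tts": tts, "intergenic": intergenic}

    for cls, density in repeat_density_by_class.items():
        if not 0.0 <= density <= 1.0:
            raise ValueError("repeat density must be in [0, 1]")
        rep_len = _REPEAT_LENGTHS.get(cls, 500)
        rows = []
        for chrom, s, e in intergenic[["chrom", "start", "end"]].itertuples(index=False):
            n_slots = (e - s) // rep_len
            occupied = np.nonzero(rng.random(n_slots) < density)[0]
            for k in occupied:
                rows.append((chrom, s + k * rep_len, s + (k + 1) * rep_len))
        ann[cls] = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return ann


# ---------------------------------------------------------------------------
# methylome
# ---------------------------------------------------------------------------

@dataclass
class DomainPlan:
    """Planted methylation domains: non-overlapping labeled intervals with a
    mean methylation level each, plus the Beta concentration for site-to-site
    scatter within a domain."""

    intervals: pd.DataFrame  # chrom, start, end, label, mean_level
    dispersion: float = 30.0

    def __post_init__(self):
        df = self.intervals
        need = {"chrom", "start", "end", "label", "mean_level"}
        if not need <= set(df.columns):
            raise ValueError(f"plan needs columns {sorted(need)}")
        if len(df) and not df["mean_level"].between(0, 1).all():
            raise ValueError("mean_level must be in [0, 1]")
        self.intervals = df.sort_values(["chrom", "start"]).reset_index(drop=True)
        for _, sub in self.intervals.groupby("chrom"):
            if (sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]).any():
                raise ValueError("plan intervals overlap")

    def filled(self, genome: SyntheticGenome, label: str = "HMD", mean_level: float = 0.85) -> "DomainPlan":
        """Plan with uncovered genome filled by a background domain."""
        gaps = iv.complement(self.intervals, genome.chrom_lengths)
        gaps["label"] = label
        gaps["mean_level"] = mean_level
        allp = pd.concat([self.intervals, gaps], ignore_index=True)
        return DomainPlan(allp, self.dispersion)


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside simulated data."""

    true_domains: DomainPlan | None = None
    true_site_levels: pd.DataFrame | None = None      # chrom, pos0, p_site, label
    true_peak_labels: pd.DataFrame | None = None      # fragment_id, label
    true_clone_states: np.ndarray | None = None       # clones x sites, boolean


def _cpg_positions(seq_bytes: np.ndarray) -> np.ndarray:
    return np.nonzero((seq_bytes[:-1] == ord("C")) & (seq_bytes[1:] == ord("G")))[0]


def _noncpg_contexts(seq_bytes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Positions and contexts (CHG/CHH) of non-CpG cytosines on both strands.

    Returns (plus_pos, plus_is_chg, minus_pos, minus_is_chg); edge positions
    lacking two downstream bases are skipped.
    """
    b = seq_bytes
    n = len(b)
    C, G = ord("C"), ord("G")
    pos = np.arange(n - 2)
    is_c = b[:-2] == C
    plus = pos[is_c & (b[1:-1] != G)]
    plus_chg = b[plus + 2] == G
    pos_m = np.arange(2, n)
    is_g = b[2:] == G
    minus = pos_m[is_g & (b[1:-1] != C)]
    minus_chg = b[minus - 2] == C
    return plus, plus_chg, minus, minus_chg


def simulate_methylome(
    genome: SyntheticGenome,
    plan: DomainPlan,
    mean_coverage: float = 6.0,
    conversion_failure_rate: float = 0.005,
    seed: int = 0,
    non_cpg_sites: int | None = 20_000,
    stream: str = "methylome",
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Per-cytosine bisulfite call table with planted domain structure.

    Every CpG dyad covered by the plan yields one record per strand (plus
    strand at the C, minus strand at the G).  Per-site methylation probability
    is Beta-distributed around the domain mean (concentration
    ``plan.dispersion``); read depth per dyad is Poisson(mean_coverage) split
    binomially between strands; unmethylated cytosines read as C with
    probability ``conversion_failure_rate``.  Non-CpG cytosines (CHG/CHH) are
    emitted unmethylated except for conversion failures; to bound output size
    at most ``non_cpg_sites`` of them are sampled (None = all).
    """
    if mean_coverage <= 0:
        raise ValueError("mean_coverage must be positive")
    if not 0.0 <= conversion_failure_rate < 1.0:
        raise ValueError("conversion_failure_rate must be in [0, 1)")
    pl = plan.intervals
    for chrom, sub in pl.groupby("chrom"):
        if chrom not in genome.chrom_lengths:
            raise ValueError(f"plan chromosome {chrom} not in genome")
        if sub["start"].min() < 0 or sub["end"].max() > genome.chrom_lengths[chrom]:
            raise ValueError(f"plan interval outside genome on {chrom}")

    rng = substream(seed, stream)
    rec_frames = []
    truth_frames = []
    for chrom in genome.chrom_lengths:
        b = np.frombuffer(genome.sequences[chrom].encode(), dtype=np.uint8)
        cpg = _cpg_positions(b)
        sub = pl[pl["chrom"] == chrom]
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        levels = sub["mean_level"].to_numpy()
        labels = sub["label"].to_numpy()
        idx = np.searchsorted(starts, cpg, side="right") - 1
        inside = (idx >= 0) & (cpg < ends[np.clip(idx, 0, None)])
        cpg = cpg[inside]
        idx = idx[inside]
        if len(cpg) == 0:
            continue
        m = levels[idx]
        if np.isfinite(plan.dispersion):
            a = np.clip(m * plan.dispersion, 1e-9, None)
            bb = np.clip((1 - m) * plan.dispersion, 1e-9, None)
            p_site = np.where((m <= 0) | (m >= 1), m, rng.beta(a, bb))
        else:
            p_site = m.astype(float)

        total = rng.poisson(mean_coverage, size=len(cpg))
        keep = total > 0
        cpg_k, p_k, tot_k, lab_k = cpg[keep], p_site[keep], total[keep], labels[idx[keep]]
        plus_cov = rng.binomial(tot_k, 0.5)
        minus_cov = tot_k - plus_cov
        rows = []
        for strand, pos_off, cov in (("+", 0, plus_cov), ("-", 1, minus_cov)):
            has = cov > 0
            meth_true = rng.binomial(cov[has], p_k[has])
            meth_obs = meth_true + rng.binomial(cov[has] - meth_true, conversion_failure_rate)
            rows.append(pd.DataFrame({
                "chrom": chrom,
                "pos0": cpg_k[has] + pos_off,
                "strand": strand,
                "context": "CG",
                "meth_count": meth_obs,
                "total_count": cov[has],
            }))
        rec_frames.extend(rows)
        truth_frames.append(pd.DataFrame({
            "chrom": chrom, "pos0": cpg, "p_site": p_site, "label": labels[idx],
        }))

        # non-CpG cytosines: unmethylated except conversion failures
        pp, p_chg, mm, m_chg = _noncpg_contexts(b)
        pos_all = np.concatenate([pp, mm])
        strand_all = np.concatenate([np.full(len(pp), "+"), np.full(len(mm), "-")])
        ctx_all = np.concatenate([np.where(p_chg, "CHG", "CHH"), np.where(m_chg, "CHG", "CHH")])
        if non_cpg_sites is not None and len(pos_all) > 0:
            share = max(1, int(round(non_cpg_sites * genome.chrom_lengths[chrom] / sum(genome.chrom_lengths.values()))))
            if share < len(pos_all):
                pick = np.sort(rng.choice(len(pos_all), size=share, replace=False))
                pos_all, strand_all, ctx_all = pos_all[pick], strand_all[pick], ctx_all[pick]
        cov_nc = rng.poisson(mean_coverage, size=len(pos_all))
        has = cov_nc > 0
        meth_nc = rng.binomial(cov_nc[has], conversion_failure_rate)
        rec_frames.append(pd.DataFrame({
            "chrom": chrom,
            "pos0": pos_all[has],
            "strand": strand_all[has],
            "context": ctx_all[has],
            "meth_count": meth_nc,
            "total_count": cov_nc[has],
        }))

    records = pd.concat(rec_frames, ignore_index=True) if rec_frames else pd.DataFrame(
        columns=["chrom", "pos0", "strand", "context", "meth_count", "total_count"])
    records = records.sort_values(["chrom", "pos0", "strand"], kind="stable").reset_index(drop=True)
    truth = SyntheticTruth(
        true_domains=plan,
        true_site_levels=pd.concat(truth_frames, ignore_index=True) if truth_frames else None,
    )
    return records, truth


# ---------------------------------------------------------------------------
# DRIP peak sets
# ---------------------------------------------------------------------------

@dataclass
class PeakSimPlan:
    """Plan for multi-sample peak occupancy on a fragmented genome.

    Fragments labeled ``common`` are peak-positive in the control and in AGS
    samples (each with probability ``p_ags_given_common``, redrawn until at
    least one AGS sample is positive).  Unique fragments are positive only in
    their own sample.  ``feature_bias`` maps a feature interval frame to a
    relative placement weight for unique-peak selection (fragment midpoint
    rule).  Each of the two replicates per sample independently drops a
    positive fragment with probability ``dropout``.
    """

    sample_ids: list[str] = field(default_factory=lambda: ["AGS1", "AGS2", "AGS4", "AGS5"])
    control_id: str = "control"
    p_common: float = 0.2
    p_unique: float = 0.03          # per AGS subtype
    p_control_unique: float = 0.01
    n_common: int | None = None     # counts override probabilities when set
    n_unique: int | None = None
    feature_bias: dict[str, tuple[pd.DataFrame, float]] | None = None
    p_ags_given_common: float = 1.0
    dropout: float = 0.0

    def __post_init__(self):
        for p in (self.p_common, self.p_unique, self.p_control_unique, self.dropout, self.p_ags_given_common):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")


def _midpoint_weights(fragments: pd.DataFrame, feature_bias) -> np.ndarray:
    w = np.ones(len(fragments))
    if not feature_bias:
        return w
    mid = ((fragments["start"] + fragments["end"]) // 2).to_numpy()
    for _name, (feat, weight) in feature_bias.items():
        if weight <= 0:
            raise ValueError("feature weights must be > 0")
        m = iv.merge(feat)
        for chrom, sub in m.groupby("chrom"):
            sel = (fragments["chrom"] == chrom).to_numpy()
            if not sel.any():
                continue
            s = sub["start"].to_numpy()
            e = sub["end"].to_numpy()
            j = np.searchsorted(s, mid[sel], side="right") - 1
            hit = (j >= 0) & (mid[sel] < e[np.clip(j, 0, None)])
            wsel = w[sel]
            wsel[hit] = weight
            w[sel] = wsel
    return w


def simulate_drip_samples(
    fragments: pd.DataFrame,
    plan: PeakSimPlan,
    seed: int = 0,
) -> tuple[dict[str, dict[str, pd.DataFrame]], SyntheticTruth]:
    """Per-sample, per-replicate peak BED frames over a fragment universe.

    Returns ``peaks[sample_id][rep1|rep2]`` (peak intervals = positive
    fragments) and the truth labeling of every fragment.
    """
    if len(fragments) == 0:
        raise ValueError("empty fragment set")
    frag = fragments.reset_index(drop=True).copy()
    if "fragment_id" not in frag.columns:
        frag["fragment_id"] = np.arange(len(frag))
    rng = substream(seed, "peaks")
    n = len(frag)
    labels = np.full(n, "absent", dtype=object)

    n_common = plan.n_common if plan.n_common is not None else rng.binomial(n, plan.p_common)
    common_idx = rng.choice(n, size=min(n_common, n), replace=False)
    labels[common_idx] = "common"

    free = np.nonzero(labels == "absent")[0]
    weights = _midpoint_weights(frag, plan.feature_bias)
    all_samples = [plan.control_id] + list(plan.sample_ids)
    unique_of: dict[str, np.ndarray] = {}
    for sid in plan.sample_ids:
        k = plan.n_unique if plan.n_unique is not None else rng.binomial(n, plan.p_unique)
        k = min(k, len(free))
        if k > 0:
            w = weights[free] / weights[free].sum()
            pick = rng.choice(len(free), size=k, replace=False, p=w)
            chosen = free[pick]
        else:
            chosen = np.empty(0, dtype=int)
        labels[chosen] = f"unique:{sid}"
        unique_of[sid] = chosen
        free = np.setdiff1d(free, chosen, assume_unique=True)
    k = rng.binomial(n, plan.p_control_unique)
    k = min(k, len(free))
    ctrl_unique = rng.choice(free, size=k, replace=False) if k else np.empty(0, dtype=int)
    labels[ctrl_unique] = f"unique:{plan.control_id}"

    # merged-sample presence
    presence = {sid: np.zeros(n, dtype=bool) for sid in all_samples}
    presence[plan.control_id][common_idx] = True
    presence[plan.control_id][ctrl_unique] = True
    is_common = labels == "common"
    for i in np.nonzero(is_common)[0]:
        hits = rng.random(len(plan.sample_ids)) < plan.p_ags_given_common
        while not hits.any():
            hits = rng.random(len(plan.sample_ids)) < max(plan.p_ags_given_common, 1e-9)
        for sid, h in zip(plan.sample_ids, hits):
            presence[sid][i] |= bool(h)
    for sid in plan.sample_ids:
        presence[sid][unique_of[sid]] = True

    peaks: dict[str, dict[str, pd.DataFrame]] = {}
    for sid in all_samples:
        reps = {}
        for rep in ("rep1", "rep2"):
            kept = presence[sid] & (rng.random(n) >= plan.dropout)
            reps[rep] = frag.loc[kept, ["chrom", "start", "end", "fragment_id"]].reset_index(drop=True)
        peaks[sid] = reps

    truth = SyntheticTruth(true_peak_labels=pd.DataFrame({
        "fragment_id": frag["fragment_id"], "label": labels,
        **{f"present_{sid}": presence[sid] for sid in all_samples},
    }))
    return peaks, truth


# ---------------------------------------------------------------------------
# bisulfite clones
# ---------------------------------------------------------------------------

def simulate_clone_set(
    reference_amplicon: str,
    per_site_meth_prob: float | np.ndarray,
    n_clones: int = 16,
    conversion_failure_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[str], SyntheticTruth]:
    """Bisulfite-converted clone sequences from a reference amplicon.

    Each clone is the bisulfite image of the reference: the C of each CpG
    stays C when that site is methylated (probability ``per_site_meth_prob``,
    scalar or per-site array) and reads T otherwise; non-CpG cytosines read T
    except for conversion failures.  Truth is the clones x sites boolean
    methylation state matrix.
    """
    ref = reference_amplicon.upper()
    b = np.frombuffer(ref.encode(), dtype=np.uint8)
    cpg = _cpg_positions(b)
    if len(cpg) == 0:
        raise ValueError("reference amplicon contains no CpG")
    p = np.broadcast_to(np.asarray(per_site_meth_prob, dtype=float), (len(cpg),))
    if (p < 0).any() or (p > 1).any():
        raise ValueError("per_site_meth_prob must be in [0, 1]")
    if not 0.0 <= conversion_failure_rate < 1.0:
        raise ValueError("conversion_failure_rate must be in [0, 1)")
    rng = substream(seed, "clones")
    c_pos = np.nonzero(b == ord("C"))[0]
    noncpg_c = np.setdiff1d(c_pos, cpg, assume_unique=True)

    states = rng.random((n_clones, len(cpg))) < p
    clones = []
    for i in range(n_clones):
        arr = bytearray(ref.encode())
        for pos in noncpg_c:
            if rng.random() >= conversion_failure_rate:
                arr[pos] = ord("T")
        for j, pos in enumerate(cpg):
            if states[i, j]:
                arr[pos] = ord("C")
            elif rng.random() < conversion_failure_rate:
                arr[pos] = ord("C")
            else:
                arr[pos] = ord("T")
        clones.append(arr.decode())
    truth = SyntheticTruth(true_clone_states=states)
    return clones, truth
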