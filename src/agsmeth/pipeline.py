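"""End-to-end synthetic study: simulate, QC, segment, classify, enrich, report.

``run_all`` executes the whole pipeline from a single :class:`RunConfig`:
a synthetic genome and annotation, a control methylome plus AGS-like
hypomethylated methylomes (shared fibroblast PMDs, extra AGS-specific PMDs),
restriction-fragment DRIP peak sets with AGS-unique peaks biased into the
AGS-specific PMDs, then the full downstream analysis.  All stage parameters
default to the study design values (coverage filter 4x / 99.9th percentile,
25-kb stratified training at 25-55% and 60-100%, 500 shuffles, significance
at p < 0.002 with >20% fold deviation).  Everything is deterministic under
the master seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import enrichment as enr
from . import intervals as iv
from . import io as aio
from . import peaks as pk
from . import segmentation as seg
from . import simulate as sim
from .amplicon import CloneMatrix, compare_conditions
from .methylome import MethylomeSample


@dataclass
class RunConfig:
    seed: int = 0
    chrom_lengths: dict[str, int] = field(default_factory=lambda: {"chr1": 5_000_000, "chr2": 3_000_000})
    gc_fraction: float = 0.42
    n_genes: int = 160
    repeat_density: dict[str, float] = field(default_factory=lambda: {"LINE": 0.15, "SINE": 0.05})
    n_skew_blocks: int = 20
    skew_block_bp: int = 3_000
    skew_value: float = 0.35

    ags_samples: list[str] = field(default_factory=lambda: ["AGS4"])
    control_id: str = "control"
    shared_pmd_fraction: float = 0.15
    ags_extra_pmd_fraction: float = 0.15
    pmd_mean: float = 0.40
    hmd_mean: float = 0.85
    n_pmds: int = 12
    dispersion: float = 30.0
    mean_coverage: float = 8.0
    conversion_failure_rate: float = 0.005

    min_cov: int = 4
    upper_pct: float = 99.9
    window_bp: int = 1000
    region_bp: int = 25_000
    strata: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"PMD": (0.25, 0.55), "HMD": (0.60, 1.00)})
    expected_domain_bp: int = 100_000
    min_domain_bp: int = 10_000
    min_pool: int = 200

    enzymes: dict[str, tuple[str, int]] = field(default_factory=lambda: dict(pk.DEFAULT_ENZYMES))
    p_common: float = 0.08
    n_unique: int = 600
    unique_pmd_weight: float = 40.0
    dropout: float = 0.05
    min_overlap_fraction: float = 0.25

    n_shuffles: int = 500
    alpha: float = 0.002
    min_fold_dev: float = 0.20

    n_clones: int = 16
    clone_scramble_prob: float = 0.8
    clone_ko_prob: float = 0.5
    amplicon_n_cpgs: int = 20

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "strata" in data:
            data["strata"] = {k: tuple(v) for k, v in data["strata"].items()}
        if "enzymes" in data:
            data["enzymes"] = {k: (v[0], int(v[1])) for k, v in data["enzymes"].items()}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def validate(self) -> None:
        if not self.chrom_lengths or any(L <= 0 for L in self.chrom_lengths.values()):
            raise ValueError("chrom_lengths must be non-empty with positive lengths")
        if self.shared_pmd_fraction + self.ags_extra_pmd_fraction >= 0.9:
            raise ValueError("planted PMD fractions leave too little HMD background")
        if not self.ags_samples:
            raise ValueError("need at least one AGS sample")


def random_domain_intervals(
    chrom_lengths: dict[str, int],
    fraction: float,
    n_domains: int,
    rng: np.random.Generator,
    exclude: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Place ``n_domains`` equal-length PMD intervals covering ``fraction`` of
    the genome, avoiding ``exclude`` intervals."""
    total = sum(chrom_lengths.values())
    dom_len = max(int(fraction * total / n_domains), 1)
    chroms = list(chrom_lengths)
    w = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    w /= w.sum()
    placed: list[tuple[str, int, int]] = []
    taken = exclude[["chrom", "start", "end"]].copy() if exclude is not None else pd.DataFrame(
        columns=["chrom", "start", "end"])
    attempts = 0
    while len(placed) < n_domains and attempts < 200 * n_domains:
        attempts += 1
        chrom = chroms[rng.choice(len(chroms), p=w)]
        if chrom_lengths[chrom] <= dom_len:
            continue
        start = int(rng.integers(0, chrom_lengths[chrom] - dom_len))
        cand = pd.DataFrame([(chrom, start, start + dom_len)], columns=["chrom", "start", "end"])
        if iv.intersect_bp(cand, taken) > 0:
            continue
        placed.append((chrom, start, start + dom_len))
        taken = pd.concat([taken, cand], ignore_index=True)
    if len(placed) < n_domains:
        raise RuntimeError("could not place all planted domains; lower the fraction")
    return pd.DataFrame(placed, columns=["chrom", "start", "end"])


def _random_amplicon(n_cpgs: int, rng: np.random.Generator) -> str:
    """Random amplicon with exactly n_cpgs CpG sites and scattered non-CpG Cs."""
    parts = []
    for _ in range(n_cpgs):
        spacer = "".join(rng.choice(list("ATG"), size=12)) + "CA" + "".join(rng.choice(list("ATG"), size=6))
        parts.append(spacer + "CG")
    return "".join(parts) + "".join(rng.choice(list("ATG"), size=20))


def run_all(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Execute every stage in dependency order; returns the summary dict.

    When ``outdir`` is given, genome FASTA, BED/TSV tracks, classification
    tables and the JSON summary (with config hash and seed) are written there.
    """
    config.validate()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config_hash": config.digest(), "seed": config.seed}
    master = config.seed

    # --- stage 1: genome + annotation -------------------------------------
    rng_plan = sim.substream(master, "plan")
    skew_blocks = []
    for chrom, L in config.chrom_lengths.items():
        n_c = max(1, int(round(config.n_skew_blocks * L / sum(config.chrom_lengths.values()))))
        starts = np.sort(rng_plan.choice(L - config.skew_block_bp, size=n_c, replace=False))
        keep = np.concatenate([[True], np.diff(starts) > config.skew_block_bp])
        for s in starts[keep]:
            skew_blocks.append((chrom, int(s), int(s) + config.skew_block_bp, config.skew_value))
    genome = sim.make_genome(config.chrom_lengths, config.gc_fraction, skew_blocks, seed=master)
    annotation = sim.make_annotation(genome, config.n_genes, config.repeat_density, seed=master)

    # --- stage 2: domain plans & methylomes -------------------------------
    shared = random_domain_intervals(config.chrom_lengths, config.shared_pmd_fraction,
                                     config.n_pmds, rng_plan)
    extra = random_domain_intervals(config.chrom_lengths, config.ags_extra_pmd_fraction,
                                    config.n_pmds, rng_plan, exclude=shared)
    plans: dict[str, sim.DomainPlan] = {}
    shared_pl = shared.assign(label="PMD", mean_level=config.pmd_mean)
    plans[config.control_id] = sim.DomainPlan(shared_pl, config.dispersion).filled(
        genome, "HMD", config.hmd_mean)
    ags_pl = pd.concat([shared_pl, extra.assign(label="PMD", mean_level=config.pmd_mean)],
                       ignore_index=True)
    for sid in config.ags_samples:
        plans[sid] = sim.DomainPlan(ags_pl, config.dispersion).filled(genome, "HMD", config.hmd_mean)

    samples: dict[str, MethylomeSample] = {}
    for i, (sid, plan) in enumerate(plans.items()):
        calls, _truth = sim.simulate_methylome(
            genome, plan, mean_coverage=config.mean_coverage,
            conversion_failure_rate=config.conversion_failure_rate,
            seed=master, stream=f"methylome:{sid}")
        ms = MethylomeSample.from_calls(sid, calls, min_cov=config.min_cov, upper_pct=config.upper_pct)
        samples[sid] = ms
    summary["methylome_qc"] = {
        sid: {"conversion_rate": ms.conversion_rate,
              "mean_cpg_coverage": ms.mean_cpg_coverage,
              "global_pct_methylation": ms.global_methylation(),
              "n_sites_kept": int(len(ms.records))}
        for sid, ms in samples.items()}

    # --- stage 3: segmentation --------------------------------------------
    segs: dict[str, pd.DataFrame] = {}
    for sid, ms in samples.items():
        s, _hmm, _pools = seg.segment_methylome(
            ms.records, config.chrom_lengths, window_bp=config.window_bp,
            region_bp=config.region_bp, strata=config.strata,
            expected_domain_bp=config.expected_domain_bp,
            min_domain_bp=config.min_domain_bp, min_pool=config.min_pool, seed=master)
        segs[sid] = s
    summary["pmd_bp"] = {
        sid: int(iv.total_bp(s[s["label"] == "PMD"])) for sid, s in segs.items()}
    summary["pmd_overlap"] = seg.compare_pmds(segs).to_dict(orient="records")

    ags0 = config.ags_samples[0]
    ags_pmds = segs[ags0][segs[ags0]["label"] == "PMD"]
    ctrl_pmds = segs[config.control_id][segs[config.control_id]["label"] == "PMD"]
    ags_specific_pmds = iv.complement(
        ctrl_pmds, config.chrom_lengths).pipe(lambda gaps: iv.intersect(ags_pmds, gaps))

    # --- stage 4: digest + DRIP simulation + classification ---------------
    fragset = pk.digest_genome(genome.sequences, config.enzymes)
    bias_intervals = extra if len(extra) else ags_specific_pmds
    plan = sim.PeakSimPlan(
        sample_ids=list(config.ags_samples), control_id=config.control_id,
        p_common=config.p_common, n_unique=config.n_unique,
        feature_bias={"ags_pmd": (bias_intervals, config.unique_pmd_weight)},
        dropout=config.dropout)
    peak_sets, peak_truth = sim.simulate_drip_samples(fragset.fragments, plan, seed=master)
    merged: dict[str, set[int]] = {}
    for sid, reps in peak_sets.items():
        r1 = pk.assign_peaks_to_fragments(reps["rep1"], fragset, config.min_overlap_fraction) \
            if len(reps["rep1"]) else set()
        r2 = pk.assign_peaks_to_fragments(reps["rep2"], fragset, config.min_overlap_fraction) \
            if len(reps["rep2"]) else set()
        merged[sid] = pk.merge_replicates(r1, r2)
    matrix = pk.build_presence_matrix(merged, fragset)
    classification = pk.classify(matrix, config.control_id, fragset)
    summary["peak_categories"] = {"counts": classification.counts, "bp": classification.bp}
    cat_frames = classification.category_frames(fragset)
    common = cat_frames.get("common", pd.DataFrame(columns=iv.BED_COLS))
    unique_all = cat_frames.get("ags_unique_all", pd.DataFrame(columns=iv.BED_COLS))

    # --- stage 5: enrichment, skew, occupancy, peak methylation -----------
    features = {"intergenic": annotation["intergenic"], "gene": annotation["gene"]}
    for cls_name in config.repeat_density:
        features[cls_name] = annotation[cls_name]
    enrich_rows = []
    if len(unique_all) and len(common):
        for name, feat in features.items():
            res = enr.monte_carlo_enrichment(
                unique_all, common, feat, feature_name=name,
                n_shuffles=config.n_shuffles,
                seed=sim.substream(master, f"mc:{name}"),
                alpha=config.alpha, min_fold_dev=config.min_fold_dev)
            enrich_rows.append(res.summary())
    summary["enrichment"] = enrich_rows

    skew = enr.gc_skew_blocks(genome.sequences)
    occupancy_sets = {"common": common, "ags_unique": unique_all}
    summary["skew_overlap"] = enr.overlap_with_skew(occupancy_sets, skew).to_dict()
    pmd_sub = pd.concat([
        iv.intersect(ags_pmds, ctrl_pmds).assign(sublabel="common"),
        ags_specific_pmds.assign(sublabel="unique"),
    ], ignore_index=True).sort_values(["chrom", "start"]).reset_index(drop=True)
    occ = enr.domain_occupancy(occupancy_sets, segs[ags0], pmd_sublabels=pmd_sub)
    summary["domain_occupancy"] = occ.to_dict(orient="records")

    meth_frames = {sid: ms.records for sid, ms in samples.items()}
    pm = enr.peak_methylation_by_sample(occupancy_sets, meth_frames, config.control_id)
    summary["peak_methylation"] = pm.to_dict(orient="records")

    # --- stage 6: clone comparison ----------------------------------------
    rng_amp = sim.substream(master, "amplicon")
    ref = _random_amplicon(config.amplicon_n_cpgs, rng_amp)
    scr_clones, _ = sim.simulate_clone_set(ref, config.clone_scramble_prob, config.n_clones,
                                           config.conversion_failure_rate, seed=master + 1)
    ko_clones, _ = sim.simulate_clone_set(ref, config.clone_ko_prob, config.n_clones,
                                          config.conversion_failure_rate, seed=master + 2)
    m_scr = CloneMatrix.from_clones("L1", ref, scr_clones)
    m_ko = CloneMatrix.from_clones("L1", ref, ko_clones)
    summary["clone_comparison"] = compare_conditions(m_ko, m_scr)

    # --- outputs ------------------------------------------------------------
    if out is not None:
        aio.write_fasta(genome.sequences, out / "genome.fa")
        for name, feat in annotation.items():
            aio.write_bed(feat, out / f"{name}.bed")
        for sid, ms in samples.items():
            aio.write_cytosine_tsv(ms.records, out / f"{sid}.cpg.tsv")
            track = segs[sid].copy()
            track["name"] = track["label"]
            track["score"] = (track["pct_methylation"].fillna(0) * 10).round().astype(int)
            aio.write_bed(track, out / f"{sid}.domains.bed", ["chrom", "start", "end", "name", "score"])
        fragset.fragments.to_csv(out / "fragments.bed", sep="\t", header=False, index=False)
        matrix.astype(int).to_csv(out / "presence_matrix.tsv", sep="\t")
        classification.labels.to_csv(out / "classification.tsv", sep="\t")
        pm.to_csv(out / "peak_methylation.tsv", sep="\t", index=False)
        if enrich_rows:
            pd.DataFrame(enrich_rows).to_csv(out / "enrichment.tsv", sep="\t", index=False)
        aio.write_bed(skew, out / "skew_blocks.bed", ["chrom", "start", "end", "skew", "strand"])
        m_ko.to_tsv(out / "clones_ko.tsv")
        m_scr.to_tsv(out / "clones_scramble.tsv")
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=float)
    return summary
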