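import numpy as np
import pandas as pd
import pytest

from agsmeth import simulate as sim


@pytest.fixture(scope="session")
def toy_genome():
    """Small two-chromosome genome reused across read-only tests."""
    return sim.make_genome({"chrA": 120_000, "chrB": 80_000}, gc_fraction=0.42, seed=11)


@pytest.fixture(scope="session")
def half_and_half():
    """Genome with the left half PMD-like (40%) and the right half HMD-like (85%)."""
    genome = sim.make_genome({"chr1": 400_000}, gc_fraction=0.42, seed=21)
    plan = sim.DomainPlan(pd.DataFrame(
        [("chr1", 0, 200_000, "PMD", 0.40), ("chr1", 200_000, 400_000, "HMD", 0.85)],
        columns=["chrom", "start", "end", "label", "mean_level"]))
    records, truth = sim.simulate_methylome(genome, plan, mean_coverage=10, seed=22)
    return genome, plan, records, truth


def random_intervals(rng: np.random.Generator, n: int, genome_bp: int, max_len: int, chrom: str = "chr1"):
    starts = rng.integers(0, genome_bp - max_len, size=n)
    lens = rng.integers(1, max_len, size=n)
    return pd.DataFrame({"chrom": chrom, "start": starts, "end": starts + lens}).sort_values(
        ["start"]).reset_index(drop=True)


def bitmap(df: pd.DataFrame, genome_bp: int, chrom: str = "chr1") -> np.ndarray:
    """Per-bp boolean oracle for interval arithmetic on a single toy chromosome."""
    b = np.zeros(genome_bp, dtype=bool)
    for _, r in df[df["chrom"] == chrom].iterrows():
        b[int(r["start"]):int(r["end"])] = True
    return b
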