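"""Bisulfite amplicon clone analysis (LINE-1-style locus sequencing).

Each sequenced clone is aligned globally to the amplicon reference with a
bisulfite-aware scoring scheme (reference C matching clone T is not
penalized), the clone base at every reference CpG is read as
methylated (C) / unmethylated (T) / missing (gap or other base), and per-site
percent methylation is the ratio of unconverted (CG) over unconverted plus
converted (TG) molecules.  The clone's non-CpG cytosines give its private
conversion rate; poorly converted clones are excluded by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .methylome import EmptyInputError, paired_wilcoxon_less


def locate_cpgs(reference_seq: str) -> list[int]:
    """0-based positions p with reference[p:p+2] == 'CG'."""
    ref = reference_seq.upper()
    return [i for i in range(len(ref) - 1) if ref[i] == "C" and ref[i + 1] == "G"]


def _bisulfite_aligner() -> Align.PairwiseAligner:
    alphabet = "ACGT"
    m = substitution_matrices.Array(alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            m[a, b] = 2.0 if a == b else -2.0
    m["C", "T"] = 2.0  # bisulfite conversion: ref C read as T is expected
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = m
    aligner.open_gap_score = -6.0
    aligner.extend_gap_score = -1.0
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    return aligner


class CloneRejected(ValueError):
    """Clone alignment failed the identity/length floor."""


def call_clone(
    reference: str,
    clone_seq: str,
    min_aligned_fraction: float = 0.9,
    min_identity: float = 0.8,
) -> tuple[dict[int, str], float]:
    """Per-CpG-site calls for one clone plus its non-CpG conversion rate.

    Returns ({cpg_position: 'M'|'U'|'.'}, conversion_rate).  Identity is
    evaluated outside reference C positions (where bisulfite conversion makes
    mismatches uninformative).
    """
    ref = reference.upper()
    clone = clone_seq.upper()
    cpgs = locate_cpgs(ref)
    aligner = _bisulfite_aligner()
    aln = aligner.align(ref, clone)[0]
    ref_to_clone: dict[int, str] = {}
    aligned_ref = 0
    for (rs, re_), (qs, _qe) in zip(*aln.aligned):
        for k in range(re_ - rs):
            ref_to_clone[rs + k] = clone[qs + k]
        aligned_ref += re_ - rs
    if aligned_ref < min_aligned_fraction * len(ref):
        raise CloneRejected(f"aligned {aligned_ref}/{len(ref)} reference bases")

    non_c = [i for i in range(len(ref)) if ref[i] != "C"]
    comparable = [i for i in non_c if i in ref_to_clone]
    if comparable:
        ident = np.mean([ref_to_clone[i] == ref[i] for i in comparable])
        if ident < min_identity:
            raise CloneRejected(f"identity {ident:.2f} below floor outside C positions")

    calls = {}
    for p in cpgs:
        base = ref_to_clone.get(p)
        calls[p] = {"C": "M", "T": "U"}.get(base, ".")

    noncpg_c = [i for i in range(len(ref)) if ref[i] == "C" and i not in set(cpgs)]
    conv = tot = 0
    for i in noncpg_c:
        base = ref_to_clone.get(i)
        if base == "T":
            conv += 1
            tot += 1
        elif base == "C":
            tot += 1
    conversion_rate = conv / tot if tot else float("nan")
    return calls, conversion_rate


@dataclass
class CloneMatrix:
    """Clones x CpG-sites methylation call matrix for one amplicon."""

    amplicon_id: str
    cpg_positions: list[int]
    calls: pd.DataFrame                      # rows clones, cols positions, 'M'/'U'/'.'
    conversion_rates: pd.Series
    rejected: list[str] = field(default_factory=list)

    @classmethod
    def from_clones(
        cls,
        amplicon_id: str,
        reference: str,
        clone_seqs: dict[str, str] | list[str],
        min_conversion: float = 0.95,
    ) -> "CloneMatrix":
        """Align and call every clone; exclude poorly converted or unalignable ones."""
        if not isinstance(clone_seqs, dict):
            clone_seqs = {f"clone{i + 1}": s for i, s in enumerate(clone_seqs)}
        cpgs = locate_cpgs(reference)
        if not cpgs:
            raise ValueError("reference contains no CpG site")
        rows, convs, rejected = {}, {}, []
        for name, seq in clone_seqs.items():
            try:
                calls, conv = call_clone(reference, seq)
            except CloneRejected:
                rejected.append(name)
                continue
            if not np.isnan(conv) and conv < min_conversion:
                rejected.append(name)
                continue
            rows[name] = [calls[p] for p in cpgs]
            convs[name] = conv
        mat = pd.DataFrame.from_dict(rows, orient="index", columns=cpgs)
        mat.index.name = "clone"
        return cls(amplicon_id, cpgs, mat, pd.Series(convs, name="conversion_rate"), rejected)

    def to_tsv(self, path) -> None:
        out = self.calls.copy()
        out.insert(0, "conversion_rate", self.conversion_rates.round(6))
        out.index.name = "clone"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, amplicon_id: str = "amplicon") -> "CloneMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        conv = df.pop("conversion_rate")
        df.columns = [int(c) for c in df.columns]
        return cls(amplicon_id, list(df.columns), df, conv)


def site_percent_methylation(matrix: CloneMatrix) -> pd.DataFrame:
    """Per-site % methylation: 100 * M / (M + U); missing calls excluded.

    Sites with no informative call get NaN.  Also reports per-site call counts.
    """
    rows = []
    for p in matrix.cpg_positions:
        col = matrix.calls[p]
        m = int((col == "M").sum())
        u = int((col == "U").sum())
        pct = 100.0 * m / (m + u) if (m + u) else np.nan
        rows.append((p, m, u, int((col == ".").sum()), pct))
    return pd.DataFrame(rows, columns=["cpg_pos", "n_meth", "n_unmeth", "n_missing", "pct_methylation"])


def compare_conditions(matrix_a: CloneMatrix, matrix_b: CloneMatrix) -> dict:
    """One-sided paired Wilcoxon over per-site % methylation: H1 a < b.

    Sites are paired by reference CpG position; sites missing (no informative
    call) in either condition are dropped and counted.
    """
    pa = site_percent_methylation(matrix_a).set_index("cpg_pos")["pct_methylation"]
    pb = site_percent_methylation(matrix_b).set_index("cpg_pos")["pct_methylation"]
    shared = sorted(set(pa.index) & set(pb.index))
    va = pa.reindex(shared)
    vb = pb.reindex(shared)
    ok = (~va.isna()) & (~vb.isna())
    dropped = int((~ok).sum())
    va, vb = va[ok], vb[ok]
    if len(va) < 2:
        raise EmptyInputError("fewer than 2 shared informative CpG sites")
    p = paired_wilcoxon_less(va.to_numpy(), vb.to_numpy())
    return {"p_value": p, "n_sites": int(len(va)), "n_sites_dropped": dropped,
            "mean_pct_a": float(va.mean()), "mean_pct_b": float(vb.mean())}
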