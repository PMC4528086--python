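"""Restriction-fragment peak universe and common/unique peak classification.

DRIP resolution is set by the restriction digest, not by sonication: called
peaks are projected onto the fragments of an in-silico digest, replicates are
merged by union at the fragment level, and fragments are classified as common
(control and at least one AGS sample), control-unique, AGS-unique per subtype,
or absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Default DRIP digest cocktail: recognition sequence and cut offset within it.
DEFAULT_ENZYMES: dict[str, tuple[str, int]] = {
    "HindIII": ("AAGCTT", 1),
    "EcoRI": ("GAATTC", 1),
    "BsrGI": ("TGTACA", 1),
    "XbaI": ("TCTAGA", 1),
    "SspI": ("AATATT", 3),
}

_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


@dataclass
class FragmentSet:
    fragments: pd.DataFrame  # chrom, start, end, fragment_id
    enzymes: dict[str, tuple[str, int]]
    chrom_lengths: dict[str, int] = field(default_factory=dict)


def _find_all(seq: str, motif: str) -> list[int]:
    out, i = [], seq.find(motif)
    while i != -1:
        out.append(i)
        i = seq.find(motif, i + 1)
    return out


def digest_genome(
    sequences: dict[str, str],
    enzymes: dict[str, tuple[str, int]] | None = None,
) -> FragmentSet:
    """In-silico digest: fragments between consecutive cut positions.

    Both strands are scanned; palindromic recognition sites are counted once,
    non-palindromic sites on the minus strand cut at the mirrored offset.
    """
    enzymes = enzymes or DEFAULT_ENZYMES
    for name, (site, off) in enzymes.items():
        if len(site) < 4:
            raise ValueError(f"{name}: recognition sequence shorter than 4")
        if set(site) - set("ACGT"):
            raise ValueError(f"{name}: ambiguous IUPAC codes not supported")
        if not 0 <= off <= len(site):
            raise ValueError(f"{name}: cut offset outside recognition site")
    rows = []
    fid = 0
    for chrom, seq in sequences.items():
        seq = seq.upper()
        cuts: set[int] = set()
        for site, off in enzymes.values():
            for i in _find_all(seq, site):
                cuts.add(i + off)
            rc = _revcomp(site)
            if rc != site:
                for i in _find_all(seq, rc):
                    cuts.add(i + len(site) - off)
        bounds = [0] + sorted(c for c in cuts if 0 < c < len(seq)) + [len(seq)]
        for s, e in zip(bounds[:-1], bounds[1:]):
            rows.append((chrom, s, e, fid))
            fid += 1
    frags = pd.DataFrame(rows, columns=["chrom", "start", "end", "fragment_id"])
    return FragmentSet(frags, dict(enzymes), {c: len(s) for c, s in sequences.items()})


def assign_peaks_to_fragments(
    peaks: pd.DataFrame,
    fragments: FragmentSet | pd.DataFrame,
    min_overlap_fraction: float = 0.25,
) -> set[int]:
    """Fragments overlapped by peaks: positive when overlap_bp / min(fragment,
    peak length) >= min_overlap_fraction for at least one peak."""
    frag = fragments.fragments if isinstance(fragments, FragmentSet) else fragments
    if len(peaks) == 0:
        return set()
    lengths = (fragments.chrom_lengths if isinstance(fragments, FragmentSet) else {})
    positive: set[int] = set()
    for chrom, sub_p in peaks.groupby("chrom"):
        sub_f = frag[frag["chrom"] == chrom]
        if len(sub_f) == 0:
            raise ValueError(f"peaks on unknown chromosome {chrom}")
        if lengths and (sub_p["end"].max() > lengths[chrom] or sub_p["start"].min() < 0):
            raise ValueError(f"peak outside genome bounds on {chrom}")
        fs = sub_f["start"].to_numpy()
        fe = sub_f["end"].to_numpy()
        fids = sub_f["fragment_id"].to_numpy()
        for ps, pe in sub_p[["start", "end"]].itertuples(index=False):
            lo = np.searchsorted(fe, ps, side="right")
            hi = np.searchsorted(fs, pe, side="left")
            for j in range(lo, hi):
                ov = min(pe, fe[j]) - max(ps, fs[j])
                denom = min(fe[j] - fs[j], pe - ps)
                if denom > 0 and ov / denom >= min_overlap_fraction:
                    positive.add(int(fids[j]))
    return positive


def merge_replicates(rep1: set[int], rep2: set[int], universe: set[int] | None = None) -> set[int]:
    """Union of replicate fragment sets (peak in either replicate counts)."""
    if universe is not None and not (rep1 <= universe and rep2 <= universe):
        raise ValueError("replicate fragments outside the fragment universe")
    return rep1 | rep2


def build_presence_matrix(sample_sets: dict[str, set[int]], fragments: FragmentSet) -> pd.DataFrame:
    """fragments x samples boolean occupancy matrix."""
    idx = fragments.fragments["fragment_id"].to_numpy()
    data = {sid: np.isin(idx, sorted(s)) for sid, s in sample_sets.items()}
    return pd.DataFrame(data, index=pd.Index(idx, name="fragment_id"))


@dataclass
class PeakClassification:
    labels: pd.Series                 # fragment_id -> category label
    counts: dict[str, int]
    bp: dict[str, int]
    control_id: str
    ags_samples: list[str]

    def category_frames(self, fragments: FragmentSet) -> dict[str, pd.DataFrame]:
        """Interval frame per category (ags_unique pooled and per subtype)."""
        frag = fragments.fragments.set_index("fragment_id")
        out = {}
        for cat in sorted(self.labels.unique()):
            ids = self.labels.index[self.labels == cat]
            out[cat] = frag.loc[ids, ["chrom", "start", "end"]].reset_index()
        ags = self.labels.index[self.labels.str.startswith("ags_unique")]
        out["ags_unique_all"] = frag.loc[ags, ["chrom", "start", "end"]].reset_index()
        return out


def classify(matrix: pd.DataFrame, control_id: str, fragments: FragmentSet) -> PeakClassification:
    """Common / control-unique / AGS-unique / absent classification.

    common: positive in control AND >= 1 AGS sample.  control_unique: positive
    in control only.  ags_unique:X: positive in X and negative in control (a
    fragment positive in several AGS subtypes but not control is labeled with
    all of them, and counted once in the pooled AGS-specific union).
    """
    if control_id not in matrix.columns:
        raise ValueError(f"unknown control sample '{control_id}'")
    ags = [c for c in matrix.columns if c != control_id]
    if not ags:
        raise ValueError("need at least one AGS sample")
    ctrl = matrix[control_id].to_numpy()
    any_ags = matrix[ags].to_numpy().any(axis=1)
    labels = np.full(len(matrix), "absent", dtype=object)
    labels[ctrl & any_ags] = "common"
    labels[ctrl & ~any_ags] = "control_unique"
    uniq = ~ctrl & any_ags
    for i in np.nonzero(uniq)[0]:
        subs = [s for s in ags if matrix[s].iloc[i]]
        labels[i] = "ags_unique:" + "+".join(subs)
    ser = pd.Series(labels, index=matrix.index, name="category")

    frag = fragments.fragments.set_index("fragment_id")
    flen = (frag["end"] - frag["start"]).reindex(ser.index)
    counts: dict[str, int] = {}
    bp: dict[str, int] = {}
    for cat in ("common", "control_unique", "absent"):
        sel = ser == cat
        counts[cat] = int(sel.sum())
        bp[cat] = int(flen[sel].sum())
    for sid in ags:
        sel = ser.str.startswith("ags_unique") & ser.str.contains(sid, regex=False)
        counts[f"ags_unique:{sid}"] = int(sel.sum())
        bp[f"ags_unique:{sid}"] = int(flen[sel].sum())
    sel = ser.str.startswith("ags_unique")
    counts["ags_unique_all"] = int(sel.sum())
    bp["ags_unique_all"] = int(flen[sel].sum())
    return PeakClassification(ser, counts, bp, control_id, ags)
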