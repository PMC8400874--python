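"""HBD segment records and group-level summary tables.

A Viterbi state path is decomposed into maximal runs of a constant HBD class;
each run becomes one segment bounded by its first and last marker (1-based
inclusive bp). Runs never span chromosome boundaries and adjacent runs of
different HBD classes stay distinct segments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MarkerMap
from .model import HBDModel


@dataclass
class HBDSegment:
    sample_id: str
    group: str
    chrom: object
    class_rate: float
    start_bp: int
    end_bp: int
    n_snps: int
    length_mb: float
    length_morgans: float

    def __post_init__(self):
        if self.end_bp < self.start_bp:
            raise ValueError("end_bp < start_bp")
        if self.n_snps < 1:
            raise ValueError("segment must contain at least one marker")


def path_to_segments(path: np.ndarray, mmap: MarkerMap, model: HBDModel,
                     sample_id: str, group: str = "NA") -> list[HBDSegment]:
    """Run-length decompose a per-marker state path into HBD segments."""
    path = np.asarray(path)
    if len(path) != mmap.n_markers:
        raise ValueError("path length does not match marker count")
    non_hbd = model.non_hbd_state
    out = []
    for chrom, sl in mmap.chrom_slices():
        sub = path[sl]
        start = 0
        for i in range(1, len(sub) + 1):
            if i == len(sub) or sub[i] != sub[start]:
                state = int(sub[start])
                if state != non_hbd:
                    lo, hi = sl.start + start, sl.start + i - 1
                    out.append(HBDSegment(
                        sample_id=sample_id, group=group, chrom=chrom,
                        class_rate=float(model.rates[state]),
                        start_bp=int(mmap.bp[lo]), end_bp=int(mmap.bp[hi]),
                        n_snps=i - start,
                        length_mb=(mmap.bp[hi] - mmap.bp[lo]) / 1e6,
                        length_morgans=float(mmap.gpos[hi] - mmap.gpos[lo])))
                start = i
    return out


def segments_to_frame(segments: list[HBDSegment]) -> pd.DataFrame:
    cols = ["sample_id", "group", "chrom", "class_rate", "start_bp", "end_bp",
            "n_snps", "length_mb", "length_morgans"]
    if not segments:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([vars(s) for s in segments])[cols]


@dataclass
class SegmentSummary:
    """Per group x class counts and mean segment length, plus group totals."""

    per_class: pd.DataFrame   # group, class_rate, count, mean_length_mb, se_length_mb
    per_group: pd.DataFrame   # group, n_animals, total, per_animal, mean length/snps


def summarize(segments: list[HBDSegment], sample_groups: dict) -> SegmentSummary:
    """Group-level segment summaries.

    ``sample_groups`` maps every sample id to its group label; per-animal
    means use all animals of the group, including those with zero segments.
    SE is the sample standard deviation over sqrt(count).
    """
    if not sample_groups:
        raise ValueError("sample_groups must not be empty")
    for seg in segments:
        if seg.sample_id not in sample_groups:
            raise ValueError(f"segment sample {seg.sample_id!r} has no group label")
    df = segments_to_frame(segments)
    groups = sorted(set(sample_groups.values()))
    n_animals = {g: sum(1 for v in sample_groups.values() if v == g) for g in groups}

    pc_rows, pg_rows = [], []
    for g in groups:
        sub = df[df["group"] == g] if len(df) else df
        for rate in (sorted(sub["class_rate"].unique()) if len(sub) else []):
            lens = sub.loc[sub["class_rate"] == rate, "length_mb"].to_numpy()
            se = float(np.std(lens, ddof=1) / np.sqrt(len(lens))) if len(lens) > 1 else np.nan
            pc_rows.append({"group": g, "class_rate": rate, "count": len(lens),
                            "mean_length_mb": float(lens.mean()),
                            "se_length_mb": se})
        total = int(len(sub))
        pg_rows.append({
            "group": g, "n_animals": n_animals[g], "total_segments": total,
            "segments_per_animal": total / n_animals[g],
            "mean_length_mb": float(sub["length_mb"].mean()) if total else np.nan,
            "mean_n_snps": float(sub["n_snps"].mean()) if total else np.nan})
    return SegmentSummary(pd.DataFrame(pc_rows, columns=["group", "class_rate",
                                                         "count", "mean_length_mb",
                                                         "se_length_mb"]),
                          pd.DataFrame(pg_rows))


def longest_segments(segments: list[HBDSegment], classes, top_n: int
                     ) -> tuple[list[HBDSegment], pd.DataFrame]:
    """Top segments of the given classes plus a chromosome x group count table.

    Sorted by length_mb descending, ties by (chrom, start_bp).
    """
    classes = set(float(c) for c in classes)
    if not classes:
        raise ValueError("classes must be non-empty")
    sel = [s for s in segments if s.class_rate in classes]
    ranked = sorted(sel, key=lambda s: (-s.length_mb, str(s.chrom), s.start_bp))
    counts = pd.DataFrame([(s.chrom, s.group) for s in sel],
                          columns=["chrom", "group"])
    table = (counts.value_counts().rename("count").reset_index()
             .sort_values(["chrom", "group"]).reset_index(drop=True)
             if len(counts) else pd.DataFrame(columns=["chrom", "group", "count"]))
    return ranked[:top_n], table


def inbreeding_table(F_values: dict, sample_groups: dict) -> pd.DataFrame:
    """Five-number summary plus mean of per-sample F, per group.

    Quartiles use linear interpolation (the type-7 convention).
    """
    groups = sorted(set(sample_groups.values()))
    rows = []
    for g in groups:
        vals = np.array([F_values[s] for s, grp in sample_groups.items()
                         if grp == g and s in F_values])
        if len(vals) == 0:
            raise ValueError(f"group {g!r} has no samples with F values")
        q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75])
        rows.append({"group": g, "n": len(vals), "min": vals.min(), "q1": q1,
                     "median": med, "mean": vals.mean(), "q3": q3,
                     "max": vals.max()})
    return pd.DataFrame(rows)


def write_segments_tsv(segments: list[HBDSegment], path: str):
    segments_to_frame(segments).to_csv(path, sep="\t", index=False,
                                       float_format="%.6g")


def write_segments_bed(segments: list[HBDSegment], path: str):
    """Segments as 0-based half-open BED for genome-browser use."""
    with open(path, "w") as fh:
        for s in segments:
            fh.write(f"{s.chrom}\t{s.start_bp - 1}\t{s.end_bp}\t"
                     f"{s.sample_id}:R_{s.class_rate:g}\n")
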