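"""Overlap of decoded HBD segments with genomic feature intervals (QTL/genes).

Features are 0-based half-open (BED convention); segments carry 1-based
inclusive marker bounds and are converted to half-open as
``(start_bp - 1, end_bp)`` before intersection. Any non-empty intersection
counts as an overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

from .segments import HBDSegment


@dataclass
class FeatureSet:
    """Named, categorised intervals in 0-based half-open coordinates."""

    intervals: pd.DataFrame  # chrom, start, end, name, category

    def __post_init__(self):
        df = self.intervals
        required = ["chrom", "start", "end", "name", "category"]
        if list(df.columns[:5]) != required:
            df = df.rename(columns=dict(zip(df.columns[:5], required)))
        if (df["end"] <= df["start"]).any():
            bad = df[df["end"] <= df["start"]].iloc[0]
            raise ValueError(f"feature {bad['name']!r}: end must exceed start")
        self.intervals = df.reset_index(drop=True)


def read_features_bed(path: str) -> FeatureSet:
    """BED with 3 required + up to 2 optional columns (name, category)."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) == 1:  # tolerate space-separated minimal BED
                parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}: line {ln}: expected >=3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as e:
                raise ValueError(f"{path}: line {ln}: non-integer coordinate") from e
            name = parts[3] if len(parts) > 3 else f"feature_{ln}"
            category = parts[4] if len(parts) > 4 else "NA"
            rows.append((parts[0], start, end, name, category))
    return FeatureSet(pd.DataFrame(rows, columns=["chrom", "start", "end",
                                                  "name", "category"]))


@dataclass
class OverlapResult:
    per_segment: list[list[int]]       # feature row indices per input segment
    per_category: pd.DataFrame         # category, n_features, n_hits
    per_chrom: pd.DataFrame            # chrom, n_features
    n_features_overlapped: int         # unique features hit by any segment


def overlap(segments: list[HBDSegment], features: FeatureSet) -> OverlapResult:
    """Intersect segments with features.

    Per-segment listings repeat a feature for every segment it touches;
    the unique-feature total and the per-category / per-chromosome counts
    count each feature once.
    """
    trees: dict = {}
    for idx, row in features.intervals.iterrows():
        trees.setdefault(row["chrom"], IntervalTree()).addi(
            row["start"], row["end"], idx)

    per_segment = []
    hit: set[int] = set()
    for seg in segments:
        tree = trees.get(seg.chrom)
        if tree is None:
            per_segment.append([])
            continue
        ids = sorted(iv.data for iv in tree.overlap(seg.start_bp - 1, seg.end_bp))
        per_segment.append(ids)
        hit.update(ids)

    fi = features.intervals
    hit_mask = fi.index.isin(hit)
    per_category = (fi.assign(hit=hit_mask).groupby("category")
                    .agg(n_features=("name", "size"), n_hits=("hit", "sum"))
                    .reset_index())
    per_chrom = (fi[hit_mask].groupby("chrom").size()
                 .rename("n_features").reset_index())
    return OverlapResult(per_segment=per_segment, per_category=per_category,
                         per_chrom=per_chrom, n_features_overlapped=len(hit))
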