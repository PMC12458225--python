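"""Proximity of genomic features to differentially expressed genes.

Relates feature sets (e.g. H-H motif sites, TnG repeat regions) to a
differential-expression table: mean feature density (feature bp per Mb) in
windows expanding from gene bodies, stratified by DE significance, and the
fraction of genes with at least one feature within a fixed expansion
(default 2 kb), binned by adjusted p-value and split by effect direction.

Feature density counts base pairs of the (merged) feature set overlapping
each expanded gene window, so overlapping features are not double-counted.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core_seq import GenomicInterval, PeakSet, load_intervals

__all__ = [
    "GeneRecord",
    "load_gene_table",
    "feature_density_windows",
    "fraction_with_feature",
    "DEFAULT_PADJ_BINS",
]

DEFAULT_PADJ_BINS = (0.0, 1e-5, 1e-3, 0.05, 0.5, 1.0)


@dataclass(frozen=True)
class GeneRecord:
    """A gene body with DE statistics; missing padj is treated as 1.0."""

    gene_id: str
    interval: GenomicInterval
    log2fc: float = 0.0
    padj: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.padj <= 1.0) or np.isnan(self.padj):
            object.__setattr__(self, "padj", 1.0)

    @property
    def tss(self) -> int:
        return self.interval.start if self.interval.strand != "-" else self.interval.end - 1

    @property
    def significant(self) -> bool:
        return self.padj < 0.05


def load_gene_table(genes_bed: str | Path, de_tsv: str | Path) -> list[GeneRecord]:
    """Join a BED6 gene-body file with a DE table (columns gene, log2fc, padj)."""
    peaks = load_intervals(genes_bed)
    de = pd.read_csv(de_tsv, sep="\t").set_index("gene")
    records = []
    for iv in peaks:
        if iv.name in de.index:
            row = de.loc[iv.name]
            lfc = float(row["log2fc"])
            padj = float(row["padj"]) if pd.notna(row["padj"]) else 1.0
        else:
            lfc, padj = 0.0, 1.0
        records.append(GeneRecord(iv.name, iv, lfc, padj))
    return records


class _MergedFeatures:
    """Per-chromosome merged intervals with prefix sums for fast bp overlap."""

    def __init__(self, features: Sequence[GenomicInterval] | PeakSet):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in features:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        self._chroms: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            merged: list[list[int]] = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            starts = np.array([m[0] for m in merged], dtype=np.int64)
            ends = np.array([m[1] for m in merged], dtype=np.int64)
            cum = np.concatenate([[0], np.cumsum(ends - starts)])
            self._chroms[chrom] = (starts, ends, cum)

    def overlap_bp(self, chrom: str, start: int, end: int) -> int:
        if chrom not in self._chroms or end <= start:
            return 0
        starts, ends, _ = self._chroms[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        if hi <= lo:
            return 0
        ov = np.minimum(ends[lo:hi], end) - np.maximum(starts[lo:hi], start)
        return int(ov.sum())

    def any_overlap(self, chrom: str, start: int, end: int) -> bool:
        return self.overlap_bp(chrom, start, end) > 0


def feature_density_windows(
    genes: Sequence[GeneRecord],
    features: Sequence[GenomicInterval] | PeakSet,
    windows: Sequence[int] = (1_000, 10_000, 100_000, 1_000_000),
) -> pd.DataFrame:
    """Mean feature density (bp/Mb) per (gene group, expansion window).

    Each gene body is expanded by w on both sides (clipped at 0); density is
    overlapping feature bp divided by the expanded window length in Mb, and
    the mean is reported per group ("significant" padj < 0.05 vs
    "non_significant") at each window size.
    """
    windows = sorted(windows)
    if any(w <= 0 for w in windows):
        raise ValueError("windows must be positive")
    merged = _MergedFeatures(features)
    rows = []
    for w in windows:
        dens: dict[str, list[float]] = {"significant": [], "non_significant": []}
        for g in genes:
            start = max(0, g.interval.start - w)
            end = g.interval.end + w
            bp = merged.overlap_bp(g.interval.chrom, start, end)
            dens["significant" if g.significant else "non_significant"].append(
                bp / ((end - start) / 1e6)
            )
        for group, vals in dens.items():
            rows.append((group, w, float(np.mean(vals)) if vals else np.nan, len(vals)))
    return pd.DataFrame(rows, columns=["group", "window", "mean_density_bp_per_mb", "n_genes"])


def fraction_with_feature(
    genes: Sequence[GeneRecord],
    features: Sequence[GenomicInterval] | PeakSet,
    expand_bp: int = 2000,
    padj_bins: Sequence[float] = DEFAULT_PADJ_BINS,
    direction_split: bool = True,
) -> pd.DataFrame:
    """Fraction of genes with >= 1 feature within *expand_bp* per padj bin.

    Bins must partition [0, 1] (ascending edges starting at 0 and ending at
    1); gene padj falls into bin i when edges[i] <= padj < edges[i+1]
    (the last bin is closed). With *direction_split*, fractions are
    additionally split by the sign of log2fc. Empty bins report NaN.
    """
    edges = list(padj_bins)
    if edges[0] != 0.0 or edges[-1] != 1.0 or any(a >= b for a, b in zip(edges, edges[1:])):
        raise ValueError("padj bins must ascend from 0 to 1")
    merged = _MergedFeatures(features)
    directions = ["up", "down"] if direction_split else ["all"]
    hits: dict[tuple[int, str], list[bool]] = {
        (i, d): [] for i in range(len(edges) - 1) for d in directions
    }
    for g in genes:
        i = int(np.searchsorted(edges, g.padj, side="right")) - 1
        i = min(i, len(edges) - 2)
        d = ("up" if g.log2fc >= 0 else "down") if direction_split else "all"
        hit = merged.any_overlap(
            g.interval.chrom, max(0, g.interval.start - expand_bp), g.interval.end + expand_bp
        )
        hits[(i, d)].append(hit)
    rows = []
    for (i, d), vals in hits.items():
        rows.append(
            (
                edges[i],
                edges[i + 1],
                d,
                float(np.mean(vals)) if vals else np.nan,
                len(vals),
            )
        )
    return pd.DataFrame(rows, columns=["padj_lo", "padj_hi", "direction", "fraction", "n_genes"])
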