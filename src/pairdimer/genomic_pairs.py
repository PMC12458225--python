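"""Genomic paired-motif scanning and enrichment statistics.

Scans peak sequences (foreground ChIP-like peaks vs background open
chromatin regions) for orientation-resolved motif pairs, counts
non-overlapping matches on the positive strand only, normalises counts per
Mb of total peak length, tests foreground enrichment with a one-sided exact
binomial test, and profiles pair frequency as a function of gap size.

In genomic scans the spacer between the two half-sites is matched as N^g
(unconstrained bases): the fixed TCGA spacer of the oligo libraries is a
library construction artifact, not a binding requirement.
"""

from __future__ import annotations

import re
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_seq import GenomicInterval, PeakSet, iupac_regex
from .pair_orientation import MotifPair, pattern_for

__all__ = [
    "scan_nonoverlapping",
    "genomic_pattern",
    "scan_peakset",
    "count_by_pair",
    "pair_enrichment",
    "gap_profile",
    "subtract_blacklist",
]


def scan_nonoverlapping(seq: str, pattern: str) -> list[int]:
    """Left-to-right greedy non-overlapping match offsets of *pattern* in *seq*.

    After a match at i, scanning resumes at i + len(pattern), so matches of
    one pattern never overlap each other (matches of different patterns
    may).

    >>> scan_nonoverlapping("TGTGTG", "TG")
    [0, 2, 4]
    """
    rx = re.compile(iupac_regex(pattern))
    starts: list[int] = []
    pos = 0
    while True:
        m = rx.search(seq, pos)
        if m is None:
            return starts
        starts.append(m.start())
        pos = m.start() + len(pattern)


def genomic_pattern(pair: MotifPair, gap_size: int) -> str:
    """The pair's pattern with an unconstrained N^gap_size genomic spacer."""
    return pattern_for(pair.motif_a, pair.motif_b, pair.orientation, "N" * gap_size)


def scan_peakset(
    peaks: PeakSet,
    genome: Mapping[str, str],
    dictionary: Sequence[MotifPair],
    gap_sizes: Sequence[int] = (4,),
) -> pd.DataFrame:
    """Scan every peak for every (pair, gap) pattern on the positive strand.

    Returns a table of occurrences with genome coordinates (columns
    motif_a, motif_b, orientation, gap, chrom, start, end, peak_index).
    Peaks shorter than a pattern contribute zero occurrences; a peak
    extending past its chromosome end is an error.
    """
    rows = []
    seqs: list[tuple[int, GenomicInterval, str]] = []
    for idx, peak in enumerate(peaks):
        if peak.chrom not in genome:
            raise KeyError(f"peak chromosome {peak.chrom!r} absent from genome")
        chrom_seq = genome[peak.chrom]
        if peak.end > len(chrom_seq):
            raise ValueError(f"peak {peak.chrom}:{peak.start}-{peak.end} beyond chromosome end")
        seqs.append((idx, peak, chrom_seq[peak.start : peak.end].upper()))
    for pair in dictionary:
        for g in gap_sizes:
            pattern = genomic_pattern(pair, g)
            width = len(pattern)
            for idx, peak, seq in seqs:
                for off in scan_nonoverlapping(seq, pattern):
                    rows.append(
                        (
                            pair.motif_a,
                            pair.motif_b,
                            pair.orientation,
                            g,
                            peak.chrom,
                            peak.start + off,
                            peak.start + off + width,
                            idx,
                        )
                    )
    return pd.DataFrame(
        rows,
        columns=["motif_a", "motif_b", "orientation", "gap", "chrom", "start", "end", "peak_index"],
    )


def count_by_pair(occurrences: pd.DataFrame) -> pd.Series:
    """Occurrence counts keyed by (motif_a, motif_b, orientation, gap)."""
    if occurrences.empty:
        return pd.Series(dtype="int64")
    return occurrences.groupby(["motif_a", "motif_b", "orientation", "gap"]).size()


def _binomial_pvalue(fg_count: int, fg_len_bp: int, bg_count: int, bg_len_bp: int) -> float:
    """One-sided exact binomial tail P[X >= fg_count], X ~ Bin(fg_len_bp, p_hat).

    The per-bp background rate p_hat = bg_count / bg_len_bp is floored at
    1 / bg_len_bp so a zero background count does not force p to 0.
    """
    p_hat = max(bg_count, 1) / bg_len_bp
    p_hat = min(p_hat, 1.0)
    return float(stats.binom.sf(fg_count - 1, fg_len_bp, p_hat))


def pair_enrichment(
    fg_counts: pd.Series | pd.DataFrame,
    fg_len_bp: int,
    bg_counts: pd.Series | pd.DataFrame,
    bg_len_bp: int,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-pair foreground-vs-background enrichment records.

    Frequencies are occurrences per Mb of total peak length; fold change is
    freq_fg / freq_bg with a 0.5-count continuity correction applied to
    both counts when the background count is 0; the p-value is the
    one-sided exact binomial tail with trials = foreground bp.
    """
    if fg_len_bp <= 0 or bg_len_bp <= 0:
        raise ValueError("peak-set total lengths must be positive")
    if isinstance(fg_counts, pd.DataFrame):
        fg_counts = count_by_pair(fg_counts)
    if isinstance(bg_counts, pd.DataFrame):
        bg_counts = count_by_pair(bg_counts)
    keys = fg_counts.index.union(bg_counts.index)
    fg = fg_counts.reindex(keys, fill_value=0).astype(int)
    bg = bg_counts.reindex(keys, fill_value=0).astype(int)
    fg_mb, bg_mb = fg_len_bp / 1e6, bg_len_bp / 1e6
    rows = []
    for key in keys:
        cf, cb = int(fg[key]), int(bg[key])
        if cb == 0:
            fc = ((cf + 0.5) / fg_mb) / ((cb + 0.5) / bg_mb)
        else:
            fc = (cf / fg_mb) / (cb / bg_mb)
        pval = _binomial_pvalue(cf, fg_len_bp, cb, bg_len_bp)
        rows.append((*key, cf, cb, cf / fg_mb, cb / bg_mb, fc, pval, pval < alpha))
    df = pd.DataFrame(
        rows,
        columns=[
            "motif_a", "motif_b", "orientation", "gap",
            "count_fg", "count_bg", "freq_fg", "freq_bg",
            "fold_change", "p_value", "significant",
        ],
    )
    return df.sort_values("p_value", kind="mergesort").reset_index(drop=True)


def gap_profile(
    peaks_fg: PeakSet,
    peaks_bg: PeakSet,
    genome: Mapping[str, str],
    dictionary: Sequence[MotifPair],
    gap_range: Sequence[int] = tuple(range(1, 11)),
) -> pd.DataFrame:
    """Per-(pair, gap) normalised frequencies in foreground and background.

    Each pair's pattern is rebuilt with an N^g spacer for every g in
    *gap_range*; occurrences are counted per Mb in both peak sets, and the
    foreground/background frequency ratio plus the per-pair argmax gap are
    reported. Zero denominators take a 0.5-count continuity correction.
    """
    gap_range = list(gap_range)
    if not gap_range:
        return pd.DataFrame(
            columns=["motif_a", "motif_b", "orientation", "gap",
                     "count_fg", "count_bg", "freq_fg", "freq_bg", "ratio", "argmax_gap"]
        )
    if any(g < 0 or g > 20 for g in gap_range):
        raise ValueError("gap sizes must lie in [0, 20]")
    fg_occ = scan_peakset(peaks_fg, genome, dictionary, gap_range)
    bg_occ = scan_peakset(peaks_bg, genome, dictionary, gap_range)
    fg_c = count_by_pair(fg_occ)
    bg_c = count_by_pair(bg_occ)
    fg_mb = peaks_fg.total_length_bp / 1e6
    bg_mb = peaks_bg.total_length_bp / 1e6
    rows = []
    for pair in dictionary:
        for g in gap_range:
            key = (pair.motif_a, pair.motif_b, pair.orientation, g)
            cf = int(fg_c.get(key, 0))
            cb = int(bg_c.get(key, 0))
            if cb == 0:
                ratio = ((cf + 0.5) / fg_mb) / ((cb + 0.5) / bg_mb)
            else:
                ratio = (cf / fg_mb) / (cb / bg_mb)
            rows.append((pair.motif_a, pair.motif_b, pair.orientation, g,
                         cf, cb, cf / fg_mb, cb / bg_mb, ratio))
    df = pd.DataFrame(
        rows,
        columns=["motif_a", "motif_b", "orientation", "gap",
                 "count_fg", "count_bg", "freq_fg", "freq_bg", "ratio"],
    )
    argmax = (
        df.loc[df.groupby(["motif_a", "motif_b", "orientation"])["ratio"].idxmax()]
        .set_index(["motif_a", "motif_b", "orientation"])["gap"]
    )
    df["argmax_gap"] = [
        int(argmax[(a, b, o)]) for a, b, o in zip(df["motif_a"], df["motif_b"], df["orientation"])
    ]
    return df


def subtract_blacklist(peaks: PeakSet, blacklist: PeakSet) -> PeakSet:
    """Remove whole peaks overlapping any blacklist interval by >= 1 bp."""
    bl = blacklist.by_chrom()
    kept = []
    for peak in peaks:
        hits = bl.get(peak.chrom, [])
        starts = np.array([iv.start for iv in hits], dtype=np.int64)
        ends = np.array([iv.end for iv in hits], dtype=np.int64)
        if not len(hits) or not np.any((starts < peak.end) & (ends > peak.start)):
            kept.append(peak)
    return PeakSet(kept)
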