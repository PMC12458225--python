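"""Random-rcFKHM pull-down-seq enrichment and 2N-motif discovery.

This stage consumes merged reads from a library whose oligos carry a
variable 7-nt site 1, a fixed 4-nt TCGA gap, and a fixed reverse-complement
forkhead motif (rcFKHM, GTAAACA) as site 2. It extracts variable regions by
exact structure matching, tabulates unique-sequence counts (dense over all
4^7 = 16,384 site-1 sequences), computes pull-down/input fold enrichment in
RPM, and performs "2N motif" discovery: every 7-mer spawns the 21 degenerate
patterns obtained by replacing two positions with N; counts of the 16
concrete instantiations of each pattern are summed and ranked by aggregate
enrichment.
"""

from __future__ import annotations

import itertools
from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_seq import LibraryDesign

__all__ = [
    "ParsedRead",
    "CountTable",
    "parse_library_read",
    "tabulate_counts",
    "fold_enrichment",
    "enumerate_2n_patterns",
    "aggregate_2n",
    "coverage_rank",
]

REJECT_STRUCTURE = "structure_mismatch"
REJECT_AMBIGUOUS = "ambiguous_base"
REJECT_QUALITY = "low_quality"


@dataclass(frozen=True)
class ParsedRead:
    """Outcome of structure extraction: site sequences or a rejection code."""

    sites: tuple[str, ...] | None
    reject: str | None = None

    @property
    def ok(self) -> bool:
        return self.sites is not None


def parse_library_read(
    read: str,
    quals: Sequence[int] | None,
    design: LibraryDesign,
    min_phred: int = 20,
) -> ParsedRead:
    """Locate the design template in *read* and extract variable regions.

    The template is anchored by an exact match of NBS1; all remaining fixed
    regions (gap, fixed site 2 when present, NBS2) must then match exactly.
    Rejections are returned as codes, never raised: ``structure_mismatch``
    (fixed regions absent/mismatched or read too short), ``ambiguous_base``
    (non-ACGT in a variable region), ``low_quality`` (any variable-region
    Phred score below *min_phred*, only checked when quals are given).
    """
    read = read.upper()
    anchor = read.find(design.nbs1)
    if anchor < 0 or anchor + design.total_length > len(read):
        return ParsedRead(None, REJECT_STRUCTURE)
    oligo = read[anchor : anchor + design.total_length]
    if oligo[design.gap_start : design.site2_start] != design.gap:
        return ParsedRead(None, REJECT_STRUCTURE)
    if design.site2 is not None and oligo[design.site2_start : design.nbs2_start] != design.site2:
        return ParsedRead(None, REJECT_STRUCTURE)
    if oligo[design.nbs2_start :] != design.nbs2:
        return ParsedRead(None, REJECT_STRUCTURE)

    sites = tuple(oligo[sl] for sl in design.variable_slices())
    if any(c not in "ACGT" for site in sites for c in site):
        return ParsedRead(None, REJECT_AMBIGUOUS)
    if quals is not None:
        for sl in design.variable_slices():
            window = quals[anchor + sl.start : anchor + sl.stop]
            if min(window) < min_phred:
                return ParsedRead(None, REJECT_QUALITY)
    return ParsedRead(sites)


# ---------------------------------------------------------------------------
# Count tables
# ---------------------------------------------------------------------------

def _all_kmers(k: int) -> list[str]:
    return ["".join(p) for p in itertools.product("ACGT", repeat=k)]


@dataclass
class CountTable:
    """Unique variable-region sequence -> raw count and reads-per-million.

    ``counts`` is a pandas Series indexed by sequence. In dense mode the
    index enumerates all 4^k sequences with zero-filled counts. RPM is
    count / total accepted reads * 1e6.
    """

    counts: pd.Series
    total_reads: int
    dense: bool = False

    @property
    def rpm(self) -> pd.Series:
        if self.total_reads == 0:
            return self.counts.astype(float)
        return self.counts / self.total_reads * 1e6


def tabulate_counts(site_seqs: Iterable[str], dense: bool = False, length: int | None = None) -> CountTable:
    """Tabulate unique sequences into a CountTable.

    In dense mode all 4^length keys are enumerated with zero counts, which
    the 2N aggregation stage requires. Mixed-length sequences are an error.
    """
    seqs = list(site_seqs)
    if seqs:
        lens = {len(s) for s in seqs}
        if len(lens) > 1:
            raise ValueError(f"mixed sequence lengths in count table: {sorted(lens)}")
        if length is None:
            length = lens.pop()
    counts = pd.Series(seqs, dtype="object").value_counts() if seqs else pd.Series(dtype="int64")
    if dense:
        if length is None:
            raise ValueError("dense tabulation with an empty stream requires an explicit length")
        counts = counts.reindex(_all_kmers(length), fill_value=0).astype("int64")
    else:
        counts = counts.sort_index().astype("int64")
    return CountTable(counts=counts, total_reads=len(seqs), dense=dense)


def fold_enrichment(
    pd_table: CountTable,
    input_table: CountTable,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-sequence pull-down/input enrichment of RPM-normalised counts.

    enrichment = (pd_rpm + pseudocount) / (input_rpm + pseudocount), over
    the shared key universe (dense) or the union of keys (sparse). The
    result is sorted in descending enrichment and carries a 1-based rank.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    keys = pd_table.counts.index.union(input_table.counts.index)
    df = pd.DataFrame(
        {
            "count_pd": pd_table.counts.reindex(keys, fill_value=0),
            "count_input": input_table.counts.reindex(keys, fill_value=0),
            "rpm_pd": pd_table.rpm.reindex(keys, fill_value=0.0),
            "rpm_input": input_table.rpm.reindex(keys, fill_value=0.0),
        }
    )
    df["enrichment"] = (df["rpm_pd"] + pseudocount) / (df["rpm_input"] + pseudocount)
    df = df.sort_values("enrichment", ascending=False, kind="mergesort")
    df["rank"] = np.arange(1, len(df) + 1)
    df.index.name = "sequence"
    return df


# ---------------------------------------------------------------------------
# 2N motif discovery
# ---------------------------------------------------------------------------

def enumerate_2n_patterns(seq: str) -> list[str]:
    """The 21 patterns obtained by replacing 2 of 7 positions with N.

    >>> "TGTTTNN" in enumerate_2n_patterns("TGTTTAC")
    True
    """
    if len(seq) != 7:
        raise ValueError(f"expected a 7-mer, got {seq!r}")
    out = []
    for i, j in itertools.combinations(range(7), 2):
        chars = list(seq)
        chars[i] = "N"
        chars[j] = "N"
        out.append("".join(chars))
    return out


def _mask_positions(index: pd.Index, i: int, j: int) -> np.ndarray:
    """Replace positions i < j of every sequence in *index* with N."""
    return np.array([s[:i] + "N" + s[i + 1 : j] + "N" + s[j + 1 :] for s in index], dtype=object)


def aggregate_2n(
    pd_table: CountTable,
    input_table: CountTable,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Aggregate dense per-sequence counts into ranked 2N-motif records.

    Every observed 7-mer contributes its 21 two-N degenerations; duplicates
    across sequences collapse, so each record's aggregate counts are the
    sums over its 16 concrete instantiations. Enrichment is computed on
    aggregated RPM with the same pseudocount rule as per-sequence
    enrichment. Requires dense tables (sparse aggregation would bias sums).
    """
    if not (pd_table.dense and input_table.dense):
        raise ValueError("2N aggregation requires dense count tables")
    keys = pd_table.counts.index
    frames = []
    for i, j in itertools.combinations(range(7), 2):
        masked = _mask_positions(keys, i, j)
        grp = pd.DataFrame(
            {
                "count_pd": pd_table.counts.to_numpy(),
                "count_input": input_table.counts.reindex(keys, fill_value=0).to_numpy(),
                "rpm_pd": pd_table.rpm.to_numpy(),
                "rpm_input": input_table.rpm.reindex(keys, fill_value=0.0).to_numpy(),
            },
            index=masked,
        ).groupby(level=0).sum()
        frames.append(grp)
    df = pd.concat(frames)
    df["enrichment"] = (df["rpm_pd"] + pseudocount) / (df["rpm_input"] + pseudocount)
    df = df.sort_values("enrichment", ascending=False, kind="mergesort")
    df["rank"] = np.arange(1, len(df) + 1)
    df.index.name = "pattern"
    return df


def coverage_rank(
    per_seq: pd.DataFrame,
    two_n: pd.DataFrame,
    quantile: float = 0.10,
) -> int:
    """Minimal number of top-ranked 2N motifs covering the top-q sequences.

    The top-q set is the ``ceil(q * n)`` sequences with highest per-sequence
    enrichment. Motifs are selected greedily in descending 2N enrichment
    order until every top-q sequence is an instantiation of at least one
    selected motif; the number selected is returned.
    """
    if not 0 < quantile <= 1:
        raise ValueError("quantile must be in (0, 1]")
    n_top = int(np.ceil(quantile * len(per_seq)))
    top = set(per_seq.index[:n_top])
    uncovered = set(top)
    chosen = 0
    for pattern in two_n.index:
        if not uncovered:
            break
        chosen += 1
        npos = [k for k, c in enumerate(pattern) if c == "N"]
        matched = {
            s for s in uncovered
            if all(s[k] == c for k, c in enumerate(pattern) if c != "N") and len(npos) == 2
        }
        uncovered -= matched
    if uncovered:
        raise RuntimeError("2N universe failed to cover the top-quantile set")
    return chosen
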