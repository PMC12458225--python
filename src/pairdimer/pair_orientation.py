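"""Random-random pull-down-seq paired-motif orientation analysis.

Given 10 seed motifs (7-nt IUPAC patterns), this stage builds the 400-entry
paired-motif dictionary (10 x 10 ordered pairs x 4 orientations, each an
18-nt pattern with a fixed 4-nt spacer), scans reads with five positional
shifts (0, +/-1, +/-2) around the central spacer, counts each read at most
once per pair, and normalises observed pair counts by the baseline
probability that a uniformly random variable region would match the pair at
any allowed shift given the design's fixed flank and gap bases.

Orientation conventions (on the forward strand of the oligo):
    H-H: a + gap + rc(b)   (inverted repeat; head-to-head)
    H-T: a + gap + b
    T-H: rc(a) + gap + rc(b)
    T-T: rc(a) + gap + b
which gives the strand identities rc(HT(a,b)) == TH(b,a) and
rc(HH(a,b)) == HH(b,a), rc(TT(a,b)) == TT(b,a).
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_seq import (
    IUPAC_SETS,
    PATTERN_MASK_LUT,
    TEXT_BIT_LUT,
    LibraryDesign,
    is_iupac,
    reverse_complement,
)

__all__ = [
    "ORIENTATIONS",
    "MotifPair",
    "PairCountMatrix",
    "build_pair_dictionary",
    "extract_shifted_windows",
    "count_pair_matches",
    "count_pair_matches_sites",
    "pair_baseline_probability",
    "baseline_table",
    "normalize_pair_counts",
    "pattern_for",
]

ORIENTATIONS = ("HH", "HT", "TH", "TT")
DEFAULT_SHIFTS = (-2, -1, 0, 1, 2)

#: Default 10-motif seed set: group 1 (forkhead-like, containing TGTTT/TGTTG)
#: and group 2 (GCAT-core) 7-nt patterns. The original study's exact top-10
#: list is configurable; these are the textually attested forms plus
#: FKHM-anchored variants, and users with the authoritative table should
#: substitute it via the motif-file input.
DEFAULT_MOTIFS_G1 = ["TGTTTAC", "TGTTTNN", "TGTTGNN", "TGTTKNN", "NTGTTTN"]
DEFAULT_MOTIFS_G2 = ["GCGCATC", "TGTGCAT", "NNGCATY", "NNGCATC", "GATGCNN"]
DEFAULT_MOTIFS = DEFAULT_MOTIFS_G1 + DEFAULT_MOTIFS_G2
MOTIF_GROUPS = {m: "G1" for m in DEFAULT_MOTIFS_G1} | {m: "G2" for m in DEFAULT_MOTIFS_G2}


def pattern_for(motif_a: str, motif_b: str, orientation: str, gap: str) -> str:
    """The realized pattern for an ordered motif pair in one orientation."""
    if orientation == "HH":
        return motif_a + gap + reverse_complement(motif_b)
    if orientation == "HT":
        return motif_a + gap + motif_b
    if orientation == "TH":
        return reverse_complement(motif_a) + gap + reverse_complement(motif_b)
    if orientation == "TT":
        return reverse_complement(motif_a) + gap + motif_b
    raise ValueError(f"unknown orientation {orientation!r}")


@dataclass(frozen=True)
class MotifPair:
    """An ordered motif pair with orientation and spacer.

    >>> MotifPair("TGTTTNN", "TGTTTNN", "HH").pattern
    'TGTTTNNTCGANNAAACA'
    """

    motif_a: str
    motif_b: str
    orientation: str
    gap: str = "TCGA"

    def __post_init__(self) -> None:
        if not (is_iupac(self.motif_a) and is_iupac(self.motif_b)):
            raise ValueError("motifs must be IUPAC strings")
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"orientation must be one of {ORIENTATIONS}")

    @property
    def pattern(self) -> str:
        return pattern_for(self.motif_a, self.motif_b, self.orientation, self.gap)

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.motif_a, self.motif_b, self.orientation)


def build_pair_dictionary(motifs: Sequence[str], gap: str = "TCGA") -> list[MotifPair]:
    """All ordered pairs of *motifs* in all four orientations.

    For 10 motifs this yields exactly 10 x 10 x 4 = 400 entries.
    """
    motifs = list(motifs)
    lengths = {len(m) for m in motifs}
    if len(lengths) != 1:
        raise ValueError("all motifs must share one length")
    return [
        MotifPair(a, b, o, gap)
        for a in motifs
        for b in motifs
        for o in ORIENTATIONS
    ]


# ---------------------------------------------------------------------------
# Window extraction and bit-packed matching
# ---------------------------------------------------------------------------

def extract_shifted_windows(
    read: str,
    design: LibraryDesign,
    shifts: Sequence[int] = DEFAULT_SHIFTS,
) -> list[str] | None:
    """The pattern-length windows at each shift around the variable core.

    The window at shift s starts at (site-1 start + s); windows reaching
    into the flanks therefore include the known fixed bases. Returns None
    when the design structure cannot be located in the read.
    """
    read = read.upper()
    anchor = read.find(design.nbs1)
    if anchor < 0 or anchor + design.total_length > len(read):
        return None
    width = design.site1_len + len(design.gap) + design.site2_length
    base = anchor + design.site1_start
    out = []
    for s in shifts:
        lo = base + s
        if lo < 0 or lo + width > len(read):
            return None
        out.append(read[lo : lo + width])
    return out


def _pack_codes(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pack (n, w<=24) 5-bit position codes into two uint64 columns."""
    n, w = codes.shape
    half = (w + 1) // 2
    lo = np.zeros(n, dtype=np.uint64)
    hi = np.zeros(n, dtype=np.uint64)
    for j in range(w):
        col = codes[:, j].astype(np.uint64)
        if j < half:
            lo |= col << np.uint64(5 * j)
        else:
            hi |= col << np.uint64(5 * (j - half))
    return lo, hi


def _encode_texts(windows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Encode an (n, w) uint8 char-code array of concrete windows."""
    return _pack_codes(TEXT_BIT_LUT[windows])


def _encode_patterns(patterns: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    arr = np.array([list(p.encode("ascii")) for p in patterns], dtype=np.uint8)
    return _pack_codes(PATTERN_MASK_LUT[arr])


def _windows_char_array(windows_per_read: list[list[str]]) -> np.ndarray:
    flat = [w for ws in windows_per_read for w in ws]
    return np.array([list(w.encode("ascii")) for w in flat], dtype=np.uint8)


@dataclass
class PairCountMatrix:
    """Counts (or normalised frequencies) indexed by (motif_a, motif_b, orientation)."""

    motifs: list[str]
    counts: np.ndarray  # shape (n_motifs, n_motifs, 4), orientation order ORIENTATIONS
    n_reads: int = 0
    scale_max: float = field(default=np.nan)

    def value(self, motif_a: str, motif_b: str, orientation: str) -> float:
        ia = self.motifs.index(motif_a)
        ib = self.motifs.index(motif_b)
        return float(self.counts[ia, ib, ORIENTATIONS.index(orientation)])

    def orientation_totals(self) -> dict[str, float]:
        return {o: float(self.counts[:, :, k].sum()) for k, o in enumerate(ORIENTATIONS)}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ia, a in enumerate(self.motifs):
            for ib, b in enumerate(self.motifs):
                for k, o in enumerate(ORIENTATIONS):
                    rows.append((a, b, o, self.counts[ia, ib, k]))
        return pd.DataFrame(rows, columns=["motif_a", "motif_b", "orientation", "value"])


def _count_from_windows(
    windows: np.ndarray,
    n_per_read: int,
    dictionary: Sequence[MotifPair],
    motifs: list[str],
) -> np.ndarray:
    """Once-per-read pair counts from a flat (n_reads * n_per_read, w) window array."""
    counts = np.zeros((len(motifs), len(motifs), 4), dtype=np.int64)
    if windows.shape[0] == 0:
        return counts
    w_lo, w_hi = _encode_texts(windows)
    p_lo, p_hi = _encode_patterns([p.pattern for p in dictionary])
    n_reads = windows.shape[0] // n_per_read
    for k, pair in enumerate(dictionary):
        miss = (w_lo & ~p_lo[k]) | (w_hi & ~p_hi[k])
        hit_any = (miss == 0).reshape(n_reads, n_per_read).any(axis=1)
        ia = motifs.index(pair.motif_a)
        ib = motifs.index(pair.motif_b)
        counts[ia, ib, ORIENTATIONS.index(pair.orientation)] = int(hit_any.sum())
    return counts


def count_pair_matches(
    reads: Iterable[str],
    dictionary: Sequence[MotifPair],
    design: LibraryDesign,
    shifts: Sequence[int] = DEFAULT_SHIFTS,
) -> PairCountMatrix:
    """Count reads supporting each motif pair (once per read per pair).

    A read increments a pair's count by exactly 1 when any of its shifted
    windows matches the pair's pattern; one read may support several
    distinct pairs. Reads whose structure cannot be located are skipped
    (tracked via ``n_reads`` vs the input length).
    """
    motifs = sorted({p.motif_a for p in dictionary} | {p.motif_b for p in dictionary})
    windows_per_read = []
    for read in reads:
        ws = extract_shifted_windows(read, design, shifts)
        if ws is not None:
            windows_per_read.append(ws)
    if not windows_per_read:
        return PairCountMatrix(motifs, np.zeros((len(motifs), len(motifs), 4)), 0)
    arr = _windows_char_array(windows_per_read)
    counts = _count_from_windows(arr, len(shifts), dictionary, motifs)
    return PairCountMatrix(motifs, counts, n_reads=len(windows_per_read))


def count_pair_matches_sites(
    site1: np.ndarray,
    site2: np.ndarray,
    dictionary: Sequence[MotifPair],
    design: LibraryDesign,
    shifts: Sequence[int] = DEFAULT_SHIFTS,
) -> PairCountMatrix:
    """As :func:`count_pair_matches`, but from (n, 7) uint8 base-code arrays.

    Avoids materialising full read strings for large simulated libraries;
    windows are assembled from the design template plus the variable-region
    code arrays.
    """
    from .synthetic_data import windows_from_sites  # local import to avoid cycle

    motifs = sorted({p.motif_a for p in dictionary} | {p.motif_b for p in dictionary})
    arr = windows_from_sites(site1, site2, design, shifts)
    counts = _count_from_windows(arr, len(shifts), dictionary, motifs)
    return PairCountMatrix(motifs, counts, n_reads=site1.shape[0])


# ---------------------------------------------------------------------------
# Baseline probabilities and normalisation
# ---------------------------------------------------------------------------

def pair_baseline_probability(
    pair: MotifPair,
    design: LibraryDesign,
    shifts: Sequence[int] = DEFAULT_SHIFTS,
) -> float:
    """Probability that a uniformly random variable region matches *pair*.

    Per shift s the match probability is the product over pattern positions
    of: 1 if the aligned design base is fixed and allowed, 0 if fixed and
    disallowed, |allowed|/4 if the aligned position is variable. Shifts are
    combined with the independence approximation
    ``1 - prod_s(1 - p_s)`` (an upper bound on the exact union that is
    accurate for the small per-shift probabilities involved here).
    """
    template = design.template
    var_positions = {i for sl in design.variable_slices() for i in range(sl.start, sl.stop)}
    pattern = pair.pattern
    per_shift = []
    for s in shifts:
        start = design.site1_start + s
        if start < 0 or start + len(pattern) > len(template):
            per_shift.append(0.0)
            continue
        p = 1.0
        for k, code in enumerate(pattern):
            tpos = start + k
            allowed = IUPAC_SETS[code]
            if tpos in var_positions:
                p *= len(allowed) / 4.0
            else:
                p *= 1.0 if template[tpos] in allowed else 0.0
            if p == 0.0:
                break
        per_shift.append(p)
    miss = 1.0
    for p in per_shift:
        miss *= 1.0 - p
    return 1.0 - miss


def baseline_table(
    dictionary: Sequence[MotifPair],
    design: LibraryDesign,
    shifts: Sequence[int] = DEFAULT_SHIFTS,
) -> dict[tuple[str, str, str], float]:
    return {p.key: pair_baseline_probability(p, design, shifts) for p in dictionary}


def normalize_pair_counts(
    counts: PairCountMatrix,
    baselines: dict[tuple[str, str, str], float],
    joint_scale_with: PairCountMatrix | None = None,
) -> PairCountMatrix | tuple[PairCountMatrix, PairCountMatrix]:
    """Divide counts by baseline probabilities; optionally jointly 0-100 scale.

    Cells whose baseline is 0 (unobservable pairs) are set to 0 rather than
    dividing. With *joint_scale_with*, both matrices are scaled by their
    common maximum so that the joint maximum is 100.
    """
    def _normalise(mat: PairCountMatrix) -> np.ndarray:
        out = np.zeros_like(mat.counts, dtype=float)
        for ia, a in enumerate(mat.motifs):
            for ib, b in enumerate(mat.motifs):
                for k, o in enumerate(ORIENTATIONS):
                    base = baselines.get((a, b, o), 0.0)
                    out[ia, ib, k] = mat.counts[ia, ib, k] / base if base > 0 else 0.0
        return out

    norm = _normalise(counts)
    if joint_scale_with is None:
        return PairCountMatrix(counts.motifs, norm, counts.n_reads, scale_max=float(norm.max(initial=0.0)))
    other = _normalise(joint_scale_with)
    common = max(float(norm.max(initial=0.0)), float(other.max(initial=0.0)))
    if common > 0:
        norm = norm / common * 100.0
        other = other / common * 100.0
    return (
        PairCountMatrix(counts.motifs, norm, counts.n_reads, scale_max=common),
        PairCountMatrix(joint_scale_with.motifs, other, joint_scale_with.n_reads, scale_max=common),
    )
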