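"""Sequence and interval primitives shared by every pipeline stage.

This module owns the IUPAC degenerate-DNA alphabet (codes, complements,
set expansion, matching), the 0-based half-open genomic interval types,
and plain-text readers/writers for FASTA/FASTQ, BED, bedGraph and TSV.

All genomic coordinates in this package are 0-based half-open (BED
convention); no 1-based formats are supported.
"""

from __future__ import annotations

import gzip
import itertools
import re
from collections.abc import Iterable, Iterator, Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

__all__ = [
    "IUPAC_SETS",
    "GenomicInterval",
    "PeakSet",
    "SignalTrack",
    "LibraryDesign",
    "reverse_complement",
    "iupac_match",
    "expand_iupac",
    "iupac_regex",
    "is_iupac",
    "load_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "load_intervals",
    "write_intervals",
    "load_signal",
    "write_signal",
]

# ---------------------------------------------------------------------------
# IUPAC alphabet
# ---------------------------------------------------------------------------

#: Allowed concrete bases for each IUPAC DNA code.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

# Bitmask encoding: A=1, C=2, G=4, T=8; bit 16 marks a non-ACGT text base.
# An N pattern position matches anything (including non-ACGT/softmask-derived
# bases); every other code fails on a non-ACGT base.
_BASE_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}
_CODE_MASK = {
    code: sum(_BASE_BIT[b] for b in bases) | (16 if code == "N" else 0)
    for code, bases in IUPAC_SETS.items()
}

#: uint8 lookup tables indexed by ord(char) for vectorised encoding.
TEXT_BIT_LUT = np.zeros(256, dtype=np.uint8)
for _b, _bit in _BASE_BIT.items():
    TEXT_BIT_LUT[ord(_b)] = _bit
    TEXT_BIT_LUT[ord(_b.lower())] = _bit
# any other character -> bit 16 ("unknown base")
for _i in range(256):
    if TEXT_BIT_LUT[_i] == 0:
        TEXT_BIT_LUT[_i] = 16

PATTERN_MASK_LUT = np.zeros(256, dtype=np.uint8)
for _c, _m in _CODE_MASK.items():
    PATTERN_MASK_LUT[ord(_c)] = _m


def is_iupac(seq: str) -> bool:
    """True if *seq* is non-empty and uses only IUPAC DNA codes."""
    return len(seq) > 0 and all(c in IUPAC_SETS for c in seq)


def _check_iupac(seq: str) -> None:
    for i, c in enumerate(seq):
        if c not in IUPAC_SETS:
            raise ValueError(f"invalid IUPAC character {c!r} at position {i} in {seq!r}")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an IUPAC string (degenerate codes complemented).

    ``reverse_complement`` is an involution: applying it twice returns the
    input.

    >>> reverse_complement("TGTTTAC")
    'GTAAACA'
    """
    _check_iupac(seq)
    return "".join(_COMPLEMENT[c] for c in reversed(seq))


def iupac_match(pattern: str, text: str, offset: int = 0) -> bool:
    """True iff *pattern* matches *text* starting at *offset*.

    Each pattern position matches when its allowed-base set contains the
    text base. ``N`` matches any character; any non-ACGT text base fails
    every non-N position.
    """
    _check_iupac(pattern)
    if offset < 0 or offset + len(pattern) > len(text):
        raise IndexError(
            f"offset {offset} with pattern length {len(pattern)} out of range "
            f"for text of length {len(text)}"
        )
    for i, code in enumerate(pattern):
        if not (TEXT_BIT_LUT[ord(text[offset + i])] & _CODE_MASK[code]):
            return False
    return True


def expand_iupac(pattern: str) -> Iterator[str]:
    """Yield every concrete ACGT instantiation of an IUPAC pattern."""
    _check_iupac(pattern)
    pools = [sorted(IUPAC_SETS[c]) for c in pattern]
    for combo in itertools.product(*pools):
        yield "".join(combo)


def iupac_regex(pattern: str) -> str:
    """Translate an IUPAC pattern into an equivalent regex over ACGT."""
    _check_iupac(pattern)
    parts = []
    for c in pattern:
        bases = IUPAC_SETS[c]
        parts.append(c if len(bases) == 1 else "[" + "".join(sorted(bases)) + "]")
    return "".join(parts)


def encode_bases(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes 0..3 (A,C,G,T); other chars -> 4."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        out[arr == ord(b)] = i
    return out


# ---------------------------------------------------------------------------
# Interval types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start coordinate: {self!r}")
        if self.start >= self.end:
            raise ValueError(f"start must be < end: {self!r}")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"strand must be one of +, -, .: {self!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class PeakSet:
    """An ordered collection of intervals (sorted by chrom, start).

    Overlapping intervals are retained as-is; ``total_length_bp`` is the
    plain sum of interval lengths, so overlapping peaks contribute their
    full length each.
    """

    def __init__(self, intervals: Iterable[GenomicInterval]):
        self.intervals: list[GenomicInterval] = sorted(
            intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)
        )

    @property
    def total_length_bp(self) -> int:
        return sum(iv.length for iv in self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out


class SignalTrack:
    """Piecewise-constant per-base coverage (bedGraph semantics).

    Segments per chromosome are non-overlapping and sorted; positions not
    covered by any segment have value 0.
    """

    def __init__(self, segments: Mapping[str, Iterable[tuple[int, int, float]]]):
        self._chroms: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, segs in segments.items():
            segs = sorted(segs)
            starts = np.array([s for s, _, _ in segs], dtype=np.int64)
            ends = np.array([e for _, e, _ in segs], dtype=np.int64)
            values = np.array([v for _, _, v in segs], dtype=float)
            if np.any(starts >= ends):
                raise ValueError(f"empty or inverted segment on {chrom}")
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping segments on {chrom}")
            if not np.all(np.isfinite(values)) or np.any(values < 0):
                raise ValueError(f"segment values must be finite and >= 0 on {chrom}")
            self._chroms[chrom] = (starts, ends, values)

    def chroms(self) -> list[str]:
        return list(self._chroms)

    def segments(self, chrom: str) -> list[tuple[int, int, float]]:
        if chrom not in self._chroms:
            return []
        starts, ends, values = self._chroms[chrom]
        return [(int(s), int(e), float(v)) for s, e, v in zip(starts, ends, values)]

    def window_sum(self, chrom: str, start: int, end: int) -> float:
        """Sum of per-base coverage over [start, end)."""
        if chrom not in self._chroms or end <= start:
            return 0.0
        starts, ends, values = self._chroms[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        if hi <= lo:
            return 0.0
        ov = np.minimum(ends[lo:hi], end) - np.maximum(starts[lo:hi], start)
        return float(np.sum(ov * values[lo:hi]))


# ---------------------------------------------------------------------------
# Oligo library design
# ---------------------------------------------------------------------------

# Default non-binding flanks. The exact flank oligos of the original library
# are not bundled; these are arbitrary GC-balanced stand-ins of the correct
# lengths (27 and 35 nt) and are configurable on LibraryDesign.
DEFAULT_NBS1 = "ACTGAGCTAGCTCAATGGTCACCATGA"  # 27 nt
DEFAULT_NBS2 = "TCACGATGGATCCTAGTTGACAGCTAGCATGGATC"  # 35 nt


@dataclass(frozen=True)
class LibraryDesign:
    """Fixed/variable architecture of a pull-down-seq oligo.

    Layout: ``nbs1 + site1 + gap + site2 + nbs2`` where site 1 is always
    variable (length ``site1_len``) and site 2 is either a fixed string
    (random-rcFKHM design) or variable of length ``site2_len``
    (random-random design).
    """

    nbs1: str = DEFAULT_NBS1
    site1_len: int = 7
    gap: str = "TCGA"
    site2: str | None = "GTAAACA"  # None -> variable
    site2_len: int = 7
    nbs2: str = DEFAULT_NBS2

    def __post_init__(self) -> None:
        for name in ("nbs1", "gap", "nbs2"):
            val = getattr(self, name)
            if not val or any(c not in "ACGT" for c in val):
                raise ValueError(f"{name} must be a non-empty ACGT string")
        if self.site2 is not None and any(c not in "ACGT" for c in self.site2):
            raise ValueError("fixed site2 must be an ACGT string")

    @classmethod
    def random_rcfkhm(cls, **kw) -> "LibraryDesign":
        """Variable site 1 + TCGA gap + fixed rcFKHM site 2."""
        return cls(site2="GTAAACA", **kw)

    @classmethod
    def random_random(cls, **kw) -> "LibraryDesign":
        """Both sites variable (7 + TCGA + 7)."""
        return cls(site2=None, **kw)

    @property
    def site2_length(self) -> int:
        return len(self.site2) if self.site2 is not None else self.site2_len

    @property
    def site1_start(self) -> int:
        return len(self.nbs1)

    @property
    def gap_start(self) -> int:
        return self.site1_start + self.site1_len

    @property
    def site2_start(self) -> int:
        return self.gap_start + len(self.gap)

    @property
    def nbs2_start(self) -> int:
        return self.site2_start + self.site2_length

    @property
    def total_length(self) -> int:
        return self.nbs2_start + len(self.nbs2)

    @property
    def template(self) -> str:
        """Full oligo with variable positions as ``N``."""
        site2 = self.site2 if self.site2 is not None else "N" * self.site2_len
        return self.nbs1 + "N" * self.site1_len + self.gap + site2 + self.nbs2

    def variable_slices(self) -> list[slice]:
        """Slices of the variable regions within the full oligo."""
        out = [slice(self.site1_start, self.gap_start)]
        if self.site2 is None:
            out.append(slice(self.site2_start, self.nbs2_start))
        return out


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def load_fasta(path: str | Path) -> dict[str, str]:
    """Load a (small) FASTA file into a dict of uppercase sequences."""
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(path: str | Path, seqs: Mapping[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def read_fastq(path: str | Path) -> Iterator[tuple[str, list[int]]]:
    """Yield (sequence, phred qualities) for each FASTQ record."""
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield str(rec.seq).upper(), rec.letter_annotations["phred_quality"]


def write_fastq(path: str | Path, reads: Iterable[str], phred: int = 30) -> None:
    qchar = chr(phred + 33)
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@read{i}\n{seq}\n+\n{qchar * len(seq)}\n")


def load_intervals(path: str | Path) -> PeakSet:
    """Read a BED3/BED6 file into a PeakSet (no merging, sorted).

    Strand is taken from column 6 when present, else ".". Malformed lines
    (start >= end, negative coordinates, too few columns) raise a parse
    error naming the offending line.
    """
    intervals = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns: {line!r}")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate: {line!r}") from exc
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "."
            name = fields[3] if len(fields) >= 4 else ""
            try:
                intervals.append(GenomicInterval(fields[0], start, end, strand, name))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return PeakSet(intervals)


def write_intervals(path: str | Path, peaks: PeakSet, bed6: bool = False) -> None:
    with open(path, "w") as fh:
        for iv in peaks:
            if bed6:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def load_signal(path: str | Path) -> SignalTrack:
    """Read a 4-column bedGraph into a SignalTrack (gaps are value 0)."""
    segments: dict[str, list[tuple[int, int, float]]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = re.split(r"\s+", line)
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 bedGraph columns: {line!r}")
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed bedGraph line: {line!r}") from exc
            segments.setdefault(fields[0], []).append((start, end, value))
    return SignalTrack(segments)


def write_signal(path: str | Path, track: SignalTrack) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms():
            for start, end, value in track.segments(chrom):
                fh.write(f"{chrom}\t{start}\t{end}\t{value:g}\n")
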