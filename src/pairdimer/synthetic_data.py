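"""Synthetic inputs with known ground truth for every pipeline stage.

Two generators are provided. ``simulate_oligo_pdseq`` emulates degenerate
oligo pull-down sequencing: input reads draw variable regions uniformly,
pull-down reads are drawn from a finite candidate pool with probability
proportional to a planted binding model (multiplicative bonuses for motif
pairs matched at tolerated shifts, or a site-2-only bonus for factors that
ignore site 1). ``simulate_genome`` builds a small genome bundle — FASTA,
foreground/background peak BEDs, blacklist, bedGraph signal, gene BED and a
differential-expression table — with planted paired-motif occurrences,
TnG-repeat tracts, head-to-head sites abutting a subset of repeats in
aligned orientation, occupancy-like signal boosts, and DE statistics
assigned preferentially to genes near planted elements. A truth manifest
records every planted element.

All randomness flows from one master seed through named substreams, so a
fixed seed yields byte-identical bundles.
"""

from __future__ import annotations

import json
import zlib
from collections.abc import Sequence
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .core_seq import (
    GenomicInterval,
    IUPAC_SETS,
    LibraryDesign,
    PeakSet,
    SignalTrack,
    reverse_complement,
    write_fasta,
    write_fastq,
    write_intervals,
    write_signal,
)
from .pair_orientation import pattern_for

__all__ = [
    "BindingModel",
    "GenomeConfig",
    "GenomeBundle",
    "OligoPdseqSim",
    "simulate_oligo_pdseq",
    "simulate_genome",
    "windows_from_sites",
]

_ASCII = np.frombuffer(b"ACGT", dtype=np.uint8)


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Named substream of the master seed (stable across processes)."""
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(zlib.crc32(stream.encode()),))
    )


def _instantiate(pattern: str, rng: np.random.Generator) -> str:
    """Draw one concrete ACGT realisation of an IUPAC pattern."""
    return "".join(
        c if len(IUPAC_SETS[c]) == 1 else rng.choice(sorted(IUPAC_SETS[c])) for c in pattern
    )


# ---------------------------------------------------------------------------
# Oligo PD-seq simulation
# ---------------------------------------------------------------------------

def windows_from_sites(
    site1: np.ndarray,
    site2: np.ndarray | None,
    design: LibraryDesign,
    shifts: Sequence[int],
) -> np.ndarray:
    """Assemble shifted scan windows directly from variable-region codes.

    *site1*/*site2* are (n, len) uint8 base-index arrays (0..3 = ACGT);
    *site2* is None for designs with a fixed site 2. Returns a flat
    (n * n_shifts, width) uint8 ASCII-character array, rows grouped by
    read.
    """
    n = site1.shape[0]
    width = design.site1_len + len(design.gap) + design.site2_length
    template = np.frombuffer(design.template.encode("ascii"), dtype=np.uint8)
    out = np.empty((n, len(shifts), width), dtype=np.uint8)
    for si, s in enumerate(shifts):
        start = design.site1_start + s
        for k in range(width):
            tpos = start + k
            if design.site1_start <= tpos < design.gap_start:
                out[:, si, k] = _ASCII[site1[:, tpos - design.site1_start]]
            elif design.site2 is None and design.site2_start <= tpos < design.nbs2_start:
                out[:, si, k] = _ASCII[site2[:, tpos - design.site2_start]]
            else:
                out[:, si, k] = template[tpos]
    return out.reshape(n * len(shifts), width)


@dataclass
class BindingModel:
    """Multiplicative planted-binding weights for PD sampling.

    A molecule's weight is ``base_weight`` times the bonus of every
    satisfied condition: a pair bonus is satisfied when any tolerated-shift
    window matches the pair's pattern; the site-2-only bonus is satisfied
    when the site-2 region matches the rcFKHM anchor (always true for the
    fixed-site-2 design, making enrichment independent of site 1 — the
    behaviour of factors engaging only the fixed site).
    """

    pair_bonuses: dict[tuple[str, str, str], float] = field(default_factory=dict)
    site2_only_bonus: float = 1.0
    monomer_bonus: float = 1.0
    monomer_motif: str = "TGTTTAC"
    base_weight: float = 1.0
    shifts: tuple[int, ...] = (0,)
    site2_anchor: str = "GTAAACA"

    def __post_init__(self) -> None:
        if (
            any(b < 1.0 for b in self.pair_bonuses.values())
            or self.site2_only_bonus < 1.0
            or self.monomer_bonus < 1.0
        ):
            raise ValueError("bonuses must be >= 1")

    @classmethod
    def dimer_like(cls, pairs: dict[tuple[str, str, str], float] | None = None,
                   shifts: tuple[int, ...] = (0,)) -> "BindingModel":
        """Site-1-dependent head-to-head binder.

        The default plants a relaxed forkhead-like inverted repeat; a
        degenerate motif is used so that the planted pair is realised at a
        workable rate in the 4^14 variable space of the random-random
        design.
        """
        if pairs is None:
            pairs = {("TGTTTNN", "TGTTTNN", "HH"): 300.0}
        return cls(pair_bonuses=pairs, shifts=shifts)

    @classmethod
    def site2_only(cls, bonus: float = 30.0) -> "BindingModel":
        """Binder that engages only the fixed rcFKHM anchor in site 2.

        Meaningful for the fixed-site-2 design, where it makes enrichment
        independent of site 1.
        """
        return cls(site2_only_bonus=bonus)

    @classmethod
    def monomer_like(cls, bonus: float = 30.0, motif: str = "TGTTTAC") -> "BindingModel":
        """Binder that engages any single in-register half-site.

        A molecule gets the bonus when either variable site matches the
        motif or its reverse complement. This is symmetric across the four
        pair orientations, so such a factor shows no orientational bias in
        the random-random library.
        """
        return cls(monomer_bonus=bonus, monomer_motif=motif)


def _weights(
    site1: np.ndarray,
    site2: np.ndarray | None,
    design: LibraryDesign,
    model: BindingModel,
) -> np.ndarray:
    from .pair_orientation import _encode_patterns, _encode_texts  # avoid cycle at import

    n = site1.shape[0]
    w = np.full(n, model.base_weight, dtype=float)
    if model.pair_bonuses:
        windows = windows_from_sites(site1, site2, design, model.shifts)
        w_lo, w_hi = _encode_texts(windows)
        patterns = [
            pattern_for(a, b, o, design.gap) for (a, b, o) in model.pair_bonuses
        ]
        p_lo, p_hi = _encode_patterns(patterns)
        for k, bonus in enumerate(model.pair_bonuses.values()):
            miss = (w_lo & ~p_lo[k]) | (w_hi & ~p_hi[k])
            hit = (miss == 0).reshape(n, len(model.shifts)).any(axis=1)
            w[hit] *= bonus
    if model.site2_only_bonus != 1.0:
        if design.site2 is not None:
            hit2 = np.ones(n, dtype=bool) if design.site2 == model.site2_anchor else np.zeros(n, dtype=bool)
        else:
            anchor = np.array([_ASCII.tolist().index(ord(c)) for c in model.site2_anchor], dtype=np.uint8)
            hit2 = (site2 == anchor[None, :]).all(axis=1)
        w[hit2] *= model.site2_only_bonus
    if model.monomer_bonus != 1.0:
        hit_m = _matches_half_site(site1, model.monomer_motif)
        if site2 is not None:
            hit_m |= _matches_half_site(site2, model.monomer_motif)
        elif design.site2 is not None:
            if _site_matches_pattern(design.site2, model.monomer_motif):
                hit_m |= True
        w[hit_m] *= model.monomer_bonus
    return w


def _site_matches_pattern(site: str, motif: str) -> bool:
    from .core_seq import iupac_match

    return len(site) == len(motif) and (
        iupac_match(motif, site) or iupac_match(reverse_complement(motif), site)
    )


def _matches_half_site(sites: np.ndarray, motif: str) -> np.ndarray:
    """Per-row: does the site match *motif* or its reverse complement?"""
    masks = []
    for pat in (motif, reverse_complement(motif)):
        allowed = np.zeros((len(pat), 4), dtype=bool)
        for j, code in enumerate(pat):
            for b in IUPAC_SETS[code]:
                allowed[j, "ACGT".index(b)] = True
        ok = np.ones(sites.shape[0], dtype=bool)
        for j in range(len(pat)):
            ok &= allowed[j, sites[:, j]]
        masks.append(ok)
    return masks[0] | masks[1]


def _sites_to_strings(arr: np.ndarray) -> list[str]:
    return [bytes(_ASCII[row]).decode("ascii") for row in arr]


@dataclass
class OligoPdseqSim:
    """Simulated input and pull-down read sets plus the planted-truth manifest."""

    design: LibraryDesign
    input_site1: np.ndarray
    input_site2: np.ndarray | None
    pd_site1: np.ndarray
    pd_site2: np.ndarray | None
    manifest: dict

    def _reads(self, s1: np.ndarray, s2: np.ndarray | None) -> list[str]:
        d = self.design
        site2_fixed = d.site2
        out = []
        s1s = _sites_to_strings(s1)
        s2s = _sites_to_strings(s2) if s2 is not None else None
        for i, a in enumerate(s1s):
            b = site2_fixed if s2s is None else s2s[i]
            out.append(d.nbs1 + a + d.gap + b + d.nbs2)
        return out

    def input_reads(self) -> list[str]:
        return self._reads(self.input_site1, self.input_site2)

    def pd_reads(self) -> list[str]:
        return self._reads(self.pd_site1, self.pd_site2)

    def input_site1_seqs(self) -> list[str]:
        return _sites_to_strings(self.input_site1)

    def pd_site1_seqs(self) -> list[str]:
        return _sites_to_strings(self.pd_site1)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fastq(outdir / "input.fastq.gz", self.input_reads())
        write_fastq(outdir / "pd.fastq.gz", self.pd_reads())
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2)


def simulate_oligo_pdseq(
    design: LibraryDesign,
    model: BindingModel,
    n_input: int,
    n_pd: int,
    seed: int,
    pool_factor: int = 10,
) -> OligoPdseqSim:
    """Simulate input and pull-down read sets under a planted binding model.

    Input reads draw variable regions uniformly. Pull-down reads are drawn
    with replacement from a finite candidate pool of ``pool_factor * n_pd``
    distinct molecules (mimicking library bottlenecking) with probability
    proportional to the model weight. Reads carry uniform Phred-30
    qualities when written as FASTQ.
    """
    if n_input <= 0 or n_pd <= 0:
        raise ValueError("n_input and n_pd must be positive")
    variable2 = design.site2 is None
    rng_in = _rng(seed, "oligo_input")
    rng_pool = _rng(seed, "oligo_pool")
    rng_pick = _rng(seed, "oligo_pick")

    input_site1 = rng_in.integers(0, 4, size=(n_input, design.site1_len), dtype=np.uint8)
    input_site2 = (
        rng_in.integers(0, 4, size=(n_input, design.site2_len), dtype=np.uint8) if variable2 else None
    )
    pool_n = pool_factor * n_pd
    pool_site1 = rng_pool.integers(0, 4, size=(pool_n, design.site1_len), dtype=np.uint8)
    pool_site2 = (
        rng_pool.integers(0, 4, size=(pool_n, design.site2_len), dtype=np.uint8) if variable2 else None
    )
    w = _weights(pool_site1, pool_site2, design, model)
    picks = rng_pick.choice(pool_n, size=n_pd, replace=True, p=w / w.sum())
    manifest = {
        "pair_bonuses": {"|".join(k): v for k, v in model.pair_bonuses.items()},
        "site2_only_bonus": model.site2_only_bonus,
        "shifts": list(model.shifts),
        "n_input": n_input,
        "n_pd": n_pd,
        "pool_size": pool_n,
        "seed": seed,
    }
    return OligoPdseqSim(
        design=design,
        input_site1=input_site1,
        input_site2=input_site2,
        pd_site1=pool_site1[picks],
        pd_site2=pool_site2[picks] if variable2 else None,
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# Genome bundle simulation
# ---------------------------------------------------------------------------

@dataclass
class GenomeConfig:
    """Parameters of the synthetic genome bundle.

    The last chromosome carries only background peaks and far-placed genes
    (no foreground peaks), providing unambiguously foreground-free open
    chromatin. Rates are probabilities in [0, 1]; all element placement
    keeps at least ``spacer_min`` background bp between elements.
    """

    n_chromosomes: int = 3
    gc_fraction: float = 0.42
    # peaks
    n_fg_peaks: int = 600
    fg_peak_width: int = 300
    fg_plant_rate: float = 0.9
    pair: tuple[str, str, str] = ("TGTTTAC", "TGTTTAC", "HH")
    fg_gap: int = 4
    n_bg_peaks: int = 2400
    bg_peak_width: int = 300
    bg_plant_rate: float = 0.9
    bg_gap_range: tuple[int, int] = (1, 10)
    free_ocr_fraction: float = 0.25
    # repeats
    n_repeats: int = 120
    short_len: tuple[int, int] = (12, 20)
    long_len: tuple[int, int] = (40, 60)
    repeat_periods: tuple[str, ...] = ("TTG", "TTTG", "TTTTG")
    adjacency_fraction: float = 0.5
    # genes / DE
    n_genes: int = 240
    sig_gene_fraction: float = 0.4
    gene_length: int = 1500
    # signal
    signal_baseline: float = 1.0
    boost_bound_peak: float = 5.0
    boost_long: float = 8.0
    boost_short_with_hh: float = 8.0
    boost_short_alone: float = 2.0
    boost_noise_sd: float = 0.5
    # misc
    n_blacklist: int = 2
    spacer_min: int = 600
    spacer_max: int = 2000
    seed: int = 7

    def __post_init__(self) -> None:
        for rate in (self.fg_plant_rate, self.bg_plant_rate, self.free_ocr_fraction,
                     self.adjacency_fraction, self.sig_gene_fraction):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.n_chromosomes < 2:
            raise ValueError("need at least 2 chromosomes (one is kept foreground-free)")


@dataclass
class GenomeBundle:
    """Everything ``simulate_genome`` produces, in memory."""

    genome: dict[str, str]
    fg_peaks: PeakSet
    bg_peaks: PeakSet
    blacklist: PeakSet
    track: SignalTrack
    genes: list  # list[GeneRecord]
    de: pd.DataFrame
    truth: dict

    def truth_repeat_regions(self) -> list:
        """Planted repeat tracts as RepeatRegion objects (truth coordinates)."""
        from .repeats_adjacency import RepeatRegion

        return [
            RepeatRegion(
                GenomicInterval(r["chrom"], r["start"], r["end"], r["strand"]),
                strand=r["strand"],
                length_bp=r["end"] - r["start"],
                n_matches=1,
                best_score=0.0,
                best_p_value=1.0,
            )
            for r in self.truth["repeats"]
        ]

    def truth_hh_intervals(self) -> list[GenomicInterval]:
        """Planted head-to-head sites as plus-strand intervals."""
        return [
            GenomicInterval(h["chrom"], h["start"], h["end"], "+")
            for h in self.truth["hh_sites"]
        ]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(outdir / "genome.fa", self.genome)
        write_intervals(outdir / "fg.bed", self.fg_peaks)
        write_intervals(outdir / "bg.bed", self.bg_peaks)
        write_intervals(outdir / "blacklist.bed", self.blacklist)
        write_signal(outdir / "signal.bedGraph", self.track)
        with open(outdir / "genes.bed", "w") as fh:
            for g in self.genes:
                iv = g.interval
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{g.gene_id}\t0\t{iv.strand}\n")
        self.de.to_csv(outdir / "de.tsv", sep="\t", index=False)
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=2)


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return bytes(_ASCII[rng.choice(4, size=n, p=p)]).decode("ascii")


class _ChromBuilder:
    """Appends sequence chunks left to right, tracking coordinates."""

    def __init__(self, rng: np.random.Generator, gc: float, spacer: tuple[int, int]):
        self.rng = rng
        self.gc = gc
        self.spacer = spacer
        self.chunks: list[str] = []
        self.cursor = 0

    def add_spacer(self) -> None:
        n = int(self.rng.integers(self.spacer[0], self.spacer[1] + 1))
        self.chunks.append(_random_seq(self.rng, n, self.gc))
        self.cursor += n

    def add(self, seq: str) -> int:
        """Append *seq*; return its start coordinate."""
        start = self.cursor
        self.chunks.append(seq)
        self.cursor += len(seq)
        return start

    def sequence(self) -> str:
        return "".join(self.chunks)


def simulate_genome(config: GenomeConfig) -> GenomeBundle:
    """Build the synthetic genome bundle described by *config*.

    See the module docstring for what is planted; ``truth`` records every
    planted element with coordinates.
    """
    from .gene_proximity import GeneRecord  # avoid import cycle

    seed = config.seed
    rng_layout = _rng(seed, "genome_layout")
    rng_seq = _rng(seed, "genome_sequence")
    rng_sig = _rng(seed, "genome_signal")
    rng_de = _rng(seed, "genome_de")

    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    free_chrom = chrom_names[-1]
    shared = chrom_names[:-1]

    # --- element descriptors -------------------------------------------------
    n_free = int(round(config.free_ocr_fraction * config.n_bg_peaks))
    descriptors: dict[str, list[tuple]] = {c: [] for c in chrom_names}
    shared_elems: list[tuple] = []
    for i in range(config.n_fg_peaks):
        shared_elems.append(("fg_peak", i))
    for i in range(config.n_bg_peaks - n_free):
        shared_elems.append(("bg_peak", i))
    for i in range(config.n_repeats):
        shared_elems.append(("repeat", i))
    order = rng_layout.permutation(len(shared_elems))
    for k, idx in enumerate(order):
        descriptors[shared[k % len(shared)]].append(shared_elems[idx])
    n_nonsig = config.n_genes - int(round(config.sig_gene_fraction * config.n_genes))
    for i in range(n_free):
        descriptors[free_chrom].append(("bg_peak", (config.n_bg_peaks - n_free) + i))
    for i in range(n_nonsig):
        descriptors[free_chrom].append(("nonsig_gene", i))

    pair_a, pair_b, pair_o = config.pair
    genome: dict[str, str] = {}
    fg_peaks: list[GenomicInterval] = []
    bg_peaks: list[GenomicInterval] = []
    fg_plants: list[dict] = []
    bg_plants: list[dict] = []
    repeats: list[dict] = []
    hh_sites: list[dict] = []
    nonsig_gene_pos: list[tuple[str, int, int]] = []
    boosts: dict[str, list[tuple[int, int, float]]] = {c: [] for c in chrom_names}

    def _plant_in_peak(width: int, gap: int) -> tuple[str, int]:
        pattern = pattern_for(pair_a, pair_b, pair_o, "N" * gap)
        inst = _instantiate(pattern, rng_seq)
        off = int(rng_seq.integers(10, width - len(inst) - 10))
        return inst, off

    def _noisy(value: float) -> float:
        return max(0.1, value + float(rng_sig.normal(0.0, config.boost_noise_sd)))

    for chrom in chrom_names:
        builder = _ChromBuilder(rng_seq, config.gc_fraction, (config.spacer_min, config.spacer_max))
        for kind, idx in descriptors[chrom]:
            builder.add_spacer()
            if kind in ("fg_peak", "bg_peak"):
                width = config.fg_peak_width if kind == "fg_peak" else config.bg_peak_width
                rate = config.fg_plant_rate if kind == "fg_peak" else config.bg_plant_rate
                seq = _random_seq(rng_seq, width, config.gc_fraction)
                plant = None
                if rng_seq.random() < rate:
                    gap = (
                        config.fg_gap
                        if kind == "fg_peak"
                        else int(rng_seq.integers(config.bg_gap_range[0], config.bg_gap_range[1] + 1))
                    )
                    inst, off = _plant_in_peak(width, gap)
                    seq = seq[:off] + inst + seq[off + len(inst) :]
                    plant = (off, gap, len(inst))
                start = builder.add(seq)
                iv = GenomicInterval(chrom, start, start + width)
                if kind == "fg_peak":
                    fg_peaks.append(iv)
                    boosts[chrom].append((start, start + width, _noisy(config.boost_bound_peak)))
                else:
                    bg_peaks.append(iv)
                if plant is not None:
                    off, gap, plen = plant
                    rec = {
                        "chrom": chrom, "start": start + off, "end": start + off + plen,
                        "gap": gap, "orientation": pair_o, "peak_kind": kind, "peak_index": idx,
                    }
                    (fg_plants if kind == "fg_peak" else bg_plants).append(rec)
                    if kind == "fg_peak" and pair_o == "HH":
                        hh_sites.append({"chrom": chrom, "start": start + off,
                                         "end": start + off + plen, "source": "fg_peak"})
            elif kind == "repeat":
                is_short = idx % 2 == 0
                lo, hi = config.short_len if is_short else config.long_len
                length = int(rng_seq.integers(lo, hi + 1))
                period = config.repeat_periods[int(rng_seq.integers(0, len(config.repeat_periods)))]
                tng = (period * (length // len(period) + 1))[:length]
                strand = "+" if rng_seq.random() < 0.5 else "-"
                tract = tng if strand == "+" else reverse_complement(tng)
                has_hh = rng_seq.random() < config.adjacency_fraction
                hh_seq = "TGTTTAC" + _random_seq(rng_seq, 4, 0.5) + "GTAAACA"
                if has_hh and strand == "+":
                    block, r_off, h_off = tract + hh_seq, 0, length
                elif has_hh:
                    block, r_off, h_off = hh_seq + tract, len(hh_seq), 0
                else:
                    block, r_off, h_off = tract, 0, None
                start = builder.add(block)
                repeats.append({
                    "chrom": chrom, "start": start + r_off, "end": start + r_off + length,
                    "strand": strand, "length": length,
                    "cls": "short" if is_short else "long", "has_hh": has_hh,
                })
                if h_off is not None:
                    hh_sites.append({"chrom": chrom, "start": start + h_off,
                                     "end": start + h_off + len(hh_seq), "source": "repeat_adjacent"})
                if is_short and has_hh:
                    boost = config.boost_short_with_hh
                elif is_short:
                    boost = config.boost_short_alone
                else:
                    boost = config.boost_long
                b_lo = max(0, start - 120)
                boosts[chrom].append((b_lo, start + len(block) + 120, _noisy(boost)))
            elif kind == "nonsig_gene":
                start = builder.add(_random_seq(rng_seq, config.gene_length, config.gc_fraction))
                nonsig_gene_pos.append((chrom, start, start + config.gene_length))
        builder.add_spacer()
        genome[chrom] = builder.sequence()

    # --- blacklist: cover the first n fg peaks -------------------------------
    blacklist_ivs = []
    blacklisted = []
    for k in range(min(config.n_blacklist, len(fg_peaks))):
        p = fg_peaks[k]
        blacklist_ivs.append(GenomicInterval(p.chrom, max(0, p.start - 50), p.end + 50))
        blacklisted.append(k)

    # --- signal track --------------------------------------------------------
    segments: dict[str, list[tuple[int, int, float]]] = {}
    for chrom in chrom_names:
        L = len(genome[chrom])
        segs: list[tuple[int, int, float]] = []
        cursor = 0
        for lo, hi, boost in sorted(boosts[chrom]):
            lo, hi = max(lo, cursor), min(hi, L)
            if hi <= lo:
                continue
            if lo > cursor:
                segs.append((cursor, lo, config.signal_baseline))
            segs.append((lo, hi, config.signal_baseline + boost))
            cursor = hi
        if cursor < L:
            segs.append((cursor, L, config.signal_baseline))
        segments[chrom] = segs
    track = SignalTrack(segments)

    # --- OCR bound/free classification ---------------------------------------
    fg_by_chrom: dict[str, list[GenomicInterval]] = {}
    for p in fg_peaks:
        fg_by_chrom.setdefault(p.chrom, []).append(p)
    ocr_free, ocr_bound = [], []
    for i, ocr in enumerate(bg_peaks):
        dists = [
            max(p.start - ocr.end, ocr.start - p.end, 0) for p in fg_by_chrom.get(ocr.chrom, [])
        ]
        if dists and min(dists) < 10_000:
            ocr_bound.append(i)
        elif not dists:
            ocr_free.append(i)

    # --- genes and DE table --------------------------------------------------
    anchors = [(r["chrom"], r["start"], r["end"]) for r in repeats] + [
        (h["chrom"], h["start"], h["end"]) for h in hh_sites
    ]
    n_sig = config.n_genes - len(nonsig_gene_pos) if anchors else 0
    genes: list[GeneRecord] = []
    de_rows = []
    anchor_idx = (
        rng_de.choice(len(anchors), size=n_sig, replace=len(anchors) < n_sig) if n_sig else []
    )
    for g in range(n_sig):
        chrom, a_start, a_end = anchors[int(anchor_idx[g])]
        offset = int(rng_de.integers(100, 901))
        start = a_end + offset
        iv = GenomicInterval(chrom, start, start + config.gene_length, "+")
        padj = float(10 ** rng_de.uniform(-8, np.log10(0.049)))
        sign = 1.0 if rng_de.random() < 0.8 else -1.0
        lfc = float(sign * max(0.1, rng_de.normal(1.5, 0.5)))
        genes.append(GeneRecord(f"sig_gene_{g}", iv, lfc, padj))
        de_rows.append((f"sig_gene_{g}", lfc, padj))
    for g, (chrom, start, end) in enumerate(nonsig_gene_pos):
        iv = GenomicInterval(chrom, start, end, "+")
        padj = float(rng_de.uniform(0.05, 1.0))
        lfc = float(rng_de.normal(0.0, 0.3))
        genes.append(GeneRecord(f"ns_gene_{g}", iv, lfc, padj))
        de_rows.append((f"ns_gene_{g}", lfc, padj))
    de = pd.DataFrame(de_rows, columns=["gene", "log2fc", "padj"])

    truth = {
        "config": {k: v for k, v in asdict(config).items()},
        "pair": list(config.pair),
        "fg_plants": fg_plants,
        "bg_plants": bg_plants,
        "repeats": repeats,
        "hh_sites": hh_sites,
        "ocr_free": ocr_free,
        "ocr_bound": ocr_bound,
        "blacklisted_fg": blacklisted,
        "chromosomes": {c: len(genome[c]) for c in genome},
        "free_chromosome": free_chrom,
    }
    return GenomeBundle(
        genome=genome,
        fg_peaks=PeakSet(fg_peaks),
        bg_peaks=PeakSet(bg_peaks),
        blacklist=PeakSet(blacklist_ivs),
        track=track,
        genes=genes,
        de=de,
        truth=truth,
    )
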