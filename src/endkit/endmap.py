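"""Post-alignment processing of 5'-end reads into weighted signal tracks.

Four concerns live here:

* a sequence-complexity filter that removes low-complexity reads before they
  can pile up at repetitive loci;
* capture of upstream untemplated nucleotides (uuN) soft-clipped from the
  read 5' end — an untemplated G adjacent to the genome match (uuG) is the
  signature of reverse transcription across a 7-methylguanosine cap;
* an optional k-mer bias model that reweights reads by the sequence context
  of their 5' ends;
* a "rich-get-richer" rescue of multimapping reads that assigns each read
  fractionally to its candidate loci in proportion to coverage already
  assigned there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .core_io import EndReadAlignment, EndSignalTrack, GenomeIndex, TranscriptModel

MAX_MULTIPLICITY = 100


# ---------------------------------------------------------------------------
# Complexity filter
# ---------------------------------------------------------------------------

def i_complexity(seq: str) -> float:
    """Substring-growth complexity of a sequence.

    For each position i (1-based) let d_i be the number of distinct substrings
    ending at i that do not occur ending at any earlier position; d_i equals
    i minus the length of the longest suffix of ``seq[:i]`` that also occurs
    ending earlier in the sequence.  The complexity is sum(log4(d_i)).
    A homopolymer gains one new substring per position (d_i = 1) and scores 0;
    a random sequence grows nearly i new substrings per position and scores
    on the order of ``n*log4(n)``.
    """
    if not seq:
        raise ValueError("empty sequence")
    n = len(seq)
    total = 0.0
    for i in range(1, n + 1):
        # longest L with seq[i-L:i] occurring ending at some j < i,
        # i.e. occurring as a substring of seq[:i-1]
        lo, hi = 0, i - 1  # feasible L is monotone: find the largest feasible
        while lo < hi:
            mid = (lo + hi + 1) // 2
            if seq[i - mid : i] in seq[: i - 1]:
                lo = mid
            else:
                hi = mid - 1
        total += math.log(i - lo, 4)
    return total


def complexity_filter(read_sequence: str, threshold: float = 0.15) -> bool:
    """True = keep the read; False = discard as low complexity.

    The per-nucleotide score is ``i_complexity(seq)/len(seq)``; reads scoring
    below ``threshold`` are discarded.
    """
    if not read_sequence:
        raise ValueError("empty read sequence")
    return i_complexity(read_sequence) / len(read_sequence) >= threshold


# ---------------------------------------------------------------------------
# uuG
# ---------------------------------------------------------------------------

def extract_uug(read: EndReadAlignment) -> bool:
    """True iff the soft-clipped base immediately adjacent to the aligned 5'
    end is an (untemplated) G.  Additional clipped bases further upstream —
    typically template-switch-oligo remnants — are ignored."""
    return bool(read.uun) and read.uun[-1] == "G"


# ---------------------------------------------------------------------------
# k-mer bias model
# ---------------------------------------------------------------------------

@dataclass
class KmerBiasModel:
    """Sequence-context reweighting of read 5' ends.

    The context of a read is the genomic k-mer covering offsets
    ``window[0]..window[0]+k-1`` relative to the 5'-end position, read in cDNA
    sense.  Observed frequencies come from exonic read 5' ends with the depth
    at each genomic position clipped to 1 (RNA coverage is not expected to be
    uniform); background frequencies come from every annotated exonic
    position.  A read's weight is background/observed for its context,
    clipped to ``cap_bounds``.
    """

    k: int
    window_start: int
    observed: Dict[str, float] = field(default_factory=dict)
    background: Dict[str, float] = field(default_factory=dict)
    cap_bounds: Tuple[float, float] = (0.1, 10.0)

    def weight(self, context: str) -> float:
        obs = self.observed.get(context, 0.0)
        bg = self.background.get(context, 0.0)
        if obs <= 0.0 or bg <= 0.0:
            return 1.0
        lo, hi = self.cap_bounds
        return float(min(max(bg / obs, lo), hi))

    def weight_for_read(self, read: EndReadAlignment, genome: GenomeIndex) -> float:
        return self.weight(read_context(read, genome, self.k, self.window_start))


def read_context(read: EndReadAlignment, genome: GenomeIndex, k: int, window_start: int) -> str:
    """Genomic k-mer context of a read 5' end in cDNA sense.

    ``window_start`` is the offset (in cDNA sense) of the first context base
    relative to the 5'-end position (negative = upstream of the read).
    """
    p = read.five_prime_pos
    if read.strand == "+":
        return genome.sequence(read.chrom, p + window_start, p + window_start + k, "+")
    return genome.sequence(read.chrom, p - window_start - k + 1, p - window_start + 1, "-")


def fit_bias_model(
    reads: List[EndReadAlignment],
    transcripts: List[TranscriptModel],
    genome: GenomeIndex,
    k: int = 6,
    window_start: int = -3,
    cap_bounds: Tuple[float, float] = (0.1, 10.0),
) -> KmerBiasModel:
    """Fit the k-mer frequency model from exonic read 5' ends.

    Only reads falling inside annotated exons contribute, and stacked reads
    at one genomic position count once (depth clipped to 1).
    """
    exonic: Dict[Tuple[str, str], List[Tuple[int, int]]] = {}
    for t in transcripts:
        exonic.setdefault((t.chrom, t.strand), []).extend(t.exons)

    def in_exon(chrom: str, strand: str, pos: int) -> bool:
        return any(a <= pos < b for a, b in exonic.get((chrom, strand), ()))

    observed: Dict[str, float] = {}
    seen_positions = set()
    n_obs = 0
    for r in reads:
        key = (r.chrom, r.strand, r.five_prime_pos)
        if key in seen_positions or not in_exon(r.chrom, r.strand, r.five_prime_pos):
            continue
        seen_positions.add(key)
        ctx = read_context(r, genome, k, window_start)
        if "N" in ctx or len(ctx) < k:
            continue
        observed[ctx] = observed.get(ctx, 0.0) + 1.0
        n_obs += 1
    if n_obs == 0:
        raise ValueError("no exonic reads available to fit the bias model")

    background: Dict[str, float] = {}
    n_bg = 0
    for (chrom, strand), intervals in exonic.items():
        covered = set()
        for a, b in intervals:
            covered.update(range(a, b))
        for pos in covered:
            if strand == "+":
                ctx = genome.sequence(chrom, pos + window_start, pos + window_start + k, "+")
            else:
                ctx = genome.sequence(chrom, pos - window_start - k + 1, pos - window_start + 1, "-")
            if "N" in ctx or len(ctx) < k:
                continue
            background[ctx] = background.get(ctx, 0.0) + 1.0
            n_bg += 1
    for d, n in ((observed, n_obs), (background, n_bg)):
        for key in d:
            d[key] /= n
    return KmerBiasModel(k=k, window_start=window_start, observed=observed,
                         background=background, cap_bounds=cap_bounds)


# ---------------------------------------------------------------------------
# Multimapper rescue
# ---------------------------------------------------------------------------

def rescue_multimappers(
    reads: List[EndReadAlignment],
    chrom_order: Optional[List[str]] = None,
) -> Dict[str, int]:
    """Assign fractional weights to multimapping reads in place.

    Uniquely mapping reads keep weight 1 and seed a per-position coverage
    map.  Multimappers are processed in multiplicity bins 2..100; within a
    bin reads are sorted from lowest genomic position to highest (chromosome
    order, then minimum candidate position, then read id for determinism).
    A read whose candidate locations carry any existing coverage is assigned
    proportionally, ``P_i = C_i / sum_j C_j``, and its assignment immediately
    updates coverage for subsequent reads; the bin is re-swept until a full
    pass assigns nothing, after which the still-ambiguous leftovers get
    ``P_i = 1/n``.  Reads with multiplicity > 100 are discarded (weight 0).

    Returns a stats dict (unique reads, rescued reads, discarded reads).
    """
    if chrom_order is None:
        chrom_order = sorted({r.chrom for r in reads})
    chrom_rank = {c: i for i, c in enumerate(chrom_order)}

    coverage: Dict[Tuple[str, str, int], float] = {}
    by_read: Dict[str, List[EndReadAlignment]] = {}
    stats = {"unique": 0, "rescued": 0, "discarded": 0}
    for r in reads:
        if r.multiplicity <= 1:
            r.weight = 1.0
            key = (r.chrom, r.strand, r.five_prime_pos)
            coverage[key] = coverage.get(key, 0.0) + 1.0
            stats["unique"] += 1
        else:
            by_read.setdefault(r.read_id, []).append(r)

    def sort_key(group: List[EndReadAlignment]):
        lo = min((chrom_rank[c], p) for c, _, p in group[0].candidate_locations)
        return (lo[0], lo[1], group[0].read_id)

    bins: Dict[int, List[List[EndReadAlignment]]] = {}
    for group in by_read.values():
        bins.setdefault(group[0].multiplicity, []).append(group)

    for mult in sorted(bins):
        if mult > MAX_MULTIPLICITY:
            for group in bins[mult]:
                for rec in group:
                    rec.weight = 0.0
                stats["discarded"] += 1
            continue
        pending = sorted(bins[mult], key=sort_key)
        while pending:
            leftover: List[List[EndReadAlignment]] = []
            assigned_any = False
            for group in pending:
                c = [coverage.get((rec.chrom, rec.strand, rec.five_prime_pos), 0.0) for rec in group]
                total = sum(c)
                if total > 0.0:
                    for rec, ci in zip(group, c):
                        rec.weight = ci / total
                        key = (rec.chrom, rec.strand, rec.five_prime_pos)
                        coverage[key] = coverage.get(key, 0.0) + rec.weight
                    assigned_any = True
                    stats["rescued"] += 1
                else:
                    leftover.append(group)
            if not assigned_any:
                break
            pending = leftover
        for group in pending:  # still ambiguous: equal weighting
            n = len(group)
            for rec in group:
                rec.weight = 1.0 / n
                key = (rec.chrom, rec.strand, rec.five_prime_pos)
                coverage[key] = coverage.get(key, 0.0) + rec.weight
            stats["rescued"] += 1
        bins[mult] = []
    return stats


# ---------------------------------------------------------------------------
# Track building
# ---------------------------------------------------------------------------

def build_tracks(
    reads: List[EndReadAlignment],
    bias_model: Optional[KmerBiasModel] = None,
    genome: Optional[GenomeIndex] = None,
    stranded: bool = True,
) -> Tuple[EndSignalTrack, EndSignalTrack]:
    """Accumulate weighted read 5' ends into (signal track, uuG-only track).

    Each read contributes ``rescue_weight * bias_weight`` at its 5' position.
    """
    if bias_model is not None and genome is None:
        raise ValueError("bias correction requires the genome sequence")
    track = EndSignalTrack(stranded=stranded)
    uug_track = EndSignalTrack(stranded=stranded)
    for r in reads:
        w = r.weight
        if w <= 0.0:
            continue
        if bias_model is not None:
            w *= bias_model.weight_for_read(r, genome)
        track.add(r.chrom, r.strand, r.five_prime_pos, w)
        if extract_uug(r):
            uug_track.add(r.chrom, r.strand, r.five_prime_pos, w)
    return track, uug_track
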