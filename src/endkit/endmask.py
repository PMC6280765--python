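"""Transcript-coordinate 5P signal with capped regions masked out.

Downstream cleavage-site statistics operate on transcript-level tracks in
which (a) each gene is represented by its dominant isoform (the isoform with
the most BODY reads in its exons), (b) 5P reads inside replicable capped
features have been discarded — those are transcription start sites, not
cleavage products — and (c) genomic positions are re-expressed as spliced
offsets from the dominant isoform's 5' start.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .core_io import EndFeature, EndSignalTrack, TranscriptModel


@dataclass
class TranscriptTrack:
    """Weighted 5P counts on spliced transcript coordinates (sense strand)."""

    transcript_id: str
    length: int
    values: Dict[int, float] = field(default_factory=dict)
    masked_mass: float = 0.0

    def add(self, offset: int, weight: float) -> None:
        if not 0 <= offset < self.length:
            raise IndexError(f"offset {offset} outside transcript {self.transcript_id}")
        self.values[offset] = self.values.get(offset, 0.0) + weight

    @property
    def total_mass(self) -> float:
        return float(sum(self.values.values()))

    def dense(self) -> np.ndarray:
        arr = np.zeros(self.length, dtype=np.float64)
        for off, w in self.values.items():
            arr[off] = w
        return arr


def dominant_isoform(
    isoforms: List[TranscriptModel], body_track: EndSignalTrack
) -> TranscriptModel:
    """Isoform with the greatest weighted BODY read mass in its exons.

    Ties break to the longer isoform, then lexicographic transcript id.
    """
    if not isoforms:
        raise ValueError("gene has no isoforms")

    def key(t: TranscriptModel):
        mass = sum(body_track.mass_in(t.chrom, t.strand, a, b) for a, b in t.exons)
        return (-mass, -t.length, t.transcript_id)

    return min(isoforms, key=key)


def cap_mask(
    track: EndSignalTrack, capped_features: List[EndFeature]
) -> Tuple[EndSignalTrack, float]:
    """Discard all 5P signal inside capped features; report removed mass."""
    intervals: Dict[Tuple[str, str], List[Tuple[int, int]]] = {}
    for f in capped_features:
        intervals.setdefault((f.chrom, f.strand), []).append((f.start, f.end))
    for v in intervals.values():
        v.sort()
    out = EndSignalTrack(stranded=track.stranded)
    removed = 0.0
    for chrom, strand in track.keys():
        ivs = intervals.get((chrom, strand), [])
        starts = np.array([a for a, _ in ivs], dtype=np.int64)
        ends = np.array([b for _, b in ivs], dtype=np.int64)
        for pos, w in track.positions(chrom, strand).items():
            i = np.searchsorted(starts, pos, side="right") - 1
            if i >= 0 and pos < ends[i]:
                removed += w
            else:
                out.add(chrom, strand, pos, w)
    return out, removed


def project_to_transcript(
    track: EndSignalTrack, transcript: TranscriptModel
) -> TranscriptTrack:
    """Map sense-strand genomic 5P signal to spliced offsets from the
    transcript 5' start; intronic and intergenic signal is dropped."""
    tt = TranscriptTrack(transcript_id=transcript.transcript_id, length=transcript.length)
    d = track.positions(transcript.chrom, transcript.strand)
    exon_starts = np.array([a for a, _ in transcript.exons], dtype=np.int64)
    exon_ends = np.array([b for _, b in transcript.exons], dtype=np.int64)
    cum = np.concatenate([[0], np.cumsum(exon_ends - exon_starts)])
    for pos, w in d.items():
        if pos < transcript.start or pos >= transcript.end:
            continue
        i = int(np.searchsorted(exon_starts, pos, side="right")) - 1
        if i < 0 or pos >= exon_ends[i]:
            continue  # intronic
        plus_off = int(cum[i]) + (pos - int(exon_starts[i]))
        off = plus_off if transcript.strand == "+" else transcript.length - 1 - plus_off
        tt.add(off, w)
    return tt


def masked_transcript_tracks(
    track: EndSignalTrack,
    capped_features: List[EndFeature],
    transcripts_by_gene: Dict[str, List[TranscriptModel]],
    body_track: EndSignalTrack,
) -> Dict[str, TranscriptTrack]:
    """Cap-mask the 5P track, then project onto each gene's dominant isoform.

    Returns ``{gene_id: TranscriptTrack}``; each track's ``masked_mass``
    records the capped-feature mass removed from that isoform's exons.
    """
    masked, _ = cap_mask(track, capped_features)
    out: Dict[str, TranscriptTrack] = {}
    for gene_id, isoforms in transcripts_by_gene.items():
        dom = dominant_isoform(isoforms, body_track)
        tt = project_to_transcript(masked, dom)
        pre = project_to_transcript(track, dom)
        tt.masked_mass = pre.total_mass - tt.total_mass
        out[gene_id] = tt
    return out


def cleavage_proportion(cleaved: float, capped: float) -> Optional[float]:
    """Cleaved / (cleaved + capped); None when both signals are zero."""
    if cleaved < 0 or capped < 0:
        raise ValueError("counts must be >= 0")
    total = cleaved + capped
    if total == 0:
        return None
    return cleaved / total
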