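"""End-to-end orchestration: SAM pairs -> features -> cap calls -> cleavage tests.

These helpers wire the individual stages together the way a whole experiment
is processed: each replicate's 5P/BODY SAM pair becomes signal tracks and
per-replicate features; replicates are merged and classified; the cap-masked
5P signal is projected onto dominant isoforms; and the cleavage-site test
runs against the transcript-level tracks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import pandas as pd

from .core_io import (
    EndFeature,
    EndSignalTrack,
    GenomeIndex,
    TranscriptModel,
    estimate_tpm,
    pool_tracks,
    read_alignments,
)
from .endclass import classify_features, merge_replicable
from .endcut import run_endcut
from .endgraph import DEFAULT_TSO, KdeConfig, LibraryStats, call_features
from .endmap import build_tracks, rescue_multimappers
from .endmask import TranscriptTrack, dominant_isoform, masked_transcript_tracks


@dataclass
class ReplicateResult:
    """Signal tracks, library stats and per-replicate features for one pair."""

    track: EndSignalTrack
    uug_track: EndSignalTrack
    body_track: EndSignalTrack
    stats: LibraryStats
    features: List[EndFeature]


def process_replicate(
    path_5p: str,
    path_body: str,
    genome: GenomeIndex,
    transcripts: List[TranscriptModel],
    fragment_length: float = 500.0,
    tso_sequence: str = DEFAULT_TSO,
    kde_cfg: Optional[KdeConfig] = None,
) -> ReplicateResult:
    """Run the per-replicate half of the pipeline on one 5P/BODY SAM pair."""
    reads5, _ = read_alignments(path_5p, "5P", genome)
    rescue_multimappers(reads5, chrom_order=genome.chrom_names)
    track, uug_track = build_tracks(reads5)
    readsb, _ = read_alignments(path_body, "BODY", genome)
    rescue_multimappers(readsb, chrom_order=genome.chrom_names)
    body_track, _ = build_tracks(readsb, stranded=False)
    estimate_tpm(transcripts, body_track)
    stats = LibraryStats(
        mean_fragment_length=fragment_length,
        total_body_reads=body_track.total_mass,
        total_5p_reads=track.total_mass,
    )
    features = call_features(
        track, body_track, transcripts, genome, stats,
        uug_track=uug_track, tso_sequence=tso_sequence, cfg=kde_cfg,
    )
    return ReplicateResult(track=track, uug_track=uug_track, body_track=body_track,
                           stats=stats, features=features)


def merge_and_classify(
    replicates: List[ReplicateResult],
    min_support: int = 2,
    uug_threshold: float = 0.10,
) -> List[EndFeature]:
    """Merge replicable features across replicates and classify cap status
    from the pooled (pre-masking) uuG and signal tracks."""
    pooled = pool_tracks([r.track for r in replicates])
    pooled_uug = pool_tracks([r.uug_track for r in replicates])
    merged = merge_replicable(
        [r.features for r in replicates], min_support=min_support,
        pooled_track=pooled, pooled_uug_track=pooled_uug,
    )
    return classify_features(merged, uug_threshold=uug_threshold)


def endcut_inputs(
    track: EndSignalTrack,
    merged_features: List[EndFeature],
    transcripts: List[TranscriptModel],
    body_track: EndSignalTrack,
    genome: GenomeIndex,
) -> Tuple[Dict[str, str], Dict[str, TranscriptTrack]]:
    """Cap-masked transcript tracks and spliced sequences, keyed by the
    dominant isoform's transcript id (one per gene)."""
    by_gene: Dict[str, List[TranscriptModel]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    capped = [f for f in merged_features if f.cap_class == "capped"]
    gene_tracks = masked_transcript_tracks(track, capped, by_gene, body_track)
    seqs: Dict[str, str] = {}
    tx_tracks: Dict[str, TranscriptTrack] = {}
    for gene_id, tt in gene_tracks.items():
        dom = dominant_isoform(by_gene[gene_id], body_track)
        seqs[dom.transcript_id] = dom.spliced_sequence(genome)
        tx_tracks[dom.transcript_id] = tt
    return seqs, tx_tracks


def run_cleavage_analysis(
    srnas: Dict[str, str],
    replicate: ReplicateResult,
    merged_features: List[EndFeature],
    transcripts: List[TranscriptModel],
    genome: GenomeIndex,
    n_shuffles: int = 1000,
    seed: int = 1,
    **endcut_kwargs,
) -> pd.DataFrame:
    """Cleavage-site calls for one library against merged capped features."""
    seqs, tx_tracks = endcut_inputs(
        replicate.track, merged_features, transcripts, replicate.body_track, genome
    )
    return run_endcut(
        srnas, seqs, tx_tracks,
        total_transcriptome_reads=replicate.track.total_mass,
        n_shuffles=n_shuffles, seed=seed, **endcut_kwargs,
    )
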