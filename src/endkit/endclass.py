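"""Merge per-replicate 5'-end features and classify them as capped/noncapped.

Replicate merging is positional: a genomic position is retained when features
from at least ``min_support`` distinct replicates (same strand) cover it, and
maximal retained runs become merged features.  Cap classification pools reads
across all replicates of a sample type: a feature is "capped" when at least
10% of the pooled reads inside it carry an upstream untemplated G (uuG), the
sequence signature left by reverse transcription across an m7G cap.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Tuple

import numpy as np

from .core_io import EndFeature, EndSignalTrack


def merge_replicable(
    replicates: List[List[EndFeature]],
    min_support: int = 2,
    pooled_track: Optional[EndSignalTrack] = None,
    pooled_uug_track: Optional[EndSignalTrack] = None,
) -> List[EndFeature]:
    """Positions covered by >= min_support replicates become merged features.

    Counts are re-aggregated over the merged intervals from the pooled
    (all-replicate) tracks when provided.  Raises if fewer than two
    replicates are supplied.
    """
    if len(replicates) < 2:
        raise ValueError("replicate merging requires at least 2 replicates")
    events: Dict[Tuple[str, str], List[Tuple[int, int]]] = {}
    for rep in replicates:
        for f in rep:
            ev = events.setdefault((f.chrom, f.strand), [])
            ev.append((f.start, +1))
            ev.append((f.end, -1))
    merged: List[EndFeature] = []
    for (chrom, strand), ev in sorted(events.items()):
        # coverage sweep; a replicate contributes at most depth 1 per position
        # only if its own features are disjoint, which extract_features
        # guarantees (maximal runs are separated by >= 1 position)
        ev.sort()
        depth = 0
        run_start = None
        segments: List[Tuple[int, int]] = []
        i = 0
        while i < len(ev):
            pos = ev[i][0]
            while i < len(ev) and ev[i][0] == pos:
                depth += ev[i][1]
                i += 1
            if depth >= min_support and run_start is None:
                run_start = pos
            elif depth < min_support and run_start is not None:
                segments.append((run_start, pos))
                run_start = None
        support_by_segment = []
        for start, end in segments:
            # replicate support: number of replicates with any feature overlap
            support = sum(
                any(f.chrom == chrom and f.strand == strand and f.start < end and f.end > start
                    for f in rep)
                for rep in replicates
            )
            support_by_segment.append(support)
        for (start, end), support in zip(segments, support_by_segment):
            rc = pooled_track.mass_in(chrom, strand, start, end) if pooled_track else 0.0
            ug = pooled_uug_track.mass_in(chrom, strand, start, end) if pooled_uug_track else 0.0
            merged.append(
                EndFeature(chrom=chrom, strand=strand, start=start, end=end,
                           read_count=rc, uug_count=min(ug, rc), support=support)
            )
    return merged


def classify_cap(feature: EndFeature, uug_threshold: float = 0.10) -> str:
    """"capped" iff pooled uuG fraction >= threshold (boundary inclusive);
    "noncapped" otherwise; "unclassified" when the feature holds no reads."""
    if feature.read_count <= 0:
        feature.cap_class = "unclassified"
    elif feature.uug_count / feature.read_count >= uug_threshold:
        feature.cap_class = "capped"
    else:
        feature.cap_class = "noncapped"
    return feature.cap_class


def classify_features(features: List[EndFeature], uug_threshold: float = 0.10) -> List[EndFeature]:
    for f in features:
        classify_cap(f, uug_threshold)
    return features
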