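"""Data model and format I/O shared by the whole 5'-end analysis pipeline.

Coordinate conventions
----------------------
All internal coordinates are 0-based half-open intervals on a named
chromosome, with strand in ``{'+', '-'}``.  Gene-body (BODY) libraries are
non-stranded: their signal is stored under the pseudo-strand ``'.'`` and a
stranded consumer sees the same values on both strands.

A "5P" library is a stranded 5'-end library in which each read marks the 5'
terminus of a cDNA (template-switching 5'-capture protocols); a "BODY"
library is a non-stranded full-length cDNA library (Smart-seq2) made from the
same sample.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pysam

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: File suffix used for each strand of a per-position signal track.
STRAND_SUFFIX = {"+": ".plus.bedgraph", "-": ".minus.bedgraph", ".": ".unstranded.bedgraph"}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA sequence (keeps N; case-insensitive input)."""
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeIndex:
    """Random-access genome sequence with strand-aware slicing.

    ``sequence(chrom, start, end, strand)`` returns the uppercase sequence of
    the 0-based half-open interval; minus-strand queries return the reverse
    complement (i.e. the cDNA-sense sequence of a minus-strand RNA).
    """

    def __init__(self, sequences: Dict[str, str]):
        self._seqs = {name: seq.upper() for name, seq in sequences.items()}
        for name, seq in self._seqs.items():
            if len(seq) == 0:
                raise ValueError(f"chromosome {name} has zero length")
        self.chrom_names: List[str] = list(self._seqs)
        self.chrom_lengths: Dict[str, int] = {n: len(s) for n, s in self._seqs.items()}

    @classmethod
    def from_fasta(cls, path: str) -> "GenomeIndex":
        import pyfaidx

        fa = pyfaidx.Fasta(path)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    @classmethod
    def from_dict(cls, sequences: Dict[str, str]) -> "GenomeIndex":
        return cls(dict(sequences))

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def sequence(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        if chrom not in self._seqs:
            raise KeyError(f"unknown chromosome: {chrom}")
        seq = self._seqs[chrom][max(start, 0) : end]
        if start < 0 or end > self.chrom_lengths[chrom]:
            # pad out-of-range flanks with N so upstream-context queries near
            # chromosome edges stay well defined
            seq = "N" * max(0, -start) + seq + "N" * max(0, end - self.chrom_lengths[chrom])
        if strand == "-":
            seq = revcomp(seq)
        return seq


@dataclass
class TranscriptModel:
    """One transcript isoform: exon structure plus an abundance estimate.

    ``exons`` are 0-based half-open genomic intervals, sorted and
    non-overlapping, all on one chromosome and strand.  ``tpm`` (transcripts
    per million) and exonic length feed the 5P/BODY scaling factor.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: List[Tuple[int, int]]
    tpm: float = 0.0
    biotype: str = "mRNA"

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.transcript_id}")
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        prev_end = None
        for a, b in self.exons:
            if a >= b:
                raise ValueError(f"empty exon [{a},{b}) in {self.transcript_id}")
            if prev_end is not None and a < prev_end:
                raise ValueError(f"overlapping exons in {self.transcript_id}")
            prev_end = b
        if self.tpm < 0:
            raise ValueError("TPM must be >= 0")

    @property
    def length(self) -> int:
        """Exonic (spliced) length in nucleotides."""
        return sum(b - a for a, b in self.exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def genomic_to_offset(self, pos: int) -> Optional[int]:
        """Spliced offset from the transcript 5' end, or None if intronic/outside."""
        off = 0
        for a, b in self.exons:
            if a <= pos < b:
                plus_off = off + (pos - a)
                return plus_off if self.strand == "+" else self.length - 1 - plus_off
            off += b - a
        return None

    def offset_to_genomic(self, offset: int) -> int:
        """Inverse of :meth:`genomic_to_offset` for on-transcript offsets."""
        if not 0 <= offset < self.length:
            raise IndexError(f"offset {offset} outside [0,{self.length})")
        plus_off = offset if self.strand == "+" else self.length - 1 - offset
        for a, b in self.exons:
            if plus_off < b - a:
                return a + plus_off
            plus_off -= b - a
        raise AssertionError("unreachable")

    def spliced_sequence(self, genome: GenomeIndex) -> str:
        """cDNA-sense spliced sequence of the transcript."""
        seq = "".join(genome.sequence(self.chrom, a, b, "+") for a, b in self.exons)
        return seq if self.strand == "+" else revcomp(seq)


class EndSignalTrack:
    """Sparse per-position weighted 5'-end counts, per chromosome and strand.

    Weights are strictly positive; a position is absent rather than zero.
    Unstranded (BODY) signal lives under strand ``'.'`` and is served for
    either strand on request.
    """

    def __init__(self, stranded: bool = True):
        self.stranded = stranded
        self._data: Dict[Tuple[str, str], Dict[int, float]] = {}

    def add(self, chrom: str, strand: str, pos: int, weight: float) -> None:
        if weight <= 0:
            return
        key = (chrom, strand if self.stranded else ".")
        d = self._data.setdefault(key, {})
        d[pos] = d.get(pos, 0.0) + weight

    def keys(self) -> List[Tuple[str, str]]:
        return sorted(self._data)

    def chroms(self) -> List[str]:
        return sorted({c for c, _ in self._data})

    def positions(self, chrom: str, strand: str) -> Dict[int, float]:
        """Raw position->weight mapping for one (chrom, strand).

        For an unstranded track any strand returns the shared data.
        """
        key = (chrom, strand if self.stranded else ".")
        return self._data.get(key, {})

    def arrays(self, chrom: str, strand: str) -> Tuple[np.ndarray, np.ndarray]:
        d = self.positions(chrom, strand)
        if not d:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.float64)
        pos = np.fromiter(d.keys(), dtype=np.int64, count=len(d))
        w = np.fromiter(d.values(), dtype=np.float64, count=len(d))
        order = np.argsort(pos, kind="stable")
        return pos[order], w[order]

    @property
    def total_mass(self) -> float:
        return float(sum(sum(d.values()) for d in self._data.values()))

    def mass_in(self, chrom: str, strand: str, start: int, end: int) -> float:
        d = self.positions(chrom, strand)
        if len(d) <= end - start:
            return float(sum(w for p, w in d.items() if start <= p < end))
        return float(sum(d.get(p, 0.0) for p in range(start, end)))

    def copy(self) -> "EndSignalTrack":
        t = EndSignalTrack(stranded=self.stranded)
        t._data = {k: dict(d) for k, d in self._data.items()}
        return t

    def allclose(self, other: "EndSignalTrack", tol: float = 1e-9) -> bool:
        if self.keys() != other.keys():
            return False
        for key in self.keys():
            a, b = self._data[key], other._data[key]
            if set(a) != set(b):
                return False
            if any(abs(a[p] - b[p]) > tol for p in a):
                return False
        return True


def pool_tracks(tracks: List["EndSignalTrack"]) -> "EndSignalTrack":
    """Position-wise sum of several tracks (e.g. replicates of a sample type)."""
    if not tracks:
        raise ValueError("no tracks to pool")
    out = EndSignalTrack(stranded=all(t.stranded for t in tracks))
    for t in tracks:
        for (chrom, strand), d in t._data.items():
            for pos, w in d.items():
                out.add(chrom, strand, pos, w)
    return out


@dataclass
class EndFeature:
    """A genomic interval of continuous positive subtractive 5P density."""

    chrom: str
    strand: str
    start: int
    end: int
    read_count: float = 0.0
    uug_count: float = 0.0
    cap_class: str = "unclassified"
    support: int = 1
    name: str = ""

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty feature [{self.start},{self.end})")
        if not 0.0 <= self.uug_count <= self.read_count + 1e-9:
            raise ValueError("uuG count must lie in [0, read_count]")

    @property
    def uug_fraction(self) -> float:
        return self.uug_count / self.read_count if self.read_count > 0 else float("nan")


@dataclass
class EndReadAlignment:
    """One aligned read reduced to its 5'-end position and mapping context.

    ``five_prime_pos`` is the genomic coordinate of the read's 5'-most aligned
    base in read orientation (the alignment end for reverse-strand reads).
    ``uun`` holds the soft-clipped upstream nucleotides in cDNA sense, with the
    last character adjacent to the genome-matching sequence.  Multimapped
    reads produce one record per alignment, all sharing ``candidate_locations``
    and ``multiplicity``; the rescue step fills ``weight`` so that one read's
    weights sum to 1.
    """

    read_id: str
    chrom: str
    strand: str
    five_prime_pos: int
    uun: str = ""
    multiplicity: int = 1
    candidate_locations: List[Tuple[str, str, int]] = field(default_factory=list)
    weight: float = 1.0


# ---------------------------------------------------------------------------
# SAM/BAM ingestion
# ---------------------------------------------------------------------------

def read_alignments(
    path: str,
    library_type: str = "5P",
    genome: Optional[GenomeIndex] = None,
    multiplicity_tag: Optional[str] = None,
    min_complexity: Optional[float] = None,
) -> Tuple[List[EndReadAlignment], Dict[str, int]]:
    """Reduce a SAM/BAM file to 5'-end alignment records.

    For 5P libraries the 5' soft-clipped nucleotides are captured in cDNA
    sense (reverse-strand clips are reverse-complemented).  BODY records carry
    the fragment start (leftmost aligned base) and are flagged unstranded.

    Multiplicity is the number of best-score alignments present in the file
    for a read (grouped by read name), matching an upstream aligner that
    reports all best-score hits as primary; ``multiplicity_tag`` (e.g. "NH")
    overrides the grouped count when given.

    Returns (records, stats) where stats counts kept/rejected reads.
    """
    if library_type not in ("5P", "BODY"):
        raise ValueError(f"library_type must be 5P or BODY, got {library_type!r}")
    if min_complexity is not None:
        from .endmap import complexity_filter
    mode = "rb" if path.endswith(".bam") else "r"
    stats = {"alignments": 0, "missing_cigar": 0, "reads": 0, "low_complexity": 0}
    groups: Dict[str, List[Tuple[str, str, int, str, int]]] = {}
    with pysam.AlignmentFile(path, mode, check_sq=False) as af:
        for a in af.fetch(until_eof=True):
            if a.is_unmapped or a.is_secondary or a.is_supplementary:
                continue
            stats["alignments"] += 1
            ct = a.cigartuples
            if ct is None:
                stats["missing_cigar"] += 1
                continue
            chrom = a.reference_name
            if genome is not None and chrom not in genome:
                raise KeyError(f"alignment on unknown chromosome: {chrom}")
            if min_complexity is not None and a.query_sequence:
                if not complexity_filter(a.query_sequence, min_complexity):
                    stats["low_complexity"] += 1
                    continue
            if library_type == "BODY":
                groups.setdefault(a.query_name, []).append((chrom, ".", a.reference_start, "", 1))
                continue
            if a.is_reverse:
                strand, pos5 = "-", a.reference_end - 1
                # stored SEQ is the reverse complement of the cDNA: the read's
                # 5' soft clip is the trailing CIGAR op
                uun = ""
                if ct[-1][0] == 4:
                    n = ct[-1][1]
                    seq = a.query_sequence or ""
                    uun = revcomp(seq[len(seq) - n :]) if seq else ""
            else:
                strand, pos5 = "+", a.reference_start
                uun = ""
                if ct[0][0] == 4:
                    seq = a.query_sequence or ""
                    uun = seq[: ct[0][1]]
            mult = 1
            if multiplicity_tag is not None and a.has_tag(multiplicity_tag):
                mult = int(a.get_tag(multiplicity_tag))
            groups.setdefault(a.query_name, []).append((chrom, strand, pos5, uun, mult))

    records: List[EndReadAlignment] = []
    for name, hits in groups.items():
        stats["reads"] += 1
        mult = hits[0][4] if multiplicity_tag is not None else len(hits)
        mult = max(mult, len(hits))
        locs = [(c, s, p) for c, s, p, _, _ in hits]
        for chrom, strand, pos, uun, _ in hits:
            records.append(
                EndReadAlignment(
                    read_id=name,
                    chrom=chrom,
                    strand=strand,
                    five_prime_pos=pos,
                    uun=uun,
                    multiplicity=mult,
                    candidate_locations=locs,
                )
            )
    return records, stats


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def write_bedgraph(track: EndSignalTrack, prefix: str) -> List[str]:
    """Write one bedGraph file per strand present (0-based half-open lines).

    Runs of adjacent positions with equal value are merged into one line.
    Returns the list of paths written.
    """
    by_strand: Dict[str, List[Tuple[str, int, float]]] = {}
    for (chrom, strand), d in sorted(track._data.items()):
        for pos in sorted(d):
            by_strand.setdefault(strand, []).append((chrom, pos, d[pos]))
    paths = []
    for strand, rows in sorted(by_strand.items()):
        path = prefix + STRAND_SUFFIX[strand]
        with open(path, "w") as fh:
            run = None  # (chrom, start, end, value)
            for chrom, pos, val in rows:
                if run is not None and run[0] == chrom and run[2] == pos and run[3] == val:
                    run = (run[0], run[1], pos + 1, run[3])
                else:
                    if run is not None:
                        fh.write(f"{run[0]}\t{run[1]}\t{run[2]}\t{run[3]!r}\n")
                    run = (chrom, pos, pos + 1, val)
            if run is not None:
                fh.write(f"{run[0]}\t{run[1]}\t{run[2]}\t{run[3]!r}\n")
        paths.append(path)
    return paths


def read_bedgraph(prefix: str) -> EndSignalTrack:
    """Read the per-strand bedGraph files written by :func:`write_bedgraph`."""
    present = {s: prefix + suf for s, suf in STRAND_SUFFIX.items() if os.path.exists(prefix + suf)}
    track = EndSignalTrack(stranded="." not in present)
    for strand, path in sorted(present.items()):
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("track", "#")):
                    continue
                parts = line.split("\t")
                try:
                    chrom, start, end, val = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
                except (IndexError, ValueError) as exc:
                    raise ValueError(f"{path}: malformed bedGraph line {lineno}: {line!r}") from exc
                for pos in range(start, end):
                    track.add(chrom, strand, pos, val)
    return track


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def load_annotation(path: str, genome: Optional[GenomeIndex] = None) -> List[TranscriptModel]:
    """Load transcript models from GTF/GFF3 (1-based inclusive -> 0-based half-open)."""
    import gffutils

    db = gffutils.create_db(
        path,
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_transcripts=True,
        disable_infer_genes=True,
    )
    grouped: Dict[str, dict] = {}
    for exon in db.features_of_type("exon"):
        tid = exon.attributes.get("transcript_id", [None])[0]
        gid = exon.attributes.get("gene_id", [tid])[0]
        if tid is None:
            raise ValueError(f"exon without transcript_id at {exon.seqid}:{exon.start}")
        rec = grouped.setdefault(
            tid, {"gene_id": gid, "chrom": exon.seqid, "strand": exon.strand, "exons": [],
                  "biotype": (exon.attributes.get("gene_biotype", ["mRNA"])[0])}
        )
        if rec["chrom"] != exon.seqid or rec["strand"] != exon.strand:
            raise ValueError(f"transcript {tid} has exons on multiple chroms/strands")
        rec["exons"].append((exon.start - 1, exon.end))
    models = []
    for tid, rec in grouped.items():
        if genome is not None and rec["chrom"] not in genome:
            raise KeyError(f"transcript {tid} references absent chromosome {rec['chrom']}")
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=rec["gene_id"],
                chrom=rec["chrom"],
                strand=rec["strand"],
                exons=rec["exons"],
                biotype=rec["biotype"],
            )
        )
    models.sort(key=lambda t: (t.chrom, t.start, t.transcript_id))
    return models


def estimate_tpm(transcripts: List[TranscriptModel], body_track: EndSignalTrack) -> None:
    """Assign TPM in place from BODY exonic coverage (reads per exonic base,
    normalized to one million)."""
    raw = []
    for t in transcripts:
        mass = sum(body_track.mass_in(t.chrom, t.strand, a, b) for a, b in t.exons)
        raw.append(mass / t.length)
    total = sum(raw)
    for t, r in zip(transcripts, raw):
        t.tpm = 1e6 * r / total if total > 0 else 0.0


# ---------------------------------------------------------------------------
# BED and FASTA
# ---------------------------------------------------------------------------

def write_bed(features: Iterable[EndFeature], path: str) -> None:
    """BED6 with three extra columns: replicate support, uuG count, cap class."""
    with open(path, "w") as fh:
        for i, f in enumerate(features):
            name = f.name or f"feature_{i}"
            fh.write(
                f"{f.chrom}\t{f.start}\t{f.end}\t{name}\t{f.read_count:.6g}\t{f.strand}"
                f"\t{f.support}\t{f.uug_count:.6g}\t{f.cap_class}\n"
            )


def read_bed(path: str) -> List[EndFeature]:
    feats = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            p = line.split("\t")
            try:
                feats.append(
                    EndFeature(
                        chrom=p[0], start=int(p[1]), end=int(p[2]), name=p[3],
                        read_count=float(p[4]), strand=p[5],
                        support=int(p[6]) if len(p) > 6 else 1,
                        uug_count=float(p[7]) if len(p) > 7 else 0.0,
                        cap_class=p[8] if len(p) > 8 else "unclassified",
                    )
                )
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}: malformed BED line {lineno}") from exc
    return feats


def write_fasta(sequences: Dict[str, str], path: str) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=n, description="") for n, s in sequences.items()]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> Dict[str, str]:
    from Bio import SeqIO

    return {r.id: str(r.seq).upper() for r in SeqIO.parse(path, "fasta")}
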