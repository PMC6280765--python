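"""Synthetic 5P/BODY experiments with known ground truth.

The generator emulates the data model of a paired 5'-end (5P) and gene-body
(BODY) sequencing experiment:

* capped reads pile at each gene's transcription start site with a small
  positional jitter and carry an upstream untemplated G at a ~15% rate — the
  reverse-transcription signature of the m7G cap;
* noncapped degradation 5' ends are spread along transcripts with linearly
  increasing density toward the 3' end and a ~2% background uuG rate;
* planted sRNA cleavage products start exactly at the duplex position-10/11
  scissile bond of an embedded target site;
* BODY reads tile transcripts uniformly (non-stranded library);
* an in-vitro 5'->3' exonuclease treatment mode (``xrn1_mode``) removes a
  configured fraction of the noncapped-label (degradation + cleavage) reads
  while leaving capped reads untouched.

All outputs are plain-text FASTA/GTF/SAM plus truth tables, and parse with
:mod:`endkit.core_io`.  Every read name embeds its truth label.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core_io import GenomeIndex, TranscriptModel, revcomp, write_fasta
from .endcut import _encode  # noqa: F401  (shared alphabet)

_BASES = np.array(list("ACGT"))
_WC = {"A": "T", "C": "G", "G": "C", "T": "A"}
_WOBBLE_PARTNER = {"G": "T", "T": "G"}  # sRNA base -> target base forming G:U


@dataclass
class PlantedSite:
    """A target site embedded in a transcript for a given sRNA.

    ``duplex_start`` is the transcript offset of the 5'-most target base of
    the duplex; the cleavage product 5' end falls at
    ``duplex_start + len(srna) - 10``.  ``efficiency`` is the fraction of the
    gene's 5P reads redirected to the cleavage product (0 embeds the sequence
    motif without any cleavage signal).  ``n_core_mutations`` target bases
    opposite sRNA positions 2-13 are mutated to non-pairing bases, degrading
    the Allen score by 2 per mutation.
    """

    srna_name: str
    srna_seq: str
    gene_index: int
    duplex_start: int
    efficiency: float = 0.0
    n_core_mutations: int = 0

    @property
    def cleavage_offset(self) -> int:
        return self.duplex_start + len(self.srna_seq) - 10


@dataclass
class SimConfig:
    """Study conditions for one synthetic experiment."""

    seed: int = 1
    n_genes: int = 200
    n_replicates: int = 1
    gene_length_range: Tuple[int, int] = (1000, 2000)
    intergenic_length: int = 500
    two_exon_fraction: float = 0.25
    intron_length_range: Tuple[int, int] = (100, 300)
    n_chromosomes: int = 2
    expression_sigma: float = 1.0  # sd of log TPM
    capped_uug_rate: float = 0.15
    noncapped_uug_rate: float = 0.02
    tss_jitter_sd: float = 2.0  # nt
    degradation_fraction: float = 0.3  # of non-cleavage 5P reads
    depth_5p: int = 200_000
    depth_body: int = 200_000
    fragment_length: float = 500.0  # F of the BODY library
    read_length: int = 50
    planted_sites: List[PlantedSite] = field(default_factory=list)
    xrn1_mode: bool = False
    xrn1_removal: float = 0.9

    def __post_init__(self):
        for rate in (self.capped_uug_rate, self.noncapped_uug_rate,
                     self.degradation_fraction, self.xrn1_removal):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.depth_5p <= 0 or self.depth_body <= 0:
            raise ValueError("read depths must be > 0")


@dataclass
class SimTruth:
    """Ground truth for one simulated experiment."""

    tss: Dict[str, Tuple[str, str, int]]  # gene_id -> (chrom, strand, genomic TSS)
    cleavage: List[Dict]  # one row per planted site
    read_labels: Dict[str, str] = field(default_factory=dict)  # read_id -> label


class SimulatedExperiment:
    """Genome + annotation + per-replicate read sampling for one config."""

    def __init__(self, cfg: SimConfig):
        self.cfg = cfg
        rng = np.random.default_rng([cfg.seed, 0])
        n = cfg.n_genes

        lengths = rng.integers(cfg.gene_length_range[0], cfg.gene_length_range[1] + 1, n)
        strands = rng.choice(["+", "-"], n)
        two_exon = rng.random(n) < cfg.two_exon_fraction
        cdnas = ["".join(rng.choice(_BASES, L)) for L in lengths]

        # embed planted target motifs into the cDNA sequences
        self._plant_rows: List[Dict] = []
        for site in cfg.planted_sites:
            g = site.gene_index
            if not 0 <= g < n:
                raise ValueError(f"planted site gene index {g} out of range")
            m = len(site.srna_seq)
            motif = list(revcomp(site.srna_seq.upper().replace("U", "T")))
            core = [p for p in range(2, 14)]
            chosen = rng.choice(core, size=site.n_core_mutations, replace=False)
            for p in chosen:  # sRNA position p pairs with motif index m - p
                srna_base = site.srna_seq.upper().replace("U", "T")[p - 1]
                banned = {_WC[srna_base], _WOBBLE_PARTNER.get(srna_base, "")}
                choices = [b for b in "ACGT" if b not in banned]
                motif[m - p] = str(rng.choice(choices))
            if site.duplex_start < 0 or site.duplex_start + m > lengths[g]:
                raise ValueError(
                    f"planted site [{site.duplex_start},{site.duplex_start + m}) outside "
                    f"transcript of length {lengths[g]}"
                )
            c = cdnas[g]
            cdnas[g] = c[: site.duplex_start] + "".join(motif) + c[site.duplex_start + m :]

        # lay genes onto chromosomes, inserting introns for two-exon genes
        self.transcripts: List[TranscriptModel] = []
        chrom_seqs: Dict[str, List[str]] = {}
        cursor: Dict[str, int] = {}
        per_chrom = int(np.ceil(n / cfg.n_chromosomes))
        for g in range(n):
            chrom = f"chr{g // per_chrom + 1}"
            parts = chrom_seqs.setdefault(chrom, [])
            if chrom not in cursor:
                cursor[chrom] = 0
            spacer = "".join(rng.choice(_BASES, cfg.intergenic_length))
            parts.append(spacer)
            cursor[chrom] += cfg.intergenic_length
            L = int(lengths[g])
            strand = str(strands[g])
            genomic = cdnas[g] if strand == "+" else revcomp(cdnas[g])
            if two_exon[g] and L > 200:
                ilen = int(rng.integers(*cfg.intron_length_range))
                split = int(rng.integers(100, L - 100))  # position on the + genome axis
                intron = "".join(rng.choice(_BASES, ilen))
                genomic = genomic[:split] + intron + genomic[split:]
                start = cursor[chrom]
                exons = [(start, start + split), (start + split + ilen, start + L + ilen)]
            else:
                start = cursor[chrom]
                exons = [(start, start + L)]
            parts.append(genomic)
            cursor[chrom] += len(genomic)
            self.transcripts.append(
                TranscriptModel(
                    transcript_id=f"t{g:04d}", gene_id=f"g{g:04d}", chrom=chrom,
                    strand=strand, exons=exons,
                )
            )
        for chrom in chrom_seqs:
            chrom_seqs[chrom].append("".join(rng.choice(_BASES, cfg.intergenic_length)))
        self.genome = GenomeIndex({c: "".join(p) for c, p in sorted(chrom_seqs.items())})

        tpm = np.exp(rng.normal(0.0, cfg.expression_sigma, n))
        tpm = tpm / tpm.sum() * 1e6
        for t, v in zip(self.transcripts, tpm):
            t.tpm = float(v)

        self.truth = SimTruth(tss={}, cleavage=[])
        for t in self.transcripts:
            tss_genomic = t.offset_to_genomic(0)
            self.truth.tss[t.gene_id] = (t.chrom, t.strand, tss_genomic)
        for site in cfg.planted_sites:
            t = self.transcripts[site.gene_index]
            self.truth.cleavage.append(
                {
                    "srna": site.srna_name,
                    "gene_id": t.gene_id,
                    "transcript_id": t.transcript_id,
                    "duplex_start": site.duplex_start,
                    "cleavage_offset": site.cleavage_offset,
                    "cleavage_genomic": t.offset_to_genomic(site.cleavage_offset),
                    "efficiency": site.efficiency,
                    "n_core_mutations": site.n_core_mutations,
                }
            )

    # -- read sampling ------------------------------------------------------

    def sample_5p(self, replicate: int) -> List[Tuple[str, str, int, int, bool, str]]:
        """Sample one 5P replicate.

        Returns per-read tuples (label, chrom, transcript offset, gene index,
        uug, read_id).  The xrn1 filter, when active, uses an independent
        random stream so that the surviving capped reads are identical to the
        untreated library sampled from the same seed.
        """
        cfg = self.cfg
        rng = np.random.default_rng([cfg.seed, 1, replicate])
        n_genes = len(self.transcripts)
        tpm = np.array([t.tpm for t in self.transcripts])
        gene_of_read = rng.choice(n_genes, size=cfg.depth_5p, p=tpm / tpm.sum())

        site_by_gene: Dict[int, List[PlantedSite]] = {}
        for s in cfg.planted_sites:
            if s.efficiency > 0:
                site_by_gene.setdefault(s.gene_index, []).append(s)

        reads = []
        counts = np.bincount(gene_of_read, minlength=n_genes)
        idx = 0
        for g in range(n_genes):
            k = int(counts[g])
            if k == 0:
                continue
            t = self.transcripts[g]
            L = t.length
            sites = site_by_gene.get(g, [])
            eff = np.array([s.efficiency for s in sites])
            p_cle = eff.sum()
            p_deg = (1.0 - p_cle) * cfg.degradation_fraction
            u = rng.random(k)
            for i in range(k):
                rid = f"r{replicate}_{idx:07d}"
                idx += 1
                if u[i] < p_cle:
                    j = int(np.searchsorted(np.cumsum(eff), u[i], side="right"))
                    off = sites[j].cleavage_offset
                    label, uug_rate = "cleavage", cfg.noncapped_uug_rate
                elif u[i] < p_cle + p_deg:
                    off = min(int(L * np.sqrt(rng.random())), L - 1)
                    label, uug_rate = "degradation", cfg.noncapped_uug_rate
                else:
                    off = int(np.clip(round(rng.normal(0.0, cfg.tss_jitter_sd)), 0, L - 1))
                    label, uug_rate = "capped", cfg.capped_uug_rate
                uug = bool(rng.random() < uug_rate)
                reads.append((label, t.chrom, off, g, uug, rid))
        if cfg.xrn1_mode and cfg.xrn1_removal > 0:
            rng_x = np.random.default_rng([cfg.seed, 2, replicate])
            keep = rng_x.random(len(reads)) >= cfg.xrn1_removal
            reads = [r for r, k in zip(reads, keep) if k or r[0] == "capped"]
        return reads

    def sample_body(self, replicate: int) -> List[Tuple[int, int, str]]:
        """Sample one BODY replicate: (gene index, transcript start offset, read_id)."""
        cfg = self.cfg
        rng = np.random.default_rng([cfg.seed, 3, replicate])
        n_genes = len(self.transcripts)
        weights = np.array([t.tpm * t.length for t in self.transcripts])
        gene_of_read = rng.choice(n_genes, size=cfg.depth_body, p=weights / weights.sum())
        counts = np.bincount(gene_of_read, minlength=n_genes)
        reads = []
        idx = 0
        for g in range(n_genes):
            k = int(counts[g])
            if k == 0:
                continue
            L = self.transcripts[g].length
            hi = max(L - cfg.read_length, 1)
            offs = rng.integers(0, hi, size=k)
            for off in offs:
                reads.append((g, int(off), f"b{replicate}_{idx:07d}"))
                idx += 1
        return reads

    # -- SAM emission -------------------------------------------------------

    def _sam_header(self) -> str:
        lines = ["@HD\tVN:1.6\tSO:unsorted"]
        for chrom in self.genome.chrom_names:
            lines.append(f"@SQ\tSN:{chrom}\tLN:{self.genome.chrom_lengths[chrom]}")
        return "\n".join(lines) + "\n"

    def _genomic_run(self, t: TranscriptModel, offset: int) -> Tuple[int, int]:
        """(genomic position of the offset base, contiguous run length 3'-ward
        within the exon, in transcript direction)."""
        pos = t.offset_to_genomic(offset)
        for a, b in t.exons:
            if a <= pos < b:
                return pos, (b - pos) if t.strand == "+" else (pos - a + 1)
        raise AssertionError("offset not exonic")

    def write_5p_sam(self, path: str, replicate: int, truth: Optional[SimTruth] = None) -> int:
        cfg = self.cfg
        reads = self.sample_5p(replicate)
        with open(path, "w") as fh:
            fh.write(self._sam_header())
            for label, chrom, off, g, uug, rid in reads:
                t = self.transcripts[g]
                pos, run = self._genomic_run(t, off)
                rl = min(cfg.read_length, run)
                body = self.genome.sequence(
                    chrom, pos, pos + rl, "+"
                ) if t.strand == "+" else self.genome.sequence(chrom, pos - rl + 1, pos + 1, "-")
                if t.strand == "+":
                    cigar = (f"1S{rl}M" if uug else f"{rl}M")
                    seq = ("G" + body) if uug else body
                    fh.write(f"{rid}\t0\t{chrom}\t{pos + 1}\t255\t{cigar}\t*\t0\t0\t{seq}\t*\n")
                else:
                    cigar = (f"{rl}M1S" if uug else f"{rl}M")
                    seq = revcomp(("G" + body) if uug else body)
                    left = pos - rl + 1
                    fh.write(f"{rid}\t16\t{chrom}\t{left + 1}\t255\t{cigar}\t*\t0\t0\t{seq}\t*\n")
                if truth is not None:
                    truth.read_labels[rid] = label
        return len(reads)

    def write_body_sam(self, path: str, replicate: int) -> int:
        cfg = self.cfg
        reads = self.sample_body(replicate)
        rng = np.random.default_rng([cfg.seed, 4, replicate])
        flags = rng.choice([0, 16], size=len(reads))
        with open(path, "w") as fh:
            fh.write(self._sam_header())
            for (g, off, rid), flag in zip(reads, flags):
                t = self.transcripts[g]
                pos, run = self._genomic_run(t, off)
                rl = min(cfg.read_length, run)
                left = pos if t.strand == "+" else pos - rl + 1
                seq = self.genome.sequence(t.chrom, left, left + rl, "+")
                if flag == 16:
                    seq = revcomp(seq)
                fh.write(f"{rid}\t{flag}\t{t.chrom}\t{left + 1}\t255\t{rl}M\t*\t0\t0\t{seq}\t*\n")
        return len(reads)

    def write_gtf(self, path: str) -> None:
        with open(path, "w") as fh:
            for t in self.transcripts:
                attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
                fh.write(
                    f"{t.chrom}\tendkit_sim\ttranscript\t{t.start + 1}\t{t.end}\t.\t{t.strand}\t.\t{attrs}\n"
                )
                for a, b in t.exons:
                    fh.write(
                        f"{t.chrom}\tendkit_sim\texon\t{a + 1}\t{b}\t.\t{t.strand}\t.\t{attrs}\n"
                    )

    def write(self, out_dir: str) -> Dict[str, object]:
        """Write FASTA, GTF, per-replicate SAM pairs, and truth TSVs."""
        os.makedirs(out_dir, exist_ok=True)
        paths: Dict[str, object] = {}
        fasta = os.path.join(out_dir, "genome.fa")
        write_fasta({c: self.genome.sequence(c, 0, self.genome.chrom_lengths[c]) for c in
                     self.genome.chrom_names}, fasta)
        paths["genome"] = fasta
        gtf = os.path.join(out_dir, "annotation.gtf")
        self.write_gtf(gtf)
        paths["annotation"] = gtf
        truth = SimTruth(tss=self.truth.tss, cleavage=self.truth.cleavage)
        paths["5p"], paths["body"] = [], []
        for rep in range(self.cfg.n_replicates):
            p5 = os.path.join(out_dir, f"rep{rep}.5p.sam")
            pb = os.path.join(out_dir, f"rep{rep}.body.sam")
            self.write_5p_sam(p5, rep, truth)
            self.write_body_sam(pb, rep)
            paths["5p"].append(p5)
            paths["body"].append(pb)
        with open(os.path.join(out_dir, "tss_truth.tsv"), "w") as fh:
            fh.write("gene_id\tchrom\tstrand\ttss\n")
            for gid, (chrom, strand, tss) in sorted(truth.tss.items()):
                fh.write(f"{gid}\t{chrom}\t{strand}\t{tss}\n")
        with open(os.path.join(out_dir, "cleavage_truth.tsv"), "w") as fh:
            cols = ["srna", "gene_id", "transcript_id", "duplex_start", "cleavage_offset",
                    "cleavage_genomic", "efficiency", "n_core_mutations"]
            fh.write("\t".join(cols) + "\n")
            for row in truth.cleavage:
                fh.write("\t".join(str(row[c]) for c in cols) + "\n")
        with open(os.path.join(out_dir, "read_labels.tsv"), "w") as fh:
            fh.write("read_id\tlabel\n")
            for rid, label in truth.read_labels.items():
                fh.write(f"{rid}\t{label}\n")
        self.truth = truth
        return paths


def simulate_dataset(cfg: SimConfig, out_dir: str) -> Tuple[SimulatedExperiment, Dict[str, object]]:
    """Build a synthetic experiment and write all its files to ``out_dir``."""
    sim = SimulatedExperiment(cfg)
    paths = sim.write(out_dir)
    return sim, paths


def random_srnas(n: int, length: int = 21, seed: int = 0) -> Dict[str, str]:
    """n random sRNA sequences of the given length."""
    rng = np.random.default_rng(seed)
    return {f"srna{i:02d}": "".join(rng.choice(_BASES, length)) for i in range(n)}


def cleavage_study(
    seed: int,
    n_srnas: int = 20,
    sites_per_srna: int = 4,
    cleave: bool = False,
    efficiency: float = 0.05,
    n_genes: int = 20,
    depth_5p: int = 6000,
) -> Tuple[SimConfig, Dict[str, str]]:
    """Study conditions for the cleavage-site test (null or power design).

    Random sRNAs each get ``sites_per_srna`` target motifs embedded at random
    transcript positions.  In the null design (``cleave=False``) the motifs
    carry 1-3 core mutations and receive no cleavage reads, so every tested
    site is a true negative; in the power design the motifs are perfect
    complements and each receives an ``efficiency`` share of its gene's 5P
    reads.  Degradation background and TSS piles are generated as usual.
    """
    srnas = random_srnas(n_srnas, seed=seed + 7)
    rng = np.random.default_rng([seed, 11])
    # deterministic site slots, spaced so that no slot falls inside another
    # slot's 50-nt flanking window or the TSS pile near offset 0
    slot_offsets = (150, 320, 490, 660)
    slots = [(g, off) for g in range(n_genes) for off in slot_offsets]
    need = n_srnas * sites_per_srna
    if need > len(slots):
        raise ValueError("not enough site slots: increase n_genes")
    order = rng.permutation(len(slots))[:need]
    planted: List[PlantedSite] = []
    k = 0
    for name, seq in sorted(srnas.items()):
        for _ in range(sites_per_srna):
            g, start = slots[order[k]]
            k += 1
            planted.append(
                PlantedSite(
                    srna_name=name, srna_seq=seq, gene_index=g, duplex_start=start,
                    efficiency=efficiency if cleave else 0.0,
                    n_core_mutations=0 if cleave else int(rng.integers(1, 4)),
                )
            )
    cfg = SimConfig(
        seed=seed,
        n_genes=n_genes,
        n_replicates=2,
        gene_length_range=(900, 1100),
        expression_sigma=0.5,
        depth_5p=depth_5p,
        depth_body=depth_5p,
        planted_sites=planted,
    )
    return cfg, srnas


# ---------------------------------------------------------------------------
# Multimapper rescue fixtures
# ---------------------------------------------------------------------------

def bruteforce_rescue(
    unique_positions: List[Tuple[str, str, int]],
    multi_reads: List[Tuple[str, List[Tuple[str, str, int]]]],
    chrom_order: Optional[List[str]] = None,
) -> Dict[str, Dict[Tuple[str, str, int], float]]:
    """Literal replay of the rich-get-richer assignment loop.

    Independent of :func:`endkit.endmap.rescue_multimappers`; used as the
    oracle it is checked against.  ``multi_reads`` holds (read_id, candidate
    locations); reads with more than 100 locations are dropped.
    """
    if chrom_order is None:
        chroms = {c for c, _, _ in unique_positions}
        for _, locs in multi_reads:
            chroms.update(c for c, _, _ in locs)
        chrom_order = sorted(chroms)
    rank = {c: i for i, c in enumerate(chrom_order)}

    cov: Dict[Tuple[str, str, int], float] = {}
    for loc in unique_positions:
        cov[loc] = cov.get(loc, 0.0) + 1.0

    result: Dict[str, Dict[Tuple[str, str, int], float]] = {}
    by_mult: Dict[int, List[Tuple[str, List[Tuple[str, str, int]]]]] = {}
    for rid, locs in multi_reads:
        by_mult.setdefault(len(locs), []).append((rid, locs))

    for mult in sorted(by_mult):
        if mult > 100:
            continue
        todo = sorted(
            by_mult[mult],
            key=lambda item: (min((rank[c], p) for c, _, p in item[1]), item[0]),
        )
        while True:
            still = []
            progressed = False
            for rid, locs in todo:
                cs = [cov.get(loc, 0.0) for loc in locs]
                s = sum(cs)
                if s > 0.0:
                    result[rid] = {}
                    for loc, ci in zip(locs, cs):
                        w = ci / s
                        result[rid][loc] = w
                        cov[loc] = cov.get(loc, 0.0) + w
                    progressed = True
                else:
                    still.append((rid, locs))
            todo = still
            if not progressed or not todo:
                break
        for rid, locs in todo:
            result[rid] = {}
            for loc in locs:
                w = 1.0 / len(locs)
                result[rid][loc] = w
                cov[loc] = cov.get(loc, 0.0) + w
    return result


def make_multimap_fixture(
    n_reads: int, n_loci: int, seed: int
) -> Tuple[List, Dict[str, Dict[Tuple[str, str, int], float]]]:
    """Random rescue instance plus oracle-expected weights.

    Builds a mixture of unique reads (seeding coverage) and multimapped reads
    with 2..n_loci candidate locations over a small position pool, then
    replays the published assignment loop to obtain the expected weights.
    """
    if n_reads > 20:
        raise ValueError("fixture instances are capped at 20 reads")
    from .core_io import EndReadAlignment

    rng = np.random.default_rng(seed)
    pool = [("chr1", "+", int(p)) for p in rng.choice(200, size=max(2 * n_loci, 8), replace=False)]
    n_unique = int(rng.integers(0, n_reads + 1))
    unique_positions = [pool[int(rng.integers(len(pool)))] for _ in range(n_unique)]

    multi_reads = []
    records: List[EndReadAlignment] = []
    for i, loc in enumerate(unique_positions):
        records.append(
            EndReadAlignment(read_id=f"u{i:03d}", chrom=loc[0], strand=loc[1],
                             five_prime_pos=loc[2], multiplicity=1,
                             candidate_locations=[loc])
        )
    for i in range(n_reads - n_unique):
        k = int(rng.integers(2, n_loci + 1))
        locs = [pool[j] for j in rng.choice(len(pool), size=k, replace=False)]
        rid = f"m{i:03d}"
        multi_reads.append((rid, locs))
        for loc in locs:
            records.append(
                EndReadAlignment(read_id=rid, chrom=loc[0], strand=loc[1],
                                 five_prime_pos=loc[2], multiplicity=k,
                                 candidate_locations=locs)
            )
    expected = bruteforce_rescue(unique_positions, multi_reads)
    return records, expected
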