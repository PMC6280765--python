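import numpy as np
import pytest

from endkit.core_io import GenomeIndex, revcomp


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_genome(rng):
    """Two random chromosomes, 600 and 400 nt."""
    return GenomeIndex(
        {
            "chr1": "".join(rng.choice(list("ACGT"), 600)),
            "chr2": "".join(rng.choice(list("ACGT"), 400)),
        }
    )


def sam_header(genome: GenomeIndex) -> str:
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for c in genome.chrom_names:
        lines.append(f"@SQ\tSN:{c}\tLN:{genome.chrom_lengths[c]}")
    return "\n".join(lines) + "\n"


def forward_5p_record(name, genome, chrom, pos, length, clip=""):
    """SAM line for a plus-strand 5P read starting at ``pos`` with an
    optional cDNA-sense 5' soft clip."""
    body = genome.sequence(chrom, pos, pos + length, "+")
    cigar = f"{len(clip)}S{length}M" if clip else f"{length}M"
    return f"{name}\t0\t{chrom}\t{pos + 1}\t255\t{cigar}\t*\t0\t0\t{clip + body}\t*\n"


def reverse_5p_record(name, genome, chrom, pos5, length, clip=""):
    """SAM line for a minus-strand 5P read whose 5' end is at ``pos5``.

    ``clip`` is given in cDNA sense (adjacent base last); the stored sequence
    and CIGAR are emitted in reference orientation.
    """
    left = pos5 - length + 1
    cdna = genome.sequence(chrom, left, pos5 + 1, "-")
    cigar = f"{length}M{len(clip)}S" if clip else f"{length}M"
    seq = revcomp(clip + cdna)
    return f"{name}\t16\t{chrom}\t{left + 1}\t255\t{cigar}\t*\t0\t0\t{seq}\t*\n"
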