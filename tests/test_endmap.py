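"""Complexity filter, uuG capture, bias model, and multimapper rescue."""

import numpy as np
import pytest

from endkit.core_io import EndReadAlignment, GenomeIndex, TranscriptModel, read_alignments
from endkit.endmap import (
    build_tracks,
    complexity_filter,
    extract_uug,
    fit_bias_model,
    i_complexity,
    rescue_multimappers,
)
from endkit.simulate import bruteforce_rescue, make_multimap_fixture

from conftest import reverse_5p_record, sam_header


class TestComplexityFilter:
    def test_homopolymer_discarded(self):
        assert complexity_filter("A" * 20) is False

    def test_empty_sequence_is_an_error(self):
        with pytest.raises(ValueError):
            complexity_filter("")

    def test_random_50mers_almost_always_kept(self):
        rng = np.random.default_rng(0)
        kept = sum(
            complexity_filter("".join(rng.choice(list("ACGT"), 50))) for _ in range(4000)
        )
        assert kept / 4000 >= 0.99

    def test_score_is_deterministic_and_lengthwise_sane(self):
        s = "ACGTACGGTTACGATCGATG"
        assert i_complexity(s) == i_complexity(s)
        assert i_complexity("A" * 30) == 0.0


class TestExtractUug:
    @pytest.mark.parametrize(
        "uun,expected",
        [("", False), ("G", True), ("TG", True), ("GT", False), ("AG", True)],
    )
    def test_adjacent_base_decides(self, uun, expected):
        r = EndReadAlignment(read_id="r", chrom="c", strand="+", five_prime_pos=0, uun=uun)
        assert extract_uug(r) is expected

    def test_orientation_on_reverse_strand_sam(self, tiny_genome, tmp_path):
        # cDNA-sense clip "TG" on a minus-strand read: adjacent base is G
        sam = tmp_path / "a.sam"
        sam.write_text(
            sam_header(tiny_genome)
            + reverse_5p_record("r1", tiny_genome, "chr1", 200, 40, clip="TG")
        )
        (r,), _ = read_alignments(str(sam), "5P", tiny_genome)
        assert r.uun == "TG"
        assert extract_uug(r) is True


class TestBiasModel:
    def _exonic_genome(self, seq):
        genome = GenomeIndex({"chr1": seq})
        tx = TranscriptModel(
            transcript_id="t1", gene_id="g1", chrom="chr1", strand="+",
            exons=[(0, len(seq))],
        )
        return genome, [tx]

    def _reads_at(self, positions):
        return [
            EndReadAlignment(read_id=f"r{i}", chrom="chr1", strand="+", five_prime_pos=int(p))
            for i, p in enumerate(positions)
        ]

    def test_uniform_starts_give_unit_weights(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 400))
        genome, txs = self._exonic_genome(seq)
        # one read at every exonic position: observed == background
        model = fit_bias_model(self._reads_at(range(0, 399)), txs, genome, k=2, window_start=0)
        for ctx in model.observed:
            assert model.weight(ctx) == pytest.approx(1.0, abs=1e-12)

    def test_stacked_reads_count_once(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 400))
        genome, txs = self._exonic_genome(seq)
        single = fit_bias_model(self._reads_at([50, 100]), txs, genome, k=2, window_start=0)
        stacked = fit_bias_model(
            self._reads_at([50] * 100 + [100]), txs, genome, k=2, window_start=0
        )
        assert single.observed == stacked.observed

    def test_known_enrichment_recovered(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 6000))
        genome, txs = self._exonic_genome(seq)
        limit = len(seq) - 2
        ac = [i for i in range(limit) if seq[i : i + 2] == "AC"]
        other = [i for i in range(limit) if seq[i : i + 2] != "AC"]
        # choose read-start positions so AC contexts are 4x enriched over background
        q = (limit / 4 - len(ac)) / len(other)
        chosen = ac + [p for p in other if rng.random() < q]
        model = fit_bias_model(self._reads_at(chosen), txs, genome, k=2, window_start=0)
        assert model.weight("AC") == pytest.approx(0.25, rel=0.10)

    def test_no_exonic_reads_is_an_error(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 100))
        genome, txs = self._exonic_genome(seq)
        with pytest.raises(ValueError):
            fit_bias_model(self._reads_at([500]), txs, genome, k=2, window_start=0)


def _multi_read(rid, locs):
    return [
        EndReadAlignment(
            read_id=rid, chrom=c, strand=s, five_prime_pos=p,
            multiplicity=len(locs), candidate_locations=list(locs),
        )
        for c, s, p in locs
    ]


def _unique_read(rid, loc):
    c, s, p = loc
    return EndReadAlignment(
        read_id=rid, chrom=c, strand=s, five_prime_pos=p,
        multiplicity=1, candidate_locations=[loc],
    )


class TestRescue:
    def test_proportional_to_existing_coverage(self):
        a, b = ("chr1", "+", 10), ("chr1", "+", 50)
        reads = (
            [_unique_read(f"u{i}", a) for i in range(3)]
            + [_unique_read("u3", b)]
            + _multi_read("mm", [a, b])
        )
        rescue_multimappers(reads)
        weights = {r.five_prime_pos: r.weight for r in reads if r.read_id == "mm"}
        assert weights[10] == pytest.approx(0.75)
        assert weights[50] == pytest.approx(0.25)

    def test_no_evidence_gives_equal_weighting(self):
        locs = [("chr1", "+", 10), ("chr1", "+", 50), ("chr2", "-", 7)]
        reads = _multi_read("mm", locs)
        rescue_multimappers(reads)
        assert all(r.weight == pytest.approx(1 / 3) for r in reads)

    def test_cross_bin_cascade(self):
        """A leftover 1/n assignment in the multiplicity-2 bin seeds coverage
        that makes a multiplicity-3 read unambiguous."""
        a, b, c, d = [("chr1", "+", p) for p in (10, 50, 90, 130)]
        reads = _multi_read("r2", [a, b]) + _multi_read("r3", [b, c, d])
        rescue_multimappers(reads)
        w2 = {r.five_prime_pos: r.weight for r in reads if r.read_id == "r2"}
        w3 = {r.five_prime_pos: r.weight for r in reads if r.read_id == "r3"}
        assert w2 == {10: pytest.approx(0.5), 50: pytest.approx(0.5)}
        assert w3[50] == pytest.approx(1.0)
        assert w3[90] == w3[130] == 0.0

    def test_weights_sum_to_one_per_read(self, rng):
        records, _ = make_multimap_fixture(15, 4, seed=3)
        rescue_multimappers(records)
        sums = {}
        for r in records:
            sums[r.read_id] = sums.get(r.read_id, 0.0) + r.weight
        assert all(abs(v - 1.0) < 1e-9 for v in sums.values())

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_bruteforce_oracle(self, seed):
        records, expected = make_multimap_fixture(
            n_reads=int(np.random.default_rng(seed).integers(2, 21)), n_loci=5, seed=seed
        )
        rescue_multimappers(records)
        for r in records:
            if r.multiplicity <= 1:
                continue
            loc = (r.chrom, r.strand, r.five_prime_pos)
            assert r.weight == pytest.approx(expected[r.read_id][loc], abs=1e-9)

    def test_excessive_multiplicity_discarded(self):
        locs = [("chr1", "+", p) for p in range(101)]
        reads = _multi_read("big", locs)
        stats = rescue_multimappers(reads)
        assert stats["discarded"] == 1
        assert all(r.weight == 0.0 for r in reads)


class TestBuildTracks:
    def test_two_unit_reads_stack(self):
        reads = [_unique_read("a", ("chr1", "+", 5)), _unique_read("b", ("chr1", "+", 5))]
        track, _ = build_tracks(reads)
        assert track.positions("chr1", "+")[5] == pytest.approx(2.0)

    def test_weight_times_bias(self, rng):
        from endkit.endmap import KmerBiasModel

        seq = "".join(rng.choice(list("ACGT"), 50))
        genome = GenomeIndex({"chr1": seq})
        r = _unique_read("a", ("chr1", "+", 10))
        r.weight = 0.75
        ctx = seq[10:12]
        model = KmerBiasModel(k=2, window_start=0, observed={ctx: 0.4}, background={ctx: 0.2})
        track, _ = build_tracks([r], bias_model=model, genome=genome)
        assert track.positions("chr1", "+")[10] == pytest.approx(0.375)

    def test_mass_conservation(self, rng):
        records, _ = make_multimap_fixture(18, 5, seed=11)
        rescue_multimappers(records)
        track, _ = build_tracks(records)
        n_reads = len({r.read_id for r in records})
        assert track.total_mass == pytest.approx(n_reads, abs=1e-9)
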