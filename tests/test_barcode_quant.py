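"""Read-to-barcode assignment: rule examples, oracle equivalence,
conservation, and composition properties."""

import numpy as np
import pytest

from metpool.barcode_quant import (
    AMBIGUOUS,
    InvalidReadError,
    MatchParams,
    TruncatedFastqError,
    count_barcodes,
    depth_normalize,
    estimate_composition,
    iter_fastq,
    match_read,
    reverse_complement,
)
from metpool.core_io import SampleMeta

from conftest import make_library, random_seq
from oracle import oracle_assignment, oracle_candidates


class TestMatchRule:
    def test_full_containment_at_any_offset(self, rng, small_library):
        bc = small_library.barcodes[0]
        read = random_seq(rng, 20) + bc.sequence + random_seq(rng, 29)
        assert match_read(read, small_library) == bc.id

    def test_half_overlap_is_not_enough(self, rng, small_library):
        # 13 of 26 nt is exactly 50%, which the rule reads strictly
        bc = small_library.barcodes[0]
        read = random_seq(rng, 40) + bc.sequence[:13]
        assert oracle_candidates(read, small_library) == set()
        assert match_read(read, small_library) is None

    def test_fourteen_nt_terminal_prefix_matches(self, rng, small_library):
        bc = small_library.barcodes[0]
        read = random_seq(rng, 40) + bc.sequence[:14]
        assert oracle_assignment(read, small_library) == bc.id
        assert match_read(read, small_library) == bc.id

    def test_terminal_suffix_at_read_start(self, rng, small_library):
        bc = small_library.barcodes[1]
        read = bc.sequence[-14:] + random_seq(rng, 40)
        assert match_read(read, small_library) == bc.id

    def test_two_full_barcodes_is_ambiguous(self, small_library):
        a, b = small_library.barcodes[0], small_library.barcodes[1]
        read = a.sequence + "AC" + b.sequence
        assert match_read(read, small_library) == AMBIGUOUS

    def test_reverse_complement_found_by_default(self, rng, small_library):
        bc = small_library.barcodes[2]
        read = random_seq(rng, 10) + reverse_complement(bc.sequence) + random_seq(rng, 10)
        assert match_read(read, small_library) == bc.id
        params = MatchParams(count_reverse_complement=False)
        assert match_read(read, small_library, params) is None

    def test_n_bases_never_match(self, small_library):
        bc = small_library.barcodes[0]
        read = bc.sequence.replace("A", "N")
        assert match_read(read, small_library) is None

    def test_invalid_characters_rejected(self, small_library):
        with pytest.raises(InvalidReadError):
            match_read("ACGTXACGT" * 5, small_library)

    def test_one_mismatch_tolerated_when_allowed(self, rng, small_library):
        bc = small_library.barcodes[0]
        mutated = "G" + bc.sequence[1:] if bc.sequence[0] != "G" else "T" + bc.sequence[1:]
        read = random_seq(rng, 15) + mutated + random_seq(rng, 15)
        assert match_read(read, small_library) is None
        assert match_read(read, small_library, MatchParams(max_mismatches=1)) == bc.id


@pytest.mark.parametrize("length,n_barcodes", [(8, 6), (12, 8), (26, 8)])
def test_matcher_equals_sliding_window_oracle(length, n_barcodes):
    """Randomized reads against randomized libraries: the indexed matcher
    must agree with the exhaustive offset-enumeration oracle exactly."""
    rng = np.random.default_rng(1000 + length)
    for rep in range(4):
        library = make_library(rng, n_barcodes, length)
        seqs = library.sequences
        reads = []
        for _ in range(90):
            kind = rng.integers(0, 5)
            bc = seqs[rng.integers(0, len(seqs))]
            if kind == 0:  # pure noise
                reads.append(random_seq(rng, int(rng.integers(length, 80))))
            elif kind == 1:  # embedded full barcode
                reads.append(
                    random_seq(rng, int(rng.integers(0, 30)))
                    + bc
                    + random_seq(rng, int(rng.integers(0, 30)))
                )
            elif kind == 2:  # terminal prefix of random size
                k = int(rng.integers(1, length + 1))
                reads.append(random_seq(rng, int(rng.integers(5, 40))) + bc[:k])
            elif kind == 3:  # terminal suffix of random size
                k = int(rng.integers(1, length + 1))
                reads.append(bc[-k:] + random_seq(rng, int(rng.integers(5, 40))))
            else:  # two barcodes
                other = seqs[rng.integers(0, len(seqs))]
                reads.append(bc + random_seq(rng, 3) + other)
        for mm in (0, 1):
            params = MatchParams(max_mismatches=mm)
            for read in reads:
                got = match_read(read, library, params)
                want = oracle_assignment(
                    read, library, max_mismatches=mm
                )
                assert got == want, (read, length, mm)


class TestCountBarcodes:
    def _reads(self, seqs):
        return [(f"r{i}", s) for i, s in enumerate(seqs)]

    def test_uniform_counts(self, rng, small_library, sample):
        bc = small_library.barcodes[0]
        reads = self._reads(
            random_seq(rng, 20) + bc.sequence + random_seq(rng, 20)
            for _ in range(100)
        )
        table = count_barcodes(reads, small_library, sample=sample)
        assert table.counts[0, 0] == 100
        assert table.unassigned[0] == 0 and table.ambiguous[0] == 0

    def test_mixed_counts_against_oracle(self, rng, small_library, sample):
        a, b = small_library.barcodes[0], small_library.barcodes[1]
        reads = (
            [random_seq(rng, 10) + a.sequence + random_seq(rng, 10) for _ in range(50)]
            + [b.sequence + random_seq(rng, 30) for _ in range(30)]
            + [random_seq(rng, 60) for _ in range(20)]
        )
        expected = {a.id: 0, b.id: 0, "C": 0}
        unassigned = 0
        for r in reads:
            res = oracle_assignment(r, small_library)
            if res is None:
                unassigned += 1
            elif res != "ambiguous":
                expected[res] += 1
        table = count_barcodes(self._reads(reads), small_library, sample=sample)
        got = dict(zip(small_library.ids, table.counts[:, 0]))
        assert got == expected
        assert table.unassigned[0] == unassigned

    def test_empty_input(self, small_library, sample):
        table = count_barcodes([], small_library, sample=sample)
        assert table.counts.sum() == 0
        assert table.unassigned[0] == 0

    def test_conservation_with_invalid_reads(self, rng, small_library, sample):
        bc = small_library.barcodes[0]
        reads = self._reads(
            [bc.sequence + random_seq(rng, 10), "ACGTX" + random_seq(rng, 40)]
        )
        table = count_barcodes(reads, small_library, sample=sample)
        total = int(table.counts.sum() + table.unassigned[0] + table.ambiguous[0])
        assert total == 2
        assert table.rejected_reads == 1

    def test_paired_end_fragment_counts_once(self, rng, small_library, sample):
        a, b = small_library.barcodes[0], small_library.barcodes[1]
        r1 = [("f1", a.sequence + random_seq(rng, 10)), ("f2", random_seq(rng, 40))]
        r2 = [("f1", random_seq(rng, 40)), ("f2", a.sequence + random_seq(rng, 5))]
        table = count_barcodes(r1, small_library, sample=sample, reads2=r2)
        assert table.counts[0, 0] == 2  # both fragments assigned to A once each
        # disagreeing mates -> ambiguous
        r1 = [("f1", a.sequence + random_seq(rng, 10))]
        r2 = [("f1", b.sequence + random_seq(rng, 10))]
        table = count_barcodes(r1, small_library, sample=sample, reads2=r2)
        assert table.ambiguous[0] == 1 and table.counts.sum() == 0

    def test_truncated_fastq_raises_with_index(self, tmp_path, small_library):
        path = tmp_path / "bad.fastq"
        path.write_text("@r0\nACGT\n+\nIIII\n@r1\nACGT\n")
        with pytest.raises(TruncatedFastqError, match="record 1"):
            list(iter_fastq(path))


class TestComposition:
    def _table(self, small_library, counts):
        from metpool.core_io import BarcodeCountTable

        arr = np.array(counts)
        if arr.ndim == 1:
            arr = arr[:, None]
        return BarcodeCountTable(
            counts=arr,
            library=small_library,
            samples=[SampleMeta(sample_id=f"s{i}") for i in range(arr.shape[1])],
        )

    def test_equal_split(self, small_library):
        comp = estimate_composition(self._table(small_library, [50, 50, 0]))
        assert np.allclose(comp.fractions[:, 0], [0.5, 0.5, 0.0])

    def test_single_line_dominates(self, small_library):
        comp = estimate_composition(self._table(small_library, [0, 100, 0]))
        assert np.allclose(comp.fractions[:, 0], [0.0, 1.0, 0.0])

    def test_three_way(self, small_library):
        comp = estimate_composition(self._table(small_library, [30, 20, 50]))
        assert np.allclose(comp.fractions[:, 0], [0.3, 0.2, 0.5])

    def test_zero_sample_flagged_undefined(self, small_library):
        comp = estimate_composition(self._table(small_library, [0, 0, 0]))
        assert not comp.defined[0]
        assert np.isnan(comp.fractions[:, 0]).all()

    def test_pseudocount_defines_zero_sample(self, small_library):
        comp = estimate_composition(self._table(small_library, [0, 0, 0]), pseudocount=1)
        assert np.allclose(comp.fractions[:, 0], 1 / 3)

    def test_negative_pseudocount_rejected(self, small_library):
        with pytest.raises(ValueError):
            estimate_composition(self._table(small_library, [1, 1, 1]), pseudocount=-1)

    def test_simplex_and_monotonicity(self, rng, small_library):
        counts = rng.integers(0, 500, size=(3, 6))
        counts[:, 0] += 1  # avoid the degenerate column
        table = self._table(small_library, counts)
        comp = estimate_composition(table)
        sums = np.nansum(comp.fractions, axis=0)
        assert np.all(np.abs(sums[comp.defined] - 1) < 1e-12)
        # adding reads for barcode 0 never decreases its fraction
        bumped = counts.copy()
        bumped[0] += 37
        comp2 = estimate_composition(self._table(small_library, bumped))
        assert np.all(
            comp2.fractions[0, comp.defined] >= comp.fractions[0, comp.defined] - 1e-15
        )


class TestDepthNormalize:
    def test_scales_to_cpm(self, small_library):
        t = TestComposition()._table(small_library, [800, 200, 0])
        norm = depth_normalize(t)
        assert np.allclose(norm[:, 0], [800000, 200000, 0])

    def test_proportional_samples_identical(self, small_library):
        t = TestComposition()._table(
            small_library, np.array([[10, 30], [20, 60], [70, 210]])
        )
        norm = depth_normalize(t)
        assert np.allclose(norm[:, 0], norm[:, 1])

    def test_zero_total_sample_named(self, small_library):
        t = TestComposition()._table(small_library, np.array([[1, 0], [1, 0], [1, 0]]))
        with pytest.raises(ValueError, match="s1"):
            depth_normalize(t)
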