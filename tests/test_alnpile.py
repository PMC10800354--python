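import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trmc import alnpile, simreads
from trmc.alnpile import (
    AlignmentHit,
    align_reads,
    build_pileup,
    compute_rates,
    ingest_sam,
    trim_adapter,
)
from trmc.refset import ReferenceRecord
from trmc.simreads import FastqRead


def mkref(ref_id, seq, group=None):
    return ReferenceRecord(ref_id, "unknown", "", seq, group or ref_id)


def brute_force_best(read: str, refs: list[str]) -> int:
    """Minimum Hamming distance of the read over every ungapped offset
    of every reference (independent oracle)."""
    best = len(read) + 1
    for ref in refs:
        for off in range(len(ref) - len(read) + 1):
            d = sum(a != b for a, b in zip(read, ref[off : off + len(read)]))
            best = min(best, d)
    return best


REF_A = "ACGTACGTACGTACGTACGTGGGGCCCCAAAATTTT"
REF_B = "TTTTAAAACCCCGGGGTGCATGCATGCATGCATGCA"


class TestAlign:
    def test_perfect_substring_single_hit(self):
        refs = [mkref("a", REF_A), mkref("b", REF_B)]
        read = FastqRead("r1", REF_A[4:24], "I" * 20)
        hits = align_reads([read], refs)
        assert len(hits) == 1
        h = hits[0]
        assert (h.ref_id, h.start, h.end, h.n_mismatch, h.weight) == ("a", 5, 24, 0, 1.0)

    def test_three_mismatches_unmapped(self):
        refs = [mkref("a", REF_A)]
        read = list(REF_A)
        read[0], read[5], read[10] = "T", "G", "C"  # three substitutions
        hits = align_reads([FastqRead("r1", "".join(read), "I" * len(read))], refs)
        assert hits == []

    def test_two_mismatches_mapped(self):
        refs = [mkref("a", REF_A)]
        read = list(REF_A)
        read[0], read[5] = "T", "G"
        hits = align_reads([FastqRead("r1", "".join(read), "")], refs)
        assert len(hits) == 1
        assert hits[0].n_mismatch == 2

    def test_identical_references_one_group_hit(self):
        refs = [mkref("a1", REF_A, "grp"), mkref("a2", REF_A, "grp")]
        hits = align_reads([FastqRead("r1", REF_A[:20], "")], refs)
        assert len(hits) == 1
        assert hits[0].weight == 1.0
        assert hits[0].ref_id == "grp"

    def test_tie_across_groups_fractional_weights(self):
        shared = "ACGTACGTACGTACGTACGT"
        refs = [
            mkref("a", shared + "GGGGGGGGGGGG"),
            mkref("b", shared + "TTTTTTTTTTTT"),
        ]
        hits = align_reads([FastqRead("r1", shared, "")], refs)
        assert len(hits) == 2
        assert all(h.weight == 0.5 for h in hits)
        assert sum(h.weight for h in hits) == 1.0

    def test_high_n_read_skipped(self):
        refs = [mkref("a", REF_A)]
        hits = align_reads([FastqRead("r1", "N" * 15 + REF_A[:5], "")], refs)
        assert hits == []

    def test_empty_reference_set_errors(self):
        with pytest.raises(ValueError):
            align_reads([FastqRead("r1", "ACGT", "")], [])

    @settings(max_examples=60, deadline=None)
    @given(st.data())
    def test_matches_brute_force_hamming(self, data):
        rng_seqs = st.text(alphabet="ACGT", min_size=25, max_size=100)
        n_refs = data.draw(st.integers(1, 10))
        refs = [data.draw(rng_seqs) for _ in range(n_refs)]
        base = data.draw(st.integers(0, n_refs - 1))
        mut_n = data.draw(st.integers(0, 3))
        src = refs[base]
        read_len = data.draw(st.integers(15, len(src)))
        start = data.draw(st.integers(0, len(src) - read_len))
        read = list(src[start : start + read_len])
        for _ in range(mut_n):
            i = data.draw(st.integers(0, read_len - 1))
            read[i] = data.draw(st.sampled_from("ACGT"))
        read = "".join(read)

        records = [mkref(f"r{i}", s) for i, s in enumerate(refs)]
        hits = align_reads([FastqRead("q", read, "")], records, max_mismatch=2)
        oracle = brute_force_best(read, refs)
        if oracle <= 2:
            assert hits, f"oracle found distance {oracle} but aligner unmapped"
            assert hits[0].n_mismatch == oracle
        else:
            assert hits == []


class TestAdapter:
    def test_full_adapter_removed(self):
        assert trim_adapter("ACGTACGT" + "AGATCGGAAGAG", "AGATCGGAAGAG") == "ACGTACGT"

    def test_partial_adapter_suffix(self):
        assert trim_adapter("ACGTACGT" + "AGATC", "AGATCGGAAGAG") == "ACGTACGT"

    def test_untrimmed_read_unchanged(self):
        assert trim_adapter("ACGTACGTACGT", "AGATCGGAAGAG") == "ACGTACGTACGT"


class TestIngestSam:
    def _write_sam(self, tmp_path, lines):
        path = tmp_path / "aln.sam"
        header = f"@SQ\tSN:a\tLN:{len(REF_A)}\n"
        path.write_text(header + "".join(lines))
        return path

    def test_perfect_primary_alignment(self, tmp_path):
        refs = [mkref("a", REF_A)]
        seq = REF_A[4:24]
        sam = self._write_sam(
            tmp_path, [f"r1\t0\ta\t5\t42\t20M\t*\t0\t0\t{seq}\tIIIIIIIIIIIIIIIIIIII\tNM:i:0\n"]
        )
        hits = ingest_sam(sam, refs)
        assert len(hits) == 1
        assert (hits[0].start, hits[0].end, hits[0].n_mismatch) == (5, 24, 0)

    def test_unmapped_record_ignored(self, tmp_path):
        refs = [mkref("a", REF_A)]
        sam = self._write_sam(tmp_path, ["r1\t4\t*\t0\t0\t*\t*\t0\t0\tACGT\tIIII\n"])
        assert ingest_sam(sam, refs) == []

    def test_nm_above_cap_dropped(self, tmp_path):
        refs = [mkref("a", REF_A)]
        seq = REF_A[0:20]
        sam = self._write_sam(
            tmp_path, [f"r1\t0\ta\t1\t42\t20M\t*\t0\t0\t{seq}\t{'I'*20}\tNM:i:5\n"]
        )
        assert ingest_sam(sam, refs) == []

    def test_nm_computed_when_absent(self, tmp_path):
        refs = [mkref("a", REF_A)]
        seq = "T" + REF_A[1:20]
        sam = self._write_sam(
            tmp_path, [f"r1\t0\ta\t1\t42\t20M\t*\t0\t0\t{seq}\t{'I'*20}\n"]
        )
        hits = ingest_sam(sam, refs)
        assert len(hits) == 1 and hits[0].n_mismatch == 1

    def test_unknown_target_errors(self, tmp_path):
        refs = [mkref("other", REF_B)]
        path = tmp_path / "aln.sam"
        path.write_text(
            f"@SQ\tSN:a\tLN:{len(REF_A)}\n"
            f"r1\t0\ta\t1\t42\t4M\t*\t0\t0\tACGT\tIIII\n"
        )
        with pytest.raises(ValueError, match="a"):
            ingest_sam(path, refs)


class TestPileup:
    def test_identical_perfect_reads(self):
        refs = [mkref("a", REF_A)]
        reads = [FastqRead(f"r{i}", REF_A[:30], "") for i in range(10)]
        hits = align_reads(reads, refs)
        pile = build_pileup(hits, reads, refs)
        depth = pile.depth("a")
        assert (depth[:30] == 10).all()
        assert (depth[30:] == 0).all()
        # only reference-base counters incremented
        rates = compute_rates(pile, refs, min_depth=1)
        assert (rates["misinc_rate"][:30] == 0).all()

    def test_mixed_base_counts(self):
        seq = "AAAACCCCGGGGTTTTAAAA"
        refs = [mkref("a", seq)]
        reads = [FastqRead(f"c{i}", seq, "") for i in range(8)]
        mutant = seq[:4] + "T" + seq[5:]
        reads += [FastqRead(f"t{i}", mutant, "") for i in range(2)]
        hits = align_reads(reads, refs)
        pile = build_pileup(hits, reads, refs)
        assert pile.base_counts["a"][1, 4] == 8  # C
        assert pile.base_counts["a"][3, 4] == 2  # T
        assert pile.depth("a")[4] == 10

    def test_fractional_weights_split(self):
        shared = "ACGTACGTACGTACGTACGT"
        refs = [
            mkref("a", shared + "GGGGGGGGGGGG"),
            mkref("b", shared + "TTTTTTTTTTTT"),
        ]
        reads = [FastqRead("r1", shared, "")]
        hits = align_reads(reads, refs)
        pile = build_pileup(hits, reads, refs)
        assert pile.depth("a")[0] == 0.5
        assert pile.depth("b")[0] == 0.5

    def test_end_counters(self):
        refs = [mkref("a", REF_A)]
        reads = [FastqRead("r1", REF_A[4:24], "")]
        hits = align_reads(reads, refs)
        pile = build_pileup(hits, reads, refs)
        assert pile.five_prime["a"][4] == 1
        assert pile.three_prime["a"][23] == 1

    def test_conservation(self):
        rng = np.random.default_rng(0)
        refs = [mkref("a", REF_A), mkref("b", REF_B)]
        reads = []
        for i in range(50):
            src = REF_A if i % 2 else REF_B
            ln = int(rng.integers(15, len(src) + 1))
            off = int(rng.integers(0, len(src) - ln + 1))
            reads.append(FastqRead(f"r{i}", src[off : off + ln], ""))
        hits = align_reads(reads, refs)
        pile = build_pileup(hits, reads, refs)
        total_depth = sum(pile.depth(g).sum() for g in pile.sequences)
        read_len = {r.read_id: len(r.sequence) for r in reads}
        expected = sum(read_len[h.read_id] * h.weight for h in hits)
        assert total_depth == pytest.approx(expected)

    def test_roundtrip_through_frame(self):
        refs = [mkref("a", REF_A)]
        reads = [FastqRead("r1", REF_A, "")]
        hits = align_reads(reads, refs)
        pile = build_pileup(hits, reads, refs)
        df = pile.to_frame()
        pile2 = alnpile.Pileup.from_frame(df, refs)
        assert np.allclose(pile.base_counts["a"], pile2.base_counts["a"])


class TestRates:
    def _single_pos_pile(self, counts):
        seq = "C" * 10
        refs = [mkref("a", seq)]
        pile = alnpile.Pileup(refs)
        for base, n in counts.items():
            pile.base_counts["a"]["ACGT".index(base), 4] = n
        return pile, refs

    def test_arithmetic_example(self):
        pile, refs = self._single_pos_pile({"C": 80, "T": 20})
        rates = compute_rates(pile, refs, min_depth=1)
        row = rates[rates["pos"] == 5].iloc[0]
        assert row["misinc_rate"] == pytest.approx(0.20)
        assert row["dominant_alt"] == "T"
        assert row["ct_rate"] == pytest.approx(0.20)

    def test_depth_zero_nan(self):
        pile, refs = self._single_pos_pile({})
        rates = compute_rates(pile, refs, min_depth=1)
        assert np.isnan(rates[rates["pos"] == 1].iloc[0]["misinc_rate"])

    def test_all_reference_base(self):
        pile, refs = self._single_pos_pile({"C": 50})
        rates = compute_rates(pile, refs, min_depth=1)
        assert rates[rates["pos"] == 5].iloc[0]["misinc_rate"] == 0.0

    def test_low_coverage_flag(self):
        pile, refs = self._single_pos_pile({"C": 10})
        rates = compute_rates(pile, refs, min_depth=50)
        assert rates[rates["pos"] == 5].iloc[0]["low_coverage"]

    def test_rate_recovery_from_simulation(self):
        records, _ = simreads.synthetic_references((("Ser", "GCT", 1, 76, (12,)),))
        cfg = simreads.SimConfig(
            records,
            [simreads.Site(records[0].ref_id, 12, 0.25)],
            depth_per_ref=2000,
            background_error=0.002,
            seed=6,
        )
        reads, truth = simreads.simulate_library(cfg)
        hits = align_reads(reads, records)
        pile = build_pileup(hits, reads, records)
        rates = compute_rates(pile, records)
        row = rates[(rates["ref"] == records[0].ref_id) & (rates["pos"] == 12)].iloc[0]
        realized = truth.realized_mismatches[(records[0].ref_id, 12)]
        # realized counts every non-C draw; the pileup loses the few reads
        # whose site T plus two background errors exceed the mismatch cap
        assert row["misinc_rate"] * row["depth"] == pytest.approx(realized, abs=15)
        assert row["dominant_alt"] == "T"
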