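"""Read restructuring: quality trimming, anchor location, pair emission."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mnsbs import THREE_PRIME, FIVE_PRIME, PhredRead
from mnsbs.chemistry import AnchorKind, DiscardReason, reverse_complement
from mnsbs.restructure import (
    SimulatedPair,
    convert_stream,
    locate_anchor,
    quality_trim_3prime,
    restructure_read,
)
from mnsbs.simulate import simulate_reads

from conftest import random_phred_read


def brute_force_trim(quals, threshold):
    """Oracle: evaluate S_i at every cut point, keep the longest minimiser."""
    n = len(quals)
    best_i, best_s = n, 0  # S_n = 0 (no trim)
    for i in range(n - 1, -1, -1):
        s = sum(q - threshold for q in quals[i:])
        if s < best_s or (s == best_s and i > best_i):
            best_i, best_s = i, s
    # ties between no-trim and an interior minimum of 0 keep the read whole
    return n if best_s >= 0 else best_i


class TestQualityTrim:
    @pytest.mark.parametrize(
        "quals,threshold,expected_len",
        [
            ([40] * 5, 30, 5),          # no negative partial sum
            ([40, 40, 2, 2, 2], 30, 2),  # minimum at the quality cliff
            ([2] * 5, 30, 0),            # whole read below threshold
            ([], 30, 0),
        ],
    )
    def test_examples(self, quals, threshold, expected_len):
        read = PhredRead("r", "A" * len(quals), list(quals))
        out = quality_trim_3prime(read, threshold)
        assert len(out) == expected_len
        assert out.bases == read.bases[:expected_len]
        assert out.quals == quals[:expected_len]

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(42)
        for i in range(10_000):
            read = random_phred_read(rng, f"r{i}", 0, 30)
            got = len(quality_trim_3prime(read, 30))
            assert got == brute_force_trim(read.quals, 30), read.quals

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            quality_trim_3prime(PhredRead("r", "A", [30]), -1)


class TestLocateAnchor:
    def _read(self, prefix_len, tail):
        bases = "G" * prefix_len + tail
        return PhredRead("r", bases, [37] * len(bases))

    def test_polyt_at_threshold(self):
        read = self._read(28, "T" * 8 + "ACGTACGT")
        assert locate_anchor(read, THREE_PRIME) == (28, 36)

    def test_polyt_below_threshold(self):
        read = self._read(28, "T" * 7 + "ACGTACGT")
        assert locate_anchor(read, THREE_PRIME) is None

    def test_polyt_span_covers_maximal_run(self):
        read = self._read(28, "T" * 12 + "AACGT")
        assert locate_anchor(read, THREE_PRIME) == (28, 40)

    @pytest.mark.parametrize("n_mm,found", [(0, True), (2, True), (3, False)])
    def test_tso_mismatch_budget(self, n_mm, found):
        tso = list(FIVE_PRIME.tso_seq)
        for i in range(n_mm):
            tso[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[tso[i]]
        read = self._read(26, "".join(tso) + "ACGT" * 15)
        span = locate_anchor(read, FIVE_PRIME)
        if found:
            assert span == (26, 26 + len(FIVE_PRIME.tso_seq))
        else:
            assert span is None

    def test_short_read_returns_none(self):
        read = self._read(10, "TTTT")
        assert locate_anchor(read, THREE_PRIME) is None


class TestRestructure:
    def test_3prime_trace(self):
        """Hand-constructed trace: 28-base prefix, 12 Ts, 100-base cDNA."""
        rng = np.random.default_rng(0)
        prefix = "".join(rng.choice(list("ACG"), size=28))
        cdna = "A" + "".join(rng.choice(list("ACGT"), size=99))
        bases = prefix + "T" * 12 + cdna
        read = PhredRead("r", bases, [37] * len(bases))
        pair = restructure_read(read, THREE_PRIME)
        assert isinstance(pair, SimulatedPair)
        assert pair.anchor_span == (28, 40)
        assert len(pair.r2) == 90
        assert pair.r2.bases == reverse_complement(cdna[5:95])
        assert pair.r1.bases[:25] == prefix[:25]
        assert pair.r1.bases[25:] == "AAA"
        assert pair.r1.quals[25:] == [40, 40, 40]

    def test_short_cdna_boundary(self):
        prefix = "G" * 28
        for clen, expect_pair in [(54, False), (55, True)]:
            bases = prefix + "T" * 10 + "A" + "C" * (clen - 1)
            read = PhredRead("r", bases, [37] * len(bases))
            out = restructure_read(read, THREE_PRIME)
            # 10-T anchor, clip 5: retained cDNA = clen - 5
            if expect_pair:
                assert isinstance(out, SimulatedPair)
                assert len(out.r2) == clen - 5
            else:
                assert out is DiscardReason.SHORT_CDNA

    def test_5prime_trace(self):
        prefix = "G" * 26
        cdna = "ACGT" * 15  # 60 bases
        bases = prefix + FIVE_PRIME.tso_seq + cdna
        read = PhredRead("r", bases, [37] * len(bases))
        pair = restructure_read(read, FIVE_PRIME)
        assert isinstance(pair, SimulatedPair)
        assert pair.r2.bases == reverse_complement(cdna[3:60])
        assert len(pair.r2) == 57
        assert pair.r1.bases == prefix  # no masking in 5' chemistry

    def test_too_short_after_trim(self):
        bases = "G" * 40
        read = PhredRead("r", bases, [2] * 40)  # trimmed to nothing
        assert restructure_read(read, THREE_PRIME) is DiscardReason.TOO_SHORT

    def test_mask_trim_mode(self):
        bases = "G" * 28 + "T" * 10 + "A" * 100
        read = PhredRead("r", bases, [37] * len(bases))
        pair = restructure_read(read, THREE_PRIME, mask_mode="trim")
        assert len(pair.r1) == 25


@settings(max_examples=200, deadline=None)
@given(st.text(alphabet="ACGTN", max_size=60))
def test_reverse_complement_involution(s):
    assert reverse_complement(reverse_complement(s)) == s


def test_quality_reversal_involution():
    rng = np.random.default_rng(1)
    read = random_phred_read(rng, "r", 10, 40)
    assert read.quals[::-1][::-1] == read.quals


class TestConvertStream:
    def test_empty(self):
        pairs, rep = convert_stream([], THREE_PRIME)
        assert pairs == [] and rep.n_input == 0

    def test_mixed_composition(self):
        clean = "G" * 28 + "T" * 10 + "A" + "C" * 99
        anchorless = "G" * 28 + "T" * 7 + "A" + "C" * 99
        reads = [PhredRead(f"r{i}", clean, [37] * len(clean)) for i in range(3)]
        reads.insert(1, PhredRead("bad", anchorless, [37] * len(anchorless)))
        pairs, rep = convert_stream(reads, THREE_PRIME)
        assert len(pairs) == 3
        assert rep.n_no_anchor == 1
        assert [p.source_id for p in pairs] == ["r0", "r1", "r2"]

    def test_roundtrip_against_fixture_truth(self):
        reads, truth = simulate_reads(
            THREE_PRIME, n_reads=3000, seed=9,
            frac_no_anchor=0.05, frac_short_cdna=0.05,
        )
        pairs, rep = convert_stream(reads, THREE_PRIME)
        expected = truth["expected_outcome"].value_counts()
        assert rep.n_emitted == expected.get("emitted", 0)
        assert rep.n_no_anchor == expected.get("no_anchor", 0)
        assert rep.n_short_cdna == expected.get("short_cdna", 0)
        tmap = truth.set_index("read_id")
        for p in pairs:
            t = tmap.loc[p.source_id]
            assert p.r1.bases[:16] == t["cbc"]
            assert p.r1.bases[16:25] == t["umi"][:9]
            assert reverse_complement(p.r2.bases) == t["cdna_kept"]

    def test_5prime_roundtrip_against_fixture_truth(self):
        reads, truth = simulate_reads(
            FIVE_PRIME, n_reads=1500, seed=17, frac_no_anchor=0.05
        )
        pairs, rep = convert_stream(reads, FIVE_PRIME)
        expected = truth["expected_outcome"].value_counts()
        assert rep.n_emitted == expected.get("emitted", 0)
        assert rep.n_no_anchor == expected.get("no_anchor", 0)
        tmap = truth.set_index("read_id")
        for p in pairs:
            t = tmap.loc[p.source_id]
            assert p.r1.bases == t["cbc"] + t["umi"]  # 5' UMIs unmasked
            assert reverse_complement(p.r2.bases) == t["cdna_kept"]

    def test_malformed_fastq_reports_record_index(self, tmp_path):
        from mnsbs.fastq import read_fastq

        path = tmp_path / "bad.fastq"
        path.write_text("@r0\nACGT\n+\nIIII\n@r1\nACGT\nnot-a-plus\nIIII\n")
        with pytest.raises(ValueError, match="index 1"):
            list(read_fastq(path))

    def test_counter_conservation(self):
        rng = np.random.default_rng(3)
        reads = [random_phred_read(rng, f"r{i}", 0, 150) for i in range(500)]
        _, rep = convert_stream(reads, THREE_PRIME)
        rep.check()
        assert rep.n_input == 500
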