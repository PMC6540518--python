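import math
import random
from collections import Counter

import pytest

from conftest import make_read
from oracles import (
    oracle_detect_singletons,
    oracle_scan_hexamers,
    random_telomere_like_sequence,
    revcomp,
)
from telomere_profiler.tvr import (
    DEFAULT_TVR_CONTEXT_LIST,
    TvrSampleCounts,
    detect_singletons,
    extract_contexts,
    scan_hexamers,
    summarize_tvr_profile,
)

T = "TTAGGG"


class TestScanHexamers:
    def test_pure_ttype_tiling(self):
        assert scan_hexamers(make_read(T * 10)) == {T: 10}

    def test_single_variant_among_ttype(self):
        read = make_read(T * 4 + "TGAGGG" + T * 5)
        assert scan_hexamers(read) == {T: 9, "TGAGGG": 1}

    def test_low_quality_base_drops_one_count(self):
        qualities = [30] * 60
        qualities[14] = 10  # third repeat, middle base
        read = make_read(T * 10, qualities=qualities)
        assert scan_hexamers(read) == {T: 9}

    def test_antisense_reported_forward(self):
        assert scan_hexamers(make_read("CCCTAA" * 10)) == {T: 10}

    def test_arbitrary_nnnggg_counted(self):
        read = make_read("AAAGGG" + T * 6)
        assert scan_hexamers(read) == {"AAAGGG": 1, T: 6}

    def test_n_bases_never_match(self):
        assert scan_hexamers(make_read("TTANGG" * 10)) == {}

    def test_low_quality_match_still_advances_scan_frame(self):
        # failed-quality match consumes its 6 bases: the next repeat stays in frame
        qualities = [30] * 18
        qualities[0] = 5
        read = make_read(T * 3, qualities=qualities)
        assert scan_hexamers(read) == {T: 2}

    def test_quality_monotonicity(self):
        rng = random.Random(11)
        for _ in range(200):
            seq = random_telomere_like_sequence(rng, max_length=150)
            quals = [rng.randrange(0, 45) for _ in seq]
            read = make_read(seq, qualities=quals)
            strict = scan_hexamers(read, min_base_quality=30)
            lax = scan_hexamers(read, min_base_quality=10)
            for hexamer, count in strict.items():
                assert lax.get(hexamer, 0) >= count


class TestDetectSingletons:
    def test_canonical_singleton(self):
        read = make_read(T * 3 + "TCAGGG" + T * 3)
        assert detect_singletons(read) == {"TCAGGG": 1}

    def test_insufficient_left_flank(self):
        read = make_read(T * 2 + "TCAGGG" + T * 3)
        assert detect_singletons(read) == {}

    def test_pure_ttype_no_singleton(self):
        assert detect_singletons(make_read(T * 10)) == {}

    def test_longer_flanks_still_qualify(self):
        read = make_read(T * 4 + "TCAGGG" + T * 4)
        assert detect_singletons(read) == {"TCAGGG": 1}

    def test_antisense_singleton_reported_forward(self):
        read = make_read(revcomp(T * 3 + "TCAGGG" + T * 3))
        assert detect_singletons(read) == {"TCAGGG": 1}

    def test_central_quality_filter(self):
        seq = T * 3 + "TCAGGG" + T * 3
        qualities = [30] * len(seq)
        qualities[20] = 10  # inside the central hexamer
        assert detect_singletons(make_read(seq, qualities=qualities)) == {}

    def test_flank_quality_ignored(self):
        seq = T * 3 + "TCAGGG" + T * 3
        qualities = [30] * len(seq)
        qualities[0] = 2  # flank base: quality rule applies to central hexamer only
        assert detect_singletons(make_read(seq, qualities=qualities)) == {"TCAGGG": 1}

    def test_two_adjacent_variants_not_singletons(self):
        read = make_read(T * 3 + "TCAGGG" + "TGAGGG" + T * 3)
        assert detect_singletons(read) == {}


class TestExtractContexts:
    def test_flanks_recorded(self):
        read = make_read(T * 3 + "TCAGGG" + T * 3 + "ACGTAC")
        table = extract_contexts(read)
        assert table["TCAGGG"] == Counter({(T * 3, T * 3): 1})

    def test_incomplete_left_flank_dropped(self):
        read = make_read("ACGTA" + "TCAGGG" + T * 4)
        assert extract_contexts(read) == {}

    def test_singleton_context_is_ttype_flanks(self):
        read = make_read(T * 4 + "TGAGGG" + T * 4)
        ((left, right), count), = extract_contexts(read)["TGAGGG"].items()
        assert left == T * 3 and right == T * 3 and count == 1

    def test_antisense_occurrence_reported_forward(self):
        fwd = T * 3 + "TCAGGG" + T * 3
        table = extract_contexts(make_read(revcomp(fwd)))
        assert table["TCAGGG"] == Counter({(T * 3, T * 3): 1})

    def test_unlisted_tvr_ignored(self):
        read = make_read(T * 3 + "AAAGGG" + T * 3)
        assert "AAAGGG" not in extract_contexts(read)

    def test_custom_list(self):
        read = make_read(T * 3 + "AAAGGG" + T * 3)
        table = extract_contexts(read, tvr_list=["AAAGGG"])
        assert table["AAAGGG"] == Counter({(T * 3, T * 3): 1})

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            extract_contexts(make_read(T * 7), tvr_list=[])


class TestOracleEquivalence:
    def test_scan_hexamers_matches_regex_oracle(self):
        rng = random.Random(5)
        for _ in range(2000):
            seq = random_telomere_like_sequence(rng)
            quals = [rng.randrange(0, 45) for _ in seq]
            read = make_read(seq, qualities=quals)
            assert scan_hexamers(read) == oracle_scan_hexamers(seq, quals, 20), seq

    def test_detect_singletons_matches_window_oracle(self):
        rng = random.Random(6)
        for _ in range(2000):
            seq = random_telomere_like_sequence(rng)
            quals = [rng.randrange(0, 45) for _ in seq]
            read = make_read(seq, qualities=quals)
            assert detect_singletons(read) == oracle_detect_singletons(seq, quals, 20), seq


class TestInvariants:
    def test_singleton_subset_of_arbitrary(self):
        rng = random.Random(8)
        for _ in range(500):
            seq = random_telomere_like_sequence(rng)
            read = make_read(seq)
            hexamers = scan_hexamers(read)
            for hexamer, count in detect_singletons(read).items():
                assert hexamers.get(hexamer, 0) >= count, seq

    def test_strand_symmetry_on_tiled_reads(self):
        # per-hexamer symmetry holds where the scan frame is locked
        # (hexamer tilings); arbitrary G-runs can re-frame between strands
        from telomere_profiler.simulate import make_telomere_sequence

        rng = random.Random(9)
        for _ in range(500):
            seq, _, _ = make_telomere_sequence(
                120, {"TGAGGG": 0.1, "TTGGGG": 0.1}, 0.3, rng
            )
            fwd = make_read(seq)
            rev = make_read(revcomp(seq))
            assert scan_hexamers(fwd) == scan_hexamers(rev), seq
            assert detect_singletons(fwd) == detect_singletons(rev), seq

    def test_singleton_strand_symmetry_on_random_reads(self):
        # singleton detection enumerates all windows, so it is symmetric
        # even on arbitrary sequences
        rng = random.Random(10)
        for _ in range(500):
            seq = random_telomere_like_sequence(rng)
            fwd = make_read(seq)
            rev = make_read(revcomp(seq))
            assert detect_singletons(fwd) == detect_singletons(rev), seq


class TestSummarizeTvrProfile:
    def _counts(self, hexamers, singletons, n_intra, n_total):
        counts = TvrSampleCounts(
            hexamers=Counter(hexamers),
            singletons=Counter(singletons),
            intratelomeric_read_count=n_intra,
            total_read_count=n_total,
        )
        return counts

    def test_identical_composition_log2_zero(self):
        sample = self._counts({T: 100, "TCAGGG": 10}, {"TCAGGG": 4}, 10, 1000)
        profile = summarize_tvr_profile(sample, sample)
        assert (profile.hexamer_table["log2_tc"] == 0).all()
        assert (profile.singleton_table["log2_tc"] == 0).all()

    def test_fourfold_singleton_rate_log2_two(self):
        tumor = self._counts({T: 100}, {"TCAGGG": 8}, 10, 1000)
        control = self._counts({T: 100}, {"TCAGGG": 2}, 10, 1000)
        profile = summarize_tvr_profile(tumor, control)
        row = profile.singleton_table.set_index("hexamer").loc["TCAGGG"]
        assert row["log2_tc"] == pytest.approx(2.0)

    def test_normalizations(self):
        tumor = self._counts({T: 90, "TGAGGG": 10}, {"TGAGGG": 5}, 20, 500)
        profile = summarize_tvr_profile(tumor)
        hexamers = profile.hexamer_table.set_index("hexamer")
        assert hexamers.loc["TGAGGG", "tumor_normalized"] == pytest.approx(10 / 20)
        singles = profile.singleton_table.set_index("hexamer")
        assert singles.loc["TGAGGG", "tumor_normalized"] == pytest.approx(5 / 500)

    def test_hexamer_missing_on_one_side_flagged_nan(self):
        tumor = self._counts({T: 90, "TGAGGG": 10}, {}, 10, 100)
        control = self._counts({T: 90}, {}, 10, 100)
        profile = summarize_tvr_profile(tumor, control)
        row = profile.hexamer_table.set_index("hexamer").loc["TGAGGG"]
        assert math.isnan(row["log2_tc"])

    def test_zero_intratelomeric_flagged(self):
        tumor = self._counts({}, {}, 0, 100)
        profile = summarize_tvr_profile(tumor)
        assert profile.hexamer_table.empty

    def test_unpaired_has_no_log2_columns(self):
        tumor = self._counts({T: 10}, {}, 5, 100)
        profile = summarize_tvr_profile(tumor)
        assert "log2_tc" not in profile.hexamer_table.columns
        assert not profile.paired

    def test_context_table_schema(self):
        counts = TvrSampleCounts(intratelomeric_read_count=1, total_read_count=1)
        counts.add_read(make_read(T * 4 + "TCAGGG" + T * 4))
        profile = summarize_tvr_profile(counts)
        row = profile.context_table.iloc[0]
        assert row["tvr"] == "TCAGGG"
        assert row["left_flank"] == T * 3 and row["right_flank"] == T * 3
        assert row["count"] == 1

    def test_default_context_list_has_ten_non_ttype_entries(self):
        assert len(DEFAULT_TVR_CONTEXT_LIST) == 10
        assert T not in DEFAULT_TVR_CONTEXT_LIST
        assert all(len(h) == 6 and h.endswith("GGG") for h in DEFAULT_TVR_CONTEXT_LIST)
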