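"""Read containers, FASTQ round-trips, trimming, concatemer flagging, filters."""

import io

import numpy as np
import pytest

from doodlekit.qc import (
    FilterParams,
    apply_filters,
    extract_between_flanks,
    flag_concatemers,
    is_concatemer,
    median_q,
    qc_pipeline,
    trim_terminal_adapters,
)
from doodlekit.reads import AdapterSet, FastqParseError, Read, ReadPool, load_fastq, write_fastq
from doodlekit.simulate import (
    DEFAULT_ADAPTER,
    LengthModel,
    PoolComponent,
    PoolSpec,
    add_sequencing_artifacts,
    simulate_pool,
)

from conftest import make_read

ADAPTER = DEFAULT_ADAPTER


class TestFastqIO:
    def test_single_record_phred33(self):
        pool = load_fastq(io.StringIO("@r1\nACGT\n+\nIIII\n"))
        assert len(pool) == 1
        assert pool[0].sequence == "ACGT"
        assert list(pool[0].qualities) == [40, 40, 40, 40]

    def test_empty_file_gives_empty_pool(self):
        assert len(load_fastq(io.StringIO(""))) == 0

    def test_length_mismatch_is_parse_error(self):
        with pytest.raises(FastqParseError, match="index 0"):
            load_fastq(io.StringIO("@r1\nACGT\n+\nIII\n"))

    def test_round_trip_identity(self, tmp_path, random_pool):
        path = tmp_path / "pool.fastq"
        write_fastq(random_pool, path)
        back = load_fastq(path)
        assert len(back) == len(random_pool)
        for a, b in zip(random_pool, back):
            assert a.sequence == b.sequence
            assert np.array_equal(a.qualities, b.qualities)

    def test_sequence_quality_length_must_match(self):
        with pytest.raises(ValueError):
            Read("bad", "ACGT", np.array([30, 30]))


class TestMedianQ:
    @pytest.mark.parametrize(
        "quals, expected",
        [([10, 13, 20], 13.0), ([10, 20], 15.0), ([17] * 5, 17.0)],
    )
    def test_median_conventions(self, quals, expected):
        read = Read("r", "A" * len(quals), np.array(quals))
        assert median_q(read) == expected

    def test_empty_read_undefined(self):
        with pytest.raises(ValueError):
            median_q(Read("r", "", np.array([], dtype=int)))


class TestTrimming:
    def test_exact_prefix_adapter_removed(self, adapter_set):
        core = "ACGTAC" * 20
        read = make_read(ADAPTER + core)
        out = trim_terminal_adapters(read, adapter_set, FilterParams())
        assert out.sequence == core
        assert "trimmed_5p" in out.flags

    def test_clean_read_unchanged(self, adapter_set):
        read = make_read("ACGGTCAGTT" * 15)
        out = trim_terminal_adapters(read, adapter_set, FilterParams())
        assert out.sequence == read.sequence
        assert not out.flags

    def test_one_mismatch_adapter_still_trimmed(self):
        # 20-nt adapter with one mismatch at the 5' end: identity 0.95 >= 0.8
        adapter = "ACGTACGTACGTACGTACGT"
        mutated = "T" + adapter[1:]
        adapters = AdapterSet((adapter,))
        core = "CCGGTTAACCGGTTAA" * 10
        out = trim_terminal_adapters(make_read(mutated + core), adapters, FilterParams())
        assert out.sequence == core

    def test_trimming_is_idempotent(self, adapter_set):
        core = "ACGGTCAGTT" * 20
        read = make_read(ADAPTER + core + ADAPTER)
        params = FilterParams()
        once = trim_terminal_adapters(read, adapter_set, params)
        twice = trim_terminal_adapters(once, adapter_set, params)
        assert once.sequence == twice.sequence == core

    def test_three_prime_adapter_removed(self, adapter_set):
        core = "ACGGTCAGTT" * 20
        out = trim_terminal_adapters(make_read(core + ADAPTER), adapter_set, FilterParams())
        assert out.sequence == core
        assert "trimmed_3p" in out.flags


class TestConcatemer:
    def test_internal_adapter_outside_windows_flags(self, adapter_set):
        rng = np.random.default_rng(0)
        a = "".join(rng.choice(list("ACGT"), size=200))
        b = "".join(rng.choice(list("ACGT"), size=200))
        read = make_read(a + ADAPTER + b)
        assert is_concatemer(read, adapter_set, FilterParams())

    def test_terminal_adapters_do_not_flag(self, adapter_set):
        rng = np.random.default_rng(1)
        core = "".join(rng.choice(list("ACGT"), size=400))
        read = make_read(ADAPTER + core + ADAPTER)
        assert not is_concatemer(read, adapter_set, FilterParams())

    def test_boundary_straddle_resolved_by_midpoint(self, adapter_set):
        params = FilterParams()
        rng = np.random.default_rng(2)
        tail = "".join(rng.choice(list("ACGT"), size=400))
        # adapter midpoint inside the 150-nt end window -> not a concatemer
        lead_inside = "".join(rng.choice(list("ACGT"), size=params.end_window - len(ADAPTER)))
        read = make_read(lead_inside + ADAPTER + tail)
        assert not is_concatemer(read, adapter_set, params)
        # shift the adapter so its midpoint crosses the window boundary
        lead_outside = "".join(rng.choice(list("ACGT"), size=params.end_window + 2))
        read = make_read(lead_outside + ADAPTER + tail)
        assert is_concatemer(read, adapter_set, params)

    def test_recall_and_precision_on_synthetic_pool(self, adapter_set):
        spec = PoolSpec(
            components=(PoolComponent("GT", 0.5), PoolComponent("RANDOM", 0.5)),
            length_model=LengthModel(modes=((400.0, 0.3, 1.0),)),
            n_reads=2000,
            seed=7,
            target_median_q=20,
        )
        art = add_sequencing_artifacts(simulate_pool(spec), concatemer_rate=0.1, seed=8)
        params = FilterParams()
        trimmed = ReadPool(trim_terminal_adapters(r, adapter_set, params) for r in art)
        tp = fp = fn = 0
        for r in trimmed:
            pred = is_concatemer(r, adapter_set, params)
            truth = r.meta["is_concatemer_truth"]
            tp += pred and truth
            fp += pred and not truth
            fn += (not pred) and truth
        assert tp / (tp + fn) >= 0.95
        assert tp / (tp + fp) >= 0.95


class TestFilters:
    def test_length_boundary_exclusive(self):
        pool = ReadPool([make_read("A" * 65, rid="len65"), make_read("A" * 66, rid="len66")])
        kept, report = apply_filters(pool, FilterParams())
        assert [r.id for r in kept] == ["len66"]
        assert report.fail_length == 1

    def test_median_q_boundary_inclusive(self):
        low = Read("q12.5", "A" * 100, np.array([12, 13] * 50))
        ok = Read("q13", "A" * 100, np.full(100, 13))
        kept, report = apply_filters(ReadPool([low, ok]), FilterParams())
        assert [r.id for r in kept] == ["q13"]
        assert report.fail_quality == 1

    def test_concatemer_flag_removes(self):
        read = make_read("A" * 100)
        read.flags.add("concatemer")
        kept, report = apply_filters(ReadPool([read]), FilterParams())
        assert len(kept) == 0 and report.concatemers == 1

    def test_empty_pool(self):
        kept, report = apply_filters(ReadPool(), FilterParams())
        assert len(kept) == 0
        assert report.to_dict() == {
            "input_reads": 0, "trimmed_5p": 0, "trimmed_3p": 0, "concatemers": 0,
            "fail_length": 0, "fail_quality": 0, "retained": 0,
        }

    def test_filtering_idempotent_and_subset(self, random_pool):
        kept, _ = apply_filters(random_pool, FilterParams())
        again, report2 = apply_filters(kept, FilterParams())
        assert [r.id for r in again] == [r.id for r in kept]
        ids = {r.id for r in random_pool}
        assert all(r.id in ids for r in kept)
        assert report2.retained == len(kept)

    def test_full_rate_concatemer_pool_all_flagged(self, adapter_set):
        spec = PoolSpec(
            components=(PoolComponent("RANDOM", 1.0),),
            length_model=LengthModel(modes=((400.0, 0.2, 1.0),)),
            n_reads=50,
            seed=3,
            target_median_q=20,
        )
        art = add_sequencing_artifacts(simulate_pool(spec), concatemer_rate=1.0, seed=4)
        _, report = qc_pipeline(art, adapter_set)
        assert report.concatemers == 50
        # and a zero-rate pool yields none
        clean = add_sequencing_artifacts(simulate_pool(spec), concatemer_rate=0.0, seed=4)
        _, report0 = qc_pipeline(clean, adapter_set)
        assert report0.concatemers == 0


class TestExtractBetweenFlanks:
    def test_exact_flanks(self):
        read = make_read("G" * 30 + "AAAGGG" + "CGC" + "TTTCCC" + "G" * 30)
        out = extract_between_flanks(read, "AAAGGG", "TTTCCC", FilterParams())
        assert out == "CGC"

    def test_missing_flank_gives_none(self):
        read = make_read("G" * 30 + "AAAGGG" + "CGC" + "G" * 30)
        assert extract_between_flanks(read, "AAAGGG", "TTTCCC", FilterParams()) is None

    def test_repeated_flanks_leftmost_then_nearest(self):
        seq = "AAAGGG" + "C" * 5 + "TTTCCC" + "AAAGGG" + "G" * 9 + "TTTCCC"
        out = extract_between_flanks(make_read(seq), "AAAGGG", "TTTCCC", FilterParams())
        assert out == "C" * 5
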