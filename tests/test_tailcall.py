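import itertools

import pytest
from hypothesis import given, settings, strategies as st

from tenttail import simulate
from tenttail.tailcall import (
    AdapterSpec,
    CallStatus,
    ReadRecord,
    RejectReason,
    SubstrateSpec,
    call_batch,
    call_read,
    locate_adapter,
    locate_prefix,
    trim_substrate_run,
)

from _oracles import leading_run_trim

PREFIX = simulate.DEFAULT_PREFIX
ADAPTER = simulate.DEFAULT_ADAPTER
SUB = SubstrateSpec("ss22-A4", PREFIX, "A", 4)
AD = AdapterSpec("ra3-like", ADAPTER)


class TestLocatePrefix:
    def test_exact_match_returns_prefix_end(self):
        read = ReadRecord("r", PREFIX + "AAAACC" + ADAPTER)
        assert locate_prefix(read, SUB) == (True, 22)

    def test_single_substitution_fails(self):
        mutated = "T" + PREFIX[1:] if PREFIX[0] != "T" else "A" + PREFIX[1:]
        assert locate_prefix(ReadRecord("r", mutated + ADAPTER), SUB) == (False, -1)

    def test_read_shorter_than_prefix_fails(self):
        assert locate_prefix(ReadRecord("r", PREFIX[:10]), SUB) == (False, -1)

    def test_mismatch_tolerance_knob(self):
        mutated = ("T" if PREFIX[0] != "T" else "A") + PREFIX[1:]
        read = ReadRecord("r", mutated + ADAPTER)
        assert locate_prefix(read, SUB, max_mismatches=1) == (True, 22)


class TestLocateAdapter:
    def test_leftmost_occurrence(self):
        read = ReadRecord("r", PREFIX + "AAAA" + ADAPTER)
        assert locate_adapter(read, AD, 22) == (True, 26)

    def test_absent(self):
        assert locate_adapter(ReadRecord("r", PREFIX + "AAAA"), AD) == (False, -1)

    def test_duplicate_adapter_leftmost_wins(self):
        read = ReadRecord("r", PREFIX + ADAPTER + "CCCC" + ADAPTER)
        assert locate_adapter(read, AD, 22) == (True, 22)


class TestTrimSubstrateRun:
    @pytest.mark.parametrize(
        "insert, expected",
        [
            ("AAAACC", (4, "CC")),
            ("AAAAAA", (4, "AA")),  # tail adenosines beyond the quota are kept
            ("AAACC", (3, "CC")),  # "up to four" semantics
            ("", (0, "")),
            ("CCCC", (0, "CCCC")),
        ],
    )
    def test_examples(self, insert, expected):
        assert trim_substrate_run(insert, SUB) == expected

    def test_matches_reference_rule_for_all_short_inserts(self):
        # exhaustive over every insert of length <= 6
        for n in range(7):
            for combo in itertools.product("ACGT", repeat=n):
                insert = "".join(combo)
                assert trim_substrate_run(insert, SUB) == leading_run_trim(insert, "A", 4)


class TestCallRead:
    def test_tailed_read(self):
        call = call_read(ReadRecord("r", PREFIX + "AAAA" + "CC" + ADAPTER), SUB, AD)
        assert call.status is CallStatus.TAILED
        assert call.tail == "CC" and call.trimmed_substrate_bases == 4

    def test_untailed_read(self):
        call = call_read(ReadRecord("r", PREFIX + "AAAA" + ADAPTER), SUB, AD)
        assert call.status is CallStatus.UNTAILED
        assert call.tail == "" and call.insert == "AAAA"

    def test_insert_length_boundary(self):
        at_limit = call_read(ReadRecord("r", PREFIX + "A" * 100 + ADAPTER), SUB, AD)
        over = call_read(ReadRecord("r", PREFIX + "A" * 101 + ADAPTER), SUB, AD)
        assert at_limit.status is not CallStatus.REJECTED
        assert over.status is CallStatus.REJECTED
        assert over.reject_reason is RejectReason.INSERT_TOO_LONG

    def test_prefix_and_adapter_rejections(self):
        assert call_read(ReadRecord("r", "ACGT"), SUB, AD).reject_reason is RejectReason.PREFIX_MISSING
        no_ad = call_read(ReadRecord("r", PREFIX + "AAAACC"), SUB, AD)
        assert no_ad.reject_reason is RejectReason.ADAPTER_MISSING

    def test_idempotent(self):
        read = ReadRecord("r", PREFIX + "AAAA" + "CGU".replace("U", "T") + ADAPTER)
        assert call_read(read, SUB, AD) == call_read(read, SUB, AD)


class TestCallBatch:
    def test_empty_input(self):
        calls, summary = call_batch([], SUB, AD)
        assert calls == [] and summary.n_reads == 0

    def test_three_read_mix(self):
        reads = [
            ReadRecord("good", PREFIX + "AAAACC" + ADAPTER),
            ReadRecord("noad", PREFIX + "AAAACC"),
            ReadRecord("long", PREFIX + "A" * 101 + ADAPTER),
        ]
        calls, summary = call_batch(reads, SUB, AD)
        assert [c.read_id for c in calls] == ["good", "noad", "long"]
        assert summary.n_tailed == 1 and summary.n_rejected == 2
        assert summary.reject_reasons == {"ADAPTER_MISSING": 1, "INSERT_TOO_LONG": 1}

    def test_partition_invariant(self, substrate, adapter, tail_model):
        reads, _ = simulate.simulate_reads(
            substrate, adapter, tail_model, 2000, simulate.default_contaminants(), seed=2
        )
        _, summary = call_batch(reads, substrate, adapter)
        assert summary.n_tailed + summary.n_untailed + summary.n_rejected == summary.n_reads == 2000

    def test_roundtrip_against_ground_truth(self, substrate, adapter, tail_model):
        reads, truth = simulate.simulate_reads(
            substrate, adapter, tail_model, 3000, simulate.default_contaminants(), seed=4
        )
        calls, _ = call_batch(reads, substrate, adapter)
        by_id = {c.read_id: c for c in calls}
        for _, row in truth.iterrows():
            call = by_id[row["read_id"]]
            if row["class"] == "clean":
                assert call.status is not CallStatus.REJECTED
                assert call.tail == row["true_tail"]
            else:
                assert call.status is CallStatus.REJECTED
                assert call.reject_reason.value == simulate.EXPECTED_REJECT_REASON[row["class"]]

    def test_reconstruction_invariant(self, substrate, adapter, tail_model):
        reads, _ = simulate.simulate_reads(substrate, adapter, tail_model, 500, seed=6)
        calls, _ = call_batch(reads, substrate, adapter)
        by_id = {r.id: r for r in reads}
        for call in calls:
            rebuilt = (
                substrate.prefix
                + substrate.terminal_base * call.trimmed_substrate_bases
                + call.tail
                + adapter.sequence
            )
            assert by_id[call.read_id].sequence.startswith(rebuilt)


@settings(max_examples=200, derandomize=True)
@given(
    tail=st.text(alphabet="ACGT", min_size=0, max_size=10),
    n_substrate=st.integers(min_value=0, max_value=4),
    trailing=st.text(alphabet="ACGT", min_size=0, max_size=8),
)
def test_call_read_properties_on_constructed_reads(tail, n_substrate, trailing):
    """Partition + reconstruction hold for arbitrary constructed amplicons.

    The called tail may attribute leading adenosines differently from the
    construction when fewer than 4 substrate bases were present, but the
    insert itself must always be recovered exactly.
    """
    read = ReadRecord("r", PREFIX + "A" * n_substrate + tail + ADAPTER + trailing)
    call = call_read(read, SUB, AD)
    if ADAPTER in "A" * n_substrate + tail:  # pathological: adapter inside insert
        return
    assert call.status in (CallStatus.TAILED, CallStatus.UNTAILED)
    assert call.insert == "A" * n_substrate + tail
    assert call.insert == SUB.terminal_base * call.trimmed_substrate_bases + call.tail
    assert call.trimmed_substrate_bases <= SUB.terminal_count
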