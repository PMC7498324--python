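"""Tail calling for 3'-RACE-seq reads.

A 3'-RACE-seq amplicon read (sense orientation) has the layout::

    [substrate prefix][substrate terminal homopolymer][added tail][3' adapter]...

The enzyme under study adds a short nontemplated 3' tail to a synthetic RNA
substrate; the read selection and trimming rules implemented here recover that
tail:

1. the read must begin with the *entirely correct* substrate prefix
   (zero mismatches by default);
2. the full adapter sequence must occur downstream (leftmost exact match);
3. the insert between prefix end and adapter start must not exceed
   ``max_insert`` nucleotides (longer inserts are treated as contaminants);
4. up to ``terminal_count`` substrate-encoded terminal bases are trimmed from
   the substrate-proximal end of the insert; whatever remains is the added
   tail.

Because trimming is anchored at the substrate (5') side of the insert, it is
equivalent to reversing the insert and right-trimming the homopolymer, i.e.
the added tail is always assigned the 3'-most residues.  A read whose insert
is exhausted by substrate-encoded bases is UNTAILED, not rejected: untailed
reaction products are a quantity of interest.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

__all__ = [
    "DNA_ALPHABET",
    "SubstrateSpec",
    "AdapterSpec",
    "ReadRecord",
    "CallStatus",
    "RejectReason",
    "TailCall",
    "CallSummary",
    "locate_prefix",
    "locate_adapter",
    "trim_substrate_run",
    "call_read",
    "call_batch",
]

DNA_ALPHABET = frozenset("ACGT")

_VALID_SEQ = re.compile(r"^[ACGT]+$")


def _check_dna(seq: str, what: str) -> None:
    if not seq or not _VALID_SEQ.match(seq):
        raise ValueError(f"{what} must be a non-empty A/C/G/T string, got {seq!r}")


@dataclass(frozen=True)
class SubstrateSpec:
    """A synthetic RNA substrate: prefix + terminal homopolymer.

    The substrates used for tailing assays are a fixed prefix (22 nt by
    convention) followed by ``terminal_count`` copies of ``terminal_base``
    (e.g. four adenosines or four uridines, DNA-encoded as A/T).
    """

    name: str
    prefix: str
    terminal_base: str
    terminal_count: int = 4

    def __post_init__(self) -> None:
        _check_dna(self.prefix, "substrate prefix")
        if self.terminal_base not in DNA_ALPHABET:
            raise ValueError(f"terminal_base must be one of A/C/G/T, got {self.terminal_base!r}")
        if self.terminal_count < 0:
            raise ValueError("terminal_count must be >= 0")

    @property
    def full_sequence(self) -> str:
        return self.prefix + self.terminal_base * self.terminal_count


@dataclass(frozen=True)
class AdapterSpec:
    """The 3' adapter ligated before reverse transcription (21 nt by convention)."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        _check_dna(self.sequence, "adapter sequence")


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read in sense orientation (DNA alphabet)."""

    id: str
    sequence: str
    quality: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.id!r}: sequence must be non-empty")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(f"read {self.id!r}: quality length != sequence length")


class CallStatus(str, Enum):
    TAILED = "TAILED"
    UNTAILED = "UNTAILED"
    REJECTED = "REJECTED"


class RejectReason(str, Enum):
    PREFIX_MISSING = "PREFIX_MISSING"
    ADAPTER_MISSING = "ADAPTER_MISSING"
    INSERT_TOO_LONG = "INSERT_TOO_LONG"
    LOW_COMPLEXITY = "LOW_COMPLEXITY"


@dataclass(frozen=True)
class TailCall:
    """Per-read outcome of the tail-calling procedure.

    ``insert`` is the sequence between prefix end and adapter start;
    ``trimmed_substrate_bases`` counts substrate-encoded terminal bases
    removed from its 5' end (capped at the substrate's ``terminal_count``);
    ``tail`` is the remaining added tail, 5'->3'.
    """

    read_id: str
    status: CallStatus
    reject_reason: Optional[RejectReason] = None
    insert: str = ""
    trimmed_substrate_bases: int = 0
    tail: str = ""

    def __post_init__(self) -> None:
        if (self.status is CallStatus.REJECTED) != (self.reject_reason is not None):
            raise ValueError("reject_reason must be set iff status is REJECTED")
        if self.status is CallStatus.UNTAILED and self.tail:
            raise ValueError("UNTAILED call cannot carry a tail")
        if self.status is CallStatus.TAILED and not self.tail:
            raise ValueError("TAILED call must carry a non-empty tail")

    @property
    def tail_length(self) -> int:
        return len(self.tail)


@dataclass
class CallSummary:
    """Counts per status and per reject reason over a batch of reads."""

    n_reads: int = 0
    n_tailed: int = 0
    n_untailed: int = 0
    n_rejected: int = 0
    reject_reasons: Counter = field(default_factory=Counter)
    # reads retained with fewer substrate-encoded bases than expected
    n_short_substrate_run: int = 0

    def add(self, call: TailCall, expected_trim: int) -> None:
        self.n_reads += 1
        if call.status is CallStatus.TAILED:
            self.n_tailed += 1
        elif call.status is CallStatus.UNTAILED:
            self.n_untailed += 1
        else:
            self.n_rejected += 1
            self.reject_reasons[call.reject_reason.value] += 1
        if call.status is not CallStatus.REJECTED and call.trimmed_substrate_bases < expected_trim:
            self.n_short_substrate_run += 1

    def to_dict(self) -> dict:
        return {
            "n_reads": self.n_reads,
            "n_tailed": self.n_tailed,
            "n_untailed": self.n_untailed,
            "n_rejected": self.n_rejected,
            "reject_reasons": dict(sorted(self.reject_reasons.items())),
            "n_short_substrate_run": self.n_short_substrate_run,
        }


def locate_prefix(read: ReadRecord, substrate: SubstrateSpec, max_mismatches: int = 0) -> tuple[bool, int]:
    """Test whether the read begins with the substrate prefix.

    Returns ``(matched, end_offset)`` where ``end_offset`` is the 0-based
    half-open end of the prefix (== prefix length) when matched, else -1.
    ``max_mismatches`` defaults to 0: the selection rule requires an entirely
    correct prefix.
    """
    prefix = substrate.prefix
    seq = read.sequence
    if len(seq) < len(prefix):
        return False, -1
    if max_mismatches == 0:
        ok = seq.startswith(prefix)
    else:
        mismatches = sum(a != b for a, b in zip(seq, prefix))
        ok = mismatches <= max_mismatches
    return (True, len(prefix)) if ok else (False, -1)


def locate_adapter(read: ReadRecord, adapter: AdapterSpec, search_from: int = 0) -> tuple[bool, int]:
    """Find the leftmost exact occurrence of the full adapter at or after ``search_from``.

    Returns ``(matched, start_offset)``; bases after the adapter are ignored
    by the caller.
    """
    if search_from > len(read.sequence):
        raise ValueError("search_from beyond read end")
    pos = read.sequence.find(adapter.sequence, search_from)
    return (pos >= 0), pos


def trim_substrate_run(insert: str, substrate: SubstrateSpec) -> tuple[int, str]:
    """Remove up to ``terminal_count`` leading substrate terminal bases from the insert.

    The trim count is ``min(leading run of terminal_base, terminal_count)``;
    the remainder is the added tail.  A tail that itself begins with the
    terminal base therefore keeps those bases once the substrate-encoded quota
    is exhausted.
    """
    base = substrate.terminal_base
    run = 0
    for ch in insert:
        if ch != base or run >= substrate.terminal_count:
            break
        run += 1
    return run, insert[run:]


def call_read(
    read: ReadRecord,
    substrate: SubstrateSpec,
    adapter: AdapterSpec,
    max_insert: int = 100,
    max_mismatches: int = 0,
    min_insert_complexity: Optional[int] = None,
) -> TailCall:
    """Classify one read and extract its added tail.

    Rejection order: prefix, adapter, insert length.  The optional
    low-complexity ("short stretch of ACTG") rule is off by default
    (``min_insert_complexity=None``); when set, non-rejected inserts shorter
    than the threshold *after* trimming substrate bases are still never
    rejected — the rule applies only to reads failing the prefix match whose
    remaining sequence is a short arbitrary stretch, and is deliberately
    conservative because untailed products must be retained.
    """
    ok, prefix_end = locate_prefix(read, substrate, max_mismatches=max_mismatches)
    if not ok:
        if (
            min_insert_complexity is not None
            and len(read.sequence) < len(substrate.prefix) + min_insert_complexity
        ):
            return TailCall(read.id, CallStatus.REJECTED, RejectReason.LOW_COMPLEXITY)
        return TailCall(read.id, CallStatus.REJECTED, RejectReason.PREFIX_MISSING)
    ok, adapter_start = locate_adapter(read, adapter, search_from=prefix_end)
    if not ok:
        return TailCall(read.id, CallStatus.REJECTED, RejectReason.ADAPTER_MISSING)
    insert = read.sequence[prefix_end:adapter_start]
    if len(insert) > max_insert:
        return TailCall(read.id, CallStatus.REJECTED, RejectReason.INSERT_TOO_LONG)
    trimmed, tail = trim_substrate_run(insert, substrate)
    status = CallStatus.TAILED if tail else CallStatus.UNTAILED
    return TailCall(read.id, status, None, insert, trimmed, tail)


def call_batch(
    reads: Iterable[ReadRecord],
    substrate: SubstrateSpec,
    adapter: AdapterSpec,
    max_insert: int = 100,
    max_mismatches: int = 0,
    min_insert_complexity: Optional[int] = None,
) -> tuple[list[TailCall], CallSummary]:
    """Call every read in order; returns the calls and a consistent summary."""
    calls: list[TailCall] = []
    summary = CallSummary()
    for i, read in enumerate(reads):
        try:
            call = call_read(
                read,
                substrate,
                adapter,
                max_insert=max_insert,
                max_mismatches=max_mismatches,
                min_insert_complexity=min_insert_complexity,
            )
        except Exception as exc:  # pragma: no cover - defensive context wrap
            raise RuntimeError(f"tail calling failed at read index {i} ({read.id!r})") from exc
        calls.append(call)
        summary.add(call, expected_trim=substrate.terminal_count)
    return calls, summary
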