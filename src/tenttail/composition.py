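"""Tail length and nucleotide-composition statistics from tail calls.

Summarises a batch of :class:`~tenttail.tailcall.TailCall` results the way a
tailing study reports them:

* tail length distribution (mean, median, histogram), with and without
  untailed products;
* overall nucleotide frequencies pooled across all tail nucleotides;
* a 3'-anchored per-position frequency matrix: position 1 is the last added
  nucleotide, position p is read from tails of length >= p.  Positions are
  reported only while covered by at least ``min_coverage`` of the tailed
  reads and at most ``max_positions`` from the 3' end; coverage itself is
  recorded for every position.

Rejected reads never enter a denominator.  The tailed fraction is computed
over TAILED + UNTAILED reads.  All user-facing output uses the RNA alphabet
(U, not T); internally sequences are DNA.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .tailcall import CallStatus, TailCall

__all__ = [
    "CompositionResult",
    "LengthStats",
    "UndefinedResultError",
    "length_stats",
    "overall_frequencies",
    "positional_composition",
    "compare_variants",
]

RNA_BASES = ("A", "C", "G", "U")


class UndefinedResultError(ValueError):
    """Raised when a statistic has an empty denominator (e.g. no tailed reads)."""


def _kept(calls: Iterable[TailCall]) -> list[TailCall]:
    return [c for c in calls if c.status is not CallStatus.REJECTED]


@dataclass(frozen=True)
class LengthStats:
    mean: float
    median: float
    histogram: dict  # length -> count
    n: int


def length_stats(calls: Iterable[TailCall], include_untailed: bool = True) -> LengthStats:
    """Tail length statistics over non-rejected calls.

    ``include_untailed=True`` (default) counts untailed products as length 0;
    the excluded variant restricts to tailed reads only.
    """
    kept = _kept(calls)
    if not kept:
        raise UndefinedResultError("length statistics undefined: no non-rejected calls")
    lengths = [c.tail_length for c in kept if include_untailed or c.tail_length > 0]
    if not lengths:
        raise UndefinedResultError("length statistics undefined: no tailed calls")
    arr = np.array(lengths)
    hist = dict(sorted(Counter(lengths).items()))
    return LengthStats(float(arr.mean()), float(np.median(arr)), hist, len(lengths))


def _pooled_counts(kept: Sequence[TailCall]) -> Counter:
    counts: Counter = Counter()
    for c in kept:
        counts.update(c.tail)
    return counts


def overall_frequencies(calls: Iterable[TailCall]) -> dict:
    """Pooled base frequencies over all tail nucleotides (RNA alphabet)."""
    kept = _kept(calls)
    counts = _pooled_counts(kept)
    total = sum(counts.values())
    if total == 0:
        raise UndefinedResultError("overall frequencies undefined: no tail nucleotides")
    return {b: counts["T" if b == "U" else b] / total for b in RNA_BASES}


@dataclass
class CompositionResult:
    """Composition report for one read set / enzyme variant.

    ``per_position`` holds only the reported positions (coverage >=
    min_coverage and position <= max_positions); ``coverage`` is recorded for
    every position up to the longest tail, as the fraction of *tailed* reads
    whose tail reaches that position.
    """

    per_position: pd.DataFrame  # index: 3'-anchored position, columns A/C/G/U
    coverage: pd.Series  # every position 1..max tail length
    overall: dict
    tailed_fraction: float
    length_mean: float
    length_median: float
    length_mean_tailed: float
    length_median_tailed: float
    length_histogram: dict
    n_tailed: int
    n_untailed: int
    min_coverage: float
    max_positions: int

    def to_dict(self) -> dict:
        return {
            "tailed_fraction": self.tailed_fraction,
            "overall": self.overall,
            "length_mean": self.length_mean,
            "length_median": self.length_median,
            "length_mean_tailed": self.length_mean_tailed,
            "length_median_tailed": self.length_median_tailed,
            "length_histogram": {str(k): v for k, v in self.length_histogram.items()},
            "n_tailed": self.n_tailed,
            "n_untailed": self.n_untailed,
            "min_coverage": self.min_coverage,
            "max_positions": self.max_positions,
        }


def positional_composition(
    calls: Iterable[TailCall],
    min_coverage: float = 0.05,
    max_positions: int = 25,
) -> CompositionResult:
    """3'-anchored per-position composition with the coverage reporting rule.

    Position p is computed over tails of length >= p; coverage(p) is the
    fraction of tailed reads reaching p.  Positions with coverage below
    ``min_coverage`` (strict) or beyond ``max_positions`` are dropped from
    ``per_position`` but their coverage is still recorded.
    """
    kept = _kept(calls)
    tails = [c.tail for c in kept if c.tail]
    if not tails:
        raise UndefinedResultError("positional composition undefined: no tailed calls")
    n_tailed = len(tails)
    n_untailed = len(kept) - n_tailed
    max_len = max(len(t) for t in tails)

    counts = np.zeros((max_len, 4), dtype=np.int64)
    dna_index = {"A": 0, "C": 1, "G": 2, "T": 3}
    reach = np.zeros(max_len, dtype=np.int64)
    for t in tails:
        n = len(t)
        reach[:n] += 1
        for p in range(1, n + 1):  # 3'-anchored: position 1 = last character
            counts[p - 1, dna_index[t[n - p]]] += 1

    positions = np.arange(1, max_len + 1)
    coverage = pd.Series(reach / n_tailed, index=positions, name="coverage")
    freq = counts / reach[:, None]
    per_position = pd.DataFrame(freq, index=positions, columns=["A", "C", "G", "U"])
    keep = (coverage >= min_coverage) & (positions <= max_positions)
    per_position = per_position.loc[keep.values]

    ls_all = length_stats(kept, include_untailed=True)
    ls_tailed = length_stats(kept, include_untailed=False)
    return CompositionResult(
        per_position=per_position,
        coverage=coverage,
        overall=overall_frequencies(kept),
        tailed_fraction=n_tailed / len(kept),
        length_mean=ls_all.mean,
        length_median=ls_all.median,
        length_mean_tailed=ls_tailed.mean,
        length_median_tailed=ls_tailed.median,
        length_histogram=ls_all.histogram,
        n_tailed=n_tailed,
        n_untailed=n_untailed,
        min_coverage=min_coverage,
        max_positions=max_positions,
    )


def compare_variants(results: Mapping[str, CompositionResult]) -> pd.DataFrame:
    """Tidy long-format table across variants, suitable for plotting.

    One row per (variant, position, base) from the per-position matrices,
    plus ``kind='overall'`` rows for pooled frequencies and ``kind='summary'``
    rows for scalar statistics.
    """
    items = list(results.items())
    labels = [k for k, _ in items]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate variant labels")
    if not items:
        raise ValueError("no results to compare")
    rows = []
    for variant, res in items:
        for pos, row in res.per_position.iterrows():
            for base in RNA_BASES:
                rows.append(
                    {
                        "variant": variant,
                        "kind": "per_position",
                        "position": int(pos),
                        "base": base,
                        "value": float(row[base]),
                        "coverage": float(res.coverage[pos]),
                    }
                )
        for base, f in res.overall.items():
            rows.append(
                {
                    "variant": variant,
                    "kind": "overall",
                    "position": pd.NA,
                    "base": base,
                    "value": float(f),
                    "coverage": pd.NA,
                }
            )
        for stat in ("tailed_fraction", "length_mean", "length_median"):
            rows.append(
                {
                    "variant": variant,
                    "kind": "summary",
                    "position": pd.NA,
                    "base": stat,
                    "value": float(getattr(res, stat)),
                    "coverage": pd.NA,
                }
            )
    return pd.DataFrame(rows)
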