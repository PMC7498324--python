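"""Independent brute-force oracles used only by the tests.

These deliberately avoid the package's analytic code paths: the composition
oracle enumerates every possible tail over the finite length support and
accumulates exact probabilities.
"""

import itertools

import numpy as np
import pandas as pd

BASES = "ACGT"


def enumerate_tail_distribution(model):
    """All (tail, probability) pairs for a finite-support tail model."""
    out = []
    for length, p_len in model.length_probs.items():
        if length == 0:
            out.append(("", p_len))
            continue
        per_pos = [
            [model.base_distribution(length, j)[BASES.index(b)] for b in BASES]
            for j in range(1, length + 1)
        ]
        for combo in itertools.product(range(4), repeat=length):
            p = p_len
            for j, bi in enumerate(combo):
                p *= per_pos[j][bi]
            if p > 0:
                out.append(("".join(BASES[bi] for bi in combo), p))
    return out


def brute_force_composition(model, max_positions=25):
    """Exact 3'-anchored per-position frequencies, coverage and overall usage
    by exhaustive enumeration of all tails (feasible for L_max <= 4)."""
    tails = enumerate_tail_distribution(model)
    max_len = max((len(t) for t, _ in tails), default=0)
    max_p = min(max_positions, max_len)
    freq = pd.DataFrame(np.nan, index=range(1, max_p + 1), columns=list("ACGU"))
    coverage = pd.Series(0.0, index=range(1, max_p + 1))
    for p in range(1, max_p + 1):
        acc = np.zeros(4)
        mass = 0.0
        for tail, prob in tails:
            if len(tail) >= p:
                mass += prob
                acc[BASES.index(tail[len(tail) - p])] += prob
        coverage[p] = mass
        if mass > 0:
            freq.loc[p] = acc / mass
    counts = np.zeros(4)
    e_len = 0.0
    for tail, prob in tails:
        e_len += prob * len(tail)
        for ch in tail:
            counts[BASES.index(ch)] += prob
    overall = {}
    if e_len > 0:
        vec = counts / e_len
        overall = {("U" if b == "T" else b): vec[i] for i, b in enumerate(BASES)}
    return freq, coverage, overall


def leading_run_trim(insert, base, cap):
    """Reference trimming rule: remove min(leading run of base, cap)."""
    k = 0
    while k < len(insert) and k < cap and insert[k] == base:
        k += 1
    return k, insert[k:]
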