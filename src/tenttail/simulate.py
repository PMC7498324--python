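"""Synthetic 3'-RACE-seq reads and anisotropy titrations with known ground truth.

The raw sequencing reads and raw titration tables behind a tailing study are
rarely redeposited at desk scale, so this module generates stand-ins with a
fully known ground truth:

* ``simulate_reads`` builds FASTQ-style read sets with the amplicon layout
  ``prefix + terminal homopolymer + added tail + adapter`` plus four
  contaminant classes that exercise each rejection rule of the tail caller.
  Contaminant counts are allocated *exactly* (``round(fraction * n)``), so a
  round-trip through the caller can be checked to the read.
* ``TailModel`` describes the added-tail distribution: a length distribution
  over 0..L_max and per-position base frequencies, with optional overrides
  keyed by distance from the 3' end (distance 1 = last added nucleotide) to
  model the enzyme's positional bias — for the C/U-tailing enzyme emulated by
  the defaults, a strong preference for cytidine at the last and penultimate
  positions.
* ``expected_composition`` is the analytic counterpart of the empirical
  composition statistics: exact per-position frequencies, coverage and
  overall base usage computed by summation over the finite length support.
* ``simulate_saturation`` / ``simulate_competition`` generate anisotropy
  titrations from the binding models plus Gaussian noise.

All generators take an integer seed and are bit-reproducible (NumPy PCG64).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .binding import AnisotropyMeasurement, competition_model, saturation_model
from .tailcall import AdapterSpec, ReadRecord, SubstrateSpec

__all__ = [
    "TailModel",
    "ContaminantModel",
    "TitrationDesign",
    "ExpectedComposition",
    "sample_tail",
    "simulate_reads",
    "expected_composition",
    "simulate_saturation",
    "simulate_competition",
    "default_substrate",
    "default_adapter",
    "default_tail_model",
    "default_contaminants",
    "saturation_design",
    "competition_design",
    "EXPECTED_REJECT_REASON",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_PROB_TOL = 1e-12

# Placeholder substrate prefix and adapter.  The true oligonucleotide
# sequences are experiment-specific reagents and must be supplied in the
# configuration when analysing real data; these defaults exist so that the
# simulator and pipeline are runnable out of the box without presenting an
# invented sequence as the real reagent.  The adapter placeholder is
# border-free (no proper prefix equals a suffix), so an exact adapter match
# can never shift left into the insert.
DEFAULT_PREFIX = "ACGTACGTACGTACGTACGTAC"  # 22 nt
DEFAULT_ADAPTER = "TACGGTCCATGCAATCGTGAG"  # 21 nt

# Which rejection reason the tail caller should assign to each contaminant
# class (junk reads carry no substrate prefix, so they fail the prefix rule).
EXPECTED_REJECT_REASON = {
    "no_prefix": "PREFIX_MISSING",
    "no_adapter": "ADAPTER_MISSING",
    "long_insert": "INSERT_TOO_LONG",
    "junk": "PREFIX_MISSING",
}


def _check_prob_vector(probs: Mapping[str, float], what: str) -> np.ndarray:
    vec = np.zeros(4)
    for b, p in probs.items():
        if b not in _BASE_INDEX:
            raise ValueError(f"{what}: unknown base {b!r}")
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"{what}: probability {p} outside [0, 1]")
        vec[_BASE_INDEX[b]] = p
    if abs(vec.sum() - 1.0) > _PROB_TOL:
        raise ValueError(f"{what}: probabilities sum to {vec.sum()!r}, not 1")
    return vec


@dataclass
class TailModel:
    """Distribution of added tails.

    ``length_probs`` maps tail length (0..L_max) to probability.
    ``base_probs_by_start_position`` gives, for each position counted 5'->3'
    along the added tail (entry 0 = first added nucleotide), a probability
    vector over A/C/G/T; the last entry is reused for longer tails.
    ``terminal_override`` maps distance from the 3' end (1 = last added
    nucleotide) to a probability vector that takes precedence at that
    distance.
    """

    length_probs: Mapping[int, float]
    base_probs_by_start_position: Sequence[Mapping[str, float]]
    terminal_override: Optional[Mapping[int, Mapping[str, float]]] = None
    description: str = ""
    _lengths: np.ndarray = field(init=False, repr=False)
    _length_p: np.ndarray = field(init=False, repr=False)
    _base_vecs: list = field(init=False, repr=False)
    _override_vecs: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.length_probs:
            raise ValueError("length_probs must be non-empty")
        lengths = sorted(self.length_probs)
        if lengths[0] < 0:
            raise ValueError("tail lengths must be >= 0")
        probs = np.array([self.length_probs[l] for l in lengths], dtype=float)
        if np.any((probs < 0) | (probs > 1)):
            raise ValueError("length probabilities must lie in [0, 1]")
        if abs(probs.sum() - 1.0) > _PROB_TOL:
            raise ValueError(f"length probabilities sum to {probs.sum()!r}, not 1")
        self._lengths = np.array(lengths, dtype=int)
        self._length_p = probs
        if self.max_length > 0 and not self.base_probs_by_start_position:
            raise ValueError("base_probs_by_start_position required for nonzero tail lengths")
        self._base_vecs = [
            _check_prob_vector(p, f"base_probs position {i + 1}")
            for i, p in enumerate(self.base_probs_by_start_position)
        ]
        self._override_vecs = {}
        for dist, p in (self.terminal_override or {}).items():
            if dist < 1:
                raise ValueError("terminal_override distances are 1-based from the 3' end")
            self._override_vecs[int(dist)] = _check_prob_vector(
                p, f"terminal_override distance {dist}"
            )

    @property
    def max_length(self) -> int:
        return int(self._lengths.max(initial=0))

    def base_distribution(self, length: int, start_position: int) -> np.ndarray:
        """Effective base distribution at ``start_position`` (1-based, 5'->3')
        of a tail of the given length; the 3'-end override wins on conflict."""
        distance = length - start_position + 1
        if distance in self._override_vecs:
            return self._override_vecs[distance]
        idx = min(start_position, len(self._base_vecs)) - 1
        return self._base_vecs[idx]


@dataclass(frozen=True)
class ContaminantModel:
    """Fractions of reads allocated to each contaminant class."""

    fraction_no_prefix: float = 0.0
    fraction_no_adapter: float = 0.0
    fraction_long_insert: float = 0.0
    fraction_junk: float = 0.0
    long_insert_length: int = 150

    def __post_init__(self) -> None:
        fracs = (
            self.fraction_no_prefix,
            self.fraction_no_adapter,
            self.fraction_long_insert,
            self.fraction_junk,
        )
        if any(f < 0 or f > 1 for f in fracs):
            raise ValueError("contaminant fractions must lie in [0, 1]")
        if sum(fracs) > 1.0 + _PROB_TOL:
            raise ValueError(f"contaminant fractions sum to {sum(fracs)} > 1")
        if self.long_insert_length <= 100:
            raise ValueError("long_insert_length must exceed the 100 nt insert limit")

    def counts(self, n_reads: int) -> dict[str, int]:
        """Exact per-class allocation: round(fraction * n) per class."""
        counts = {
            "no_prefix": int(round(self.fraction_no_prefix * n_reads)),
            "no_adapter": int(round(self.fraction_no_adapter * n_reads)),
            "long_insert": int(round(self.fraction_long_insert * n_reads)),
            "junk": int(round(self.fraction_junk * n_reads)),
        }
        total = sum(counts.values())
        if total > n_reads:
            raise ValueError("contaminant allocation exceeds n_reads")
        counts["clean"] = n_reads - total
        return counts


@dataclass(frozen=True)
class TitrationDesign:
    """Design of a simulated anisotropy titration.

    ``n_series`` is the number of replicates (saturation mode) or independent
    experiments (competition mode).  ``truth`` carries the generating
    parameters: {kd, a_free, a_max} for saturation, {ic50, a_free, a_bound}
    for competition (plateaus may be scalars or one value per experiment).
    Concentrations are nM throughout.
    """

    mode: str
    concentrations_nm: tuple
    n_series: int
    noise_sd: float
    truth: Mapping[str, object]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("saturation", "competition"):
            raise ValueError(f"mode must be 'saturation' or 'competition', got {self.mode!r}")
        conc = np.asarray(self.concentrations_nm, dtype=float)
        if np.any(conc < 0):
            raise ValueError("concentrations must be >= 0")
        if np.unique(conc).size < 2:
            raise ValueError("need at least 2 distinct concentrations")
        if self.n_series < 1:
            raise ValueError("n_series must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.mode == "saturation":
            if float(self.truth["kd"]) <= 0:
                raise ValueError("truth kd must be > 0")
        else:
            if float(self.truth["ic50"]) <= 0:
                raise ValueError("truth ic50 must be > 0")


def sample_tail(model: TailModel, rng: np.random.Generator) -> str:
    """Draw one added tail (5'->3') from a TailModel."""
    length = int(rng.choice(model._lengths, p=model._length_p))
    if length == 0:
        return ""
    chars = []
    for pos in range(1, length + 1):
        dist = model.base_distribution(length, pos)
        chars.append(_BASES[int(rng.choice(4, p=dist))])
    return "".join(chars)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def _mutated_prefix(rng: np.random.Generator, prefix: str, adapter: str) -> str:
    """Random same-length replacement guaranteed to differ from the prefix
    in >= 1 position and to not contain the adapter."""
    while True:
        cand = _random_seq(rng, len(prefix))
        if cand == prefix:
            i = int(rng.integers(0, len(cand)))
            other = rng.choice([b for b in _BASES if b != cand[i]])
            cand = cand[:i] + str(other) + cand[i + 1 :]
        if adapter not in cand + prefix[: len(adapter) - 1]:
            return cand


def simulate_reads(
    substrate: SubstrateSpec,
    adapter: AdapterSpec,
    tail_model: TailModel,
    n_reads: int,
    contaminants: Optional[ContaminantModel] = None,
    seed: int = 0,
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Generate a labelled read set.

    Returns ``(reads, truth)`` where ``truth`` has one row per read:
    ``read_id``, ``class`` (clean / no_prefix / no_adapter / long_insert /
    junk), ``true_tail`` and ``true_length``.  Contaminant counts follow the
    exact allocation of :meth:`ContaminantModel.counts`; read order is a
    seeded permutation of the classes.  Byte-identical output for equal
    inputs and seed.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be > 0")
    contaminants = contaminants or ContaminantModel()
    rng = np.random.default_rng(seed)
    counts = contaminants.counts(n_reads)
    homopolymer = substrate.terminal_base * substrate.terminal_count

    classes: list[str] = []
    for cls in ("clean", "no_prefix", "no_adapter", "long_insert", "junk"):
        classes += [cls] * counts[cls]
    order = rng.permutation(n_reads)
    classes = [classes[i] for i in order]

    reads: list[ReadRecord] = []
    rows = []
    width = len(str(n_reads))
    for i, cls in enumerate(classes):
        read_id = f"read{i + 1:0{width}d}"
        tail = ""
        if cls == "junk":
            n_lead = int(rng.integers(0, 6))  # <= 5 arbitrary bases, then adapter
            seq = _random_seq(rng, n_lead) + adapter.sequence
            if seq.startswith(substrate.prefix):  # pragma: no cover - astronomically rare
                seq = ("C" if seq[0] != "C" else "G") + seq[1:]
        else:
            tail = sample_tail(tail_model, rng)
            insert = homopolymer + tail
            if cls == "long_insert":
                pad = contaminants.long_insert_length - len(insert)
                while True:
                    padded = insert + _random_seq(rng, pad)
                    if adapter.sequence not in padded:
                        break
                insert = padded
            prefix = (
                _mutated_prefix(rng, substrate.prefix, adapter.sequence)
                if cls == "no_prefix"
                else substrate.prefix
            )
            seq = prefix + insert
            if cls != "no_adapter":
                seq += adapter.sequence
        reads.append(ReadRecord(id=read_id, sequence=seq, quality="I" * len(seq)))
        rows.append(
            {"read_id": read_id, "class": cls, "true_tail": tail, "true_length": len(tail)}
        )
    truth = pd.DataFrame(rows, columns=["read_id", "class", "true_tail", "true_length"])
    return reads, truth


@dataclass
class ExpectedComposition:
    """Analytic composition of a TailModel (RNA alphabet, 3'-anchored).

    ``per_position`` rows are NaN where coverage is zero (undefined, not 0).
    ``coverage[p]`` is P(tail length >= p) over the *full* length
    distribution including length 0; conditional-on-tailed coverage, the
    convention of the empirical statistics, is ``coverage[p] / coverage[1]``.
    """

    per_position: pd.DataFrame  # index: position (1 = 3'-terminal), columns A/C/G/U
    coverage: pd.Series
    overall: dict
    length_mean: float
    tailed_probability: float


def expected_composition(model: TailModel, max_positions: int = 25) -> ExpectedComposition:
    """Exact per-position and overall tail composition by finite summation."""
    lengths = model._lengths
    probs = model._length_p
    max_p = min(max_positions, model.max_length) if model.max_length else 0

    positions = range(1, max_p + 1)
    freq = pd.DataFrame(np.nan, index=list(positions), columns=list("ACGT"))
    coverage = pd.Series(0.0, index=list(positions), dtype=float)
    for p in positions:
        mass = 0.0
        acc = np.zeros(4)
        for l, pl in zip(lengths, probs):
            if l >= p:
                mass += pl
                acc += pl * model.base_distribution(int(l), int(l) - p + 1)
        coverage[p] = mass
        if mass > 0:
            freq.loc[p] = acc / mass

    counts = np.zeros(4)
    e_len = 0.0
    for l, pl in zip(lengths, probs):
        e_len += pl * l
        for j in range(1, int(l) + 1):
            counts += pl * model.base_distribution(int(l), j)
    overall = {}
    if e_len > 0:
        vec = counts / e_len
        overall = {("U" if b == "T" else b): float(vec[_BASE_INDEX[b]]) for b in _BASES}
    freq = freq.rename(columns={"T": "U"})
    tailed_p = float(probs[lengths >= 1].sum())
    return ExpectedComposition(
        per_position=freq,
        coverage=coverage,
        overall=overall,
        length_mean=float(e_len),
        tailed_probability=tailed_p,
    )


def simulate_saturation(design: TitrationDesign) -> list[AnisotropyMeasurement]:
    """Simulate replicate saturation titrations (protein titrated against probe)."""
    if design.mode != "saturation":
        raise ValueError("design.mode must be 'saturation'")
    rng = np.random.default_rng(design.seed)
    kd = float(design.truth["kd"])
    a_free = float(design.truth["a_free"])
    a_max = float(design.truth["a_max"])
    conc = np.asarray(design.concentrations_nm, dtype=float)
    out = []
    for rep in range(1, design.n_series + 1):
        a = saturation_model(conc, kd, a_free, a_max)
        if design.noise_sd > 0:
            a = a + rng.normal(0.0, design.noise_sd, size=conc.size)
        out += [
            AnisotropyMeasurement("saturation", float(c), float(v), rep)
            for c, v in zip(conc, a)
        ]
    return out


def _per_experiment(value, n: int, what: str) -> list[float]:
    if np.isscalar(value):
        return [float(value)] * n
    vals = [float(v) for v in value]  # type: ignore[union-attr]
    if len(vals) != n:
        raise ValueError(f"truth {what} must be scalar or one value per experiment")
    return vals


def simulate_competition(design: TitrationDesign) -> list[AnisotropyMeasurement]:
    """Simulate independent competition titrations sharing one true IC50."""
    if design.mode != "competition":
        raise ValueError("design.mode must be 'competition'")
    rng = np.random.default_rng(design.seed)
    ic50 = float(design.truth["ic50"])
    a_free = _per_experiment(design.truth["a_free"], design.n_series, "a_free")
    a_bound = _per_experiment(design.truth["a_bound"], design.n_series, "a_bound")
    conc = np.asarray(design.concentrations_nm, dtype=float)
    out = []
    for e in range(1, design.n_series + 1):
        a = competition_model(conc, ic50, a_free[e - 1], a_bound[e - 1])
        if design.noise_sd > 0:
            a = a + rng.normal(0.0, design.noise_sd, size=conc.size)
        out += [
            AnisotropyMeasurement(f"exp{e}", float(c), float(v), e)
            for c, v in zip(conc, a)
        ]
    return out


# ---------------------------------------------------------------------------
# Default study conditions


def default_substrate(terminal_base: str = "A") -> SubstrateSpec:
    """Placeholder substrate: 22-nt prefix + 4 terminal bases (A or T=U)."""
    return SubstrateSpec(
        name=f"ss22-{'U' if terminal_base == 'T' else terminal_base}4",
        prefix=DEFAULT_PREFIX,
        terminal_base=terminal_base,
        terminal_count=4,
    )


def default_adapter() -> AdapterSpec:
    return AdapterSpec(name="adapter21", sequence=DEFAULT_ADAPTER)


def default_tail_model() -> TailModel:
    """Short heteropolymeric C-dominated tails (lengths 0-7).

    Emulates a C/U-adding enzyme profiled with all four NTPs present:
    overall ~47% C, ~43% A, ~9% U and <1% G, with the cytidine preference
    concentrated at the last two added positions.  About a quarter of the
    reaction products are untailed.
    """
    interior = {"A": 0.63, "C": 0.26, "G": 0.01, "T": 0.10}
    return TailModel(
        length_probs={0: 0.25, 1: 0.30, 2: 0.20, 3: 0.10, 4: 0.07, 5: 0.04, 6: 0.025, 7: 0.015},
        base_probs_by_start_position=[interior] * 7,
        terminal_override={
            1: {"A": 0.29, "C": 0.62, "G": 0.005, "T": 0.085},
            2: {"A": 0.42, "C": 0.48, "G": 0.008, "T": 0.092},
        },
        description="C-dominated 0-7 nt tails, 3'-end C bias",
    )


def default_contaminants() -> ContaminantModel:
    """10% contaminants split across the four classes."""
    return ContaminantModel(
        fraction_no_prefix=0.04,
        fraction_no_adapter=0.03,
        fraction_long_insert=0.02,
        fraction_junk=0.01,
        long_insert_length=150,
    )


def _log_grid(lo: float, hi: float, n: int) -> tuple:
    return tuple(float(x) for x in np.geomspace(lo, hi, n))


def saturation_design(
    kd: float = 250.0,
    a_free: float = 0.05,
    a_max: float = 0.25,
    noise_sd: float = 0.002,
    seed: int = 0,
) -> TitrationDesign:
    """Protein titration 5-3000 nM, 12 log-spaced points, triplicate."""
    return TitrationDesign(
        mode="saturation",
        concentrations_nm=_log_grid(5.0, 3000.0, 12),
        n_series=3,
        noise_sd=noise_sd,
        truth={"kd": kd, "a_free": a_free, "a_max": a_max},
        seed=seed,
    )


def competition_design(
    ic50: float,
    a_free: float = 0.18,
    a_bound: float = 0.30,
    noise_sd: float = 0.002,
    n_experiments: int = 3,
    seed: int = 0,
) -> TitrationDesign:
    """Competitor titration 50 nM - 500 uM, 12 log-spaced points, 3 experiments."""
    return TitrationDesign(
        mode="competition",
        concentrations_nm=_log_grid(50.0, 5.0e5, 12),
        n_series=n_experiments,
        noise_sd=noise_sd,
        truth={"ic50": ic50, "a_free": a_free, "a_bound": a_bound},
        seed=seed,
    )
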