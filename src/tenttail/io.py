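"""Readers, writers, configuration and the end-to-end pipeline.

File conventions: FASTQ/FASTA for reads (uppercased, U converted to T on
input), tab-separated tables for calls/compositions/titrations, JSON for
nested results and configuration.  Outputs embed the configuration hash and
seed so that any two runs with equal inputs produce identical files.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .binding import AnisotropyMeasurement, CompetitionFit, SaturationFit
from .composition import CompositionResult, UndefinedResultError, positional_composition
from .tailcall import AdapterSpec, ReadRecord, SubstrateSpec, TailCall, call_batch

__all__ = [
    "ReadParseError",
    "SchemaError",
    "PipelineConfig",
    "ReportBundle",
    "read_fastq",
    "write_fastq",
    "read_titrations",
    "write_titrations",
    "write_calls_tsv",
    "write_composition_tsv",
    "run_pipeline",
]

TITRATION_COLUMNS = ["experiment_id", "concentration_nM", "anisotropy", "replicate"]


class ReadParseError(ValueError):
    """Malformed FASTQ/FASTA record; carries the failing record index."""


class SchemaError(ValueError):
    """Tabular input does not match the documented schema."""


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_fastq(path: Union[str, Path]) -> Iterator[ReadRecord]:
    """Stream reads from FASTQ (default) or FASTA (auto-detected by '>').

    Sequences are uppercased and U is converted to T.  Malformed records
    raise :class:`ReadParseError` naming the record index (0-based).
    """
    path = Path(path)
    with open(path) as handle:
        first = handle.read(1)
        handle.seek(0)
        index = 0
        if first == ">":
            parser: Iterator = SimpleFastaParser(handle)
            try:
                for title, seq in parser:
                    yield ReadRecord(id=title.split()[0], sequence=_normalize(seq))
                    index += 1
            except (ValueError, IndexError) as exc:
                raise ReadParseError(f"{path}: malformed FASTA record at index {index}: {exc}") from exc
        else:
            it = FastqGeneralIterator(handle)
            while True:
                try:
                    title, seq, qual = next(it)
                except StopIteration:
                    return
                except ValueError as exc:
                    raise ReadParseError(
                        f"{path}: malformed FASTQ record at index {index}: {exc}"
                    ) from exc
                yield ReadRecord(id=title.split()[0], sequence=_normalize(seq), quality=qual)
                index += 1


def write_fastq(reads: Iterable[ReadRecord], path: Union[str, Path]) -> None:
    """Write 4-line FASTQ records; constant quality 'I' if a read has none."""
    with open(path, "w") as out:
        for r in reads:
            qual = r.quality or "I" * len(r.sequence)
            out.write(f"@{r.id}\n{r.sequence}\n+\n{qual}\n")


def read_titrations(path: Union[str, Path]) -> list[AnisotropyMeasurement]:
    """Read an anisotropy titration table (TSV, documented header, nM units)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in TITRATION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}; expected {TITRATION_COLUMNS}")
    out = []
    for i, row in df.iterrows():
        line_no = int(i) + 2  # 1-based, after header
        try:
            conc = float(row["concentration_nM"])
            aniso = float(row["anisotropy"])
            rep = int(row["replicate"])
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"{path}: non-numeric field at line {line_no}") from exc
        if not math.isfinite(conc) or not math.isfinite(aniso):
            raise SchemaError(f"{path}: non-finite value at line {line_no}")
        try:
            out.append(AnisotropyMeasurement(str(row["experiment_id"]), conc, aniso, rep))
        except ValueError as exc:
            raise SchemaError(f"{path}: {exc} at line {line_no}") from exc
    return out


def write_titrations(measurements: Iterable[AnisotropyMeasurement], path: Union[str, Path]) -> None:
    rows = [
        {
            "experiment_id": m.experiment_id,
            "concentration_nM": repr(m.concentration_nm),
            "anisotropy": repr(m.anisotropy),
            "replicate": m.replicate,
        }
        for m in measurements
    ]
    pd.DataFrame(rows, columns=TITRATION_COLUMNS).to_csv(path, sep="\t", index=False)


def write_calls_tsv(calls: Iterable[TailCall], path: Union[str, Path]) -> None:
    rows = [
        {
            "read_id": c.read_id,
            "status": c.status.value,
            "reject_reason": c.reject_reason.value if c.reject_reason else "",
            "insert": c.insert,
            "trimmed": c.trimmed_substrate_bases,
            "tail": c.tail,
            "tail_length": c.tail_length,
        }
        for c in calls
    ]
    pd.DataFrame(
        rows,
        columns=["read_id", "status", "reject_reason", "insert", "trimmed", "tail", "tail_length"],
    ).to_csv(path, sep="\t", index=False)


def write_composition_tsv(
    result: CompositionResult, path: Union[str, Path], variant: str = "sample"
) -> None:
    rows = []
    for pos in result.coverage.index:
        row = {
            "variant": variant,
            "position": int(pos),
            "coverage": float(result.coverage[pos]),
        }
        if pos in result.per_position.index:
            for b in "ACGU":
                row[f"freq_{b}"] = float(result.per_position.loc[pos, b])
        else:
            for b in "ACGU":
                row[f"freq_{b}"] = ""
        rows.append(row)
    cols = ["variant", "position", "coverage"] + [f"freq_{b}" for b in "ACGU"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


@dataclass
class PipelineConfig:
    """Configuration of the read-analysis pipeline; JSON round-trippable."""

    substrate: SubstrateSpec
    adapter: AdapterSpec
    max_insert: int = 100
    min_coverage: float = 0.05
    max_positions: int = 25
    include_untailed: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_insert < 1:
            raise ValueError("max_insert must be >= 1")
        if not (0.0 <= self.min_coverage <= 1.0):
            raise ValueError("min_coverage must lie in [0, 1]")
        if self.max_positions < 1:
            raise ValueError("max_positions must be >= 1")

    def to_dict(self) -> dict:
        return {
            "substrate": {
                "name": self.substrate.name,
                "prefix": self.substrate.prefix,
                "terminal_base": self.substrate.terminal_base,
                "terminal_count": self.substrate.terminal_count,
            },
            "adapter": {"name": self.adapter.name, "sequence": self.adapter.sequence},
            "max_insert": self.max_insert,
            "min_coverage": self.min_coverage,
            "max_positions": self.max_positions,
            "include_untailed": self.include_untailed,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(
            substrate=SubstrateSpec(**d["substrate"]),
            adapter=AdapterSpec(**d["adapter"]),
            max_insert=d.get("max_insert", 100),
            min_coverage=d.get("min_coverage", 0.05),
            max_positions=d.get("max_positions", 25),
            include_untailed=d.get("include_untailed", True),
            seed=d.get("seed", 0),
        )

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]


@dataclass
class ReportBundle:
    calls_path: Path
    composition_path: Optional[Path]
    summary_path: Path
    summary: dict


def run_pipeline(config: PipelineConfig, reads_path: Union[str, Path], out_dir: Union[str, Path]) -> ReportBundle:
    """Run call_batch + composition statistics and serialize all outputs.

    Writes ``calls.tsv``, ``composition.tsv`` (when any read is tailed) and
    ``summary.json`` (counts, composition summary, config echo + hash).
    Raises ``ValueError('no reads ...')`` on an empty input file.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    reads = list(read_fastq(reads_path))
    if not reads:
        raise ValueError(f"no reads in {reads_path}")
    calls, summary = call_batch(
        reads, config.substrate, config.adapter, max_insert=config.max_insert
    )
    calls_path = out_dir / "calls.tsv"
    write_calls_tsv(calls, calls_path)

    composition_path: Optional[Path] = None
    comp_dict: Optional[dict] = None
    try:
        comp = positional_composition(
            calls, min_coverage=config.min_coverage, max_positions=config.max_positions
        )
    except UndefinedResultError:
        comp = None
    if comp is not None:
        composition_path = out_dir / "composition.tsv"
        write_composition_tsv(comp, composition_path, variant=config.substrate.name)
        comp_dict = comp.to_dict()

    summary_dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "calls": summary.to_dict(),
        "composition": comp_dict,
    }
    summary_path = out_dir / "summary.json"
    summary_path.write_text(json.dumps(summary_dict, indent=2, sort_keys=True) + "\n")
    return ReportBundle(calls_path, composition_path, summary_path, summary_dict)


def saturation_fit_to_dict(fit: SaturationFit) -> dict:
    return {
        "kd_nm": fit.kd_nm,
        "kd_se_nm": fit.kd_se_nm,
        "kd_ci_nm": list(fit.kd_ci_nm),
        "a_free": fit.a_free,
        "a_free_se": fit.a_free_se,
        "a_max": fit.a_max,
        "a_max_se": fit.a_max_se,
        "residual_sum_of_squares": fit.residual_sum_of_squares,
        "n_points": fit.n_points,
        "converged": fit.converged,
        "message": fit.message,
    }


def competition_fit_to_dict(fit: CompetitionFit) -> dict:
    return {
        "ic50_nm": fit.ic50_nm,
        "ic50_se_nm": fit.ic50_se_nm,
        "ic50_ci_nm": list(fit.ic50_ci_nm),
        "level": fit.level,
        "plateaus": fit.plateaus,
        "param_names": fit.param_names,
        "covariance": fit.covariance.tolist(),
        "residual_sum_of_squares": fit.residual_sum_of_squares,
        "n_points": fit.n_points,
        "identifiable": fit.identifiable,
        "message": fit.message,
    }
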