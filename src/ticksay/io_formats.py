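"""Readers/writers for the pipeline's interchange formats, plus config.

Formats: the bioassay CSV dialect (comma separator, dot decimal, UTF-8,
required header ``tick_id,group,replicate,initial_mass_mg,dead,morbid,
egg_mass_mg,hatched,unhatched``, booleans as 0/1), plain FASTA for genomes
and gene sets, and a YAML run configuration.  Parsers reject rather than
silently coerce, and every error names the file and row/record.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .bioassay_model import TickRecord
from .genome_screen import AlignParams, Sequence

__all__ = [
    "BIOASSAY_COLUMNS",
    "RunConfig",
    "read_bioassay_csv",
    "write_bioassay_csv",
    "read_fasta",
    "write_fasta",
    "load_config",
    "setup_logging",
]

logger = logging.getLogger(__name__)

BIOASSAY_COLUMNS = (
    "tick_id",
    "group",
    "replicate",
    "initial_mass_mg",
    "dead",
    "morbid",
    "egg_mass_mg",
    "hatched",
    "unhatched",
)


def setup_logging(level: str = "INFO") -> None:
    """Timestamped logging to standard error."""
    logging.basicConfig(
        stream=sys.stderr,
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
    )


# ---------------------------------------------------------------------------
# Bioassay CSV
# ---------------------------------------------------------------------------


def _parse_bool(value: str, what: str) -> bool:
    if value not in ("0", "1"):
        raise ValueError(f"{what} must be 0 or 1, got {value!r}")
    return value == "1"


def read_bioassay_csv(path) -> list[TickRecord]:
    """Read and validate a bioassay CSV; errors name the offending row."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:
        raise ValueError(f"{path}: cannot parse CSV: {exc}") from exc
    missing = set(BIOASSAY_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records = []
    errors = []
    for pos, row in enumerate(frame.itertuples(index=False), start=2):
        try:
            group = str(row.group)
            if group != "control":
                float(group)  # must parse as a conidia/mL number
            records.append(
                TickRecord(
                    tick_id=str(row.tick_id),
                    group=group,
                    replicate=int(row.replicate),
                    initial_mass=float(row.initial_mass_mg),
                    dead=_parse_bool(row.dead, "dead"),
                    morbid=_parse_bool(row.morbid, "morbid"),
                    egg_mass=float(row.egg_mass_mg),
                    hatched=int(row.hatched),
                    unhatched=int(row.unhatched),
                )
            )
        except (ValueError, TypeError) as exc:
            errors.append(f"{path}:row {pos}: {exc}")
    if errors:
        raise ValueError("; ".join(errors))
    return records


def write_bioassay_csv(records: Iterable[TickRecord], path) -> None:
    rows = [
        {
            "tick_id": r.tick_id,
            "group": r.group,
            "replicate": r.replicate,
            "initial_mass_mg": repr(r.initial_mass),
            "dead": int(r.dead),
            "morbid": int(r.morbid),
            "egg_mass_mg": repr(r.egg_mass),
            "hatched": r.hatched,
            "unhatched": r.unhatched,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(BIOASSAY_COLUMNS)).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path) -> list[Sequence]:
    """Read FASTA into validated :class:`Sequence` records.

    Lowercase is normalised to uppercase; residues outside {A,C,G,T,N},
    empty records and duplicate ids are rejected with the record named.
    """
    path = Path(path)
    seqs: list[Sequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        try:
            seqs.append(Sequence(rec.id, str(rec.seq)))
        except ValueError as exc:
            raise ValueError(f"{path}: record {rec.id!r}: {exc}") from exc
    if not seqs:
        raise ValueError(f"{path}: no FASTA records")
    return seqs


def write_fasta(seqs: Iterable[Sequence], path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs
    ]
    with open(path, "w", encoding="utf-8") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Structured run configuration with documented defaults."""

    averaging_mode: str = "per-replicate"
    alpha: float = 0.05
    completeness_threshold: float = 90.0
    ani_fragment_len: int = 3000
    ani_min_identity: float = 80.0
    seed: int = 0
    log_level: str = "INFO"
    aligner: AlignParams = field(default_factory=AlignParams)

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 <= self.completeness_threshold <= 100:
            raise ValueError("completeness_threshold must lie in [0, 100]")
        if self.ani_fragment_len < 100:
            raise ValueError("ani_fragment_len must be >= 100")


def load_config(path) -> RunConfig:
    """Load a YAML config; unknown keys warn, they are never silently
    ignored."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    aligner_data = data.pop("aligner", {}) or {}
    known = {f.name for f in fields(RunConfig)} - {"aligner"}
    known_aligner = {f.name for f in fields(AlignParams)}
    for key in set(data) - known:
        logger.warning("%s: unknown config key %r ignored", path, key)
        data.pop(key)
    for key in set(aligner_data) - known_aligner:
        logger.warning("%s: unknown aligner config key %r ignored", path, key)
        aligner_data.pop(key)
    return RunConfig(aligner=AlignParams(**aligner_data), **data)
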