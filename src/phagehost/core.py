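"""Shared I/O, configuration and validation primitives.

All genomic intervals in this package are 0-based, half-open, on the forward
strand; strand is stored where relevant but length arithmetic is
strand-agnostic.  Ambiguous bases (``N``) never count as identical in any
comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger("phagehost")

VALID_BASES = frozenset("ACGTN")


class InputError(OSError):
    """A required input file is missing or unreadable."""


class ValidationError(ValueError):
    """Input content violates a documented precondition."""


@dataclass
class SequenceRecord:
    """A nucleotide sequence with free-form metadata.

    Metadata keys in use across the package: ``clade``, ``habitat``
    (``oyster`` or ``seawater``), ``year`` and ``replicon_type``
    (``chromosome``, ``plasmid``, ``phage``, ``prophage``, ``satellite``).
    """

    id: str
    sequence: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("sequence id must be non-empty")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValidationError(
                f"sequence {self.id!r} contains invalid characters: {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


#: Fixed analysis constants; see the methods note for provenance of each.
DEFAULT_THRESHOLDS: dict[str, float] = {
    "genus_threshold": 70.0,       # percent intergenomic similarity, inclusive
    "species_threshold": 95.0,     # percent intergenomic similarity, inclusive
    "wgrr_presence": 50.0,         # percent wGRR, strict
    "persistent_fraction": 0.90,   # gene-family prevalence, inclusive
    "min_droplets": 10_000,        # ddPCR well QC, inclusive
    "loq_copies_per_reaction": 1.0,
    "max_lag": 10,                 # sampling-date lags for ACF/CCF
    "cld_alpha": 0.05,
}


@dataclass
class RunConfig:
    """Seed, thresholds and paths shared by every pipeline stage."""

    seed: int = 0
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        merged = dict(DEFAULT_THRESHOLDS)
        merged.update(self.thresholds)
        self.thresholds = merged

    @classmethod
    def from_file(cls, path: str | Path, seed: int | None = None) -> "RunConfig":
        """Read a plain ``key=value`` config file; unknown keys go to paths."""
        path = Path(path)
        if not path.exists():
            raise InputError(f"config file not found: {path}")
        thresholds: dict = {}
        paths: dict = {}
        file_seed = 0
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValidationError(f"malformed config line: {line!r}")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key == "seed":
                file_seed = int(value)
            elif key in DEFAULT_THRESHOLDS:
                thresholds[key] = float(value)
            else:
                paths[key] = value
        cfg = cls(seed=file_seed if seed is None else seed,
                  thresholds=thresholds, paths=paths)
        return cfg

    def log_stage(self, stage: str) -> None:
        logger.info("stage=%s seed=%d thresholds=%s", stage, self.seed,
                    self.thresholds)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (wrapped or unwrapped) FASTA file into SequenceRecords.

    Sequences are uppercased and order is preserved.  Duplicate IDs and
    empty files are validation errors.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"FASTA file not found: {path}")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValidationError(f"duplicate FASTA id: {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(id=rec.id, sequence=str(rec.seq)))
    if not records:
        raise ValidationError(f"empty FASTA file: {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 70) -> Path:
    path = Path(path)
    bio = [_BioSeqRecord(Seq(r.sequence), id=r.id, description="")
           for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)
    return path


def write_table(rows: Sequence[Mapping] | pd.DataFrame, path: str | Path,
                schema: Sequence[str]) -> Path:
    """Write rows as a TSV with header in deterministic column order.

    Every row must supply every schema column; extras are a schema mismatch.
    """
    path = Path(path)
    schema = list(schema)
    if isinstance(rows, pd.DataFrame):
        missing = set(schema) - set(rows.columns)
        extra = set(rows.columns) - set(schema)
        if missing or extra:
            raise ValidationError(
                f"schema mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        df = rows.loc[:, schema]
    else:
        for i, row in enumerate(rows):
            if set(row.keys()) != set(schema):
                raise ValidationError(f"row {i} does not match schema {schema}")
        df = pd.DataFrame(list(rows), columns=schema)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_table(path: str | Path, schema: Sequence[str] | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"table not found: {path}")
    df = pd.read_csv(path, sep="\t")
    if schema is not None and list(df.columns) != list(schema):
        raise ValidationError(
            f"table {path} columns {list(df.columns)} != schema {list(schema)}")
    return df


def percent(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """Percentage rounded to the printed precision (e.g. 7/23 -> 30.4)."""
    if denominator == 0:
        raise ValidationError("zero denominator")
    return round(100.0 * numerator / denominator, ndigits)


def cross_design(dates: Sequence, strains: Sequence) -> pd.DataFrame:
    """Full factorial screening design: every sampling date crossed with
    every host strain (one plaque assay per combination)."""
    if len(dates) == 0 or len(strains) == 0:
        raise ValidationError("dates and strains must be non-empty")
    return pd.DataFrame(
        [(d, s) for d in dates for s in strains], columns=["date", "strain"]
    )
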