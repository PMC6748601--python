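"""Reading and writing external formats.

Repertoires arrive as OAS-style JSON-lines: the first line is a study-level
metadata object, every following line one sequence with region-wise
position->residue maps (keys ``fwh1``/``cdrh1``/... for heavy chains,
``fwl1``/``cdrl1``/... for light).  Queries arrive as amino-acid FASTA and
are numbered by a pluggable external numberer (e.g. ANARCI); this package
never numbers raw sequences itself.

Repertoire files are machine-generated and huge, so malformed lines are
skipped and counted rather than fatal; query inputs fail hard.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Iterator, Optional

from Bio import SeqIO

from .imgt import IMGT_SCHEME, ImgtPosition, RegionScheme, extract_regions

logger = logging.getLogger(__name__)

#: canonical amino acids plus the unknown-residue placeholder
ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY") | {"X"}


class FormatError(ValueError):
    """Structurally invalid input file."""


class FixtureError(ValueError):
    """The shipped best-identity table failed validation."""


class ConfigurationError(RuntimeError):
    """A required external component (e.g. a numberer) is missing."""


class NumberingError(RuntimeError):
    """The external numberer could not number a sequence."""


class Chain(str, Enum):
    HEAVY = "heavy"
    LIGHT = "light"

    @classmethod
    def parse(cls, label: str) -> "Chain":
        try:
            return cls(label.strip().lower())
        except ValueError:
            raise FormatError(f"unknown chain label: {label!r}") from None


@dataclass(frozen=True)
class StudyMetadata:
    """Provenance of one repertoire: study, source organism, chain type."""

    study_id: str
    species: str
    chain: Chain
    subject_id: Optional[str] = None
    immune_state: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.study_id:
            raise ValueError("study_id must be non-empty")


#: metadata tag used for query (non-repertoire) chains
QUERY_TAG = StudyMetadata(study_id="QUERY", species="n/a", chain=Chain.HEAVY)


@dataclass
class NumberedChain:
    """One antibody chain as an ordered IMGT position->residue map."""

    record_id: str
    chain: Chain
    residues: dict[ImgtPosition, str]
    meta: Optional[StudyMetadata] = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"{self.record_id}: empty residue map")
        bad = [a for a in self.residues.values() if a not in ALPHABET]
        if bad:
            raise ValueError(f"{self.record_id}: residues outside alphabet: {bad[:5]}")
        items = sorted(self.residues.items(), key=lambda kv: kv[0].sort_key)
        self.residues = dict(items)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def positions(self) -> list[ImgtPosition]:
        return list(self.residues)

    @property
    def sequence(self) -> str:
        """Residues concatenated in IMGT reading order."""
        return "".join(self.residues.values())


@dataclass(frozen=True)
class RawRecord:
    """Unnumbered sequence, possibly containing a stop codon marker '*'."""

    record_id: str
    sequence: str
    meta: Optional[StudyMetadata] = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError("sequence must be non-empty")


# ---------------------------------------------------------------------------
# OAS-style JSON-lines repertoires
# ---------------------------------------------------------------------------

_REGION_KEYS = {
    Chain.HEAVY: ("fwh1", "cdrh1", "fwh2", "cdrh2", "fwh3", "cdrh3", "fwh4"),
    Chain.LIGHT: ("fwl1", "cdrl1", "fwl2", "cdrl2", "fwl3", "cdrl3", "fwl4"),
}


class JsonlRepertoireReader:
    """Streaming reader over an OAS-style JSON-lines repertoire file.

    Iterate to obtain :class:`NumberedChain` records one at a time; the whole
    file is never held in memory.  Malformed data lines are skipped, counted
    in :attr:`skipped` and logged at WARNING.
    """

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self.skipped = 0
        self.yielded = 0
        self._meta: Optional[StudyMetadata] = None

    @property
    def metadata(self) -> StudyMetadata:
        if self._meta is None:
            with self.path.open() as fh:
                self._meta = self._parse_metadata(fh.readline())
        return self._meta

    @staticmethod
    def _parse_metadata(line: str) -> StudyMetadata:
        if not line.strip():
            raise FormatError("missing metadata line")
        try:
            obj = json.loads(line)
        except json.JSONDecodeError as exc:
            raise FormatError(f"metadata line is not valid JSON: {exc}") from exc
        if not isinstance(obj, dict) or "study_id" not in obj:
            raise FormatError("metadata line must be an object with a study_id")
        return StudyMetadata(
            study_id=str(obj["study_id"]),
            species=str(obj.get("species", "unknown")),
            chain=Chain.parse(str(obj.get("chain", ""))),
            subject_id=obj.get("subject_id"),
            immune_state=obj.get("immune_state"),
        )

    def __iter__(self) -> Iterator[NumberedChain]:
        with self.path.open() as fh:
            self._meta = self._parse_metadata(fh.readline())
            meta = self._meta
            keys = _REGION_KEYS[meta.chain]
            for lineno, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                try:
                    yield self._parse_record(line, lineno, meta, keys)
                    self.yielded += 1
                except (ValueError, KeyError, TypeError) as exc:
                    self.skipped += 1
                    logger.warning("%s:%d skipped: %s", self.path.name, lineno, exc)

    def _parse_record(
        self, line: str, lineno: int, meta: StudyMetadata, keys: tuple[str, ...]
    ) -> NumberedChain:
        obj = json.loads(line)
        residues: dict[ImgtPosition, str] = {}
        for key in keys:
            region = obj.get(key)
            if not region:
                continue
            for pos_str, aa in region.items():
                if not (isinstance(aa, str) and len(aa) == 1 and aa in ALPHABET):
                    raise ValueError(f"bad residue {aa!r} at {pos_str}")
                residues[ImgtPosition.parse(pos_str)] = aa
        record_id = str(obj.get("name", f"{meta.study_id}:{lineno - 1}"))
        return NumberedChain(record_id=record_id, chain=meta.chain, residues=residues, meta=meta)


def read_oas_jsonl(path: str | Path) -> JsonlRepertoireReader:
    """Open an OAS-style JSON-lines repertoire for streaming iteration."""
    return JsonlRepertoireReader(path)


def write_oas_jsonl(
    records: Iterable[NumberedChain],
    path: str | Path,
    meta: StudyMetadata,
    scheme: RegionScheme = IMGT_SCHEME,
) -> int:
    """Write records in the OAS-style dialect; returns the record count."""
    keys = _REGION_KEYS[meta.chain]
    names = ("fw1", "cdr1", "fw2", "cdr2", "fw3", "cdr3", "fw4")
    rename = dict(zip(names, keys))
    n = 0
    with Path(path).open("w") as fh:
        header = {
            "study_id": meta.study_id,
            "species": meta.species,
            "chain": meta.chain.value,
        }
        if meta.subject_id:
            header["subject_id"] = meta.subject_id
        if meta.immune_state:
            header["immune_state"] = meta.immune_state
        fh.write(json.dumps(header) + "\n")
        for rec in records:
            regions: dict[str, dict[str, str]] = {}
            for pos, aa in rec.residues.items():
                region = rename[scheme.region_of(pos)]
                regions.setdefault(region, {})[str(pos)] = aa
            obj: dict = {"name": rec.record_id}
            obj.update(regions)
            fh.write(json.dumps(obj) + "\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# FASTA queries + pluggable numbering
# ---------------------------------------------------------------------------

#: maps a raw amino-acid sequence to (chain type, position->residue map);
#: raises NumberingError on failure.  ANARCI wrapped this way plugs in here.
Numberer = Callable[[str], tuple[Chain, dict[ImgtPosition, str]]]


class SequentialNumberer:
    """Trivial numberer assigning positions 1..L in order.

    Useful for tests and for inputs that are already IMGT-gapped; it is NOT a
    substitute for a real antibody numberer on arbitrary sequences.
    """

    def __init__(self, chain: Chain = Chain.HEAVY):
        self.chain = chain

    def __call__(self, sequence: str) -> tuple[Chain, dict[ImgtPosition, str]]:
        if not sequence or len(sequence) > 128:
            raise NumberingError(f"cannot number sequence of length {len(sequence)}")
        return self.chain, {
            ImgtPosition(i + 1): aa for i, aa in enumerate(sequence.upper())
        }


def read_fasta_queries(
    path: str | Path, numberer: Optional[Numberer]
) -> tuple[list[NumberedChain], list[tuple[str, str]]]:
    """Read and number query chains from an amino-acid FASTA file.

    Returns (numbered chains in file order, rejects as (id, reason) pairs).
    """
    if numberer is None:
        raise ConfigurationError(
            "no numberer configured; FASTA queries require an external numbering "
            "component or pre-numbered JSON-lines input"
        )
    chains: list[NumberedChain] = []
    rejects: list[tuple[str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        try:
            chain_type, residues = numberer(seq)
            chains.append(
                NumberedChain(record_id=rec.id, chain=chain_type, residues=residues)
            )
        except (NumberingError, ValueError) as exc:
            rejects.append((rec.id, str(exc)))
    return chains, rejects


# ---------------------------------------------------------------------------
# Productivity filter
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FilterConfig:
    """Which productivity rules apply on ingest; each is independently
    toggleable.  Coverage = numbered positions / raw sequence length."""

    check_stop: bool = True
    check_c104: bool = True
    check_w118: bool = True
    min_coverage: float = 0.8


_POS_104 = ImgtPosition(104)
_POS_118 = ImgtPosition(118)


def productivity_filter(
    record: RawRecord,
    numbered: NumberedChain,
    config: FilterConfig = FilterConfig(),
) -> tuple[bool, Optional[str]]:
    """Decide keep/drop for one sequence; total function, never raises.

    Drop rules, checked in order (the reason names the first failure):
    stop codon in the raw sequence; conserved Cys missing at 104; conserved
    Trp/Phe missing at 118; numbered coverage below the configured minimum.
    """
    if config.check_stop and "*" in record.sequence:
        return False, "stop_codon"
    if config.check_c104 and numbered.residues.get(_POS_104) != "C":
        return False, "conserved_104"
    if config.check_w118 and numbered.residues.get(_POS_118) not in ("W", "F"):
        return False, "conserved_118"
    if len(numbered) < config.min_coverage * len(record.sequence):
        return False, "low_coverage"
    return True, None


# ---------------------------------------------------------------------------
# Table 1 fixture (best identities of 242 clinical-stage therapeutics)
# ---------------------------------------------------------------------------

FIXTURE_COLUMNS = ("heavy", "light", "heavy_cdrs", "light_cdrs", "cdrh3")


@dataclass(frozen=True)
class FixtureRow:
    name: str
    heavy: int
    light: int
    heavy_cdrs: int
    light_cdrs: int
    cdrh3: int

    def percent(self, column: str) -> int:
        return getattr(self, column)


def fixture_path() -> Path:
    """Path of the shipped 242-antibody best-identity table."""
    return Path(resources.files("abmatch").joinpath("data/table1_best_identities.csv"))


def read_table1_fixture(
    path: str | Path | None = None, expected_rows: int = 242
) -> list[FixtureRow]:
    """Load the best-identity table; validates shape and value range."""
    import pandas as pd

    src = Path(path) if path is not None else fixture_path()
    df = pd.read_csv(src)
    required = ("name",) + FIXTURE_COLUMNS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FixtureError(f"fixture missing columns: {missing}")
    if len(df) != expected_rows:
        raise FixtureError(f"expected {expected_rows} rows, found {len(df)}")
    rows: list[FixtureRow] = []
    for rec in df.itertuples(index=False):
        values = {}
        for col in FIXTURE_COLUMNS:
            v = getattr(rec, col)
            try:
                iv = int(v)
            except (TypeError, ValueError):
                raise FixtureError(f"{rec.name}: non-integer {col}={v!r}") from None
            if iv != v or not (0 <= iv <= 100):
                raise FixtureError(f"{rec.name}: {col}={v!r} outside 0-100")
            values[col] = iv
        rows.append(FixtureRow(name=str(rec.name), **values))
    return rows


# ---------------------------------------------------------------------------
# Report serialization lives with the report type; re-exported here so all
# format I/O is reachable from one module.
# ---------------------------------------------------------------------------

def write_report(report, path: str | Path, format: str = "csv") -> None:
    """Serialize a summary report as CSV (Table-1-style) or JSON."""
    from .summarize import write_report as _write

    _write(report, path, format)


def read_report(path: str | Path, format: str = "csv"):
    """Inverse of :func:`write_report` (lossless round-trip)."""
    from .summarize import read_report as _read

    return _read(path, format)
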