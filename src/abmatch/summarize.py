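"""Antibody-type classification and report aggregation.

International nonproprietary names (INNs) encode how an antibody was made:
``-ximab``/``-xizumab`` chimeric, ``-zumab`` humanized, ``-umab`` fully
human; a short explicit list covers the mouse-era ``-momab`` molecules.
Classification feeds the per-type stratification of best-match identities
and the attribution of best matches to source species and studies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .identity import Mode, percent_display
from .io import FIXTURE_COLUMNS, FixtureRow, StudyMetadata
from .search import MatchResult


class AntibodyType(str, Enum):
    CHIMERIC = "chimeric"
    HUMANIZED = "humanized"
    FULLY_HUMAN = "fully_human"
    MOUSE = "mouse"
    UNKNOWN = "unknown"


class UnclassifiableNameError(ValueError):
    """The name matches none of the INN suffix rules."""


#: the three pre-suffix-convention mouse antibodies
DEFAULT_MOUSE_NAMES = frozenset({"muromonab", "abagovomab", "racotumomab"})


def classify_inn(
    name: str, mouse_list: frozenset[str] | set[str] = DEFAULT_MOUSE_NAMES
) -> AntibodyType:
    """Classify one antibody name by its INN suffix.

    Matching is case-insensitive and substring-based (the printed rules'
    leading hyphen is ignored).  The explicit mouse list overrides every
    suffix rule.  Raises :class:`UnclassifiableNameError` when nothing
    applies.
    """
    if not name:
        raise UnclassifiableNameError("empty name")
    n = name.strip().lower()
    if n in {m.lower() for m in mouse_list}:
        return AntibodyType.MOUSE
    if "xizumab" in n or "ximab" in n:
        return AntibodyType.CHIMERIC
    if "zumab" in n:
        return AntibodyType.HUMANIZED
    if "umab" in n:
        return AntibodyType.FULLY_HUMAN
    raise UnclassifiableNameError(f"no INN suffix rule matches {name!r}")


def classify_names(
    names: Iterable[str], mouse_list: frozenset[str] | set[str] = DEFAULT_MOUSE_NAMES
) -> dict[str, AntibodyType]:
    """Batch classification; unmatchable names map to UNKNOWN, never raise."""
    out: dict[str, AntibodyType] = {}
    for name in names:
        try:
            out[name] = classify_inn(name, mouse_list)
        except UnclassifiableNameError:
            out[name] = AntibodyType.UNKNOWN
    return out


# ---------------------------------------------------------------------------
# Report rows and threshold predicates
# ---------------------------------------------------------------------------

#: report columns, in the order the printed table uses
REPORT_COLUMNS = FIXTURE_COLUMNS  # heavy, light, heavy_cdrs, light_cdrs, cdrh3

#: (query chain, mode) -> report column
MODE_COLUMNS = {
    ("heavy", Mode.FULL_CHAIN): "heavy",
    ("light", Mode.FULL_CHAIN): "light",
    ("heavy", Mode.CDR_TRIPLET): "heavy_cdrs",
    ("light", Mode.CDR_TRIPLET): "light_cdrs",
    ("heavy", Mode.CDRH3): "cdrh3",
}


@dataclass
class ReportRow:
    """Per-query best identities: displayed integer percents plus, when the
    row came from a live search, the raw fractional values."""

    name: str
    ab_type: AntibodyType
    percents: dict[str, Optional[int]]
    raw: dict[str, Optional[float]] = field(default_factory=dict)

    def value_for(self, column: str) -> Optional[float]:
        """Raw fraction if available, else displayed percent / 100."""
        r = self.raw.get(column)
        if r is not None:
            return r
        p = self.percents.get(column)
        return None if p is None else p / 100


@dataclass(frozen=True)
class Predicate:
    """Threshold predicate over one or more report columns (all must hold)."""

    columns: tuple[str, ...]
    op: str  # "ge" or "eq"
    threshold: int  # integer percent

    @property
    def label(self) -> str:
        cols = "+".join(self.columns)
        sym = ">=" if self.op == "ge" else "=="
        return f"{cols}{sym}{self.threshold}"

    def holds(self, row: ReportRow) -> bool:
        for col in self.columns:
            v = row.value_for(col)
            if v is None:  # no-match fails every predicate
                return False
            # raw-fraction path with a one-sided epsilon; on integer-percent
            # rows v is exactly p/100 and this reduces to integer comparison
            t = self.threshold / 100
            if self.op == "ge":
                if not v >= t - 1e-12:
                    return False
            elif self.op == "eq":
                if not abs(v - t) <= 1e-12:
                    return False
            else:
                raise ValueError(f"unknown op {self.op!r}")
        return True


#: the threshold set reported in the study this pipeline reproduces
DEFAULT_PREDICATES: tuple[Predicate, ...] = (
    Predicate(("heavy",), "ge", 90),
    Predicate(("heavy",), "ge", 95),
    Predicate(("light",), "ge", 90),
    Predicate(("light",), "ge", 95),
    Predicate(("light",), "eq", 100),
    Predicate(("heavy", "light"), "ge", 95),
    Predicate(("heavy_cdrs",), "ge", 90),
    Predicate(("heavy_cdrs",), "ge", 95),
    Predicate(("heavy_cdrs",), "eq", 100),
    Predicate(("light_cdrs",), "ge", 90),
    Predicate(("light_cdrs",), "ge", 95),
    Predicate(("light_cdrs",), "eq", 100),
    Predicate(("cdrh3",), "eq", 100),
)


def _pct_str(count: int, total: int) -> str:
    if total == 0:
        return "0.0"
    d = (Decimal(count) * 100 / Decimal(total)).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_UP
    )
    return str(d)


@dataclass
class SummaryReport:
    """Table-1-analogue: per-query rows, threshold counts, per-type strata,
    and source attribution of the retained best matches."""

    rows: list[ReportRow]
    threshold_counts: dict[str, dict]
    strata: dict[str, dict] = field(default_factory=dict)
    source_attribution: dict[str, dict[str, int]] = field(default_factory=dict)
    studies_hit: set[str] = field(default_factory=set)

    @property
    def n_queries(self) -> int:
        return len(self.rows)


def rows_from_fixture(
    fixture: Sequence[FixtureRow],
    types: Optional[Mapping[str, AntibodyType]] = None,
) -> list[ReportRow]:
    """Adapt the shipped integer-percent table into report rows."""
    if types is None:
        types = classify_names([r.name for r in fixture])
    return [
        ReportRow(
            name=r.name,
            ab_type=types.get(r.name, AntibodyType.UNKNOWN),
            percents={col: r.percent(col) for col in REPORT_COLUMNS},
        )
        for r in fixture
    ]


def rows_from_results(
    results: Iterable[MatchResult],
    types: Optional[Mapping[str, AntibodyType]] = None,
    query_chains: Optional[Mapping[str, str]] = None,
) -> list[ReportRow]:
    """Group per-(query, mode) search results into report rows.

    ``query_chains`` maps query id -> "heavy"/"light"; when omitted the
    query id is assumed to name a heavy chain.  A duplicate (query, mode)
    pair is a usage error.
    """
    types = types or {}
    grouped: dict[str, ReportRow] = {}
    seen: set[tuple[str, Mode]] = set()
    for res in results:
        key = (res.query_id, res.mode)
        if key in seen:
            raise ValueError(f"duplicate result for query {res.query_id} mode {res.mode}")
        seen.add(key)
        chain = (query_chains or {}).get(res.query_id, "heavy")
        column = MODE_COLUMNS.get((chain, res.mode))
        if column is None:
            continue  # e.g. light-chain CDR3 mode: not a report column
        row = grouped.get(res.query_id)
        if row is None:
            row = ReportRow(
                name=res.query_id,
                ab_type=types.get(res.query_id, AntibodyType.UNKNOWN),
                percents={c: None for c in REPORT_COLUMNS},
                raw={c: None for c in REPORT_COLUMNS},
            )
            grouped[res.query_id] = row
        row.percents[column] = percent_display(res.score)
        row.raw[column] = float(res.exact)
    return list(grouped.values())


def summarize(
    rows: Sequence[ReportRow],
    predicates: Sequence[Predicate] = DEFAULT_PREDICATES,
) -> SummaryReport:
    """Aggregate rows into a summary report.

    Row order in the output follows the printed convention: descending best
    heavy-chain identity, ties broken by name; rows lacking a heavy value
    sort last.  Threshold counting is permutation-invariant.
    """
    ordered = sorted(
        rows,
        key=lambda r: (
            -(r.percents.get("heavy") if r.percents.get("heavy") is not None else -1),
            r.name,
        ),
    )
    n = len(ordered)
    counts = {
        p.label: {
            "count": (c := sum(1 for r in ordered if p.holds(r))),
            "percentage": _pct_str(c, n),
        }
        for p in predicates
    }
    report = SummaryReport(rows=ordered, threshold_counts=counts)
    report.strata = stratify_by_type(report)
    return report


def stratify_by_type(report: SummaryReport, small_sample_threshold: int = 5) -> dict:
    """Per-type, per-column five-number summaries of displayed percents."""
    import numpy as np

    strata: dict[str, dict] = {}
    for ab_type in AntibodyType:
        members = [r for r in report.rows if r.ab_type is ab_type]
        if not members:
            continue
        entry: dict = {
            "n": len(members),
            "small_sample": len(members) < small_sample_threshold,
            "columns": {},
        }
        for col in REPORT_COLUMNS:
            vals = [r.percents[col] for r in members if r.percents.get(col) is not None]
            if not vals:
                continue
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            entry["columns"][col] = {
                "n": len(vals),
                "min": int(min(vals)),
                "q1": float(q1),
                "median": float(med),
                "q3": float(q3),
                "max": int(max(vals)),
            }
        strata[ab_type.value] = entry
    return strata


def source_attribution(
    results: Iterable[MatchResult],
    types: Mapping[str, AntibodyType],
) -> tuple[dict[str, dict[str, int]], set[str]]:
    """Count best-match source species per (antibody type, mode); collect the
    set of studies contributing any best match.

    Ties are attributed to the retained earliest-insertion-order template
    (its metadata rides on the result); ``tie_count`` on each result records
    that ties existed.
    """
    attribution: dict[str, dict[str, int]] = {}
    studies: set[str] = set()
    for res in results:
        if res.source is None:
            continue
        studies.add(res.source.study_id)
        ab_type = types.get(res.query_id, AntibodyType.UNKNOWN)
        key = f"{ab_type.value}:{res.mode.value}"
        bucket = attribution.setdefault(key, {})
        bucket[res.source.species] = bucket.get(res.source.species, 0) + 1
    return attribution, studies


# ---------------------------------------------------------------------------
# Serialization (CSV mirrors the printed table layout; JSON is lossless)
# ---------------------------------------------------------------------------

_CSV_HEADER = ["name", "type", *REPORT_COLUMNS]


def write_report(report: SummaryReport, path: str | Path, format: str = "csv") -> None:
    path = Path(path)
    if format == "json":
        payload = {
            "rows": [
                {
                    "name": r.name,
                    "type": r.ab_type.value,
                    "percents": r.percents,
                    "raw": {k: v for k, v in r.raw.items() if v is not None},
                }
                for r in report.rows
            ],
            "threshold_counts": report.threshold_counts,
            "strata": report.strata,
            "source_attribution": report.source_attribution,
            "studies_hit": sorted(report.studies_hit),
        }
        path.write_text(json.dumps(payload, indent=2) + "\n")
        return
    if format != "csv":
        raise ValueError(f"unknown report format {format!r}")
    lines = [",".join(_CSV_HEADER)]
    for r in report.rows:
        cells = [r.name, r.ab_type.value]
        cells += ["" if r.percents.get(c) is None else str(r.percents[c]) for c in REPORT_COLUMNS]
        lines.append(",".join(cells))
    for label, entry in report.threshold_counts.items():
        lines.append(f"#SUMMARY,{label},{entry['count']},{entry['percentage']}")
    path.write_text("\n".join(lines) + "\n")


def read_report(path: str | Path, format: str = "csv") -> SummaryReport:
    path = Path(path)
    if format == "json":
        payload = json.loads(path.read_text())
        rows = [
            ReportRow(
                name=r["name"],
                ab_type=AntibodyType(r["type"]),
                percents={k: v for k, v in r["percents"].items()},
                raw={k: v for k, v in r.get("raw", {}).items()},
            )
            for r in payload["rows"]
        ]
        report = SummaryReport(
            rows=rows,
            threshold_counts=payload["threshold_counts"],
            strata=payload.get("strata", {}),
            source_attribution=payload.get("source_attribution", {}),
            studies_hit=set(payload.get("studies_hit", [])),
        )
        return report
    rows: list[ReportRow] = []
    counts: dict[str, dict] = {}
    lines = Path(path).read_text().splitlines()
    for line in lines[1:]:
        if not line.strip():
            continue
        if line.startswith("#SUMMARY,"):
            _, label, count, pct = line.split(",")
            counts[label] = {"count": int(count), "percentage": pct}
            continue
        cells = line.split(",")
        name, ab_type, *values = cells
        rows.append(
            ReportRow(
                name=name,
                ab_type=AntibodyType(ab_type),
                percents={
                    col: (int(v) if v != "" else None)
                    for col, v in zip(REPORT_COLUMNS, values)
                },
            )
        )
    report = SummaryReport(rows=rows, threshold_counts=counts)
    report.strata = stratify_by_type(report)
    return report
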