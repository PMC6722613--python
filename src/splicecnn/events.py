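"""Exon-centric splicing-event tables: parsing, classification, filtering, stratification.

A *splicing event* is a human internal exon annotated with EST-derived
frequencies: the inclusion level (fraction of transcripts that include the
exon) and the alternative 3'/5' splice-site usage levels.  Events are
assigned one of four classes:

* ``CON``  -- constitutive: every level equals 1, no EST evidence of any AS.
* ``ES``   -- cassette / skipped exon: 0 < inclusion level < 1, no
  alternative splice-site usage.
* ``ALT3`` -- alternative acceptor (3'ss) usage, otherwise constitutive.
* ``ALT5`` -- alternative donor (5'ss) usage, otherwise constitutive.
* ``EXCLUDED`` -- evidence for more than one AS type (e.g. both an
  alternative 3' and 5' site); such exons are dropped from all datasets.

Input tables are TSV with 1-based inclusive genomic coordinates; internally
all coordinates are 0-based half-open.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

__all__ = [
    "SplicingEvent",
    "FilterThresholds",
    "TableSchemaError",
    "RowError",
    "EVENT_TSV_COLUMNS",
    "parse_event_table",
    "classify_event",
    "classify_events",
    "apply_quality_filters",
    "stratify_by_frequency",
    "relevant_level",
    "write_event_table",
    "write_bed",
]

AS_CLASSES = ("CON", "ES", "ALT3", "ALT5")

EVENT_TSV_COLUMNS = [
    "event_id",
    "chrom",
    "strand",
    "exon_start",
    "exon_end",
    "upstream_intron_len",
    "downstream_intron_len",
    "incl_level",
    "usage3_level",
    "usage5_level",
    "est_incl",
    "est_excl",
    "est_alt3",
    "est_alt5",
]

_LEVEL_FIELDS = ("incl_level", "usage3_level", "usage5_level")
_COUNT_FIELDS = ("est_incl", "est_excl", "est_alt3", "est_alt5")


class TableSchemaError(ValueError):
    """The event table header does not match the documented schema."""


@dataclass
class RowError:
    """A malformed row, reported with its 1-based line number."""

    line: int
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"line {self.line}: {self.message}"


@dataclass
class SplicingEvent:
    """One internal exon with coordinates, EST support and AS levels.

    Coordinates are 0-based half-open (``exon_len == exon_end - exon_start``).
    """

    event_id: str
    chrom: str
    strand: str
    exon_start: int
    exon_end: int
    upstream_intron_len: int
    downstream_intron_len: int
    incl_level: float
    usage3_level: float
    usage5_level: float
    est_incl: int = 0
    est_excl: int = 0
    est_alt3: int = 0
    est_alt5: int = 0
    as_class: str = ""

    @property
    def exon_len(self) -> int:
        return self.exon_end - self.exon_start

    def validate(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.event_id}: strand must be '+' or '-'")
        if self.exon_len < 1:
            raise ValueError(f"{self.event_id}: exon_len must be >= 1")
        for name in _LEVEL_FIELDS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{self.event_id}: {name}={v} outside [0,1]")
        for name in _COUNT_FIELDS:
            if getattr(self, name) < 0:
                raise ValueError(f"{self.event_id}: {name} negative")


@dataclass(frozen=True)
class FilterThresholds:
    """EST-support and length thresholds applied to classified events.

    ``min_est_skipping`` is the minimum total inclusion+exclusion EST count
    for cassette exons; ``min_est_altsite`` the minimum alternative-site EST
    count for ALT3/ALT5; ``min_est_con`` an optional minimum inclusion EST
    count for constitutive exons (0 disables it).
    """

    min_est_skipping: int = 20
    min_est_altsite: int = 4
    min_exon_len: int = 25
    min_intron_len: int = 80
    min_est_con: int = 0

    def __post_init__(self) -> None:
        for name in ("min_est_skipping", "min_est_altsite", "min_exon_len", "min_intron_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.min_est_con < 0:
            raise ValueError("min_est_con must be >= 0")


def parse_event_table(
    path,
) -> tuple[list[SplicingEvent], list[RowError]]:
    """Read an event TSV, converting coordinates to 0-based half-open.

    Returns ``(events, row_errors)``.  Malformed rows are collected as
    :class:`RowError` (with 1-based line numbers) rather than raised; a
    header that does not contain every documented column raises
    :class:`TableSchemaError`.
    """
    events: list[SplicingEvent] = []
    errors: list[RowError] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        missing = [c for c in EVENT_TSV_COLUMNS if c not in header]
        if missing:
            raise TableSchemaError(f"missing required column(s): {', '.join(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                ev = _row_to_event(row)
                ev.validate()
            except (ValueError, KeyError) as exc:
                errors.append(RowError(line=lineno, message=str(exc)))
                continue
            events.append(ev)
    return events, errors


def _row_to_event(row: dict) -> SplicingEvent:
    start_1based = int(row["exon_start"])
    end_1based = int(row["exon_end"])
    ev = SplicingEvent(
        event_id=row["event_id"],
        chrom=row["chrom"],
        strand=row["strand"],
        exon_start=start_1based - 1,  # 1-based inclusive -> 0-based half-open
        exon_end=end_1based,
        upstream_intron_len=int(row["upstream_intron_len"]),
        downstream_intron_len=int(row["downstream_intron_len"]),
        incl_level=float(row["incl_level"]),
        usage3_level=float(row["usage3_level"]),
        usage5_level=float(row["usage5_level"]),
        est_incl=int(row["est_incl"]),
        est_excl=int(row["est_excl"]),
        est_alt3=int(row["est_alt3"]),
        est_alt5=int(row["est_alt5"]),
    )
    if "as_class" in row and row.get("as_class"):
        ev.as_class = row["as_class"]
    return ev


def classify_event(e: SplicingEvent) -> str:
    """Assign the AS class from the three frequency levels.

    Exactly one label is returned for any event; exons evidencing more than
    one AS type (e.g. both an alternative acceptor and donor, or
    alternative-site usage combined with skipping) are ``EXCLUDED``.
    """
    incl, u3, u5 = e.incl_level, e.usage3_level, e.usage5_level
    alt3 = u3 < 1.0
    alt5 = u5 < 1.0
    skipped = incl < 1.0
    n_types = int(alt3) + int(alt5) + int(skipped)
    if n_types == 0:
        return "CON"
    if n_types > 1:
        return "EXCLUDED"
    if skipped:
        # strictly interior inclusion: an exon that can be either excluded
        # or included must show evidence of both
        return "ES" if incl > 0.0 else "EXCLUDED"
    return "ALT3" if alt3 else "ALT5"


def classify_events(events: Iterable[SplicingEvent]) -> list[SplicingEvent]:
    """Return copies of *events* with ``as_class`` populated."""
    return [replace(e, as_class=classify_event(e)) for e in events]


@dataclass
class Rejection:
    event: SplicingEvent
    rule: str


# fixed rule order: EST support first, then exon length, then intron lengths
def _first_failing_rule(e: SplicingEvent, t: FilterThresholds) -> str | None:
    if e.as_class == "EXCLUDED":
        return "excluded_class"
    if e.as_class == "ES" and e.est_incl + e.est_excl < t.min_est_skipping:
        return "min_est_skipping"
    if e.as_class == "ALT3" and e.est_alt3 < t.min_est_altsite:
        return "min_est_altsite"
    if e.as_class == "ALT5" and e.est_alt5 < t.min_est_altsite:
        return "min_est_altsite"
    if e.as_class == "CON" and t.min_est_con and e.est_incl < t.min_est_con:
        return "min_est_con"
    if e.exon_len < t.min_exon_len:
        return "min_exon_len"
    if min(e.upstream_intron_len, e.downstream_intron_len) < t.min_intron_len:
        return "min_intron_len"
    return None


def apply_quality_filters(
    events: Sequence[SplicingEvent],
    thresholds: FilterThresholds | None = None,
) -> tuple[list[SplicingEvent], list[Rejection]]:
    """Split classified events into kept and rejected lists.

    All thresholds are inclusive ("at least N" means >= N).  Each rejection
    carries the first failing rule in the fixed order EST support, exon
    length, intron lengths; the kept/rejected lists preserve input order and
    together reconstitute the input.
    """
    t = thresholds or FilterThresholds()
    kept: list[SplicingEvent] = []
    rejected: list[Rejection] = []
    for e in events:
        if not e.as_class:
            raise ValueError(f"{e.event_id}: events must be classified before filtering")
        rule = _first_failing_rule(e, t)
        if rule is None:
            kept.append(e)
        else:
            rejected.append(Rejection(event=e, rule=rule))
    return kept, rejected


def relevant_level(e: SplicingEvent) -> float:
    """The frequency that defines an event's stratum: inclusion level for
    cassette exons, alternative-site usage level for ALT3/ALT5."""
    if e.as_class == "ES":
        return e.incl_level
    if e.as_class == "ALT3":
        return e.usage3_level
    if e.as_class == "ALT5":
        return e.usage5_level
    raise ValueError(f"{e.event_id}: {e.as_class or '?'} events have no frequency stratum")


def stratify_by_frequency(
    events: Sequence[SplicingEvent], cutoff: float = 0.8
) -> dict[str, str]:
    """Partition non-constitutive events into HEvents / MREvents.

    ``HEvents`` are events whose relevant level is strictly greater than
    *cutoff* (default 0.8); everything else is ``MREvents``.  Constitutive
    events have no stratum and raise ``ValueError``.
    """
    if not 0.0 < cutoff < 1.0:
        raise ValueError("cutoff must lie in (0,1)")
    out: dict[str, str] = {}
    for e in events:
        level = relevant_level(e)
        out[e.event_id] = "HEvents" if level > cutoff else "MREvents"
    return out


def write_event_table(events: Sequence[SplicingEvent], path, strata: dict[str, str] | None = None) -> None:
    """Write events back to TSV (1-based inclusive coordinates on output),
    with ``as_class`` and, when *strata* is given, ``stratum`` columns."""
    cols = EVENT_TSV_COLUMNS + ["as_class"] + (["stratum"] if strata is not None else [])
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(cols)
        for e in events:
            row = [
                e.event_id,
                e.chrom,
                e.strand,
                e.exon_start + 1,
                e.exon_end,
                e.upstream_intron_len,
                e.downstream_intron_len,
                _fmt(e.incl_level),
                _fmt(e.usage3_level),
                _fmt(e.usage5_level),
                e.est_incl,
                e.est_excl,
                e.est_alt3,
                e.est_alt5,
                e.as_class,
            ]
            if strata is not None:
                row.append(strata.get(e.event_id, "NA"))
            w.writerow(row)


def _fmt(x: float) -> str:
    return format(x, ".6g")


def write_bed(events: Sequence[SplicingEvent], path) -> None:
    """Export kept exons as BED6 (0-based half-open, score = round(1000*level))."""
    with open(path, "w") as fh:
        for e in events:
            if e.as_class == "CON":
                level = 1.0
            else:
                level = relevant_level(e)
            fh.write(
                f"{e.chrom}\t{e.exon_start}\t{e.exon_end}\t{e.event_id}\t"
                f"{round(1000 * level)}\t{e.strand}\n"
            )
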