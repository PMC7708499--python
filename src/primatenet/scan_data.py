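"""Data model, readers and validation for scan-sampling logs and biography rosters.

The observational unit is one individual's state at one instantaneous scan
(every 2 minutes within a 20-minute session): its behaviour and behavioural
partner, the set of group mates within an arm's reach, its planar position
(metres) and height level (0 = ground, 1-4 = climbing-structure levels), and
two flags — ``access`` (could it reach the outdoor enclosure at all?) and
``visible`` (was it actually observable?).  Dyadic index denominators use
``access`` only: a scan where one animal sits indoors (access but not
visible) still counts as co-access time.

A scans CSV may hold more than one row per (session, scan, individual): one
row per behavioural partner.  Presence fields (access/visible/position/
height/arms-reach) must agree across such rows.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "SEXES",
    "ORIGINS",
    "PHC",
    "BEHAVIORS",
    "Biography",
    "ScanRecord",
    "SessionInfo",
    "ValidationIssue",
    "ValidationReport",
    "read_biographies",
    "write_biographies",
    "read_scans",
    "write_scans",
    "session_table",
    "validate_exclusivity",
    "access_denominator",
]

SEXES = ("F", "M")
ORIGINS = ("wild", "captive")
PHC = ("with", "without")
BEHAVIORS = ("none", "affiliative", "grooming", "other")

#: Exact scans-CSV column order (canonical dialect).
SCAN_COLUMNS = (
    "group",
    "session_id",
    "scan_index",
    "individual",
    "access",
    "visible",
    "behavior",
    "partner",
    "arms_reach",
    "pos_x",
    "pos_y",
    "height_level",
)

BIOGRAPHY_COLUMNS = (
    "id",
    "name",
    "sex",
    "origin",
    "phc_infant",
    "year_birth",
    "year_arrival",
    "group",
)


@dataclass(frozen=True)
class Biography:
    """One individual's identity and early-life attributes.

    ``origin`` distinguishes wild-caught from captive-born animals;
    ``phc_infant`` is the predominant housing condition during the first five
    years of life (``with``/``without`` conspecifics for > 2.5 of those years).
    """

    id: str
    name: str
    sex: str
    origin: str
    phc_infant: str
    year_birth: int
    year_arrival: int
    group: str

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r} for {self.id}")
        if self.origin not in ORIGINS:
            raise ValueError(f"unknown origin {self.origin!r} for {self.id}")
        if self.phc_infant not in PHC:
            raise ValueError(f"unknown phc_infant {self.phc_infant!r} for {self.id}")
        if self.year_arrival < self.year_birth:
            raise ValueError(
                f"{self.id}: year_arrival {self.year_arrival} precedes "
                f"year_birth {self.year_birth}"
            )


@dataclass(frozen=True)
class ScanRecord:
    """One individual's state at one scan."""

    group: str
    session_id: str
    scan_index: int
    individual: str
    access: bool
    visible: bool
    behavior: str = "none"
    partner: str | None = None
    arms_reach: frozenset[str] = field(default_factory=frozenset)
    position: tuple[float, float] | None = None
    height_level: int | None = None

    def __post_init__(self) -> None:
        if self.behavior not in BEHAVIORS:
            raise ValueError(f"unknown behavior {self.behavior!r}")
        if self.partner == self.individual:
            raise ValueError(f"{self.individual}: partner equals individual")
        if self.individual in self.arms_reach:
            raise ValueError(f"{self.individual}: appears in own arms_reach")
        if self.height_level is not None and not 0 <= self.height_level <= 4:
            raise ValueError(f"height_level {self.height_level} outside 0-4")
        if self.scan_index < 0:
            raise ValueError("scan_index must be >= 0")


@dataclass(frozen=True)
class SessionInfo:
    """Summary of one 20-minute observation session."""

    session_id: str
    group: str
    date: str
    period: str  # am | pm
    n_scans: int


@dataclass(frozen=True)
class ValidationIssue:
    session_id: str
    scan_index: int
    entity: str
    message: str


@dataclass
class ValidationReport:
    """Record-level problems collected during reading or auditing."""

    issues: list[ValidationIssue] = field(default_factory=list)

    def add(self, session_id: str, scan_index: int, entity: str, message: str) -> None:
        self.issues.append(ValidationIssue(session_id, scan_index, entity, message))

    @property
    def ok(self) -> bool:
        return not self.issues

    def __len__(self) -> int:
        return len(self.issues)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ValidationReport({len(self.issues)} issues)"


# ---------------------------------------------------------------------------
# biography IO


def read_biographies(path: str | Path) -> list[Biography]:
    """Read a biography roster CSV (one row per individual).

    Raises ``ValueError`` on a missing required column or a duplicate id.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in BIOGRAPHY_COLUMNS:
            if col not in header:
                raise ValueError(f"biography file missing required column {col!r}")
        roster: list[Biography] = []
        seen: set[str] = set()
        for row in reader:
            bio = Biography(
                id=row["id"].strip(),
                name=row["name"].strip(),
                sex=row["sex"].strip(),
                origin=row["origin"].strip(),
                phc_infant=row["phc_infant"].strip(),
                year_birth=int(row["year_birth"]),
                year_arrival=int(row["year_arrival"]),
                group=row["group"].strip(),
            )
            if bio.id in seen:
                raise ValueError(f"duplicate individual id {bio.id!r} in roster")
            seen.add(bio.id)
            roster.append(bio)
    return roster


def write_biographies(roster: Sequence[Biography], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(BIOGRAPHY_COLUMNS)
        for b in roster:
            writer.writerow(
                [b.id, b.name, b.sex, b.origin, b.phc_infant, b.year_birth, b.year_arrival, b.group]
            )


# ---------------------------------------------------------------------------
# scans IO


def _parse_bool(token: str, what: str) -> bool:
    if token == "1":
        return True
    if token == "0":
        return False
    raise ValueError(f"{what}: expected 0/1, got {token!r}")


def read_scans(
    path: str | Path, roster: Sequence[Biography]
) -> tuple[list[ScanRecord], ValidationReport]:
    """Read a scans CSV against a loaded roster.

    Unknown individual/partner ids and structural file problems raise
    ``ValueError``; record-level inconsistencies (malformed position, a
    grooming/affiliative row without partner, state recorded while not
    visible) are collected into the returned :class:`ValidationReport` and
    the offending field is kept as parsed.

    Records are returned sorted by (session_id, scan_index, individual).
    """
    ids = {b.id for b in roster}
    group_of = {b.id: b.group for b in roster}
    report = ValidationReport()
    records: list[ScanRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = tuple(reader.fieldnames or [])
        if header != SCAN_COLUMNS:
            raise ValueError(
                f"scans file columns {header} do not match canonical dialect {SCAN_COLUMNS}"
            )
        for lineno, row in enumerate(reader, start=2):
            ind = row["individual"].strip()
            if ind not in ids:
                raise ValueError(f"line {lineno}: unknown individual id {ind!r}")
            partner = row["partner"].strip() or None
            if partner is not None and partner not in ids:
                raise ValueError(f"line {lineno}: unknown partner id {partner!r}")
            arms = frozenset(t for t in row["arms_reach"].split(";") if t)
            for a in arms:
                if a not in ids:
                    raise ValueError(f"line {lineno}: unknown arms_reach id {a!r}")
            session_id = row["session_id"].strip()
            scan_index = int(row["scan_index"])
            position: tuple[float, float] | None = None
            px, py = row["pos_x"].strip(), row["pos_y"].strip()
            if px or py:
                try:
                    position = (float(px), float(py))
                except ValueError:
                    report.add(session_id, scan_index, ind, f"malformed position ({px!r},{py!r})")
            height = int(row["height_level"]) if row["height_level"].strip() else None
            rec = ScanRecord(
                group=row["group"].strip(),
                session_id=session_id,
                scan_index=scan_index,
                individual=ind,
                access=_parse_bool(row["access"].strip(), f"line {lineno} access"),
                visible=_parse_bool(row["visible"].strip(), f"line {lineno} visible"),
                behavior=row["behavior"].strip() or "none",
                partner=partner,
                arms_reach=arms,
                position=position,
                height_level=height,
            )
            if rec.group != group_of[ind]:
                raise ValueError(
                    f"line {lineno}: {ind} recorded in group {rec.group!r} "
                    f"but roster says {group_of[ind]!r}"
                )
            _check_record(rec, report)
            records.append(rec)
    records.sort(key=lambda r: (r.session_id, r.scan_index, r.individual))
    return records, report


def _check_record(rec: ScanRecord, report: ValidationReport) -> None:
    if rec.behavior in ("affiliative", "grooming") and rec.partner is None:
        report.add(rec.session_id, rec.scan_index, rec.individual,
                   f"behavior {rec.behavior} without partner")
    if not rec.visible and (
        rec.behavior != "none" or rec.partner or rec.arms_reach or rec.position is not None
    ):
        report.add(rec.session_id, rec.scan_index, rec.individual,
                   "state recorded for a non-visible individual")


def write_scans(records: Iterable[ScanRecord], path: str | Path) -> None:
    """Write records in the canonical dialect (inverse of :func:`read_scans`)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(SCAN_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.group,
                    r.session_id,
                    r.scan_index,
                    r.individual,
                    int(r.access),
                    int(r.visible),
                    r.behavior,
                    r.partner or "",
                    ";".join(sorted(r.arms_reach)),
                    "" if r.position is None else repr(r.position[0]),
                    "" if r.position is None else repr(r.position[1]),
                    "" if r.height_level is None else r.height_level,
                ]
            )


def session_table(records: Sequence[ScanRecord],
                  dates: dict[str, tuple[str, str]] | None = None) -> list[SessionInfo]:
    """Summarise sessions; ``dates`` optionally maps session_id -> (date, period)."""
    by_session: dict[tuple[str, str], set[int]] = {}
    for r in records:
        by_session.setdefault((r.session_id, r.group), set()).add(r.scan_index)
    out = []
    for (sid, group), scans in sorted(by_session.items()):
        date, period = (dates or {}).get(sid, ("", ""))
        out.append(SessionInfo(sid, group, date, period, len(scans)))
    return out


# ---------------------------------------------------------------------------
# dyadic audits


def _dyad_states_at_scan(
    recs: Sequence[ScanRecord],
) -> dict[frozenset[str], set[str]]:
    """Annotation categories credited to each unordered dyad at one scan.

    Categories are ``affiliative``, ``grooming`` and ``pcp`` (arm's-reach
    annotation).  Stationary vicinity is derived from geometry downstream and
    is exclusive by construction, so it cannot conflict here.
    """
    states: dict[frozenset[str], set[str]] = {}
    for r in recs:
        if r.behavior in ("affiliative", "grooming") and r.partner:
            states.setdefault(frozenset((r.individual, r.partner)), set()).add(r.behavior)
        for other in r.arms_reach:
            states.setdefault(frozenset((r.individual, other)), set()).add("pcp")
    return states


def validate_exclusivity(records: Sequence[ScanRecord]) -> ValidationReport:
    """Audit the per-dyad mutual exclusivity of the interaction annotations.

    At any one scan an unordered dyad may be credited with at most one of
    {affiliative, grooming, arm's-reach proximity}; mutual grooming (both
    directions) is a single category and is fine, as is one individual
    interacting with several different partners simultaneously.
    """
    report = ValidationReport()
    by_scan: dict[tuple[str, int], list[ScanRecord]] = {}
    for r in records:
        by_scan.setdefault((r.session_id, r.scan_index), []).append(r)
    for (sid, idx), recs in sorted(by_scan.items()):
        for dyad, states in sorted(_dyad_states_at_scan(recs).items(), key=lambda kv: sorted(kv[0])):
            if len(states) > 1:
                a, b = sorted(dyad)
                report.add(sid, idx, f"{a}-{b}",
                           f"dyad credited with multiple states: {sorted(states)}")
    return report


def access_denominator(records: Sequence[ScanRecord], a: str, b: str) -> int:
    """Number of scans where both individuals had access to each other.

    Counts scans where both have ``access`` true — including scans where one
    of them was indoors and thus not visible.  Scans where either individual
    has no record at all are not counted (no access information).
    """
    if a == b:
        raise ValueError("access_denominator needs two distinct individuals")
    access: dict[tuple[str, int], dict[str, bool]] = {}
    groups: dict[str, str] = {}
    for r in records:
        if r.individual in (a, b):
            groups[r.individual] = r.group
            access.setdefault((r.session_id, r.scan_index), {})[r.individual] = r.access
    if a in groups and b in groups and groups[a] != groups[b]:
        raise ValueError(f"{a} and {b} belong to different groups")
    return sum(1 for seen in access.values() if seen.get(a) and seen.get(b))
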