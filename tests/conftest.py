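"""Shared fixtures: tiny rosters and record builders used across the suite."""

from __future__ import annotations

import warnings

import pytest

from primatenet.scan_data import Biography, ScanRecord


@pytest.fixture
def small_roster() -> list[Biography]:
    """Two groups of three with mixed attributes."""
    rows = [
        ("A1", "a1", "F", "wild", "with", 1990, 2005, "West"),
        ("A2", "a2", "M", "captive", "without", 1992, 2006, "West"),
        ("A3", "a3", "M", "wild", "with", 1988, 2004, "West"),
        ("B1", "b1", "F", "captive", "with", 1995, 2007, "East"),
        ("B2", "b2", "M", "wild", "without", 1991, 2003, "East"),
        ("B3", "b3", "F", "captive", "without", 1993, 2008, "East"),
    ]
    return [Biography(*r) for r in rows]


def make_record(
    individual: str,
    *,
    group: str = "West",
    session: str = "S1",
    scan: int = 0,
    access: bool = True,
    visible: bool = True,
    behavior: str = "none",
    partner: str | None = None,
    arms: tuple[str, ...] = (),
    position: tuple[float, float] | None = None,
    height: int | None = None,
) -> ScanRecord:
    return ScanRecord(
        group=group,
        session_id=session,
        scan_index=scan,
        individual=individual,
        access=access,
        visible=visible,
        behavior=behavior,
        partner=partner,
        arms_reach=frozenset(arms),
        position=position,
        height_level=height,
    )


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    """Index/normalisation warnings about empty layers are routine on tiny data."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*no positive index.*")
        warnings.filterwarnings("ignore", message=".*no co-access scans.*")
        warnings.filterwarnings("ignore", message=".*empty layer.*")
        yield
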