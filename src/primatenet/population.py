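"""The published sanctuary study population and its printed scan totals.

Fourteen former pet and entertainment chimpanzees living in two social
groups (Bilinga and Mutamba) at a primate rescue centre, with the published
per-individual background attributes: sex, origin (wild-caught vs captive
born), predominant housing condition during the first five years of life
(with vs without conspecifics), estimated year of birth and year of arrival.
These rows, together with the published per-group scan totals, are the only
individual-level inputs of the study that are public; the raw observation
logs are not.
"""

from __future__ import annotations

from primatenet.scan_data import Biography

__all__ = ["study_roster", "GROUP_SCAN_TOTALS", "GROUPS"]

GROUPS = ("Bilinga", "Mutamba")

#: Published number of scans collected per group.
GROUP_SCAN_TOTALS = {"Bilinga": 32_320, "Mutamba": 35_677}

_ROWS = [
    # id, name, sex, origin, phc_infant, year_birth, year_arrival, group
    ("BEA", "Bea", "F", "wild", "with", 1985, 2012, "Bilinga"),
    ("CHE", "Cheeta", "F", "wild", "without", 1990, 2015, "Bilinga"),
    ("COC", "Coco", "F", "wild", "without", 1994, 2012, "Bilinga"),
    ("NIC", "Nico", "M", "captive", "without", 2001, 2004, "Bilinga"),
    ("TIC", "Tico", "M", "wild", "without", 1985, 2005, "Bilinga"),
    ("TOM", "Tom", "M", "wild", "with", 1985, 2011, "Bilinga"),
    ("VIC", "Victor", "M", "captive", "without", 1982, 2006, "Bilinga"),
    ("AFR", "Africa", "F", "wild", "without", 2000, 2009, "Mutamba"),
    ("BON", "Bongo", "M", "captive", "with", 2000, 2002, "Mutamba"),
    ("CHA", "Charly", "M", "captive", "with", 1989, 2001, "Mutamba"),
    ("JUA", "Juanito", "M", "captive", "with", 2003, 2005, "Mutamba"),
    ("MAR", "Marco", "M", "captive", "with", 1984, 2001, "Mutamba"),
    ("TON", "Toni", "M", "wild", "with", 1983, 2001, "Mutamba"),
    ("WAT", "Waty", "F", "captive", "with", 1996, 2002, "Mutamba"),
]


def study_roster() -> list[Biography]:
    """The 14 study individuals as :class:`Biography` objects."""
    return [Biography(*row) for row in _ROWS]
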