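"""The four mutually exclusive dyadic interaction indices.

Per ordered within-group dyad (sender, receiver) and per scan, at most one of
four states is credited:

* ``stationary_vicinity`` — beyond arm's reach but within 5 m planar distance,
  at most one height level apart, with no interaction (symmetric; derived
  from mapped positions);
* ``affiliative`` — sender directs affiliative behaviour (play, socio-sexual,
  embrace, follow, ...) at the receiver (directed);
* ``grooming`` — sender allogrooms the receiver (directed; mutual grooming
  credits both directions);
* ``passive_close_proximity`` — within an arm's reach with no further
  interaction (symmetric; taken from the recorded arm's-reach sets).

Each index is the count of credited scans divided by the number of scans the
two individuals had access to each other.  Weighted (normalized) values
divide each index by the maximum index observed for that layer across all
groups, so every layer spans [0, 1].
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable, Sequence

import pandas as pd

from primatenet.scan_data import Biography, ScanRecord

__all__ = [
    "LAYERS",
    "SYMMETRIC_LAYERS",
    "DIRECTED_LAYERS",
    "euclidean_distance",
    "count_stationary_vicinity",
    "count_passive_close_proximity",
    "count_directed",
    "compute_indices",
    "normalize_weighted",
]

#: Fixed layer order used throughout the package.
LAYERS = ("stationary_vicinity", "affiliative", "grooming", "passive_close_proximity")
SYMMETRIC_LAYERS = ("stationary_vicinity", "passive_close_proximity")
DIRECTED_LAYERS = ("affiliative", "grooming")

#: Maximum planar distance (m) for stationary vicinity.
SV_DISTANCE_M = 5.0
#: Maximum height-level difference for stationary vicinity.
SV_MAX_HEIGHT_DIFF = 1


def euclidean_distance(p: tuple[float, float], q: tuple[float, float]) -> float:
    """Planar Euclidean distance in metres between two mapped positions."""
    if p is None or q is None:
        raise ValueError("euclidean_distance requires both positions")
    return math.hypot(p[0] - q[0], p[1] - q[1])


class _ScanView:
    """Per-scan digest of a record list: presence, geometry and annotations."""

    __slots__ = ("access", "visible", "position", "height", "arms", "directed")

    def __init__(self) -> None:
        self.access: dict[str, bool] = {}
        self.visible: dict[str, bool] = {}
        self.position: dict[str, tuple[float, float]] = {}
        self.height: dict[str, int] = {}
        self.arms: set[frozenset[str]] = set()
        self.directed: set[tuple[str, str, str]] = set()  # (sender, receiver, class)


def _scan_views(records: Sequence[ScanRecord]) -> dict[tuple[str, int], _ScanView]:
    views: dict[tuple[str, int], _ScanView] = {}
    for r in records:
        v = views.setdefault((r.session_id, r.scan_index), _ScanView())
        v.access[r.individual] = v.access.get(r.individual, False) or r.access
        v.visible[r.individual] = v.visible.get(r.individual, False) or r.visible
        if r.position is not None:
            v.position[r.individual] = r.position
        if r.height_level is not None:
            v.height[r.individual] = r.height_level
        for other in r.arms_reach:
            v.arms.add(frozenset((r.individual, other)))
        if r.behavior in ("affiliative", "grooming") and r.partner:
            v.directed.add((r.individual, r.partner, r.behavior))
    return views


def _interacting(v: _ScanView, a: str, b: str) -> bool:
    return any((s, r) in ((a, b), (b, a)) for s, r, _ in v.directed)


def _is_sv(v: _ScanView, a: str, b: str) -> bool:
    if not (v.visible.get(a) and v.visible.get(b)):
        return False
    if a not in v.position or b not in v.position:
        return False
    if euclidean_distance(v.position[a], v.position[b]) > SV_DISTANCE_M:
        return False
    if frozenset((a, b)) in v.arms:
        return False
    ha, hb = v.height.get(a), v.height.get(b)
    if ha is not None and hb is not None and abs(ha - hb) > SV_MAX_HEIGHT_DIFF:
        return False
    return not _interacting(v, a, b)


def _is_pcp(v: _ScanView, a: str, b: str) -> bool:
    # arm's-reach annotation is taken as the union over both directions:
    # observers record the pair once, direction is an artefact
    return frozenset((a, b)) in v.arms and not _interacting(v, a, b)


def count_stationary_vicinity(records: Sequence[ScanRecord], a: str, b: str) -> int:
    """Scans with the dyad in stationary vicinity (see module docstring)."""
    views = _scan_views(records)
    return sum(1 for v in views.values() if _is_sv(v, a, b))


def count_passive_close_proximity(records: Sequence[ScanRecord], a: str, b: str) -> int:
    """Scans with the dyad within arm's reach and not otherwise interacting."""
    views = _scan_views(records)
    return sum(1 for v in views.values() if _is_pcp(v, a, b))


def count_directed(
    records: Sequence[ScanRecord], sender: str, receiver: str, behavior_class: str
) -> int:
    """Scans where ``sender`` directs ``behavior_class`` at ``receiver``.

    Counted once per scan per dyad direction, however many simultaneous
    sub-behaviours were noted.
    """
    if sender == receiver:
        raise ValueError("sender and receiver must differ")
    if behavior_class not in DIRECTED_LAYERS:
        raise ValueError(f"behavior_class must be one of {DIRECTED_LAYERS}")
    views = _scan_views(records)
    return sum(1 for v in views.values() if (sender, receiver, behavior_class) in v.directed)


def compute_indices(
    records: Sequence[ScanRecord], roster: Sequence[Biography]
) -> pd.DataFrame:
    """Compute all four indices for every ordered within-group dyad.

    Returns a long-format frame with columns
    ``group, sender, receiver, layer, count, denominator, index, weighted``
    (``weighted`` is NaN until :func:`normalize_weighted` fills it).
    A dyad that never had access to each other gets index 0 with a warning.
    """
    groups: dict[str, list[str]] = {}
    for b in roster:
        groups.setdefault(b.group, []).append(b.id)
    views = _scan_views(records)

    rows = []
    for group in sorted(groups):
        members = sorted(groups[group])
        counts: dict[tuple[str, str, str], int] = {}
        denoms: dict[frozenset[str], int] = {}
        pairs = [
            (a, b) for i, a in enumerate(members) for b in members[i + 1 :]
        ]
        for v in views.values():
            for a, b in pairs:
                if not (v.access.get(a) and v.access.get(b)):
                    continue
                denoms[frozenset((a, b))] = denoms.get(frozenset((a, b)), 0) + 1
                if _is_sv(v, a, b):
                    counts[a, b, "stationary_vicinity"] = counts.get((a, b, "stationary_vicinity"), 0) + 1
                elif _is_pcp(v, a, b):
                    counts[a, b, "passive_close_proximity"] = counts.get((a, b, "passive_close_proximity"), 0) + 1
                for cls in DIRECTED_LAYERS:
                    if (a, b, cls) in v.directed:
                        counts[a, b, cls] = counts.get((a, b, cls), 0) + 1
                    if (b, a, cls) in v.directed:
                        counts[b, a, cls] = counts.get((b, a, cls), 0) + 1
        for sender in members:
            for receiver in members:
                if sender == receiver:
                    continue
                denom = denoms.get(frozenset((sender, receiver)), 0)
                if denom == 0:
                    warnings.warn(
                        f"dyad {sender}-{receiver} in {group} has no co-access scans; "
                        "indices set to 0",
                        stacklevel=2,
                    )
                for layer in LAYERS:
                    if layer in SYMMETRIC_LAYERS:
                        a, b = sorted((sender, receiver))
                        count = counts.get((a, b, layer), 0)
                    else:
                        count = counts.get((sender, receiver, layer), 0)
                    rows.append(
                        {
                            "group": group,
                            "sender": sender,
                            "receiver": receiver,
                            "layer": layer,
                            "count": count,
                            "denominator": denom,
                            "index": count / denom if denom else 0.0,
                            "weighted": float("nan"),
                        }
                    )
    table = pd.DataFrame(rows, columns=["group", "sender", "receiver", "layer",
                                        "count", "denominator", "index", "weighted"])
    bad = table[table["count"] > table["denominator"]]
    if len(bad):  # pragma: no cover - internal consistency guard
        raise AssertionError(f"count exceeds denominator for {len(bad)} rows")
    return table


def normalize_weighted(table: pd.DataFrame) -> pd.DataFrame:
    """Fill the ``weighted`` column: index / per-layer maximum over all groups.

    The maximum is pooled across groups so a weighted value of 1 marks the
    single strongest dyad of that layer anywhere in the study.  A layer with
    no positive index anywhere gets weighted 0 with a warning.
    """
    out = table.copy()
    for layer, sub in out.groupby("layer"):
        m = sub["index"].max()
        if m > 0:
            out.loc[sub.index, "weighted"] = sub["index"] / m
        else:
            warnings.warn(f"layer {layer!r} has no positive index; weighted set to 0",
                          stacklevel=2)
            out.loc[sub.index, "weighted"] = 0.0
    return out
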