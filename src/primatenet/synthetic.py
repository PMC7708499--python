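"""Synthetic scan-sampling data with planted biographical effects.

The generator emulates the sampling design the analysis assumes: groups of
individuals observed in 20-minute sessions of instantaneous scans every two
minutes.  For every unordered dyad and scan, one of seven mutually exclusive
latent states is drawn

    none | stationary vicinity | passive close proximity |
    affiliative a->b | affiliative b->a | grooming a->b | grooming b->a

with per-dyad probabilities equal to layer base rates multiplied by
configurable effect multipliers keyed on the dyad's (origin, infant-housing,
sex) sender->receiver combinations.  Dyads and scans are independent, so the
per-layer index (count / co-access scans) is an unbiased binomial estimate of
the planted probability — recovery analyses are closed-form.

Two rendering modes:

* ``state`` — records carry behaviours and arm's-reach sets only (no
  geometry).  Stationary vicinity exists only in the latent state log, whose
  :func:`indices_from_log` is the reference index computation.
* ``spatial`` — every visible individual also gets a planar position and a
  height level, constructed so that the geometric index pipeline recovers
  exactly the sampled latent states (interacting dyads within arm's reach,
  stationary-vicinity dyads within 5 m and one height level, "none" dyads
  beyond 5 m or two or more levels apart).  Dense interaction patterns can be
  geometrically unrealisable, in which case :class:`InfeasibleGeometry` is
  raised; at realistic scan rates this is vanishingly rare.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from primatenet.indices import DIRECTED_LAYERS, LAYERS, SYMMETRIC_LAYERS
from primatenet.models import combo_label
from primatenet.scan_data import Biography, ScanRecord

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "SessionLog",
    "SimulationResult",
    "InfeasibleGeometry",
    "make_roster",
    "dyad_state_probs",
    "simulate",
    "simulate_scans",
    "simulate_spatial",
    "indices_from_log",
]

# latent state codes for an unordered dyad (a, b) with a < b
STATE_NONE = 0
STATE_SV = 1
STATE_PCP = 2
STATE_AFF_AB = 3
STATE_AFF_BA = 4
STATE_GRM_AB = 5
STATE_GRM_BA = 6

_FACTORS = ("origin", "phc", "sex")


class InfeasibleGeometry(RuntimeError):
    """Raised when a sampled interaction pattern admits no spatial layout."""


@dataclass
class SyntheticConfig:
    """Study-design parameters for the generator.

    Defaults mirror the sampled sanctuary population: two groups of seven
    adults with mixed sex, origin and infant-housing backgrounds.  Base rates
    are per-scan per-dyad state probabilities; the study itself reports only
    index magnitudes, so the defaults are order-of-magnitude realistic values
    (vicinity common, grooming and affiliative behaviour rare) and are meant
    to be overridden.  ``effect_multipliers`` maps
    ``layer -> factor -> "X->Y" -> positive multiplier`` applied to the base
    rate of every ordered dyad whose sender/receiver attributes match.
    """

    n_groups: int = 2
    group_size: int = 7
    n_sessions: int = 50
    scans_per_session: int = 10
    base_rates: dict[str, float] = field(
        default_factory=lambda: {
            "stationary_vicinity": 0.12,
            "affiliative": 0.01,
            "grooming": 0.02,
            "passive_close_proximity": 0.04,
        }
    )
    effect_multipliers: dict[str, dict[str, dict[str, float]]] = field(default_factory=dict)
    p_absent: float = 0.0
    p_indoor: float = 0.0
    p_male: float = 9 / 14
    p_wild: float = 0.5
    p_with: float = 8 / 14
    mode: str = "state"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("state", "spatial"):
            raise ValueError(f"mode must be state|spatial, got {self.mode!r}")
        for layer, rate in self.base_rates.items():
            if layer not in LAYERS:
                raise ValueError(f"unknown layer {layer!r} in base_rates")
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"base rate for {layer} outside [0,1]")
        for p in (self.p_absent, self.p_indoor, self.p_male, self.p_wild, self.p_with):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0,1]")
        for layer, per_factor in self.effect_multipliers.items():
            if layer not in LAYERS:
                raise ValueError(f"unknown layer {layer!r} in effect_multipliers")
            for factor, combos in per_factor.items():
                if factor not in _FACTORS:
                    raise ValueError(f"unknown factor {factor!r}")
                for combo, mult in combos.items():
                    if mult <= 0:
                        raise ValueError(f"multiplier for {layer}/{factor}/{combo} must be > 0")


@dataclass
class GroundTruth:
    """Planted per-ordered-dyad state probabilities."""

    roster: list[Biography]
    probs: dict[tuple[str, str, str], float]  # (sender, receiver, layer) -> p
    seed: int

    def p(self, sender: str, receiver: str, layer: str) -> float:
        return self.probs[sender, receiver, layer]

    def state_vector(self, a: str, b: str) -> np.ndarray:
        """Seven-state probability vector for the unordered dyad (a, b), a < b."""
        if a > b:
            a, b = b, a
        p = np.array(
            [
                0.0,
                self.probs[a, b, "stationary_vicinity"],
                self.probs[a, b, "passive_close_proximity"],
                self.probs[a, b, "affiliative"],
                self.probs[b, a, "affiliative"],
                self.probs[a, b, "grooming"],
                self.probs[b, a, "grooming"],
            ]
        )
        p[0] = 1.0 - p[1:].sum()
        return p


@dataclass
class SessionLog:
    """Latent truth for one session: who was there and what each dyad did."""

    group: str
    session_id: str
    access: dict[str, bool]
    visible: dict[str, np.ndarray]  # id -> bool per scan (only ids with access)
    states: dict[tuple[str, str], np.ndarray]  # (a, b) a<b -> state code per scan


@dataclass
class SimulationResult:
    config: SyntheticConfig
    truth: GroundTruth
    logs: list[SessionLog]
    records: list[ScanRecord]
    #: spatial mode: scans whose sampled pattern was redrawn for embeddability
    n_geometry_redraws: int = 0


# ---------------------------------------------------------------------------
# roster and ground truth


def _balanced_levels(n: int, p_first: float, levels: tuple[str, str],
                     rng: np.random.Generator) -> list[str]:
    k = int(round(p_first * n))
    values = [levels[0]] * k + [levels[1]] * (n - k)
    rng.shuffle(values)
    return values


def make_roster(config: SyntheticConfig, rng: np.random.Generator | None = None) -> list[Biography]:
    """Generate a roster of ``n_groups`` x ``group_size`` individuals.

    Attribute levels are assigned in the configured proportions (rounded to
    counts, then shuffled within each group) so that every group is mixed
    rather than left to binomial chance.
    """
    if config.group_size < 2:
        raise ValueError("group_size must be >= 2")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    roster: list[Biography] = []
    for g in range(1, config.n_groups + 1):
        group = f"G{g}"
        sexes = _balanced_levels(config.group_size, config.p_male, ("M", "F"), rng)
        origins = _balanced_levels(config.group_size, config.p_wild, ("wild", "captive"), rng)
        phcs = _balanced_levels(config.group_size, config.p_with, ("with", "without"), rng)
        for i in range(config.group_size):
            ident = f"{group}I{i + 1}"
            roster.append(
                Biography(
                    id=ident,
                    name=ident,
                    sex=sexes[i],
                    origin=origins[i],
                    phc_infant=phcs[i],
                    year_birth=1990,
                    year_arrival=2005,
                    group=group,
                )
            )
    return roster


def _multiplier(config: SyntheticConfig, layer: str, sender: Biography,
                receiver: Biography) -> float:
    mult = 1.0
    per_layer = config.effect_multipliers.get(layer, {})
    attrs = {
        "origin": (sender.origin, receiver.origin),
        "phc": (sender.phc_infant, receiver.phc_infant),
        "sex": (sender.sex, receiver.sex),
    }
    for factor, (s, r) in attrs.items():
        mult *= per_layer.get(factor, {}).get(combo_label(s, r), 1.0)
    return mult


def dyad_state_probs(roster: Sequence[Biography], config: SyntheticConfig) -> GroundTruth:
    """Planted probabilities for every ordered within-group dyad and layer.

    Directed layers use the sender->receiver attribute combination directly;
    symmetric layers average the two directional values so that p(a,b) always
    equals p(b,a).  If a dyad's seven-state total exceeds 1 the vector is
    renormalised proportionally with a warning.
    """
    by_id = {b.id: b for b in roster}
    groups: dict[str, list[str]] = {}
    for b in roster:
        groups.setdefault(b.group, []).append(b.id)
    probs: dict[tuple[str, str, str], float] = {}
    for group, members in sorted(groups.items()):
        members = sorted(members)
        for a, b in itertools.permutations(members, 2):
            for layer in LAYERS:
                p = config.base_rates.get(layer, 0.0) * _multiplier(
                    config, layer, by_id[a], by_id[b]
                )
                probs[a, b, layer] = p
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                for layer in SYMMETRIC_LAYERS:
                    m = 0.5 * (probs[a, b, layer] + probs[b, a, layer])
                    probs[a, b, layer] = probs[b, a, layer] = m
                total = (
                    probs[a, b, "stationary_vicinity"]
                    + probs[a, b, "passive_close_proximity"]
                    + probs[a, b, "affiliative"]
                    + probs[b, a, "affiliative"]
                    + probs[a, b, "grooming"]
                    + probs[b, a, "grooming"]
                )
                if total > 1.0:
                    warnings.warn(
                        f"dyad {a}-{b}: state probabilities sum to {total:.3f} > 1; "
                        "renormalising proportionally",
                        stacklevel=2,
                    )
                    for key in list(probs):
                        if key[:2] in ((a, b), (b, a)):
                            probs[key] /= total
    return GroundTruth(roster=list(roster), probs=probs, seed=config.seed)


# ---------------------------------------------------------------------------
# latent-state sampling


def _sample_logs(truth: GroundTruth, config: SyntheticConfig,
                 rng: np.random.Generator) -> list[SessionLog]:
    groups: dict[str, list[str]] = {}
    for b in truth.roster:
        groups.setdefault(b.group, []).append(b.id)
    logs: list[SessionLog] = []
    n = config.scans_per_session
    for group in sorted(groups):
        members = sorted(groups[group])
        for s in range(1, config.n_sessions + 1):
            session_id = f"{group}-S{s:04d}"
            absent = rng.random(len(members)) < config.p_absent
            access = {m: not a for m, a in zip(members, absent)}
            visible = {}
            for m in members:
                if access[m]:
                    if config.p_indoor > 0:
                        visible[m] = rng.random(n) >= config.p_indoor
                    else:
                        visible[m] = np.ones(n, dtype=bool)
            states: dict[tuple[str, str], np.ndarray] = {}
            for i, a in enumerate(members):
                for b in members[i + 1 :]:
                    if access[a] and access[b]:
                        p = truth.state_vector(a, b)
                        states[a, b] = rng.choice(7, size=n, p=p)
            logs.append(SessionLog(group, session_id, access, visible, states))
    return logs


def indices_from_log(logs: Sequence[SessionLog], roster: Sequence[Biography]):
    """Index table computed directly from the latent states (no records).

    This is the state-mode index computation: counts of each dyadic state
    over scans where both individuals were visible, divided by the co-access
    denominator.  Returns the same long-format frame as
    :func:`primatenet.indices.compute_indices`.
    """
    import pandas as pd

    groups: dict[str, list[str]] = {}
    for b in roster:
        groups.setdefault(b.group, []).append(b.id)
    rows = []
    code_for = {
        "stationary_vicinity": (STATE_SV, STATE_SV),
        "passive_close_proximity": (STATE_PCP, STATE_PCP),
        "affiliative": (STATE_AFF_AB, STATE_AFF_BA),
        "grooming": (STATE_GRM_AB, STATE_GRM_BA),
    }
    for group in sorted(groups):
        members = sorted(groups[group])
        counts: dict[tuple[str, str, str], int] = {}
        denoms: dict[tuple[str, str], int] = {}
        for log in logs:
            if log.group != group:
                continue
            for (a, b), codes in log.states.items():
                denoms[a, b] = denoms.get((a, b), 0) + len(codes)
                both_vis = log.visible[a] & log.visible[b]
                for layer, (c_ab, c_ba) in code_for.items():
                    counts[a, b, layer] = counts.get((a, b, layer), 0) + int(
                        ((codes == c_ab) & both_vis).sum()
                    )
                    if c_ab != c_ba:
                        counts[b, a, layer] = counts.get((b, a, layer), 0) + int(
                            ((codes == c_ba) & both_vis).sum()
                        )
        for sender in members:
            for receiver in members:
                if sender == receiver:
                    continue
                a, b = sorted((sender, receiver))
                denom = denoms.get((a, b), 0)
                for layer in LAYERS:
                    if layer in SYMMETRIC_LAYERS:
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
    return pd.DataFrame(rows, columns=["group", "sender", "receiver", "layer",
                                       "count", "denominator", "index", "weighted"])


# ---------------------------------------------------------------------------
# record rendering


def _scan_interactions(log: SessionLog, scan: int):
    """Visible dyadic annotations at one scan: behaviours and arm's-reach pairs."""
    behaviours: list[tuple[str, str, str]] = []  # (sender, receiver, class)
    arms: list[tuple[str, str]] = []
    sv_pairs: list[tuple[str, str]] = []
    for (a, b), codes in log.states.items():
        if not (log.visible[a][scan] and log.visible[b][scan]):
            continue
        code = codes[scan]
        if code == STATE_PCP:
            arms.append((a, b))
        elif code == STATE_SV:
            sv_pairs.append((a, b))
        elif code == STATE_AFF_AB:
            behaviours.append((a, b, "affiliative"))
        elif code == STATE_AFF_BA:
            behaviours.append((b, a, "affiliative"))
        elif code == STATE_GRM_AB:
            behaviours.append((a, b, "grooming"))
        elif code == STATE_GRM_BA:
            behaviours.append((b, a, "grooming"))
    return behaviours, arms, sv_pairs


def _render_records(
    logs: Sequence[SessionLog],
    config: SyntheticConfig,
    geometry: dict[tuple[str, int], dict[str, tuple[float, float, int]]] | None,
) -> list[ScanRecord]:
    records: list[ScanRecord] = []
    for log in logs:
        members = sorted(log.access)
        for scan in range(config.scans_per_session):
            behaviours, arms, _ = _scan_interactions(log, scan)
            arm_sets: dict[str, set[str]] = {m: set() for m in members}
            for a, b in arms:
                arm_sets[a].add(b)
                arm_sets[b].add(a)
            beh_by_sender: dict[str, list[tuple[str, str]]] = {}
            for s, r, cls in behaviours:
                beh_by_sender.setdefault(s, []).append((r, cls))
            placed = (geometry or {}).get((log.session_id, scan), {})
            for m in members:
                if not log.access[m]:
                    records.append(
                        ScanRecord(log.group, log.session_id, scan, m,
                                   access=False, visible=False)
                    )
                    continue
                if not log.visible[m][scan]:
                    records.append(
                        ScanRecord(log.group, log.session_id, scan, m,
                                   access=True, visible=False)
                    )
                    continue
                pos = height = None
                if m in placed:
                    x, y, h = placed[m]
                    pos, height = (x, y), h
                base = dict(
                    group=log.group,
                    session_id=log.session_id,
                    scan_index=scan,
                    individual=m,
                    access=True,
                    visible=True,
                    arms_reach=frozenset(arm_sets[m]),
                    position=pos,
                    height_level=height,
                )
                sent = beh_by_sender.get(m)
                if not sent:
                    records.append(ScanRecord(behavior="none", partner=None, **base))
                else:
                    # one row per behavioural partner; presence fields repeat
                    for r, cls in sorted(sent):
                        records.append(ScanRecord(behavior=cls, partner=r, **base))
    records.sort(key=lambda r: (r.session_id, r.scan_index, r.individual))
    return records


# ---------------------------------------------------------------------------
# spatial realisation

# integer-metre lattice offsets realising stationary vicinity (2-5 m)
_SV_OFFSETS = [
    (dx, dy)
    for dx in range(-5, 6)
    for dy in range(-5, 6)
    if 2.0 <= math.hypot(dx, dy) <= 5.0
]
_INT_OFFSETS = [(0, 0), (1, 0), (-1, 0), (0, 1), (0, -1)]  # within arm's reach
_GRID = 30  # placement area in metres (well inside a 50 m enclosure)


def _pair_relations(log: SessionLog, scan: int):
    behaviours, arms, sv_pairs = _scan_interactions(log, scan)
    interacting = {frozenset((a, b)) for a, b in arms}
    interacting |= {frozenset((s, r)) for s, r, _ in behaviours}
    sv = {frozenset(p) for p in sv_pairs} - interacting
    return interacting, sv


def _try_positions(
    present: list[str],
    interacting: set[frozenset[str]],
    sv: set[frozenset[str]],
    rng: np.random.Generator,
    node_limit: int = 600,
) -> dict[str, tuple[int, int]] | None:
    """Backtracking placement on a 1 m integer lattice.

    Hard constraints: interacting pairs at distance <= 1, vicinity pairs at
    2-5 m.  Pairs in neither set ("none") are soft: candidates are scored by
    how many of them end up beyond 5 m; the remainder is handed to the height
    solver.
    """

    hard = interacting | sv

    def hard_deg(m: str) -> int:
        return sum(1 for p in hard if m in p)

    # connected-expansion order over the hard-constraint graph: each placed
    # individual (after the first of its component) has an already-placed
    # anchor, so its candidate neighbourhood is well defined
    order: list[str] = []
    remaining = set(present)
    while remaining:
        linked = sorted(
            remaining,
            key=lambda m: (
                -sum(1 for o in order if frozenset((m, o)) in hard),
                -hard_deg(m),
                m,
            ),
        )
        order.append(linked[0])
        remaining.remove(linked[0])
    pos: dict[str, tuple[int, int]] = {}
    nodes = 0

    def candidates(m: str) -> list[tuple[int, int]]:
        int_anchors = [o for o in pos if frozenset((m, o)) in interacting]
        sv_anchors = [o for o in pos if frozenset((m, o)) in sv]
        cands: list[tuple[int, int]]
        if int_anchors:
            cands = [
                (pos[a][0] + dx, pos[a][1] + dy)
                for a in int_anchors
                for dx, dy in _INT_OFFSETS
            ]
        elif sv_anchors:
            cands = [
                (pos[a][0] + dx, pos[a][1] + dy)
                for a in sv_anchors
                for dx, dy in _SV_OFFSETS
            ]
        else:
            cands = [
                (int(x), int(y))
                for x, y in zip(
                    rng.integers(0, _GRID, size=60), rng.integers(0, _GRID, size=60)
                )
            ]
        cands = list(dict.fromkeys(cands))
        rng.shuffle(cands)
        scored = []
        for x, y in cands:
            if not (0 <= x < _GRID and 0 <= y < _GRID):
                continue
            ok = True
            far = 0
            for o, (ox, oy) in pos.items():
                d = math.hypot(x - ox, y - oy)
                pair = frozenset((m, o))
                if pair in interacting:
                    if d > 1.0:
                        ok = False
                        break
                elif pair in sv:
                    if not 2.0 <= d <= 5.0:
                        ok = False
                        break
                elif d > 5.0:
                    far += 1
            if ok:
                scored.append((far, (x, y)))
        scored.sort(key=lambda c: -c[0])
        return [pt for _, pt in scored[:8]]

    def height_feasible() -> bool:
        members = list(pos)
        constraints: list[tuple[str, str, str]] = []
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                pair = frozenset((a, b))
                if pair in interacting:
                    continue
                if pair in sv:
                    constraints.append((a, b, "close"))
                elif math.hypot(pos[a][0] - pos[b][0], pos[a][1] - pos[b][1]) <= 5.0:
                    constraints.append((a, b, "apart"))
        return _assign_heights(members, constraints, rng) is not None

    def adds_height_constraint(m: str) -> bool:
        for o, (ox, oy) in pos.items():
            if o == m:
                continue
            pair = frozenset((m, o))
            if pair in interacting:
                continue
            if pair in sv:
                return True
            if math.hypot(pos[m][0] - ox, pos[m][1] - oy) <= 5.0:
                return True
        return False

    def solve(idx: int) -> bool:
        nonlocal nodes
        if idx == len(order):
            return True
        nodes += 1
        if nodes > node_limit:
            return False
        m = order[idx]
        for pt in candidates(m):
            pos[m] = pt
            # prune placements whose proximity pattern already has no
            # height-level solution (an individual adding no close/apart
            # edge cannot break feasibility)
            if (not adds_height_constraint(m) or height_feasible()) and solve(idx + 1):
                return True
            del pos[m]
        return False

    return pos if solve(0) else None


def _assign_heights(
    members: list[str],
    constraints: list[tuple[str, str, str]],  # (a, b, kind) kind in {close, apart}
    rng: np.random.Generator,
    node_limit: int = 300,
) -> dict[str, int] | None:
    """Backtracking height assignment: ``close`` pairs differ by <= 1 level,
    ``apart`` pairs by >= 2 levels; unconstrained individuals sit anywhere.
    Searches are capped at ``node_limit`` nodes; a capped-out search counts
    as infeasible (the caller retries with a different layout)."""
    adj: dict[str, list[tuple[str, str]]] = {m: [] for m in members}
    for a, b, kind in constraints:
        adj[a].append((b, kind))
        adj[b].append((a, kind))
    order = sorted(members, key=lambda m: -len(adj[m]))
    heights: dict[str, int] = {}
    nodes = 0

    def ok(m: str, h: int) -> bool:
        for other, kind in adj[m]:
            if other in heights:
                d = abs(heights[other] - h)
                if kind == "close" and d > 1:
                    return False
                if kind == "apart" and d < 2:
                    return False
        return True

    def solve(idx: int) -> bool:
        nonlocal nodes
        if idx == len(order):
            return True
        nodes += 1
        if nodes > node_limit:
            return False
        m = order[idx]
        values = [0, 1, 2, 3, 4]
        rng.shuffle(values)
        for h in values:
            if ok(m, h):
                heights[m] = h
                if solve(idx + 1):
                    return True
                del heights[m]
        return False

    return heights if solve(0) else None


def _realise_scan(
    log: SessionLog, scan: int, rng: np.random.Generator, max_attempts: int = 6
) -> dict[str, tuple[float, float, int]]:
    """Positions and heights for one scan realising the sampled dyad states.

    Interacting dyads end up within arm's reach (<= 1 m), vicinity dyads at
    2-5 m on the same or an adjacent height level, and "none" dyads either
    beyond 5 m or at least two height levels apart.  Sampled patterns too
    dense to embed raise :class:`InfeasibleGeometry`.
    """
    present = [m for m in sorted(log.access) if log.access[m] and log.visible[m][scan]]
    interacting, sv = _pair_relations(log, scan)
    for _ in range(max_attempts):
        placed = _try_positions(present, interacting, sv, rng)
        if placed is None:
            continue
        constraints: list[tuple[str, str, str]] = []
        for i, a in enumerate(present):
            for b in present[i + 1 :]:
                pair = frozenset((a, b))
                if pair in interacting:
                    continue
                if pair in sv:
                    constraints.append((a, b, "close"))
                else:
                    (ax, ay), (bx, by) = placed[a], placed[b]
                    if math.hypot(ax - bx, ay - by) <= 5.0:
                        constraints.append((a, b, "apart"))
        heights = _assign_heights(present, constraints, rng)
        if heights is not None:
            return {
                m: (float(placed[m][0]), float(placed[m][1]), heights[m])
                for m in present
            }
    raise InfeasibleGeometry(
        f"no layout for session {log.session_id} scan {scan}: "
        f"{len(interacting)} interacting and {len(sv)} vicinity pairs"
    )


def _resample_scan_states(
    log: SessionLog, scan: int, truth: GroundTruth, rng: np.random.Generator
) -> None:
    """Redraw one scan's dyad states in place (used when a sampled pattern
    admits no spatial embedding)."""
    for (a, b) in sorted(log.states):
        log.states[a, b][scan] = rng.choice(7, p=truth.state_vector(a, b))


def _realise_geometry(
    logs: Sequence[SessionLog],
    truth: GroundTruth,
    config: SyntheticConfig,
    rng: np.random.Generator,
    max_redraws: int = 30,
) -> tuple[dict[tuple[str, int], dict[str, tuple[float, float, int]]], int]:
    """Realise every scan geometrically, redrawing unembeddable patterns.

    Independent per-dyad sampling occasionally produces interaction patterns
    with no planar/height embedding (e.g. one individual interacting with
    four partners that are pairwise non-associating).  Such scans are redrawn
    from the same per-dyad state distribution — the rendered data therefore
    conditions on geometric embeddability, which at realistic rates affects
    of the order of 1% of scans.  A scan that stays unembeddable after
    ``max_redraws`` raises :class:`InfeasibleGeometry`.
    """
    geometry = {}
    n_redraws = 0
    for log in logs:
        for scan in range(config.scans_per_session):
            for attempt in range(max_redraws + 1):
                try:
                    geometry[log.session_id, scan] = _realise_scan(log, scan, rng)
                    break
                except InfeasibleGeometry:
                    if attempt == max_redraws:
                        raise
                    _resample_scan_states(log, scan, truth, rng)
                    n_redraws += 1
    return geometry, n_redraws


# ---------------------------------------------------------------------------
# public entry points


def simulate(
    truth: GroundTruth, config: SyntheticConfig, rng: np.random.Generator | None = None
) -> SimulationResult:
    """Sample latent states and render scan records per ``config.mode``."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    logs = _sample_logs(truth, config, rng)
    geometry = None
    n_redraws = 0
    if config.mode == "spatial":
        geometry, n_redraws = _realise_geometry(logs, truth, config, rng)
    records = _render_records(logs, config, geometry)
    return SimulationResult(config=config, truth=truth, logs=logs, records=records,
                            n_geometry_redraws=n_redraws)


def simulate_scans(truth: GroundTruth, config: SyntheticConfig) -> list[ScanRecord]:
    """State-mode record list (behaviours and proximity, no geometry)."""
    if config.mode != "state":
        raise ValueError("simulate_scans requires mode='state'")
    return simulate(truth, config).records


def simulate_spatial(truth: GroundTruth, config: SyntheticConfig) -> list[ScanRecord]:
    """Spatial-mode record list (positions/heights realise the latent states)."""
    if config.mode != "spatial":
        raise ValueError("simulate_spatial requires mode='spatial'")
    return simulate(truth, config).records


def generate(config: SyntheticConfig) -> SimulationResult:
    """Roster -> ground truth -> simulation, all from the single config seed."""
    rng = np.random.default_rng(config.seed)
    roster = make_roster(config, rng)
    truth = dyad_state_probs(roster, config)
    return simulate(truth, config, rng)
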