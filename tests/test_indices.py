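"""The four dyadic interaction indices: counting rules and normalization."""

from __future__ import annotations

import math

import numpy as np
import pytest

from primatenet.indices import (
    LAYERS,
    compute_indices,
    count_directed,
    count_passive_close_proximity,
    count_stationary_vicinity,
    euclidean_distance,
    normalize_weighted,
)
from tests.conftest import make_record


class TestEuclideanDistance:
    def test_identity_and_345(self):
        assert euclidean_distance((0, 0), (0, 0)) == 0.0
        assert euclidean_distance((0, 0), (3, 4)) == 5.0

    def test_matches_independent_formula(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            p, q = rng.uniform(-50, 50, 2), rng.uniform(-50, 50, 2)
            oracle = math.sqrt((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2)
            assert abs(euclidean_distance(tuple(p), tuple(q)) - oracle) < 1e-12

    def test_missing_position_rejected(self):
        with pytest.raises(ValueError):
            euclidean_distance(None, (0, 0))


def _pair_at(scan, d, *, ha=0, hb=0, arms=(), behavior=None):
    """A1 at origin and A2 at distance d, with optional annotations."""
    a_kwargs = dict(scan=scan, position=(0.0, 0.0), height=ha)
    if behavior:
        a_kwargs.update(behavior=behavior, partner="A2")
    return [
        make_record("A1", arms=arms, **a_kwargs),
        make_record("A2", scan=scan, position=(d, 0.0), height=hb),
    ]


class TestStationaryVicinity:
    def test_corrections_subtract_arms_reach_and_height(self):
        # 10 scans within 5 m; 4 of them within arm's reach, 2 at height diff 2
        records = []
        for scan in range(10):
            if scan < 4:
                records += _pair_at(scan, 3.0, arms=("A2",))
            elif scan < 6:
                records += _pair_at(scan, 3.0, ha=0, hb=2)
            else:
                records += _pair_at(scan, 3.0)
        # brute-force recount: only the last 4 scans qualify
        assert count_stationary_vicinity(records, "A1", "A2") == 4

    def test_beyond_5m_never_counts(self):
        records = []
        for scan in range(5):
            records += _pair_at(scan, 6.5)
        assert count_stationary_vicinity(records, "A1", "A2") == 0

    def test_exactly_5m_counts_but_height_gap_excludes(self):
        assert count_stationary_vicinity(_pair_at(0, 5.0), "A1", "A2") == 1
        assert count_stationary_vicinity(_pair_at(0, 3.0, ha=0, hb=2), "A1", "A2") == 0
        assert count_stationary_vicinity(_pair_at(0, 3.0, ha=1, hb=2), "A1", "A2") == 1

    def test_interaction_excludes_sv(self):
        records = _pair_at(0, 1.0, behavior="grooming")
        assert count_stationary_vicinity(records, "A1", "A2") == 0


class TestPassiveCloseProximity:
    def test_plain_proximity_counts(self):
        records = []
        for scan in range(7):
            records.append(make_record("A1", scan=scan, arms=("A2",)))
            records.append(make_record("A2", scan=scan))
        assert count_passive_close_proximity(records, "A1", "A2") == 7

    def test_interaction_scans_excluded(self):
        records = []
        for scan in range(7):
            beh = "grooming" if scan < 2 else "none"
            records.append(
                make_record("A1", scan=scan, arms=("A2",), behavior=beh,
                            partner="A2" if scan < 2 else None)
            )
            records.append(make_record("A2", scan=scan))
        assert count_passive_close_proximity(records, "A1", "A2") == 5

    def test_union_convention_and_symmetry(self):
        # annotation recorded on one side only still counts for both
        records = [make_record("A1", arms=("A2",)), make_record("A2")]
        assert count_passive_close_proximity(records, "A1", "A2") == 1
        assert count_passive_close_proximity(records, "A2", "A1") == 1


class TestCountDirected:
    def test_twenty_of_hundred(self):
        records = []
        for scan in range(100):
            beh = "grooming" if scan < 20 else "none"
            records.append(make_record("A1", scan=scan, behavior=beh,
                                       partner="A2" if scan < 20 else None))
            records.append(make_record("A2", scan=scan))
        assert count_directed(records, "A1", "A2", "grooming") == 20
        assert count_directed(records, "A2", "A1", "grooming") == 0

    def test_mutual_grooming_counts_both_directions(self):
        records = [
            make_record("A1", behavior="grooming", partner="A2"),
            make_record("A2", behavior="grooming", partner="A1"),
        ]
        assert count_directed(records, "A1", "A2", "grooming") == 1
        assert count_directed(records, "A2", "A1", "grooming") == 1

    def test_no_records_zero(self):
        assert count_directed([], "A1", "A2", "affiliative") == 0

    def test_sender_equals_receiver_rejected(self):
        with pytest.raises(ValueError):
            count_directed([], "A1", "A1", "grooming")


class TestComputeIndices:
    def test_simple_arithmetic(self, small_roster):
        records = []
        for scan in range(100):
            beh = "grooming" if scan < 20 else "none"
            for ind in ("A1", "A2", "A3"):
                if ind == "A1":
                    records.append(make_record(ind, scan=scan, behavior=beh,
                                               partner="A2" if scan < 20 else None))
                else:
                    records.append(make_record(ind, scan=scan))
        west = [b for b in small_roster if b.group == "West"]
        table = compute_indices(records, west)
        row = table[(table.sender == "A1") & (table.receiver == "A2")
                    & (table.layer == "grooming")].iloc[0]
        assert row["count"] == 20 and row["denominator"] == 100
        assert row["index"] == pytest.approx(0.20)

    def test_seven_node_group_has_168_rows(self):
        from primatenet.synthetic import SyntheticConfig, generate

        cfg = SyntheticConfig(n_groups=1, group_size=7, n_sessions=2,
                              mode="spatial", seed=2)
        sim = generate(cfg)
        table = compute_indices(sim.records, sim.truth.roster)
        assert len(table) == 7 * 6 * 4 == 168

    def test_symmetric_layer_rows_mirror(self):
        from primatenet.synthetic import SyntheticConfig, generate

        cfg = SyntheticConfig(n_groups=1, group_size=4, n_sessions=5,
                              mode="spatial", seed=3)
        sim = generate(cfg)
        table = compute_indices(sim.records, sim.truth.roster)
        for layer in ("stationary_vicinity", "passive_close_proximity"):
            sub = table[table.layer == layer]
            fwd = sub.set_index(["sender", "receiver"])["index"]
            for (s, r), v in fwd.items():
                assert fwd[(r, s)] == v

    def test_layer_counts_bounded_by_denominator(self):
        from primatenet.synthetic import SyntheticConfig, generate

        cfg = SyntheticConfig(n_groups=1, group_size=5, n_sessions=10,
                              mode="spatial", seed=4)
        sim = generate(cfg)
        table = compute_indices(sim.records, sim.truth.roster)
        assert (table["count"] <= table["denominator"]).all()
        per_dyad = table.groupby(["sender", "receiver"]).agg(
            total=("count", "sum"), denom=("denominator", "first")
        )
        assert (per_dyad["total"] <= per_dyad["denom"]).all()

    def test_zero_denominator_warns_and_zeroes(self, small_roster):
        records = [make_record("A1", access=False, visible=False),
                   make_record("A2", access=False, visible=False),
                   make_record("A3", access=False, visible=False)]
        west = [b for b in small_roster if b.group == "West"]
        with pytest.warns(UserWarning, match="no co-access"):
            table = compute_indices(records, west)
        assert (table["index"] == 0).all()


class TestNormalizeWeighted:
    def _table(self, values_by_group):
        import pandas as pd

        rows = []
        for group, vals in values_by_group.items():
            ids = [f"{group}{i}" for i in range(3)]
            k = 0
            for s in ids:
                for r in ids:
                    if s == r:
                        continue
                    for layer in LAYERS:
                        v = vals[k % len(vals)] if layer == "grooming" else 0.0
                        rows.append(dict(group=group, sender=s, receiver=r,
                                         layer=layer, count=0, denominator=1,
                                         index=v, weighted=float("nan")))
                    k += 1
        return pd.DataFrame(rows)

    def test_half_of_max_is_half(self):
        table = self._table({"G": [0.4, 0.2, 0.0]})
        out = normalize_weighted(table)
        grm = out[out.layer == "grooming"]
        assert set(np.round(grm["weighted"], 10)) == {1.0, 0.5, 0.0}

    def test_max_dyad_gets_exactly_one(self):
        out = normalize_weighted(self._table({"G": [0.37, 0.1]}))
        grm = out[out.layer == "grooming"]
        assert grm["weighted"].max() == 1.0

    def test_max_pooled_across_groups(self):
        table = self._table({"GA": [0.4], "GB": [0.8]})
        out = normalize_weighted(table)
        ga = out[(out.group == "GA") & (out.layer == "grooming")]
        assert np.allclose(ga["weighted"], 0.5)

    def test_idempotent_on_normalized_values(self):
        out = normalize_weighted(self._table({"G": [0.4, 0.2]}))
        again = out.copy()
        again["index"] = again["weighted"]
        twice = normalize_weighted(again)
        assert np.allclose(twice["weighted"], out["weighted"])

    def test_all_zero_layer_warns(self):
        table = self._table({"G": [0.0]})
        with pytest.warns(UserWarning, match="no positive index"):
            out = normalize_weighted(table)
        assert (out["weighted"] == 0).all()
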