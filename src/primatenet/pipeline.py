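"""End-to-end orchestration: data -> indices -> networks -> models -> bundle.

A pipeline run is driven by a single YAML-serialisable configuration and a
single seed; it writes a bundle of plain-text artifacts (CSV/JSON/GraphML)
into an output directory, so that every number appearing in any rendered
report is traceable to a file.  Stage order is fixed: data acquisition
(synthetic simulation or CSV input), validation, index computation,
cross-group normalization, per-group multiplex analytics, dyadic mixed
models, manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

import networkx as nx

from primatenet import __version__
from primatenet.indices import LAYERS, compute_indices, normalize_weighted
from primatenet.models import RESPONSES, ModelResult, build_dyad_table, fit_models
from primatenet.multiplex import (
    MultiplexNetwork,
    build_multiplex,
    edge_overlap,
    global_edge_overlap,
    layer_density,
    multiplex_density,
    quantum_jsd,
    rank_report,
    reducibility,
)
from primatenet.scan_data import read_biographies, read_scans, validate_exclusivity, write_biographies, write_scans
from primatenet.synthetic import SyntheticConfig, generate

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("primatenet")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and offending entity."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


_KNOWN_KEYS = {
    "seed",
    "weight",
    "omega",
    "overlap_norm",
    "alpha",
    "log_level",
    "synthetic",
    "inputs",
}


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Either ``synthetic`` (generator parameters) or ``inputs`` (paths to a
    scans CSV and a biography CSV) must be given.  ``weight`` selects the
    adjacency entries used for network analytics (raw ``index`` values or
    cross-group max-normalised ``weighted`` values).
    """

    seed: int = 0
    weight: str = "weighted"
    omega: float = 1.0
    overlap_norm: str = "jaccard"
    alpha: float = 0.05
    log_level: str = "INFO"
    synthetic: dict[str, Any] | None = None
    inputs: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.weight not in ("index", "weighted"):
            raise ValueError("weight must be 'index' or 'weighted'")
        if self.overlap_norm not in ("jaccard", "min"):
            raise ValueError("overlap_norm must be 'jaccard' or 'min'")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if (self.synthetic is None) == (self.inputs is None):
            raise ValueError("exactly one of 'synthetic' or 'inputs' must be set")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        return {k: v for k, v in d.items() if v is not None}

    def synthetic_config(self) -> SyntheticConfig:
        params = dict(self.synthetic or {})
        params.setdefault("seed", self.seed)
        return SyntheticConfig(**params)


def _write_json(obj: Any, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def _jsonify(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return _jsonify(obj.to_dict(orient="list"))
    if isinstance(obj, pd.Series):
        return _jsonify(obj.to_dict())
    if isinstance(obj, frozenset):
        return sorted(obj)
    return obj


def _model_result_dict(res: ModelResult) -> dict[str, Any]:
    return _jsonify(
        {
            "response": res.response,
            "n_obs": res.n_obs,
            "converged": res.converged,
            "singular": res.singular,
            "degenerate": res.degenerate,
            "llf_full_ml": res.llf_full_ml,
            "llf_null_ml": res.llf_null_ml,
            "lrt_stat": res.lrt_stat,
            "lrt_df": res.lrt_df,
            "lrt_p": res.lrt_p,
            "anova": None if res.anova is None else res.anova.reset_index(),
            "contrasts": {f: t for f, t in res.contrasts.items()},
            "vif": res.vif,
            "level_means": res.level_means,
            "warnings": res.warnings,
        }
    )


def _export_graphml(net: MultiplexNetwork, group: str, outdir: Path) -> list[str]:
    paths = []
    for name in net.layer_names:
        g = nx.DiGraph()
        g.add_nodes_from(net.nodes)
        m = net.layer(name)
        for i, a in enumerate(net.nodes):
            for j, b in enumerate(net.nodes):
                if i != j and m[i, j] > 0:
                    g.add_edge(a, b, weight=float(m[i, j]))
        path = outdir / f"{group}_{name}.graphml"
        nx.write_graphml(g, path)
        paths.append(path.name)
    return paths


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict[str, Any]:
    """Run the full analysis and write the bundle into ``outdir``.

    Returns the in-memory bundle: index tables, per-group networks,
    densities, overlap/JSD matrices, reducibility results, centrality
    reports and model results, plus a manifest.  Deterministic for a given
    (config, seed): two runs write byte-identical CSV/JSON artifacts.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)

    # --- stage: data
    try:
        if config.synthetic is not None:
            sim = generate(config.synthetic_config())
            roster, records = sim.truth.roster, sim.records
            write_biographies(roster, outdir / "biographies.csv")
            write_scans(records, outdir / "scans.csv")
            truth_rows = [
                {"sender": s, "receiver": r, "layer": l, "p": p}
                for (s, r, l), p in sorted(sim.truth.probs.items())
            ]
            _write_json(_jsonify(truth_rows), outdir / "ground_truth.json")
        else:
            roster = read_biographies(config.inputs["biographies"])
            records, report = read_scans(config.inputs["scans"], roster)
            if not report.ok:
                log.warning("%d record-level issues while reading scans", len(report))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("data", str(exc)) from exc

    # --- stage: validation
    excl = validate_exclusivity(records)
    pd.DataFrame(
        [dataclasses.asdict(i) for i in excl.issues],
        columns=["session_id", "scan_index", "entity", "message"],
    ).to_csv(outdir / "exclusivity_issues.csv", index=False)
    if not excl.ok:
        # the counting rules resolve conflicts deterministically (behaviour
        # beats proximity), so flagged annotations are reported, not fatal
        log.warning(
            "%d exclusivity violations (see exclusivity_issues.csv)", len(excl)
        )

    # --- stage: indices
    try:
        table = normalize_weighted(compute_indices(records, roster))
    except Exception as exc:
        raise PipelineError("indices", str(exc)) from exc
    table.to_csv(outdir / "indices.csv", index=False)

    groups = sorted({b.group for b in roster})
    bundle: dict[str, Any] = {
        "indices": table,
        "groups": {},
        "config": config.to_dict(),
    }

    # --- stage: network analytics (per group)
    density_rows = []
    for group in groups:
        try:
            net = build_multiplex(table, group, weight=config.weight)
        except Exception as exc:
            raise PipelineError("network", f"group {group}: {exc}") from exc
        gdir = outdir / "graphml"
        gdir.mkdir(exist_ok=True)
        _export_graphml(net, group, gdir)
        for name in net.layer_names:
            pd.DataFrame(net.layer(name), index=net.nodes, columns=net.nodes).to_csv(
                outdir / f"matrix_{group}_{name}.csv"
            )
        dens = {name: layer_density(net.layer(name)) for name in net.layer_names}
        dens["multiplex"] = multiplex_density(net)
        density_rows.append({"group": group, **dens})

        L = net.n_layers
        overlap = np.zeros((L, L))
        jsd = np.full((L, L), np.nan)
        entropy_ok = all(net.layer(n).sum() > 0 for n in net.layer_names)
        for i in range(L):
            for j in range(L):
                overlap[i, j] = (
                    1.0 if i == j else edge_overlap(
                        net.layers[i], net.layers[j], norm=config.overlap_norm
                    )
                )
                if entropy_ok:
                    jsd[i, j] = 0.0 if i == j else quantum_jsd(net.layers[i], net.layers[j])
        pd.DataFrame(overlap, index=net.layer_names, columns=net.layer_names).to_csv(
            outdir / f"overlap_{group}.csv"
        )
        pd.DataFrame(jsd, index=net.layer_names, columns=net.layer_names).to_csv(
            outdir / f"jsd_{group}.csv"
        )

        red = None
        if entropy_ok:
            red = reducibility(net)
            _write_json(
                _jsonify(
                    {
                        "layer_names": red.layer_names,
                        "jsd_matrix": red.jsd_matrix,
                        "merge_sequence": [
                            {"step": s, "merged": [sorted(a), sorted(b)], "distance": d}
                            for s, (a, b), d in red.merge_sequence
                        ],
                        "relative_entropy_curve": red.relative_entropy_curve,
                        "optimal_n_layers": red.optimal_n_layers,
                    }
                ),
                outdir / f"reducibility_{group}.json",
            )
        else:
            log.warning("group %s: empty layer, reducibility skipped", group)

        report = rank_report(net, omega=config.omega)
        report.scores.to_csv(outdir / f"centrality_scores_{group}.csv")
        report.ranks.to_csv(outdir / f"centrality_ranks_{group}.csv")
        report.strengths.to_csv(outdir / f"strengths_{group}.csv")

        bundle["groups"][group] = {
            "network": net,
            "densities": dens,
            "overlap": overlap,
            "jsd": jsd,
            "global_overlap": global_edge_overlap(net),
            "reducibility": red,
            "centrality": report,
        }
    densities = pd.DataFrame(density_rows)
    densities.to_csv(outdir / "densities.csv", index=False)
    bundle["densities"] = densities

    # --- stage: dyadic models
    try:
        dyads = build_dyad_table(roster, table)
        dyads.to_csv(outdir / "dyad_table.csv", index=False)
        results = {resp: fit_models(dyads, resp) for resp in RESPONSES}
    except Exception as exc:
        raise PipelineError("models", str(exc)) from exc
    _write_json({r: _model_result_dict(m) for r, m in results.items()}, outdir / "models.json")
    bundle["dyad_table"] = dyads
    bundle["models"] = results

    # --- manifest
    manifest = {
        "package_version": __version__,
        "stages": ["data", "validation", "indices", "network", "models"],
        "layer_names": list(LAYERS),
        "groups": groups,
        "config": config.to_dict(),
        "n_records": len(records),
        "artifacts": sorted(p.name for p in outdir.iterdir() if p.is_file()),
    }
    _write_json(_jsonify(manifest), outdir / "manifest.json")
    bundle["manifest"] = manifest
    return bundle
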