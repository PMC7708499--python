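"""Render the bundle figures: overlap and JSD heatmaps, reducibility curves,
per-ring rank tables.  Re-runs the pipeline stages in memory from the data
written by the earlier scripts, then delegates to the report module.
Writes PNGs under results/figures/.
"""

from __future__ import annotations

import argparse
import warnings
from pathlib import Path

from primatenet.pipeline import PipelineConfig, run_pipeline
from primatenet.report import plot_reports


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    cfg = PipelineConfig(
        seed=1,
        inputs={"scans": str(args.data / "scans.csv"),
                "biographies": str(args.data / "biographies.csv")},
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bundle = run_pipeline(cfg, args.out / "bundle")
    written = plot_reports(bundle, args.out)
    for p in written:
        print(f"wrote {p}")


if __name__ == "__main__":
    main()
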