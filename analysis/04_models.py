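"""Do early-life biographies shape who interacts with whom?

Builds the directed-dyad table (one row per ordered within-group dyad with
its origin/infant-housing/sex sender->receiver combinations) and fits the
five linear mixed models: one per interaction index plus the aggregated sum,
each with a random group intercept and sender nested within group.  Reports
the full-vs-null likelihood-ratio test, Type III F tests (Satterthwaite
df), Holm-adjusted pairwise contrasts for significant factors, and VIFs.
Writes results/models.json and results/tables/dyad_table.csv.
"""

from __future__ import annotations

import argparse
import json
import warnings
from pathlib import Path

import pandas as pd

from primatenet.models import RESPONSES, build_dyad_table, fit_models
from primatenet.pipeline import _model_result_dict
from primatenet.scan_data import read_biographies


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--indices", type=Path, default=Path("results/tables/indices.csv"))
    ap.add_argument("--alpha", type=float, default=0.05)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    roster = read_biographies(args.data / "biographies.csv")
    table = pd.read_csv(args.indices)
    dyads = build_dyad_table(roster, table)
    (args.out / "tables").mkdir(parents=True, exist_ok=True)
    dyads.to_csv(args.out / "tables" / "dyad_table.csv", index=False)
    print(f"dyad table: {len(dyads)} ordered within-group dyads")

    results = {}
    for response in RESPONSES:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit_models(dyads, response)
        results[response] = res
        verdict = ("improves on null" if res.lrt_p < args.alpha
                   else "no improvement over null")
        print(f"\n--- {response}: LRT chi2({res.lrt_df}) = {res.lrt_stat:.2f}, "
              f"p = {res.lrt_p:.4g} ({verdict})")
        if res.lrt_p < args.alpha and res.anova is not None:
            for factor, row in res.anova.iterrows():
                mark = " *" if row["p"] < args.alpha else ""
                print(f"    {factor}: F({int(row['num_df'])},{row['den_df']:.1f}) "
                      f"= {row['F']:.3f}, p = {row['p']:.4g}{mark}")
                if row["p"] < args.alpha:
                    sig = res.contrasts[factor]
                    for c in sig[sig["p_holm"] < args.alpha].itertuples():
                        print(f"        {c.contrast}: z = {c.z:.2f}, "
                              f"p_holm = {c.p_holm:.4g}")
        print("    VIF: " + ", ".join(f"{k}={v:.2f}" for k, v in res.vif.items()))

    (args.out / "models.json").write_text(
        json.dumps({r: _model_result_dict(m) for r, m in results.items()},
                   indent=2, sort_keys=True) + "\n", encoding="utf-8")
    print(f"\nwrote {args.out}/models.json")


if __name__ == "__main__":
    main()
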