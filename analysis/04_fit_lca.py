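#!/usr/bin/env python
"""Fit latent class models and select the number of classes.

Estimates 1- to 5-class mixtures by multi-start EM (10 starts, 500
iterations), tabulates log-likelihood / AIC / BIC / relative entropy, selects
K by lowest BIC, and writes the selected model's parameters, posterior
memberships, and modal class assignments.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from prepdiary import lca
from prepdiary.diary_model import AdherenceLabel, read_diary
from prepdiary.indicators import build_matrix


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--in-dir", type=Path, default=Path("results/synthetic"))
    ap.add_argument("--labels", type=Path, default=Path("results/labels.csv"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    ap.add_argument("--seed", type=int, default=17)
    ap.add_argument("--k-min", type=int, default=1)
    ap.add_argument("--k-max", type=int, default=5)
    args = ap.parse_args()

    diary = read_diary(args.in_dir / "events.csv", args.in_dir / "doses.csv")
    lab_df = pd.read_csv(args.labels)
    labels = {r.event_id: AdherenceLabel(r.adherence_label)
              for r in lab_df.itertuples()}
    matrix = build_matrix(diary, labels)

    table, fits = lca.model_selection(
        matrix, args.k_min, args.k_max, n_starts=10, seed=args.seed)
    args.out_dir.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out_dir / "model_selection.csv", index=False)
    print(table.round(2).to_string(index=False))

    chosen = lca.select(table)
    print(f"selected K = {chosen} (lowest BIC)")
    best = fits[chosen]
    (args.out_dir / f"params_K{chosen}.json").write_text(json.dumps({
        "K": chosen,
        "mixing": best.mixing.tolist(),
        "response": {c: {"levels": best.levels[c],
                         "prob": best.response[c].tolist()}
                     for c in best.columns},
        "loglik": best.loglik,
        "n_params": best.n_params,
    }, indent=2) + "\n")
    pd.DataFrame(
        best.posterior, index=pd.Index(best.event_ids, name="event_id"),
        columns=[f"class_{k}" for k in range(1, chosen + 1)],
    ).to_csv(args.out_dir / "posterior.csv")
    assignments = lca.assign(best)
    pd.DataFrame({"event_id": list(assignments),
                  "class": list(assignments.values())}
                 ).to_csv(args.out_dir / "assignments.csv", index=False)

    print("mixing: " + ", ".join(
        f"class {k + 1}: {100 * p:.0f}%" for k, p in enumerate(best.mixing)))
    for c in best.columns:
        df = pd.DataFrame(best.response[c].T, index=best.levels[c],
                          columns=[f"class {k}" for k in range(1, chosen + 1)])
        print(f"-- {c}")
        print(df.round(3).to_string())
    print(f"wrote {args.out_dir}/model_selection.csv, params_K{chosen}.json, "
          "posterior.csv, assignments.csv")


if __name__ == "__main__":
    main()
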