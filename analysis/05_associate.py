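#!/usr/bin/env python
"""Associate latent class with condomless anal sex.

Tabulates the condomless proportion per assigned class, excludes classes in
which every (or no) event was condomless, and estimates the class contrast
three ways: closed-form 2x2 Wald odds ratio, maximum-likelihood logistic
regression, and random-intercept (per participant) logistic regression.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from prepdiary.association import logistic, mixed_logistic, odds_ratio_2x2
from prepdiary.pipeline import _result_dict


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--in-dir", type=Path, default=Path("results/synthetic"))
    ap.add_argument("--assignments", type=Path,
                    default=Path("results/assignments.csv"))
    ap.add_argument("--out", type=Path, default=Path("results/association.json"))
    args = ap.parse_args()

    events = pd.read_csv(args.in_dir / "events.csv")
    assignments = pd.read_csv(args.assignments)
    d = events.merge(assignments, on="event_id", validate="one_to_one")
    y = ~d["condom_used"].astype(str).str.lower().eq("true")
    cls = d["class"].to_numpy()
    pids = d["participant_id"].to_numpy()
    K = int(cls.max())

    result = {"per_class": {}, "excluded_degenerate_classes": [],
              "odds_ratio_2x2": [], "logistic": [], "mixed_logistic": []}
    for k in range(1, K + 1):
        sel = cls == k
        n, n_cl = int(sel.sum()), int(y[sel].sum())
        pct = 100 * n_cl / n if n else float("nan")
        result["per_class"][k] = {"n_events": n, "n_condomless": n_cl,
                                  "pct_condomless": pct}
        print(f"class {k}: {n_cl}/{n} ({pct:.0f}%) condomless")
        if n == 0 or n_cl in (0, n):
            result["excluded_degenerate_classes"].append(k)
            print(f"  -> class {k} excluded from regression (degenerate outcome)")

    usable = [k for k in range(1, K + 1)
              if k not in result["excluded_degenerate_classes"]]
    ref = max(usable, key=lambda k: result["per_class"][k]["n_events"])
    result["reference_class"] = ref
    print(f"reference class: {ref} (largest usable class)")

    keep = np.isin(cls, usable)
    yk, ck, gk = y.to_numpy()[keep], cls[keep], pids[keep]
    for k in usable:
        if k == ref:
            continue
        a = int(((ck == k) & yk).sum()); b = int(((ck == k) & ~yk).sum())
        c = int(((ck == ref) & yk).sum()); e = int(((ck == ref) & ~yk).sum())
        result["odds_ratio_2x2"].append(
            _result_dict(odds_ratio_2x2(a, b, c, e, comparison=(k, ref))))
    result["logistic"] = [_result_dict(r) for r in logistic(yk, ck, ref)]
    result["mixed_logistic"] = [_result_dict(r)
                                for r in mixed_logistic(yk, ck, gk, ref)]

    for method in ("odds_ratio_2x2", "logistic", "mixed_logistic"):
        for r in result[method]:
            extra = ("" if r["random_intercept_sd"] is None
                     else f", intercept sd {r['random_intercept_sd']:.2f}")
            print(f"{method}: class {r['comparison'][0]} vs {r['comparison'][1]}: "
                  f"OR {r['odds_ratio']:.2f} (95% CI {r['ci95'][0]:.2f}-"
                  f"{r['ci95'][1]:.2f}, p={r['p_value']:.3g}{extra})")

    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(result, indent=2) + "\n")
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
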