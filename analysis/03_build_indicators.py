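#!/usr/bin/env python
"""Build the event-level latent-class indicators and protection summary.

Assembles the four categorical indicators (adherence, positioning, partner
HIV status, partner-vs-participant age comparison) and tabulates how many
events were protected by PrEP, condoms, both, either, or neither.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from prepdiary.diary_model import AdherenceLabel, read_diary
from prepdiary.indicators import build_matrix, summarize_protection


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--in-dir", type=Path, default=Path("results/synthetic"))
    ap.add_argument("--labels", type=Path, default=Path("results/labels.csv"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    diary = read_diary(args.in_dir / "events.csv", args.in_dir / "doses.csv")
    lab_df = pd.read_csv(args.labels)
    labels = {r.event_id: AdherenceLabel(r.adherence_label)
              for r in lab_df.itertuples()}

    matrix = build_matrix(diary, labels)
    args.out_dir.mkdir(parents=True, exist_ok=True)
    matrix.to_frame().to_csv(args.out_dir / "indicators.csv")
    print(f"indicator matrix: {matrix.n_events} events x {len(matrix.columns)} "
          f"indicators, levels {matrix.level_counts}")

    s = summarize_protection(diary, labels)
    (args.out_dir / "protection_summary.json").write_text(
        json.dumps(s.to_dict(), indent=2) + "\n")
    n = s.n_events
    print(f"protected by either PrEP or condoms: {s.n_either}/{n} "
          f"({100 * s.n_either / n:.0f}%)")
    print(f"protected by both: {s.n_both}/{n} ({100 * s.n_both / n:.0f}%)")
    print(f"protected by neither: {s.n_neither}/{n} "
          f"({100 * s.n_neither / n:.0f}%)")
    fully = sum(r["fully_prep_protected"] for r in s.per_participant.values())
    any_un = sum(r["any_unprotected"] for r in s.per_participant.values())
    print(f"participants fully PrEP-protected: {fully}/{len(s.per_participant)}; "
          f"with >=1 fully unprotected event: {any_un}")
    print(f"wrote {args.out_dir}/indicators.csv, protection_summary.json")


if __name__ == "__main__":
    main()
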