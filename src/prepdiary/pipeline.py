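"""End-to-end pipeline: simulate -> classify -> indicators -> LCA -> association.

Every stage writes its artifact as machine-readable CSV/JSON under the output
directory, and ``run_all`` additionally renders a human-readable report with
the model-selection table, the per-class indicator profiles, the class-wise
condomless/protection breakdown, and the association results.  One master
seed fully determines every output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import adherence, association, indicators, lca, synthetic_data
from .adherence import AdherenceConfig
from .diary_model import Diary, read_diary, write_diary
from .synthetic_data import SynthConfig

__all__ = ["PipelineConfig", "PipelineResult", "run_all"]

log = logging.getLogger("prepdiary")


@dataclass
class PipelineConfig:
    """Configuration for a full pipeline run.

    When ``simulate`` is true the diary is generated from ``synth`` (with a
    stage seed derived from ``seed``); otherwise ``events_path``/``doses_path``
    must point to existing CSVs.
    """

    out_dir: str | Path = "results"
    seed: int = 0
    simulate: bool = True
    events_path: str | Path | None = None
    doses_path: str | Path | None = None
    adherence: AdherenceConfig = field(default_factory=AdherenceConfig)
    synth: SynthConfig = field(default_factory=SynthConfig)
    k_min: int = 1
    k_max: int = 5
    n_starts: int = 10
    max_iter: int = 500
    tol: float = 1e-10
    reference_class: int | None = None  # 1-based fitted class; None = largest

    def __post_init__(self) -> None:
        if not (1 <= self.k_min <= self.k_max):
            raise ValueError("need 1 <= k_min <= k_max")


@dataclass
class PipelineResult:
    out_dir: Path
    diary: Diary
    selection: pd.DataFrame
    selected_k: int
    fit: "lca.LCAFit"
    association: dict
    report: str


def _stage_seeds(seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    names = ("simulate", "lca")
    return {
        name: int(child.generate_state(1)[0] % (2**31 - 1))
        for name, child in zip(names, ss.spawn(len(names)))
    }


def run_all(config: PipelineConfig) -> PipelineResult:
    """Execute every stage in order, writing all intermediate artifacts."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    stage = "simulate"
    try:
        if config.simulate:
            scfg = dataclasses.replace(config.synth, seed=seeds["simulate"])
            log.info("simulate: %d participants, seed %d",
                     scfg.n_participants, scfg.seed)
            diary, truth = synthetic_data.generate(scfg)
            write_diary(diary, out / "events.csv", out / "doses.csv")
            truth.events.to_csv(out / "truth_events.csv", index=False)
            truth.participants.to_csv(out / "truth_participants.csv", index=False)
        else:
            log.info("load: %s / %s", config.events_path, config.doses_path)
            diary = read_diary(config.events_path, config.doses_path)
        log.info("diary: %d participants, %d events, %d dose logs",
                 len(diary.participants), len(diary.sex_events), len(diary.dose_logs))

        stage = "classify"
        labels = adherence.classify_diary(diary, config.adherence)
        pd.DataFrame(
            {"event_id": list(labels), "adherence_label": [v.value for v in labels.values()]}
        ).to_csv(out / "labels.csv", index=False)

        stage = "indicators"
        matrix = indicators.build_matrix(diary, labels)
        matrix.to_frame().to_csv(out / "indicators.csv")
        protection = indicators.summarize_protection(diary, labels)
        (out / "protection_summary.json").write_text(
            json.dumps(protection.to_dict(), indent=2) + "\n"
        )

        stage = "fit"
        log.info("lca: K in [%d, %d], %d starts, seed %d",
                 config.k_min, config.k_max, config.n_starts, seeds["lca"])
        table, fits = lca.model_selection(
            matrix, config.k_min, config.k_max,
            n_starts=config.n_starts, max_iter=config.max_iter,
            tol=config.tol, seed=seeds["lca"],
        )
        table.to_csv(out / "model_selection.csv", index=False)
        chosen = lca.select(table)
        boundary = chosen == config.k_max and config.k_max > config.k_min
        best = fits[chosen]
        params = {
            "K": chosen,
            "mixing": best.mixing.tolist(),
            "response": {
                c: {"levels": best.levels[c], "prob": best.response[c].tolist()}
                for c in best.columns
            },
            "loglik": best.loglik,
            "n_params": best.n_params,
        }
        (out / f"params_K{chosen}.json").write_text(json.dumps(params, indent=2) + "\n")
        post = pd.DataFrame(
            best.posterior, index=pd.Index(best.event_ids, name="event_id"),
            columns=[f"class_{k}" for k in range(1, chosen + 1)],
        )
        post.to_csv(out / "posterior.csv")
        assignments = lca.assign(best)
        pd.DataFrame(
            {"event_id": list(assignments), "class": list(assignments.values())}
        ).to_csv(out / "assignments.csv", index=False)

        stage = "associate"
        assoc = _associate(diary, assignments, chosen, config.reference_class)
        (out / "association.json").write_text(json.dumps(assoc, indent=2) + "\n")

        stage = "report"
        report = _render_report(
            diary, table, chosen, boundary, best, protection, assoc, config, seeds
        )
        (out / "report.txt").write_text(report)
    except Exception:
        log.exception("pipeline failed at stage %r", stage)
        raise

    return PipelineResult(
        out_dir=out, diary=diary, selection=table, selected_k=chosen,
        fit=best, association=assoc, report=report,
    )


def _associate(diary: Diary, assignments: dict[str, int], K: int,
               reference: int | None) -> dict:
    events = {e.event_id: e for e in diary.sex_events}
    cls = np.array([assignments[eid] for eid in assignments])
    condomless = np.array([not events[eid].condom_used for eid in assignments])
    pids = np.array([events[eid].participant_id for eid in assignments])

    by_class = {}
    degenerate = []
    for k in range(1, K + 1):
        sel = cls == k
        n = int(sel.sum())
        n_cl = int(condomless[sel].sum())
        by_class[k] = {"n_events": n, "n_condomless": n_cl,
                       "pct_condomless": 100.0 * n_cl / n if n else float("nan")}
        if n == 0 or n_cl in (0, n):
            degenerate.append(k)

    usable = [k for k in range(1, K + 1) if k not in degenerate]
    if reference is None:
        reference = max(usable, key=lambda k: by_class[k]["n_events"]) if usable else None

    result: dict = {
        "per_class": by_class,
        "excluded_degenerate_classes": degenerate,
        "reference_class": reference,
        "odds_ratio_2x2": [],
        "logistic": [],
        "mixed_logistic": [],
    }
    if reference is None or len(usable) < 2:
        result["note"] = "fewer than 2 non-degenerate classes; no contrasts estimated"
        return result

    keep = np.isin(cls, usable)
    y, c, g = condomless[keep], cls[keep], pids[keep]
    ref = reference
    for k in usable:
        if k == ref:
            continue
        a = int(((c == k) & y).sum()); b = int(((c == k) & ~y).sum())
        cc = int(((c == ref) & y).sum()); d = int(((c == ref) & ~y).sum())
        result["odds_ratio_2x2"].append(
            _result_dict(association.odds_ratio_2x2(a, b, cc, d, comparison=(k, ref)))
        )
    result["logistic"] = [
        _result_dict(r) for r in association.logistic(y, c, ref)
    ]
    result["mixed_logistic"] = [
        _result_dict(r) for r in association.mixed_logistic(y, c, g, ref)
    ]
    return result


def _result_dict(r: "association.AssociationResult") -> dict:
    return {
        "comparison": [str(x) for x in r.comparison],
        "odds_ratio": r.odds_ratio,
        "ci95": list(r.ci95),
        "se_log_or": r.se_log_or,
        "p_value": r.p_value,
        "method": r.method.value,
        "random_intercept_sd": r.random_intercept_sd,
        "converged": r.converged,
    }


def _render_report(diary, table, chosen, boundary, best, protection, assoc,
                   config, seeds) -> str:
    lines = []
    push = lines.append
    push("prepdiary pipeline report")
    push("=========================")
    push(f"seed: {config.seed} (stage seeds: {seeds})")
    push(f"participants: {len(diary.participants)}   "
         f"events: {len(diary.sex_events)}   dose logs: {len(diary.dose_logs)}")
    push("")
    push("Model selection (lowest BIC chosen; ties to the smaller K)")
    push(table.round(3).to_string(index=False))
    flags = []
    aic_k = int(table.loc[table["AIC"].idxmin(), "K"])
    if aic_k != chosen:
        flags.append(f"AIC prefers K={aic_k}")
    # the one-class entropy is 1.00 by convention, so compare among K > 1
    multi = table[table["K"] > 1]
    if len(multi):
        ent_k = int(multi.loc[multi["entropy"].idxmax(), "K"])
        if ent_k != chosen:
            flags.append(f"entropy prefers K={ent_k}")
    push(f"selected K = {chosen}" + (f"  [{'; '.join(flags)}]" if flags else ""))
    if boundary:
        push(f"warning: selected K equals k_max={config.k_max}; "
             "the class count may be truncated")
    push("")
    push("Class profiles (conditional response probabilities)")
    for c in best.columns:
        df = pd.DataFrame(
            best.response[c].T, index=best.levels[c],
            columns=[f"class {k}" for k in range(1, chosen + 1)],
        )
        push(f"-- {c}")
        push(df.round(3).to_string())
    push("mixing proportions: "
         + ", ".join(f"class {k + 1}: {p:.3f}" for k, p in enumerate(best.mixing)))
    push("")
    push("Protection breakdown")
    d = protection.to_dict()
    n = max(d["n_events"], 1)
    push(f"events protected by PrEP: {d['n_prep_protected']} "
         f"({100 * d['n_prep_protected'] / n:.0f}%)")
    push(f"events protected by condoms: {d['n_condom_protected']} "
         f"({100 * d['n_condom_protected'] / n:.0f}%)")
    push(f"by either: {d['n_either']} ({100 * d['n_either'] / n:.0f}%)   "
         f"by both: {d['n_both']} ({100 * d['n_both'] / n:.0f}%)   "
         f"by neither: {d['n_neither']} ({100 * d['n_neither'] / n:.0f}%)")
    push("")
    push("Condomless anal sex by class")
    for k, row in assoc["per_class"].items():
        push(f"class {k}: {row['n_condomless']}/{row['n_events']} "
             f"({row['pct_condomless']:.0f}%) condomless")
    if assoc.get("excluded_degenerate_classes"):
        push(f"excluded from regression (degenerate outcome): "
             f"{assoc['excluded_degenerate_classes']}")
    push(f"reference class: {assoc.get('reference_class')}")
    for method in ("odds_ratio_2x2", "logistic", "mixed_logistic"):
        for r in assoc.get(method, []):
            extra = (f", random-intercept sd {r['random_intercept_sd']:.3f}"
                     if r.get("random_intercept_sd") is not None else "")
            push(f"{method}: class {r['comparison'][0]} vs {r['comparison'][1]}: "
                 f"OR {r['odds_ratio']:.2f} "
                 f"(95% CI {r['ci95'][0]:.2f}-{r['ci95'][1]:.2f}, "
                 f"p={r['p_value']:.3g}{extra})")
    push("")
    return "\n".join(lines) + "\n"
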