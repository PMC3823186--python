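"""End-to-end orchestration: recordings → counts → laterality; cohort
table → statistics.  The CLI is a thin wrapper over this module.

Recording files are discovered by the naming convention
``<participant>_<limb>[_<anything>].csv`` with limb ``intact`` or
``residual``; multiple files per limb (e.g. recording days) are pooled by
summing counts before the laterality ratio, so both limbs always cover
the same epochs.  Analysis plans are declarative lists of steps (loadable
from YAML); per-analysis exclusions are expressed as subset filters on
cohort columns, not hard-coded.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .detection import DetectorParams, detect_movements, smooth_trace
from .io import AccelTrace, ValidationError, read_accel
from .metrics import laterality_index
from . import stats as st

__all__ = [
    "run_usage_pipeline",
    "run_cohort_analysis",
    "default_plan",
    "load_plan",
    "results_to_frame",
]

logger = logging.getLogger(__name__)

_FILE_RE = re.compile(r"^(?P<pid>.+?)_(?P<limb>intact|residual)(?:_.+)?\.csv$")


def run_usage_pipeline(
    input_dir: str | Path,
    out_dir: str | Path | None = None,
    params: DetectorParams | None = None,
    sample_rate: float = 100.0,
) -> pd.DataFrame:
    """Detect movements for every participant and derive laterality indices.

    Returns one row per participant with pooled per-limb counts, wear time
    and the laterality index.  Participants missing a limb's recording are
    skipped with a logged reason.  If ``out_dir`` is given, writes
    ``usage_records.csv``, per-event annotations ``events.csv`` and a
    JSON-lines run log with the effective parameters.
    """
    params = params or DetectorParams()
    input_dir = Path(input_dir)
    files: dict[str, dict[str, list[Path]]] = {}
    for path in sorted(input_dir.glob("*.csv")):
        m = _FILE_RE.match(path.name)
        if not m:
            continue
        files.setdefault(m["pid"], {}).setdefault(m["limb"], []).append(path)
    if not files:
        logger.warning("no recordings matching <pid>_<limb>.csv found in %s", input_dir)

    rows = []
    event_rows = []
    for pid, limbs in sorted(files.items()):
        if set(limbs) != {"intact", "residual"}:
            logger.warning("participant %s skipped: missing %s recording", pid,
                           ", ".join(sorted({"intact", "residual"} - set(limbs))))
            continue
        counts = {}
        wear = {}
        for limb, paths in limbs.items():
            n_events = 0
            wear_s = 0.0
            for p in paths:
                trace = read_accel(p, limb_label=limb, sample_rate=sample_rate)
                events = detect_movements(smooth_trace(trace, params), params)
                n_events += len(events)
                wear_s += trace.wear_duration
                for ev in events:
                    s, e = ev.interval_s(sample_rate)
                    event_rows.append({"participant_id": pid, "limb": limb,
                                       "file": p.name, "start_s": s, "end_s": e})
            counts[limb] = n_events
            wear[limb] = wear_s
        try:
            li = laterality_index(counts["intact"], counts["residual"])
        except ValidationError:
            logger.warning("participant %s: zero movements on both limbs; laterality undefined", pid)
            li = float("nan")
        rows.append({"participant_id": pid, "n_intact": counts["intact"],
                     "n_residual": counts["residual"], "laterality_index": li,
                     "wear_intact_s": wear["intact"], "wear_residual_s": wear["residual"]})
    table = pd.DataFrame(rows, columns=["participant_id", "n_intact", "n_residual",
                                        "laterality_index", "wear_intact_s", "wear_residual_s"])
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "usage_records.csv", index=False, float_format="%.17g")
        pd.DataFrame(event_rows, columns=["participant_id", "limb", "file", "start_s", "end_s"]
                     ).to_csv(out_dir / "events.csv", index=False, float_format="%.17g")
        with open(out_dir / "run_log.jsonl", "a") as fh:
            fh.write(json.dumps({"stage": "usage_pipeline", "params": asdict(params),
                                 "sample_rate": sample_rate,
                                 "n_participants": len(rows)}) + "\n")
    return table


# ---------------------------------------------------------------------------
# Cohort analysis plans
# ---------------------------------------------------------------------------


def default_plan() -> list[dict]:
    """The standard analysis battery over a cohort table.

    One-sample laterality tests per one-handed group, the group contrast
    of laterality and questionnaire scores (the latter also
    covariate-adjusted), the questionnaire–laterality validation
    correlation, the group × limb activation ANOVA with its four planned
    comparisons at α = 0.025 (participants whose residual arm ends above
    the elbow are excluded from arm contrasts via a subset filter), the
    usage–activation correlation with and without a deprivation-age
    nuisance regressor, the pain–usage correlation within the acquired
    group, and a Fisher r-to-z comparison of the usage–activation
    correlation between the two one-handed groups.
    """
    above_elbow_filter = [{"column": "amputation_level", "op": "ge", "value": 3,
                           "keep_missing": True}]
    return [
        {"kind": "one_sample", "name": "li_vs_zero_congenital",
         "column": "laterality_index", "subset": [{"column": "group", "op": "in", "value": ["congenital"]}]},
        {"kind": "one_sample", "name": "li_vs_zero_acquired",
         "column": "laterality_index", "subset": [{"column": "group", "op": "in", "value": ["acquired"]}]},
        {"kind": "two_sample", "name": "li_congenital_vs_acquired",
         "column": "laterality_index", "group_a": "congenital", "group_b": "acquired"},
        {"kind": "two_sample", "name": "mal_congenital_vs_acquired",
         "column": "mal_score", "group_a": "congenital", "group_b": "acquired"},
        {"kind": "covariate_contrast", "name": "mal_group_adjusted",
         "column": "mal_score", "group_a": "congenital", "group_b": "acquired",
         "covariates": ["amputation_level", "functional_prosthesis_usage",
                        "cosmetic_prosthesis_usage"]},
        {"kind": "pearson", "name": "mal_li_pearson", "x": "mal_score", "y": "laterality_index"},
        {"kind": "mixed_anova", "name": "beta_group_by_limb",
         "within": ["beta_residual_arm", "beta_intact_hand"]},
        {"kind": "two_sample", "name": "beta_residual_congenital_vs_acquired",
         "column": "beta_residual_arm", "group_a": "congenital", "group_b": "acquired",
         "planned": True, "subset": above_elbow_filter},
        {"kind": "two_sample", "name": "beta_residual_congenital_vs_control",
         "column": "beta_residual_arm", "group_a": "congenital", "group_b": "control",
         "planned": True, "subset": above_elbow_filter},
        {"kind": "two_sample", "name": "beta_intact_acquired_vs_congenital",
         "column": "beta_intact_hand", "group_a": "acquired", "group_b": "congenital",
         "planned": True},
        {"kind": "two_sample", "name": "beta_intact_acquired_vs_control",
         "column": "beta_intact_hand", "group_a": "acquired", "group_b": "control",
         "planned": True},
        {"kind": "pearson", "name": "mal_beta_pearson",
         "x": "mal_score", "y": "beta_intact_hand"},
        {"kind": "partial", "name": "mal_beta_partial_depage",
         "x": "mal_score", "y": "beta_intact_hand", "nuisance": ["deprivation_age"],
         "tails": "one", "direction": "negative"},
        {"kind": "pearson", "name": "pain_usage_pearson_acquired",
         "x": "chronic_pain", "y": "mal_score",
         "subset": [{"column": "group", "op": "in", "value": ["acquired"]}]},
        {"kind": "pearson", "name": "mal_beta_pearson_congenital",
         "x": "mal_score", "y": "beta_intact_hand",
         "subset": [{"column": "group", "op": "in", "value": ["congenital"]}]},
        {"kind": "pearson", "name": "mal_beta_pearson_acquired",
         "x": "mal_score", "y": "beta_intact_hand",
         "subset": [{"column": "group", "op": "in", "value": ["acquired"]}]},
        {"kind": "fisher_compare", "name": "mal_beta_corr_congenital_vs_acquired",
         "corr_a": "mal_beta_pearson_congenital", "corr_b": "mal_beta_pearson_acquired"},
    ]


def load_plan(path: str | Path) -> list[dict]:
    with open(path) as fh:
        plan = yaml.safe_load(fh)
    if not isinstance(plan, list):
        raise ValidationError("analysis plan must be a YAML list of steps")
    return plan


def _apply_subset(df: pd.DataFrame, subset: Sequence[Mapping] | None, step: str) -> pd.DataFrame:
    if not subset:
        return df
    for rule in subset:
        col, op, value = rule["column"], rule["op"], rule["value"]
        if col not in df.columns:
            raise ValidationError(f"step {step!r}: subset column {col!r} not in cohort")
        series = df[col]
        if op == "in":
            keep = series.isin(value if isinstance(value, list) else [value])
        elif op == "ge":
            keep = series >= value
        elif op == "le":
            keep = series <= value
        else:
            raise ValidationError(f"step {step!r}: unknown subset op {op!r}")
        if rule.get("keep_missing", False):
            keep = keep | series.isna()
        n_drop = int((~keep).sum())
        if n_drop:
            logger.info("step %r: subset filter on %s excluded %d participants", step, col, n_drop)
        df = df.loc[keep]
    return df


def _drop_missing(df: pd.DataFrame, cols: Sequence[str], step: str) -> pd.DataFrame:
    used = df.dropna(subset=list(cols))
    n_drop = len(df) - len(used)
    if n_drop:
        logger.info("step %r: excluded %d participants with missing %s", step, n_drop, list(cols))
    return used


def run_cohort_analysis(
    cohort: pd.DataFrame,
    plan: Sequence[Mapping] | None = None,
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Execute an analysis plan in order; one row per step.

    A derived ``chronic_pain`` column (pain_intensity / pain_frequency) is
    added up front.  A step that fails (e.g. an all-missing column) is
    recorded with status ``failed`` and the run continues.
    """
    plan = list(plan) if plan is not None else default_plan()
    df = cohort.copy()
    if "chronic_pain" not in df.columns and {"pain_intensity", "pain_frequency"} <= set(df.columns):
        df["chronic_pain"] = df["pain_intensity"] / df["pain_frequency"]
    rows = []
    by_name: dict[str, st.StatResult] = {}
    for step in plan:
        name = step.get("name", step.get("kind", "step"))
        try:
            res = _run_step(df, step, by_name)
            by_name[name] = res
            rows.append(_result_row(name, step, res))
        except Exception as exc:  # noqa: BLE001 - plan steps fail independently
            logger.warning("step %r failed: %s", name, exc)
            rows.append({"step": name, "kind": step.get("kind"), "status": "failed",
                         "error": str(exc)})
    out = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        out.to_csv(out_dir / "stat_results.csv", index=False, float_format="%.10g")
        with open(out_dir / "run_log.jsonl", "a") as fh:
            fh.write(json.dumps({"stage": "cohort_analysis", "n_steps": len(plan),
                                 "n_failed": int((out.get("status") == "failed").sum())}) + "\n")
    return out


def _run_step(df: pd.DataFrame, step: Mapping, by_name: Mapping[str, st.StatResult]) -> st.StatResult:
    kind = step["kind"]
    name = step.get("name", kind)
    sub = _apply_subset(df, step.get("subset"), name)
    if kind == "one_sample":
        used = _drop_missing(sub, [step["column"]], name)
        return st.one_sample_vs_zero(used[step["column"]], tails=step.get("tails", "two"))
    if kind == "two_sample":
        entry = {"name": name, "column": step["column"], "group_a": step["group_a"],
                 "group_b": step["group_b"], "planned": step.get("planned", False)}
        return st.planned_comparisons(sub, [entry])[0]
    if kind == "covariate_contrast":
        cols = [step["column"], *step.get("covariates", [])]
        used = _drop_missing(sub[sub["group"].isin([step["group_a"], step["group_b"]])], cols, name)
        return st.covariate_adjusted_contrast(
            used[step["column"]], used["group"],
            used[step.get("covariates", [])] if step.get("covariates") else None,
        )
    if kind == "mixed_anova":
        c1, c2 = step["within"]
        used = _drop_missing(sub, [c1, c2], name)
        return st.mixed_anova(used["group"], used[c1], used[c2],
                              participant_ids=used.get("participant_id"))
    if kind == "pearson":
        used = _drop_missing(sub, [step["x"], step["y"]], name)
        return st.pearson_corr(used[step["x"]], used[step["y"]],
                               tails=step.get("tails", "two"),
                               direction=step.get("direction"))
    if kind == "partial":
        cols = [step["x"], step["y"], *step["nuisance"]]
        used = _drop_missing(sub, cols, name)
        return st.partial_corr(used[step["x"]], used[step["y"]], used[step["nuisance"]],
                               tails=step.get("tails", "one"),
                               direction=step.get("direction"))
    if kind == "fisher_compare":
        ra = by_name[step["corr_a"]]
        rb = by_name[step["corr_b"]]
        return st.fisher_compare(ra.statistic, int(np.atleast_1d(ra.n)[0]),
                                 rb.statistic, int(np.atleast_1d(rb.n)[0]))
    raise ValidationError(f"unknown plan step kind {kind!r}")


def _result_row(name: str, step: Mapping, res: st.StatResult) -> dict:
    df_val = res.df if not isinstance(res.df, tuple) else f"{res.df[0]:g},{res.df[1]:g}"
    return {
        "step": name, "kind": step.get("kind"), "status": "ok",
        "test_name": res.test_name, "statistic": res.statistic, "df": df_val,
        "p_value": res.p_value, "tails": res.tails, "alpha_used": res.alpha_used,
        "decision": res.decision, "n": str(res.n),
        "detail": json.dumps(res.extra, default=str), "error": "",
    }


def results_to_frame(results: Sequence[st.StatResult]) -> pd.DataFrame:
    """Tabulate a list of StatResults (helper for library users)."""
    return pd.DataFrame([_result_row(r.extra.get("contrast", r.test_name), {}, r) for r in results])
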