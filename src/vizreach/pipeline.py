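"""End-to-end orchestration: simulate -> segment -> metrics -> score -> stats.

File formats (all UTF-8, dot decimal, units in column names):

* trajectory CSV: trial_id, participant, condition, time_s, x_m, y_m, z_m —
  one row per sample, reach and return phases alike;
* events CSV: trial_id, event (fruit_appear | collision), t_s, fruit,
  depth_class, block_index;
* counting CSV: participant, condition, block_index, fruit, said_category,
  said_number — one row per presented fruit, in presentation order;
* questionnaire CSV: participant, condition, instrument, subscale, item,
  value;
* metrics TSV: per-segment movement-quality metrics;
* stats TSVs: ANOVA / Friedman / post-hoc tables;
* manifest JSON: config snapshot, output hashes, per-stage record counts.

Coordinates are stored in meters throughout; any unit conversion happens
only at this I/O boundary.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import kinematics as kin
from . import scoring, stats, synthetic
from .protocol import build_protocol
from .synthetic import CONDITIONS, DEFAULT_EFFECTS, NULL_EFFECTS, ConditionEffectModel

__all__ = [
    "PipelineConfig",
    "write_trajectory_files",
    "read_trajectory_file",
    "simulate_to_dir",
    "run_full_pipeline",
    "report",
]

log = logging.getLogger(__name__)

TRAJ_HEADER = ["trial_id", "participant", "condition", "time_s", "x_m", "y_m", "z_m"]
EVENT_HEADER = ["trial_id", "event", "t_s", "fruit", "depth_class", "block_index"]
FLOAT_FMT = "%.9g"


@dataclass
class PipelineConfig:
    protocol_id: str = "exp2"
    n_subjects: int = 5
    seed: int = 0
    effects: str | dict = "default"  # "default" | "null" | per-condition field overrides
    counting_error_rate: float = 0.03
    alpha: float = 0.05
    outlier_grouping: str = "pooled"  # or "per_condition"
    aggregation: str = "mean"  # cell aggregation of segment metrics
    d_convention: str = "dz"
    kinematics: kin.KinematicsConfig = field(default_factory=kin.KinematicsConfig)

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 <= self.counting_error_rate <= 1:
            raise ValueError("counting_error_rate must lie in [0, 1]")
        if self.outlier_grouping not in ("pooled", "per_condition"):
            raise ValueError("outlier_grouping must be 'pooled' or 'per_condition'")

    def effect_models(self) -> dict[str, ConditionEffectModel]:
        if self.effects == "default":
            return dict(DEFAULT_EFFECTS)
        if self.effects == "null":
            return dict(NULL_EFFECTS)
        out = {}
        for cond in CONDITIONS:
            overrides = dict(self.effects.get(cond, {}))
            if "onset_latency" in overrides:
                overrides["onset_latency"] = tuple(overrides["onset_latency"])
            out[cond] = dataclasses.replace(DEFAULT_EFFECTS[cond], **overrides)
        return out

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kin_cfg = kin.KinematicsConfig(**raw.pop("kinematics", {}))
        return cls(kinematics=kin_cfg, **raw)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Trajectory / event file I/O


def write_trajectory_files(recordings, traj_path, events_path) -> None:
    traj_rows = []
    ev_rows = []
    for rec in recordings:
        for t, p in zip(rec.t, rec.p):
            traj_rows.append((rec.trial_id, rec.participant, rec.condition, t, *p))
        if rec.return_t is not None:
            for t, p in zip(rec.return_t, rec.return_p):
                traj_rows.append((rec.trial_id, rec.participant, rec.condition, t, *p))
        ev_rows.append(
            (rec.trial_id, "fruit_appear", rec.events["fruit_appear_t"],
             rec.fruit_kind.value, rec.location.depth_class.value, rec.block_index)
        )
        ev_rows.append(
            (rec.trial_id, "collision", rec.events["collision_t"],
             rec.fruit_kind.value, rec.location.depth_class.value, rec.block_index)
        )
    pd.DataFrame(traj_rows, columns=TRAJ_HEADER).to_csv(
        traj_path, index=False, float_format=FLOAT_FMT
    )
    pd.DataFrame(ev_rows, columns=EVENT_HEADER).to_csv(
        events_path, index=False, float_format=FLOAT_FMT
    )


def read_trajectory_file(traj_path, events_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate the trajectory and event CSVs.

    Rows are sorted by time within each trial; a duplicated timestamp
    within a trial is rejected naming the trial and row numbers.
    """
    traj = pd.read_csv(traj_path)
    if list(traj.columns) != TRAJ_HEADER:
        raise ValueError(
            f"malformed trajectory header: {list(traj.columns)} != {TRAJ_HEADER}"
        )
    for col in ("time_s", "x_m", "y_m", "z_m"):
        if not np.issubdtype(traj[col].dtype, np.number):
            bad = traj.index[pd.to_numeric(traj[col], errors="coerce").isna()].tolist()
            raise ValueError(f"non-numeric values in column {col}, rows {bad[:10]}")
        if traj[col].isna().any():
            bad = traj.index[traj[col].isna()].tolist()
            raise ValueError(f"missing values in column {col}, rows {bad[:10]}")
    traj = traj.sort_values(["trial_id", "time_s"], kind="mergesort").reset_index(drop=True)
    dup = traj.duplicated(subset=["trial_id", "time_s"])
    if dup.any():
        row = traj[dup].iloc[0]
        raise ValueError(
            f"duplicated timestamp {row['time_s']} in trial {row['trial_id']}"
        )
    events = pd.read_csv(events_path)
    if list(events.columns) != EVENT_HEADER:
        raise ValueError(
            f"malformed events header: {list(events.columns)} != {EVENT_HEADER}"
        )
    return traj, events


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# Stages


def simulate_to_dir(config: PipelineConfig, outdir: Path) -> dict:
    """Simulate the dataset and write the raw input files; returns counts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    s_data, s_count, s_quest = (int(x) for x in ss.generate_state(3) % 2**31)

    protocol = build_protocol(config.protocol_id)
    recordings, truth = synthetic.simulate_dataset(
        protocol, config.effect_models(), n_subjects=config.n_subjects, seed=s_data
    )
    write_trajectory_files(recordings, outdir / "trajectory.csv", outdir / "events.csv")
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False, float_format=FLOAT_FMT)

    # counting: per subject x condition, responses over the shared plan
    count_rng = np.random.default_rng(s_count)
    kinds = truth[truth["participant"] == truth["participant"].iloc[0]]
    kinds = kinds[kinds["condition"] == kinds["condition"].iloc[0]]
    count_rows = []
    participants = sorted(truth["participant"].unique())
    for pid in participants:
        for cond in CONDITIONS:
            for block, g in kinds.groupby("block_index", sort=True):
                tr = scoring.counting_truth_from_kinds(g["fruit"].tolist())
                resp = synthetic.simulate_counting(
                    tr, config.counting_error_rate, count_rng
                )
                for (fruit, _), (said_cat, said_n) in zip(tr, resp):
                    count_rows.append((pid, cond, block, fruit, said_cat, said_n))
    pd.DataFrame(
        count_rows,
        columns=["participant", "condition", "block_index", "fruit",
                 "said_category", "said_number"],
    ).to_csv(outdir / "counting.csv", index=False)

    quest = synthetic.simulate_questionnaires(config.n_subjects, seed=s_quest)
    quest.to_csv(outdir / "questionnaires.csv", index=False)
    return {"n_recordings": len(recordings), "n_trials_planned": len(kinds)}


def compute_metrics_stage(config: PipelineConfig, outdir: Path) -> dict:
    traj, events = read_trajectory_file(outdir / "trajectory.csv", outdir / "events.csv")
    segments = kin.segment_movements(traj, events)
    metrics = kin.metrics_table(segments, config.kinematics)
    metrics.to_csv(outdir / "metrics.tsv", sep="\t", index=False, float_format=FLOAT_FMT)
    return {"n_segments": len(segments)}


METRIC_LABELS = {
    "normalized_duration_s_per_m": "Normalized duration (s/m)",
    "straightness": "Trajectory straightness ratio (n.u.)",
    "peak_velocity_m_s": "Peak velocity (m/s)",
    "n_velocity_peaks": "Velocity peaks number (n.u.)",
    "onset_s": "Movement onset (s)",
}


def outlier_stage(config: PipelineConfig, outdir: Path) -> dict:
    """Remove per-participant extreme outliers for each metric separately."""
    metrics = pd.read_csv(outdir / "metrics.tsv", sep="\t")
    counts = {}
    kept_frames = {}
    for col in METRIC_LABELS:
        kept, reports = kin.remove_outliers_grouped(
            metrics, col, grouping=config.outlier_grouping
        )
        removed = metrics.loc[~metrics.index.isin(kept.index)]
        per_cond = removed.groupby("condition").size().to_dict()
        absent = int(metrics[col].isna().sum())
        counts[col] = {
            "n_in": int(metrics[col].notna().sum()),
            "n_removed": int(len(removed)),
            "n_absent": absent,
            "removed_per_condition": {c: int(per_cond.get(c, 0)) for c in CONDITIONS},
        }
        kept_frames[col] = kept
        kept[["trial_id", "participant", "condition", "depth_class", col]].to_csv(
            outdir / f"kept_{col}.tsv", sep="\t", index=False, float_format=FLOAT_FMT
        )
    return counts


def score_stage(config: PipelineConfig, outdir: Path) -> dict:
    counting = pd.read_csv(outdir / "counting.csv")
    rows = []
    for (pid, cond), g in counting.groupby(["participant", "condition"], sort=False):
        block_scores = []
        for _, b in g.groupby("block_index", sort=True):
            fruits = tuple(scoring.counting_truth_from_kinds(b["fruit"].tolist()))
            responses = tuple(zip(b["said_category"], b["said_number"]))
            block_scores.append(
                scoring.score_counting_block(scoring.CountingBlock(fruits, responses))
            )
        rows.append((pid, cond, scoring.aggregate_counting(block_scores)))
    counting_scores = pd.DataFrame(rows, columns=["participant", "condition", "accuracy_pct"])
    counting_scores.to_csv(
        outdir / "counting_scores.tsv", sep="\t", index=False, float_format=FLOAT_FMT
    )
    quest = pd.read_csv(outdir / "questionnaires.csv")
    qscores = scoring.score_questionnaires(quest)
    qscores.to_csv(
        outdir / "questionnaire_scores.tsv", sep="\t", index=False, float_format=FLOAT_FMT
    )
    return {"n_counting_cells": len(counting_scores), "n_questionnaire_scores": len(qscores)}


def stats_stage(config: PipelineConfig, outdir: Path) -> dict:
    anova_rows = []
    posthoc_rows = []
    notes = []
    for col in METRIC_LABELS:
        kept = pd.read_csv(outdir / f"kept_{col}.tsv", sep="\t")
        cells = stats.aggregate_cells(kept, col, agg=config.aggregation)
        try:
            res = stats.rm_anova_2way(cells, alpha=config.alpha)
        except ValueError as exc:
            notes.append(f"{col}: ANOVA not estimable ({exc})")
            continue
        for eff in res.effects.values():
            anova_rows.append(
                {"metric": col, "effect": eff.name, "df1": eff.df1, "df2": eff.df2,
                 "F": eff.F, "p": eff.p, "p_gg": eff.p_gg, "p_selected": eff.p_selected,
                 "eps_gg": eff.eps, "partial_eta_sq": eff.partial_eta_sq}
            )
        if res.effects["condition"].p_selected < config.alpha:
            wide = cells.pivot_table(
                index="participant", columns="condition", values="value"
            )
            for ph in stats.posthoc_paired(wide, d_convention=config.d_convention):
                posthoc_rows.append(
                    {"metric": col, "group1": ph.pair[0], "group2": ph.pair[1],
                     "t": ph.t, "p_raw": ph.p_raw, "p_adjusted": ph.p_adjusted,
                     "cohen_d": ph.cohen_d}
                )
    anova_cols = ["metric", "effect", "df1", "df2", "F", "p", "p_gg", "p_selected",
                  "eps_gg", "partial_eta_sq"]
    posthoc_cols = ["metric", "group1", "group2", "t", "p_raw", "p_adjusted", "cohen_d"]
    pd.DataFrame(anova_rows, columns=anova_cols).to_csv(
        outdir / "anova.tsv", sep="\t", index=False, float_format=FLOAT_FMT
    )
    pd.DataFrame(posthoc_rows, columns=posthoc_cols).to_csv(
        outdir / "posthoc.tsv", sep="\t", index=False, float_format=FLOAT_FMT
    )

    counting_scores = pd.read_csv(outdir / "counting_scores.tsv", sep="\t")
    wide = counting_scores.pivot_table(
        index="participant", columns="condition", values="accuracy_pct"
    )
    fr = stats.friedman_kendall(wide)
    qscores = pd.read_csv(outdir / "questionnaire_scores.tsv", sep="\t")
    sus = qscores[qscores["instrument"] == "SUS"].rename(columns={"score": "value"})
    sus_res = stats.rm_anova_1way(sus)
    manova = {}
    for instr in ("IMI", "RTLX"):
        sub = qscores[qscores["instrument"] == instr]
        tables = {
            s: g.rename(columns={"score": "value"})
            for s, g in sub.groupby("subscale", sort=False)
        }
        try:
            r = stats.rm_manova_oneway(tables)
            manova[instr] = {
                "wilks_lambda": r.wilks_lambda, "F": r.F, "df1": r.df1,
                "df2": r.df2, "p": r.p, "partial_eta_sq": r.partial_eta_sq,
                "effsize_convention": r.effsize_convention,
            }
        except ValueError as exc:
            manova[instr] = {"note": f"not estimable: {exc}"}
            notes.append(f"{instr} MANOVA not estimable ({exc})")
    summary = {
        "friedman_counting": {
            "chi_sq": fr.chi_sq, "df": fr.df, "p": fr.p, "kendalls_W": fr.kendalls_W
        },
        "sus_anova": {
            "F": sus_res.effects["condition"].F,
            "p": sus_res.effects["condition"].p_selected,
            "partial_eta_sq": sus_res.effects["condition"].partial_eta_sq,
        },
        "manova": manova,
        "notes": notes,
    }
    with open(outdir / "stats_summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return {"n_anova_rows": len(anova_rows), "n_posthoc_rows": len(posthoc_rows)}


def report(outdir: Path) -> str:
    """Human-readable summary: descriptives per condition, per condition x
    depth class, and the ANOVA table."""
    outdir = Path(outdir)
    metrics = pd.read_csv(outdir / "metrics.tsv", sep="\t")
    lines = ["Movement-quality analysis report", "=" * 40, ""]

    lines.append("Descriptives per condition (mean +/- SD)")
    header = ["Condition"] + list(METRIC_LABELS.values())
    lines.append(" | ".join(header))
    for cond in CONDITIONS:
        sub = metrics[metrics["condition"] == cond]
        cells = [cond]
        for col in METRIC_LABELS:
            v = sub[col].dropna()
            cells.append(f"{v.mean():.2f} (+/- {v.std():.2f})" if len(v) else "absent")
        lines.append(" | ".join(cells))
    lines.append("")

    lines.append("Descriptives per condition x depth usage (mean +/- SD)")
    for col, label in METRIC_LABELS.items():
        lines.append(label)
        for cond in CONDITIONS:
            row = [f"  {cond}"]
            for dc in ("no_depth", "only_depth", "combined_depth"):
                v = metrics[(metrics["condition"] == cond) & (metrics["depth_class"] == dc)][
                    col
                ].dropna()
                row.append(f"{dc}: {v.mean():.2f} (+/- {v.std():.2f})" if len(v) else f"{dc}: absent")
            lines.append(" | ".join(row))
    lines.append("")

    anova_path = outdir / "anova.tsv"
    if anova_path.exists():
        anova = pd.read_csv(anova_path, sep="\t")
        lines.append("RM-ANOVA (effect, df, F, partial eta^2, p)")
        for _, r in anova.iterrows():
            lines.append(
                f"  {r['metric']} / {r['effect']}: "
                f"F({r['df1']:.0f},{r['df2']:.0f}) = {r['F']:.2f}, "
                f"pes = {r['partial_eta_sq']:.2f}, p = {r['p_selected']:.4f}"
            )
    summary_path = outdir / "stats_summary.json"
    if summary_path.exists():
        with open(summary_path, encoding="utf-8") as fh:
            summary = json.load(fh)
        fr = summary["friedman_counting"]
        lines.append(
            f"Friedman (counting accuracy): chi2({fr['df']}) = {fr['chi_sq']:.2f}, "
            f"W = {fr['kendalls_W']:.3f}, p = {fr['p']:.4f}"
        )
    text = "\n".join(lines) + "\n"
    (outdir / "report.txt").write_text(text, encoding="utf-8")
    return text


def run_full_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage and write a manifest; returns the manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": {}}
    stages = [
        ("simulate", lambda: simulate_to_dir(config, outdir)),
        ("metrics", lambda: compute_metrics_stage(config, outdir)),
        ("outliers", lambda: outlier_stage(config, outdir)),
        ("score", lambda: score_stage(config, outdir)),
        ("stats", lambda: stats_stage(config, outdir)),
        ("report", lambda: {"chars": len(report(outdir))}),
    ]
    for name, fn in stages:
        try:
            manifest["stages"][name] = fn()
        except Exception as exc:
            manifest["stages"][name] = {"error": str(exc)}
            with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
                json.dump(manifest, fh, indent=2, sort_keys=True)
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    manifest["file_hashes"] = {
        p.name: _sha256(p) for p in sorted(outdir.iterdir())
        if p.suffix in (".csv", ".tsv", ".txt", ".json") and p.name != "manifest.json"
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
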