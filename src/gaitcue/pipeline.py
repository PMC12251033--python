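"""Session- and cohort-level analysis.

A *session* is one walk by one participant in one cue mode. This module runs
the full chain — event detection, step times, rolling %CV, walking speed,
freezing burden, and (in on-demand mode) the cue controller — and aggregates
sessions into per-(group, task, mode) summaries with pairwise percent changes
between modes, plus Pearson correlations of freezing counts with clinical
scores (UPDRS-III, disease onset duration).

Inferential tests are deliberately out of scope; the report exposes the
per-stratum samples so any statistics package can consume them.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import DegenerateInputError, GaitCueError, MissingMarkerError
from .gait_events import DetectorConfig, detect_events
from .gait_metrics import (
    count_fog_episodes,
    merge_intervals,
    percent_time_frozen,
    rolling_cv,
    step_times,
    walking_speed,
)
from .signal_model import (
    CueMode,
    CueTimeline,
    FogAnnotation,
    MarkerKind,
    SensorLog,
    read_annotations,
    read_sensor_log,
)
from .strategy import StrategyConfig, run_cue_controller

MODE_ORDER = [CueMode.NONE, CueMode.CONTINUOUS, CueMode.ON_DEMAND]
METRIC_FIELDS = [
    "mean_pairwise_cv",
    "walking_speed",
    "n_fog_episodes",
    "pct_time_frozen",
    "cue_on_fraction",
]


@dataclass
class SessionResult:
    """Per-walk outcome metrics for one participant in one cue mode."""

    participant_id: str
    group: str  # healthy | pd
    task: str  # single | dual
    mode: str  # none | continuous | on_demand
    mean_pairwise_cv: float
    walking_speed: float | None
    n_fog_episodes: int
    pct_time_frozen: float
    cue_on_fraction: float


@dataclass
class ClinicalRecord:
    participant_id: str
    updrs_iii: float
    hy: float
    disease_onset_duration: float

    def __post_init__(self) -> None:
        if min(self.updrs_iii, self.hy, self.disease_onset_duration) < 0:
            raise GaitCueError("clinical scores must be non-negative")


def analyze_session(
    log: SensorLog,
    annotations: FogAnnotation | None,
    mode: CueMode | str,
    detector_cfg: DetectorConfig = DetectorConfig(),
    strategy_cfg: StrategyConfig = StrategyConfig(),
    participant_id: str = "",
    group: str = "pd",
    task: str = "single",
    cue_timeline: CueTimeline | None = None,
) -> SessionResult:
    """Run detection -> step times -> metrics (-> controller) on one session.

    If ``cue_timeline`` is given (e.g. the timeline a device actually
    applied) it is used for the cue-on fraction; otherwise, in on-demand
    mode, the controller is replayed over the detected step series.
    """
    mode = CueMode(mode)
    seq = detect_events(log, detector_cfg)
    steps = step_times(seq)
    cv = rolling_cv(steps, window=strategy_cfg.cv_window, ddof=strategy_cfg.sd_ddof)
    mean_cv = float(cv.values.mean()) if len(cv) else 0.0

    walk_span = log.span
    try:
        speed: float | None = walking_speed(log)
        seg = (
            log.marker_time(MarkerKind.SEGMENT_START),
            log.marker_time(MarkerKind.SEGMENT_END),
        )
    except MissingMarkerError:
        speed = None
        seg = None

    # freezing burden over the marked segment when present, else the full log
    fog_span = seg if seg is not None else walk_span
    if annotations is not None:
        pct_frozen = percent_time_frozen(annotations, fog_span[0], fog_span[1])
        n_fog = count_fog_episodes(annotations)
    else:
        pct_frozen = 0.0
        n_fog = 0

    if cue_timeline is None:
        cue_timeline = run_cue_controller(steps, mode, strategy_cfg, walk_span=walk_span)
    walk_duration = walk_span[1] - walk_span[0]
    on_time = sum(e - s for s, e in merge_intervals([(iv.start, iv.end) for iv in cue_timeline]))
    cue_on_fraction = 100.0 * on_time / walk_duration if walk_duration > 0 else 0.0

    return SessionResult(
        participant_id=participant_id,
        group=group,
        task=task,
        mode=mode.value,
        mean_pairwise_cv=mean_cv,
        walking_speed=speed,
        n_fog_episodes=n_fog,
        pct_time_frozen=pct_frozen,
        cue_on_fraction=cue_on_fraction,
    )


@dataclass
class ModeComparison:
    """Per-stratum mean/SD summary and pairwise percent changes between modes."""

    summary: pd.DataFrame
    percent_change: pd.DataFrame


def compare_modes(results: Sequence[SessionResult]) -> ModeComparison:
    """Aggregate sessions per (group, task, mode).

    Percent change between modes a (baseline) and b is 100 * (a - b) / a on
    stratum means, for the ordered pairs none->continuous, none->on_demand
    and continuous->on_demand.
    """
    if not results:
        raise DegenerateInputError("compare_modes needs at least one result")
    df = pd.DataFrame([asdict(r) for r in results])
    summary = (
        df.groupby(["group", "task", "mode"], sort=True)[METRIC_FIELDS]
        .agg(["mean", "std", "count"])
        .sort_index()
    )

    rows = []
    for (group, task), sub in df.groupby(["group", "task"], sort=True):
        means = sub.groupby("mode")[METRIC_FIELDS].mean()
        for a, b in [
            (CueMode.NONE, CueMode.CONTINUOUS),
            (CueMode.NONE, CueMode.ON_DEMAND),
            (CueMode.CONTINUOUS, CueMode.ON_DEMAND),
        ]:
            if a.value not in means.index or b.value not in means.index:
                continue
            for metric in METRIC_FIELDS:
                base = means.loc[a.value, metric]
                other = means.loc[b.value, metric]
                change = 100.0 * (base - other) / base if base not in (0.0,) and not np.isnan(base) else np.nan
                rows.append(
                    {
                        "group": group,
                        "task": task,
                        "baseline_mode": a.value,
                        "other_mode": b.value,
                        "metric": metric,
                        "baseline_mean": base,
                        "other_mean": other,
                        "percent_change": change,
                    }
                )
    return ModeComparison(summary=summary, percent_change=pd.DataFrame(rows))


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation coefficient.

        r = sum((x_i - x̄)(y_i - ȳ)) / sqrt(sum((x_i - x̄)²) · sum((y_i - ȳ)²))

    Requires equal lengths >= 3 and non-zero variance in both arguments.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DegenerateInputError("pearson_r needs two equal-length 1-D sequences")
    if len(x) < 3:
        raise DegenerateInputError("pearson_r needs at least 3 pairs")
    dx = x - x.mean()
    dy = y - y.mean()
    sxx = float(dx @ dx)
    syy = float(dy @ dy)
    if sxx == 0.0 or syy == 0.0:
        raise DegenerateInputError("pearson_r is undefined for zero-variance input")
    return float((dx @ dy) / np.sqrt(sxx * syy))


def correlate_fog_with_clinical(
    results: Sequence[SessionResult], clinical: Sequence[ClinicalRecord]
) -> pd.DataFrame:
    """Correlate freezing counts with clinical covariates per (mode, task).

    Returns a table with one row per (mode, task, covariate) holding the
    Pearson r between n_fog_episodes and the covariate across participants.
    """
    clin = {c.participant_id: c for c in clinical}
    df = pd.DataFrame([asdict(r) for r in results])
    missing = sorted(set(df["participant_id"]) - set(clin))
    if missing:
        raise GaitCueError(f"no clinical record for participant(s): {missing}")
    rows = []
    for (mode, task), sub in df.groupby(["mode", "task"], sort=True):
        counts = sub["n_fog_episodes"].to_numpy(dtype=float)
        for covariate, getter in [
            ("disease_onset_duration", lambda c: c.disease_onset_duration),
            ("updrs_iii", lambda c: c.updrs_iii),
        ]:
            cov = np.array([getter(clin[p]) for p in sub["participant_id"]])
            rows.append(
                {
                    "mode": mode,
                    "task": task,
                    "covariate": covariate,
                    "r": pearson_r(counts, cov),
                    "n": len(counts),
                }
            )
    return pd.DataFrame(rows)


def run_cohort(manifest: dict | str | Path, out_json: str | Path | None = None) -> dict:
    """Run every session listed in a manifest and assemble the cohort report.

    The manifest (YAML/JSON file or an equivalent dict) lists sessions::

        sessions:
          - log: walk1.csv
            annotations: walk1_fog.csv   # optional
            mode: on_demand
            group: pd
            task: single
            participant_id: P01
        clinical_csv: clinical.csv       # optional

    The report dict contains the per-session results, the per-stratum
    summary, the pairwise percent changes, and (when clinical data is
    given) the correlation table. Fixed inputs yield a byte-identical
    report JSON.
    """
    base = Path(".")
    if not isinstance(manifest, dict):
        path = Path(manifest)
        base = path.parent
        manifest = yaml.safe_load(path.read_text())

    results = []
    for spec in manifest["sessions"]:
        log = read_sensor_log(base / spec["log"])
        ann = read_annotations(base / spec["annotations"]) if spec.get("annotations") else None
        results.append(
            analyze_session(
                log,
                ann,
                mode=spec["mode"],
                participant_id=str(spec.get("participant_id", "")),
                group=spec.get("group", "pd"),
                task=spec.get("task", "single"),
            )
        )
    comparison = compare_modes(results)
    report = {
        "sessions": [asdict(r) for r in results],
        "summary": json.loads(comparison.summary.to_json(orient="split")),
        "percent_change": comparison.percent_change.to_dict(orient="records"),
    }
    if manifest.get("clinical_csv"):
        cdf = pd.read_csv(base / manifest["clinical_csv"])
        clinical = [
            ClinicalRecord(
                participant_id=str(r.participant_id),
                updrs_iii=float(r.updrs_iii),
                hy=float(r.hy),
                disease_onset_duration=float(r.onset_years),
            )
            for r in cdf.itertuples()
        ]
        pd_results = [r for r in results if r.group == "pd"]
        report["correlations"] = correlate_fog_with_clinical(pd_results, clinical).to_dict(
            orient="records"
        )
    if out_json is not None:
        Path(out_json).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
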