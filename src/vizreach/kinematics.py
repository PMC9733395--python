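"""Segmentation, movement-quality metrics, onset, collision and outliers.

The analyzed unit is one fruit reach: samples from the instant the fruit
appears (home sphere disappears) to the instant the cursor collides with
the fruit. Five quantities are computed per reach:

* normalized duration (s/m): movement time divided by the straight-line
  (chord) distance between the last and first positions;
* trajectory straightness ratio (n.u.): traveled path length over chord;
* peak velocity (m/s): maximum of the filtered speed profile;
* number of velocity peaks: local speed maxima above a prominence floor,
  a discrete smoothness measure (more peaks = more corrective submovements);
* movement onset (s): latency until speed first crosses 0.2 m/s, absent
  when the reach never crosses the threshold.

Velocity estimation: positions are linearly resampled to a uniform 500 Hz
grid, differentiated with central differences, and low-passed with a
zero-phase 4th-order Butterworth at 10 Hz — standard practice for reach
kinematics; the raw recordings carry timestamp jitter and tracker noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, find_peaks, sosfiltfilt

from .protocol import ColliderSpec, DepthClass, FruitKind

__all__ = [
    "KinematicsConfig",
    "ReachSegment",
    "SpeedProfile",
    "MovementMetrics",
    "OutlierReport",
    "resample_uniform",
    "compute_speed",
    "segment_movements",
    "detect_collision",
    "normalized_duration",
    "straightness_ratio",
    "peak_velocity",
    "count_velocity_peaks",
    "movement_onset",
    "compute_metrics",
    "metrics_table",
    "remove_extreme_outliers",
    "remove_outliers_grouped",
]

log = logging.getLogger(__name__)

CHORD_EPS = 0.001  # m; below this the chord-normalized metrics are undefined


@dataclass(frozen=True)
class KinematicsConfig:
    fs: float = 500.0  # uniform resampling rate, Hz
    filter_cutoff: float = 10.0  # zero-phase low-pass, Hz
    filter_order: int = 4
    onset_threshold: float = 0.2  # m/s
    peak_min_prominence_floor: float = 0.02  # m/s
    peak_min_prominence_frac: float = 0.05  # fraction of peak speed
    peak_min_separation: float = 0.05  # s
    path_positions: str = "filtered"  # or "raw"


@dataclass
class ReachSegment:
    participant: str
    condition: str
    depth_class: DepthClass
    fruit_kind: FruitKind
    t: np.ndarray  # re-zeroed at fruit appearance
    p: np.ndarray  # (n, 3) m
    trial_id: str = ""

    def __post_init__(self):
        if len(self.t) < 2:
            raise ValueError("segment needs at least 2 samples")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")


@dataclass
class SpeedProfile:
    t: np.ndarray
    speed: np.ndarray  # m/s, filtered, non-negative
    fs: float


@dataclass
class MovementMetrics:
    normalized_duration: float | None  # s/m
    straightness_ratio: float | None
    peak_velocity: float
    n_velocity_peaks: int
    onset: float | None  # s; None when 0.2 m/s never reached


@dataclass
class OutlierReport:
    metric: str
    group: tuple
    kept: np.ndarray
    removed: np.ndarray
    lower_fence: float
    upper_fence: float


# ---------------------------------------------------------------------------


def resample_uniform(
    t: np.ndarray, p: np.ndarray, fs: float
) -> tuple[np.ndarray, np.ndarray]:
    """Linearly interpolate samples onto a uniform 1/fs grid over [t0, tN]."""
    t = np.asarray(t, dtype=float)
    p = np.atleast_2d(np.asarray(p, dtype=float))
    if len(t) < 2:
        raise ValueError("need at least 2 samples")
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    n = int(np.floor((t[-1] - t[0]) * fs)) + 1
    tg = t[0] + np.arange(n) / fs
    pg = np.column_stack([np.interp(tg, t, p[:, i]) for i in range(p.shape[1])])
    return tg, pg


def _lowpass(x: np.ndarray, fs: float, cutoff: float, order: int) -> np.ndarray:
    sos = butter(order, cutoff, fs=fs, output="sos")
    # pad with ~3 filter time constants so edge transients die out within
    # the padding, not within the segment
    padlen = min(int(3 * fs / cutoff), x.shape[0] - 1)
    return sosfiltfilt(sos, x, axis=0, padlen=padlen)


def compute_speed(
    t: np.ndarray, p: np.ndarray, cfg: KinematicsConfig = KinematicsConfig()
) -> SpeedProfile:
    """Filtered speed magnitude on a uniform grid.

    Positions are zero-phase low-passed before central differencing and
    the magnitude is taken last: rectifying first would turn zero-mean
    tracker noise into a positive speed bias that no subsequent filter can
    remove.
    """
    tg, pg = resample_uniform(t, p, cfg.fs)
    if len(tg) < 5:
        raise ValueError("segment too short for speed estimation")
    pf = _lowpass(pg, cfg.fs, cfg.filter_cutoff, cfg.filter_order)
    v = np.gradient(pf, 1.0 / cfg.fs, axis=0)
    return SpeedProfile(t=tg, speed=np.linalg.norm(v, axis=1), fs=cfg.fs)


def segment_movements(
    traj: pd.DataFrame, events: pd.DataFrame, meta: pd.DataFrame | None = None
) -> list[ReachSegment]:
    """Cut a recording stream into one segment per fruit reach.

    ``traj`` holds columns trial_id, participant, condition, time_s, x_m,
    y_m, z_m; ``events`` holds trial_id, event ('fruit_appear'/'collision'),
    t_s and, optionally, fruit and depth_class columns. A fruit appearance
    without a subsequent collision drops the trial with a logged warning.
    Return-to-home samples (outside the appear->collision window) are
    excluded.
    """
    segments: list[ReachSegment] = []
    ev_by_trial = dict(tuple(events.groupby("trial_id", sort=False)))
    for trial_id, g in traj.groupby("trial_id", sort=False):
        ev = ev_by_trial.get(trial_id)
        if ev is None:
            log.warning("trial %s: no events, dropped", trial_id)
            continue
        appear = ev.loc[ev["event"] == "fruit_appear", "t_s"]
        collide = ev.loc[ev["event"] == "collision", "t_s"]
        if len(appear) == 0:
            log.warning("trial %s: no fruit appearance, dropped", trial_id)
            continue
        t_appear = float(appear.iloc[0])
        later = collide[collide >= t_appear]
        if len(later) == 0:
            log.warning("trial %s: appearance without collision, dropped", trial_id)
            continue
        t_collide = float(later.iloc[0])
        g = g.sort_values("time_s")
        mask = (g["time_s"] >= t_appear) & (g["time_s"] <= t_collide)
        sub = g.loc[mask]
        if len(sub) < 2:
            log.warning("trial %s: fewer than 2 samples in reach window, dropped", trial_id)
            continue
        fruit = FruitKind(ev["fruit"].iloc[0]) if "fruit" in ev else FruitKind.PEAR
        dc = DepthClass(ev["depth_class"].iloc[0]) if "depth_class" in ev else DepthClass.NO_DEPTH
        segments.append(
            ReachSegment(
                participant=str(sub["participant"].iloc[0]),
                condition=str(sub["condition"].iloc[0]),
                depth_class=dc,
                fruit_kind=fruit,
                t=sub["time_s"].to_numpy() - t_appear,
                p=sub[["x_m", "y_m", "z_m"]].to_numpy(),
                trial_id=str(trial_id),
            )
        )
    return segments


def _point_segment_distance(q: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    ab = b - a
    tt = np.clip((q - a) @ ab / (ab @ ab), 0.0, 1.0)
    return float(np.linalg.norm(q - (a + tt * ab)))


def detect_collision(
    cursor_center,
    cursor_radius: float,
    fruit_center,
    collider: ColliderSpec,
    up=(0.0, 1.0, 0.0),
) -> bool:
    """True iff the cursor sphere overlaps the fruit collider.

    Sphere: center distance <= r_fruit + r_cursor. The pear adds a vertical
    capsule sitting on its lower sphere; its core axis segment spans
    capsule_height minus the two hemispherical end caps, and contact means
    point-to-axis distance <= capsule_radius + r_cursor.
    """
    q = np.asarray(cursor_center, dtype=float)
    c = np.asarray(fruit_center, dtype=float)
    r_s = collider.sphere_diameter / 2
    if np.linalg.norm(q - c) <= r_s + cursor_radius:
        return True
    if collider.shape == "sphere_plus_capsule":
        up = np.asarray(up, dtype=float)
        r_cap = collider.capsule_diameter / 2
        core = max(collider.capsule_height - collider.capsule_diameter, 0.0)
        a = c + up * r_s
        b = a + up * core
        if _point_segment_distance(q, a, b) <= r_cap + cursor_radius:
            return True
    return False


# ---------------------------------------------------------------------------
# Per-segment metrics


def _chord(p: np.ndarray) -> float:
    return float(np.linalg.norm(p[-1] - p[0]))


def normalized_duration(segment: ReachSegment) -> float | None:
    """Movement time over chord length (s/m); None for a degenerate chord."""
    chord = _chord(segment.p)
    if chord <= CHORD_EPS:
        log.warning("trial %s: chord %.4g m below eps, duration absent", segment.trial_id, chord)
        return None
    return float(segment.t[-1] - segment.t[0]) / chord


def _path_positions(segment: ReachSegment, cfg: KinematicsConfig) -> np.ndarray:
    tg, pg = resample_uniform(segment.t, segment.p, cfg.fs)
    if cfg.path_positions == "filtered" and len(tg) >= 5:
        pg = _lowpass(pg, cfg.fs, cfg.filter_cutoff, cfg.filter_order)
    return pg

def straightness_ratio(
    segment: ReachSegment, cfg: KinematicsConfig = KinematicsConfig()
) -> float | None:
    """Path length over chord length; 1 for a perfectly straight reach."""
    chord = _chord(segment.p)
    if chord <= CHORD_EPS:
        log.warning("trial %s: chord below eps, straightness absent", segment.trial_id)
        return None
    pg = _path_positions(segment, cfg)
    path = float(np.linalg.norm(np.diff(pg, axis=0), axis=1).sum())
    return path / float(np.linalg.norm(pg[-1] - pg[0]))


def peak_velocity(profile: SpeedProfile) -> float:
    return float(profile.speed.max())


def count_velocity_peaks(
    profile: SpeedProfile,
    min_prominence: float | None = None,
    min_separation: float | None = None,
    cfg: KinematicsConfig = KinematicsConfig(),
) -> int:
    """Local speed maxima with a prominence and separation floor.

    Defaults: prominence >= max(0.02 m/s, 5% of peak speed), separation
    >= 50 ms — suppresses noise maxima while keeping genuine corrective
    submovements.
    """
    vmax = profile.speed.max()
    if vmax <= 0:
        return 0
    if min_prominence is None:
        min_prominence = max(
            cfg.peak_min_prominence_floor, cfg.peak_min_prominence_frac * vmax
        )
    if min_separation is None:
        min_separation = cfg.peak_min_separation
    distance = max(int(round(min_separation * profile.fs)), 1)
    peaks, _ = find_peaks(profile.speed, prominence=min_prominence, distance=distance)
    return int(len(peaks))


def movement_onset(
    profile: SpeedProfile, v_threshold: float = 0.2
) -> float | None:
    """Latency until speed first reaches the threshold; None if never."""
    idx = np.flatnonzero(profile.speed >= v_threshold)
    if len(idx) == 0:
        return None
    return float(profile.t[idx[0]] - profile.t[0])


def compute_metrics(
    segment: ReachSegment, cfg: KinematicsConfig = KinematicsConfig()
) -> MovementMetrics:
    profile = compute_speed(segment.t, segment.p, cfg)
    return MovementMetrics(
        normalized_duration=normalized_duration(segment),
        straightness_ratio=straightness_ratio(segment, cfg),
        peak_velocity=peak_velocity(profile),
        n_velocity_peaks=count_velocity_peaks(profile, cfg=cfg),
        onset=movement_onset(profile, cfg.onset_threshold),
    )


METRIC_COLUMNS = (
    "normalized_duration_s_per_m",
    "straightness",
    "peak_velocity_m_s",
    "n_velocity_peaks",
    "onset_s",
)


def metrics_table(
    segments: list[ReachSegment], cfg: KinematicsConfig = KinematicsConfig()
) -> pd.DataFrame:
    """Per-segment metrics in the pipeline's long format."""
    rows = []
    for seg in segments:
        m = compute_metrics(seg, cfg)
        flags = []
        if m.onset is None:
            flags.append("onset_absent")
        if m.normalized_duration is None:
            flags.append("degenerate_chord")
        rows.append(
            {
                "trial_id": seg.trial_id,
                "participant": seg.participant,
                "condition": seg.condition,
                "depth_class": seg.depth_class.value,
                "fruit": seg.fruit_kind.value,
                "normalized_duration_s_per_m": m.normalized_duration,
                "straightness": m.straightness_ratio,
                "peak_velocity_m_s": m.peak_velocity,
                "n_velocity_peaks": m.n_velocity_peaks,
                "onset_s": m.onset,
                "flags": ";".join(flags),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Extreme-outlier removal (Tukey fences with factor 3)


def remove_extreme_outliers(
    values, metric: str = "", group: tuple = (), factor: float = 3.0
) -> OutlierReport:
    """Remove values strictly outside [Q1 - 3 IQR, Q3 + 3 IQR].

    Quartiles use linear interpolation between order statistics. Single
    pass: fences are not recomputed after removal. Values exactly on a
    fence are kept. Groups with fewer than 4 values pass through untouched
    with a warning.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if len(v) < 4:
        log.warning("group %s/%s: only %d values, outlier removal skipped", metric, group, len(v))
        return OutlierReport(metric, group, v, np.array([]), -np.inf, np.inf)
    q1, q3 = np.quantile(v, [0.25, 0.75])
    iqr = q3 - q1
    lo, hi = q1 - factor * iqr, q3 + factor * iqr
    mask = (v < lo) | (v > hi)
    return OutlierReport(metric, group, v[~mask], v[mask], float(lo), float(hi))


def remove_outliers_grouped(
    df: pd.DataFrame,
    value_col: str,
    grouping: str = "pooled",
    factor: float = 3.0,
) -> tuple[pd.DataFrame, list[OutlierReport]]:
    """Apply the extreme-outlier rule per participant (optionally per
    condition) for one metric column; returns the kept rows and reports.

    ``grouping``: 'pooled' fences per participant across conditions, or
    'per_condition' fences per participant x condition.
    """
    if grouping not in ("pooled", "per_condition"):
        raise ValueError("grouping must be 'pooled' or 'per_condition'")
    keys = ["participant"] if grouping == "pooled" else ["participant", "condition"]
    keep = pd.Series(True, index=df.index)
    reports = []
    present = df[value_col].notna()
    for group, g in df[present].groupby(keys, sort=False):
        rep = remove_extreme_outliers(
            g[value_col].to_numpy(), metric=value_col,
            group=group if isinstance(group, tuple) else (group,), factor=factor,
        )
        reports.append(rep)
        if len(rep.removed):
            out = (g[value_col] < rep.lower_fence) | (g[value_col] > rep.upper_fence)
            keep.loc[g.index[out]] = False
    return df[keep], reports
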