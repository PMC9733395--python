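"""Seeded synthetic data with the statistical structure the analysis assumes.

The generator emulates the experiment end to end: ~500 Hz 3D position
streams of reach-and-return movements to the 22 workspace targets under the
three visualization conditions (IVR, AR, 2D screen), counting responses
with occasional off-by-one errors, and Likert/slider questionnaire tables.

Ground-truth reaches are minimum-jerk point-to-point movements; condition
effects are injected as a duration multiplier, a lateral curvature bump,
corrective submovements (extra speed peaks), an onset latency, and additive
tracker noise. Default magnitudes reproduce the ordering
2D screen > AR > IVR for duration / curvature / submovements / onset; the
magnitudes themselves are simulation parameters, not empirical claims.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .protocol import (
    DepthClass,
    ExperimentProtocol,
    FruitKind,
    TargetLocation,
    TrialPlanEntry,
    plan_trial_sequence,
)

__all__ = [
    "CONDITIONS",
    "ConditionEffectModel",
    "SubjectModel",
    "TrialRecording",
    "DEFAULT_EFFECTS",
    "NULL_EFFECTS",
    "min_jerk_trajectory",
    "add_curved_deviation",
    "add_submovements",
    "simulate_trial",
    "simulate_dataset",
    "simulate_counting",
    "simulate_questionnaires",
    "simulate_cell_table",
]

CONDITIONS = ("IVR", "AR", "Screen")

#: Nominal sampling grid (s) and timestamp jitter sd (s): a uniform 2 ms
#: grid with 0.1 ms Gaussian jitter, i.e. "approximately 500 Hz".
SAMPLE_DT = 0.002
TIMESTAMP_JITTER_SD = 0.0001


@dataclass(frozen=True)
class ConditionEffectModel:
    """Injected effects for one visualization condition.

    duration_scale multiplies the baseline movement time per meter;
    curvature_amplitude is the peak lateral deviation of the path (m);
    submovement_rate is the Poisson mean of corrective submovements per
    reach; onset_latency is (mean, sd) of a non-negative truncated normal
    (s); noise_sd is additive isotropic position noise (m).
    """

    condition: str
    duration_scale: float = 1.0
    curvature_amplitude: float = 0.01
    submovement_rate: float = 0.5
    onset_latency: tuple[float, float] = (0.35, 0.05)
    noise_sd: float = 0.001

    def __post_init__(self):
        if self.duration_scale <= 0:
            raise ValueError("duration_scale must be positive")
        if self.noise_sd < 0 or self.onset_latency[1] < 0 or self.onset_latency[0] < 0:
            raise ValueError("sds and latency mean must be non-negative")


#: Default per-condition effects: the 2D screen yields the longest, most
#: curved, least smooth and latest-starting reaches; IVR the best.
DEFAULT_EFFECTS: dict[str, ConditionEffectModel] = {
    "IVR": ConditionEffectModel("IVR", 1.00, 0.010, 0.5, (0.35, 0.05), 0.001),
    "AR": ConditionEffectModel("AR", 1.10, 0.015, 1.0, (0.42, 0.06), 0.001),
    "Screen": ConditionEffectModel("Screen", 1.35, 0.030, 2.5, (0.60, 0.10), 0.001),
}

#: All conditions exchangeable: used for type-I-error calibration.
NULL_EFFECTS: dict[str, ConditionEffectModel] = {
    c: replace(DEFAULT_EFFECTS["IVR"], condition=c) for c in CONDITIONS
}

#: Depth-usage duration multipliers: depth-only reaches are hardest,
#: planar reaches easiest (applied on top of the condition scale).
DEFAULT_DEPTH_DURATION_SCALE: dict[DepthClass, float] = {
    DepthClass.NO_DEPTH: 0.90,
    DepthClass.ONLY_DEPTH: 1.15,
    DepthClass.COMBINED_DEPTH: 1.00,
}


@dataclass(frozen=True)
class SubjectModel:
    subject_id: str
    baseline_duration_per_m: float = 3.0  # s/m; elderly-like reach tempo
    subject_random_effect: float = 1.0  # multiplicative, lognormal across subjects
    counting_error_rate: float = 0.03  # probability of an off-by-one per fruit

    def __post_init__(self):
        if self.baseline_duration_per_m <= 0:
            raise ValueError("baseline must be positive")
        if not 0 <= self.counting_error_rate <= 1:
            raise ValueError("counting_error_rate must be in [0, 1]")


@dataclass
class TrialRecording:
    """One fruit-reach episode: latency + reach (+ flagged return phase).

    ``t``/``p`` span the analyzed window from fruit appearance (t = 0) to
    collision; ``return_t``/``return_p`` hold the flagged return-to-home
    movement that the analysis excludes.
    """

    trial_id: str
    participant: str
    condition: str
    block_index: int
    fruit_kind: FruitKind
    location: TargetLocation
    t: np.ndarray
    p: np.ndarray
    events: dict
    return_t: np.ndarray | None = None
    return_p: np.ndarray | None = None


# ---------------------------------------------------------------------------
# Trajectory primitives


def _mj(tau: np.ndarray) -> np.ndarray:
    """Minimum-jerk position profile, 0 -> 1 over tau in [0, 1]."""
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def _time_grid(T: float, fs: float) -> np.ndarray:
    t = np.arange(int(np.floor(T * fs)) + 1) / fs
    if t[-1] < T - 1e-12:
        t = np.append(t, T)
    return t


def min_jerk_trajectory(p0, p1, T: float, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Sample a straight minimum-jerk reach from p0 to p1.

    p(t) = p0 + (p1 - p0) (10 tau^3 - 15 tau^4 + 6 tau^5), tau = t/T.
    Endpoints are exact; samples are spaced 1/fs apart (plus the exact
    endpoint). Peak speed is 1.875 |p1 - p0| / T at tau = 1/2.
    """
    if T <= 0 or fs <= 0:
        raise ValueError("T and fs must be positive")
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    if np.allclose(p0, p1):
        raise ValueError("p0 and p1 must differ")
    t = _time_grid(T, fs)
    pos = p0 + np.outer(_mj(t / T), p1 - p0)
    return t, pos


def _perpendicular(u: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random unit vector perpendicular to u."""
    while True:
        v = rng.normal(size=3)
        v -= u * (v @ u)
        n = np.linalg.norm(v)
        if n > 1e-8:
            return v / n


def add_curved_deviation(
    samples: tuple[np.ndarray, np.ndarray], amplitude: float, seed
) -> tuple[np.ndarray, np.ndarray]:
    """Bow the path sideways with a half-sine bump of the given peak (m).

    The bump is perpendicular to the chord (direction seeded), vanishes at
    both endpoints, and strictly increases path length for amplitude > 0.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    t, p = samples
    if len(t) < 3:
        raise ValueError("need at least 3 samples")
    if amplitude == 0:
        return t.copy(), p.copy()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    chord = p[-1] - p[0]
    u = chord / np.linalg.norm(chord)
    perp = _perpendicular(u, rng)
    s = (t - t[0]) / (t[-1] - t[0])
    return t.copy(), p + np.outer(amplitude * np.sin(np.pi * s), perp)


def add_submovements(
    samples: tuple[np.ndarray, np.ndarray],
    k: int,
    scale: float,
    seed,
    window_frac: float = 0.12,
    centers: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Superimpose k corrective submovements along the movement direction.

    Each submovement is a small minimum-jerk displacement pulse of net
    length ``scale`` (m) along the chord, placed late in the reach; a smooth
    ramp of total k*scale is subtracted over the whole movement so the
    endpoints are unchanged. For well-separated pulses the speed profile
    gains one local maximum per pulse (1 + k in total on a plain reach).

    ``centers`` are pulse centers as fractions of the movement duration;
    by default k pulses are spread over the deceleration phase.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    t, p = samples
    if k == 0:
        return t.copy(), p.copy()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    T = t[-1] - t[0]
    chord = p[-1] - p[0]
    u = chord / np.linalg.norm(chord)
    tau = (t - t[0]) / T
    if centers is None:
        base = np.linspace(0.68, 0.95, k) if k > 1 else np.array([0.75])
        centers = base + rng.uniform(-0.015, 0.015, size=k)
    # windows must fit inside the movement or the endpoint would shift
    centers = np.clip(np.asarray(centers, dtype=float), window_frac / 2, 1 - window_frac / 2)
    out = p - np.outer(k * scale * _mj(tau), u)
    for c in centers:
        lo = c - window_frac / 2
        tl = np.clip((tau - lo) / window_frac, 0.0, 1.0)
        out = out + np.outer(scale * _mj(tl), u)
    return t.copy(), out


def _truncated_normal(mean: float, sd: float, rng: np.random.Generator) -> float:
    if sd == 0:
        return max(mean, 0.0)
    while True:
        x = rng.normal(mean, sd)
        if x >= 0:
            return float(x)


def _jittered_timestamps(n: int, rng: np.random.Generator, t0: float = 0.0) -> np.ndarray:
    t = t0 + np.arange(n) * SAMPLE_DT + rng.normal(0, TIMESTAMP_JITTER_SD, size=n)
    # enforce strictly increasing timestamps (jitter << grid step)
    return np.maximum.accumulate(t + np.arange(n) * 1e-9)


def _reach_endpoint(location: TargetLocation, collider, cursor_radius: float) -> np.ndarray:
    """Contact point: on the line home->fruit, inside the collider surface."""
    center = np.asarray(location.offset, dtype=float)
    dist = np.linalg.norm(center)
    u = center / dist
    r_sum = collider.sphere_diameter / 2 + cursor_radius
    stop = min(0.9 * r_sum, 0.5 * dist)  # guard targets closer than the collider
    return center - u * stop


def simulate_trial(
    subject: SubjectModel,
    effects: ConditionEffectModel,
    entry: TrialPlanEntry,
    protocol: ExperimentProtocol,
    seed,
    trial_id: str = "t000",
    depth_duration_scale: dict | None = None,
    with_return: bool = True,
) -> TrialRecording:
    """Simulate one fruit reach: latency hold, reach, flagged return.

    The reach starts at the workspace center (home), ends in contact with
    the fruit collider, and lasts baseline * condition scale * depth scale *
    subject effect * distance seconds. Deterministic per seed.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    depth_scale = (depth_duration_scale or DEFAULT_DEPTH_DURATION_SCALE)[
        entry.location.depth_class
    ]
    collider = protocol.colliders[entry.fruit_kind]
    home = np.zeros(3)
    p1 = _reach_endpoint(entry.location, collider, protocol.cursor_sphere_diameter / 2)
    D = np.linalg.norm(p1 - home)
    T = (
        subject.baseline_duration_per_m
        * effects.duration_scale
        * depth_scale
        * subject.subject_random_effect
        * D
    )
    latency = _truncated_normal(*effects.onset_latency, rng)

    fs = 1.0 / SAMPLE_DT
    k = int(rng.poisson(effects.submovement_rate))
    # corrective submovements are sequential ~0.3 s hops closing an
    # undershoot of the main reach: real corrections extend the movement
    # rather than riding on top of it
    hop_T, hop_gap = 0.3, 0.02
    undershoot = min(k * hop_gap, 0.4 * D)
    u = (p1 - home) / D
    tr, pr = min_jerk_trajectory(home, p1 - u * undershoot, T, fs)
    amp = effects.curvature_amplitude
    if amp > 0:
        tr, pr = add_curved_deviation((tr, pr), amp, rng)
    for j in range(k):
        start = pr[-1]
        th, ph = min_jerk_trajectory(start, start + u * (undershoot / k), hop_T, fs)
        tr = np.concatenate([tr, tr[-1] + th[1:]])
        pr = np.vstack([pr, ph[1:]])

    n_lat = max(int(round(latency / SAMPLE_DT)), 0)
    p_lat = np.tile(home, (n_lat, 1))
    p_all = np.vstack([p_lat, pr])
    t_all = _jittered_timestamps(len(p_all), rng)
    t_all[0] = 0.0
    if effects.noise_sd > 0:
        p_all = p_all + rng.normal(0, effects.noise_sd, size=p_all.shape)
    # the recorded collision sample is the noise-free contact point
    p_all[-1] = p1

    events = {"fruit_appear_t": 0.0, "collision_t": float(t_all[-1])}
    rec = TrialRecording(
        trial_id=trial_id,
        participant=subject.subject_id,
        condition=effects.condition,
        block_index=entry.block_index,
        fruit_kind=entry.fruit_kind,
        location=entry.location,
        t=t_all,
        p=p_all,
        events=events,
    )
    if with_return:
        t_ret, p_ret = min_jerk_trajectory(p1, home + [0, 0, 1e-6], 0.9 * T, fs)
        dwell = rng.uniform(*protocol.dwell_interval)
        n_dwell = int(round(dwell / SAMPLE_DT))
        p_ret = np.vstack([p_ret, np.tile(p_ret[-1], (n_dwell, 1))])
        if effects.noise_sd > 0:
            p_ret = p_ret + rng.normal(0, effects.noise_sd, size=p_ret.shape)
        rec.return_t = _jittered_timestamps(len(p_ret), rng, t0=t_all[-1] + SAMPLE_DT)
        rec.return_p = p_ret
    return rec


def simulate_dataset(
    protocol: ExperimentProtocol,
    effect_config: dict[str, ConditionEffectModel] | None = None,
    n_subjects: int = 5,
    seed: int = 0,
    subject_sd: float = 0.10,
    with_return: bool = True,
) -> tuple[list[TrialRecording], pd.DataFrame]:
    """Simulate the full crossed design: every subject x 3 conditions x plan.

    Returns the recordings plus a ground-truth table of the injected
    parameters per trial. The trial plan (fruit/location sequence) is
    canonical per seed and shared across subjects and conditions.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    effect_config = effect_config or DEFAULT_EFFECTS
    ss = np.random.SeedSequence(seed)
    plan_seed, subj_seed, trial_entropy = ss.spawn(3)
    plan = plan_trial_sequence(protocol, seed=plan_seed.generate_state(1)[0] % 2**31)
    subj_rng = np.random.default_rng(subj_seed)
    subjects = [
        SubjectModel(
            subject_id=f"s{i + 1:02d}",
            subject_random_effect=float(np.exp(subj_rng.normal(0, subject_sd))),
        )
        for i in range(n_subjects)
    ]
    recordings: list[TrialRecording] = []
    truth_rows = []
    trial_streams = trial_entropy.spawn(n_subjects * len(effect_config))
    idx = 0
    for subject in subjects:
        for cond in effect_config:
            eff = effect_config[cond]
            rng = np.random.default_rng(trial_streams[idx])
            idx += 1
            for j, entry in enumerate(plan):
                rec = simulate_trial(
                    subject, eff, entry, protocol, rng,
                    trial_id=f"{subject.subject_id}_{cond}_{j:04d}",
                    with_return=with_return,
                )
                recordings.append(rec)
                truth_rows.append(
                    {
                        "trial_id": rec.trial_id,
                        "participant": subject.subject_id,
                        "condition": cond,
                        "block_index": entry.block_index,
                        "fruit": entry.fruit_kind.value,
                        "depth_class": entry.location.depth_class.value,
                        "duration_scale": eff.duration_scale,
                        "curvature_amplitude": eff.curvature_amplitude,
                        "submovement_rate": eff.submovement_rate,
                        "onset_mean": eff.onset_latency[0],
                        "subject_effect": subject.subject_random_effect,
                    }
                )
    return recordings, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Counting and questionnaires


def simulate_counting(
    truth: list[tuple[str, int]],
    error_rate: float,
    seed,
    continue_from_error: float = 1.0,
) -> list[tuple[str, int]]:
    """Simulate spoken counting responses over one block.

    ``truth`` is the ordered (category, true cumulative count) sequence.
    With probability ``error_rate`` a response is off by +1; afterwards the
    participant keeps counting from the erroneous value with probability
    ``continue_from_error`` (else snaps back to the true count).
    """
    if not 0 <= error_rate <= 1:
        raise ValueError("error_rate must be in [0, 1]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    internal: dict[str, int] = {}
    responses: list[tuple[str, int]] = []
    for category, true_count in truth:
        said = internal.get(category, 0) + 1
        if rng.random() < error_rate:
            said += 1
        responses.append((category, said))
        if said != true_count and rng.random() >= continue_from_error:
            internal[category] = true_count
        else:
            internal[category] = said
    return responses


#: Instrument layouts: item counts per subscale.
IMI_SUBSCALES = {
    "interest_enjoyment": 7,
    "perceived_competence": 5,
    "effort_importance": 5,
    "pressure_tension": 5,
}
RTLX_SUBSCALES = (
    "mental_demand",
    "physical_demand",
    "temporal_demand",
    "performance",
    "effort",
    "frustration",
)
SUS_N_ITEMS = 10


def simulate_questionnaires(
    n_subjects: int,
    condition_shifts: dict[str, float] | None = None,
    seed: int = 0,
    likert_max: int = 7,
) -> pd.DataFrame:
    """Simulate SUS / IMI / RTLX response tables for each condition.

    Returns a long table (participant, condition, instrument, subscale,
    item, value). Likert items are integers in 1..likert_max; RTLX sliders
    are integers in 0..100. ``condition_shifts`` adds a location shift (in
    item units for Likert instruments, slider units for RTLX) before
    clipping; values pushed out of range are clipped with a warning.
    """
    rng = np.random.default_rng(seed)
    shifts = condition_shifts or {}
    rows = []
    clipped = 0
    for i in range(n_subjects):
        pid = f"s{i + 1:02d}"
        subj_bias = rng.normal(0, 0.4)
        for cond in CONDITIONS:
            shift = shifts.get(cond, 0.0)
            for item in range(1, SUS_N_ITEMS + 1):
                v = rng.normal(5.5 + subj_bias + shift, 1.0)
                vi = int(np.clip(round(v), 1, likert_max))
                clipped += shift != 0 and vi != round(v)
                rows.append((pid, cond, "SUS", "usability", item, vi))
            for subscale, n_items in IMI_SUBSCALES.items():
                for item in range(1, n_items + 1):
                    v = rng.normal(5.0 + subj_bias + shift, 1.2)
                    vi = int(np.clip(round(v), 1, 7))
                    clipped += shift != 0 and vi != round(v)
                    rows.append((pid, cond, "IMI", subscale, item, vi))
            for subscale in RTLX_SUBSCALES:
                v = rng.normal(30 + 10 * subj_bias + shift, 18)
                vi = int(np.clip(round(v), 0, 100))
                clipped += shift != 0 and vi != round(v)
                rows.append((pid, cond, "RTLX", subscale, 1, vi))
    if clipped:
        warnings.warn(
            f"{clipped} questionnaire values pushed out of range by the "
            "condition shift were clipped"
        )
    return pd.DataFrame(
        rows, columns=["participant", "condition", "instrument", "subscale", "item", "value"]
    )


# ---------------------------------------------------------------------------
# Cell-level generator for statistical calibration studies


def simulate_cell_table(
    effect_config: dict[str, ConditionEffectModel] | None = None,
    n_subjects: int = 17,
    seed: int = 0,
    baseline: float = 3.0,
    subject_sd: float = 0.10,
    interaction_sd: float = 0.10,
    cell_noise_sd: float = 0.15,
    depth_duration_scale: dict | None = None,
) -> pd.DataFrame:
    """Generate per-participant 3x3 cell means of normalized duration (s/m).

    Draws directly from the same effect model the trajectory simulator uses
    (cell mean = baseline * condition scale * depth scale * subject effect,
    plus subject-by-condition and residual Gaussian noise), skipping the
    trajectory layer. This is the desk-scale input for type-I-error
    calibration and power studies of the repeated-measures harness.
    """
    effect_config = effect_config or DEFAULT_EFFECTS
    depth_scale = depth_duration_scale or DEFAULT_DEPTH_DURATION_SCALE
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subjects):
        pid = f"s{i + 1:02d}"
        subj = np.exp(rng.normal(0, subject_sd))
        cond_noise = {c: rng.normal(0, interaction_sd) for c in effect_config}
        for cond, eff in effect_config.items():
            for dc in DepthClass:
                value = (
                    baseline * eff.duration_scale * depth_scale[dc] * subj
                    + cond_noise[cond]
                    + rng.normal(0, cell_noise_sd)
                )
                rows.append((pid, cond, dc.value, value))
    return pd.DataFrame(rows, columns=["participant", "condition", "depth_class", "value"])
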