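"""Monte-Carlo studies of the statistical harness on synthetic cell tables.

These studies operate on the desk-scale cell-level generator
(:func:`vizreach.synthetic.simulate_cell_table`), which draws per-subject
3x3 cell means directly from the same effect model that drives the
trajectory simulator; full trajectory simulation is exercised separately
by the pipeline tests.
"""

from __future__ import annotations

import numpy as np

from .stats import rm_anova_2way
from .synthetic import DEFAULT_EFFECTS, NULL_EFFECTS, simulate_cell_table

__all__ = [
    "type1_error_rate",
    "detection_power",
    "ordering_recovery_rate",
]


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % 2**31


def type1_error_rate(
    n_reps: int = 1000,
    n_subjects: int = 17,
    alpha: float = 0.05,
    seed: int = 0,
    effect: str = "condition",
) -> float:
    """Rejection rate of the visualization effect under the null model.

    All conditions share one effect model, so any rejection is a false
    positive; a calibrated test rejects at about ``alpha``. The selected p
    (GG-corrected when Mauchly rejects) is used, as in the analysis.
    """
    rejections = 0
    for s in _child_seeds(seed, n_reps):
        table = simulate_cell_table(NULL_EFFECTS, n_subjects=n_subjects, seed=int(s))
        res = rm_anova_2way(table, alpha=alpha)
        rejections += res.effects[effect].p_selected < alpha
    return rejections / n_reps


def detection_power(
    n_reps: int = 200,
    n_subjects: int = 17,
    alpha: float = 0.05,
    seed: int = 0,
    effect: str = "condition",
) -> float:
    """Detection rate of the default HMD-vs-screen duration effect."""
    detections = 0
    for s in _child_seeds(seed, n_reps):
        table = simulate_cell_table(DEFAULT_EFFECTS, n_subjects=n_subjects, seed=int(s))
        res = rm_anova_2way(table, alpha=alpha)
        detections += res.effects[effect].p_selected < alpha
    return detections / n_reps


def ordering_recovery_rate(
    n_reps: int = 200,
    n_subjects: int = 17,
    seed: int = 0,
) -> float:
    """Fraction of simulations whose condition means order Screen > AR > IVR.

    The default effect model injects the longest normalized durations for
    the 2D screen and the shortest for IVR; recovery means the sample
    condition means (across subjects and depth cells) reproduce that
    ordering.
    """
    hits = 0
    for s in _child_seeds(seed, n_reps):
        table = simulate_cell_table(DEFAULT_EFFECTS, n_subjects=n_subjects, seed=int(s))
        means = table.groupby("condition")["value"].mean()
        hits += means["Screen"] > means["AR"] > means["IVR"]
    return hits / n_reps
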