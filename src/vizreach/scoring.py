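"""Dual-task counting scores and SUS / IMI / RTLX questionnaire scoring.

Counting uses carry-forward scoring: after an off-by-one error a response
is still credited if it continues correctly from the erroneous value —
e.g. if the expected count was three but the participant said four, both
four and five are accepted next for that category. The acceptance set for
every fruit is {true cumulative count, last said value + 1}, recomputed
fruit by fruit, so a participant may also recover to the true count at any
time (the most permissive reading consistent with the rule).
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountingBlock",
    "counting_truth_from_kinds",
    "score_counting_block",
    "aggregate_counting",
    "score_sus",
    "score_imi",
    "score_rtlx",
    "digitize_rtlx_paper",
    "score_questionnaires",
]


@dataclass(frozen=True)
class CountingBlock:
    """One block's truth and responses.

    ``fruits``: ordered (category, true cumulative count within the block);
    counting restarts from zero each block, so the first fruit of each
    category has true count 1. ``responses``: ordered (category said,
    number said), one per fruit.
    """

    fruits: tuple[tuple[str, int], ...]
    responses: tuple[tuple[str, int], ...]

    def __post_init__(self):
        seen: dict[str, int] = {}
        for cat, n in self.fruits:
            seen[cat] = seen.get(cat, 0) + 1
            if n != seen[cat]:
                raise ValueError(
                    f"true counts must increment per category from 1; got {cat}={n}"
                )


def counting_truth_from_kinds(kinds: Sequence[str]) -> list[tuple[str, int]]:
    """Cumulative per-category counts for an ordered fruit sequence."""
    seen: dict[str, int] = defaultdict(int)
    out = []
    for k in kinds:
        seen[k] += 1
        out.append((k, seen[k]))
    return out


def score_counting_block(block: CountingBlock) -> float:
    """Percentage of correctly counted fruits in one block.

    A response is correct iff the said category matches the presented fruit
    and the said number is in {true cumulative count, last said + 1} for
    that category. Saying the wrong category scores the presented fruit
    incorrect and does not advance the said category's counter.
    """
    if len(block.responses) != len(block.fruits):
        raise ValueError(
            f"{len(block.responses)} responses for {len(block.fruits)} fruits"
        )
    last_said: dict[str, int] = {}
    correct = 0
    for (cat, true_n), (said_cat, said_n) in zip(block.fruits, block.responses):
        accepted = {true_n}
        if cat in last_said:
            accepted.add(last_said[cat] + 1)
        if said_cat == cat and said_n in accepted:
            correct += 1
        if said_cat == cat:
            last_said[cat] = said_n
    return 100.0 * correct / len(block.fruits)


def aggregate_counting(block_scores: Sequence[float]) -> float:
    """Unweighted mean of per-block percentages (one value per participant)."""
    if len(block_scores) == 0:
        raise ValueError("need at least one block score")
    return float(np.mean(block_scores))


def score_sus(items: Sequence[float], scale_max: int = 7) -> float:
    """Single usability score: item mean rescaled from 1..scale_max to 0-100.

    The 7-point form is the default; the patient experiment used a 5-point
    form (``scale_max=5``).
    """
    items = np.asarray(items, dtype=float)
    if items.size == 0:
        raise ValueError("no items")
    if np.any(items < 1) or np.any(items > scale_max):
        raise ValueError(f"items must lie in [1, {scale_max}]")
    return float(100.0 * (items.mean() - 1.0) / (scale_max - 1.0))


def score_imi(items_by_subscale: Mapping[str, Sequence[float]]) -> dict[str, float]:
    """Per-subscale arithmetic mean on the native 1-7 scale (no rescaling)."""
    out = {}
    for subscale, items in items_by_subscale.items():
        items = np.asarray(items, dtype=float)
        if items.size == 0:
            raise ValueError(f"empty subscale {subscale!r}")
        if np.any(items < 1) or np.any(items > 7):
            raise ValueError(f"subscale {subscale!r}: items must lie in [1, 7]")
        out[subscale] = float(items.mean())
    return out


RTLX_SUBSCALES = (
    "mental_demand",
    "physical_demand",
    "temporal_demand",
    "performance",
    "effort",
    "frustration",
)


def score_rtlx(
    sliders: Sequence[float], with_mean: bool = False
) -> dict[str, float]:
    """Raw (unweighted) task-load index: the six 0-100 sliders pass through
    per subscale; the overall mean is an optional convenience."""
    sliders = np.asarray(sliders, dtype=float)
    if sliders.shape != (6,):
        raise ValueError("RTLX needs exactly six slider values")
    if np.any(sliders < 0) or np.any(sliders > 100):
        raise ValueError("slider values must lie in [0, 100]")
    out = dict(zip(RTLX_SUBSCALES, (float(v) for v in sliders)))
    if with_mean:
        out["mean"] = float(sliders.mean())
    return out


def digitize_rtlx_paper(distance_mm: float, scale_length_mm: float) -> float:
    """Convert a paper-form mark to a 0-100 value.

    The mark's distance from the left border is rounded to the nearest
    0.5 mm (half rounds up), divided by the physical scale length (which
    varies 122-125.5 mm with printing), and multiplied by 100.
    """
    if not 122.0 <= scale_length_mm <= 125.5:
        raise ValueError("scale length must lie in [122, 125.5] mm")
    if not 0.0 <= distance_mm <= scale_length_mm:
        raise ValueError("distance must lie within the scale")
    rounded = math.floor(distance_mm * 2.0 + 0.5) / 2.0
    return 100.0 * rounded / scale_length_mm


def score_questionnaires(responses: pd.DataFrame, sus_scale_max: int = 7) -> pd.DataFrame:
    """Score a long response table into participant x condition x subscale.

    Expects columns participant, condition, instrument (SUS/IMI/RTLX),
    subscale, item, value; returns rows (participant, condition,
    instrument, subscale, score).
    """
    rows = []
    for (pid, cond, instr), g in responses.groupby(
        ["participant", "condition", "instrument"], sort=False
    ):
        if instr == "SUS":
            rows.append((pid, cond, instr, "usability",
                         score_sus(g["value"].to_numpy(), scale_max=sus_scale_max)))
        elif instr == "IMI":
            by_sub = {s: sg["value"].to_numpy() for s, sg in g.groupby("subscale", sort=False)}
            for s, score in score_imi(by_sub).items():
                rows.append((pid, cond, instr, s, score))
        elif instr == "RTLX":
            vals = g.set_index("subscale")["value"]
            sliders = [float(vals[s]) for s in RTLX_SUBSCALES]
            for s, score in score_rtlx(sliders).items():
                rows.append((pid, cond, instr, s, score))
        else:
            raise ValueError(f"unknown instrument {instr!r}")
    return pd.DataFrame(
        rows, columns=["participant", "condition", "instrument", "subscale", "score"]
    )
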