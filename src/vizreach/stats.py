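"""Repeated-measures statistical harness with effect sizes and corrections.

The design is fully within-subject: every participant contributes a cell
mean for each visualization condition (IVR, AR, 2D screen), optionally
crossed with depth usage (no / only / combined). Provided tests:

* two-way 3x3 repeated-measures ANOVA with classical within-subject sums
  of squares, Mauchly's sphericity test per effect, Greenhouse-Geisser
  degrees-of-freedom correction, and partial eta squared
  (SS_effect / (SS_effect + SS_error));
* one-way repeated-measures MANOVA (Wilks' lambda on the within-subject
  contrast space, exact F for a single between-DV root);
* Friedman rank test with Kendall's W = chi2 / (n (k-1));
* Bonferroni-adjusted paired post-hoc t-tests with Cohen's d.

Sphericity quantities are computed on each effect's orthonormal contrast
space (main effects collapse the other factor first), the same convention
as afex / SPSS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.linalg import helmert

__all__ = [
    "EffectResult",
    "AnovaResult",
    "ManovaResult",
    "FriedmanResult",
    "PosthocResult",
    "aggregate_cells",
    "rm_anova_2way",
    "rm_anova_1way",
    "greenhouse_geisser_epsilon",
    "mauchly_test",
    "rm_manova_oneway",
    "friedman_kendall",
    "posthoc_paired",
    "partial_eta_squared",
]


@dataclass
class EffectResult:
    name: str
    df1: float
    df2: float
    ss_effect: float
    ss_error: float
    F: float
    p: float
    partial_eta_sq: float
    eps: float
    p_gg: float
    mauchly_W: float
    mauchly_p: float
    sphericity_violated: bool

    @property
    def p_selected(self) -> float:
        """GG-corrected p when Mauchly indicates a violation, else raw p."""
        return self.p_gg if self.sphericity_violated else self.p


@dataclass
class AnovaResult:
    effects: dict[str, EffectResult]
    alpha: float = 0.05

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.effects.values():
            rows.append(
                {
                    "effect": e.name, "df1": e.df1, "df2": e.df2, "F": e.F,
                    "p": e.p, "eps_gg": e.eps, "p_gg": e.p_gg,
                    "p_selected": e.p_selected, "partial_eta_sq": e.partial_eta_sq,
                    "mauchly_W": e.mauchly_W, "mauchly_p": e.mauchly_p,
                }
            )
        return pd.DataFrame(rows)


@dataclass
class ManovaResult:
    wilks_lambda: float
    F: float
    df1: float
    df2: float
    p: float
    partial_eta_sq: float
    n: int
    m: int
    effsize_convention: str = "partial eta^2 = 1 - lambda^(1/s), s = 1"


@dataclass
class FriedmanResult:
    chi_sq: float
    df: int
    p: float
    kendalls_W: float
    n: int
    k: int


@dataclass
class PosthocResult:
    pair: tuple[str, str]
    t: float
    df: int
    p_raw: float
    p_adjusted: float
    cohen_d: float
    d_convention: str = "dz"
    degenerate: bool = False


# ---------------------------------------------------------------------------


def partial_eta_squared(ss_effect: float, ss_error: float) -> float:
    """SS_effect / (SS_effect + SS_error)."""
    if ss_effect < 0 or ss_error < 0:
        raise ValueError("sums of squares must be non-negative")
    if ss_effect == 0 and ss_error == 0:
        raise ValueError("both sums of squares are zero")
    return ss_effect / (ss_effect + ss_error)


def aggregate_cells(
    metrics: pd.DataFrame,
    value_col: str,
    by: Sequence[str] = ("participant", "condition", "depth_class"),
    agg: str = "mean",
) -> pd.DataFrame:
    """Collapse segment-level metrics to one cell value per grouping key.

    Rows with a missing value (e.g. onset-absent segments) are excluded
    from that metric's cells only.
    """
    present = metrics[metrics[value_col].notna()]
    out = present.groupby(list(by), sort=False)[value_col].agg(agg).reset_index()
    return out.rename(columns={value_col: "value"})


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1, k) matrix with orthonormal rows, each orthogonal to ones."""
    return helmert(k, full=False)


def greenhouse_geisser_epsilon(cov: np.ndarray) -> float:
    """Box's epsilon from a k x k within-cell covariance matrix.

    Computed on the orthonormal contrast space and clipped to
    [1/(k-1), 1]; equals 1 under compound symmetry (sphericity).
    """
    cov = np.asarray(cov, dtype=float)
    k = cov.shape[0]
    if k < 2:
        raise ValueError("need at least 2 levels")
    C = _orthonormal_contrasts(k)
    return _epsilon_from_contrast_cov(C @ cov @ C.T)


def _epsilon_from_contrast_cov(M: np.ndarray) -> float:
    q = M.shape[0]
    tr = np.trace(M)
    tr2 = np.trace(M @ M)
    if tr2 <= 0:
        warnings.warn("degenerate contrast covariance; epsilon at lower bound")
        return 1.0 / q
    eps = tr**2 / (q * tr2)
    return float(np.clip(eps, 1.0 / q, 1.0))


def mauchly_test(scores: np.ndarray) -> tuple[float, float]:
    """Mauchly's sphericity test on orthonormal-contrast scores (n x q).

    Returns (W, p). With q = 1 sphericity holds trivially; with a singular
    covariance (too few subjects) W is 0 and p is reported as 0.
    """
    scores = np.asarray(scores, dtype=float)
    n, q = scores.shape
    if q <= 1:
        return 1.0, 1.0
    S = np.cov(scores, rowvar=False, ddof=1)
    det = np.linalg.det(S)
    mean_tr = np.trace(S) / q
    if det <= 0 or mean_tr <= 0:
        return 0.0, 0.0
    W = det / mean_tr**q
    d = 1.0 - (2 * q**2 + q + 2) / (6.0 * q * (n - 1))
    chi2 = -(n - 1) * d * np.log(W)
    df = q * (q + 1) // 2 - 1
    return float(W), float(sps.chi2.sf(chi2, df))


def _effect_stats(
    scores: np.ndarray, F: float, df1: float, df2: float, alpha: float
) -> tuple[float, float, float, float, bool]:
    """Sphericity quantities and GG-corrected p for one effect."""
    eps = _epsilon_from_contrast_cov(np.cov(scores, rowvar=False, ddof=1).reshape(
        scores.shape[1], scores.shape[1]))
    W, p_m = mauchly_test(scores)
    p_gg = float(sps.f.sf(F, eps * df1, eps * df2))
    return eps, p_gg, W, p_m, p_m < alpha


def _pivot_checked(
    table: pd.DataFrame, dv: str, within: Sequence[str], subject: str
) -> pd.DataFrame:
    """Wide subject x cell matrix; raise listing any missing cells."""
    wide = table.pivot_table(
        index=subject, columns=list(within), values=dv, aggfunc="mean", observed=True
    )
    if wide.isna().any().any():
        missing = [
            f"{s} x {c}" for s in wide.index for c in wide.columns
            if pd.isna(wide.loc[s, c])
        ]
        raise ValueError(f"missing cells: {', '.join(map(str, missing))}")
    return wide


def rm_anova_2way(
    table: pd.DataFrame,
    dv: str = "value",
    within: Sequence[str] = ("condition", "depth_class"),
    subject: str = "participant",
    alpha: float = 0.05,
) -> AnovaResult:
    """Two-way fully within-subject ANOVA (one value per cell).

    Classical sums-of-squares decomposition with each effect tested
    against its own effect-by-subject interaction; Greenhouse-Geisser
    correction is reported for every effect and selected when Mauchly's
    test rejects sphericity at ``alpha``.
    """
    fa, fb = within
    wide = _pivot_checked(table, dv, within, subject)
    a_levels = wide.columns.get_level_values(0).unique()
    b_levels = wide.columns.get_level_values(1).unique()
    a, b = len(a_levels), len(b_levels)
    n = wide.shape[0]
    if n < 3:
        raise ValueError("need at least 3 participants")
    Y = wide.to_numpy().reshape(n, a, b)

    m = Y.mean()
    m_s = Y.mean(axis=(1, 2))
    m_a = Y.mean(axis=(0, 2))
    m_b = Y.mean(axis=(0, 1))
    m_sa = Y.mean(axis=2)
    m_sb = Y.mean(axis=1)
    m_ab = Y.mean(axis=0)

    ss_a = n * b * np.sum((m_a - m) ** 2)
    ss_b = n * a * np.sum((m_b - m) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + m) ** 2)
    ss_as = b * np.sum((m_sa - m_a[None, :] - m_s[:, None] + m) ** 2)
    ss_bs = a * np.sum((m_sb - m_b[None, :] - m_s[:, None] + m) ** 2)
    resid = (
        Y
        - m_ab[None, :, :]
        - m_sa[:, :, None]
        - m_sb[:, None, :]
        + m_a[None, :, None]
        + m_b[None, None, :]
        + m_s[:, None, None]
        - m
    )
    ss_abs = np.sum(resid**2)

    Ca = _orthonormal_contrasts(a)
    Cb = _orthonormal_contrasts(b)
    specs = {
        fa: (ss_a, ss_as, a - 1, (a - 1) * (n - 1), m_sa @ Ca.T),
        fb: (ss_b, ss_bs, b - 1, (b - 1) * (n - 1), m_sb @ Cb.T),
        f"{fa}:{fb}": (
            ss_ab, ss_abs, (a - 1) * (b - 1), (a - 1) * (b - 1) * (n - 1),
            Y.reshape(n, a * b) @ np.kron(Ca, Cb).T,
        ),
    }
    effects = {}
    for name, (ss_e, ss_err, df1, df2, scores) in specs.items():
        F = (ss_e / df1) / (ss_err / df2) if ss_err > 0 else np.inf
        p = float(sps.f.sf(F, df1, df2))
        eps, p_gg, W, p_m, violated = _effect_stats(scores, F, df1, df2, alpha)
        effects[name] = EffectResult(
            name=name, df1=df1, df2=df2, ss_effect=float(ss_e),
            ss_error=float(ss_err), F=float(F), p=p,
            partial_eta_sq=partial_eta_squared(ss_e, ss_err),
            eps=eps, p_gg=p_gg, mauchly_W=W, mauchly_p=p_m,
            sphericity_violated=violated,
        )
    return AnovaResult(effects=effects, alpha=alpha)


def rm_anova_1way(
    table: pd.DataFrame,
    dv: str = "value",
    within: str = "condition",
    subject: str = "participant",
    alpha: float = 0.05,
) -> AnovaResult:
    """One-way within-subject ANOVA (used for the usability score)."""
    wide = _pivot_checked(table, dv, [within], subject)
    Y = wide.to_numpy()
    n, k = Y.shape
    if n < 2:
        raise ValueError("need at least 2 participants")
    m = Y.mean()
    m_s = Y.mean(axis=1)
    m_c = Y.mean(axis=0)
    ss_c = n * np.sum((m_c - m) ** 2)
    ss_err = np.sum((Y - m_s[:, None] - m_c[None, :] + m) ** 2)
    df1, df2 = k - 1, (k - 1) * (n - 1)
    F = (ss_c / df1) / (ss_err / df2) if ss_err > 0 else np.inf
    p = float(sps.f.sf(F, df1, df2))
    scores = Y @ _orthonormal_contrasts(k).T
    eps, p_gg, W, p_m, violated = _effect_stats(scores, F, df1, df2, alpha)
    eff = EffectResult(
        name=within, df1=df1, df2=df2, ss_effect=float(ss_c), ss_error=float(ss_err),
        F=float(F), p=p, partial_eta_sq=partial_eta_squared(ss_c, ss_err),
        eps=eps, p_gg=p_gg, mauchly_W=W, mauchly_p=p_m, sphericity_violated=violated,
    )
    return AnovaResult(effects={within: eff}, alpha=alpha)


def rm_manova_oneway(
    tables: dict[str, pd.DataFrame],
    dv: str = "value",
    within: str = "condition",
    subject: str = "participant",
) -> ManovaResult:
    """One-way repeated-measures MANOVA across several dependent variables.

    ``tables`` maps each DV name to a long table (participant, condition,
    value). All DVs must cover the same participants and conditions. The
    within-subject condition effect is tested jointly with Wilks' lambda on
    the stacked contrast scores; with a single root (one-sample structure)
    the F transformation is exact with (m, n - m) degrees of freedom,
    m = n_dvs x (k - 1).
    """
    if not tables:
        raise ValueError("need at least one dependent variable")
    wides = {}
    index = None
    cols = None
    for name, tbl in tables.items():
        w = _pivot_checked(tbl, dv, [within], subject)
        if index is None:
            index, cols = w.index, w.columns
        else:
            if not (w.index.equals(index) and w.columns.equals(cols)):
                w = w.reindex(index=index, columns=cols)
                if w.isna().any().any():
                    raise ValueError(f"DV {name!r}: participants/conditions mismatch")
        wides[name] = w
    k = len(cols)
    n = len(index)
    C = _orthonormal_contrasts(k)
    Yd = np.hstack([w.to_numpy() @ C.T for w in wides.values()])  # (n, m)
    m_dim = Yd.shape[1]
    if m_dim >= n:
        raise ValueError(
            f"{m_dim} contrast dimensions with only {n} participants: "
            "more DVs than error degrees of freedom"
        )
    ybar = Yd.mean(axis=0)
    Yc = Yd - ybar
    E = Yc.T @ Yc
    H = n * np.outer(ybar, ybar)
    if np.allclose(E + H, 0):  # all conditions identical per participant
        lam = 1.0
    else:
        lam = float(np.linalg.det(E) / np.linalg.det(E + H))
    df1, df2 = m_dim, n - m_dim
    F = (1 - lam) / lam * df2 / df1 if lam > 0 else np.inf
    p = float(sps.f.sf(F, df1, df2))
    return ManovaResult(
        wilks_lambda=lam, F=float(F), df1=df1, df2=df2, p=p,
        partial_eta_sq=1.0 - lam, n=n, m=m_dim,
    )


def friedman_kendall(wide: pd.DataFrame | np.ndarray) -> FriedmanResult:
    """Friedman rank test over a participants x conditions table.

    Mid-ranks for ties with the standard tie correction; Kendall's
    coefficient of concordance W = chi2 / (n (k - 1)). A table where every
    participant's values are all tied yields chi2 = 0, W = 0.
    """
    X = np.asarray(wide, dtype=float)
    n, k = X.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 participants and 2 conditions")
    if np.isnan(X).any():
        raise ValueError("missing cells")
    ranks = np.apply_along_axis(sps.rankdata, 1, X)
    ssbn = np.sum(ranks.sum(axis=0) ** 2)
    chisq = 12.0 / (n * k * (k + 1)) * ssbn - 3 * n * (k + 1)
    ties = 0.0
    for row in X:
        _, counts = np.unique(row, return_counts=True)
        ties += np.sum(counts**3 - counts)
    c = 1.0 - ties / (n * k * (k**2 - 1))
    chisq = 0.0 if c == 0 else chisq / c
    W = chisq / (n * (k - 1))
    return FriedmanResult(
        chi_sq=float(chisq), df=k - 1, p=float(sps.chi2.sf(chisq, k - 1)),
        kendalls_W=float(W), n=n, k=k,
    )


def posthoc_paired(
    wide: pd.DataFrame,
    pairs: Sequence[tuple[str, str]] | None = None,
    m_comparisons: int | None = None,
    d_convention: str = "dz",
) -> list[PosthocResult]:
    """Bonferroni-adjusted paired t-tests over columns of a wide table.

    p_adjusted = min(1, m * p_raw) with m = ``m_comparisons`` (default: the
    number of pairs). Cohen's d defaults to d_z = mean(diff) / sd(diff);
    ``d_convention='dav'`` divides by the mean of the two sds instead.
    Zero-variance differences are flagged degenerate (|t| infinite when the
    means differ).
    """
    if d_convention not in ("dz", "dav"):
        raise ValueError("d_convention must be 'dz' or 'dav'")
    if pairs is None:
        pairs = list(combinations(wide.columns, 2))
    if m_comparisons is None:
        m_comparisons = len(pairs)
    out = []
    for x_name, y_name in pairs:
        x = wide[x_name].to_numpy(dtype=float)
        y = wide[y_name].to_numpy(dtype=float)
        if len(x) < 2:
            raise ValueError("need at least 2 paired samples")
        d = x - y
        md = d.mean()
        sd = d.std(ddof=1)
        n = len(d)
        if sd == 0:
            degenerate = True
            t = 0.0 if md == 0 else float(np.sign(md) * np.inf)
            p_raw = 1.0 if md == 0 else 0.0
            cd = 0.0 if md == 0 else float(np.sign(md) * np.inf)
        else:
            degenerate = False
            t = float(md / (sd / np.sqrt(n)))
            p_raw = float(2 * sps.t.sf(abs(t), n - 1))
            if d_convention == "dz":
                cd = float(md / sd)
            else:
                cd = float(md / ((x.std(ddof=1) + y.std(ddof=1)) / 2))
        out.append(
            PosthocResult(
                pair=(str(x_name), str(y_name)), t=t, df=n - 1, p_raw=p_raw,
                p_adjusted=min(1.0, m_comparisons * p_raw), cohen_d=cd,
                d_convention=d_convention, degenerate=degenerate,
            )
        )
    return out
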