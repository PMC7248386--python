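"""Pre/post-fatigue statistical battery.

Individual-level rank tests with Bonferroni control, a permutation paired
Hotelling T^2 gate for group comparisons, signed-rank group tests, Cohen's
d effect sizes on the Sawilowsky verbal scale, Spearman correlation
matrices, and population-level summary percentages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "bonferroni_threshold",
    "mann_whitney",
    "hotelling_t2_paired",
    "wilcoxon_group",
    "cohens_d",
    "EFFECT_SIZE_SCALE",
    "spearman_matrix",
    "summarize_population",
    "ParameterResult",
    "ComparisonReport",
    "PARAMETER_CATEGORIES",
    "FAMILY_SIZES",
]

# verbal magnitude scale for |d|: label of the largest point <= |d|
EFFECT_SIZE_SCALE = (
    (0.01, "very small"),
    (0.20, "small"),
    (0.50, "medium"),
    (0.80, "large"),
    (1.20, "very large"),
    (2.00, "huge"),
)

PARAMETER_CATEGORIES: dict[str, tuple[str, ...]] = {
    "central": ("t0", "delta_t0", "D", "theta_s", "theta_e",
                "abs_cos_theta_s", "abs_cos_theta_e"),
    "peripheral": ("mu", "sigma"),
    "motor_program": ("mode", "median", "time_delay", "response_time", "asymmetry"),
    "global_state": ("nblog", "snr", "snr_per_nblog"),
    "reaction": ("rt",),
    "conduction": ("conduction",),
}

# per-parameter family sizes for Bonferroni control
FAMILY_SIZES = {
    ("individual", "simple"): 16,
    ("individual", "triangle"): 16,
    ("individual", "h_osc"): 12,
    ("individual", "v_osc"): 12,
    ("group", "simple"): 13,
    ("group", "triangle"): 13,
    ("group", "h_osc"): 12,
    ("group", "v_osc"): 12,
}


@dataclass
class ParameterResult:
    parameter: str
    p_value: float
    significant: bool
    d: float | None = None
    magnitude: str | None = None
    n_pre: int = 0
    n_post: int = 0


@dataclass
class ComparisonReport:
    """Per-parameter pre/post comparison for one test x fatigue type."""

    level: str                    # "individual" | "group"
    test_type: str
    fatigue_type: str
    role: str | None = None
    alpha: float = 0.05
    family_size: int = 1
    multivariate_p: float | None = None
    parameters: dict[str, ParameterResult] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    @property
    def threshold(self) -> float:
        return bonferroni_threshold(self.alpha, self.family_size)

    def category_flags(self) -> dict[str, bool]:
        """Significance flags aggregated into parameter categories."""
        flags = {}
        for category, members in PARAMETER_CATEGORIES.items():
            flags[category] = any(
                r.significant for name, r in self.parameters.items() if name in members
            )
        flags["both"] = flags["central"] and flags["peripheral"]
        return flags

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "test_type": self.test_type,
            "fatigue_type": self.fatigue_type,
            "role": self.role,
            "alpha": self.alpha,
            "family_size": self.family_size,
            "threshold": self.threshold,
            "multivariate_p": self.multivariate_p,
            "parameters": {
                k: {"p_value": r.p_value, "significant": r.significant,
                    "d": r.d, "magnitude": r.magnitude,
                    "n_pre": r.n_pre, "n_post": r.n_post}
                for k, r in self.parameters.items()
            },
            "categories": self.category_flags(),
            "metadata": self.metadata,
        }


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-comparison threshold alpha/m."""
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if m < 1:
        raise ValueError(f"family size must be >= 1, got {m}")
    return alpha / m


def mann_whitney(pre: Sequence[float], post: Sequence[float]) -> tuple[float, float]:
    """Two-sample Mann-Whitney U, two-sided.

    Exact enumeration when both samples have n <= 8 and no ties are
    present; otherwise the tie-corrected normal approximation (without
    continuity correction, so identical samples give p = 1 exactly).
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.size < 2 or post.size < 2:
        raise ValueError("both samples need at least two observations")
    pooled = np.concatenate([pre, post])
    has_ties = np.unique(pooled).size < pooled.size
    if pre.size <= 8 and post.size <= 8 and not has_ties:
        res = sps.mannwhitneyu(pre, post, alternative="two-sided", method="exact")
    else:
        res = sps.mannwhitneyu(pre, post, alternative="two-sided",
                               method="asymptotic", use_continuity=False)
    return float(res.statistic), min(1.0, float(res.pvalue))


def hotelling_t2_paired(
    pre: np.ndarray,
    post: np.ndarray,
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Permutation paired Hotelling T^2 on matched participant rows.

    The null distribution is built by random sign flips of the
    per-participant difference rows; p = (1 + #{T* >= T}) / (1 + n_perm).
    Rows with missing cells are dropped first.  When n <= n_params the
    covariance is shrunk toward its diagonal (with a warning recorded in
    the returned statistic being still well defined).
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape or pre.ndim != 2:
        raise ValueError("pre and post must be matching 2-D participant x parameter arrays")
    if pre.shape[1] < 2:
        raise ValueError("at least two parameters are required")
    keep = np.isfinite(pre).all(axis=1) & np.isfinite(post).all(axis=1)
    diffs = (post - pre)[keep]
    n, k = diffs.shape
    if n < 2:
        raise ValueError("need at least two complete participant rows")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    # The Gram matrix G = sum_i d_i d_i^T is invariant under sign flips, so
    # the flipped covariance is S* = (G - n m* m*^T)/(n-1) and
    # T*^2 = n q / (1 - q n/(n-1)) with q = m*^T (G/(n-1))^{-1} m*,
    # which makes the whole permutation null a single matrix product.
    gram = diffs.T @ diffs
    a = gram / (n - 1)
    if n <= k:  # shrink toward the diagonal when the covariance is rank-deficient
        a = 0.9 * a + 0.1 * np.diag(np.diag(a))
    a = a + 1e-12 * np.trace(a) / k * np.eye(k)
    a_inv = np.linalg.pinv(a)
    c = n / (n - 1)

    def t2_of_means(means: np.ndarray) -> np.ndarray:
        q = np.einsum("pi,ij,pj->p", means, a_inv, means)
        denom = 1.0 - c * q
        out = np.where(denom > 1e-12, n * q / np.where(denom > 1e-12, denom, 1.0),
                       np.inf)
        return out

    observed = float(t2_of_means(diffs.mean(axis=0)[None, :])[0])
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    perm_means = signs @ diffs / n
    perm_stats = t2_of_means(perm_means)
    exceed = int(np.sum(perm_stats >= observed - 1e-12))
    return observed, (1 + exceed) / (1 + n_perm)


def wilcoxon_group(pre: Sequence[float], post: Sequence[float]) -> float:
    """Paired Wilcoxon signed-rank test on participant means, two-sided.

    Exact for n <= 25 when there are no zero differences or tied absolute
    differences; returns p = 1 when every difference is zero.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must be matched")
    if pre.size < 6:
        raise ValueError("need at least 6 matched pairs")
    diffs = post - pre
    if np.all(diffs == 0):
        return 1.0
    nonzero = diffs[diffs != 0]
    tied = np.unique(np.abs(nonzero)).size < nonzero.size
    method = "exact" if (nonzero.size <= 25 and not tied and nonzero.size == diffs.size) else "approx"
    res = sps.wilcoxon(pre, post, alternative="two-sided", method=method)
    return float(res.pvalue)


def cohens_d(pre: Sequence[float], post: Sequence[float]) -> tuple[float, str]:
    """Cohen's d (post minus pre over pooled SD) with its verbal magnitude."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.size < 2 or post.size < 2:
        raise ValueError("both samples need at least two observations")
    pooled_var = (
        (pre.size - 1) * pre.var(ddof=1) + (post.size - 1) * post.var(ddof=1)
    ) / (pre.size + post.size - 2)
    if pooled_var <= 0:
        raise ValueError("pooled SD is zero; d is undefined")
    d = float((post.mean() - pre.mean()) / math.sqrt(pooled_var))
    return d, effect_size_label(d)


def effect_size_label(d: float) -> str:
    label = "very small"
    for point, name in EFFECT_SIZE_SCALE:
        if abs(d) >= point:
            label = name
    return label


def spearman_matrix(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman rank correlations between every pair of columns.

    Requires at least 4 paired observations per cell; constant columns
    yield NaN entries (flagged as undefined rather than raised).
    """
    cols = list(table.columns)
    rho = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    pval = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j, b in enumerate(cols):
            if j <= i:
                continue
            paired = table[[a, b]].dropna()
            if len(paired) < 4 or paired[a].nunique() < 2 or paired[b].nunique() < 2:
                r = p = float("nan")
            else:
                r, p = sps.spearmanr(paired[a], paired[b])
            rho.loc[a, b] = rho.loc[b, a] = r
            pval.loc[a, b] = pval.loc[b, a] = p
    return rho, pval


def summarize_population(
    reports: Sequence[ComparisonReport],
    n_participants: int | None = None,
) -> pd.DataFrame:
    """Population summary: % of participants affected per category and role.

    ``reports`` are individual-level reports carrying
    ``metadata['participant']`` and a role.  For each test x fatigue x
    role, the percentage of participants with at least one significant
    parameter in each category is reported; a ``Total`` row counts a
    participant once it is significant in any role of that test.
    """
    rows = []
    for rep in reports:
        if rep.level != "individual":
            raise ValueError("summarize_population expects individual-level reports")
        flags = rep.category_flags()
        rows.append({
            "participant": rep.metadata.get("participant"),
            "test_type": rep.test_type,
            "fatigue_type": rep.fatigue_type,
            "role": rep.role,
            **flags,
        })
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    categories = list(PARAMETER_CATEGORIES) + ["both"]
    n = n_participants or df["participant"].nunique()
    out = []
    for (test, fatigue), sub in df.groupby(["test_type", "fatigue_type"], sort=False):
        for role, role_sub in sub.groupby("role", sort=False):
            pct = {c: 100.0 * role_sub.groupby("participant")[c].any().sum() / n
                   for c in categories}
            out.append({"test_type": test, "fatigue_type": fatigue, "role": role, **pct})
        total = {c: 100.0 * sub.groupby("participant")[c].any().sum() / n
                 for c in categories}
        out.append({"test_type": test, "fatigue_type": fatigue, "role": "Total", **total})
    return pd.DataFrame(out)
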