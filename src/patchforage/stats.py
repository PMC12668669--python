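"""Preference indices, cohort tests, effect sizes and compositional analysis.

The reporting layer of the analysis: per-plate two-choice preference indices
with one-sample t statistics and 95% CIs, one-way ANOVA with eta squared,
Welch-corrected two-sample comparisons, Mann-Whitney with rank-biserial
correlation, the isometric log-ratio (ILR) transform for state-probability
compositions, and the extreme-outlier box-plot rule.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

SQRT_2_3 = np.sqrt(2.0 / 3.0)
SQRT_1_2 = np.sqrt(0.5)


# ---------------------------------------------------------------------------
# Preference index
# ---------------------------------------------------------------------------

def preference_index(n_N, n_L) -> float:
    """Two-choice preference index I = (n_N - n_L) / (n_N + n_L).

    Positive values indicate preference for the normal-bacteria arm,
    negative for the elongated-bacteria arm; bounded in [-1, 1] and
    antisymmetric under swapping arms.
    """
    n_N, n_L = float(n_N), float(n_L)
    if n_N < 0 or n_L < 0:
        raise ValueError("counts must be non-negative")
    if n_N + n_L == 0:
        raise ValueError("plate has no countable worms")
    return (n_N - n_L) / (n_N + n_L)


def plate_indices(plates: pd.DataFrame) -> pd.Series:
    """Per-plate preference indices; plates with zero countable worms are
    excluded and logged."""
    total = plates["n_normal"] + plates["n_elongated"]
    empty = total == 0
    if empty.any():
        logger.warning("excluding %d plate(s) with zero countable worms",
                       int(empty.sum()))
    ok = plates[~empty]
    return (ok["n_normal"] - ok["n_elongated"]) / (
        ok["n_normal"] + ok["n_elongated"]
    )


@dataclass(frozen=True)
class PreferenceSummary:
    """Cohort summary of per-plate preference indices."""

    indices: np.ndarray
    mean: float
    ci_low: float
    ci_high: float
    t: float
    df: int
    p: float
    n: int

    def __str__(self) -> str:
        return (
            f"I = {self.mean:+.3f} [95% CI {self.ci_low:+.3f}, {self.ci_high:+.3f}]"
            f"  t({self.df}) = {self.t:.3f}, p = {self.p:.3g}, n = {self.n} plates"
        )


def summarize_preference(plates) -> PreferenceSummary:
    """Mean preference index with one-sample t test against zero and 95% CI.

    ``plates`` is either a plate-count table (columns n_normal, n_elongated)
    or a sequence of per-plate indices.  Requires at least two scorable
    plates for the CI.
    """
    if isinstance(plates, pd.DataFrame):
        idx = plate_indices(plates).to_numpy(float)
    else:
        idx = np.asarray(plates, float)
    n = len(idx)
    if n < 2:
        raise ValueError("need at least two scorable plates")
    mean = float(idx.mean())
    sd = float(idx.std(ddof=1))
    se = sd / np.sqrt(n)
    if se == 0.0:
        t_stat, p = 0.0, 1.0
        ci = (mean, mean)
    else:
        t_stat = mean / se
        p = float(2.0 * sps.t.sf(abs(t_stat), n - 1))
        half = float(sps.t.ppf(0.975, n - 1)) * se
        ci = (mean - half, mean + half)
    return PreferenceSummary(idx, mean, ci[0], ci[1], float(t_stat), n - 1, p, n)


# ---------------------------------------------------------------------------
# ANOVA and effect sizes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    eta_squared: float
    ss_between: float
    ss_within: float
    ss_total: float


def oneway_anova(groups) -> AnovaResult:
    """One-way ANOVA with eta squared = SS_between / SS_total.

    The sum-of-squares decomposition is computed explicitly because the
    effect size is defined on it.  Groups with zero variance are allowed;
    when every value is identical overall, F = 0.
    """
    arrays = [np.asarray(g, float) for g in groups]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise ValueError("need >=2 groups with >=2 values each")
    grand = np.concatenate(arrays)
    gm = grand.mean()
    ss_between = sum(len(a) * (a.mean() - gm) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    ss_total = ((grand - gm) ** 2).sum()
    df_b = len(arrays) - 1
    df_w = len(grand) - len(arrays)
    if ss_within == 0.0:
        F = 0.0 if ss_between == 0.0 else float("inf")
    else:
        F = (ss_between / df_b) / (ss_within / df_w)
    p = float(sps.f.sf(F, df_b, df_w)) if np.isfinite(F) else 0.0
    eta2 = ss_between / ss_total if ss_total > 0 else 0.0
    return AnovaResult(float(F), df_b, df_w, p, float(eta2),
                       float(ss_between), float(ss_within), float(ss_total))


def cohens_d(x, y) -> float:
    """Cohen's d with pooled standard deviation."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("need >=2 values per group")
    pooled = np.sqrt(
        ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    )
    if pooled == 0.0:
        return 0.0
    return float((x.mean() - y.mean()) / pooled)


def rank_biserial(U: float, n1: int, n2: int) -> float:
    """Rank-biserial correlation r = 2U/(n1 n2) - 1 from a Mann-Whitney U."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    return 2.0 * U / (n1 * n2) - 1.0


def mannwhitney(x, y) -> tuple[float, float, float]:
    """Mann-Whitney U test with rank-biserial effect size: (U, p, r)."""
    res = sps.mannwhitneyu(x, y, alternative="two-sided")
    return float(res.statistic), float(res.pvalue), rank_biserial(
        float(res.statistic), len(x), len(y)
    )


def eta_squared(ss_effect: float, ss_total: float) -> float:
    """Eta squared = SS_effect / SS_total."""
    if ss_total <= 0:
        raise ValueError("SS_total must be positive")
    return ss_effect / ss_total


def partial_eta_squared(ss_effect: float, ss_error: float) -> float:
    """Partial eta squared = SS_effect / (SS_effect + SS_error)."""
    denom = ss_effect + ss_error
    if denom <= 0:
        raise ValueError("SS_effect + SS_error must be positive")
    return ss_effect / denom


def welch_ttest(x, y) -> tuple[float, float, float, float]:
    """Welch two-sample t test: (t, df, p, Cohen's d).

    The Welch-Satterthwaite df is fractional, matching reports such as
    df = 123.57 for unequal-variance worm cohorts.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    res = sps.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue), cohens_d(x, y)


def tukey_pairwise(groups: dict) -> pd.DataFrame:
    """Tukey HSD over all group pairs; critical values computed, not tabulated."""
    names = list(groups)
    res = sps.tukey_hsd(*[np.asarray(groups[k], float) for k in names])
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            rows.append({
                "group_a": names[i], "group_b": names[j],
                "statistic": res.statistic[i, j], "p": res.pvalue[i, j],
            })
    return pd.DataFrame(rows)


def dunnett_vs_control(control, treatments: dict) -> pd.DataFrame:
    """Dunnett many-to-one comparisons against a control group."""
    names = list(treatments)
    res = sps.dunnett(*[np.asarray(treatments[k], float) for k in names],
                      control=np.asarray(control, float))
    return pd.DataFrame({
        "group": names,
        "statistic": res.statistic,
        "p": res.pvalue,
    })


# ---------------------------------------------------------------------------
# Compositional analysis (ILR)
# ---------------------------------------------------------------------------

def multiplicative_replacement(comp, eps: float) -> np.ndarray:
    """Replace zero components with ``eps``, shrinking the rest to keep sum 1.

    ``eps`` should be half the smallest observable nonzero fraction (one
    frame over the total frame count for state probabilities).
    """
    comp = np.asarray(comp, float)
    if np.any(comp < 0):
        raise ValueError("composition components must be non-negative")
    zeros = comp == 0.0
    if not zeros.any():
        return comp
    if zeros.all():
        raise ValueError("composition is entirely zero")
    out = comp * (1.0 - zeros.sum() * eps)
    out[zeros] = eps
    return out / out.sum()


def ilr_transform(P_F: float, P_B: float, P_O: float) -> tuple[float, float]:
    """Isometric log-ratio coordinates with the partition {F} | {B, O}.

    z1 = sqrt(2/3) * ln(P_F / sqrt(P_B * P_O)) contrasts time on food
    against the border and off-food states; z2 = sqrt(1/2) * ln(P_B / P_O)
    contrasts border against off food.  Components must be strictly
    positive (apply ``multiplicative_replacement`` first) and sum to 1.
    """
    comp = np.array([P_F, P_B, P_O], float)
    if np.any(comp <= 0.0):
        raise ValueError(
            "ILR requires strictly positive components; replace zeros first"
        )
    if abs(comp.sum() - 1.0) > 1e-6:
        raise ValueError("components must sum to 1")
    z1 = SQRT_2_3 * np.log(P_F / np.sqrt(P_B * P_O))
    z2 = SQRT_1_2 * np.log(P_B / P_O)
    return float(z1), float(z2)


def ilr_inverse(z1: float, z2: float) -> tuple[float, float, float]:
    """Inverse ILR: coordinates back to a composition summing to 1."""
    # orthonormal balance basis in clr space for the {F}|{B,O}, {B}|{O} partition
    e1 = SQRT_2_3 * np.array([1.0, -0.5, -0.5])
    e2 = SQRT_1_2 * np.array([0.0, 1.0, -1.0])
    clr = z1 * e1 + z2 * e2
    comp = np.exp(clr - clr.max())
    comp = comp / comp.sum()
    return float(comp[0]), float(comp[1]), float(comp[2])


def aitchison_distance(p, q) -> float:
    """Aitchison distance: Euclidean distance between ILR images."""
    zp = np.array(ilr_transform(*np.asarray(p, float)))
    zq = np.array(ilr_transform(*np.asarray(q, float)))
    return float(np.linalg.norm(zp - zq))


# ---------------------------------------------------------------------------
# Outlier rule
# ---------------------------------------------------------------------------

def flag_outliers(values, k: float = 3.0) -> np.ndarray:
    """Extreme-outlier box-plot rule: outside [Q1 - k*IQR, Q3 + k*IQR].

    With an IQR of zero every value off the quartile point is flagged.
    Returns a boolean mask (True = outlier).
    """
    values = np.asarray(values, float)
    if len(values) < 4:
        raise ValueError("need at least 4 values for quartiles")
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    return (values < q1 - k * iqr) | (values > q3 + k * iqr)


# ---------------------------------------------------------------------------
# Report table
# ---------------------------------------------------------------------------

def statistics_report(rows: list[dict]) -> pd.DataFrame:
    """Assemble a report table with the standard columns (test, statistic,
    df, p, effect-size metric and value)."""
    cols = ["test", "comparison", "statistic", "value", "df", "p",
            "effect_size_metric", "effect_size"]
    return pd.DataFrame(rows, columns=cols)
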