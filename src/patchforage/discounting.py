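"""Effort-discounting model: discount factors and indifference-point prediction.

At an indifference point the two options have equal perceived value:
V(E) = d(E) * V0, where V0 is the undiscounted (easy-option) value, V(E)
the value of the effortful option at indifference, and d(E) in [0, 1] the
discount factor for effort level E.  Perceived value is assumed linear in
bacterial optical density (OD) with zero intercept, so OD substitutes for
value and the slope cancels from every ratio.  Assuming d(E) independent of
V0, new indifference points follow from a single measured one: any OD pair
in the ratio d : 1 is predicted to be an indifference point.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd


def discount_factor(v_indiff: float, v0: float) -> float:
    """Discount factor d(E) = V(E) / V0 from a measured indifference point.

    ``v_indiff`` is the value (or OD) of the easy option at indifference and
    ``v0`` the value (or OD) of the effortful option.  E.g. indifference
    between normal food at OD 1.0 and elongated food at OD 1.5 gives
    d = 2/3; $20 now vs $80 with effort gives d = 1/4.
    """
    if v0 <= 0:
        raise ValueError("v0 must be positive")
    if not 0 <= v_indiff <= v0:
        raise ValueError("require 0 <= v_indiff <= v0 so that 0 <= d <= 1")
    return v_indiff / v0


def predict_indifference(v0: float, d: float) -> float:
    """Predicted indifference value V = d * V0; inverse of discount_factor.

    With d = 2/3: V0 = OD 3 predicts indifference at OD 2, and V0 = OD 0.75
    predicts indifference at OD 0.5.
    """
    if v0 <= 0:
        raise ValueError("v0 must be positive")
    if not 0 <= d <= 1:
        raise ValueError("d must lie in [0, 1]")
    return d * v0


@dataclass(frozen=True)
class ChoiceLink:
    """Link from discounted values to expected preference.

    ``matching`` sets P(normal) to the normal option's share of total value
    (Herrnstein matching); ``logistic`` is a softmax in the value difference
    with sensitivity beta.  Either link yields zero expected preference at
    equal discounted values, for any beta.
    """

    form: str = "matching"
    beta: float = 1.0

    def __post_init__(self) -> None:
        if self.form not in ("matching", "logistic"):
            raise ValueError("link form must be 'matching' or 'logistic'")
        if self.beta <= 0:
            raise ValueError("beta must be positive")

    def p_normal(self, v_normal: float, v_elongated: float) -> float:
        if self.form == "matching":
            total = v_normal + v_elongated
            if total == 0:
                raise ValueError("both discounted values are zero")
            return v_normal / total
        return 1.0 / (1.0 + math.exp(-self.beta * (v_normal - v_elongated)))


@dataclass(frozen=True)
class EffortDiscountModel:
    """Economic model of two-patch choice under effort discounting.

    Parameters
    ----------
    d : float
        Discount factor for the (fixed) effort level of the elongated
        option, in [0, 1].
    value_slope : float
        Perceived value per OD unit (linear, zero intercept); cancels in
        every ratio and preference computation but is kept explicit.
    effort_label : str
        Opaque identifier of the effort manipulation the factor refers to.
    link : ChoiceLink
        Micro-to-macro link used by :meth:`expected_preference`.
    """

    d: float
    value_slope: float = 1.0
    effort_label: str = "cephalexin-450uM-2h"
    link: ChoiceLink = ChoiceLink()

    def __post_init__(self) -> None:
        if not 0 <= self.d <= 1:
            raise ValueError("d must lie in [0, 1]")
        if self.value_slope <= 0:
            raise ValueError("value_slope must be positive")

    @classmethod
    def from_indifference(cls, v_indiff: float, v0: float, **kwargs) -> "EffortDiscountModel":
        """Build the model from one measured indifference pair (easy, effortful)."""
        return cls(d=discount_factor(v_indiff, v0), **kwargs)

    def predict_indifference(self, v0: float) -> float:
        """Indifference value of the easy option when the effortful option is v0."""
        return predict_indifference(v0, self.d)

    def expected_preference(self, od_normal: float, od_elongated: float) -> float:
        """Expected preference index I for a given OD pair."""
        return expected_preference(od_normal, od_elongated, self, self.link)

    def report(self, v0_grid: Sequence[float] = (0.75, 1.5, 3.0)) -> str:
        lines = [
            "Effort-discounting model",
            f"  effort: {self.effort_label}",
            f"  discount factor d = {self.d:.6g}",
            "  predicted indifference points (elongated OD -> normal OD):",
        ]
        for v0 in v0_grid:
            lines.append(f"    OD {v0:g} -> OD {self.predict_indifference(v0):g}")
        return "\n".join(lines)


def expected_preference(
    od_normal: float,
    od_elongated: float,
    model: EffortDiscountModel,
    link: ChoiceLink | None = None,
) -> float:
    """Expected preference index I = 2 P(normal) - 1 for an OD pair.

    The normal option carries value slope * od_normal and the elongated one
    d * slope * od_elongated; I is exactly zero whenever the discounted
    values are equal (the indifference structure), positive iff
    od_normal > d * od_elongated.
    """
    if od_normal < 0 or od_elongated < 0:
        raise ValueError("ODs must be non-negative")
    if od_normal == 0 and od_elongated == 0:
        raise ValueError("both ODs are zero: preference undefined")
    link = link or model.link
    v_n = model.value_slope * od_normal
    v_e = model.d * model.value_slope * od_elongated
    if v_n == v_e:
        return 0.0
    return 2.0 * link.p_normal(v_n, v_e) - 1.0


@dataclass(frozen=True)
class IndifferenceEstimate:
    """Indifference OD estimated from a measured preference curve.

    ``od_ci_rule``: the condition whose 95% CI contains zero (the criterion
    used to declare indifference experimentally); None when no condition
    qualifies or CIs are not given.  ``od_crossing``: zero crossing of the
    piecewise-linear interpolation of mean I against OD; None with a flag
    when every mean has the same sign.
    """

    od_ci_rule: float | None
    od_crossing: float | None
    no_indifference_in_range: bool = False


def estimate_indifference_od(curve) -> IndifferenceEstimate:
    """Estimate the indifference OD from (od_elongated, mean I[, CI]) points.

    ``curve`` is a DataFrame with columns ``od``, ``mean`` and optionally
    ``ci_low``/``ci_high``, or an iterable of (od, mean) / (od, mean,
    ci_low, ci_high) tuples, covering at least two distinct ODs.
    """
    if isinstance(curve, pd.DataFrame):
        df = curve.copy()
    else:
        rows = [list(r) for r in curve]
        cols = ["od", "mean", "ci_low", "ci_high"][: len(rows[0])]
        df = pd.DataFrame(rows, columns=cols)
    if df["od"].nunique() < 2:
        raise ValueError("need at least two distinct OD conditions")
    df = df.sort_values("od").reset_index(drop=True)

    od_ci = None
    if {"ci_low", "ci_high"}.issubset(df.columns):
        hit = df[(df["ci_low"] <= 0) & (df["ci_high"] >= 0)]
        if len(hit):
            # nearest-to-zero mean among qualifying conditions
            od_ci = float(hit.loc[hit["mean"].abs().idxmin(), "od"])

    od = df["od"].to_numpy(float)
    m = df["mean"].to_numpy(float)
    crossing = None
    exact = np.flatnonzero(m == 0.0)
    if len(exact):
        crossing = float(od[exact[0]])
    else:
        sign_change = np.flatnonzero(np.sign(m[:-1]) * np.sign(m[1:]) < 0)
        if len(sign_change):
            i = sign_change[0]
            frac = m[i] / (m[i] - m[i + 1])
            crossing = float(od[i] + frac * (od[i + 1] - od[i]))

    no_indiff = crossing is None and od_ci is None
    return IndifferenceEstimate(od_ci, crossing, no_indiff)


# ---------------------------------------------------------------------------
# Conventional discount-function catalog (unfitted: effort is never
# quantified in the assay, so these map a nominal effort scalar to d)
# ---------------------------------------------------------------------------

def linear_discount(E: float, k: float) -> float:
    """d(E) = max(0, 1 - k E)."""
    return max(0.0, 1.0 - k * E)


def hyperbolic_discount(E: float, k: float) -> float:
    """d(E) = 1 / (1 + k E)."""
    return 1.0 / (1.0 + k * E)


def exponential_discount(E: float, k: float) -> float:
    """d(E) = exp(-k E)."""
    return math.exp(-k * E)


DISCOUNT_FORMS: dict[str, Callable[[float, float], float]] = {
    "linear": linear_discount,
    "hyperbolic": hyperbolic_discount,
    "exponential": exponential_discount,
}
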