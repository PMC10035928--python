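"""Statistical layer: two-sample KS tests, Pearson correlation matrices,
intraclass correlation reliability, BMI classification and group contrasts.

Conventions follow common practice in surface-topography validation studies:
curvature and coordinate distributions are compared with the two-sample
Kolmogorov-Smirnov test at alpha = 0.05; subject-level metrics are related to
demographics through a Pearson correlation matrix (gender coded Female = 1,
Male = 2, i.e. a point-biserial correlation); observer reliability is
quantified with ICC(2,1) — two-way random effects, absolute agreement,
single measures — where a value above 0.81 denotes almost perfect agreement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats as sps

ALPHA_DEFAULT = 0.05

#: BMI class boundaries in kg/m^2: below 18.5 underweight, 18.5 inclusive to
#: below 25 healthy, 25 inclusive and above overweight (cohorts modelled here
#: do not extend into the obese range).
BMI_UNDERWEIGHT_UPPER = 18.5
BMI_HEALTHY_UPPER = 25.0

BmiClass = Literal["underweight", "healthy", "overweight"]


# ---------------------------------------------------------------------------
# BMI
# ---------------------------------------------------------------------------

def bmi_and_class(weight_kg: float, height_m: float) -> tuple[float, BmiClass]:
    """Body mass index weight/height^2 and its weight-status class.

    Boundaries are inclusive upward: 18.5 is healthy, 25.0 is overweight.
    """
    if weight_kg <= 0 or height_m <= 0:
        raise ValueError(
            f"weight and height must be positive, got {weight_kg} kg, {height_m} m"
        )
    bmi = weight_kg / height_m**2
    return bmi, classify_bmi(bmi)


def classify_bmi(bmi: float) -> BmiClass:
    if bmi < BMI_UNDERWEIGHT_UPPER:
        return "underweight"
    if bmi < BMI_HEALTHY_UPPER:
        return "healthy"
    return "overweight"


# ---------------------------------------------------------------------------
# Kolmogorov-Smirnov
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KSResult:
    """Two-sample KS test outcome at a fixed significance level."""

    d_statistic: float
    p_value: float
    n1: int
    n2: int
    alpha: float = ALPHA_DEFAULT

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    @property
    def nonsignificant(self) -> bool:
        return not self.significant


def ks_two_sample(
    x: Sequence[float],
    y: Sequence[float],
    method: Literal["auto", "exact", "asymp"] = "auto",
    alpha: float = ALPHA_DEFAULT,
) -> KSResult:
    """Two-sample Kolmogorov-Smirnov test.

    D is the maximum absolute difference between the two empirical CDFs
    (right-continuous, so ties are handled by the ECDF convention). The
    p-value uses the exact null distribution of D when ``n1 * n2 <= 10_000``
    and otherwise the asymptotic Kolmogorov distribution evaluated at
    D * sqrt(n1 n2 / (n1 + n2)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if method == "auto":
        method = "exact" if x.size * y.size <= 10_000 else "asymp"
    if method == "exact":
        res = sps.ks_2samp(x, y, method="exact")
        d, p = float(res.statistic), float(res.pvalue)
    else:
        d = float(sps.ks_2samp(x, y, method="asymp").statistic)
        en = np.sqrt(x.size * y.size / (x.size + y.size))
        p = float(special.kolmogorov(d * en))
    return KSResult(
        d_statistic=d,
        p_value=min(p, 1.0),
        n1=int(x.size),
        n2=int(y.size),
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# Pearson correlation matrix
# ---------------------------------------------------------------------------

Strength = Literal["strong", "moderate", "low", "undefined"]


@dataclass(frozen=True)
class CorrelationEntry:
    var_a: str
    var_b: str
    r: float | None
    p: float | None
    strength: Strength
    n: int

    @property
    def defined(self) -> bool:
        return self.r is not None


def correlation_strength(r: float) -> Strength:
    """|r| >= 0.5 strong, 0.3-0.49 moderate, below 0.3 low."""
    a = abs(r)
    if a >= 0.5:
        return "strong"
    if a >= 0.3:
        return "moderate"
    return "low"


def pearson_matrix(table: pd.DataFrame) -> list[CorrelationEntry]:
    """Pairwise Pearson r and two-sided p (t distribution, n-2 df) for every
    column pair of a subject-level table.

    A column with zero variance yields an explicitly flagged undefined entry
    rather than a silent NaN.
    """
    if len(table) < 4:
        raise ValueError(f"need >= 4 complete subjects, got {len(table)}")
    if table.isna().any().any():
        raise ValueError("table contains missing values")
    entries: list[CorrelationEntry] = []
    for a, b in combinations(table.columns, 2):
        xa = table[a].to_numpy(dtype=float)
        xb = table[b].to_numpy(dtype=float)
        if np.std(xa) == 0 or np.std(xb) == 0:
            entries.append(
                CorrelationEntry(a, b, None, None, "undefined", len(table))
            )
            continue
        r, p = sps.pearsonr(xa, xb)
        entries.append(
            CorrelationEntry(a, b, float(r), float(p), correlation_strength(r), len(table))
        )
    return entries


def correlation_frame(entries: Sequence[CorrelationEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "var_a": e.var_a,
                "var_b": e.var_b,
                "r": e.r,
                "p": e.p,
                "strength": e.strength,
                "n": e.n,
            }
            for e in entries
        ]
    )


# ---------------------------------------------------------------------------
# Intraclass correlation
# ---------------------------------------------------------------------------

Agreement = Literal["almost perfect", "substantial", "moderate", "fair", "slight"]


@dataclass(frozen=True)
class ICCResult:
    axis: str
    icc: float
    n_points: int
    n_sessions: int

    @property
    def agreement(self) -> Agreement:
        return agreement_category(self.icc)


def agreement_category(icc: float) -> Agreement:
    """Landis-Koch style bands; above 0.81 is 'almost perfect agreement'."""
    if icc > 0.81:
        return "almost perfect"
    if icc > 0.60:
        return "substantial"
    if icc > 0.40:
        return "moderate"
    if icc > 0.20:
        return "fair"
    return "slight"


def icc_absolute_agreement(ratings: np.ndarray, consistency: bool = False) -> float:
    """Single-measure two-way random-effects ICC from an n_targets x k_raters
    matrix of ratings.

    Default is the absolute-agreement form ICC(2,1),

        (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n),

    where MSR, MSC and MSE are the row (target), column (rater) and residual
    mean squares of the two-way ANOVA. With ``consistency=True`` the column
    variance term is dropped, giving the consistency form ICC(3,1).
    """
    ratings = np.asarray(ratings, dtype=float)
    if ratings.ndim != 2 or ratings.shape[1] < 2:
        raise ValueError("ratings must be an (n_targets, k>=2) matrix")
    n, k = ratings.shape
    if n < 3:
        raise ValueError(f"need at least 3 matched points, got {n}")
    grand = ratings.mean()
    row_means = ratings.mean(axis=1)
    col_means = ratings.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((ratings - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse
    if not consistency:
        denom += k * (msc - mse) / n
    if denom == 0:
        # all ratings identical across targets and raters: perfect agreement
        return 1.0
    return float((msr - mse) / denom)


def icc_two_session(
    session1: Sequence[float],
    session2: Sequence[float],
    axis: str,
    consistency: bool = False,
) -> ICCResult:
    """ICC(2,1) between two selection sessions of the same landmark points
    along one coordinate axis."""
    s1 = np.asarray(session1, dtype=float)
    s2 = np.asarray(session2, dtype=float)
    if s1.shape != s2.shape:
        raise ValueError(f"session size mismatch: {s1.shape} vs {s2.shape}")
    ratings = np.column_stack([s1, s2])
    if np.array_equal(s1, s2):
        icc = 1.0  # identical sessions agree perfectly even when degenerate
    else:
        icc = icc_absolute_agreement(ratings, consistency=consistency)
    return ICCResult(axis=axis, icc=icc, n_points=len(s1), n_sessions=2)


# ---------------------------------------------------------------------------
# Group contrasts
# ---------------------------------------------------------------------------

def group_percent_change(
    values: Sequence[float],
    classes: Sequence[str],
    from_class: str,
    to_class: str,
) -> float:
    """Percent change of the group mean from one class to another:
    100 * (mean(to) - mean(from)) / mean(from)."""
    values = np.asarray(values, dtype=float)
    classes = np.asarray(classes)
    v_from = values[classes == from_class]
    v_to = values[classes == to_class]
    if v_from.size == 0 or v_to.size == 0:
        raise ValueError(
            f"empty class: {from_class} has {v_from.size}, {to_class} has {v_to.size}"
        )
    m_from = v_from.mean()
    if m_from == 0:
        warnings.warn("from-class mean is zero; percent change undefined")
        return float("nan")
    return float(100.0 * (v_to.mean() - m_from) / m_from)
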