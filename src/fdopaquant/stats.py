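"""Statistical battery for the lesion-asymmetry analysis.

Paired Student's t (lesioned vs contralateral side within animals), one-way
ANOVA across dose groups with Dunnett's many-to-one post hoc against the
shared control, ordinary linear regression with Pearson correlation, and the
common-log transform of rotation counts.  All tests are two-sided with
alpha = 0.05.

Dunnett adjustment is computed by seeded Monte Carlo on the max-|t| statistic
of the correlated multivariate t null (correlation induced by the shared
control group); exact tables only cover balanced designs, and dose groups
here are unbalanced.  Degenerate-variance inputs raise instead of returning
NaN — silent NaN propagation corrupts cohort tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _st

__all__ = [
    "ALPHA",
    "TestResult",
    "RegressionResult",
    "paired_t_test",
    "one_way_anova",
    "dunnett_test",
    "linear_regression",
    "log_rotations",
]

ALPHA = 0.05


@dataclass(frozen=True)
class TestResult:
    """Outcome of a t/F-type test.

    ``statistic`` is t or F (for Dunnett, the largest |t_i|); ``df`` holds the
    degrees of freedom (a pair for F); ``per_group`` maps each treatment group
    to its (statistic, adjusted p, unadjusted p) for Dunnett.
    """

    statistic: float
    df: tuple[float, ...]
    p_value: float
    method: str
    alpha: float = ALPHA
    per_group: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit y = slope*x + intercept with Pearson correlation.

    ``p_value`` is the two-sided test of zero slope, from
    t = r * sqrt((n-2)/(1-r^2)) on n-2 df.  Standard errors are kept so
    parameter-recovery checks can be phrased in SE units.
    """

    slope: float
    intercept: float
    pearson_r: float
    p_value: float
    n: int
    stderr_slope: float
    stderr_intercept: float


def _as_pairs(pairs, second=None) -> tuple[np.ndarray, np.ndarray]:
    if second is not None:
        a = np.asarray(pairs, dtype=float)
        b = np.asarray(second, dtype=float)
    else:
        arr = np.asarray(list(pairs), dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("pairs must be a sequence of (ipsi, contra) tuples")
        a, b = arr[:, 0], arr[:, 1]
    if a.size != b.size:
        raise ValueError("paired samples must have equal length")
    return a, b


def paired_t_test(pairs, second=None) -> TestResult:
    """Two-sided paired Student's t on within-animal differences.

    Accepts either a sequence of (a, b) pairs or two parallel arrays.
    Degrees of freedom: n - 1.  Raises on fewer than 2 pairs or zero
    difference variance (t undefined).
    """
    a, b = _as_pairs(pairs, second)
    n = a.size
    if n < 2:
        raise ValueError("paired t test needs at least 2 pairs")
    d = a - b
    if np.ptp(d) == 0:
        raise ValueError("all paired differences identical: t statistic undefined")
    res = _st.ttest_rel(a, b)
    return TestResult(
        statistic=float(res.statistic),
        df=(float(n - 1),),
        p_value=float(res.pvalue),
        method="paired t",
    )


def _group_arrays(groups) -> list[np.ndarray]:
    if isinstance(groups, dict):
        groups = [groups[k] for k in groups]
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(a.ndim != 1 or a.size == 0 for a in arrs):
        raise ValueError("each group must be a non-empty 1-D sample")
    return arrs


def one_way_anova(groups) -> TestResult:
    """One-factor ANOVA; F = MS_between / MS_within on (k-1, N-k) df.

    ``groups`` is a dict (label -> values) or list of samples.  Zero
    within-group variance with unequal means yields an explicit infinite F
    (p = 0); zero variance everywhere raises.
    """
    arrs = _group_arrays(groups)
    k = len(arrs)
    if k < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    n_total = sum(a.size for a in arrs)
    df = (float(k - 1), float(n_total - k))
    if df[1] < 1:
        raise ValueError("ANOVA needs at least 1 within-group degree of freedom")
    ssw = sum(float(((a - a.mean()) ** 2).sum()) for a in arrs)
    if ssw == 0:
        means = [a.mean() for a in arrs]
        if np.ptp(means) == 0:
            raise ValueError("all observations identical: F undefined")
        return TestResult(statistic=float("inf"), df=df, p_value=0.0, method="one-way ANOVA")
    res = _st.f_oneway(*arrs)
    return TestResult(
        statistic=float(res.statistic),
        df=df,
        p_value=float(res.pvalue),
        method="one-way ANOVA",
    )


def dunnett_test(
    control,
    treatments: dict,
    n_draws: int = 100_000,
    seed: int = 0,
) -> TestResult:
    """Dunnett's many-to-one comparisons against a shared control.

    Per treatment group i: t_i = (mean_i - mean_ctrl) / sqrt(s2*(1/n_i+1/n_0))
    with s2 the variance pooled over all groups (df = N - k).  The family-wise
    adjusted p for group i is P(max_j |T_j| >= |t_i|) under the joint
    multivariate t null with correlation
    rho_ij = sqrt(n_i n_j / ((n_i+n_0)(n_j+n_0))), evaluated by seeded Monte
    Carlo (``n_draws`` samples).  Handles unbalanced designs.

    Adjusted p values are floored at the single-contrast unadjusted p (a
    mathematical lower bound the Monte Carlo estimate may dip below by
    sampling noise).
    """
    c = np.asarray(control, dtype=float)
    if c.size == 0:
        raise ValueError("control group is empty")
    if not treatments:
        raise ValueError("at least one treatment group is required")
    labels = list(treatments)
    arrs = [np.asarray(treatments[lab], dtype=float) for lab in labels]
    groups = [c] + arrs
    n = np.array([g.size for g in groups])
    n_total = int(n.sum())
    k = len(groups)
    df = n_total - k
    if df < 1:
        raise ValueError("Dunnett test needs at least 1 pooled degree of freedom")
    ssw = sum(float(((g - g.mean()) ** 2).sum()) for g in groups)
    if ssw == 0:
        raise ValueError("pooled within-group variance is zero")
    s2 = ssw / df
    t_obs = np.array(
        [(a.mean() - c.mean()) / np.sqrt(s2 * (1.0 / a.size + 1.0 / c.size)) for a in arrs]
    )

    # correlation of the contrasts, induced by the shared control
    lam = np.sqrt(n[1:] / (n[1:] + n[0]))
    corr = np.outer(lam, lam)
    np.fill_diagonal(corr, 1.0)

    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(corr)
    max_abs = np.empty(n_draws)
    chunk = 200_000
    done = 0
    while done < n_draws:
        m = min(chunk, n_draws - done)
        z = rng.standard_normal((m, k - 1)) @ chol.T
        w = rng.chisquare(df, size=m) / df
        max_abs[done : done + m] = np.abs(z).max(axis=1) / np.sqrt(w)
        done += m

    per_group = {}
    for lab, t in zip(labels, t_obs):
        p_adj = float(np.mean(max_abs >= abs(t)))
        p_un = float(2.0 * _st.t.sf(abs(t), df))
        per_group[lab] = (float(t), max(p_adj, p_un), p_un)
    t_max = float(np.max(np.abs(t_obs)))
    p_family = min(p for _, p, _ in per_group.values())
    return TestResult(
        statistic=t_max,
        df=(float(df),),
        p_value=p_family,
        method=f"Dunnett (Monte Carlo, {n_draws} draws)",
        per_group=per_group,
    )


def linear_regression(x, y) -> RegressionResult:
    """OLS regression of y on x with Pearson r and two-sided slope p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("regression needs at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant: slope undefined")
    res = _st.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        p_value=float(res.pvalue),
        n=int(x.size),
        stderr_slope=float(res.stderr),
        stderr_intercept=float(res.intercept_stderr),
    )


def log_rotations(count, offset: float = 1.0):
    """Common logarithm of rotation counts, log10(count + offset).

    The unit offset keeps zero-rotation control animals finite; it is recorded
    in output metadata wherever the transform is applied.
    """
    c = np.asarray(count, dtype=float)
    if np.any(c < 0):
        raise ValueError("rotation counts must be non-negative")
    out = np.log10(c + offset)
    return float(out) if out.ndim == 0 else out
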