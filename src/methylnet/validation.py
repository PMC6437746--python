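"""Case-control validation statistics for the targeted methylation panel.

Per locus: a two-sample t test (Welch by default), a univariate logistic
regression of case status on methylation level, and a multivariable logistic
regression additionally adjusted for age and sex.  Baseline group comparisons
use Welch's t test for continuous variables and the Pearson chi-square
(without continuity correction) for sex.  The module also provides the
two-sample sample-size/power computation used to design the validation
cohort: the smallest n per arm at which a two-sided t test, with the variance
of the group difference taken as (sd1^2 + sd2^2)/n, reaches the requested
power, evaluated with the noncentral t distribution.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import (
    ConvergenceWarning,
    PerfectSeparationWarning,
)

__all__ = [
    "SeparationError",
    "LogisticResult",
    "PowerSpec",
    "two_sample_ttest",
    "two_sample_ttest_from_stats",
    "chi2_2x2",
    "logistic_fit",
    "validate_panel",
    "power_two_sample",
    "sample_size_two_sample",
    "simulate_power",
]

logger = logging.getLogger(__name__)


class SeparationError(RuntimeError):
    """The logistic likelihood has no finite maximizer (perfect separation)."""


@dataclass
class LogisticResult:
    """Coefficients, standard errors and Wald two-sided P values, indexed by
    term name ('const' first)."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    llf: float
    converged: bool


@dataclass(frozen=True)
class PowerSpec:
    """Design parameters of a two-sample mean comparison: mean difference
    ``delta``, per-group SDs, two-sided ``alpha`` and target ``power``;
    ``allocation`` is the control:case size ratio (1.0 for 1:1)."""

    delta: float
    sd1: float
    sd2: float
    alpha: float = 0.05
    power: float = 0.90
    allocation: float = 1.0

    def __post_init__(self) -> None:
        if self.sd1 <= 0 or self.sd2 <= 0:
            raise ValueError("group SDs must be positive")
        if not 0 < self.alpha < 1 or not 0 < self.power < 1:
            raise ValueError("alpha and power must lie in (0, 1)")
        if self.power <= self.alpha:
            raise ValueError("power must exceed alpha")
        if self.allocation <= 0:
            raise ValueError("allocation ratio must be positive")


def two_sample_ttest(case, ctrl, welch: bool = True) -> tuple[float, float, float]:
    """Two-sided independent-sample t test; returns (t, df, p)."""
    case = np.asarray(case, dtype=float)
    ctrl = np.asarray(ctrl, dtype=float)
    if case.size < 2 or ctrl.size < 2:
        raise ValueError("each group needs at least two observations")
    if np.ptp(case) == 0 and np.ptp(ctrl) == 0:
        if case.mean() == ctrl.mean():
            # degenerate but well-defined null: identical constant groups
            df = case.size + ctrl.size - 2
            return 0.0, float(df), 1.0
        raise ValueError("both groups constant with unequal means: t undefined")
    res = stats.ttest_ind(case, ctrl, equal_var=not welch)
    return float(res.statistic), float(res.df), float(res.pvalue)


def two_sample_ttest_from_stats(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int,
    welch: bool = True,
) -> tuple[float, float]:
    """Two-sided t test from group summary statistics; returns (t, p)."""
    res = stats.ttest_ind_from_stats(
        mean1, sd1, n1, mean2, sd2, n2, equal_var=not welch
    )
    return float(res.statistic), float(res.pvalue)


def chi2_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table [[a, b], [c, d]], 1 df, two-sided,
    WITHOUT Yates continuity correction."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: zero marginal")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def logistic_fit(outcome, covariates, add_intercept: bool = True) -> LogisticResult:
    """Maximum-likelihood logistic regression with Wald two-sided P values.

    Fitting uses Newton iterations (equivalently iteratively reweighted least
    squares) with a score tolerance of 1e-8 and at most 100 iterations.
    Perfect separation is raised as :class:`SeparationError` rather than
    returned as a silently diverging coefficient.
    """
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")
    X = pd.DataFrame(covariates).copy() if covariates is not None else pd.DataFrame(index=range(y.size))
    if add_intercept:
        X = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            res = sm.Logit(y, X.astype(float)).fit(disp=0, maxiter=100, tol=1e-8)
        except PerfectSeparationWarning as err:
            raise SeparationError(str(err)) from err
        except np.linalg.LinAlgError as err:
            # Newton's information matrix goes singular when fitted
            # probabilities saturate (separation) or covariates are collinear
            raise SeparationError(
                f"singular information matrix (perfect separation or collinear covariates): {err}"
            ) from err
        except Exception as err:
            if "separation" in str(err).lower():
                raise SeparationError(str(err)) from err
            raise
    slopes = res.params.drop("const", errors="ignore")
    # the intercept can be legitimately large with uncentered covariates;
    # only diverging slopes indicate quasi-separation
    if len(slopes) and np.abs(slopes.to_numpy()).max() > 50:
        raise SeparationError("diverging coefficients suggest quasi-separation")
    return LogisticResult(
        params=res.params, bse=res.bse, pvalues=res.pvalues,
        llf=float(res.llf), converged=bool(res.mle_retvals.get("converged", True)),
    )


def validate_panel(
    validation_cohort: pd.DataFrame,
    phenotypes: pd.DataFrame,
    alpha: float = 0.05,
    welch: bool = True,
) -> pd.DataFrame:
    """Run the per-locus validation battery on an enlarged cohort.

    Parameters
    ----------
    validation_cohort : DataFrame
        Samples x loci percent-methylation table with a ``group`` column
        ("case"/"ctrl"); index = sample id.
    phenotypes : DataFrame
        Samples x clinical variables; ``age`` and ``sex`` are used for the
        adjusted model (sex encoded 0/1 for F/M).
    alpha : float
        Significance level for the ``significant`` flag (adjusted model).

    Returns one row per locus: direction (sign of case-control mean
    difference), group means, the three P values and the significance flag.
    A locus whose fit fails is reported with NaN P values and an ``error``
    note instead of aborting the panel.
    """
    if "group" not in validation_cohort.columns:
        raise ValueError("validation cohort must carry a 'group' column")
    shared = validation_cohort.index.intersection(phenotypes.index)
    if shared.empty:
        raise ValueError("no shared sample ids between cohort and phenotypes")
    cohort = validation_cohort.loc[shared]
    is_case = (cohort["group"] == "case").to_numpy()
    y = is_case.astype(float)
    age = pd.to_numeric(phenotypes.loc[shared, "age"], errors="coerce")
    sex = phenotypes.loc[shared, "sex"].map({"F": 0.0, "M": 1.0})

    rows = []
    for locus in [c for c in cohort.columns if c != "group"]:
        lv = pd.to_numeric(cohort[locus], errors="coerce")
        mean_case = float(lv[is_case].mean())
        mean_ctrl = float(lv[~is_case].mean())
        row = {
            "locus": locus,
            "direction": "hypo" if mean_case < mean_ctrl else "hyper",
            "mean_case": mean_case,
            "mean_ctrl": mean_ctrl,
            "p_ttest": np.nan,
            "p_logistic": np.nan,
            "p_logistic_adjusted": np.nan,
            "significant": False,
            "error": "",
        }
        try:
            _, _, row["p_ttest"] = two_sample_ttest(lv[is_case], lv[~is_case], welch=welch)
            uni = logistic_fit(y, pd.DataFrame({"methylation": lv}))
            row["p_logistic"] = float(uni.pvalues["methylation"])
            adj = logistic_fit(
                y, pd.DataFrame({"methylation": lv, "age": age, "sex": sex})
            )
            row["p_logistic_adjusted"] = float(adj.pvalues["methylation"])
            row["significant"] = bool(row["p_logistic_adjusted"] < alpha)
        except (SeparationError, ValueError) as err:
            row["error"] = f"{type(err).__name__}: {err}"
            logger.warning("locus %s failed: %s", locus, err)
        rows.append(row)
    return pd.DataFrame(rows)


def power_two_sample(spec: PowerSpec, n_per_arm: int) -> float:
    """Power of the two-sided two-sample t test at n cases per arm
    (controls = allocation * n), via the noncentral t distribution with the
    combined-variance form Var(diff) = sd1^2/n1 + sd2^2/n2."""
    n1 = n_per_arm
    n2 = max(2, int(round(spec.allocation * n_per_arm)))
    if n1 < 2:
        raise ValueError("need at least two samples per arm")
    df = n1 + n2 - 2
    ncp = spec.delta / np.sqrt(spec.sd1**2 / n1 + spec.sd2**2 / n2)
    tcrit = stats.t.ppf(1 - spec.alpha / 2, df)
    return float(
        1 - stats.nct.cdf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp)
    )


def sample_size_two_sample(spec: PowerSpec, n_max: int = 1_000_000) -> int:
    """Smallest n per arm reaching the requested power (see
    :func:`power_two_sample`); raises if delta is zero."""
    if spec.delta == 0:
        raise ValueError("no finite sample size for a zero mean difference")
    n = 2
    while n <= n_max:
        if power_two_sample(spec, n) >= spec.power:
            return n
        n += 1
    raise RuntimeError("sample size search exceeded n_max")


def simulate_power(
    spec: PowerSpec, n_per_arm: int, n_reps: int = 10_000, seed: int = 0,
    welch: bool = True,
) -> float:
    """Monte-Carlo power of the two-sided t test at the design point:
    fraction of replicates with P < alpha.  Vectorized Welch (or pooled)
    t statistics on normal draws."""
    rng = np.random.default_rng(seed)
    n1 = n_per_arm
    n2 = max(2, int(round(spec.allocation * n_per_arm)))
    g1 = rng.normal(spec.delta, spec.sd1, size=(n_reps, n1))
    g2 = rng.normal(0.0, spec.sd2, size=(n_reps, n2))
    m1, m2 = g1.mean(axis=1), g2.mean(axis=1)
    v1, v2 = g1.var(axis=1, ddof=1), g2.var(axis=1, ddof=1)
    if welch:
        se2 = v1 / n1 + v2 / n2
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    else:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        t = (m1 - m2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = np.full(n_reps, n1 + n2 - 2.0)
    p = 2 * stats.t.sf(np.abs(t), df)
    return float(np.mean(p < spec.alpha))
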