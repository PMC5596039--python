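"""Agreement and association statistics for method evaluation.

The battery used to validate a quantitative imaging metric against
alternative measurements and clinical visual scores: bootstrapped Spearman
rank correlations, Bland-Altman limits of agreement (on percentage
differences relative to pair means, suited to method comparison across a
wide dynamic range), paired Wilcoxon/t tests, analysis of covariance of the
follow-up measurement on baseline + visual change score, and plain change
scores.

Multiple-testing correction is not applied by default; Holm-adjusted
p-values are available via :func:`holm_adjust` for users who want them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "CorrelationResult",
    "AgreementResult",
    "AncovaResult",
    "PairedTestResult",
    "bootstrap_spearman",
    "bland_altman",
    "ancova_followup",
    "paired_tests",
    "change_scores",
    "holm_adjust",
]

DEFAULT_N_BOOT = 2000


def _paired(x, y, min_n: int) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"inputs must be paired: lengths {len(x)} vs {len(y)}")
    if len(x) < min_n:
        raise ValueError(f"need at least {min_n} pairs, got {len(x)}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs contain non-finite values")
    return x, y


# ---------------------------------------------------------------------------
# Bootstrapped Spearman correlation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    n_boot: int


def bootstrap_spearman(
    x,
    y,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    ci: float = 0.95,
) -> CorrelationResult:
    """Spearman rho with a percentile-bootstrap confidence interval.

    rho and its asymptotic p-value are computed on the full sample (ties by
    average ranks); the CI comes from ``n_boot`` paired resamples, taking the
    (1−ci)/2 and 1−(1−ci)/2 percentiles of the resampled rho distribution.
    Deterministic given ``seed``.
    """
    x, y = _paired(x, y, min_n=5)
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman rho is undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    rng = np.random.default_rng(seed)
    n = len(x)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        xb, yb = x[idx], y[idx]
        if np.all(xb == xb[0]) or np.all(yb == yb[0]):
            boots[b] = np.nan  # degenerate resample carries no rank information
        else:
            boots[b] = stats.spearmanr(xb, yb).statistic
    boots = boots[np.isfinite(boots)]
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
    return CorrelationResult(
        rho=float(rho), ci_low=float(lo), ci_high=float(hi),
        p_value=float(p), n=n, n_boot=n_boot,
    )


# ---------------------------------------------------------------------------
# Bland-Altman agreement
# ---------------------------------------------------------------------------

@dataclass
class AgreementResult:
    """Bland-Altman summary: mean difference and 1.96·SD limits of agreement.

    In relative mode differences are 100·(a−b)/pair-mean, i.e. percent of
    the average of the two measurements.
    """

    mean_diff: float
    loa_low: float
    loa_high: float
    differences: np.ndarray
    pair_means: np.ndarray
    relative: bool
    n: int


def bland_altman(a, b, relative: bool = True) -> AgreementResult:
    """Agreement between two paired measurement series.

    ``relative=True`` (default) expresses each difference as a percentage of
    the pair mean; pairs with zero mean are an error in that mode.  Limits
    of agreement are mean ± 1.96 · SD (sample SD, ddof=1).
    """
    a, b = _paired(a, b, min_n=3)
    means = (a + b) / 2.0
    diffs = a - b
    if relative:
        zero = np.flatnonzero(means == 0)
        if zero.size:
            raise ValueError(
                f"relative differences undefined for zero pair means at indices {zero.tolist()}"
            )
        diffs = 100.0 * diffs / means
    mean_diff = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return AgreementResult(
        mean_diff=mean_diff,
        loa_low=mean_diff - 1.96 * sd,
        loa_high=mean_diff + 1.96 * sd,
        differences=diffs,
        pair_means=means,
        relative=relative,
        n=len(a),
    )


# ---------------------------------------------------------------------------
# ANCOVA of follow-up on baseline + visual change score
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AncovaResult:
    """OLS fit of followup ~ baseline + score; the score coefficient answers
    whether the visual change score tracks the quantitative follow-up
    measurement once baseline burden is adjusted for."""

    coef_score: float
    ci_low: float
    ci_high: float
    p_value: float
    coef_baseline: float
    intercept: float
    n_used: int
    n_dropped: int
    condition_number: float
    log_outcome: bool


def ancova_followup(
    followup,
    baseline,
    score,
    log_outcome: bool = False,
    cond_warn: float = 1e6,
) -> AncovaResult:
    """ANCOVA: regress the follow-up measurement on baseline + change score.

    Missing values are dropped listwise (the count is reported in the
    result).  ``log_outcome=True`` log-transforms the outcome first (useful
    for right-skewed damage metrics; requires positive follow-up values).
    """
    f = np.asarray(followup, dtype=float).ravel()
    b = np.asarray(baseline, dtype=float).ravel()
    s = np.asarray(score, dtype=float).ravel()
    if not (len(f) == len(b) == len(s)):
        raise ValueError("followup, baseline and score must have equal length")
    keep = np.isfinite(f) & np.isfinite(b) & np.isfinite(s)
    n_dropped = int(np.sum(~keep))
    f, b, s = f[keep], b[keep], s[keep]
    if len(f) <= 10:
        raise ValueError(f"need more than 10 complete cases, got {len(f)}")
    if log_outcome:
        if np.any(f <= 0):
            raise ValueError("log_outcome requires strictly positive follow-up values")
        f = np.log(f)
    X = sm.add_constant(np.column_stack([b, s]))
    fit = sm.OLS(f, X).fit()
    if fit.condition_number > cond_warn:
        import warnings

        warnings.warn(
            f"design matrix is ill-conditioned (condition number "
            f"{fit.condition_number:.3g}); the score coefficient may be unstable",
            stacklevel=2,
        )
    ci = fit.conf_int()
    return AncovaResult(
        coef_score=float(fit.params[2]),
        ci_low=float(ci[2][0]),
        ci_high=float(ci[2][1]),
        p_value=float(fit.pvalues[2]),
        coef_baseline=float(fit.params[1]),
        intercept=float(fit.params[0]),
        n_used=len(f),
        n_dropped=n_dropped,
        condition_number=float(fit.condition_number),
        log_outcome=log_outcome,
    )


# ---------------------------------------------------------------------------
# Paired tests and change scores
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairedTestResult:
    wilcoxon_p: float
    ttest_p: float
    n: int
    degenerate: bool  # all paired differences were exactly zero


def paired_tests(a, b) -> PairedTestResult:
    """Two-sided paired Wilcoxon signed-rank and t tests.

    Zero differences are handled by the Pratt method (kept in the ranking).
    When every difference is zero both tests are vacuous; p = 1 is reported
    with the ``degenerate`` flag set.
    """
    a, b = _paired(a, b, min_n=6)
    d = a - b
    if np.all(d == 0):
        return PairedTestResult(wilcoxon_p=1.0, ttest_p=1.0, n=len(a), degenerate=True)
    w = stats.wilcoxon(a, b, zero_method="pratt", alternative="two-sided")
    t = stats.ttest_rel(a, b)
    tp = float(t.pvalue)
    if not np.isfinite(tp):  # zero-variance nonzero differences
        tp = 0.0
    return PairedTestResult(
        wilcoxon_p=float(w.pvalue), ttest_p=tp, n=len(a), degenerate=False
    )


def change_scores(baseline, followup) -> np.ndarray:
    """Per-subject change: follow-up minus baseline."""
    b = np.asarray(baseline, dtype=float).ravel()
    f = np.asarray(followup, dtype=float).ravel()
    if b.shape != f.shape:
        raise ValueError("baseline and followup must be paired")
    return f - b


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (for users who want a correction)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(p_values, dtype=float), method="holm")[1]
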