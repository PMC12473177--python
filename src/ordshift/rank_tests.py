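"""Competing hypothesis tests for a two-arm ordinal outcome.

All tests consume the grouped 2 x K count table directly (no per-participant
expansion except the t test, where expansion is the definition):

* Mann-Whitney U with midranks and the tie-corrected normal approximation,
* the linear-by-linear (Cochran-Armitage-type) trend test,
* the Pearson chi-square omnibus test,
* Welch's t test on sequential integer scores,
* and the *deliberately invalid* pretest hybrid: test the proportional-odds
  assumption first, then pick the chi-square or the PO likelihood-ratio test
  depending on the result.  The hybrid exists to demonstrate that this
  strategy inflates the type-I error; it should never be used for inference.

The shift-targeted tests (Mann-Whitney, trend, PO LR/Wald, t) have nearly
identical power against proportional-odds shift alternatives; the chi-square
trades that power for sensitivity to arbitrary distributional differences.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .data import TwoArmCounts
from .model import TestResult, fit_po

__all__ = [
    "mann_whitney_test",
    "linear_by_linear_test",
    "pearson_chi2_test",
    "t_test_scores",
    "hybrid_test",
]


def mann_whitney_test(data: TwoArmCounts) -> TestResult:
    """Two-sided Mann-Whitney U test from grouped counts with midranks.

    The normal approximation uses the tie-corrected variance
    ``n1*n2/12 * [(N+1) - sum(t^3 - t) / (N*(N-1))]`` with t the pooled count
    per category; no continuity correction (ties dominate at trial sizes).
    The reported U counts treatment wins plus half the ties, so U above its
    mean means a shift toward clinically better outcomes in the treated arm.
    """
    n = data.goodness_counts().astype(float)
    nc, nt = n.sum(axis=1)
    pooled = n.sum(axis=0)
    # wins_j = n_t[j] * (# controls in strictly worse categories)
    ctrl_worse_than = nc - np.cumsum(n[0])
    wins = float(np.sum(n[1] * ctrl_worse_than))
    ties = float(np.sum(n[1] * n[0]))
    u = wins + 0.5 * ties
    mean_u = nc * nt / 2.0
    n_total = nc + nt
    tie_term = np.sum(pooled**3 - pooled) / (n_total * (n_total - 1.0))
    var_u = nc * nt / 12.0 * ((n_total + 1.0) - tie_term)
    extras = {"u": u, "p_win": wins / (nc * nt), "p_tie": ties / (nc * nt)}
    if var_u <= 0:  # every observation in one category
        extras["warning"] = "all observations tied: zero variance"
        return TestResult("Mann-Whitney U test", 0.0, None, 1.0, extras)
    z = (u - mean_u) / np.sqrt(var_u)
    extras["z"] = float(z)
    return TestResult(
        method="Mann-Whitney U test",
        statistic=float(u),
        df=None,
        p_value=float(2.0 * stats.norm.sf(abs(z))),
        extras=extras,
    )


def linear_by_linear_test(
    data: TwoArmCounts, scores: np.ndarray | None = None
) -> TestResult:
    """Linear-by-linear association (Cochran-Armitage trend) test.

    ``M^2 = (N - 1) r^2`` where r is the Pearson correlation between the
    arm indicator and the category scores over all N observations; df = 1.
    Default scores are the sequential integers 0..K-1; any affine transform
    gives the identical statistic.
    """
    if scores is None:
        scores = np.arange(data.k, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if scores.size != data.k:
        raise ValueError(f"need {data.k} scores, got {scores.size}")
    n = data.counts.astype(float)
    n_arm = n.sum(axis=1)
    n_total = n.sum()
    pooled = n.sum(axis=0)
    x = np.array([0.0, 1.0])
    mean_x = (x * n_arm).sum() / n_total
    mean_s = (scores * pooled).sum() / n_total
    cov = float(((x[:, None] - mean_x) * (scores[None, :] - mean_s) * n).sum())
    var_x = float(((x - mean_x) ** 2 * n_arm).sum())
    var_s = float(((scores - mean_s) ** 2 * pooled).sum())
    if var_x == 0 or var_s == 0:
        raise ValueError("zero variance in category scores")
    r = cov / np.sqrt(var_x * var_s)
    m2 = (n_total - 1.0) * r * r
    return TestResult(
        method="linear-by-linear trend test",
        statistic=float(m2),
        df=1,
        p_value=float(stats.chi2.sf(m2, 1)),
        extras={"r": float(r)},
    )


def pearson_chi2_test(data: TwoArmCounts) -> TestResult:
    """Pearson chi-square omnibus test on the 2 x K table (df = K - 1).

    No Yates correction.  Requires every pooled category count positive
    (merge or drop sparse categories first); annotates a warning when any
    expected cell count falls below 5, the usual trigger for merging.
    """
    n = data.counts
    if np.any(n.sum(axis=0) == 0):
        raise ValueError(
            "zero pooled category count: merge_categories or "
            "drop_empty_categories first"
        )
    statistic, p, df, expected = stats.chi2_contingency(n, correction=False)
    extras = {}
    if np.any(expected < 5):
        extras["warning"] = (
            f"{int(np.sum(expected < 5))} expected cell(s) < 5; "
            "consider merging sparse categories"
        )
    return TestResult(
        method="Pearson chi-square test",
        statistic=float(statistic),
        df=int(df),
        p_value=float(p),
        extras=extras,
    )


def t_test_scores(data: TwoArmCounts) -> TestResult:
    """Welch two-sample t test on sequential integer scores 0..K-1."""
    n = data.counts
    if np.any(n.sum(axis=1) < 2):
        raise ValueError("need at least 2 observations per arm")
    scores = np.arange(data.k, dtype=float)
    samples = [np.repeat(scores, row) for row in n]
    if all(np.ptp(s) == 0 for s in samples):
        return TestResult(
            "Welch t test on integer scores",
            0.0,
            None,
            1.0,
            extras={"warning": "zero variance in both arms"},
        )
    t, p = stats.ttest_ind(samples[1], samples[0], equal_var=False)
    nu = stats.ttest_ind(samples[1], samples[0], equal_var=False).df
    return TestResult(
        method="Welch t test on integer scores",
        statistic=float(t),
        df=float(nu),
        p_value=float(p),
        extras={
            "mean_control": float(samples[0].mean()),
            "mean_treatment": float(samples[1].mean()),
        },
    )


HYBRID_WARNING = (
    "pretesting the proportional-odds assumption to choose the treatment-effect "
    "test inflates the type-I error; do not use this strategy for inference"
)


def hybrid_test(data: TwoArmCounts, alpha_pretest: float = 0.05) -> TestResult:
    """The invalid pretest strategy: PO-assumption LR pretest, then pick a test.

    If the pretest rejects at ``alpha_pretest``, the Pearson chi-square test
    is returned; otherwise the PO-model LR test of the common odds ratio.
    Implemented solely to reproduce its type-I-error inflation; the result
    carries a warning saying so.
    """
    if data.k < 3:
        raise ValueError("hybrid pretest undefined for binary outcomes")
    res = fit_po(data)
    pretest = res.lr_test_po_assumption()
    if pretest.p_value < alpha_pretest:
        out = pearson_chi2_test(data)
        branch = "chi-square (pretest rejected PO)"
    else:
        out = res.lr_test_effect()
        branch = "PO LR (pretest did not reject)"
    out = TestResult(
        method=f"hybrid pretest strategy -> {out.method}",
        statistic=out.statistic,
        df=out.df,
        p_value=out.p_value,
        extras={
            **out.extras,
            "branch": branch,
            "pretest_p": pretest.p_value,
            "warning": HYBRID_WARNING,
        },
    )
    return out
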