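"""Proportional-odds (cumulative logit) model for two-arm ordinal outcomes.

The model behind "shift analysis".  For an ordinal outcome with K categories
and a binary treatment indicator x, write gamma_j(x) for the probability of
an outcome *at or better than* category j (orientation applied, so that
"better" is always the clinical direction).  The model is

    logit gamma_j(x) = alpha_j + beta * x,    j = 1, ..., K-1,

with strictly increasing thresholds alpha_1 < ... < alpha_{K-1} and a single
slope beta shared by all K-1 dichotomizations.  exp(beta) is the common odds
ratio (cOR): under the proportional-odds assumption every cut-point odds
ratio equals it, and the maximum-likelihood estimate acts as a weighted
average of the observed cut-point odds ratios.  cOR > 1 always means a shift
toward clinically better categories.

Fitting is by Newton-Raphson on the count-weighted multinomial likelihood
with analytic gradient and Hessian (the observed information, whose inverse
is the variance estimate), with step-halving to keep the thresholds ordered
and a quasi-Newton fallback on a reparameterized unconstrained space.

The saturated comparator -- separate multinomials per arm -- is available in
closed form and supplies the likelihood-ratio test of the proportional-odds
assumption (df = K-2: the saturated model has 2(K-1) free parameters, the
PO model K-1 thresholds plus one slope).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy import optimize, special, stats

from .data import Orientation, OrdinalScale, TwoArmCounts

__all__ = [
    "TestResult",
    "POResults",
    "POFit",
    "SaturatedFit",
    "ProportionalOddsModel",
    "loglik_po",
    "fit_po",
    "fit_saturated",
    "lr_test_effect",
    "wald_test_effect",
    "lr_test_po_assumption",
]

SEPARATION_BETA = 15.0  # |beta| beyond this is treated as complete separation


@dataclass
class TestResult:
    """A named hypothesis test: statistic, degrees of freedom, p-value.

    ``df`` is None for tests without a chi-square/t reference count (or when
    not applicable); ``extras`` carries estimates, CIs and warnings.
    """

    method: str
    statistic: float
    df: float | None
    p_value: float
    extras: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")

    def __str__(self) -> str:
        df = "" if self.df is None else f", df = {self.df:g}"
        return f"{self.method}: statistic = {self.statistic:.4f}{df}, p = {self.p_value:.4g}"


@dataclass(frozen=True)
class SaturatedFit:
    """Unconstrained per-arm multinomial fit (the PO model's saturated comparator)."""

    probs: np.ndarray  # 2 x K, rows sum to 1
    loglik: float


def _xlogy_sum(n: np.ndarray, p: np.ndarray) -> float:
    # 0 * log 0 = 0; n > 0 with p <= 0 yields -inf
    return float(np.sum(special.xlogy(n, p)))


def _cell_probs(alpha: np.ndarray, beta: float) -> np.ndarray:
    """2 x K category probabilities from thresholds and slope (goodness order)."""
    eta = np.vstack([alpha, alpha + beta])
    gamma = special.expit(eta)
    cum = np.hstack([np.zeros((2, 1)), gamma, np.ones((2, 1))])
    return np.diff(cum, axis=1)


def _loglik_grad_hess(
    n: np.ndarray, alpha: np.ndarray, beta: float, want_hess: bool = True
) -> tuple[float, np.ndarray, np.ndarray | None]:
    """Log-likelihood, gradient and Hessian at (alpha, beta), goodness-ordered counts."""
    km1 = alpha.size
    eta = np.vstack([alpha, alpha + beta])  # 2 x (K-1)
    gamma = special.expit(eta)
    cum = np.hstack([np.zeros((2, 1)), gamma, np.ones((2, 1))])
    p = np.diff(cum, axis=1)  # 2 x K
    ll = _xlogy_sum(n, p)
    d = gamma * (1.0 - gamma)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(n > 0, n / p, 0.0)  # n_j / p_j, 0 when n_j = 0
        r2 = np.where(n > 0, n / p**2, 0.0)
    u = r[:, :km1] - r[:, 1:]  # per cut c: n_{c-1}/p_{c-1} - n_c/p_c
    score_eta = d * u  # 2 x (K-1)
    grad = np.empty(km1 + 1)
    grad[:km1] = score_eta.sum(axis=0)
    grad[km1] = score_eta[1].sum()
    if not want_hess:
        return ll, grad, None
    # Per-arm tridiagonal Hessian in eta, then chain-rule to (alpha, beta).
    diag = d * (1.0 - 2.0 * gamma) * u - d**2 * (r2[:, :km1] + r2[:, 1:])
    off = d[:, :-1] * d[:, 1:] * r2[:, 1:km1] if km1 > 1 else np.zeros((2, 0))
    H = np.zeros((km1 + 1, km1 + 1))
    dsum = diag.sum(axis=0)
    osum = off.sum(axis=0)
    H[np.arange(km1), np.arange(km1)] = dsum
    if km1 > 1:
        idx = np.arange(km1 - 1)
        H[idx, idx + 1] = osum
        H[idx + 1, idx] = osum
    # treatment-arm block couples thresholds and slope
    At = np.zeros((km1, km1))
    At[np.arange(km1), np.arange(km1)] = diag[1]
    if km1 > 1:
        At[idx, idx + 1] = off[1]
        At[idx + 1, idx] = off[1]
    rowsum = At.sum(axis=1)
    H[:km1, km1] = rowsum
    H[km1, :km1] = rowsum
    H[km1, km1] = rowsum.sum()
    return ll, grad, H


def _start_values(n: np.ndarray) -> np.ndarray:
    pooled = n.sum(axis=0).astype(float)
    cum = np.cumsum(pooled)[:-1] / pooled.sum()
    cum = np.clip(cum, 1e-6, 1 - 1e-6)
    # force strict monotonicity when pooled cells are empty
    cum = np.maximum.accumulate(cum + 1e-9 * np.arange(cum.size))
    params = np.empty(n.shape[1])
    params[:-1] = special.logit(cum)
    params[-1] = 0.0
    return params


def _newton_fit(
    n: np.ndarray, gtol: float = 1e-9, maxiter: int = 200
) -> tuple[np.ndarray, float, np.ndarray, bool, int]:
    """Maximize the PO likelihood for goodness-ordered counts ``n`` (2 x K).

    Returns (params, loglik, hessian, converged, n_iter).
    """
    km1 = n.shape[1] - 1
    params = _start_values(n)
    ll, grad, H = _loglik_grad_hess(n, params[:km1], params[km1])
    converged = False
    it = 0
    for it in range(1, maxiter + 1):
        if np.max(np.abs(grad)) < gtol:
            converged = True
            break
        try:
            step = np.linalg.solve(-H, grad)
        except np.linalg.LinAlgError:
            break
        scale = 1.0
        for _ in range(40):
            cand = params + scale * step
            alpha = cand[:km1]
            if np.all(np.diff(alpha) > 0) or km1 == 1:
                ll_new, grad_new, H_new = _loglik_grad_hess(n, alpha, cand[km1])
                if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                    params, ll, grad, H = cand, ll_new, grad_new, H_new
                    break
            scale *= 0.5
        else:  # no acceptable step found
            break
    if not converged and np.max(np.abs(grad)) < 1e-6:
        converged = True  # flat enough for all practical purposes
    return params, ll, H, converged, it


def _fallback_fit(n: np.ndarray, x0: np.ndarray) -> tuple[np.ndarray, float, np.ndarray, bool, int]:
    """BFGS on the unconstrained reparameterization alpha_c = t0 + sum exp(t_i)."""
    km1 = n.shape[1] - 1

    def unpack(t: np.ndarray) -> tuple[np.ndarray, float]:
        alpha = np.empty(km1)
        alpha[0] = t[0]
        if km1 > 1:
            alpha[1:] = t[0] + np.cumsum(np.exp(t[1:km1]))
        return alpha, t[km1]

    def negll(t: np.ndarray) -> tuple[float, np.ndarray]:
        alpha, beta = unpack(t)
        ll, grad, _ = _loglik_grad_hess(n, alpha, beta, want_hess=False)
        gt = np.empty(km1 + 1)
        gt[0] = grad[:km1].sum()
        for i in range(1, km1):
            gt[i] = grad[i:km1].sum() * np.exp(t[i])
        gt[km1] = grad[km1]
        return -ll, -gt

    t0 = np.empty(km1 + 1)
    t0[0] = x0[0]
    if km1 > 1:
        diffs = np.maximum(np.diff(x0[:km1]), 1e-6)
        t0[1:km1] = np.log(diffs)
    t0[km1] = x0[km1]
    res = optimize.minimize(negll, t0, jac=True, method="BFGS", options={"gtol": 1e-10, "maxiter": 500})
    alpha, beta = unpack(res.x)
    params = np.append(alpha, beta)
    ll, _, H = _loglik_grad_hess(n, alpha, beta)
    return params, ll, H, bool(res.success), int(res.nit)


@dataclass
class POResults:
    """Fitted proportional-odds model for a two-arm ordinal table.

    ``params`` is ``(alpha_1, ..., alpha_{K-1}, beta)`` on the goodness
    (clinically-best-first) scale; ``exp(beta)`` is the common odds ratio,
    oriented so that values above 1 mean benefit.
    """

    model: "ProportionalOddsModel"
    params: np.ndarray
    loglik: float
    vcov: np.ndarray
    converged: bool
    n_iter: int
    separation: bool = False

    @property
    def thresholds(self) -> np.ndarray:
        return self.params[:-1]

    @property
    def beta(self) -> float:
        return float(self.params[-1])

    @property
    def common_or(self) -> float:
        return float(np.exp(self.beta))

    @property
    def se_beta(self) -> float:
        v = self.vcov[-1, -1]
        return float(np.sqrt(v)) if v >= 0 else float("nan")

    @property
    def fitted_probs(self) -> np.ndarray:
        """Model-implied 2 x K category probabilities (goodness order)."""
        return _cell_probs(self.thresholds, self.beta)

    def conf_int_common_or(self, level: float = 0.95) -> tuple[float, float]:
        """Wald interval for the common odds ratio."""
        if self.separation:
            return (0.0, float("inf"))
        z = stats.norm.ppf(0.5 + level / 2)
        return (
            float(np.exp(self.beta - z * self.se_beta)),
            float(np.exp(self.beta + z * self.se_beta)),
        )

    # -- tests ------------------------------------------------------------
    def lr_test_effect(self) -> TestResult:
        ll0 = self.model.null_loglik()
        statistic = max(0.0, 2.0 * (self.loglik - ll0))
        out = TestResult(
            method="PO model LR test (common OR = 1)",
            statistic=statistic,
            df=1,
            p_value=float(stats.chi2.sf(statistic, 1)),
            extras={"common_or": self.common_or, "beta": self.beta},
        )
        if not self.converged:
            out.extras["warning"] = "PO fit did not converge"
        return out

    def wald_test_effect(self) -> TestResult:
        extras: dict[str, Any] = {
            "beta": self.beta,
            "se": self.se_beta,
            "common_or": self.common_or,
            "ci_95": self.conf_int_common_or(),
        }
        if self.separation or not np.isfinite(self.se_beta) or self.se_beta == 0:
            extras["warning"] = (
                "complete separation: Wald statistic unreliable, CI unbounded"
            )
            return TestResult(
                method="PO model Wald test (common OR = 1)",
                statistic=float("nan"),
                df=1,
                p_value=float("nan"),
                extras=extras,
            )
        z = self.beta / self.se_beta
        return TestResult(
            method="PO model Wald test (common OR = 1)",
            statistic=float(z * z),
            df=1,
            p_value=float(stats.chi2.sf(z * z, 1)),
            extras=extras,
        )

    def lr_test_po_assumption(self) -> TestResult:
        k = self.model.data.k
        if k < 3:
            raise ValueError(
                "PO assumption test undefined for binary outcomes (df = 0)"
            )
        sat = self.model.fit_saturated()
        statistic = max(0.0, 2.0 * (sat.loglik - self.loglik))
        df = k - 2
        return TestResult(
            method="LR test of the proportional-odds assumption",
            statistic=statistic,
            df=df,
            p_value=float(stats.chi2.sf(statistic, df)),
        )

    def summary(self) -> str:
        data = self.model.data
        lines = [
            "Proportional-odds (cumulative logit) model",
            "=" * 58,
            f"Arms: {data.arm_names[0]} (n={data.n_control}) vs "
            f"{data.arm_names[1]} (n={data.n_treatment})",
            f"Categories (K={data.k}): {', '.join(data.scale.labels)}",
            f"Orientation: {data.scale.orientation.value}",
            f"Log-likelihood: {self.loglik:.4f}   converged: {self.converged} "
            f"({self.n_iter} iter)",
            "-" * 58,
            f"{'param':<12}{'estimate':>10}{'std err':>10}{'z':>9}{'P>|z|':>10}",
        ]
        se = np.sqrt(np.clip(np.diag(self.vcov), 0, None))
        names = [f"alpha_{j + 1}" for j in range(data.k - 1)] + ["beta"]
        for name, est, s in zip(names, self.params, se):
            z = est / s if s > 0 else float("nan")
            p = 2 * stats.norm.sf(abs(z)) if np.isfinite(z) else float("nan")
            lines.append(f"{name:<12}{est:>10.4f}{s:>10.4f}{z:>9.3f}{p:>10.4g}")
        lo, hi = self.conf_int_common_or()
        lines += [
            "-" * 58,
            f"Common odds ratio: {self.common_or:.4f}  (95% CI {lo:.4f} to {hi:.4f})",
        ]
        if self.separation:
            lines.append("WARNING: complete separation; CI unbounded")
        if data.k >= 3:
            po = self.lr_test_po_assumption()
            lines.append(
                f"PO assumption LR test: stat = {po.statistic:.3f}, "
                f"df = {po.df:g}, p = {po.p_value:.4g}"
            )
        return "\n".join(lines)


# spec-facing alias: a fitted PO model object
POFit = POResults


class ProportionalOddsModel:
    """Two-arm proportional-odds model, built from a :class:`TwoArmCounts`.

    Examples
    --------
    >>> from ordshift import OrdinalScale, TwoArmCounts, ProportionalOddsModel
    >>> scale = OrdinalScale(("0", "1", "2"))
    >>> data = TwoArmCounts(scale, [[10, 10, 10], [15, 10, 5]])
    >>> res = ProportionalOddsModel(data).fit()
    >>> round(res.common_or, 2)
    2.14
    """

    def __init__(self, data: TwoArmCounts):
        if data.k < 2:
            raise ValueError("need at least 2 categories")
        self.data = data
        self._n = data.goodness_counts().astype(float)

    @classmethod
    def from_dataframe(
        cls,
        frame,
        scale: OrdinalScale,
        control_arm: str | None = None,
    ) -> "ProportionalOddsModel":
        """Build from a long per-participant DataFrame with columns arm, category."""
        from .data import _tabulate

        return cls(_tabulate(frame.assign(count=1), scale, control_arm))

    def loglike(self, params: np.ndarray) -> float:
        """Count-weighted multinomial log-likelihood at (alpha_1..alpha_{K-1}, beta)."""
        params = np.asarray(params, dtype=float)
        alpha, beta = params[:-1], params[-1]
        if alpha.size > 1 and np.any(np.diff(alpha) <= 0):
            raise ValueError("thresholds must be strictly increasing")
        p = _cell_probs(alpha, beta)
        if np.any((p <= 0) & (self._n > 0)):
            raise ValueError("non-positive category probability at evaluation point")
        return _xlogy_sum(self._n, p)

    def null_loglik(self) -> float:
        """Maximized log-likelihood with beta = 0 (pooled multinomial, closed form)."""
        pooled = self._n.sum(axis=0)
        return _xlogy_sum(pooled, pooled / pooled.sum())

    def fit_saturated(self) -> SaturatedFit:
        """Per-arm empirical multinomial (closed-form maximum likelihood)."""
        n = self.data.counts.astype(float)
        probs = n / n.sum(axis=1, keepdims=True)
        return SaturatedFit(probs=probs, loglik=_xlogy_sum(n, probs))

    def fit(self, gtol: float = 1e-9, maxiter: int = 200) -> POResults:
        params, ll, H, converged, n_iter = _newton_fit(self._n, gtol, maxiter)
        if not converged:
            params, ll, H, converged, n_iter = _fallback_fit(self._n, params)
        try:
            vcov = np.linalg.inv(-H)
        except np.linalg.LinAlgError:
            vcov = np.full_like(H, np.nan)
        separation = bool(abs(params[-1]) > SEPARATION_BETA)
        if separation:
            converged = False
        if not converged:
            warnings.warn(
                "PO model fit did not converge"
                + (" (complete separation)" if separation else ""),
                RuntimeWarning,
                stacklevel=2,
            )
        return POResults(
            model=self,
            params=params,
            loglik=ll,
            vcov=vcov,
            converged=converged,
            n_iter=n_iter,
            separation=separation,
        )


# ---------------------------------------------------------------------------
# Functional surface
# ---------------------------------------------------------------------------


def loglik_po(params, data: TwoArmCounts) -> float:
    """PO-model log-likelihood at explicit parameters (see the model docstring)."""
    return ProportionalOddsModel(data).loglike(np.asarray(params, dtype=float))


def fit_po(data: TwoArmCounts, **kwargs) -> POResults:
    """Maximum-likelihood PO fit; ``exp(beta)`` is the common odds ratio."""
    return ProportionalOddsModel(data).fit(**kwargs)


def fit_saturated(data: TwoArmCounts) -> SaturatedFit:
    """Unconstrained per-arm multinomial fit (saturated comparator)."""
    return ProportionalOddsModel(data).fit_saturated()


def lr_test_effect(data: TwoArmCounts) -> TestResult:
    """Likelihood-ratio test that the common odds ratio equals 1 (df = 1)."""
    return fit_po(data).lr_test_effect()


def wald_test_effect(data: TwoArmCounts) -> TestResult:
    """Wald test of the common odds ratio, with estimate, SE and 95% CI."""
    return fit_po(data).wald_test_effect()


def lr_test_po_assumption(data: TwoArmCounts) -> TestResult:
    """LR test of the proportional-odds assumption against the saturated model (df = K-2)."""
    return fit_po(data).lr_test_po_assumption()
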