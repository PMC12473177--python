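"""Single-number effect summaries: win statistics and utility contrasts.

Win statistics compare every treated participant with every control and
score a win when the treated outcome is clinically better, a loss when
worse, a tie when equal.  From the win/tie/loss probabilities:

* probabilistic index  PI = P(win) + P(tie)/2,
* net benefit          NB = P(win) - P(loss) = 2 PI - 1,
* win ratio            WR = P(win) / P(loss),
* win odds             WO = (P(win) + P(tie)/2) / (P(loss) + P(tie)/2).

Like the common odds ratio, all of these faithfully summarize the effect
only when the treatment shifts the whole distribution in one direction.

Utility weighting maps each ordinal category to a preference value
(typically 0 = worst state to 1 = perfect health, negatives allowed for
states considered worse than death) and contrasts mean utilities between
arms, optionally standardized by the pooled per-observation utility SD.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .data import TwoArmCounts

__all__ = ["WinStatistics", "UtilitySet", "UtilitySummary", "win_statistics", "utility_summary"]


@dataclass(frozen=True)
class WinStatistics:
    p_win: float
    p_tie: float
    p_loss: float
    probabilistic_index: float
    net_benefit: float
    win_ratio: float  # inf when p_loss == 0
    win_odds: float
    ci: dict[str, tuple[float, float]]
    n_boot: int
    seed: int | None

    def __str__(self) -> str:
        lines = [
            f"P(win) = {self.p_win:.4f}, P(tie) = {self.p_tie:.4f}, "
            f"P(loss) = {self.p_loss:.4f}",
        ]
        for name, value in [
            ("probabilistic index", self.probabilistic_index),
            ("net benefit", self.net_benefit),
            ("win ratio", self.win_ratio),
            ("win odds", self.win_odds),
        ]:
            lo, hi = self.ci.get(name.replace(" ", "_"), (np.nan, np.nan))
            lines.append(f"{name}: {value:.4f} (95% CI {lo:.4f} to {hi:.4f})")
        return "\n".join(lines)


@dataclass(frozen=True)
class UtilitySet:
    """One utility value per category, in scale order."""

    utilities: tuple[float, ...]
    source_label: str = "user-supplied"

    def __post_init__(self) -> None:
        values = tuple(float(u) for u in self.utilities)
        if not all(np.isfinite(values)):
            raise ValueError("utilities must be finite")
        object.__setattr__(self, "utilities", values)


@dataclass(frozen=True)
class UtilitySummary:
    mean_control: float
    mean_treatment: float
    difference: float  # treatment - control
    standardized_difference: float  # difference / pooled per-observation SD
    ci: tuple[float, float]  # for the unstandardized difference
    method: Literal["bootstrap", "delta"]
    source_label: str = "user-supplied"
    standardizer: str = "pooled per-observation utility SD (ddof=1)"


def _win_tie_loss(data: TwoArmCounts) -> tuple[float, float, float]:
    """Exact win/tie/loss probabilities over all nT*nC pairs from the counts."""
    n = data.goodness_counts().astype(float)
    nc, nt = n.sum(axis=1)
    ctrl_worse = nc - np.cumsum(n[0])  # controls strictly worse than category j
    ctrl_better = np.concatenate([[0.0], np.cumsum(n[0])[:-1]])
    wins = float(np.sum(n[1] * ctrl_worse))
    losses = float(np.sum(n[1] * ctrl_better))
    ties = float(np.sum(n[1] * n[0]))
    total = nc * nt
    return wins / total, ties / total, losses / total


def _summaries(p_win: float, p_tie: float, p_loss: float) -> dict[str, float]:
    pi = p_win + 0.5 * p_tie
    return {
        "probabilistic_index": pi,
        "net_benefit": p_win - p_loss,
        "win_ratio": p_win / p_loss if p_loss > 0 else float("inf"),
        "win_odds": (p_win + 0.5 * p_tie) / (p_loss + 0.5 * p_tie)
        if (p_loss + 0.5 * p_tie) > 0
        else float("inf"),
    }


def win_statistics(
    data: TwoArmCounts, n_boot: int = 2000, seed: int | None = None
) -> WinStatistics:
    """Win statistics with seeded percentile-bootstrap 95% CIs.

    Probabilities are computed exactly from the 2 x K counts (no pair
    enumeration); CIs resample category counts within each arm.  When
    ``p_loss`` is zero the win ratio is reported as infinite and its CI
    upper bound is unbounded.
    """
    p_win, p_tie, p_loss = _win_tie_loss(data)
    point = _summaries(p_win, p_tie, p_loss)
    ci: dict[str, tuple[float, float]] = {}
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        n = data.counts
        props = data.proportions()
        draws = {k: np.empty(n_boot) for k in point}
        for b in range(n_boot):
            resampled = np.vstack(
                [
                    rng.multinomial(n[0].sum(), props[0]),
                    rng.multinomial(n[1].sum(), props[1]),
                ]
            )
            boot = TwoArmCounts(data.scale, resampled, data.arm_names)
            for k, v in _summaries(*_win_tie_loss(boot)).items():
                draws[k][b] = v
        for k, arr in draws.items():
            finite = arr[np.isfinite(arr)]
            if finite.size < n_boot:  # infinite win ratios in resamples
                lo = float(np.percentile(finite, 2.5)) if finite.size else float("nan")
                ci[k] = (lo, float("inf"))
            else:
                ci[k] = (
                    float(np.percentile(arr, 2.5)),
                    float(np.percentile(arr, 97.5)),
                )
    return WinStatistics(
        p_win=p_win,
        p_tie=p_tie,
        p_loss=p_loss,
        **point,
        ci=ci,
        n_boot=n_boot,
        seed=seed,
    )


def utility_summary(
    data: TwoArmCounts,
    utilities: UtilitySet,
    method: Literal["bootstrap", "delta"] = "bootstrap",
    n_boot: int = 2000,
    seed: int | None = None,
) -> UtilitySummary:
    """Mean-utility contrast between arms with a 95% CI for the difference.

    The standardized difference divides by the pooled (both arms combined,
    ddof=1) per-observation utility SD; it is invariant to affine rescaling
    of the value set.  When all utilities are equal the standardized
    difference is undefined (NaN).
    """
    u = np.asarray(utilities.utilities, dtype=float)
    if u.size != data.k:
        raise ValueError(f"need {data.k} utilities, got {u.size}")
    n = data.counts.astype(float)
    n_arm = n.sum(axis=1)
    means = (n * u).sum(axis=1) / n_arm
    diff = float(means[1] - means[0])
    pooled = n.sum(axis=0)
    n_total = pooled.sum()
    pooled_mean = (pooled * u).sum() / n_total
    pooled_var = (pooled * (u - pooled_mean) ** 2).sum() / (n_total - 1)
    std_diff = diff / np.sqrt(pooled_var) if pooled_var > 0 else float("nan")

    if method == "delta":
        var_means = ((n * u**2).sum(axis=1) / n_arm - means**2) / n_arm
        half = 1.959963984540054 * float(np.sqrt(var_means.sum()))
        ci = (diff - half, diff + half)
    elif method == "bootstrap":
        rng = np.random.default_rng(seed)
        props = data.proportions()
        draws = np.empty(n_boot)
        for b in range(n_boot):
            mc = rng.multinomial(int(n_arm[0]), props[0]) @ u / n_arm[0]
            mt = rng.multinomial(int(n_arm[1]), props[1]) @ u / n_arm[1]
            draws[b] = mt - mc
        ci = (float(np.percentile(draws, 2.5)), float(np.percentile(draws, 97.5)))
    else:
        raise ValueError(f"unknown CI method: {method!r}")
    return UtilitySummary(
        mean_control=float(means[0]),
        mean_treatment=float(means[1]),
        difference=diff,
        standardized_difference=float(std_diff),
        ci=ci,
        method=method,
        source_label=utilities.source_label,
    )
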