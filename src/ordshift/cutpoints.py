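"""Cut-point odds-ratio diagnostics of the proportional-odds assumption.

An ordinal scale with K categories can be dichotomized at K-1 cut-points.
The proportional-odds assumption says the K-1 resulting binary odds ratios
are all equal, so plotting them with confidence intervals next to the fitted
common odds ratio is a direct graphical check -- usually more informative
than the formal likelihood-ratio test, which trials are rarely powered for.

Odds ratios are oriented clinically: each cut-point compares the odds of an
outcome *at or better than* the cut, treatment over control, so values above
1 mean benefit at that dichotomization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .data import Orientation, TwoArmCounts
from .model import TestResult, fit_po

__all__ = ["CutpointOR", "CORPlotData", "cumulative_ors", "build_cor_plot_data"]

ZeroCellRule = Literal["haldane", "strict"]


@dataclass(frozen=True)
class CutpointOR:
    """One dichotomization's 2x2 odds ratio with a 95% Wald CI on the log scale."""

    cutpoint_index: int  # j in 1..K-1, counted on the goodness-ordered scale
    label: str
    table: np.ndarray  # 2x2 collapsed counts [[ctrl good, ctrl bad], [trt good, trt bad]]
    or_value: float
    log_se: float
    ci_low: float
    ci_high: float
    corrected: bool = False  # Haldane-Anscombe +0.5 applied
    defined: bool = True

    @property
    def log_or(self) -> float:
        return float(np.log(self.or_value))


@dataclass(frozen=True)
class CORPlotData:
    """Everything a cumulative odds-ratio diagnostic plot needs."""

    cutpoint_ors: tuple[CutpointOR, ...]
    common_or: float
    common_or_ci: tuple[float, float]
    po_test: TestResult

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per cut-point with OR and CI bounds."""
        return pd.DataFrame(
            [
                {
                    "cutpoint": c.cutpoint_index,
                    "label": c.label,
                    "or": c.or_value if c.defined else np.nan,
                    "ci_low": c.ci_low if c.defined else np.nan,
                    "ci_high": c.ci_high if c.defined else np.nan,
                    "defined": c.defined,
                    "corrected": c.corrected,
                }
                for c in self.cutpoint_ors
            ]
        )

    def to_json(self, **kwargs) -> str:
        payload = {
            "cutpoint_ors": self.to_frame().to_dict(orient="records"),
            "common_or": self.common_or,
            "common_or_ci": list(self.common_or_ci),
            "po_assumption_test": {
                "statistic": self.po_test.statistic,
                "df": self.po_test.df,
                "p_value": self.po_test.p_value,
            },
        }
        return json.dumps(payload, **kwargs)


def _clinical_label(data: TwoArmCounts, j: int) -> str:
    """Label on the original clinical scale, e.g. 'mRS 0-2 vs 3-6' style."""
    labels = data.scale.labels
    if data.scale.orientation is Orientation.lower_better:
        good = labels[:j]
        bad = labels[j:]
    else:
        good = labels[data.k - j :]
        bad = labels[: data.k - j]

    def span(part: tuple[str, ...]) -> str:
        return part[0] if len(part) == 1 else f"{part[0]}-{part[-1]}"

    return f"{span(tuple(good))} vs {span(tuple(bad))}"


def cumulative_ors(
    data: TwoArmCounts, zero_cell_rule: ZeroCellRule = "haldane"
) -> list[CutpointOR]:
    """The K-1 dichotomization odds ratios with 95% Wald CIs.

    ``zero_cell_rule='haldane'`` adds 0.5 to all four cells of any 2x2 with
    a zero cell (that cut-point only), keeping the CI finite for plotting;
    ``'strict'`` flags such entries undefined instead of fabricating values.
    """
    n = data.goodness_counts().astype(float)
    out: list[CutpointOR] = []
    z = stats.norm.ppf(0.975)
    for j in range(1, data.k):
        good = n[:, :j].sum(axis=1)
        bad = n[:, j:].sum(axis=1)
        table = np.array([[good[0], bad[0]], [good[1], bad[1]]])
        cells = table.copy()
        corrected = False
        if np.any(cells == 0):
            if zero_cell_rule == "strict":
                out.append(
                    CutpointOR(
                        cutpoint_index=j,
                        label=_clinical_label(data, j),
                        table=table,
                        or_value=np.nan,
                        log_se=np.nan,
                        ci_low=np.nan,
                        ci_high=np.nan,
                        defined=False,
                    )
                )
                continue
            cells = cells + 0.5
            corrected = True
        log_or = float(
            np.log(cells[1, 0] * cells[0, 1] / (cells[1, 1] * cells[0, 0]))
        )
        log_se = float(np.sqrt(np.sum(1.0 / cells)))
        out.append(
            CutpointOR(
                cutpoint_index=j,
                label=_clinical_label(data, j),
                table=table,
                or_value=float(np.exp(log_or)),
                log_se=log_se,
                ci_low=float(np.exp(log_or - z * log_se)),
                ci_high=float(np.exp(log_or + z * log_se)),
                corrected=corrected,
            )
        )
    return out


def build_cor_plot_data(
    data: TwoArmCounts, zero_cell_rule: ZeroCellRule = "haldane"
) -> CORPlotData:
    """Bundle cut-point ORs, the fitted common OR with CI, and the PO test."""
    if data.k < 3:
        raise ValueError("cumulative OR diagnostic needs K >= 3 categories")
    res = fit_po(data)
    return CORPlotData(
        cutpoint_ors=tuple(cumulative_ors(data, zero_cell_rule)),
        common_or=res.common_or,
        common_or_ci=res.conf_int_common_or(),
        po_test=res.lr_test_po_assumption(),
    )
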