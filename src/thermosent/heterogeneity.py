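"""Sample-split (heterogeneity) analyses.

Who suffers more under extreme temperatures?  The battery refits the
base specification on complementary halves of the panel defined by
declarative rules — clean-air vs polluted days (PM2.5 at 15 µg/m³),
calm vs windy days (3.3 m/s, the top of Beaufort force 2), weekdays vs
weekends, city-days with vs without newly confirmed COVID-19 cases,
cities north vs south of the Qinling-Huai line, and richer vs poorer
cities split at the median per-capita disposable income.  Each group is
re-estimated with all controls and fixed effects (two separate
regressions per rule, not an interaction-constrained single fit).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import PanelSpec, RegressionResult, fit_fe_ols

log = logging.getLogger("thermosent")


@dataclass(frozen=True)
class SplitRule:
    """Binary partition of panel rows.

    ``op`` is one of ``">"``, ``">="`` or ``"=="``; rows satisfying
    ``variable op threshold`` form the "high" (experimental) group, the
    rest the "low" group.  With ``">="`` threshold-equal rows go high
    (the wind rule); with ``">"`` they go low (the PM2.5 rule).
    """

    name: str
    variable: str
    op: str
    threshold: float | str
    high_label: str = "high"
    low_label: str = "low"

    def mask(self, panel: pd.DataFrame) -> pd.Series:
        x = panel[self.variable]
        if self.op == ">":
            return x > self.threshold
        if self.op == ">=":
            return x >= self.threshold
        if self.op == "==":
            return x == self.threshold
        raise ValueError(f"unknown split operator {self.op!r}")


def default_rules(panel: pd.DataFrame) -> list[SplitRule]:
    """The packaged battery; the income cut is the median PCDI across
    the panel's cities (computed per city, not per row)."""
    rules = [
        SplitRule("pm25", "PM25", ">", 15.0, "polluted", "clean"),
        SplitRule("wind", "WS", ">=", 3.3, "windy", "calm"),
        SplitRule("weekend", "weekend", "==", 1, "weekend", "weekday"),
    ]
    if "NEWC" in panel.columns:
        rules.append(SplitRule("covid", "NEWC", ">", 0, "new_cases", "no_new_cases"))
    if "region" in panel.columns:
        rules.append(SplitRule("region", "region", "==", "north", "north", "south"))
    if "PCDI" in panel.columns:
        cut = float(panel.groupby("city_id")["PCDI"].first().median())
        rules.append(SplitRule("income", "PCDI", ">", cut, "rich", "poor"))
    return rules


def split_sample(panel: pd.DataFrame, rule: SplitRule
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Route rows into (high, low) groups; sizes are logged.

    Rows missing the split variable are excluded from both groups.
    """
    present = panel[rule.variable].notna()
    hi_mask = rule.mask(panel)
    hi = panel[present & hi_mask].reset_index(drop=True)
    lo = panel[present & ~hi_mask].reset_index(drop=True)
    log.info("split %s: %s=%d, %s=%d", rule.name, rule.high_label, len(hi),
             rule.low_label, len(lo))
    return hi, lo


def run_battery(panel: pd.DataFrame, base_spec: PanelSpec,
                rules: list[SplitRule]) -> pd.DataFrame:
    """Fit the base spec per group for every rule.

    Returns a tidy report with one row per (rule, group, term) holding
    the estimate, clustered SE, p-value and group N, in deterministic
    order.  Empty groups are skipped with a warning.  The fitted
    :class:`RegressionResult` objects are kept in ``attrs["fits"]``.
    """
    rows = []
    fits: dict[tuple[str, str], RegressionResult] = {}
    for rule in rules:
        hi, lo = split_sample(panel, rule)
        for label, part in ((rule.high_label, hi), (rule.low_label, lo)):
            if part.empty:
                log.warning("rule %s: group %s empty, fit skipped", rule.name, label)
                continue
            res = fit_fe_ols(part, base_spec)
            fits[(rule.name, label)] = res
            for term in base_spec.regressors:
                rows.append({
                    "rule": rule.name, "group": label, "term": term,
                    "estimate": res.coef(term), "se": res.stderr(term),
                    "p_value": float(res.pvalues[res.terms.index(term)]),
                    "n": res.n,
                })
    report = pd.DataFrame(rows, columns=["rule", "group", "term",
                                         "estimate", "se", "p_value", "n"])
    report.attrs["fits"] = fits
    return report
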