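"""Feature-robustness statistics: |Spearman r_s| and the two-way ICC.

Two assessment metrics are provided, matching how feature robustness is
usually summarized in radiomics stability studies:

* the absolute Spearman rank correlation between a feature's values and the
  number of voxels N across data sets, with a Fisher-z 95% CI, categorized
  as no (< 0.5), moderate (0.5-0.9) or high (> 0.9) correlation; and
* the intraclass correlation coefficient

      ICC = (BMS - RMS) / (BMS + (d - 1) * RMS),

  where BMS is the between-subjects mean square, d the number of levels
  (here: gray-level counts) and RMS a residual mean square.  Two models
  share this algebraic form and both are provided:

  - ``model="oneway"`` (default): one-way random-effects ICC(1,1); RMS is
    the within-subject mean square, so a systematic gray-level trend counts
    as instability.  This is the reading under which a gray-level
    normalization can improve stability at all — a two-way model would
    absorb the common gray-level effect that the normalization is designed
    to remove.
  - ``model="twoway"``: consistency ICC(3,1) from a two-way subjects x
    levels ANOVA without replication; RMS is the residual after removing
    subject and level main effects.

  ICC can be negative when within-subject variance exceeds between-subject
  variance.  The 95% CI uses F-distribution bounds on BMS/RMS.  ICC is
  categorized as not stable (< 0.5), intermediately stable (0.5-0.8) or
  highly stable (> 0.8).

Boundary values fall in the middle category in both scales.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SpearmanResult",
    "ICCResult",
    "spearman_abs",
    "categorize_rs",
    "icc",
    "categorize_icc",
    "RobustnessReport",
]


@dataclass(frozen=True)
class SpearmanResult:
    abs_rs: float
    rs: float
    ci_low: float
    ci_high: float
    n: int


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    n_subjects: int
    n_levels: int


def spearman_abs(x, y, alpha: float = 0.05) -> SpearmanResult:
    """|Spearman r_s| between two sequences with a Fisher-z CI.

    Ties get average ranks (the standard Spearman convention).  The CI is
    computed on the signed coefficient via the Fisher z-transform with
    standard error ``1/sqrt(n - 3)``.  Requires >= 4 pairs and >= 2 distinct
    values in each sequence.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D sequences of equal length")
    n = x.size
    if n < 4:
        raise ValueError(f"correlation requires at least 4 pairs, got {n}")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("correlation undefined: constant sequence")
    rs = float(sps.spearmanr(x, y).statistic)
    z = np.arctanh(np.clip(rs, -1 + 1e-15, 1 - 1e-15))
    se = 1.0 / np.sqrt(n - 3)
    zc = sps.norm.ppf(1 - alpha / 2)
    ci_low = float(np.tanh(z - zc * se))
    ci_high = float(np.tanh(z + zc * se))
    return SpearmanResult(abs_rs=abs(rs), rs=rs, ci_low=ci_low, ci_high=ci_high, n=n)


def categorize_rs(abs_rs: float) -> str:
    """Map |r_s| to the no / moderate / high correlation category."""
    if not 0.0 <= abs_rs <= 1.0:
        raise ValueError(f"|r_s| must be in [0, 1], got {abs_rs}")
    if abs_rs < 0.5:
        return "no"
    if abs_rs <= 0.9:
        return "moderate"
    return "high"


def icc(table, alpha: float = 0.05, model: str = "oneway") -> ICCResult:
    """ICC from a complete subjects x levels table.

    ``ICC = (BMS - RMS) / (BMS + (d - 1) RMS)`` with BMS the
    between-subjects mean square and RMS the within-subject mean square
    (``model="oneway"``, default) or the two-way residual mean square after
    removing subject and level main effects (``model="twoway"``).  95% CI
    from F bounds on BMS/RMS.
    """
    x = np.asarray(table, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("table must be 2D (subjects x levels)")
    n, d = x.shape
    if d < 2:
        raise ValueError("ICC undefined: need at least 2 levels")
    if n < 3:
        raise ValueError("ICC requires at least 3 subjects")
    if not np.all(np.isfinite(x)):
        raise ValueError("table contains missing or non-finite cells")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_total = float(((x - grand) ** 2).sum())
    if ss_total == 0.0:
        raise ValueError("ICC undefined: zero total variance")
    ss_subjects = float(d * ((row_means - grand) ** 2).sum())
    bms = ss_subjects / (n - 1)
    if model == "oneway":
        ss_within = float(((x - row_means[:, None]) ** 2).sum())
        df2 = n * (d - 1)
        rms = ss_within / df2
    elif model == "twoway":
        ss_levels = float(n * ((col_means - grand) ** 2).sum())
        ss_resid = ss_total - ss_subjects - ss_levels
        df2 = (n - 1) * (d - 1)
        rms = max(ss_resid, 0.0) / df2
    else:
        raise ValueError(f"unknown ICC model: {model!r}")

    if rms == 0.0:
        return ICCResult(icc=1.0, ci_low=1.0, ci_high=1.0, n_subjects=n, n_levels=d)

    value = (bms - rms) / (bms + (d - 1) * rms)

    df1 = n - 1
    f_obs = bms / rms
    f_low = f_obs / sps.f.ppf(1 - alpha / 2, df1, df2)
    f_high = f_obs * sps.f.ppf(1 - alpha / 2, df2, df1)
    ci_low = (f_low - 1) / (f_low + d - 1)
    ci_high = (f_high - 1) / (f_high + d - 1)
    return ICCResult(icc=float(value), ci_low=float(ci_low), ci_high=float(ci_high),
                     n_subjects=n, n_levels=d)


def categorize_icc(value: float) -> str:
    """Map an ICC to the not stable / intermediate / highly stable category."""
    if not -1.0 <= value <= 1.0:
        raise ValueError(f"ICC must be in [-1, 1], got {value}")
    if value < 0.5:
        return "not stable"
    if value <= 0.8:
        return "intermediate"
    return "highly stable"


class RobustnessReport:
    """Per-feature robustness statistics with CIs and category labels.

    A thin results object around a tidy DataFrame with columns
    ``feature, variant, statistic, value, ci_low, ci_high, category, n``.
    """

    COLUMNS = ("feature", "variant", "statistic", "value", "ci_low", "ci_high",
               "category", "n")

    def __init__(self, rows: list[dict]):
        self.table = pd.DataFrame(rows, columns=list(self.COLUMNS))

    def value(self, feature: str, variant: str) -> float:
        sub = self.table[(self.table.feature == feature) & (self.table.variant == variant)]
        if len(sub) != 1:
            raise KeyError(f"no unique entry for ({feature!r}, {variant!r})")
        return float(sub.value.iloc[0])

    def category(self, feature: str, variant: str) -> str:
        sub = self.table[(self.table.feature == feature) & (self.table.variant == variant)]
        if len(sub) != 1:
            raise KeyError(f"no unique entry for ({feature!r}, {variant!r})")
        return str(sub.category.iloc[0])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_records(self) -> list[dict]:
        return self.table.to_dict(orient="records")

    def summary(self) -> str:
        """Human-readable fixed-width table of the report."""
        lines = [f"{'feature':<26} {'variant':<18} {'stat':<13} "
                 f"{'value':>8} {'95% CI':>18} {'category':<14} {'n':>5}"]
        lines.append("-" * len(lines[0]))
        for _, r in self.table.iterrows():
            ci = f"[{r.ci_low: .3f},{r.ci_high: .3f}]"
            lines.append(
                f"{r.feature:<26} {r.variant:<18} {r.statistic:<13} "
                f"{r.value:>8.3f} {ci:>18} {r.category:<14} {int(r.n):>5}"
            )
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<RobustnessReport: {len(self.table)} entries>"
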