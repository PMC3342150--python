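"""Performance and validation statistics.

Everything needed to turn classifier output and qPCR measurements into the
numbers a biomarker study reports: 2x2 confusion tables with sensitivity and
specificity, odds ratios with Woolf 95% confidence intervals, delta-Ct relative
quantification against a reference miRNA (miR-16), Welch t-tests between
clinical groups, and Pearson correlation between sequencing counts and
PCR-determined levels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConfusionTable",
    "OddsRatioResult",
    "PcrTable",
    "confusion_metrics",
    "confusion_from_predictions",
    "odds_ratio",
    "pcr_relative_level",
    "group_t_test",
    "seq_pcr_correlation",
    "round_half_up_percent",
]

POSITIVE_LABEL = "relapsed"
NEGATIVE_LABEL = "non-relapsed"
PCR_REFERENCE_GENE = "hsa-miR-16"


def round_half_up_percent(fraction: float) -> int:
    """Round a fraction to an integer percent with ties going up (7/8 -> 88%)."""
    return int(math.floor(fraction * 100.0 + 0.5))


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 predicted-vs-observed table.

    tp: observed positive, predicted positive; fn: observed positive, predicted
    negative; fp: observed negative, predicted positive; tn: observed negative,
    predicted negative.
    """

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a non-negative integer, got {v}")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def swapped(self) -> "ConfusionTable":
        """Simultaneously swap the positive/negative label of predictions and observations."""
        return ConfusionTable(tp=self.tn, fn=self.fp, fp=self.fn, tn=self.tp)


@dataclass(frozen=True)
class OddsRatioResult:
    or_value: float
    ci_low: float
    ci_high: float
    p_value: float
    corrected: bool = False  # Haldane-Anscombe +0.5 applied
    defined: bool = True


@dataclass
class PcrTable:
    """Per-sample per-gene qPCR threshold cycles.

    ``ct`` is a samples x genes DataFrame of Ct values; ``reference`` names the
    normalisation gene (miR-16 by default) and must be a column of ``ct``.
    """

    ct: pd.DataFrame
    reference: str = PCR_REFERENCE_GENE

    def __post_init__(self) -> None:
        if self.reference not in self.ct.columns:
            raise ValueError(f"reference gene {self.reference!r} missing from Ct table")
        ref = self.ct[self.reference]
        if not np.isfinite(ref.to_numpy(dtype=float)).all():
            raise ValueError("reference gene must have a finite Ct in every sample")

    def relative_levels(self) -> pd.DataFrame:
        """miR-16-normalised relative levels 2^(Ct_ref - Ct_gene) per sample."""
        ref = self.ct[self.reference].to_numpy(dtype=float)
        vals = 2.0 ** (ref[:, None] - self.ct.to_numpy(dtype=float))
        return pd.DataFrame(vals, index=self.ct.index, columns=self.ct.columns)


def confusion_from_predictions(
    predicted: Sequence[str], observed: Sequence[str], positive: str = POSITIVE_LABEL
) -> ConfusionTable:
    """Tally a ConfusionTable from aligned predicted and observed label sequences."""
    if len(predicted) != len(observed):
        raise ValueError("predicted and observed must be the same length")
    tp = fn = fp = tn = 0
    for p, o in zip(predicted, observed):
        if o == positive:
            if p == positive:
                tp += 1
            else:
                fn += 1
        else:
            if p == positive:
                fp += 1
            else:
                tn += 1
    return ConfusionTable(tp, fn, fp, tn)


def confusion_metrics(t: ConfusionTable) -> tuple[float, float]:
    """Sensitivity tp/(tp+fn) and specificity tn/(tn+fp) as fractions.

    Percent display uses :func:`round_half_up_percent`. A zero row total makes
    the corresponding metric NaN (flagged undefined) rather than raising.
    """
    sens = t.tp / (t.tp + t.fn) if (t.tp + t.fn) > 0 else float("nan")
    spec = t.tn / (t.tn + t.fp) if (t.tn + t.fp) > 0 else float("nan")
    return sens, spec


def odds_ratio(t: ConfusionTable) -> OddsRatioResult:
    """Cross-product odds ratio with Woolf 95% CI and Wald p-value.

    For a single binary predictor the unconditional logistic-regression odds
    ratio equals (tp*tn)/(fn*fp); the CI is exp(log OR +/- 1.96*SE) with
    SE = sqrt(1/tp + 1/fn + 1/fp + 1/tn). When any cell is zero every cell gets
    the Haldane-Anscombe +0.5 correction and the result is flagged
    ``corrected``. Two zero cells in the same margin leave the OR undefined.
    """
    a, b, c, d = float(t.tp), float(t.fn), float(t.fp), float(t.tn)
    margins = [(a, b), (c, d), (a, c), (b, d)]
    if any(x == 0 and y == 0 for x, y in margins):
        return OddsRatioResult(float("nan"), float("nan"), float("nan"), float("nan"),
                               corrected=False, defined=False)
    corrected = False
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    or_value = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(or_value)
    ci_low = math.exp(log_or - 1.959963984540054 * se)
    ci_high = math.exp(log_or + 1.959963984540054 * se)
    z = log_or / se
    p = 2.0 * stats.norm.sf(abs(z))
    return OddsRatioResult(or_value, ci_low, ci_high, float(p), corrected=corrected)


def pcr_relative_level(ct_gene: float, ct_ref: float) -> float:
    """Delta-Ct relative quantification: 2^(Ct_ref - Ct_gene)."""
    if not (math.isfinite(ct_gene) and math.isfinite(ct_ref)):
        raise ValueError("Ct values must be finite")
    return 2.0 ** (ct_ref - ct_gene)


def group_t_test(
    values_g1: Sequence[float], values_g2: Sequence[float]
) -> tuple[float, float, tuple[float, float], tuple[float, float]]:
    """Two-sided Welch t-test between two groups of (log2) relative levels.

    Returns (t, p, (mean1, mean2), (sem1, sem2)). If both groups have zero
    variance and equal means the test is degenerate and (0, 1) is returned.
    """
    x = np.asarray(values_g1, dtype=float)
    y = np.asarray(values_g2, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    means = (float(x.mean()), float(y.mean()))
    sems = (float(stats.sem(x)), float(stats.sem(y)))
    if x.std(ddof=1) == 0.0 and y.std(ddof=1) == 0.0:
        if means[0] == means[1]:
            return 0.0, 1.0, means, sems
        return float("inf") if means[0] > means[1] else float("-inf"), 0.0, means, sems
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p), means, sems


def seq_pcr_correlation(
    log2_counts: Sequence[float], pcr_levels: Sequence[float]
) -> tuple[float, float]:
    """Pearson correlation between sequencing log2 counts and PCR relative levels.

    PCR levels are log2-transformed internally before correlating; the p-value
    is the two-sided t transform with n-2 degrees of freedom. Zero variance on
    either side yields (nan, nan), flagged undefined.
    """
    x = np.asarray(log2_counts, dtype=float)
    y = np.log2(np.asarray(pcr_levels, dtype=float))
    if x.size != y.size:
        raise ValueError("paired vectors must be the same length")
    if x.size < 3:
        raise ValueError("need at least 3 paired samples")
    if x.std() == 0.0 or y.std() == 0.0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
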