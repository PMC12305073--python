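"""Assumption-gated two-group comparisons shared across the pipeline.

The same decision rule is used for peri-stimulation jaw displacement and for
bouton-density contrasts: check distributional assumptions first (Shapiro-Wilk
normality; Levene equal-variance for independent samples), then run the
parametric test if they hold and the rank-based analogue otherwise.  All tests
are two-sided with significance declared at P < 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import InsufficientDataError, PairingError

ALPHA = 0.05


@dataclass
class TestReport:
    """Outcome of a single hypothesis test.

    Attributes
    ----------
    method : str
        Name of the test that was actually run after assumption gating.
    statistic, pvalue : float
        Test statistic and two-sided p-value.
    estimate : float
        Point estimate of the effect (mean difference, or model coefficient).
    se : float
        Standard error of the estimate where the method provides one, else NaN.
    significant : bool
        ``pvalue < 0.05``.
    n : int
        Number of observations (pairs for paired tests).
    assumptions : dict
        P-values of the gating tests that were evaluated.
    """

    method: str
    statistic: float
    pvalue: float
    estimate: float = float("nan")
    se: float = float("nan")
    n: int = 0
    assumptions: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return bool(self.pvalue < ALPHA)


def _shapiro_p(x: np.ndarray) -> float:
    # constant samples make Shapiro-Wilk undefined; treat them as non-normal
    if np.ptp(x) == 0:
        return 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(sps.shapiro(x).pvalue)


def gated_group_comparison(
    x, y, *, paired: bool = False, alpha: float = ALPHA
) -> TestReport:
    """Compare two samples with an assumption-gated parametric/rank test.

    Paired branch: Shapiro-Wilk on the differences decides between the paired
    t test and the Wilcoxon signed-rank test.  Independent branch: Shapiro-Wilk
    on each sample plus Levene's test decide between Student's t test and the
    Wilcoxon rank-sum test.

    Parameters
    ----------
    x, y : array-like
        The two samples; equal length required when ``paired``.
    paired : bool
        Whether observations are matched across samples.
    alpha : float
        Level for both the assumption gates and the significance call.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size < 3:
        raise InsufficientDataError(
            f"need at least 3 observations per group, got {x.size} and {y.size}"
        )
    if paired:
        if x.size != y.size:
            raise PairingError(
                f"paired comparison requires equal sizes, got {x.size} vs {y.size}"
            )
        d = x - y
        if np.all(d == 0):
            # all differences are zero: no evidence of any effect
            return TestReport(
                method="degenerate (all differences zero)",
                statistic=0.0,
                pvalue=1.0,
                estimate=0.0,
                se=0.0,
                n=x.size,
                assumptions={},
            )
        sw = _shapiro_p(d)
        if sw > alpha:
            res = sps.ttest_rel(x, y)
            method = "paired t test"
        else:
            res = sps.wilcoxon(x, y, alternative="two-sided")
            method = "Wilcoxon signed-rank"
        return TestReport(
            method=method,
            statistic=float(res.statistic),
            pvalue=float(res.pvalue),
            estimate=float(np.mean(d)),
            se=float(np.std(d, ddof=1) / np.sqrt(d.size)),
            n=x.size,
            assumptions={"shapiro_diff": sw},
        )

    sw_x, sw_y = _shapiro_p(x), _shapiro_p(y)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lev = float(sps.levene(x, y).pvalue) if (np.ptp(x) or np.ptp(y)) else 1.0
    if sw_x > alpha and sw_y > alpha and lev > alpha:
        res = sps.ttest_ind(x, y, equal_var=True)
        method = "independent t test"
    else:
        res = sps.ranksums(x, y)
        method = "Wilcoxon rank-sum"
    est = float(np.mean(x) - np.mean(y))
    se = float(
        np.sqrt(np.var(x, ddof=1) / x.size + np.var(y, ddof=1) / y.size)
    )
    return TestReport(
        method=method,
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        estimate=est,
        se=se,
        n=int(x.size + y.size),
        assumptions={"shapiro_x": sw_x, "shapiro_y": sw_y, "levene": lev},
    )
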