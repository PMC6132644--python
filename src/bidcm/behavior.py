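"""Behavioural analysis: paired comparisons of novel vs practiced trials.

The task manipulation is validated behaviourally by paired-sample t tests
on per-subject condition means: practiced items should be answered faster
and more accurately than novel items (successful pre-scan automatisation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["PairedTestResult", "paired_t", "behavior_tests"]


@dataclass(frozen=True)
class PairedTestResult:
    """Paired-sample t test on d = x - y."""

    t: float
    df: int
    p: float
    mean_difference: float
    ci95: tuple[float, float]
    overflow: bool = False   # zero-variance differences with nonzero mean

    def summary(self) -> str:
        return (f"t({self.df}) = {self.t:.2f}, p = {self.p:.3g}, "
                f"mean difference = {self.mean_difference:.2f} "
                f"[{self.ci95[0]:.2f}, {self.ci95[1]:.2f}]")


def paired_t(x, y) -> PairedTestResult:
    """Two-sided paired-sample t test.

    t = mean(d) / (sd(d) / sqrt(n)) on d = x - y, with n - 1 degrees of
    freedom.  Zero-variance differences with a nonzero mean give an
    infinite t (flagged ``overflow``) rather than an error.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    d = x - y
    n = d.size
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        if md == 0.0:
            return PairedTestResult(t=0.0, df=df, p=1.0, mean_difference=0.0,
                                    ci95=(0.0, 0.0))
        return PairedTestResult(t=float(np.sign(md)) * np.inf, df=df, p=0.0,
                                mean_difference=md, ci95=(md, md),
                                overflow=True)
    se = sd / np.sqrt(n)
    t = md / se
    p = float(2.0 * stats.t.sf(abs(t), df))
    crit = float(stats.t.ppf(0.975, df))
    return PairedTestResult(t=float(t), df=df, p=min(p, 1.0),
                            mean_difference=md,
                            ci95=(md - crit * se, md + crit * se))


def behavior_tests(table: pd.DataFrame) -> dict[str, PairedTestResult]:
    """Run the two planned comparisons on a behaviour table.

    ``rt``: novel minus practiced reaction time (positive = slowing for
    novel items); ``accuracy``: practiced minus novel accuracy (positive =
    more accurate after practice).
    """
    return {
        "rt": paired_t(table["rt_novel"], table["rt_practiced"]),
        "accuracy": paired_t(table["accuracy_practiced"],
                             table["accuracy_novel"]),
    }
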