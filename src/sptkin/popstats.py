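"""Aggregate bound fractions across repeats and compare conditions."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from scipy import stats

from .errors import InsufficientDataError

__all__ = ["RepeatSet", "summarize", "compare_fbound", "write_comparison_csv"]


@dataclass
class RepeatSet:
    """Per-repeat bound-fraction values for one condition."""

    label: str
    fbound_values: list[float] = field(default_factory=list)
    pooled_fbound: float | None = None

    def __post_init__(self):
        for v in self.fbound_values:
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"F_bound value {v} outside [0, 1]")
        if self.pooled_fbound is not None and not 0.0 <= self.pooled_fbound <= 1.0:
            raise ValueError("pooled F_bound outside [0, 1]")


def summarize(repeats: RepeatSet) -> tuple[float, float, float]:
    """Sample mean, sample SD (n-1 denominator) and SEM of the repeat values."""
    vals = repeats.fbound_values
    n = len(vals)
    if n < 2:
        raise InsufficientDataError(
            f"condition '{repeats.label}' has {n} repeat(s); need >= 2"
        )
    mean = sum(vals) / n
    var = sum((v - mean) ** 2 for v in vals) / (n - 1)
    sd = math.sqrt(var)
    return mean, sd, sd / math.sqrt(n)


def compare_fbound(a: RepeatSet, b: RepeatSet) -> tuple[float, float, int]:
    """Unpaired two-tailed Student's t-test (pooled variance).

    Returns (t, p, df). When both groups have zero variance and equal means
    the test is degenerate; p = 1 is returned with a warning.
    """
    mean_a, sd_a, _ = summarize(a)
    mean_b, sd_b, _ = summarize(b)
    na, nb = len(a.fbound_values), len(b.fbound_values)
    df = na + nb - 2
    pooled_var = ((na - 1) * sd_a**2 + (nb - 1) * sd_b**2) / df
    if pooled_var == 0.0:
        if mean_a == mean_b:
            warnings.warn(
                "zero pooled variance with equal means; p = 1 by convention",
                RuntimeWarning,
            )
            return 0.0, 1.0, df
        t = math.inf if mean_a > mean_b else -math.inf
        return t, 0.0, df
    t = (mean_a - mean_b) / math.sqrt(pooled_var * (1.0 / na + 1.0 / nb))
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, float(p), df


def write_comparison_csv(pairs: list[tuple[RepeatSet, RepeatSet]], path) -> None:
    """Write one row per condition pair:
    label_a, label_b, mean_a, mean_b, t, df, p."""
    with open(path, "w") as fh:
        fh.write("label_a,label_b,mean_a,mean_b,t,df,p\n")
        for a, b in pairs:
            mean_a, _, _ = summarize(a)
            mean_b, _, _ = summarize(b)
            t, p, df = compare_fbound(a, b)
            fh.write(
                f"{a.label},{b.label},{mean_a:.6g},{mean_b:.6g},"
                f"{t:.6g},{df},{p:.6g}\n"
            )
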