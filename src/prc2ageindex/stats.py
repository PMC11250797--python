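"""Group comparisons, age/passage correlation, and sample-QC outlier rules."""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .core import Methylome


@dataclass
class GroupComparison:
    """One-sided independent two-sample t-test result."""

    mean_a: float
    mean_b: float
    t: float
    p: float
    df: float
    alternative: str
    variant: str


@dataclass
class OutlierReport:
    means: dict[str, float]
    rule: str
    flagged: list[str]
    bounds: tuple[float, float] | None = None


@dataclass
class CorrelationResult:
    r: float
    p: float
    slope: float
    intercept: float
    n: int


def one_sided_t_test(
    a: Sequence[float],
    b: Sequence[float],
    alternative: str = "b_greater",
    variant: str = "pooled",
) -> GroupComparison:
    """One-sided independent t-test between two groups of index values.

    ``variant='pooled'`` is the classic equal-variance Student test
    (df = na + nb - 2); ``'welch'`` uses the Welch–Satterthwaite df.  With
    identical data t = 0 and p = 0.5 by symmetry.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two values")
    if alternative not in ("a_greater", "b_greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown variant {variant!r}")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        # degenerate: both groups constant
        if a.mean() == b.mean():
            df = a.size + b.size - 2
            return GroupComparison(
                float(a.mean()), float(b.mean()), 0.0, 0.5, df, alternative, variant
            )
        t = np.inf if a.mean() > b.mean() else -np.inf
        p = 0.0 if (t > 0) == (alternative == "a_greater") else 1.0
        return GroupComparison(
            float(a.mean()),
            float(b.mean()),
            float(t),
            float(p),
            float(a.size + b.size - 2),
            alternative,
            variant,
        )
    scipy_alt = "greater" if alternative == "a_greater" else "less"
    res = sps.ttest_ind(
        a, b, equal_var=(variant == "pooled"), alternative=scipy_alt
    )
    return GroupComparison(
        float(a.mean()),
        float(b.mean()),
        float(res.statistic),
        float(res.pvalue),
        float(res.df),
        alternative,
        variant,
    )


def _global_means(samples) -> dict[str, float]:
    if isinstance(samples, Mapping):
        return {str(k): float(v) for k, v in samples.items()}
    out = {}
    for m in samples:
        if not isinstance(m, Methylome):
            raise TypeError("expected Methylomes or a sample -> mean mapping")
        out[m.sample_id] = m.global_mean_beta()
    return out


def detect_outliers(
    samples,
    rule: str = "anchor_range",
    anchors: tuple[str, str] | tuple[float, float] | None = None,
    z_cut: float = 3.0,
) -> OutlierReport:
    """Flag samples whose global mean methylation is anomalous.

    ``anchor_range`` flags samples outside the interval spanned by two anchor
    samples (e.g. the neonatal and centenarian extremes); ``zscore`` flags
    |z| > ``z_cut`` on the global means and needs at least three samples.
    """
    means = _global_means(samples)
    if rule == "anchor_range":
        if anchors is None or len(anchors) != 2:
            raise ValueError("anchor_range needs a pair of anchors")
        vals = []
        anchor_ids = set()
        for anc in anchors:
            if isinstance(anc, str):
                if anc not in means:
                    raise KeyError(f"anchor sample {anc!r} not found")
                vals.append(means[anc])
                anchor_ids.add(anc)
            else:
                vals.append(float(anc))
        lo, hi = min(vals), max(vals)
        flagged = [
            s
            for s, v in means.items()
            if s not in anchor_ids and not (lo <= v <= hi)
        ]
        return OutlierReport(means, rule, flagged, bounds=(lo, hi))
    if rule == "zscore":
        if len(means) < 3:
            raise ValueError("zscore rule needs at least three samples")
        vals = np.array(list(means.values()))
        mu, sd = vals.mean(), vals.std(ddof=1)
        if sd == 0.0:
            return OutlierReport(means, rule, [])
        flagged = [
            s for s, v in means.items() if abs((v - mu) / sd) > z_cut
        ]
        return OutlierReport(means, rule, flagged)
    raise ValueError(f"unknown rule {rule!r}")


def correlate(values: Sequence[float], covariate: Sequence[float]) -> CorrelationResult:
    """Pearson correlation and least-squares line of index versus age/passage."""
    y = np.asarray(values, dtype=float)
    x = np.asarray(covariate, dtype=float)
    if y.size != x.size:
        raise ValueError("values and covariate differ in length")
    if y.size < 3:
        raise ValueError("need at least three paired values")
    if np.all(x == x[0]):
        raise ValueError("covariate is constant")
    lr = sps.linregress(x, y)
    return CorrelationResult(
        r=float(lr.rvalue),
        p=float(lr.pvalue),
        slope=float(lr.slope),
        intercept=float(lr.intercept),
        n=int(y.size),
    )
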