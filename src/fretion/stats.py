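"""Two-sample statistics and the permutation power analysis.

Per-image FRET indices are compared between genotypes or states with Welch's
unequal-variance t-test; association is measured by Pearson's r.  The power
analysis estimates, for each sample size ``k``, the minimal detectable
difference (MDD): the smallest shift of the group mean that a two-sample
t-test at significance ``alpha`` would detect with the requested power,
given the spread actually observed in the data.  The observed spread is
estimated by repeatedly drawing ``k`` values without replacement and
averaging the subsample standard deviation; the detectable standardized
effect size d*(alpha, power, k) comes from the noncentral-t power equation,
so ``MDD(k) = d*(k) * mean SD``.  A closed-form version
(:func:`mdd_closed_form`) serves as an independent oracle for the
permutation estimate on Gaussian data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

__all__ = [
    "SampleSet",
    "TestResult",
    "PowerCurve",
    "welch_test",
    "pearson",
    "effect_size",
    "detectable_effect_size",
    "mdd_closed_form",
    "mdd_permutation",
    "significance_stars",
]


@dataclass(frozen=True)
class SampleSet:
    """A labelled group of per-image (per-animal) scalar values."""

    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or vals.size < 2:
            raise ValueError("SampleSet needs a 1-D array of >= 2 values")
        if not np.all(np.isfinite(vals)):
            raise ValueError("SampleSet values must be finite")

    @property
    def n(self) -> int:
        return int(self.values.size)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1))


def significance_stars(p: float) -> str:
    """Star convention: *** p<=0.001, ** p<=0.01, * p<=0.05, else n.s."""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "n.s."


@dataclass(frozen=True)
class TestResult:
    t: float
    df: float
    p: float
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    label_a: str = "a"
    label_b: str = "b"
    flag: str | None = None

    @property
    def stars(self) -> str:
        return significance_stars(self.p)


def welch_test(a: SampleSet, b: SampleSet) -> TestResult:
    """Welch's unequal-variance two-sample t-test (two-sided).

    t = (mean_a - mean_b) / sqrt(s_a^2/n_a + s_b^2/n_b) with
    Welch-Satterthwaite degrees of freedom.  Implemented from the formula;
    agrees with ``scipy.stats.ttest_ind(equal_var=False)``.
    """
    va, vb = a.values, b.values
    na, nb = a.n, b.n
    ma, mb = va.mean(), vb.mean()
    sa2 = va.var(ddof=1)
    sb2 = vb.var(ddof=1)
    se2 = sa2 / na + sb2 / nb
    flag = None
    if se2 == 0.0:
        if ma == mb:
            t, df, p = 0.0, float(na + nb - 2), 1.0
        else:
            t = math.copysign(math.inf, ma - mb)
            df, p = float(na + nb - 2), 0.0
            flag = "zero-variance samples with unequal means"
        return TestResult(t, df, p, ma, mb, na, nb, a.label, b.label, flag)
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / (sa2**2 / (na**2 * (na - 1)) + sb2**2 / (nb**2 * (nb - 1)))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(float(t), float(df), float(p), ma, mb, na, nb, a.label, b.label)


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation; NaN (flagged) on zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("pearson needs two equal-length arrays with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(sps.pearsonr(x, y).statistic)


def effect_size(a: SampleSet, b: SampleSet) -> float:
    """Standardized mean difference d = (mu1 - mu2) / sigma, pooled sigma."""
    na, nb = a.n, b.n
    pooled = math.sqrt(
        ((na - 1) * a.values.var(ddof=1) + (nb - 1) * b.values.var(ddof=1))
        / (na + nb - 2)
    )
    if pooled == 0:
        raise ValueError("effect size undefined: pooled standard deviation is 0")
    return (a.mean - b.mean) / pooled


def _power_two_sample(d: float, n_per_group: int, alpha: float) -> float:
    """Power of a two-sided two-sample t-test at standardized effect d."""
    df = 2 * n_per_group - 2
    ncp = d * math.sqrt(n_per_group / 2.0)
    tcrit = sps.t.isf(alpha / 2.0, df)
    # rejection in either tail under the noncentral alternative; scipy's nct
    # CDF underflows to NaN at large noncentrality, where the tail is 0
    upper = sps.nct.sf(tcrit, df, ncp)
    lower = sps.nct.cdf(-tcrit, df, ncp)
    return float(np.nan_to_num(upper) + np.nan_to_num(lower))


def detectable_effect_size(
    n_per_group: int, alpha: float = 0.05, power: float = 0.8
) -> float:
    """Smallest standardized effect d* reaching the requested power."""
    if n_per_group < 2:
        raise ValueError("need n >= 2 per group")
    lo, hi = 1e-9, 50.0
    if _power_two_sample(hi, n_per_group, alpha) < power:
        raise ValueError("no detectable effect size in bracket")
    return float(
        optimize.brentq(
            lambda d: _power_two_sample(d, n_per_group, alpha) - power, lo, hi
        )
    )


def mdd_closed_form(
    sigma: float, n_per_group: int, alpha: float = 0.05, power: float = 0.8
) -> float:
    """Closed-form minimal detectable difference d*(alpha, power, n) * sigma."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    return detectable_effect_size(n_per_group, alpha, power) * sigma


@dataclass(frozen=True)
class PowerCurve:
    """Per-sample-size permutation power summary.

    ``table`` columns: k, d_mean (mean absolute half-split effect size over
    permutations), sd_mean (mean subsample SD), mdd_units (index units),
    mdd_percent (as % of the dataset mean).
    """

    table: pd.DataFrame
    alpha: float
    power: float
    n_permutations: int
    seed: int
    dataset_label: str = ""
    extras: dict = field(default_factory=dict)

    def mdd(self, k: int) -> float:
        row = self.table.loc[self.table["k"] == k]
        if row.empty:
            raise KeyError(f"no sample size k={k} in power curve")
        return float(row["mdd_units"].iloc[0])


def mdd_permutation(
    dataset: SampleSet,
    alpha: float = 0.05,
    power: float = 0.8,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> PowerCurve:
    """Permutation estimate of the minimal detectable difference.

    For each subsample size k = 2..n the dataset is resampled without
    replacement ``n_permutations`` times; each draw contributes its sample
    SD and the absolute standardized difference between a random half-split
    of the draw.  MDD(k) = d*(alpha, power, k) x mean SD, reported both in
    index units and as a percentage of the dataset mean.
    """
    values = dataset.values
    n = values.size
    if n < 4:
        raise ValueError("permutation power analysis needs n >= 4")
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(2, n + 1):
        sds = np.empty(n_permutations)
        dvals = np.empty(n_permutations)
        for i in range(n_permutations):
            draw = rng.choice(values, size=k, replace=False)
            sd = draw.std(ddof=1)
            sds[i] = sd
            half = k // 2
            if sd > 0 and half >= 1 and k - half >= 1:
                perm = rng.permutation(draw)
                dvals[i] = abs(perm[:half].mean() - perm[half:].mean()) / sd
            else:
                dvals[i] = 0.0
        mean_sd = float(sds.mean())
        dstar = detectable_effect_size(k, alpha, power) if k >= 2 else float("nan")
        mdd_units = dstar * mean_sd
        rows.append(
            {
                "k": k,
                "d_mean": float(dvals.mean()),
                "sd_mean": mean_sd,
                "d_star": dstar,
                "mdd_units": mdd_units,
                "mdd_percent": 100.0 * mdd_units / abs(dataset.mean)
                if dataset.mean != 0
                else float("nan"),
            }
        )
    return PowerCurve(
        table=pd.DataFrame(rows),
        alpha=alpha,
        power=power,
        n_permutations=n_permutations,
        seed=seed,
        dataset_label=dataset.label,
    )
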