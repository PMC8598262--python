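"""Assay statistics: 3-SD outlier removal, carrier-control normalization,
paired and nested t-tests, one-way ANOVA with Tukey HSD, 95% confidence
intervals and significance star codes.

The nested t-test treats the *patient* as the experimental unit: droplets
(technical replicates) are first collapsed to unweighted per-patient means
and an equal-variance two-sample Student t is run on those means, the exact
equivalent of the nested mixed model for balanced designs.  Droplet-level
pseudo-replication therefore never inflates the degrees of freedom.

Equal-variance (Student, not Welch) forms are used throughout, matching the
classical named tests.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatsResult",
    "OutlierResult",
    "star_code",
    "remove_outliers",
    "normalize_to_control",
    "paired_t_test",
    "nested_t_test",
    "two_sample_t_test",
    "anova_tukey",
    "mean_ci95",
]


def star_code(p: float) -> str:
    """Map a p-value to the conventional star code.

    ``ns`` for p >= 0.05, then ``*`` < 0.05, ``**`` < 0.01, ``***`` < 0.001
    and ``****`` < 0.0001 — strict inequalities at every boundary.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p-value {p} outside [0, 1]")
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class StatsResult:
    """One hypothesis-test or summary outcome."""

    test_name: str
    groups: tuple
    n: tuple
    statistic: float
    df: float
    p_value: float
    ci95: tuple | None = None
    adjusted: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0 + 1e-12:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")
        self.p_value = float(min(self.p_value, 1.0))
        if self.ci95 is not None and self.ci95[0] > self.ci95[1]:
            raise ValueError("ci95 low > high")

    @property
    def stars(self) -> str:
        return star_code(self.p_value)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["groups"] = list(self.groups)
        d["n"] = [int(x) for x in self.n]
        d["ci95"] = list(self.ci95) if self.ci95 is not None else None
        d["stars"] = self.stars
        return d


@dataclass
class OutlierResult:
    kept: np.ndarray
    removed_indices: np.ndarray
    mean: float
    sd: float


def remove_outliers(values) -> OutlierResult:
    """Drop values more than three sample SDs from the mean — one pass.

    Mean and SD (n-1 denominator) are computed on the *full* input; points
    with |x - mean| > 3*SD are removed.  No re-iteration after removal.
    Below n = 3 (or at zero SD) nothing is removed.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("remove_outliers expects a 1D sample")
    if x.size < 3:
        warnings.warn(
            f"outlier filter skipped: only {x.size} values", stacklevel=2
        )
        return OutlierResult(x.copy(), np.empty(0, int), float("nan"), float("nan"))
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0:
        return OutlierResult(x.copy(), np.empty(0, int), mean, sd)
    out = np.abs(x - mean) > 3.0 * sd
    return OutlierResult(x[~out], np.flatnonzero(out), mean, sd)


def normalize_to_control(
    table: pd.DataFrame,
    metric: str,
    control_level: str,
    group_col: str = "condition",
    replicate_col: str | None = None,
) -> pd.DataFrame:
    """Divide each droplet's metric by the mean of the carrier/control group.

    When ``replicate_col`` is given, normalization is within each replicate
    experiment (each replicate must contain the control level); otherwise a
    single pooled control mean is used.  Adds ``{metric}_fold``; the control
    group's normalized mean is exactly 1 within each replicate.
    """
    if metric not in table.columns:
        raise KeyError(f"metric column {metric!r} not in table")
    if control_level not in set(table[group_col]):
        raise ValueError(f"control level {control_level!r} absent from {group_col!r}")
    out = table.copy()
    fold_col = f"{metric}_fold"

    def _control_mean(df: pd.DataFrame, label: str) -> float:
        ctrl = df.loc[df[group_col] == control_level, metric].dropna()
        if ctrl.empty:
            raise ValueError(f"no control ({control_level!r}) values in {label}")
        m = float(ctrl.mean())
        if m == 0:
            raise ValueError(
                f"control group {control_level!r} has zero mean in {label}"
            )
        return m

    if replicate_col is None:
        out[fold_col] = out[metric] / _control_mean(out, "the pooled table")
    else:
        missing = [
            rep
            for rep, sub in out.groupby(replicate_col)
            if not (sub[group_col] == control_level).any()
        ]
        if missing:
            raise ValueError(
                f"replicates missing the control level {control_level!r}: {missing}"
            )
        out[fold_col] = np.nan
        for rep, sub in out.groupby(replicate_col):
            out.loc[sub.index, fold_col] = sub[metric] / _control_mean(
                sub, f"replicate {rep!r}"
            )
    return out


def _t_ci(mean: float, se: float, df: float) -> tuple:
    if se == 0 or df < 1:
        return (mean, mean)
    half = float(sps.t.ppf(0.975, df)) * se
    return (mean - half, mean + half)


def paired_t_test(x, y, groups: tuple = ("x", "y")) -> StatsResult:
    """Classical paired Student t on the within-pair differences.

    Two-sided p and a 95% CI of the mean difference.  Identical samples
    (zero-variance, zero-mean differences) give t = 0, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"paired samples differ in length: {x.size} vs {y.size}")
    n = x.size
    if n < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    d = x - y
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    if sd == 0:
        t = 0.0 if md == 0 else float(np.inf) * np.sign(md)
        p = 1.0 if md == 0 else 0.0
    else:
        t = md / (sd / np.sqrt(n))
        p = float(2.0 * sps.t.sf(abs(t), df))
    return StatsResult(
        test_name="paired_t",
        groups=tuple(groups),
        n=(n, n),
        statistic=float(t),
        df=float(df),
        p_value=p,
        ci95=_t_ci(md, sd / np.sqrt(n) if sd else 0.0, df),
    )


def two_sample_t_test(a, b, groups: tuple = ("a", "b"), test_name: str = "student_t") -> StatsResult:
    """Unpaired equal-variance (pooled-SD) Student t, two-sided."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    n1, n2 = a.size, b.size
    df = n1 + n2 - 2
    diff = float(a.mean() - b.mean())
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df
    se = float(np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2)))
    if se == 0:
        t, p = (0.0, 1.0) if diff == 0 else (float(np.inf) * np.sign(diff), 0.0)
    else:
        t = diff / se
        p = float(2.0 * sps.t.sf(abs(t), df))
    return StatsResult(
        test_name=test_name,
        groups=tuple(groups),
        n=(n1, n2),
        statistic=float(t),
        df=float(df),
        p_value=p,
        ci95=_t_ci(diff, se, df),
    )


def nested_t_test(
    table: pd.DataFrame,
    value_col: str,
    group_col: str,
    patient_col: str = "patient_id",
) -> StatsResult:
    """Two-group comparison with droplets nested within patients.

    Droplet values are collapsed to unweighted per-patient means and an
    unpaired Student t is run on those means: the patient, not the droplet,
    is the experimental unit, so n (and the degrees of freedom) count
    patients.  A patient appearing in both groups is rejected.
    """
    levels = list(pd.unique(table[group_col]))
    if len(levels) != 2:
        raise ValueError(f"nested t-test needs exactly 2 groups, got {levels}")
    membership = table.groupby(patient_col)[group_col].nunique()
    crossed = membership[membership > 1].index.tolist()
    if crossed:
        raise ValueError(f"patients present in both groups: {crossed}")
    means = (
        table.groupby([group_col, patient_col], sort=False)[value_col]
        .mean()
        .reset_index()
    )
    a = means.loc[means[group_col] == levels[0], value_col].to_numpy()
    b = means.loc[means[group_col] == levels[1], value_col].to_numpy()
    if a.size < 2 or b.size < 2:
        raise ValueError("nested t-test needs >= 2 patients per group")
    res = two_sample_t_test(a, b, groups=tuple(levels), test_name="nested_t")
    return res


def anova_tukey(groups: dict) -> tuple[StatsResult, list[StatsResult]]:
    """One-way fixed-effects ANOVA plus all-pairs Tukey HSD.

    ``groups`` maps level name → 1D values (each n >= 2).  Returns the
    ANOVA result and one :class:`StatsResult` per pair with the
    studentized-range-adjusted p-value.  With exactly two groups the
    procedure degrades to an unpaired Student t with a warning.
    """
    names = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in names]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    for name, arr in zip(names, arrays):
        if arr.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 values")
    if len(arrays) == 2:
        warnings.warn(
            "only 2 groups: ANOVA+Tukey degrades to an unpaired t-test",
            stacklevel=2,
        )
        res = two_sample_t_test(arrays[0], arrays[1], groups=tuple(names))
        return res, [res]

    f_stat, f_p = sps.f_oneway(*arrays)
    n_total = sum(a.size for a in arrays)
    k = len(arrays)
    anova = StatsResult(
        test_name="one_way_anova",
        groups=tuple(names),
        n=tuple(a.size for a in arrays),
        statistic=float(f_stat),
        df=float(k - 1),
        p_value=float(f_p),
    )
    hsd = sps.tukey_hsd(*arrays)
    ci = hsd.confidence_interval(0.95)
    pairs: list[StatsResult] = []
    for i in range(k):
        for j in range(i + 1, k):
            pairs.append(
                StatsResult(
                    test_name="tukey_hsd",
                    groups=(names[i], names[j]),
                    n=(arrays[i].size, arrays[j].size),
                    statistic=float(hsd.statistic[i, j]),
                    df=float(n_total - k),
                    p_value=float(hsd.pvalue[i, j]),
                    ci95=(float(ci.low[i, j]), float(ci.high[i, j])),
                    adjusted=True,
                )
            )
    return anova, pairs


def mean_ci95(values) -> tuple[float, float, float]:
    """Sample mean with its 95% t-based confidence interval:
    mean ± t(0.975, n-1) * SD / sqrt(n)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("mean_ci95 needs at least 2 values")
    mean = float(x.mean())
    se = float(x.std(ddof=1) / np.sqrt(x.size))
    low, high = _t_ci(mean, se, x.size - 1)
    return mean, low, high
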