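"""Standard-related validity and Bland-Altman agreement statistics.

The battery used to validate marker-based joint angles against the plate
ground truth: Pearson correlation (validity), Bland-Altman mean difference
with 1.96-SD limits of agreement (systematic bias), a fixed/proportional
bias classification, and unpaired t-tests for peak comparisons between
models.

Bias criteria (classical Bland-Altman practice):

* fixed bias -- the 95% t-based confidence interval of the mean difference
  excludes zero;
* proportional bias -- the OLS slope of the differences on the pairwise
  means is significant at the 5% level.

No multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationResult",
    "BlandAltmanResult",
    "TTestResult",
    "pearson_validity",
    "bland_altman",
    "classify_bias",
    "compare_peaks",
    "validity_report",
    "plot_validity_scatter",
    "plot_bland_altman",
]


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int
    label: str = ""


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float            # mean difference (measured - truth), degrees
    sd: float              # SD of differences (ddof=1)
    loa: tuple[float, float]  # bias -/+ 1.96 * SD
    fixed_bias: bool
    proportional_bias: bool
    slope: float           # OLS slope of difference on mean
    slope_p: float
    inside_loa: float      # fraction of points within the limits
    n: int
    label: str = ""


@dataclass(frozen=True)
class TTestResult:
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int
    t: float
    df: float
    p: float
    significant: bool  # at the 5% level


def _paired(measured, truth, min_n: int = 3) -> tuple[np.ndarray, np.ndarray]:
    m = np.asarray(measured, dtype=float).ravel()
    t = np.asarray(truth, dtype=float).ravel()
    if m.shape != t.shape:
        raise ValueError(f"length mismatch: {m.shape[0]} vs {t.shape[0]}")
    if m.shape[0] < min_n:
        raise ValueError(f"need at least {min_n} paired samples, got {m.shape[0]}")
    if not (np.all(np.isfinite(m)) and np.all(np.isfinite(t))):
        raise ValueError("inputs must be finite")
    return m, t


def pearson_validity(measured, truth, label: str = "") -> CorrelationResult:
    """Pearson r between measured and true angles, two-sided p (n-2 df)."""
    m, t = _paired(measured, truth)
    if m.std() == 0 or t.std() == 0:
        raise ValueError("correlation undefined: zero variance in an input")
    res = stats.pearsonr(m, t)
    return CorrelationResult(float(res.statistic), float(res.pvalue), m.shape[0], label)


def bland_altman(
    measured, truth, alpha: float = 0.05, label: str = "", exact_tol: float = 1e-10
) -> BlandAltmanResult:
    """Bland-Altman agreement of measured angles with the ground truth.

    Differences are ``measured - truth``; limits of agreement use the fixed
    1.96 multiplier of the classical method.  A difference spread below
    ``exact_tol`` (degrees) is treated as exact agreement so that rounding
    residue at machine precision cannot trigger bias flags.
    """
    m, t = _paired(measured, truth)
    d = m - t
    n = d.shape[0]
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    loa = (bias - 1.96 * sd, bias + 1.96 * sd)

    if sd <= exact_tol:
        fixed = abs(bias) > exact_tol
        slope, slope_p, proportional = 0.0, 1.0, False
    else:
        tcrit = stats.t.ppf(1 - alpha / 2, n - 1)
        fixed = abs(bias) > tcrit * sd / np.sqrt(n)
        means = 0.5 * (m + t)
        if means.std() == 0.0:
            slope, slope_p, proportional = 0.0, 1.0, False
        else:
            reg = stats.linregress(means, d)
            slope, slope_p = float(reg.slope), float(reg.pvalue)
            proportional = slope_p < alpha

    inside = float(np.mean((d >= loa[0]) & (d <= loa[1])))
    return BlandAltmanResult(
        bias=bias, sd=sd, loa=loa, fixed_bias=bool(fixed),
        proportional_bias=bool(proportional), slope=slope, slope_p=slope_p,
        inside_loa=inside, n=n, label=label,
    )


def classify_bias(result: BlandAltmanResult) -> str:
    """Deterministic label from the two bias flags."""
    if result.fixed_bias and result.proportional_bias:
        return "fixed+proportional"
    if result.fixed_bias:
        return "fixed"
    if result.proportional_bias:
        return "proportional"
    return "none"


def compare_peaks(group_a, group_b, equal_var: bool = True, alpha: float = 0.05) -> TTestResult:
    """Unpaired two-sample t-test on peak angles (pooled variance by default).

    Degenerate zero-variance input with equal means yields t = 0, p = 1 by
    convention; with unequal means the test is reported as infinitely
    significant (p = 0).
    """
    a = np.asarray(group_a, dtype=float).ravel()
    b = np.asarray(group_b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    na, nb = a.size, b.size
    df = na + nb - 2 if equal_var else np.nan

    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        if a.mean() == b.mean():
            t_stat, p = 0.0, 1.0
        else:
            t_stat = np.inf if a.mean() > b.mean() else -np.inf
            p = 0.0
    else:
        res = stats.ttest_ind(a, b, equal_var=equal_var)
        t_stat, p = float(res.statistic), float(res.pvalue)
        if not equal_var:
            df = float(res.df)
    return TTestResult(
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)), sd_b=float(b.std(ddof=1)),
        n_a=na, n_b=nb, t=t_stat, df=float(df), p=p, significant=p < alpha,
    )


def validity_report(cells) -> pd.DataFrame:
    """Tidy agreement table over (model, joint, plane) validation cells.

    ``cells`` iterates over ``(model, joint, plane, measured, truth)``
    tuples (one sweep per cell).  One row per cell: Pearson r and p,
    Bland-Altman bias, SD, limits of agreement and bias class.
    """
    rows = []
    for model, joint, plane, measured, truth in cells:
        corr = pearson_validity(measured, truth, label=f"{model}/{joint}/{plane}")
        ba = bland_altman(measured, truth, label=corr.label)
        rows.append(
            {
                "model": model, "joint": joint, "plane": plane, "n": corr.n,
                "r": corr.r, "p": corr.p, "bias": ba.bias, "sd_diff": ba.sd,
                "loa_lower": ba.loa[0], "loa_upper": ba.loa[1],
                "bias_class": classify_bias(ba), "inside_loa": ba.inside_loa,
            }
        )
    if not rows:
        raise ValueError("no validation cells supplied")
    return pd.DataFrame(rows)


# --- plots (scatter with identity line; Bland-Altman with bias/LoA lines) ----

def plot_validity_scatter(measured, truth, path: str | Path, label: str = "") -> Path:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    m, t = _paired(measured, truth)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(t, m, s=12, alpha=0.8)
    lims = [min(t.min(), m.min()), max(t.max(), m.max())]
    ax.plot(lims, lims, "k--", lw=0.8)
    ax.set_xlabel("true angle (deg)")
    ax.set_ylabel("measured angle (deg)")
    ax.set_title(label)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_bland_altman(measured, truth, path: str | Path, label: str = "") -> Path:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    m, t = _paired(measured, truth)
    ba = bland_altman(m, t)
    means, d = 0.5 * (m + t), m - t
    if ba.proportional_bias and np.mean(np.abs(means)) > 0:
        # with proportional bias the difference is shown relative to the mean
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.where(means != 0, d / means, np.nan)
        ylabel = "difference / mean"
        lines = [np.nanmean(d)]
    else:
        ylabel = "measured - true (deg)"
        lines = [ba.bias] if classify_bias(ba) == "none" else [ba.loa[0], ba.bias, ba.loa[1]]
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.scatter(means, d, s=12, alpha=0.8)
    for y in lines:
        ax.axhline(y, color="tab:blue", lw=1)
    ax.set_xlabel("mean of measured and true (deg)")
    ax.set_ylabel(ylabel)
    ax.set_title(label)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
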