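"""Culture quality control: proliferation metrics, screening and correlation.

Population doublings PD = log2(N / N0) and doubling time PDT = I / PD are
computed from the inoculated count N0, harvested count N and days in
culture I.  A culture is screened as substandard when its mean motion
speed falls strictly below a threshold (40 μm/h in the reference culture
system; the value is culture-system specific and therefore configurable).
The MMS–PDT association is summarized by Spearman's rank correlation with
a Fisher-z confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CultureCount",
    "Verdict",
    "QCResult",
    "DEFAULT_THRESHOLD_UM_PER_H",
    "population_doublings",
    "doubling_time",
    "classify",
    "spearman_correlation",
    "SpearmanResult",
    "scatter_report",
    "plot_scatter",
]

DEFAULT_THRESHOLD_UM_PER_H = 40.0


@dataclass(frozen=True)
class CultureCount:
    """Cell counts of one culture interval.

    n0: inoculated cell count; n: harvested cell count;
    days_in_culture: elapsed days I.
    """

    n0: float
    n: float
    days_in_culture: float

    def __post_init__(self) -> None:
        if self.n0 <= 0 or self.n <= 0:
            raise ValueError("cell counts must be positive")
        if self.days_in_culture <= 0:
            raise ValueError("days_in_culture must be positive")


class Verdict(str, Enum):
    ACCEPTABLE = "ACCEPTABLE"
    SUBSTANDARD = "SUBSTANDARD"


@dataclass(frozen=True)
class QCResult:
    mms: float
    threshold: float
    verdict: Verdict
    pdt: float | None = None
    protocol_label: str = ""


def population_doublings(counts: CultureCount) -> float:
    """PD = log2(N / N0); negative when cells were lost."""
    return float(np.log2(counts.n / counts.n0))


def doubling_time(pd_value: float, days_in_culture: float) -> float:
    """PDT = I / PD, in days.

    Raises
    ------
    ValueError
        If PD <= 0: the culture did not grow and its doubling time is
        undefined.
    """
    if pd_value <= 0:
        raise ValueError("PDT undefined: culture did not grow (PD <= 0)")
    if days_in_culture <= 0:
        raise ValueError("days_in_culture must be positive")
    return float(days_in_culture / pd_value)


def classify(
    mms: float,
    threshold: float = DEFAULT_THRESHOLD_UM_PER_H,
    pdt: float | None = None,
    protocol_label: str = "",
) -> QCResult:
    """Screen a culture by its mean motion speed.

    SUBSTANDARD iff ``mms`` is strictly below ``threshold`` (an MMS equal
    to the threshold is acceptable).  The default 40 μm/h is the empirical
    minimum of the reference standard-protocol cohort and applies only to
    that culture system — override it for any other.
    """
    if mms < 0:
        raise ValueError("mms must be >= 0")
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    verdict = Verdict.SUBSTANDARD if mms < threshold else Verdict.ACCEPTABLE
    return QCResult(
        mms=float(mms),
        threshold=float(threshold),
        verdict=verdict,
        pdt=pdt,
        protocol_label=protocol_label,
    )


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p_value: float
    ci_low: float
    ci_high: float
    n: int


def spearman_correlation(x, y, confidence: float = 0.95) -> SpearmanResult:
    """Spearman rank correlation with a Fisher-z confidence interval.

    Rho uses average ranks for ties; the two-sided p-value uses the
    t-approximation.  The CI transforms rho with Fisher's z and a standard
    error of ``1.03 / sqrt(n - 3)`` (the conventional inflation over the
    Pearson case for ranked data), then maps back with tanh.

    Raises
    ------
    ValueError
        On length mismatch, fewer than 4 pairs, missing values, or a
        constant input (rho undefined).
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 4:
        raise ValueError("need at least 4 pairs")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values are not allowed")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: rho undefined")
    rho, p = stats.spearmanr(x, y)
    rho = float(rho)
    n = x.size
    if abs(rho) >= 1.0:
        ci_low, ci_high = rho, rho
    else:
        z = np.arctanh(rho)
        se = 1.03 / np.sqrt(n - 3)
        zcrit = stats.norm.ppf(0.5 + confidence / 2.0)
        ci_low = float(np.tanh(z - zcrit * se))
        ci_high = float(np.tanh(z + zcrit * se))
    return SpearmanResult(rho=rho, p_value=float(p), ci_low=ci_low,
                          ci_high=ci_high, n=n)


def spearman_ci_bootstrap(
    x, y, confidence: float = 0.95, n_boot: int = 2000, seed: int = 0
) -> tuple[float, float]:
    """Percentile-bootstrap CI for Spearman's rho (alternative to Fisher z)."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    rng = np.random.default_rng(seed)
    n = x.size
    rhos = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        if np.ptp(x[idx]) == 0 or np.ptp(y[idx]) == 0:
            rhos[b] = np.nan
            continue
        rhos[b] = stats.spearmanr(x[idx], y[idx]).statistic
    alpha = 1.0 - confidence
    lo, hi = np.nanquantile(rhos, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def scatter_report(
    samples,
    threshold: float = DEFAULT_THRESHOLD_UM_PER_H,
) -> pd.DataFrame:
    """Tidy per-sample QC table for an MMS-vs-PDT scatter.

    Parameters
    ----------
    samples : iterable of (mms, pdt, protocol_label)
        One entry per culture sample; an empty label is grouped under
        ``"unlabelled"``.
    threshold : float
        Screening threshold (μm/h), stored per row and applied to the
        verdict column.

    Returns
    -------
    pandas.DataFrame with columns ``sample_id, mms_um_per_h, pdt_days,
    protocol, verdict, threshold_um_per_h``.
    """
    rows = []
    for i, (mms_val, pdt_val, label) in enumerate(samples):
        res = classify(mms_val, threshold, pdt=pdt_val,
                       protocol_label=label or "unlabelled")
        rows.append(
            {
                "sample_id": i,
                "mms_um_per_h": float(mms_val),
                "pdt_days": float(pdt_val) if pdt_val is not None else np.nan,
                "protocol": label or "unlabelled",
                "verdict": res.verdict.value,
                "threshold_um_per_h": float(threshold),
            }
        )
    if not rows:
        raise ValueError("no samples")
    return pd.DataFrame(rows)


def plot_scatter(report: pd.DataFrame, ax=None):
    """MMS-vs-PDT scatter grouped by protocol, with the threshold line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for label, grp in report.groupby("protocol"):
        ax.scatter(grp["mms_um_per_h"], grp["pdt_days"], label=str(label), s=24)
    thr = float(report["threshold_um_per_h"].iloc[0])
    ax.axvline(thr, color="0.4", ls="--", lw=1,
               label=f"threshold {thr:g} μm/h")
    ax.set_xlabel("MMS (μm/h)")
    ax.set_ylabel("PDT (days)")
    ax.legend(frameon=False, fontsize=8)
    return ax
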