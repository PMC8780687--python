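"""Agreement analysis between ground-truth-based and segmentation-based measurements.

For each of the 19 morphometric items, paired values (G-based, S-based)
across cases are summarized by Pearson's r, the Bland-Altman mean
difference with 1.96 SD limits of agreement, the absolute error and error
rate (mean and standard error, SE = sd/sqrt(n)), and the proportional-error
correlation r_p between the per-case difference and the per-case mean.
Fixed errors are tested with a two-sided paired t-test; a Bonferroni family
correction over the 19 items sets the significance threshold at
0.05 / 19 ≈ 0.0026.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "PairedMeasurements",
    "agreement_summary",
    "paired_t",
    "bonferroni_threshold",
    "bland_altman_plot",
    "scatter_plot",
    "summarize_pairs",
]

N_MEASUREMENT_ITEMS = 19


@dataclass
class PairedMeasurements:
    """Paired per-case values of one measurement item (mm)."""

    value_g: np.ndarray
    value_s: np.ndarray
    item: str = ""
    case_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.value_g = np.asarray(self.value_g, dtype=float).ravel()
        self.value_s = np.asarray(self.value_s, dtype=float).ravel()
        if self.value_g.shape != self.value_s.shape:
            raise ValueError("paired vectors must have equal length")
        if np.any(~np.isfinite(self.value_g)) or np.any(~np.isfinite(self.value_s)):
            raise ValueError("missing or non-finite pairs are not allowed")

    @property
    def n(self) -> int:
        return len(self.value_g)

    @property
    def diff(self) -> np.ndarray:
        return self.value_s - self.value_g


def bonferroni_threshold(alpha_family: float = 0.05,
                         n_items: int = N_MEASUREMENT_ITEMS) -> float:
    """Family-wise alpha divided across the measurement items (0.05/19)."""
    return alpha_family / n_items


def agreement_summary(pm: PairedMeasurements) -> dict:
    """Correlation, Bland-Altman and error-rate summary of one item.

    Cases with a zero ground-truth value are excluded from the error rate
    (denominator is the ground-truth value); their count is reported as
    ``err_rate_n_excluded``.  Zero variance in either vector leaves the
    correlations undefined (NaN) with ``r_defined``/``r_p_defined`` flags.
    """
    if pm.n < 3:
        raise ValueError("need at least 3 pairs for agreement analysis")
    g, s, d = pm.value_g, pm.value_s, pm.diff
    mean_pair = (g + s) / 2.0

    def _pearson(x, y):
        if np.std(x) == 0 or np.std(y) == 0:
            return float("nan"), float("nan"), False
        r, p = sps.pearsonr(x, y)
        return float(r), float(p), True

    r, r_pval, r_ok = _pearson(g, s)
    r_p, r_p_pval, r_p_ok = _pearson(d, mean_pair)

    sd_d = float(np.std(d, ddof=1))
    mean_d = float(np.mean(d))
    abs_err = np.abs(d)
    nz = g != 0
    err_rate = np.abs(d[nz]) / g[nz] * 100.0

    def _se(x):
        return float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else float("nan")

    return {
        "item": pm.item,
        "n": pm.n,
        "mean_g": float(np.mean(g)),
        "sd_g": float(np.std(g, ddof=1)),
        "mean_s": float(np.mean(s)),
        "sd_s": float(np.std(s, ddof=1)),
        "r": r,
        "r_pvalue": r_pval,
        "r_defined": r_ok,
        "mean_diff": mean_d,
        "sd_diff": sd_d,
        "loa_low": mean_d - 1.96 * sd_d,
        "loa_high": mean_d + 1.96 * sd_d,
        "abs_err_mean": float(np.mean(abs_err)),
        "abs_err_se": _se(abs_err),
        "err_rate_mean": float(np.mean(err_rate)) if err_rate.size else float("nan"),
        "err_rate_se": _se(err_rate) if err_rate.size else float("nan"),
        "err_rate_n_excluded": int((~nz).sum()),
        "r_p": r_p,
        "r_p_pvalue": r_p_pval,
        "r_p_defined": r_p_ok,
    }


def paired_t(pm: PairedMeasurements, alpha_family: float = 0.05,
             n_items: int = N_MEASUREMENT_ITEMS) -> dict:
    """Two-sided paired t-test of the fixed error, Bonferroni-corrected.

    Degenerate case: if sd(diff) = 0 the statistic is undefined; by
    convention p = 1 when the constant difference is 0 (no evidence of any
    error) and p = 0 otherwise (the nonzero offset is exact).
    """
    if pm.n < 3:
        raise ValueError("need at least 3 pairs for a paired t-test")
    d = pm.diff
    threshold = bonferroni_threshold(alpha_family, n_items)
    if np.std(d, ddof=1) == 0:
        if np.mean(d) == 0:
            t, p = 0.0, 1.0
        else:
            t, p = float(np.sign(np.mean(d)) * np.inf), 0.0
    else:
        res = sps.ttest_rel(pm.value_s, pm.value_g)
        t, p = float(res.statistic), float(res.pvalue)
    return {"t": t, "p": p, "threshold": threshold, "significant": bool(p < threshold)}


def summarize_pairs(df, alpha_family: float = 0.05, n_items: int | None = None):
    """Per-item summary table from a long-format pairs DataFrame.

    ``df`` needs columns case_id, item, value_gt, value_seg.  Returns a
    pandas DataFrame with one row per item mirroring the per-item report
    (mean±SD for both readings, difference, absolute error, error rate,
    r, paired-t p-value, r_p).
    """
    import pandas as pd

    items = list(dict.fromkeys(df["item"]))
    if n_items is None:
        n_items = len(items)
    rows = []
    for item in items:
        sub = df[df["item"] == item]
        pm = PairedMeasurements(sub["value_gt"].to_numpy(),
                                sub["value_seg"].to_numpy(), item=item,
                                case_ids=list(sub["case_id"]))
        row = agreement_summary(pm)
        row.update({f"t_{k}": v for k, v in
                    paired_t(pm, alpha_family, n_items).items()})
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Basic plot export
# ---------------------------------------------------------------------------

def bland_altman_plot(pm: PairedMeasurements, ax=None, path=None):
    """Difference vs. mean plot with the 1.96 SD limits of agreement."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    summ = agreement_summary(pm)
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((pm.value_g + pm.value_s) / 2.0, pm.diff, s=12, alpha=0.7)
    for y, style in ((summ["mean_diff"], "-"), (summ["loa_low"], "--"),
                     (summ["loa_high"], "--")):
        ax.axhline(y, color="k", linestyle=style, linewidth=1)
    ax.set_xlabel("mean of G and S [mm]")
    ax.set_ylabel("S - G [mm]")
    ax.set_title(pm.item or "Bland-Altman")
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
    return ax


def scatter_plot(pm: PairedMeasurements, ax=None, path=None):
    """G vs. S scatter with the identity line."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(pm.value_g, pm.value_s, s=12, alpha=0.7)
    lo = min(pm.value_g.min(), pm.value_s.min())
    hi = max(pm.value_g.max(), pm.value_s.max())
    ax.plot([lo, hi], [lo, hi], "k-", linewidth=1)
    ax.set_xlabel("ground-truth based [mm]")
    ax.set_ylabel("segmentation based [mm]")
    ax.set_title(pm.item or "agreement")
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
    return ax
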