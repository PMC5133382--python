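"""Per-bin summary statistics of profile matrices.

A matrix column is reduced over its non-missing rows to a sample mean,
standard error and a normal-approximation 95% confidence interval
(z = 1.959964; with hundreds to thousands of feature rows the Student-t
correction is negligible). Missing entries are excluded pairwise per
column rather than by dropping whole rows, which preserves information
near chromosome edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import ProfileMatrix

#: Normal quantile for a two-sided 95% interval.
Z95 = 1.959964


@dataclass
class ProfileSummary:
    """Per-bin mean, SE and 95% CI across the rows of a ProfileMatrix."""

    bin_centers: np.ndarray
    mean: np.ndarray
    se: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    n: np.ndarray
    signal_label: str = ""
    feature_label: str = ""

    @property
    def label(self) -> str:
        return f"{self.signal_label} @ {self.feature_label}"

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {
                "offset": self.bin_centers,
                "mean": self.mean,
                "se": self.se,
                "ci_lo": self.ci_lo,
                "ci_hi": self.ci_hi,
                "n": self.n,
            }
        ).to_csv(path, sep="\t", index=False)


def summarize(matrix: ProfileMatrix) -> ProfileSummary:
    """Reduce a matrix to per-bin mean / SE / 95% CI curves.

    Per column, over non-missing entries: mean is the sample mean, SE is
    the sample standard deviation (n-1 denominator) over sqrt(n), and the
    CI is mean +/- 1.959964*SE. Columns with n = 0 have missing mean;
    columns with n < 2 have missing SE and CI.
    """
    if matrix.n_features < 1:
        raise ValueError("matrix must have at least one row")
    v = matrix.values
    n = np.sum(~np.isnan(v), axis=0).astype(float)
    mean = np.full(v.shape[1], np.nan)
    sd = np.full(v.shape[1], np.nan)
    has_any = n > 0
    mean[has_any] = np.nanmean(v[:, has_any], axis=0)
    has_two = n > 1
    if has_two.any():
        sd[has_two] = np.nanstd(v[:, has_two], axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        se = sd / np.sqrt(n)  # sd is NaN where n < 2, so NaN propagates
    ci_lo = mean - Z95 * se
    ci_hi = mean + Z95 * se
    return ProfileSummary(
        bin_centers=np.asarray(matrix.bin_centers, dtype=float),
        mean=mean,
        se=se,
        ci_lo=ci_lo,
        ci_hi=ci_hi,
        n=n,
        signal_label=matrix.signal_label,
        feature_label=matrix.feature_label,
    )


def row_strength(matrix: ProfileMatrix) -> np.ndarray:
    """Per-row mean signal over non-missing bins (NaN for all-missing rows).

    Used to sort heatmap rows by signal strength; all-missing rows sort
    last.
    """
    v = matrix.values
    out = np.full(v.shape[0], np.nan)
    ok = np.sum(~np.isnan(v), axis=1) > 0
    if ok.any():
        out[ok] = np.nanmean(v[ok], axis=1)
    return out


def strength_order(strength: np.ndarray) -> np.ndarray:
    """Row order by descending strength; NaN (all-missing) rows last."""
    key = np.where(np.isnan(strength), -np.inf, strength)
    return np.argsort(-key, kind="stable")
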