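"""Test-retest repeatability via the one-way random-effects ICC(1,1).

For two scans per subject under unchanged conditions, both the
between-subject and the within-subject (scan-to-scan) variability are
modelled as independent random effects.  With BMS the between-subjects
mean squares and WMS the within-subjects mean squares of the one-way
ANOVA, the intraclass correlation for a single measurement is

    ICC(1,1) = (BMS - WMS) / (BMS + WMS)        (k = 2 replicates)

ICC is invariant under affine rescaling of the measurements, which makes
it comparable across features living on different scales — the property
that justifies ranking heterogeneous radiomics features by it.
Confidence intervals use the Shrout-Fleiss F-based construction.
Negative estimates are retained (the estimator's natural range is
[-1, 1]); truncating at zero would bias rank summaries.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .feature_engine import FeatureTable


class InsufficientDataError(ValueError):
    """Fewer than two complete test-retest pairs."""


@dataclasses.dataclass(frozen=True)
class ICCResult:
    """Per-feature repeatability estimate with variance components."""

    icc: float
    bms: float
    wms: float
    ci_low: float
    ci_high: float
    alpha: float
    n_subjects: int

    def __post_init__(self) -> None:
        if np.isfinite(self.icc) and not (-1.0 - 1e-12 <= self.icc <= 1.0 + 1e-12):
            raise ValueError(f"ICC out of range: {self.icc}")

    @property
    def missing(self) -> bool:
        return not np.isfinite(self.icc)


def icc_1_1(pairs: Sequence[tuple[float, float]] | np.ndarray,
            alpha: float = 0.1) -> ICCResult:
    """ICC(1,1) for paired test-retest measurements, with a (1-alpha) CI.

    ``pairs`` is an (n, 2) collection of per-subject (test, retest)
    values.  Pairs containing non-finite values are dropped; at least two
    complete pairs must remain.  If all retained values are identical
    (BMS = WMS = 0) the ICC is undefined and returned as NaN.
    """
    x = np.asarray(pairs, dtype=np.float64)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError("pairs must have shape (n, 2)")
    x = x[np.isfinite(x).all(axis=1)]
    n = x.shape[0]
    if n < 2:
        raise InsufficientDataError(f"need >= 2 complete pairs, have {n}")
    k = 2
    subject_means = x.mean(axis=1)
    grand = x.mean()
    bms = k * float(((subject_means - grand) ** 2).sum()) / (n - 1)
    wms = float(((x - subject_means[:, None]) ** 2).sum()) / (n * (k - 1))
    if bms == 0.0 and wms == 0.0:
        return ICCResult(icc=np.nan, bms=0.0, wms=0.0, ci_low=np.nan,
                         ci_high=np.nan, alpha=alpha, n_subjects=n)
    icc = (bms - wms) / (bms + wms)

    # Shrout-Fleiss interval: F = BMS/WMS against F(n-1, n(k-1))
    df1, df2 = n - 1, n * (k - 1)
    if wms == 0.0:
        lo = hi = 1.0
    else:
        f_obs = bms / wms
        fl = f_obs / stats.f.ppf(1.0 - alpha / 2.0, df1, df2)
        fu = f_obs * stats.f.ppf(1.0 - alpha / 2.0, df2, df1)
        lo = (fl - 1.0) / (fl + k - 1.0)
        hi = (fu - 1.0) / (fu + k - 1.0)
    return ICCResult(icc=float(icc), bms=bms, wms=wms,
                     ci_low=float(lo), ci_high=float(hi), alpha=alpha, n_subjects=n)


#: columns identifying one ICC analysis unit within a feature table
ICC_KEY = ["image_type", "roi", "normalization", "filter", "bin_width", "dim",
           "feature_class", "feature"]

ICC_COLUMNS = ICC_KEY + ["n", "icc", "ci_low", "ci_high", "bms", "wms"]


def icc_table(features: FeatureTable, alpha: float = 0.1) -> pd.DataFrame:
    """One ICC row per (roi, image type, config fingerprint, feature).

    Subjects with a missing value at either timepoint are dropped
    pairwise per key; the retained n is recorded.  Keys where the ICC is
    undefined (all values identical, or fewer than two complete pairs)
    appear with NaN estimates rather than being dropped.
    """
    df = features.df
    timepoints = sorted(df["timepoint"].unique())
    if len(timepoints) != 2:
        raise ValueError(f"need exactly 2 timepoints, found {timepoints}")
    wide = df.pivot_table(index=ICC_KEY + ["subject_id"], columns="timepoint",
                          values="value", aggfunc="first").reset_index()
    rows = []
    for key, grp in wide.groupby(ICC_KEY, sort=True, dropna=False):
        pairs = grp[timepoints].to_numpy(dtype=np.float64)
        try:
            res = icc_1_1(pairs, alpha=alpha)
            rows.append(dict(zip(ICC_KEY, key), n=res.n_subjects, icc=res.icc,
                             ci_low=res.ci_low, ci_high=res.ci_high,
                             bms=res.bms, wms=res.wms))
        except InsufficientDataError:
            rows.append(dict(zip(ICC_KEY, key),
                             n=int(np.isfinite(pairs).all(axis=1).sum()),
                             icc=np.nan, ci_low=np.nan, ci_high=np.nan,
                             bms=np.nan, wms=np.nan))
    return pd.DataFrame(rows, columns=ICC_COLUMNS)
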