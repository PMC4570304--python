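"""Effective-band selection by correlation magnitude or significance.

Selection compares |r| against either a fixed threshold (e.g. 0.40) or the
critical correlation at a given two-sided significance level.  Thresholds
are sign-agnostic: strongly negative correlations are as informative as
positive ones.  No multiple-testing correction is applied across bands —
the per-band p < 0.01 rule is reproduced as stated.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Optional, Union

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted

from .lcm import CorrelationProfile, OCCResult, _pearson_columns


def critical_r(n: int, alpha: float) -> float:
    """Critical |r| for a two-sided Pearson test at level alpha with n samples.

    Inverts the exact t transform t = r*sqrt((n-2)/(1-r^2)) with n-2 degrees
    of freedom: returns r* whose two-sided p-value equals alpha.  For n=150,
    alpha=0.01 this is ~0.2097.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    df = n - 2
    t = stats.t.ppf(1 - alpha / 2, df)
    return float(t / np.sqrt(df + t**2))


@dataclasses.dataclass
class BandSelection:
    """Boolean band mask plus the criterion that produced it."""

    mask: np.ndarray
    criterion: str
    threshold: float

    @property
    def n_selected(self) -> int:
        return int(self.mask.sum())

    @property
    def empty(self) -> bool:
        return self.n_selected == 0


def select_bands(
    occ: Union[OCCResult, CorrelationProfile],
    criterion: str = "p<0.01",
    n: Optional[int] = None,
) -> BandSelection:
    """Select bands from an OCC result or a fixed-level correlation profile.

    ``criterion`` is either ``"p<ALPHA"`` (significance; needs the sample
    count, taken from the profile if not given) or ``"|r|>T"`` with T in
    (0, 1).  Bands flagged incomputable/excluded are never selected.
    """
    if isinstance(occ, OCCResult):
        r = occ.occ_r
        usable = ~occ.excluded
    else:
        r = occ.r
        usable = occ.computable
        if n is None:
            n = occ.n
    crit = criterion.replace(" ", "")
    if crit.startswith("p<"):
        alpha = float(crit[2:])
        if n is None:
            raise ValueError("significance criterion needs the sample count n")
        threshold = critical_r(n, alpha)
    elif crit.startswith("|r|>"):
        threshold = float(crit[4:])
        if not 0 < threshold < 1:
            raise ValueError("|r| threshold must be in (0, 1)")
    else:
        raise ValueError(f"unrecognised criterion {criterion!r}")
    mask = usable & (np.abs(r) > threshold)
    sel = BandSelection(mask=mask, criterion=criterion, threshold=threshold)
    if sel.empty:
        warnings.warn(
            f"criterion {criterion!r} selected no bands (max |r| = {np.abs(r).max():.4f})"
        )
    return sel


class CorrelationBandSelector(SelectorMixin, BaseEstimator):
    """Sklearn feature selector keeping bands whose |r| with y passes a rule.

    Parameters
    ----------
    criterion : str, default "p<0.01"
        ``"p<ALPHA"`` for a significance rule (exact t inversion) or
        ``"|r|>T"`` for a fixed magnitude threshold.

    Attributes
    ----------
    r_ : per-band Pearson correlation with the fit target.
    threshold_ : the |r| cutoff the criterion resolved to.
    """

    def __init__(self, criterion: str = "p<0.01"):
        self.criterion = criterion

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        self.n_features_in_ = X.shape[1]
        self.r_, computable = _pearson_columns(X, y)
        crit = self.criterion.replace(" ", "")
        if crit.startswith("p<"):
            self.threshold_ = critical_r(y.size, float(crit[2:]))
        elif crit.startswith("|r|>"):
            self.threshold_ = float(crit[4:])
        else:
            raise ValueError(f"unrecognised criterion {self.criterion!r}")
        self.mask_ = computable & (np.abs(self.r_) > self.threshold_)
        if not self.mask_.any():
            warnings.warn(
                f"criterion {self.criterion!r} selected no bands "
                f"(max |r| = {np.abs(self.r_).max():.4f})"
            )
        return self

    def _get_support_mask(self):
        check_is_fitted(self)
        return self.mask_
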