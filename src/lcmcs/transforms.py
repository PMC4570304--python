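"""Spectral pre-processing transforms: log(1/R) and the first derivative.

Both are exposed two ways: as plain functions on :class:`SpectrumSet` and as
scikit-learn transformers operating on raw matrices, so they compose with
``sklearn.pipeline.Pipeline``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .spectra_io import SpectrumSet

_TAG_AFTER_FDR = {"REF": "FDR", "LOG_INV": "FDR_LOG_INV", "FDR": "FDR", "FDR_LOG_INV": "FDR_LOG_INV"}


def reciprocal_log_values(R: np.ndarray) -> np.ndarray:
    """log10(1/R) elementwise; requires R in (0, 1]."""
    R = np.asarray(R, dtype=float)
    if np.any(R <= 0):
        i = np.unravel_index(int(np.argmax(R <= 0)), R.shape)
        raise ValueError(f"reflectance <= 0 at index {tuple(int(k) for k in i)}")
    return -np.log10(R)


def first_derivative_values(values: np.ndarray, spacing: float = 1.0) -> np.ndarray:
    """First derivative along the wavelength axis, per nm.

    Central differences at interior bands, one-sided differences at the two
    edge bands — exact for affine spectra and length-preserving, so band
    indices stay aligned with wavelengths.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[1] < 3:
        raise ValueError("need at least 3 bands to differentiate")
    return np.gradient(values, spacing, axis=1)


def reciprocal_log(s: SpectrumSet) -> SpectrumSet:
    """Reciprocal-logarithm (absorbance-like) transform of a reflectance set."""
    if s.transform_tag != "REF":
        raise ValueError("reciprocal_log expects original reflectance (tag REF)")
    if np.any(s.values <= 0):
        i, j = np.unravel_index(int(np.argmax(s.values <= 0)), s.values.shape)
        raise ValueError(
            f"reflectance <= 0 for sample {s.sample_ids[i]!r} at {s.wavelengths[j]:g} nm"
        )
    return s.with_values(-np.log10(s.values), transform_tag="LOG_INV")


def first_derivative(s: SpectrumSet) -> SpectrumSet:
    """First-derivative transform of a spectrum set (per nm)."""
    out = first_derivative_values(s.values, s.spacing)
    return s.with_values(out, transform_tag=_TAG_AFTER_FDR[s.transform_tag])


def apply_transform(s: SpectrumSet, tag: str) -> SpectrumSet:
    """Produce the spectrum variant named by ``tag`` from original reflectance.

    ``FDR_LOG_INV`` is by definition the first derivative of log(1/R), so it
    is computed as that exact composition.
    """
    if tag == "REF":
        return s
    if tag == "LOG_INV":
        return reciprocal_log(s)
    if tag == "FDR":
        return first_derivative(s)
    if tag == "FDR_LOG_INV":
        return first_derivative(reciprocal_log(s))
    raise ValueError(f"unknown transform tag {tag!r}")


class ReciprocalLog(BaseEstimator, TransformerMixin):
    """Stateless sklearn transformer computing log10(1/R) per cell."""

    def fit(self, X, y=None):
        check_array(X)
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X)
        return reciprocal_log_values(X)


class FirstDerivative(BaseEstimator, TransformerMixin):
    """Sklearn transformer taking the per-band first derivative.

    Parameters
    ----------
    spacing : float, default 1.0
        Wavelength step in nm (1 nm on the package's standard grid).
    """

    def __init__(self, spacing: float = 1.0):
        self.spacing = spacing

    def fit(self, X, y=None):
        check_array(X)
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X)
        return first_derivative_values(X, self.spacing)
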