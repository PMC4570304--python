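"""Local Correlation Maximization (LCM) wavelet denoising.

The idea: decompose every spectrum into a ladder of progressively smoother
versions (multilevel wavelet approximation reconstructions, sym8 by default,
5 levels), compute the per-band Pearson correlation of each version with the
target property across samples, and at every wavelength keep the version
whose correlation magnitude is largest.  The per-band winning correlations
form the Optimal Correlative Curve (OCC); the band-wise reassembled chimera
spectrum is the Optimal Spectrum (OSP).  Smoothing a band suppresses the
fine-scale "burr" noise riding on it, which can only raise its correlation
with the target where that noise is uninformative; keeping the raw band
where smoothing hurts preserves detail.

"Decomposed spectrum at level k" means: discrete wavelet decomposition to
depth k along the wavelength axis, all detail coefficients zeroed, inverse
transform.  No coefficient thresholding is applied.  Level 0 is the
untouched input.
"""

from __future__ import annotations

import dataclasses
from typing import List, Optional, Sequence

import numpy as np
import pywt
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .spectra_io import SpectrumSet, TargetVector

DEFAULT_WAVELET = "sym8"
DEFAULT_MAX_LEVEL = 5
_BOUNDARY_MODE = "symmetric"


# ---------------------------------------------------------------------------
# Multilevel approximation smoothing


def smooth_to_level(values: np.ndarray, level: int, wavelet: str = DEFAULT_WAVELET) -> np.ndarray:
    """Reconstruct spectra keeping only the level-``level`` approximation.

    Per-sample 1-D transform along the wavelength axis, symmetric boundary
    extension; detail coefficients at scales 1..level are zeroed before the
    inverse transform.  ``level == 0`` returns the input unchanged.  Output
    length always equals input length.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if level == 0:
        return values.copy()
    n = values.shape[1]
    max_feasible = pywt.dwt_max_level(n, pywt.Wavelet(wavelet).dec_len)
    if level > max_feasible:
        raise ValueError(
            f"level {level} exceeds the maximum feasible decomposition depth "
            f"{max_feasible} for {n} bands with wavelet {wavelet!r}"
        )
    coeffs = pywt.wavedec(values, wavelet, mode=_BOUNDARY_MODE, level=level, axis=1)
    coeffs = [coeffs[0]] + [np.zeros_like(c) for c in coeffs[1:]]
    rec = pywt.waverec(coeffs, wavelet, mode=_BOUNDARY_MODE, axis=1)
    return rec[:, :n]


@dataclasses.dataclass
class DecomposedStack:
    """A SpectrumSet together with its level 1..L smoothed versions."""

    base: SpectrumSet
    levels: List[SpectrumSet]
    wavelet_name: str = DEFAULT_WAVELET

    @property
    def max_level(self) -> int:
        return len(self.levels)

    def level(self, k: int) -> SpectrumSet:
        """Spectrum set at smoothing level k (0 = base)."""
        if k == 0:
            return self.base
        return self.levels[k - 1]

    def as_array(self) -> np.ndarray:
        """Stacked values, shape (L+1, n_samples, n_bands)."""
        return np.stack([self.level(k).values for k in range(self.max_level + 1)])


def decompose_stack(
    s: SpectrumSet, wavelet: str = DEFAULT_WAVELET, max_level: int = DEFAULT_MAX_LEVEL
) -> DecomposedStack:
    """Build the ladder of approximation-smoothed spectra, levels 1..max_level."""
    if max_level < 1:
        raise ValueError("max_level must be >= 1")
    levels = [
        s.with_values(smooth_to_level(s.values, k, wavelet))
        for k in range(1, max_level + 1)
    ]
    return DecomposedStack(base=s, levels=levels, wavelet_name=wavelet)


# ---------------------------------------------------------------------------
# Per-band correlations


@dataclasses.dataclass
class CorrelationProfile:
    """Per-band Pearson correlation of one smoothing level with the target."""

    r: np.ndarray            # signed correlation; 0.0 at incomputable bands
    computable: np.ndarray   # False where the band had zero variance
    n: int
    level: int


def _pearson_columns(V: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r of every column of V with y; zero-variance columns flagged."""
    Vc = V - V.mean(axis=0)
    yc = y - y.mean()
    sv = np.sqrt((Vc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    computable = (sv > 0) & (sy > 0)
    r = np.zeros(V.shape[1])
    np.divide(Vc.T @ yc, sv * sy, out=r, where=computable)
    np.clip(r, -1.0, 1.0, out=r)
    return r, computable


def band_correlations(stack: DecomposedStack, y: TargetVector) -> List[CorrelationProfile]:
    """Correlation profiles for levels 0..L (level 0 = initial spectrum)."""
    yv = y.aligned_to(stack.base)
    if yv.size < 3:
        raise ValueError("need at least 3 samples for correlation")
    profiles = []
    for k in range(stack.max_level + 1):
        r, computable = _pearson_columns(stack.level(k).values, yv)
        profiles.append(CorrelationProfile(r=r, computable=computable, n=yv.size, level=k))
    return profiles


# ---------------------------------------------------------------------------
# OCC / OSP assembly


@dataclasses.dataclass
class OCCResult:
    """Optimal correlative curve and optimal spectrum.

    ``occ_r[j]`` is the signed correlation of the winning level at band j,
    ``level_map[j]`` the winning level (ties broken toward the lowest level,
    i.e. least smoothing), ``osp`` the band-wise reassembled spectrum, and
    ``excluded[j]`` marks bands where no level had computable correlation.
    """

    occ_r: np.ndarray
    level_map: np.ndarray
    osp: SpectrumSet
    excluded: np.ndarray
    wavelet_name: str
    max_level: int


def build_occ_osp(stack: DecomposedStack, profiles: Sequence[CorrelationProfile]) -> OCCResult:
    """Pick, per band, the level with maximum |r|; assemble OCC and OSP."""
    if len(profiles) != stack.max_level + 1:
        raise ValueError("profiles must cover levels 0..L")
    R = np.stack([p.r for p in profiles])                  # (L+1, bands)
    C = np.stack([p.computable for p in profiles])
    absR = np.where(C, np.abs(R), -np.inf)
    # argmax returns the first (= lowest-level) maximiser on ties
    level_map = np.argmax(absR, axis=0)
    excluded = ~C.any(axis=0)
    level_map[excluded] = 0
    bands = np.arange(R.shape[1])
    occ_r = R[level_map, bands]
    occ_r[excluded] = 0.0
    osp_values = stack.as_array()[level_map, :, bands].T   # (samples, bands)
    osp = stack.base.with_values(osp_values)
    return OCCResult(
        occ_r=occ_r,
        level_map=level_map,
        osp=osp,
        excluded=excluded,
        wavelet_name=stack.wavelet_name,
        max_level=stack.max_level,
    )


def apply_level_map(
    s_new: SpectrumSet,
    level_map: np.ndarray,
    wavelet: str = DEFAULT_WAVELET,
    max_level: Optional[int] = None,
) -> SpectrumSet:
    """Assemble the OSP of new spectra using an already-learned level map.

    Needed to denoise validation spectra with the calibration-learned map
    without touching their target values.
    """
    level_map = np.asarray(level_map, dtype=int)
    if level_map.size != s_new.n_bands:
        raise ValueError(
            f"level_map covers {level_map.size} bands but spectra have {s_new.n_bands}"
        )
    if max_level is None:
        max_level = int(level_map.max(initial=0))
    stack = (
        decompose_stack(s_new, wavelet, max_level)
        if max_level >= 1
        else DecomposedStack(base=s_new, levels=[], wavelet_name=wavelet)
    )
    bands = np.arange(s_new.n_bands)
    values = stack.as_array()[level_map, :, bands].T
    return s_new.with_values(values)


# ---------------------------------------------------------------------------
# sklearn-style estimator


class LCMDenoiser(BaseEstimator, TransformerMixin):
    """Correlation-maximizing wavelet denoiser (sklearn transformer).

    ``fit(X, y)`` learns the per-band optimal smoothing level from the
    calibration data; ``transform(X)`` assembles the optimal spectrum of any
    matrix on the same band grid using the frozen map, so validation rows
    never influence the learned state.

    Parameters
    ----------
    wavelet : str, default "sym8"
        Wavelet family for the decomposition ladder.
    max_level : int, default 5
        Deepest smoothing level offered to the per-band argmax.

    Attributes
    ----------
    level_map_ : ndarray of int, shape (n_bands,)
        Chosen smoothing level per band (0 = untouched).
    occ_r_ : ndarray, shape (n_bands,)
        Signed correlation of the winning level per band.
    excluded_ : ndarray of bool
        Bands where no level had computable correlation.
    """

    def __init__(self, wavelet: str = DEFAULT_WAVELET, max_level: int = DEFAULT_MAX_LEVEL):
        self.wavelet = wavelet
        self.max_level = max_level

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        if y.size != X.shape[0]:
            raise ValueError("X and y sample counts differ")
        if y.size < 3:
            raise ValueError("need at least 3 samples")
        self.n_features_in_ = X.shape[1]
        levels = [X] + [smooth_to_level(X, k, self.wavelet) for k in range(1, self.max_level + 1)]
        R, C = [], []
        for V in levels:
            r, c = _pearson_columns(V, y)
            R.append(r)
            C.append(c)
        R, C = np.stack(R), np.stack(C)
        absR = np.where(C, np.abs(R), -np.inf)
        self.level_map_ = np.argmax(absR, axis=0)
        self.excluded_ = ~C.any(axis=0)
        self.level_map_[self.excluded_] = 0
        bands = np.arange(X.shape[1])
        self.occ_r_ = np.where(self.excluded_, 0.0, R[self.level_map_, bands])
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError("band count mismatch with fitted level map")
        levels = np.stack(
            [X] + [smooth_to_level(X, k, self.wavelet) for k in range(1, self.max_level + 1)]
        )
        bands = np.arange(X.shape[1])
        return levels[self.level_map_, :, bands].T
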