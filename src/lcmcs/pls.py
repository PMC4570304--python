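"""Partial least squares regression via NIPALS, with score extraction.

Univariate-response PLS1: X and y are mean-centered, components are
extracted sequentially (weight w from the X'y covariance, score t = Xw,
loadings p, q, inner coefficient b), and X is deflated after each
component; with a single response, deflating y is redundant.  The composite
coefficient vector beta = W (P'W)^-1 diag(b...) collapses the recursion so
prediction is a single centered matrix product, and the same projector
R = W (P'W)^-1 maps new centered spectra onto latent scores — the inputs
handed to the fuzzy regressor in the CS/LCMCS pipelines.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted


class PLSRegression(BaseEstimator, RegressorMixin):
    """NIPALS PLS1 regressor exposing scores, loadings and residuals.

    Parameters
    ----------
    n_components : int, default 5
        Number of latent variables to extract.

    Attributes
    ----------
    x_mean_, y_mean_ : centering vectors.
    W_ : (p, A) X-weight vectors (unit norm).
    P_ : (p, A) X-loadings;  Q_ : (A,) y-loadings (here y-side scaling).
    T_ : (n, A) X-scores (mutually orthogonal);  U_ : (n, A) y-scores.
    B_ : (A,) inner regression coefficients linking u to t.
    beta_ : (p,) composite coefficients: yhat = (x - x_mean) @ beta + y_mean.
    R_ : (p, A) score projector: t = (x - x_mean) @ R.
    E_, F_, Ed_ : X-, y- and inner-relation residuals on the training set.
    """

    def __init__(self, n_components: int = 5):
        self.n_components = n_components

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        if y.size != n:
            raise ValueError("X and y sample counts differ")
        A = self.n_components
        if A < 1 or A > min(n - 1, p):
            raise ValueError(
                f"n_components={A} infeasible for {n} samples x {p} features"
            )
        if np.ptp(y) == 0:
            raise ValueError("zero-variance target")
        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = float(y.mean())
        Xc = X - self.x_mean_
        yc = y - self.y_mean_
        if not np.any(Xc):
            raise ValueError("X is constant after centering")

        W = np.zeros((p, A))
        P = np.zeros((p, A))
        T = np.zeros((n, A))
        U = np.zeros((n, A))
        Q = np.zeros(A)
        B = np.zeros(A)
        Xd = Xc.copy()
        yd = yc.copy()
        for a in range(A):
            w = Xd.T @ yd
            nw = np.linalg.norm(w)
            if nw == 0:
                raise ValueError(
                    f"deflated X orthogonal to y at component {a + 1}; "
                    f"reduce n_components"
                )
            w /= nw
            t = Xd @ w
            tt = t @ t
            if tt == 0:
                raise ValueError(f"degenerate score at component {a + 1}")
            p_a = Xd.T @ t / tt
            q_a = yd @ t / tt
            # y-score u and inner coefficient b: with univariate y the inner
            # relation u = b t has b absorbing q's magnitude
            u = yd * np.sign(q_a) if q_a != 0 else yd
            W[:, a], P[:, a], T[:, a], U[:, a] = w, p_a, t, u
            Q[a] = q_a
            B[a] = (u @ t) / tt
            Xd -= np.outer(t, p_a)
            yd = yd - t * q_a
        self.W_, self.P_, self.T_, self.U_, self.Q_, self.B_ = W, P, T, U, Q, B
        self.R_ = W @ np.linalg.inv(P.T @ W)
        self.beta_ = self.R_ @ Q
        self.E_ = Xd
        self.F_ = yd
        self.Ed_ = U - T * B
        self.n_features_in_ = p
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features; model was fit with {self.n_features_in_}"
            )
        return (X - self.x_mean_) @ self.beta_ + self.y_mean_

    def transform(self, X):
        """Latent scores t = (x - x_mean) @ R for new spectra."""
        check_is_fitted(self)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count mismatch")
        return (X - self.x_mean_) @ self.R_

    # common chemometric alias
    scores = transform

    def to_dict(self) -> dict:
        check_is_fitted(self)
        return {
            "n_components": self.n_components,
            "x_mean": self.x_mean_.tolist(),
            "y_mean": self.y_mean_,
            "beta": self.beta_.tolist(),
            "R": self.R_.tolist(),
            "Q": self.Q_.tolist(),
            "B": self.B_.tolist(),
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()) + "\n")


def fit_pls(X, y, n_components: int) -> PLSRegression:
    return PLSRegression(n_components=n_components).fit(X, y)


def choose_components(
    X, y, max_components: int, rel_tol: float = 1e-6
) -> int:
    """Latent-variable count from the calibration prediction error.

    Adds components while calibration RMSE improves by more than ``rel_tol``
    times the target's standard deviation (so an already machine-zero error
    never invites further components); returns the count at the first
    minimum within tolerance.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    cap = min(max_components, min(X.shape[0] - 1, X.shape[1]))
    scale = float(np.std(y))
    best_a, best_rmse = 1, np.inf
    for a in range(1, cap + 1):
        try:
            model = PLSRegression(n_components=a).fit(X, y)
        except ValueError:
            break
        rmse = float(np.sqrt(np.mean((model.predict(X) - y) ** 2)))
        improvement = best_rmse - rmse if np.isfinite(best_rmse) else np.inf
        if improvement > rel_tol * scale:
            best_a, best_rmse = a, rmse
        else:
            break
    return best_a
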