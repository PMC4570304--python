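"""First-order Takagi-Sugeno ANFIS with hybrid learning.

Five-layer network: (1) generalized-bell memberships per input, (2) rule
firing strengths as products of memberships over inputs (grid partition:
one rule per combination of membership functions), (3) normalization of
firing strengths across rules, (4) rule outputs as linear functions of the
inputs weighted by normalized firing, (5) summation.

Hybrid learning alternates, per epoch, an exact global least-squares solve
for all rule consequent coefficients (the output is linear in them once
premises are frozen) with a full-batch gradient-descent step on the bell
premise parameters (a, b, c), guarded by step-halving so the training loss
never increases.  Because the normalized firings sum to one, any target
that is globally linear in the inputs is fitted exactly by the very first
least-squares pass, whatever the premise initialization — the key
correctness handle on the trainer.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import warnings
from pathlib import Path
from typing import List, Optional

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

_MIN_AB = 1e-6   # positivity floor for bell widths/shapes
_RIDGE = 1e-8
_EPS = 1e-300


def bell_membership(x, a, b, c):
    """Generalized bell function 1 / (1 + ((x-c)/a)^(2b)).

    Equals 1 at x=c and 0.5 at x = c +/- a for any shape b; a sets the
    half-width, b the shoulder steepness.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("bell parameters a and b must be strictly positive")
    z = ((np.asarray(x, dtype=float) - c) / a) ** 2
    return 1.0 / (1.0 + z**b)


@dataclasses.dataclass
class TrainConfig:
    """Hybrid-training hyperparameters (the method itself fixes none)."""

    epochs: int = 100
    learning_rate: float = 0.01
    seed: Optional[int] = None
    patience: int = 20
    init_jitter: float = 0.0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


class ANFISRegressor(BaseEstimator, RegressorMixin):
    """Takagi-Sugeno fuzzy regressor trained by hybrid LSE / gradient descent.

    Parameters
    ----------
    mfs_per_input : int, default 2
        Bell membership functions per input; the rule base is the full grid,
        so ``mfs_per_input ** n_inputs`` rules (32 for the standard 5-score,
        2-MF design).
    epochs, learning_rate, patience, init_jitter, random_state :
        Training controls; see :class:`TrainConfig`.  ``init_jitter`` adds
        seed-controlled relative noise to the initial centers/widths.

    Attributes
    ----------
    a_, b_, c_ : (n_inputs, mfs_per_input) bell premise parameters.
    rules_ : (n_rules, n_inputs) membership index per rule.
    consequent_ : (n_rules, n_inputs + 1) linear coefficients + intercept.
    loss_trace_ : per-epoch training RMSE (non-increasing).
    input_ranges_ : (n_inputs, 2) training min/max per input.
    """

    def __init__(
        self,
        mfs_per_input: int = 2,
        epochs: int = 100,
        learning_rate: float = 0.01,
        patience: int = 20,
        init_jitter: float = 0.0,
        consequent_penalty: float = 0.05,
        random_state: Optional[int] = None,
    ):
        self.mfs_per_input = mfs_per_input
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.patience = patience
        self.init_jitter = init_jitter
        self.consequent_penalty = consequent_penalty
        self.random_state = random_state

    # -- network forward pass --------------------------------------------
    def _memberships(self, X, a, b, c):
        # X: (n, d) -> mu: (n, d, m)
        z = ((X[:, :, None] - c[None]) / a[None]) ** 2
        return 1.0 / (1.0 + z ** b[None])

    def _firing(self, mu):
        # mu: (n, d, m) -> w: (n, R) product over inputs of the rule's MF
        n, d, _ = mu.shape
        w = np.ones((n, self.rules_.shape[0]))
        for j in range(d):
            w *= mu[:, j, self.rules_[:, j]]
        return w

    def _normalized_firing(self, X, a=None, b=None, c=None):
        a = self.a_ if a is None else a
        b = self.b_ if b is None else b
        c = self.c_ if c is None else c
        mu = self._memberships(X, a, b, c)
        w = self._firing(mu)
        s = w.sum(axis=1, keepdims=True)
        wbar = w / np.maximum(s, _EPS)
        return mu, w, wbar

    def _design(self, wbar, X):
        # (n, R, d+1) blocks wbar_i * [x, 1] flattened to (n, R*(d+1))
        n, d = X.shape
        Xe = np.concatenate([X, np.ones((n, 1))], axis=1)
        return (wbar[:, :, None] * Xe[:, None, :]).reshape(n, -1)

    def _forward(self, X, a=None, b=None, c=None, consequent=None):
        consequent = self.consequent_ if consequent is None else consequent
        _, _, wbar = self._normalized_firing(X, a, b, c)
        Xe = np.concatenate([X, np.ones((X.shape[0], 1))], axis=1)
        f = Xe @ consequent.T          # (n, R) rule outputs
        return (wbar * f).sum(axis=1), wbar

    # -- learning ---------------------------------------------------------
    def _init_premise(self, X, rng):
        d = X.shape[1]
        m = self.mfs_per_input
        lo, hi = X.min(axis=0), X.max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)
        if m == 1:
            c = ((lo + hi) / 2)[:, None]
            a = (span / 2)[:, None]
        else:
            c = lo[:, None] + span[:, None] * np.linspace(0, 1, m)[None, :]
            a = np.full((d, m), 0.5) * (span / (m - 1))[:, None]
        b = np.full((d, m), 2.0)
        if self.init_jitter > 0:
            c = c + rng.normal(scale=self.init_jitter, size=c.shape) * span[:, None]
            a = a * np.exp(rng.normal(scale=self.init_jitter, size=a.shape))
        a = np.maximum(a, _MIN_AB)
        return a, b, c

    def _solve_consequent(self, wbar, X, y):
        """Global least-squares pass for all rule consequents.

        The rule count times (n_inputs + 1) routinely exceeds the sample
        count, so the plain LSE would interpolate.  The solve is therefore
        split: an unpenalized global linear stage (exact because the
        normalized firings sum to one, so a shared consequent reproduces
        any linear map — a linear target is always fitted exactly), then a
        ridge-penalized stage for the rule-wise deviations that carry the
        nonlinearity.  ``consequent_penalty`` scales the ridge relative to
        the design; 0 recovers the raw LSE with a small-ridge fallback on
        ill conditioning.
        """
        n, d = X.shape
        R = self.rules_.shape[0]
        D = self._design(wbar, X)
        q = D.shape[1]
        if self.consequent_penalty > 0:
            Xe = np.concatenate([X, np.ones((n, 1))], axis=1)
            g, *_ = np.linalg.lstsq(Xe, y, rcond=None)
            resid = y - Xe @ g
            G = D.T @ D
            lam = self.consequent_penalty * np.trace(G) / q
            delta = np.linalg.solve(G + lam * np.eye(q), D.T @ resid)
            theta = np.tile(g, R) + delta
            return theta.reshape(R, d + 1)
        # raw LSE with a conditioning check and small-ridge fallback
        G = D.T @ D
        cond = np.linalg.cond(G)
        if not np.isfinite(cond) or cond > 1e12:
            if not self._warned_illcond:
                warnings.warn(
                    f"ill-conditioned consequent system (cond={cond:.2e}); "
                    f"applying ridge {_RIDGE:g}"
                )
                self._warned_illcond = True
            G = G + _RIDGE * np.eye(q)
            theta = np.linalg.solve(G, D.T @ y)
        else:
            theta, *_ = np.linalg.lstsq(D, y, rcond=None)
        return theta.reshape(R, d + 1)

    def _premise_gradient(self, X, y, a, b, c, consequent):
        """Full-batch gradient of the mean squared error wrt a, b, c."""
        n, d = X.shape
        mu = self._memberships(X, a, b, c)
        w = self._firing(mu)
        s = np.maximum(w.sum(axis=1, keepdims=True), _EPS)
        wbar = w / s
        Xe = np.concatenate([X, np.ones((n, 1))], axis=1)
        f = Xe @ consequent.T
        yhat = (wbar * f).sum(axis=1)
        err = yhat - y                                   # (n,)
        # d yhat / d w_i = (f_i - yhat) / sum_w
        dy_dw = (f - yhat[:, None]) / s                  # (n, R)
        g = (2.0 / n) * err[:, None] * dy_dw             # dMSE/dw (n, R)
        mu_safe = np.maximum(mu, _EPS)
        # accumulate dMSE/dmu_{j,k} = sum_{rules using (j,k)} g * w / mu
        gmu = np.zeros_like(mu)
        gw = g * w
        for j in range(d):
            idx = self.rules_[:, j]                      # (R,)
            contrib = gw / mu_safe[:, j, idx]            # (n, R)
            for k in range(self.mfs_per_input):
                gmu[:, j, k] = contrib[:, idx == k].sum(axis=1)
        # bell partials: mu = 1/(1+z^b), z = ((x-c)/a)^2
        diff = X[:, :, None] - c[None]
        z = (diff / a[None]) ** 2
        zb = z ** b[None]
        dmu_dz = np.where(z > 0, -b[None] * zb / np.maximum(z, _EPS) * mu**2, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            logz = np.where(z > 0, np.log(np.maximum(z, _EPS)), 0.0)
        dmu_db = -zb * logz * mu**2
        dz_da = -2.0 * z / a[None]
        dz_dc = -2.0 * diff / a[None] ** 2
        ga = (gmu * dmu_dz * dz_da).sum(axis=0)
        gb = (gmu * dmu_db).sum(axis=0)
        gc = (gmu * dmu_dz * dz_dc).sum(axis=0)
        return ga, gb, gc

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float).ravel()
        if y.size != X.shape[0]:
            raise ValueError("X and y sample counts differ")
        d = X.shape[1]
        self.n_features_in_ = d
        self._warned_illcond = False
        rng = np.random.default_rng(self.random_state)
        self.rules_ = np.array(
            list(itertools.product(range(self.mfs_per_input), repeat=d)), dtype=int
        )
        self.input_ranges_ = np.stack([X.min(axis=0), X.max(axis=0)], axis=1)
        a, b, c = self._init_premise(X, rng)

        def rmse(a_, b_, c_, cons):
            yhat, _ = self._forward(X, a_, b_, c_, cons)
            return float(np.sqrt(np.mean((yhat - y) ** 2)))

        _, _, wbar = self._normalized_firing(X, a, b, c)
        consequent = self._solve_consequent(wbar, X, y)
        loss = rmse(a, b, c, consequent)
        trace = [loss]
        lr = self.learning_rate
        best = (a.copy(), b.copy(), c.copy(), consequent.copy(), loss)
        stall = 0
        for _ in range(self.epochs - 1):
            ga, gb, gc = self._premise_gradient(X, y, a, b, c, consequent)
            # scale-free step: normalize the concatenated gradient
            gnorm = np.sqrt((ga**2).sum() + (gb**2).sum() + (gc**2).sum())
            if gnorm < 1e-14:
                trace.append(loss)
                break
            step = lr / gnorm
            accepted = False
            for _half in range(12):
                a2 = np.maximum(a - step * ga, _MIN_AB)
                b2 = np.maximum(b - step * gb, _MIN_AB)
                c2 = c - step * gc
                _, _, wbar2 = self._normalized_firing(X, a2, b2, c2)
                cons2 = self._solve_consequent(wbar2, X, y)
                loss2 = rmse(a2, b2, c2, cons2)
                if loss2 <= loss:
                    accepted = True
                    break
                step /= 2
            if accepted:
                a, b, c, consequent, loss = a2, b2, c2, cons2, loss2
            trace.append(loss)
            if loss < best[4] - 1e-12:
                best = (a.copy(), b.copy(), c.copy(), consequent.copy(), loss)
                stall = 0
            else:
                stall += 1
                if stall >= self.patience:
                    break
        self.a_, self.b_, self.c_, self.consequent_, _ = best
        self.loss_trace_ = np.array(trace)
        return self

    def predict(self, X):
        check_is_fitted(self)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError("input dimension mismatch")
        yhat, _ = self._forward(X)
        return yhat

    def normalized_firing_strengths(self, X):
        """Layer-3 outputs; rows sum to 1 for any finite input."""
        check_is_fitted(self)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        _, _, wbar = self._normalized_firing(X)
        return wbar

    def to_dict(self) -> dict:
        check_is_fitted(self)
        return {
            "mfs_per_input": self.mfs_per_input,
            "a": self.a_.tolist(),
            "b": self.b_.tolist(),
            "c": self.c_.tolist(),
            "rules": self.rules_.tolist(),
            "consequent": self.consequent_.tolist(),
            "input_ranges": self.input_ranges_.tolist(),
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()) + "\n")


def fit_hybrid(S, y, cfg: TrainConfig = TrainConfig(), mfs_per_input: int = 2) -> ANFISRegressor:
    """Functional wrapper: train an ANFIS on PLS scores S against y."""
    model = ANFISRegressor(
        mfs_per_input=mfs_per_input,
        epochs=cfg.epochs,
        learning_rate=cfg.learning_rate,
        patience=cfg.patience,
        init_jitter=cfg.init_jitter,
        random_state=cfg.seed,
    )
    return model.fit(S, y)
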