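"""Multiple linear regression baseline: CARs to voxels, and its inversion.

Ordinary least squares predicts each voxel from the 66 CAR attributes
(intercept included, one voxel at a time — equivalently one joint lstsq).
Because the map is linear it can be inverted: given a sentence's observed
fMRI, the minimum-norm adjustment to the sentence's word CARs that zeroes
the linear prediction error has a closed form. The contrast between this
baseline and the nonlinear network is that the linear revisions tend to
regress word attributes toward the mean rather than gaining content.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted


class LinearCarModel(BaseEstimator, RegressorMixin):
    """Per-voxel OLS from CAR attributes, with minimum-norm pseudoinverse fit.

    Fitted attributes: ``coef_`` (n_features x n_voxels), ``intercept_``
    (n_voxels,), ``residuals_`` (training residuals Y - Yhat), ``rank_``.
    """

    def fit(self, X, y):
        X = check_array(X)
        Y = check_array(y)
        if X.shape[0] < 2:
            raise ValueError("need >=2 training rows")
        design = np.hstack([np.ones((X.shape[0], 1)), X])
        beta, _, rank, _ = np.linalg.lstsq(design, Y, rcond=None)
        if rank < design.shape[1]:
            warnings.warn(
                "rank-deficient design; minimum-norm coefficients returned",
                RuntimeWarning,
            )
        self.intercept_ = beta[0]
        self.coef_ = beta[1:]
        self.rank_ = int(rank)
        self.residuals_ = Y - (design @ beta)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X)
        return X @ self.coef_ + self.intercept_


def fit_lreg(X: np.ndarray, Y: np.ndarray) -> LinearCarModel:
    """OLS fit of voxels on CAR attributes (least squares per voxel)."""
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise ValueError("non-finite values in regression inputs")
    return LinearCarModel().fit(X, Y)


def predict_sentence_lreg(model: LinearCarModel, cars: np.ndarray) -> np.ndarray:
    """Linear sentence prediction: mean of the per-word linear predictions."""
    cars = np.atleast_2d(np.asarray(cars, dtype=float))
    return model.predict(cars).mean(axis=0)


def invert_lreg(
    model: LinearCarModel,
    cars: np.ndarray,
    observed: np.ndarray,
    clamp: bool = True,
    atol: float = 1e-9,
) -> tuple[np.ndarray, dict]:
    """Minimum-norm CAR adjustment that zeroes the linear sentence error.

    The sentence prediction is linear in the mean of the word CARs, so the
    stacked minimum-norm correction gives every word the same adjustment:
    the pseudoinverse solution of ``delta @ coef_ = error``. When the error
    lies outside the row space of the coefficients the least-squares best
    adjustment is returned and ``info["exact"]`` is False. Components are
    clamped to [0, 1] afterward; ``info["clamp_changed"]`` reports whether
    clamping broke exactness.
    """
    check_is_fitted(model, "coef_")
    X = np.atleast_2d(np.asarray(cars, dtype=float))
    observed = np.asarray(observed, dtype=float)
    pred0 = predict_sentence_lreg(model, X)
    err = observed - pred0
    delta = err @ np.linalg.pinv(model.coef_)
    revised_raw = X + delta
    residual = observed - predict_sentence_lreg(model, revised_raw)
    exact = bool(np.max(np.abs(residual)) <= atol)
    if clamp:
        revised = np.clip(revised_raw, 0.0, 1.0)
    else:
        revised = revised_raw
    clamp_changed = bool(np.max(np.abs(revised - revised_raw)) > 0.0)
    info = {
        "exact": exact,
        "pre_clamp_residual_max": float(np.max(np.abs(residual))),
        "clamp_changed": clamp_changed,
        "adjustment_norm": float(np.linalg.norm(np.broadcast_to(
            delta, X.shape))),
    }
    return revised, info


def compare_models(
    revised_lreg: pd.DataFrame,
    revised_cerebra: pd.DataFrame,
    originals: pd.DataFrame,
    attributes: list[str],
) -> dict:
    """Per-token contrast of the linear and nonlinear revisions.

    All three frames must cover the same (subject, sentence_id, position)
    tokens; ``originals`` maps each token to its generic CAR (same tidy
    format). Reports per-token change magnitudes, the cosine agreement of
    the two methods' change directions, and a regression-to-the-mean
    statistic: the mean signed movement of revised values toward the grand
    attribute mean (positive = regressing toward the mean).
    """
    key = ["subject", "sentence_id", "position"]
    for frame, name in ((revised_lreg, "lreg"), (revised_cerebra, "cerebra"),
                        (originals, "originals")):
        if frame[key].duplicated().any():
            raise ValueError(f"duplicate tokens in {name} frame")
    a = revised_lreg.sort_values(key).reset_index(drop=True)
    b = revised_cerebra.sort_values(key).reset_index(drop=True)
    o = originals.sort_values(key).reset_index(drop=True)
    if not (a[key].equals(b[key]) and a[key].equals(o[key])):
        raise ValueError("token sets differ between the three frames")
    A = a[attributes].to_numpy(float)
    B = b[attributes].to_numpy(float)
    O = o[attributes].to_numpy(float)
    change_l = A - O
    change_c = B - O
    grand_mean = O.mean(axis=0)

    def toward_mean(change, orig):
        direction = np.sign(grand_mean - orig)
        return float(np.mean(change * direction))

    def cosines(U, V):
        nu = np.linalg.norm(U, axis=1)
        nv = np.linalg.norm(V, axis=1)
        ok = (nu > 0) & (nv > 0)
        out = np.full(len(U), np.nan)
        out[ok] = np.sum(U[ok] * V[ok], axis=1) / (nu[ok] * nv[ok])
        return out

    return {
        "n_tokens": len(A),
        "lreg_change_magnitude": np.linalg.norm(change_l, axis=1),
        "cerebra_change_magnitude": np.linalg.norm(change_c, axis=1),
        "direction_agreement": cosines(change_l, change_c),
        "lreg_toward_mean": toward_mean(change_l, O),
        "cerebra_toward_mean": toward_mean(change_c, O),
    }
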