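"""Chemometric calibration: MSC, Savitzky-Golay derivative, PLS1.

Transformers and the PLS1 regressor follow the scikit-learn estimator
protocol (fit/transform/predict, get_params/set_params) and compose with
sklearn pipelines; the module-level functions are thin wrappers operating
on :class:`~nilqtl.spectra.SpectraSet` objects.

Calibration quality is summarised as the Pearson correlation r between
reference and predicted values and the standard error of calibration

    SEC = sqrt( sum (y_hat - y)^2 / (n - 1 - n_params) ),

with n_params the number of model parameters beyond the intercept (the
number of latent components for PLS1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import savgol_filter

from ._base import BaseEstimator
from .spectra import SpectraSet

logger = logging.getLogger(__name__)

__all__ = [
    "MultiplicativeScatterCorrection",
    "SavitzkyGolayDerivative",
    "PLS1Regression",
    "CalibrationStats",
    "LinearCalibration",
    "msc",
    "savitzky_golay_first_derivative",
    "pls1_fit",
    "pls1_predict",
    "calibration_stats",
    "nmr_linear_calibration",
    "calibration_validation_split",
]


def _as_array(X) -> np.ndarray:
    if isinstance(X, SpectraSet):
        return X.values
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float)
    return np.asarray(X, dtype=float)


class MultiplicativeScatterCorrection(BaseEstimator):
    """Remove multiplicative/additive scatter against a reference spectrum.

    Each spectrum x is regressed on the reference m by least squares,
    x ~ a + b*m, and corrected to (x - a) / b.  The reference defaults to
    the mean training spectrum.  Correcting an already-corrected matrix with
    the same fitted reference is an exact no-op (a=0, b=1), so the
    transform is idempotent.
    """

    def __init__(self, reference: np.ndarray | None = None):
        self.reference = reference

    def fit(self, X, y=None):
        X = _as_array(X)
        if self.reference is not None:
            self.reference_ = np.asarray(self.reference, dtype=float)
            if self.reference_.shape != (X.shape[1],):
                raise ValueError("reference spectrum length mismatch")
        else:
            if X.shape[0] < 2:
                raise ValueError(
                    "MSC needs >= 2 samples to form a mean reference spectrum"
                )
            self.reference_ = X.mean(axis=0)
        return self

    def transform(self, X):
        self._check_is_fitted("reference_")
        A = _as_array(X)
        m = self.reference_
        mc = m - m.mean()
        denom = float(mc @ mc)
        if denom == 0.0:
            raise ValueError("reference spectrum is constant")
        b = (A - A.mean(axis=1, keepdims=True)) @ mc / denom
        if np.any(b == 0.0):
            bad = int(np.flatnonzero(b == 0.0)[0])
            raise ValueError(
                f"sample {bad} is uncorrelated with the reference spectrum (b=0)"
            )
        a = A.mean(axis=1) - b * m.mean()
        out = (A - a[:, None]) / b[:, None]
        if isinstance(X, SpectraSet):
            return X.with_values(out)
        return out

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)


class SavitzkyGolayDerivative(BaseEstimator):
    """Savitzky-Golay derivative of each spectrum.

    A polynomial of order ``polyorder`` is least-squares fitted in a moving
    window of ``window`` points and differentiated; edge points come from
    the polynomial fitted to the first/last window (asymmetric windows, no
    padding).  Output units are absorbance per nm: the wavelength spacing is
    taken from the data when a :class:`SpectraSet` is given, else from
    ``spacing``.
    """

    def __init__(
        self,
        window: int = 11,
        polyorder: int = 2,
        deriv: int = 1,
        spacing: float = 10.0,
    ):
        self.window = window
        self.polyorder = polyorder
        self.deriv = deriv
        self.spacing = spacing

    def _validate(self, n_wavelengths: int) -> None:
        if self.window % 2 == 0:
            raise ValueError("window must be odd")
        if not self.window > self.polyorder >= self.deriv:
            raise ValueError("need window > polyorder >= deriv")
        if self.window > n_wavelengths:
            raise ValueError("window exceeds the number of wavelengths")

    def fit(self, X, y=None):
        self._validate(_as_array(X).shape[1])
        return self

    def transform(self, X):
        A = _as_array(X)
        self._validate(A.shape[1])
        delta = self.spacing
        if isinstance(X, SpectraSet):
            steps = np.diff(X.wavelengths)
            if not np.allclose(steps, steps[0]):
                raise ValueError("Savitzky-Golay requires an even wavelength grid")
            delta = float(steps[0])
        out = savgol_filter(
            A, self.window, self.polyorder, deriv=self.deriv, delta=delta,
            axis=1, mode="interp",
        )
        if isinstance(X, SpectraSet):
            return X.with_values(out)
        return out

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)


class PLS1Regression(BaseEstimator):
    """NIPALS partial least squares with a single response (PLS1).

    On column-centered X and centered y, each component extracts the weight
    w ∝ X'y, scores t = Xw, loadings p = X't/t't and q = y't/t't, then
    deflates X ← X - t p' and y ← y - q t.  Regression coefficients for
    raw-scale prediction are assembled as B = W (P'W)^{-1} q.

    n_components : int or "loo"
        Number of latent components, or "loo" to pick the component count
        (up to ``max_components``) minimising leave-one-out prediction
        error.
    """

    def __init__(self, n_components: int | str = "loo", max_components: int = 15):
        self.n_components = n_components
        self.max_components = max_components

    def _fit_nipals(self, X: np.ndarray, y: np.ndarray, a_max: int):
        n, p = X.shape
        x_mean = X.mean(axis=0)
        y_mean = y.mean()
        Xc = X - x_mean
        yc = y - y_mean
        W = np.zeros((p, a_max))
        P = np.zeros((p, a_max))
        T = np.zeros((n, a_max))
        q = np.zeros(a_max)
        for a in range(a_max):
            w = Xc.T @ yc
            norm = np.linalg.norm(w)
            if norm == 0.0:  # nothing left to extract
                a_max = a
                break
            w /= norm
            t = Xc @ w
            tt = float(t @ t)
            if tt == 0.0:
                a_max = a
                break
            pl = Xc.T @ t / tt
            qa = float(yc @ t) / tt
            Xc = Xc - np.outer(t, pl)
            yc = yc - qa * t
            W[:, a], P[:, a], T[:, a], q[a] = w, pl, t, qa
        W, P, T, q = W[:, :a_max], P[:, :a_max], T[:, :a_max], q[:a_max]
        if a_max == 0:
            coef = np.zeros(p)
        else:
            coef = W @ np.linalg.solve(P.T @ W, q)
        return x_mean, y_mean, W, P, T, q, coef, a_max

    def fit(self, X, y):
        A = _as_array(X)
        y = np.asarray(
            y.to_numpy() if isinstance(y, (pd.Series, pd.DataFrame)) else y,
            dtype=float,
        ).ravel()
        if A.shape[0] != y.size:
            raise ValueError("X and y have different numbers of samples")
        if np.std(y) == 0.0:
            raise ValueError("response has zero variance")
        cap = min(A.shape[0] - 1, A.shape[1])
        if self.n_components == "loo":
            a_use = self._select_loo(A, y, min(cap, self.max_components))
        else:
            a_use = int(self.n_components)
            if not 1 <= a_use <= cap:
                raise ValueError(
                    f"n_components must be in [1, {cap}] for this data"
                )
        (self.x_mean_, self.y_mean_, self.weights_, self.loadings_, self.scores_,
         self.y_loadings_, self.coef_, self.n_components_) = self._fit_nipals(
            A, y, a_use
        )
        self.intercept_ = self.y_mean_ - float(self.x_mean_ @ self.coef_)
        fitted = A @ self.coef_ + self.intercept_
        self.training_stats_ = calibration_stats(fitted, y, self.n_components_)
        return self

    def _select_loo(self, A: np.ndarray, y: np.ndarray, a_cap: int) -> int:
        press = self.loo_press(A, y, a_cap)
        return int(np.argmin(press)) + 1

    def loo_press(self, A: np.ndarray, y: np.ndarray, a_cap: int) -> np.ndarray:
        """Leave-one-out PRESS for component counts 1..a_cap.

        One incremental NIPALS pass per left-out sample; coefficients for
        every component count are read off the same decomposition.
        """
        n = A.shape[0]
        press = np.zeros(a_cap)
        for i in range(n):
            mask = np.arange(n) != i
            preds = self._loo_path_predict(A[mask], y[mask], A[i], a_cap)
            press[: preds.size] += (preds - y[i]) ** 2
            press[preds.size:] += (preds[-1] - y[i]) ** 2 if preds.size else y[i] ** 2
        return press

    def _loo_path_predict(
        self, Xi: np.ndarray, yi: np.ndarray, x_new: np.ndarray, a_cap: int
    ) -> np.ndarray:
        x_mean, y_mean, W, P, _, q, _, a_eff = self._fit_nipals(Xi, yi, a_cap)
        preds = np.empty(a_eff)
        for a in range(1, a_eff + 1):
            coef = W[:, :a] @ np.linalg.solve(P[:, :a].T @ W[:, :a], q[:a])
            preds[a - 1] = float((x_new - x_mean) @ coef) + y_mean
        return preds

    def predict(self, X) -> np.ndarray:
        self._check_is_fitted("coef_")
        A = _as_array(X)
        if A.shape[1] != self.coef_.size:
            raise ValueError(
                f"wavelength grid mismatch: model has {self.coef_.size} "
                f"channels, data has {A.shape[1]}"
            )
        return A @ self.coef_ + self.intercept_

    def score(self, X, y) -> float:
        """Pearson r between reference and predicted values."""
        return float(calibration_stats(self.predict(X), y, self.n_components_).r)


@dataclass(frozen=True)
class CalibrationStats:
    """Correlation and standard error of a calibration."""

    r: float
    sec: float
    n: int
    n_params: int

    def __str__(self) -> str:
        return f"r={self.r:.3f}, SEC={self.sec:.3f} (n={self.n})"


def calibration_stats(predicted, reference, n_params: int) -> CalibrationStats:
    """Pearson r and SEC between predicted and reference values."""
    yhat = np.asarray(
        predicted.to_numpy() if isinstance(predicted, pd.Series) else predicted,
        dtype=float,
    ).ravel()
    y = np.asarray(
        reference.to_numpy() if isinstance(reference, pd.Series) else reference,
        dtype=float,
    ).ravel()
    if yhat.size != y.size:
        raise ValueError("predicted and reference lengths differ")
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 samples for calibration statistics")
    tol = 1e-12
    if (
        np.std(yhat) <= tol * (abs(float(np.mean(yhat))) + 1.0)
        or np.std(y) <= tol * (abs(float(np.mean(y))) + 1.0)
    ):
        logger.warning("constant predictions or references: r undefined")
        r = float("nan")
    else:
        r = float(stats.pearsonr(yhat, y).statistic)
    dof = n - 1 - n_params
    if dof <= 0:
        raise ValueError("non-positive degrees of freedom for SEC")
    sec = float(np.sqrt(np.sum((yhat - y) ** 2) / dof))
    return CalibrationStats(r=r, sec=sec, n=n, n_params=n_params)


@dataclass(frozen=True)
class LinearCalibration:
    """Single-predictor least-squares calibration (e.g. NMR resonance)."""

    slope: float
    intercept: float
    stats: CalibrationStats

    def predict(self, resonance) -> np.ndarray:
        x = np.asarray(
            resonance.to_numpy() if isinstance(resonance, pd.Series) else resonance,
            dtype=float,
        ).ravel()
        return self.intercept + self.slope * x


def nmr_linear_calibration(resonance, reference) -> LinearCalibration:
    """Calibrate a single-signal instrument against reference chemistry.

    ``resonance`` may be 1-D (already averaged) or 2-D with one column per
    replicate reading, in which case replicates are averaged per sample.
    The reference is regressed on the mean resonance, reference ~ alpha +
    beta * resonance, and the fit is summarised with n_params = 1.
    """
    x = _as_array(resonance)
    if x.ndim == 2:
        x = x.mean(axis=1)
    y = np.asarray(
        reference.to_numpy() if isinstance(reference, pd.Series) else reference,
        dtype=float,
    ).ravel()
    if x.size != y.size:
        raise ValueError("resonance and reference lengths differ")
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    if np.std(x) == 0.0:
        raise ValueError("resonance values have zero variance")
    fit = stats.linregress(x, y)
    predicted = fit.intercept + fit.slope * x
    return LinearCalibration(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        stats=calibration_stats(predicted, y, n_params=1),
    )


def calibration_validation_split(
    n_samples: int, n_validation: int = 20, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded random calibration/validation index split (e.g. 190/20)."""
    if not 0 < n_validation < n_samples:
        raise ValueError("n_validation must be in (0, n_samples)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_samples)
    return np.sort(perm[n_validation:]), np.sort(perm[:n_validation])


# ---------------------------------------------------------------------------
# SpectraSet-level convenience functions


def msc(spectra: SpectraSet, reference: np.ndarray | None = None) -> SpectraSet:
    """Multiplicative scatter correction against the mean (or given) spectrum."""
    return MultiplicativeScatterCorrection(reference=reference).fit_transform(spectra)


def savitzky_golay_first_derivative(
    spectra: SpectraSet, window: int = 11, polyorder: int = 2
) -> SpectraSet:
    """First derivative of each spectrum (absorbance per nm)."""
    return SavitzkyGolayDerivative(window=window, polyorder=polyorder).fit_transform(
        spectra
    )


def pls1_fit(
    X: SpectraSet | np.ndarray, y, n_components: int | str = "loo"
) -> PLS1Regression:
    """Fit a PLS1 calibration on (preprocessed) spectra."""
    return PLS1Regression(n_components=n_components).fit(X, y)


def pls1_predict(model: PLS1Regression, X: SpectraSet | np.ndarray) -> np.ndarray:
    return model.predict(X)
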