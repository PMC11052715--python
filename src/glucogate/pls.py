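"""Chemometric glucose quantification: mean-centering, single-response
PLSR (NIPALS), leave-one-out cross-validation, latent-variable selection
and exploratory PCA.

PLSR finds latent variables maximizing covariance between the spectral
matrix X (n spectra x p wavenumbers) and the reference glucose vector y.
With the maximal number of latent variables the training fit coincides
with ordinary least squares on centered X, a property used as a test
oracle.  RMSECV is the root-mean-square error of the leave-one-out
out-of-fold predictions, with centering (and optional autoscaling)
recomputed inside every fold so no fold sees its held-out sample.

The statsmodels-style surface is :class:`GlucosePLS` (model, built from
data) whose ``fit()`` returns :class:`GlucosePLSResults` (estimates,
cross-validation diagnostics and a ``summary()`` table).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpectraMatrix",
    "PLSRModel",
    "CVResult",
    "mean_center",
    "fit_plsr",
    "predict",
    "loocv",
    "select_n_lv",
    "pca_decompose",
    "align_reference",
    "GlucosePLS",
    "GlucosePLSResults",
]


@dataclass(frozen=True)
class SpectraMatrix:
    """Spectra with aligned reference glucose values."""

    X: np.ndarray  # (n_samples, n_wavenumbers)
    wavenumbers: np.ndarray
    timestamps_min: np.ndarray
    y: np.ndarray  # mg/dl

    def __post_init__(self):
        X = np.asarray(self.X, dtype=float)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        object.__setattr__(self, "wavenumbers", np.asarray(self.wavenumbers, dtype=float))
        object.__setattr__(self, "timestamps_min", np.asarray(self.timestamps_min, dtype=float))
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if not np.all(np.isfinite(X)) or not np.all(np.isfinite(self.y)):
            raise ValueError("X and y must be finite")
        if self.y.shape[0] != X.shape[0]:
            raise ValueError("y length must equal the number of rows of X")
        if self.wavenumbers.shape[0] != X.shape[1]:
            raise ValueError("wavenumber grid length must equal the number of columns")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_wavenumbers(self) -> int:
        return self.X.shape[1]


@dataclass(frozen=True)
class PLSRModel:
    """Fitted single-response PLSR in terms of the original variables."""

    n_lv: int
    x_mean: np.ndarray
    y_mean: float
    x_scale: np.ndarray  # ones unless autoscaled
    weights: np.ndarray  # (p, n_lv)
    x_loadings: np.ndarray  # (p, n_lv)
    y_loadings: np.ndarray  # (n_lv,)
    coef: np.ndarray  # (p,), on centered/scaled variables


@dataclass(frozen=True)
class CVResult:
    """Leave-one-out predictions and RMSECV."""

    predictions: np.ndarray  # out-of-fold, mg/dl, at n_lv
    rmsecv: float
    n_lv: int
    rmsecv_curve: np.ndarray = field(default=None)  # RMSECV at 1..max_lv
    predictions_per_lv: np.ndarray = field(default=None, repr=False)  # (n, max_lv)

    def at_n_lv(self, n_lv: int) -> "CVResult":
        """The same cross-validation truncated to a smaller component count."""
        if self.predictions_per_lv is None or not 1 <= n_lv <= self.predictions_per_lv.shape[1]:
            raise ValueError("per-component predictions unavailable for that count")
        return CVResult(
            predictions=self.predictions_per_lv[:, n_lv - 1],
            rmsecv=float(self.rmsecv_curve[n_lv - 1]),
            n_lv=n_lv,
            rmsecv_curve=self.rmsecv_curve,
            predictions_per_lv=self.predictions_per_lv,
        )


def mean_center(X: np.ndarray, y: np.ndarray | None = None):
    """Column-center X (and y); returns centered arrays and the stored means."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("mean centering needs at least 2 samples")
    x_mean = X.mean(axis=0)
    Xc = X - x_mean
    if y is None:
        return Xc, x_mean
    y = np.asarray(y, dtype=float)
    y_mean = float(y.mean())
    return Xc, y - y_mean, x_mean, y_mean


def _max_lv(n: int, p: int) -> int:
    return min(n - 1, p)


def _nipals(Xc: np.ndarray, yc: np.ndarray, n_lv: int):
    """Single-response NIPALS with deflation of X only.

    Returns weights W, X-loadings P and y-loadings q for n_lv components
    (possibly fewer if the residual is exhausted).
    """
    n, p = Xc.shape
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    q = np.zeros(n_lv)
    X = Xc.copy()
    used = 0
    for a in range(n_lv):
        w = X.T @ yc
        nw = np.linalg.norm(w)
        if nw < 1e-14 * max(1.0, np.abs(yc).max(initial=0.0)):
            break
        w /= nw
        t = X @ w
        tt = t @ t
        if tt <= 0:
            break
        P[:, a] = X.T @ t / tt
        q[a] = (yc @ t) / tt
        W[:, a] = w
        X -= np.outer(t, P[:, a])
        used += 1
    return W[:, :used], P[:, :used], q[:used]


def _coef_path(W: np.ndarray, P: np.ndarray, q: np.ndarray) -> np.ndarray:
    """(p, A) regression coefficients for every truncation 1..A."""
    p, A = W.shape
    out = np.zeros((p, A))
    for a in range(1, A + 1):
        out[:, a - 1] = W[:, :a] @ np.linalg.solve(P[:, :a].T @ W[:, :a], q[:a])
    return out


def fit_plsr(M: SpectraMatrix, n_lv: int, autoscale: bool = False) -> PLSRModel:
    """Fit single-response PLSR with ``n_lv`` latent variables.

    Preprocessing is mean-centering of X columns and y; optional
    autoscaling divides the centered columns by their standard deviation.
    """
    n, p = M.X.shape
    if not 1 <= n_lv <= _max_lv(n, p):
        raise ValueError(f"n_lv must be in [1, {_max_lv(n, p)}], got {n_lv}")
    Xc, yc, x_mean, y_mean = mean_center(M.X, M.y)
    scale = np.ones(p)
    if autoscale:
        sd = Xc.std(axis=0, ddof=1)
        scale = np.where(sd > 0, sd, 1.0)
        Xc = Xc / scale
    W, P, q = _nipals(Xc, yc, n_lv)
    coef = _coef_path(W, P, q)[:, -1] if W.shape[1] else np.zeros(p)
    return PLSRModel(
        n_lv=W.shape[1] if W.shape[1] else n_lv,
        x_mean=x_mean,
        y_mean=y_mean,
        x_scale=scale,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        coef=coef,
    )


def predict(model: PLSRModel, X_new: np.ndarray) -> np.ndarray:
    """y_hat = y_mean + ((X_new - x_mean) / x_scale) . coef"""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.x_mean.shape[0]:
        raise ValueError(
            f"X_new has {X_new.shape[1]} columns, model expects {model.x_mean.shape[0]}"
        )
    return model.y_mean + ((X_new - model.x_mean) / model.x_scale) @ model.coef


def loocv(M: SpectraMatrix, n_lv: int, autoscale: bool = False) -> CVResult:
    """Leave-one-out cross-validation at 1..n_lv latent variables.

    Each fold refits the centering (and scaling) on the retained rows
    only.  The result is invariant to row permutation up to reordering
    of the out-of-fold predictions.  A fold whose retained y is constant
    predicts that constant with a warning instead of failing.
    """
    n, p = M.X.shape
    if n < 3:
        raise ValueError("leave-one-out cross-validation needs at least 3 samples")
    if not 1 <= n_lv <= _max_lv(n - 1, p):
        raise ValueError(
            f"n_lv must be in [1, {_max_lv(n - 1, p)}] to be feasible in every fold"
        )
    preds = np.zeros((n, n_lv))
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        Xt, yt = M.X[keep], M.y[keep]
        x_mean = Xt.mean(axis=0)
        y_mean = yt.mean()
        Xc, yc = Xt - x_mean, yt - y_mean
        scale = np.ones(p)
        if autoscale:
            sd = Xc.std(axis=0, ddof=1)
            scale = np.where(sd > 0, sd, 1.0)
            Xc = Xc / scale
        if np.allclose(yc, 0):
            warnings.warn("constant y in a fold; predicting the fold mean")
            preds[i, :] = y_mean
            continue
        W, P, q = _nipals(Xc, yc, n_lv)
        if W.shape[1] == 0:
            preds[i, :] = y_mean
            continue
        B = _coef_path(W, P, q)  # (p, used)
        xi = (M.X[i] - x_mean) / scale
        fold_preds = y_mean + xi @ B
        preds[i, : B.shape[1]] = fold_preds
        preds[i, B.shape[1]:] = fold_preds[-1]
    curve = np.sqrt(np.mean((preds - M.y[:, None]) ** 2, axis=0))
    return CVResult(
        predictions=preds[:, n_lv - 1],
        rmsecv=float(curve[n_lv - 1]),
        n_lv=n_lv,
        rmsecv_curve=curve,
        predictions_per_lv=preds,
    )


def select_n_lv(
    M: SpectraMatrix, max_lv: int = 10, rel_tol: float = 0.02, autoscale: bool = False
) -> tuple[int, CVResult]:
    """Parsimonious latent-variable count.

    Runs LOOCV up to ``max_lv`` (capped at feasibility) and returns the
    smallest count whose RMSECV is within ``rel_tol`` of the global
    minimum, together with the CV result.
    """
    if max_lv < 1:
        raise ValueError("max_lv must be >= 1")
    feasible = min(max_lv, _max_lv(M.n_samples - 1, M.n_wavenumbers))
    cv = loocv(M, feasible, autoscale=autoscale)
    curve = cv.rmsecv_curve
    best = curve.min()
    n_lv = int(np.flatnonzero(curve <= best * (1.0 + rel_tol))[0]) + 1
    return n_lv, cv.at_n_lv(n_lv)


def pca_decompose(M: SpectraMatrix, k: int):
    """PCA of the centered spectra via SVD.

    Returns (scores, loadings, explained_variance): loadings are
    orthonormal columns, variances are non-increasing, and the full
    decomposition reconstructs the centered matrix.
    """
    n, p = M.X.shape
    if not 1 <= k <= min(n - 1, p):
        raise ValueError(f"k must be in [1, {min(n - 1, p)}]")
    Xc, _ = mean_center(M.X)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = U[:, :k] * s[:k]
    loadings = Vt[:k].T
    explained = (s[:k] ** 2) / (n - 1)
    return scores, loadings, explained


def align_reference(
    timestamps_min: np.ndarray,
    ref_times_min: np.ndarray,
    ref_values: np.ndarray,
    tolerance_min: float = 1.5,
    interpolate: bool = False,
) -> np.ndarray:
    """Reference glucose aligned to spectrum timestamps.

    Default: nearest reference sample within ``tolerance_min`` (the
    spectrum acquisition time); with ``interpolate=True`` linear
    interpolation between reference samples is used instead.
    """
    t = np.asarray(timestamps_min, dtype=float)
    rt = np.asarray(ref_times_min, dtype=float)
    rv = np.asarray(ref_values, dtype=float)
    if interpolate:
        return np.interp(t, rt, rv)
    idx = np.searchsorted(rt, t)
    idx = np.clip(idx, 1, rt.size - 1)
    left, right = rt[idx - 1], rt[idx]
    nearest = np.where(np.abs(t - left) <= np.abs(right - t), idx - 1, idx)
    gaps = np.abs(rt[nearest] - t)
    if np.any(gaps > tolerance_min + 1e-9):
        worst = float(gaps.max())
        raise ValueError(
            f"spectrum timestamp has no reference within {tolerance_min} min "
            f"(largest gap {worst:.2f} min); use interpolate=True or widen the tolerance"
        )
    return rv[nearest]


# ---------------------------------------------------------------------------
# model/results surface


class GlucosePLS:
    """PLSR glucose calibration model on a spectra matrix.

    Parameters
    ----------
    spectra : SpectraMatrix
        Gated spectra with aligned reference glucose.
    n_lv : int, optional
        Latent-variable count; selected by the parsimony rule when None.
    max_lv : int
        Upper bound for latent-variable selection.
    autoscale : bool
        Divide centered columns by their s.d. ("mean scale" is read as
        centering only; autoscaling is off by default).
    """

    def __init__(
        self,
        spectra: SpectraMatrix,
        n_lv: int | None = None,
        max_lv: int = 10,
        autoscale: bool = False,
    ):
        self.spectra = spectra
        self.n_lv = n_lv
        self.max_lv = max_lv
        self.autoscale = autoscale

    @classmethod
    def from_dataframe(
        cls,
        spectra_df,
        reference_df,
        tolerance_min: float = 1.5,
        interpolate: bool = False,
        **kwargs,
    ) -> "GlucosePLS":
        """Build from a spectra table and a reference-glucose table.

        ``spectra_df`` has a ``timestamp_min`` column plus one column per
        wavenumber (numeric column names, cm^-1); ``reference_df`` has
        ``timestamp_min`` and ``glucose_mgdl`` columns.
        """
        ts = spectra_df["timestamp_min"].to_numpy(dtype=float)
        wn_cols = [c for c in spectra_df.columns if c != "timestamp_min"]
        wn = np.asarray([float(c) for c in wn_cols])
        X = spectra_df[wn_cols].to_numpy(dtype=float)
        y = align_reference(
            ts,
            reference_df["timestamp_min"].to_numpy(dtype=float),
            reference_df["glucose_mgdl"].to_numpy(dtype=float),
            tolerance_min=tolerance_min,
            interpolate=interpolate,
        )
        return cls(SpectraMatrix(X=X, wavenumbers=wn, timestamps_min=ts, y=y), **kwargs)

    def fit(self) -> "GlucosePLSResults":
        M = self.spectra
        if self.n_lv is None:
            n_lv, cv = select_n_lv(M, max_lv=self.max_lv, autoscale=self.autoscale)
        else:
            n_lv = self.n_lv
            cv = loocv(M, n_lv, autoscale=self.autoscale)
        model = fit_plsr(M, n_lv, autoscale=self.autoscale)
        return GlucosePLSResults(self, model, cv)


class GlucosePLSResults:
    """Fitted calibration: coefficients, LOOCV diagnostics, summary."""

    def __init__(self, model: GlucosePLS, plsr: PLSRModel, cv: CVResult):
        self.model = model
        self.plsr = plsr
        self.cv = cv

    @property
    def params(self) -> np.ndarray:
        return self.plsr.coef

    @property
    def n_lv(self) -> int:
        return self.cv.n_lv

    @property
    def rmsecv(self) -> float:
        return self.cv.rmsecv

    @property
    def fittedvalues(self) -> np.ndarray:
        return predict(self.plsr, self.model.spectra.X)

    @property
    def cv_predictions(self) -> np.ndarray:
        return self.cv.predictions

    @property
    def pearson_r(self) -> float:
        from .errorgrid import pearson

        return pearson(self.model.spectra.y, self.cv.predictions)

    def predict(self, X_new: np.ndarray) -> np.ndarray:
        return predict(self.plsr, X_new)

    def summary(self) -> str:
        M = self.model.spectra
        lines = [
            "Glucose PLSR calibration (leave-one-out cross-validation)",
            "=" * 58,
            f"n spectra            {M.n_samples:>10d}",
            f"n wavenumbers        {M.n_wavenumbers:>10d}",
            f"latent variables     {self.n_lv:>10d}",
            f"RMSECV (mg/dl)       {self.rmsecv:>10.2f}",
            f"Pearson r (CV)       {self.pearson_r:>10.3f}",
            f"autoscaled           {str(self.model.autoscale):>10s}",
            "=" * 58,
        ]
        return "\n".join(lines)
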