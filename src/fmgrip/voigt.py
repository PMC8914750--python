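"""Grip strength-forearm muscle model.

The forearm is abstracted as a Voigt viscoelastic element (spring and
damper in parallel, a linearization of the Hill muscle model): grip force
is an affine function of the 12-channel muscle-deformation signal ``X``
and its time derivative,

    F = a . X + b . Xdot + c

with elastic coefficients ``a`` (12), viscosity coefficients ``b`` (12)
and an offset ``c`` — 25 free parameters per wrist angle, estimated by
ordinary least squares on ramp-grip calibration trials.

Deformation is consumed in sensor-voltage units (the filtered, quantized
photoresistor output); the fitted coefficients absorb the voltage-to-
displacement calibration, so no inversion of the sensor nonlinearity is
applied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

N_CHANNELS = 12
ANGLES = (-90, 0, 90)

__all__ = [
    "VoigtParams",
    "FitReport",
    "GripTrace",
    "VoigtModel",
    "estimate_derivative",
    "predict_force",
    "fit_params",
    "estimate_grip",
    "save_params_bank",
    "load_params_bank",
]


@dataclass
class VoigtParams:
    """One angle's parameter set: elastic ``a``, viscous ``b``, offset ``c``."""

    a: np.ndarray
    b: np.ndarray
    c: float
    angle: int

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.c = float(self.c)
        if self.a.shape != (N_CHANNELS,) or self.b.shape != (N_CHANNELS,):
            raise ValueError(
                f"a and b must each have length {N_CHANNELS}, "
                f"got {self.a.shape} and {self.b.shape}"
            )
        if not (np.all(np.isfinite(self.a)) and np.all(np.isfinite(self.b))
                and np.isfinite(self.c)):
            raise ValueError("VoigtParams entries must be finite")

    def to_dict(self) -> dict:
        return {"angle": int(self.angle), "a": self.a.tolist(),
                "b": self.b.tolist(), "c": self.c}

    @classmethod
    def from_dict(cls, d: dict) -> "VoigtParams":
        return cls(a=np.asarray(d["a"]), b=np.asarray(d["b"]),
                   c=float(d["c"]), angle=int(d["angle"]))


@dataclass
class FitReport:
    """Least-squares fit outcome: parameters, residual sum of squares Q, n."""

    params: VoigtParams
    Q: float
    n: int
    condition_warning: bool
    condition_number: float = field(default=np.nan)


@dataclass
class GripTrace:
    """Paired measured/estimated grip-force time series."""

    t: np.ndarray
    Fm: np.ndarray | None
    Fp: np.ndarray
    angle_pred: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.Fp = np.asarray(self.Fp, dtype=float)
        self.angle_pred = np.asarray(self.angle_pred)
        if self.Fm is not None:
            self.Fm = np.asarray(self.Fm, dtype=float)
            if len(self.Fm) != len(self.t):
                raise ValueError("Fm length must match t")
        if len(self.Fp) != len(self.t) or len(self.angle_pred) != len(self.t):
            raise ValueError("Fp/angle_pred length must match t")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("t must be strictly increasing")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "t": self.t,
            "F_measured": self.Fm if self.Fm is not None else np.nan,
            "F_estimated": self.Fp,
            "angle_predicted": self.angle_pred,
        })


def estimate_derivative(X: np.ndarray, dt: float,
                        half_width: int = 1) -> np.ndarray:
    """Time derivative of a (n, k) or (n,) series on a uniform grid.

    Central differences at interior points, one-sided at both ends
    (second-order accurate; exact on linear signals).  ``half_width`` > 1
    widens the symmetric stencil to (x[i+h] - x[i-h]) / (2 h dt), which
    attenuates sample-level noise (ADC quantization steps) by 1/h with no
    phase lag; the near-edge points fall back to the h=1 scheme.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 time points")
    if half_width < 1:
        raise ValueError("half_width must be >= 1")
    out = np.gradient(X, dt, axis=0, edge_order=2)
    h = half_width
    if h > 1 and X.shape[0] > 2 * h:
        out[h:-h] = (X[2 * h:] - X[:-2 * h]) / (2.0 * h * dt)
    return out


def predict_force(params: VoigtParams, X: np.ndarray, Xdot: np.ndarray) -> np.ndarray:
    """Evaluate F = a.X + b.Xdot + c for one state or a series of states."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Xdot = np.atleast_2d(np.asarray(Xdot, dtype=float))
    if X.shape[1] != N_CHANNELS or Xdot.shape != X.shape:
        raise ValueError(f"X and Xdot must both be (n, {N_CHANNELS})")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Xdot))):
        raise ValueError("non-finite deformation state")
    F = X @ params.a + Xdot @ params.b + params.c
    return F[0] if F.shape == (1,) else F


class VoigtModel(RegressorMixin, BaseEstimator):
    """Angle-conditioned Voigt grip-force model, fitted by linear least squares.

    Parameters
    ----------
    angle : int or None
        Wrist angle (degrees) this parameter set belongs to; metadata only.
    ridge : float
        Optional Tikhonov penalty on (a, b). Default 0 — plain least squares.
    cond_threshold : float
        Condition number of the design matrix above which
        ``condition_warning_`` is set.

    Attributes
    ----------
    a_, b_, c_ : fitted elastic, viscous and offset parameters.
    q_ : residual sum of squares (N^2) on the training data.
    n_ : number of samples used.
    condition_warning_ : bool, design matrix ill-conditioned or rank deficient.
    """

    def __init__(self, angle: int | None = None, ridge: float = 0.0,
                 cond_threshold: float = 1e8):
        self.angle = angle
        self.ridge = ridge
        self.cond_threshold = cond_threshold

    @staticmethod
    def _design(X: np.ndarray, Xdot: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        Xdot = np.asarray(Xdot, dtype=float)
        if X.ndim != 2 or X.shape[1] != N_CHANNELS or Xdot.shape != X.shape:
            raise ValueError(f"X and Xdot must both be (n, {N_CHANNELS})")
        return np.hstack([X, Xdot, np.ones((X.shape[0], 1))])

    def fit(self, X: np.ndarray, y: np.ndarray, Xdot: np.ndarray | None = None):
        """Fit (a, b, c) minimizing Q = sum_i (F_i - F(X_i))^2.

        ``X`` is either the (n, 24) stacked [deformation | derivative]
        matrix, or (n, 12) deformation with ``Xdot`` passed separately.
        """
        X = np.asarray(X, dtype=float)
        if Xdot is None:
            if X.ndim != 2 or X.shape[1] != 2 * N_CHANNELS:
                raise ValueError(
                    f"X must be (n, {2 * N_CHANNELS}) when Xdot is not given")
            X, Xdot = X[:, :N_CHANNELS], X[:, N_CHANNELS:]
        A = self._design(X, Xdot)
        y = np.asarray(y, dtype=float)
        n, p = A.shape
        if y.shape != (n,):
            raise ValueError("y length must match X")
        if n < p:
            raise ValueError(
                f"under-determined fit: n={n} < {p} free parameters")
        if self.ridge > 0:
            G = np.eye(p) * self.ridge
            G[-1, -1] = 0.0  # intercept unpenalized
            coef = np.linalg.solve(A.T @ A + G, A.T @ y)
            rank = p
            sv = np.linalg.svd(A, compute_uv=False)
        else:
            coef, _, rank, sv = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else np.inf
        self.coef_ = coef
        self.a_ = coef[:N_CHANNELS]
        self.b_ = coef[N_CHANNELS:2 * N_CHANNELS]
        self.c_ = float(coef[-1])
        self.q_ = float(resid @ resid)
        self.n_ = n
        self.rank_ = int(rank)
        self.condition_ = cond
        self.condition_warning_ = bool(rank < p or cond > self.cond_threshold)
        return self

    def predict(self, X: np.ndarray, Xdot: np.ndarray | None = None) -> np.ndarray:
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        if Xdot is None:
            X, Xdot = X[:, :N_CHANNELS], X[:, N_CHANNELS:]
        return self._design(X, Xdot) @ self.coef_

    @property
    def params_(self) -> VoigtParams:
        check_is_fitted(self, "coef_")
        return VoigtParams(a=self.a_, b=self.b_, c=self.c_,
                           angle=self.angle if self.angle is not None else 0)

    def report_(self) -> FitReport:
        check_is_fitted(self, "coef_")
        return FitReport(params=self.params_, Q=self.q_, n=self.n_,
                         condition_warning=self.condition_warning_,
                         condition_number=self.condition_)


def fit_params(X: np.ndarray, Xdot: np.ndarray, forces: np.ndarray,
               angle: int) -> FitReport:
    """Least-squares estimation of one angle's VoigtParams (thin wrapper)."""
    model = VoigtModel(angle=angle).fit(np.asarray(X), np.asarray(forces),
                                        Xdot=np.asarray(Xdot))
    return model.report_()


def estimate_grip(stream, classifier, params_bank: dict[int, VoigtParams],
                  sampling_rate: float = 1000.0, window_s: float = 0.2,
                  maf_window: int = 6) -> GripTrace:
    """End-to-end grip-force estimation on a raw sensor stream.

    Per 200 ms window the wrist angle is classified from the three Hall
    channels, that angle's Voigt parameters are selected, and per-sample
    force is computed from the MAF-filtered photoresistor voltages and
    their central-difference derivative.  The angle (and parameter set)
    is held constant within a window.
    """
    from . import preprocess

    missing = [a for a in ANGLES if a not in params_bank]
    if missing:
        raise ValueError(f"params_bank missing angles {missing}")
    from sklearn.exceptions import NotFittedError
    try:
        check_is_fitted(classifier)
    except NotFittedError as exc:
        raise ValueError("classifier is not trained") from exc

    t = np.asarray(stream["t"], dtype=float)
    photo = stream[[f"p{i:02d}" for i in range(1, N_CHANNELS + 1)]].to_numpy(float)
    n = len(t)
    dt = 1.0 / sampling_rate
    w = int(round(window_s * sampling_rate))
    if n < w:
        raise ValueError("stream shorter than one window")

    # gate: classify each full window; trailing partial window inherits the
    # last classified angle so every sample gets an estimate
    windows = preprocess.stitch_windows(stream, window_s=window_s,
                                        sampling_rate=sampling_rate)
    Xw = np.vstack([win.values for win in windows])
    pred = classifier.predict(Xw)

    Xf = preprocess.moving_average_filter(photo, w=maf_window)
    # wide symmetric stencil tames the amplified ADC quantization steps
    # without phase lag; must match the fitting-side processing
    Xdot = estimate_derivative(Xf, dt, half_width=3)

    Fp = np.empty(n)
    angle_pred = np.empty(n, dtype=int)
    for k in range(len(windows)):
        lo, hi = k * w, min((k + 1) * w, n)
        ang = int(pred[k])
        p = params_bank[ang]
        Fp[lo:hi] = Xf[lo:hi] @ p.a + Xdot[lo:hi] @ p.b + p.c
        angle_pred[lo:hi] = ang
    tail = len(windows) * w
    if tail < n:
        ang = int(pred[-1])
        p = params_bank[ang]
        Fp[tail:] = Xf[tail:] @ p.a + Xdot[tail:] @ p.b + p.c
        angle_pred[tail:] = ang

    Fm = None
    if "force" in stream and not np.all(np.isnan(np.asarray(stream["force"], float))):
        Fm = np.asarray(stream["force"], dtype=float)
    return GripTrace(t=t, Fm=Fm, Fp=Fp, angle_pred=angle_pred)


def save_params_bank(bank: dict[int, VoigtParams], path) -> None:
    with open(path, "w") as fh:
        json.dump([bank[a].to_dict() for a in sorted(bank)], fh, indent=1)


def load_params_bank(path) -> dict[int, VoigtParams]:
    with open(path) as fh:
        entries = json.load(fh)
    return {int(e["angle"]): VoigtParams.from_dict(e) for e in entries}
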