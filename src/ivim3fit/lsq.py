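"""Constrained nonlinear least-squares IVIM fitting.

Voxel-wise and ROI-wise bounded fits of the bi-exponential model (directly)
and the tri-exponential model (in the primed parameterisation f0', f1', f2',
D, D1*, D2*), using trust-region-reflective least squares with analytic
Jacobians.  The default constraint intervals are:

bi:  3e-4 < D < 5e-3 mm²/s, 0 < f < 0.7, 5e-3 < D* < 3e-1 mm²/s,
     0.5 < S0 < 2.5
tri: 0 < D < 8e-3 mm²/s, 8e-3 < D1* < 80e-3 mm²/s, 60e-3 < D2* < 5 mm²/s,
     0 < f0' < 2.5, 0 < f1' < 1, 0 < f2' < 1

The D1*/D2* intervals overlap on [60e-3, 80e-3] and no ordering constraint
is added beyond the intervals themselves; ordering violations (only possible
inside the overlap) are reported in diagnostics rather than forbidden.

Fitting is deterministic: every voxel starts at the geometric midpoint of
each bound interval, with one fixed restart from the arithmetic midpoint if
the solver fails.  Non-converged or degenerate voxels are flagged and filled
with bound-midpoint defaults so parameter maps are always complete.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

from .models import (
    BiParams,
    BValueScheme,
    TriParams,
    TriParamsPrime,
    ValidationError,
    bi_signal,
    tri_signal,
)

__all__ = ["FitBounds", "FitReport", "fit_bi_lsq", "fit_tri_lsq", "fit_roi", "adjusted_r2"]

_BI_ORDER = ("S0", "D", "Dstar", "f")
_TRI_ORDER = ("f0p", "f1p", "f2p", "D", "D1star", "D2star")

_BI_DEFAULTS = {
    "S0": (0.5, 2.5),
    "D": (3e-4, 5e-3),
    "Dstar": (5e-3, 3e-1),
    "f": (0.0, 0.7),
}
_TRI_DEFAULTS = {
    "f0p": (0.0, 2.5),
    "f1p": (0.0, 1.0),
    "f2p": (0.0, 1.0),
    "D": (0.0, 8e-3),
    "D1star": (8e-3, 80e-3),
    "D2star": (60e-3, 5.0),
}


@dataclass(frozen=True)
class FitBounds:
    """Per-parameter (low, high) constraints shared by LSQ and NN back-ends."""

    model: str  # "bi" or "tri"
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        if self.model not in ("bi", "tri"):
            raise ValidationError("model must be 'bi' or 'tri'")
        defaults = _BI_DEFAULTS if self.model == "bi" else _TRI_DEFAULTS
        merged = dict(defaults)
        for name, pair in self.bounds.items():
            if name not in defaults:
                raise ValidationError(f"unknown parameter {name!r} for {self.model}")
            lo, hi = float(pair[0]), float(pair[1])
            if not lo < hi:
                raise ValidationError(f"bounds for {name} need low < high")
            merged[name] = (lo, hi)
        object.__setattr__(self, "bounds", merged)

    @classmethod
    def bi_defaults(cls) -> "FitBounds":
        return cls("bi")

    @classmethod
    def tri_defaults(cls) -> "FitBounds":
        return cls("tri")

    @property
    def order(self) -> tuple[str, ...]:
        return _BI_ORDER if self.model == "bi" else _TRI_ORDER

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([self.bounds[n][0] for n in self.order])
        hi = np.array([self.bounds[n][1] for n in self.order])
        return lo, hi

    def geometric_midpoint(self) -> np.ndarray:
        """Deterministic start point; zero lower bounds are floored at high/1000."""
        lo, hi = self.arrays()
        return np.sqrt(np.maximum(lo, hi * 1e-3) * hi)

    def arithmetic_midpoint(self) -> np.ndarray:
        lo, hi = self.arrays()
        return 0.5 * (lo + hi)

    def contains(self, values: dict[str, np.ndarray], atol: float = 1e-9) -> bool:
        for name in self.order:
            lo, hi = self.bounds[name]
            v = np.asarray(values[name])
            if np.any(v < lo - atol) or np.any(v > hi + atol):
                return False
        return True


@dataclass(frozen=True)
class FitReport:
    """Fitted parameters plus per-voxel diagnostics."""

    params: object  # BiParams or TriParams, vectorised
    residual_rms: np.ndarray
    converged: np.ndarray
    n_params: int
    bounds: FitBounds
    model: str
    adjusted_r2: Optional[float] = None  # ROI-wise fits only
    ordering_violations: int = 0  # tri only: voxels with D1* > D2*

    def maps(self) -> dict[str, np.ndarray]:
        return self.params.as_dict()


def adjusted_r2(observed, fitted, n_params: int) -> float:
    """Coefficient of determination penalised for model degrees of freedom.

    adj R² = 1 - (1 - R²)(n - 1)/(n - n_params - 1).
    """
    obs = np.asarray(observed, dtype=float).ravel()
    fit = np.asarray(fitted, dtype=float).ravel()
    if obs.shape != fit.shape:
        raise ValidationError("observed and fitted lengths differ")
    n = obs.size
    if n <= n_params + 1:
        raise ValidationError("need n > n_params + 1 observations")
    ss_res = float(np.sum((obs - fit) ** 2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        # constant data: perfect fit iff zero residuals
        return 1.0 if ss_res == 0 else -np.inf
    r2 = 1.0 - ss_res / ss_tot
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_params - 1)


def _bi_model_and_jac(x: np.ndarray, b: np.ndarray):
    S0, D, Ds, f = x
    eD = np.exp(-b * D)
    eDs = np.exp(-b * Ds)
    model = S0 * ((1 - f) * eD + f * eDs)
    jac = np.empty((b.size, 4))
    jac[:, 0] = (1 - f) * eD + f * eDs
    jac[:, 1] = -S0 * (1 - f) * b * eD
    jac[:, 2] = -S0 * f * b * eDs
    jac[:, 3] = S0 * (eDs - eD)
    return model, jac


def _tri_model_and_jac(x: np.ndarray, b: np.ndarray):
    f0, f1, f2, D, D1, D2 = x
    e0 = np.exp(-b * D)
    e1 = np.exp(-b * D1)
    e2 = np.exp(-b * D2)
    model = f0 * e0 + f1 * e1 + f2 * e2
    jac = np.empty((b.size, 6))
    jac[:, 0] = e0
    jac[:, 1] = e1
    jac[:, 2] = e2
    jac[:, 3] = -f0 * b * e0
    jac[:, 4] = -f1 * b * e1
    jac[:, 5] = -f2 * b * e2
    return model, jac


def _fit_curves(signals: np.ndarray, b: np.ndarray, bounds: FitBounds):
    """Shared voxel loop: bounded TRF solve with one deterministic restart."""
    model_jac = _bi_model_and_jac if bounds.model == "bi" else _tri_model_and_jac
    lo, hi = bounds.arrays()
    x0_primary = np.clip(bounds.geometric_midpoint(), lo, hi)
    x0_retry = bounds.arithmetic_midpoint()
    midpoint_fill = bounds.arithmetic_midpoint()

    n_vox = signals.shape[0]
    n_par = lo.size
    xs = np.empty((n_vox, n_par))
    rms = np.full(n_vox, np.nan)
    conv = np.zeros(n_vox, dtype=bool)

    for i in range(n_vox):
        y = signals[i]
        if not np.all(np.isfinite(y)) or np.all(y == 0):
            xs[i] = midpoint_fill
            continue

        def resid(x, y=y):
            return model_jac(x, b)[0] - y

        def jac(x):
            return model_jac(x, b)[1]

        sol = None
        for x0 in (x0_primary, x0_retry):
            try:
                res = least_squares(
                    resid, x0, jac=jac, bounds=(lo, hi), method="trf",
                    ftol=1e-10, xtol=1e-10, gtol=1e-10, max_nfev=1000,
                )
            except Exception:
                continue
            if res.success and np.isfinite(res.cost):
                sol = res
                break
            if sol is None and np.isfinite(res.cost):
                sol = res  # keep a usable (unconverged) solution
        if sol is not None and sol.success:
            xs[i] = np.clip(sol.x, lo, hi)
            rms[i] = np.sqrt(np.mean(sol.fun**2))
            conv[i] = True
        elif sol is not None:
            xs[i] = np.clip(sol.x, lo, hi)
            rms[i] = np.sqrt(np.mean(sol.fun**2))
        else:
            xs[i] = midpoint_fill
    return xs, rms, conv


def _check_signal_matrix(signals, b: BValueScheme, min_unique_b: int):
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    bv = b.values if isinstance(b, BValueScheme) else np.asarray(b, dtype=float)
    if signals.shape[1] != bv.size:
        raise ValidationError("signal columns do not match b-value count")
    if np.unique(bv).size < min_unique_b:
        raise ValidationError(f"need at least {min_unique_b} distinct b-values")
    return signals, bv


def fit_bi_lsq(signals, b, bounds: Optional[FitBounds] = None) -> FitReport:
    """Voxel-wise bounded least-squares fit of the bi-exponential model."""
    bounds = bounds or FitBounds.bi_defaults()
    if bounds.model != "bi":
        raise ValidationError("bi fit requires bi bounds")
    signals, bv = _check_signal_matrix(signals, b, min_unique_b=5)
    xs, rms, conv = _fit_curves(signals, bv, bounds)
    params = BiParams(S0=xs[:, 0], D=xs[:, 1], Dstar=xs[:, 2], f=xs[:, 3])
    return FitReport(
        params=params, residual_rms=rms, converged=conv, n_params=4,
        bounds=bounds, model="bi",
    )


def fit_tri_lsq(signals, b, bounds: Optional[FitBounds] = None) -> FitReport:
    """Voxel-wise bounded least-squares fit of the tri-exponential model.

    The solve runs in the primed parameterisation; results are converted to
    normalised fractions, and the summed perfusion fraction f1+2 appears in
    the report's maps.
    """
    bounds = bounds or FitBounds.tri_defaults()
    if bounds.model != "tri":
        raise ValidationError("tri fit requires tri bounds")
    signals, bv = _check_signal_matrix(signals, b, min_unique_b=7)
    xs, rms, conv = _fit_curves(signals, bv, bounds)
    prime = TriParamsPrime(
        f0p=xs[:, 0], f1p=xs[:, 1], f2p=xs[:, 2],
        D=xs[:, 3], D1star=xs[:, 4], D2star=xs[:, 5],
    )
    params = prime.to_triparams()
    n_violations = int(np.sum(xs[:, 4] > xs[:, 5]))
    return FitReport(
        params=params, residual_rms=rms, converged=conv, n_params=6,
        bounds=bounds, model="tri", ordering_violations=n_violations,
    )


def fit_roi(signals, mask, b, model: str, bounds: Optional[FitBounds] = None) -> FitReport:
    """ROI-wise fit: average masked voxel signals per b-value, fit once.

    Averaging raises the effective SNR; the single resulting parameter set is
    reported together with the adjusted R² of the fit, the goodness-of-fit
    statistic used to compare the bi- and tri-exponential models.
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    if mask is None:
        mask = np.ones(signals.shape[0], dtype=bool)
    mask = np.asarray(mask, dtype=bool).ravel()
    if mask.size != signals.shape[0]:
        raise ValidationError("mask length does not match signal rows")
    if not mask.any():
        raise ValidationError("empty ROI mask")
    mean_curve = signals[mask].mean(axis=0, keepdims=True)
    if model == "bi":
        report = fit_bi_lsq(mean_curve, b, bounds)
        fitted = bi_signal(
            BiParams(*(np.asarray(report.maps()[k])[0] for k in _BI_ORDER)), b
        )
    elif model == "tri":
        report = fit_tri_lsq(mean_curve, b, bounds)
        m = report.maps()
        fitted = tri_signal(
            TriParams(
                S0=np.asarray(m["S0"])[0], D=np.asarray(m["D"])[0],
                D1star=np.asarray(m["D1star"])[0], D2star=np.asarray(m["D2star"])[0],
                f1=np.asarray(m["f1"])[0], f2=np.asarray(m["f2"])[0],
            ),
            b,
        )
    else:
        raise ValidationError("model must be 'bi' or 'tri'")
    adj = adjusted_r2(mean_curve.ravel(), np.asarray(fitted).ravel(), report.n_params)
    return FitReport(
        params=report.params, residual_rms=report.residual_rms,
        converged=report.converged, n_params=report.n_params,
        bounds=report.bounds, model=model, adjusted_r2=adj,
        ordering_violations=report.ordering_violations,
    )
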