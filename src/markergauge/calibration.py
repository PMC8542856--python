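"""Calibrating the marker identity -> dDDH relationship and inverting it
at the 70% species boundary.

The working model is the three-parameter exponential trend

    dDDH = a * exp(b * identity) + c        ("exp3p")

fitted by nonlinear least squares with a log-linear initialization and a
small multi-start over the offset parameter. The marker species threshold
is the closed-form inverse at a target dDDH (70% by default):

    T = ln((target - c) / a) / b.

A plain OLS linear model is available for identity-vs-identity comparisons
(e.g. complete gene vs trimmed window), where the relation is linear.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Literal, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from .identity import PercentMatrix

Model = Literal["exp3p", "linear"]


class CalibrationError(RuntimeError):
    pass


@dataclass
class CalibrationFit:
    """A fitted identity->dDDH curve with its inverse."""

    model: Model
    a: float          # exp3p amplitude, or OLS slope for model="linear"
    b: float          # exp3p rate, or OLS intercept for model="linear"
    c: float          # exp3p offset (0 for linear)
    r_squared: float
    n_points: int
    residual_sd: float
    x_range: Tuple[float, float]
    y_range: Tuple[float, float]

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, float)
        if self.model == "exp3p":
            return self.a * np.exp(self.b * x) + self.c
        return self.a * x + self.b

    def invert(self, target: float) -> float:
        return invert_threshold(self, target)

    @property
    def threshold_at(self) -> Dict[float, float]:
        """Inverse evaluated at the conventional 70% dDDH boundary."""
        try:
            return {70.0: self.invert(70.0)}
        except CalibrationError:
            return {}

    def report(self) -> str:
        lines = [f"model: {self.model}", f"n_points: {self.n_points}"]
        if self.model == "exp3p":
            lines += [f"a: {self.a:.6g}", f"b: {self.b:.6g}", f"c: {self.c:.6g}"]
        else:
            lines += [f"slope: {self.a:.6g}", f"intercept: {self.b:.6g}"]
        lines.append(f"r_squared: {self.r_squared:.4f}")
        lines.append(f"residual_sd: {self.residual_sd:.3f}")
        for tgt, thr in self.threshold_at.items():
            lines.append(f"identity threshold at dDDH {tgt:g}%: {thr:.1f}%")
        return "\n".join(lines)


def _exp3p(x, a, b, c):
    return a * np.exp(b * x) + c


def fit_exp3p(points: Sequence[Tuple[float, float]]) -> CalibrationFit:
    """Nonlinear least squares for y = a*exp(b*x) + c.

    Initialization: take c0 slightly below min(y), then log-linear
    regression of log(y - c0) on x for (a0, b0); the fit is restarted from
    five perturbations of c0 and the lowest-SSE solution is kept.
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 4:
        raise ValueError("need at least 4 (identity, ddh) points")
    x, y = pts[:, 0], pts[:, 1]
    if np.any((x <= 0) | (x > 100)):
        raise ValueError("identities must lie in (0, 100]")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise CalibrationError("degenerate input: y is constant (a ~ 0)")
    yspread = float(y.max() - y.min())
    best = None
    for frac in (1e-6, 0.01, 0.05, 0.2, 1.0):
        c0 = float(y.min()) - frac * yspread
        with np.errstate(invalid="ignore"):
            logy = np.log(y - c0)
        if not np.all(np.isfinite(logy)):
            continue
        slope, intercept, *_ = stats.linregress(x, logy)
        a0, b0 = float(np.exp(intercept)), float(slope)
        try:
            popt, _ = optimize.curve_fit(_exp3p, x, y, p0=(a0, b0, c0), maxfev=20000)
        except (RuntimeError, optimize.OptimizeWarning):
            continue
        sse = float(np.sum((_exp3p(x, *popt) - y) ** 2))
        if np.isfinite(sse) and (best is None or sse < best[0]):
            best = (sse, popt)
    if best is None:
        raise CalibrationError(
            "exp3p fit failed to converge from all starts; consider model='linear'")
    sse, (a, b, c) = best
    if b <= 0:
        warnings.warn("non-increasing calibration: fitted b <= 0", stacklevel=2)
    dof = max(len(x) - 3, 1)
    return CalibrationFit(
        model="exp3p", a=float(a), b=float(b), c=float(c),
        r_squared=1.0 - sse / sst, n_points=len(x),
        residual_sd=float(np.sqrt(sse / dof)),
        x_range=(float(x.min()), float(x.max())),
        y_range=(float(y.min()), float(y.max())),
    )


def fit_linear(points: Sequence[Tuple[float, float]]) -> CalibrationFit:
    """OLS line through (identity, ddh) points, same container as exp3p."""
    pts = np.asarray(points, float)
    if len(pts) < 3:
        raise ValueError("need at least 3 points")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    res = stats.linregress(x, y)
    pred = res.slope * x + res.intercept
    sse = float(np.sum((y - pred) ** 2))
    dof = max(len(x) - 2, 1)
    return CalibrationFit(
        model="linear", a=float(res.slope), b=float(res.intercept), c=0.0,
        r_squared=float(res.rvalue) ** 2, n_points=len(x),
        residual_sd=float(np.sqrt(sse / dof)),
        x_range=(float(x.min()), float(x.max())),
        y_range=(float(y.min()), float(y.max())),
    )


def invert_threshold(fit: CalibrationFit, target_ddh: float = 70.0) -> float:
    """Marker identity at which the fitted curve crosses `target_ddh`.

    Closed form; warns when the target lies outside the fitted y-range
    (extrapolation). Full precision is returned; round to 1 decimal for
    reporting.
    """
    if not (fit.y_range[0] <= target_ddh <= fit.y_range[1]):
        warnings.warn(
            f"target dDDH {target_ddh} outside fitted range {fit.y_range}; "
            "extrapolating", stacklevel=2)
    if fit.model == "linear":
        if fit.a == 0:
            raise CalibrationError("flat linear fit has no inverse")
        return (target_ddh - fit.b) / fit.a
    if target_ddh <= fit.c:
        raise CalibrationError(
            f"target dDDH {target_ddh} is at or below the curve asymptote c={fit.c:.3g}")
    if fit.a <= 0 or fit.b == 0:
        raise CalibrationError("fitted exp3p curve is not invertible (a <= 0 or b = 0)")
    return float(np.log((target_ddh - fit.c) / fit.a) / fit.b)


def calibrate(identity_matrix: PercentMatrix, ddh_matrix: PercentMatrix,
              model: Model = "exp3p") -> CalibrationFit:
    """Fit the identity->dDDH curve from two matrices over one strain panel.

    Each unordered strain pair contributes one (identity, dDDH) point;
    n_points = n(n-1)/2.
    """
    if set(identity_matrix.strain_ids) != set(ddh_matrix.strain_ids):
        raise ValueError("identity and dDDH matrices cover different strains")
    ddh = ddh_matrix.reorder(identity_matrix.strain_ids)
    points = [(v, ddh.get(a, b)) for a, b, v in identity_matrix.off_diagonal_pairs()]
    if len(points) < 4:
        raise ValueError(f"insufficient points for calibration: {len(points)}")
    return fit_exp3p(points) if model == "exp3p" else fit_linear(points)
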