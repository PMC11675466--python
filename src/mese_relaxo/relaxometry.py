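"""T2 decay model, fit criterion, echo exclusion and water-state labels.

The unit of inversion is a single decay curve: the signal of one voxel (or
the mean over one tissue structure) at each echo time. A curve is modelled
as a discrete sum of e exponential components,

    S(theta, t) = sum_e A_e * exp(-t / T2_e),

and fitted by minimising the weighted least-squares criterion

    C(theta) = 1/(2 sigma^2) * sum_t (y_t - S(theta, t))^2.

With e = 3 the components, sorted by ascending T2, are conventionally read
as bound water (T21), semi-bound water (T22) and free water (T23), with
amplitudes A01/A02/A03 giving the relative content of each pool.

Echo exclusion removes isolated anomalous echoes (interference spikes,
reconstruction glitches) before the final fit, using robust standardized
residuals against a provisional fit; on real fruit data this reliably
raises R^2 and lowers RMSE.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "DecayCurve",
    "ExpParams",
    "FitResult",
    "ExclusionResult",
    "WATER_STATE_LABELS",
    "objective_cls",
    "fit_metrics",
    "classify_components",
    "exclude_echoes",
    "loglinear_mono_fit",
    "provisional_fit",
]

#: Conventional water-state names for the tri-exponential model, ascending T2.
WATER_STATE_LABELS = {1: ("T2",), 2: ("T21", "T22"), 3: ("T21", "T22", "T23"), 4: ("T21", "T22", "T23", "T24")}


@dataclass(frozen=True)
class DecayCurve:
    """One (TE, signal) series with an optional noise scale sigma."""

    te: np.ndarray
    y: np.ndarray
    sigma: float = 1.0

    def __post_init__(self) -> None:
        te = np.asarray(self.te, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if te.ndim != 1 or y.ndim != 1 or te.size != y.size:
            raise ValueError("te and y must be 1-D and the same length")
        if te.size == 0:
            raise ValueError("curve must have at least one echo")
        if np.any(np.diff(te) <= 0):
            raise ValueError("te must be strictly increasing")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        object.__setattr__(self, "te", te)
        object.__setattr__(self, "y", y)

    @property
    def n_echo(self) -> int:
        return int(self.te.size)

    def subset(self, keep: np.ndarray) -> "DecayCurve":
        """Curve restricted to the echoes flagged True in ``keep``."""
        keep = np.asarray(keep, dtype=bool)
        return DecayCurve(self.te[keep], self.y[keep], self.sigma)


@dataclass(frozen=True)
class ExpParams:
    """e exponential components, each an (amplitude, T2 ms) pair."""

    components: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        comps = tuple((float(a), float(t2)) for a, t2 in self.components)
        if not 1 <= len(comps) <= 4:
            raise ValueError("supported component counts are 1..4")
        for a, t2 in comps:
            if a < 0:
                raise ValueError("amplitudes must be nonnegative")
            if t2 <= 0:
                raise ValueError("relaxation times must be positive")
        object.__setattr__(self, "components", comps)

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([a for a, _ in self.components])

    @property
    def t2s(self) -> np.ndarray:
        return np.array([t2 for _, t2 in self.components])

    def sorted_by_t2(self) -> "ExpParams":
        return ExpParams(tuple(sorted(self.components, key=lambda c: c[1])))

    def predict(self, te: np.ndarray) -> np.ndarray:
        te = np.asarray(te, dtype=float)
        return np.exp(-te[:, None] / self.t2s[None, :]) @ self.amplitudes

    def as_vector(self) -> np.ndarray:
        """Flat parameter vector [A1, T2_1, A2, T2_2, ...]."""
        return np.array([v for pair in self.components for v in pair])

    @classmethod
    def from_vector(cls, vec: np.ndarray) -> "ExpParams":
        vec = np.asarray(vec, dtype=float)
        if vec.size % 2 != 0:
            raise ValueError("parameter vector length must be even")
        return cls(tuple((vec[2 * k], vec[2 * k + 1]) for k in range(vec.size // 2)))


@dataclass(frozen=True)
class FitResult:
    """Outcome of one curve inversion."""

    theta: ExpParams
    cls: float
    r2: float
    rmse: float
    excluded: tuple[int, ...] = ()
    n_iter: int = 0
    converged: bool = True

    def to_dict(self) -> dict:
        return {
            "components": [{"amplitude": a, "t2_ms": t2} for a, t2 in self.theta.components],
            "cls": self.cls,
            "r2": self.r2,
            "rmse": self.rmse,
            "excluded": list(self.excluded),
            "n_iter": self.n_iter,
            "converged": self.converged,
        }


def objective_cls(theta: ExpParams, curve: DecayCurve) -> float:
    """Weighted least-squares criterion C = sum (y - S)^2 / (2 sigma^2)."""
    resid = curve.y - theta.predict(curve.te)
    return float(np.sum(resid**2) / (2.0 * curve.sigma**2))


def fit_metrics(
    curve: DecayCurve, theta: ExpParams, normalize: bool = True
) -> tuple[float, float]:
    """Coefficient of determination and RMSE of a fitted model.

    With ``normalize=True`` (the default) both the data and the model are
    divided by the first-echo signal so that RMSE lands on the ~0-1 scale
    conventional for decay-curve goodness of fit; R^2 is scale-invariant
    either way. A constant curve (zero total variance) has no defined R^2
    and is reported as NaN.
    """
    y = curve.y.astype(float)
    yhat = theta.predict(curve.te)
    if normalize:
        scale = y[0] if y[0] != 0 else 1.0
        y = y / scale
        yhat = yhat / scale
    resid = y - yhat
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = math.nan if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    rmse = math.sqrt(ss_res / y.size)
    return r2, rmse


def classify_components(theta: ExpParams) -> dict[str, dict[str, float]]:
    """Label components by water state (ascending T2) with proportions.

    Returns ``{label: {"t2_ms", "amplitude", "proportion"}}`` where for a
    tri-exponential model the labels are T21 (bound), T22 (semi-bound) and
    T23 (free water) and the proportions A0e = A_e / sum(A) sum to one.
    """
    st = theta.sorted_by_t2()
    total = float(st.amplitudes.sum())
    if total == 0:
        raise ValueError("total amplitude is zero; proportions undefined")
    labels = WATER_STATE_LABELS[st.n_components]
    return {
        lab: {
            "t2_ms": t2,
            "amplitude": a,
            "proportion": a / total,
        }
        for lab, (a, t2) in zip(labels, st.components)
    }


# ---------------------------------------------------------------------------
# Provisional fits (preprocessing / oracle-grade helpers, not the inversion engine)


def loglinear_mono_fit(curve: DecayCurve) -> ExpParams:
    """Mono-exponential fit by linear regression on ln y.

    Exact on noiseless single-exponential data with positive signal; used
    for initialisation and as a cheap provisional model.
    """
    pos = curve.y > 0
    if pos.sum() < 2:
        raise ValueError("need at least two positive samples for a log-linear fit")
    te, y = curve.te[pos], curve.y[pos]
    slope, intercept = np.polyfit(te, np.log(y), 1)
    if slope >= 0:
        # Non-decaying data: fall back to a long T2.
        slope = -1.0 / (10.0 * te[-1])
    return ExpParams(((math.exp(intercept), -1.0 / slope),))


def provisional_fit(curve: DecayCurve, e: int, robust: bool = False) -> ExpParams:
    """Fast bounded least-squares multi-exponential fit.

    This is deliberately plain curve fitting (trust-region least squares
    from a log-linear / geometric initialisation); it serves as the
    provisional model for echo exclusion, not as the inversion engine.
    With ``robust=True`` a soft-L1 refit (scaled by the robust residual
    spread of the plain fit) downweights gross outliers so they cannot
    drag the provisional model toward themselves.
    """
    if e < 1 or e > 4:
        raise ValueError("e must be in 1..4")
    y0 = max(float(curve.y[0]), 1e-12)
    if e == 1:
        init = loglinear_mono_fit(curve).as_vector()
    else:
        t2_init = np.geomspace(curve.te[0], 0.8 * curve.te[-1], e)
        init = np.empty(2 * e)
        init[0::2] = y0 / e
        init[1::2] = t2_init
    lower = np.tile([0.0, 1e-3], e)
    upper = np.tile([10.0 * y0 + 1e-9, 50.0 * curve.te[-1]], e)
    init = np.clip(init, lower + 1e-9, upper - 1e-9)

    def resid(vec: np.ndarray) -> np.ndarray:
        amps, t2s = vec[0::2], vec[1::2]
        model = np.exp(-curve.te[:, None] / t2s[None, :]) @ amps
        return model - curve.y

    sol = least_squares(resid, init, bounds=(lower, upper), method="trf")
    if robust:
        r = resid(sol.x)
        scale = 1.4826 * float(np.median(np.abs(r - np.median(r))))
        scale = max(scale, 1e-6 * y0)
        sol = least_squares(
            resid, sol.x, bounds=(lower, upper), method="trf",
            loss="soft_l1", f_scale=scale,
        )
    return ExpParams.from_vector(sol.x).sorted_by_t2()


@dataclass(frozen=True)
class ExclusionResult:
    curve: DecayCurve
    excluded: tuple[int, ...]
    refused: bool = False
    theta: ExpParams | None = None


def exclude_echoes(
    curve: DecayCurve,
    e: int = 1,
    threshold_k: float = 3.0,
    max_fraction: float = 0.2,
    fitter: Callable[[DecayCurve, int], ExpParams] | None = None,
) -> ExclusionResult:
    """Remove anomalous echoes by robust standardized residuals.

    A provisional e-component model is fitted; echoes whose residual
    exceeds ``threshold_k`` times the robust residual scale (1.4826 x MAD)
    are removed, worst first, capped at ``max_fraction`` of the echoes and
    never leaving fewer than 2e + 2 echoes.  The reduced curve is refitted
    once and returned alongside the removed index set.  If the curve is too
    short to allow any exclusion the original curve is returned with
    ``refused=True``.
    """
    min_remaining = 2 * e + 2
    if curve.n_echo < min_remaining:
        return ExclusionResult(curve, (), refused=True)
    fit = fitter or (lambda c, n: provisional_fit(c, n, robust=True))
    theta0 = fit(curve, e)
    resid = curve.y - theta0.predict(curve.te)
    mad = np.median(np.abs(resid - np.median(resid)))
    scale = 1.4826 * mad
    if scale <= 0:
        scale = float(np.std(resid)) or np.finfo(float).tiny
    standardized = np.abs(resid) / scale
    candidates = np.argsort(standardized)[::-1]
    max_remove = min(
        int(max_fraction * curve.n_echo),
        curve.n_echo - min_remaining,
    )
    removed: list[int] = []
    for idx in candidates:
        if len(removed) >= max_remove:
            break
        if standardized[idx] > threshold_k:
            removed.append(int(idx))
    if not removed:
        return ExclusionResult(curve, (), theta=theta0)
    keep = np.ones(curve.n_echo, dtype=bool)
    keep[removed] = False
    reduced = curve.subset(keep)
    theta1 = fit(reduced, e)
    return ExclusionResult(reduced, tuple(sorted(removed)), theta=theta1)
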