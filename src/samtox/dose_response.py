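"""Five-parameter log-logistic (LL.5) concentration-response curves.

The LL.5 model expresses the surviving fraction ``N`` at toxicant
concentration ``C`` as

    N(C) = c + (d - c) / (1 + exp(b * (ln C - ln e)))**f

with shape ``b > 0``, lower/upper limits ``0 <= c < d <= 1``, scale
``e > 0`` (same units as the concentration) and asymmetry ``f > 0``
(``f = 1`` recovers the symmetric four-parameter log-logistic).

The module also provides the two pre-processing steps used before fitting
survival data from bioassays: the Williams transformation (monotonising
pool-adjacent-violators averaging, which irons out apparent hormesis) and
log-scale linear interpolation to a fixed number of smoothing points, plus
closed-form inversion to lethal concentrations LCx.

Mortality is always control-normalised (Abbott-style): the effect at
concentration C is ``1 - N(C)/d``, i.e. relative to the fitted control
response ``d``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import isotonic_regression, least_squares

from .errors import (
    DegenerateCurveError,
    DegenerateDataError,
    FitFailureError,
    InputError,
    OutOfRangeError,
    ParameterDomainError,
)

__all__ = [
    "LL5Params",
    "DoseResponseDataset",
    "ll5_survival",
    "effect_mortality",
    "lc",
    "williams_transform",
    "interpolate_log",
    "fit_ll5",
    "fit_dose_response",
]


@dataclass(frozen=True)
class LL5Params:
    """Parameters of a five-parameter log-logistic curve.

    Attributes
    ----------
    b : float
        Shape (slope) parameter, > 0.
    c : float
        Lower survival limit, fraction in [0, 1).
    d : float
        Upper survival limit (control response), fraction in (0, 1].
    e : float
        Scale parameter in concentration units, > 0.
    f : float
        Asymmetry parameter, > 0; f = 1 gives a symmetric curve.
    """

    b: float
    c: float
    d: float
    e: float
    f: float

    def __post_init__(self):
        if not (self.b > 0 and self.e > 0 and self.f > 0):
            raise ParameterDomainError(
                f"b, e, f must be > 0 (got b={self.b}, e={self.e}, f={self.f})"
            )
        if not (0.0 <= self.c < self.d <= 1.0):
            raise ParameterDomainError(
                f"limits must satisfy 0 <= c < d <= 1 (got c={self.c}, d={self.d})"
            )


@dataclass(frozen=True)
class DoseResponseDataset:
    """Observed survival of one experimental arm.

    ``concentrations`` are strictly increasing and non-negative;
    ``survival`` holds the surviving fraction at each concentration;
    ``control_survival`` is the surviving fraction at concentration 0.
    ``weights`` (optional) carry the organism counts behind each fraction,
    used by the Williams transformation and as fit weights.
    """

    concentrations: np.ndarray
    survival: np.ndarray
    control_survival: float
    weights: np.ndarray | None = None

    def __post_init__(self):
        conc = np.asarray(self.concentrations, dtype=float)
        surv = np.asarray(self.survival, dtype=float)
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "survival", surv)
        if conc.ndim != 1 or surv.shape != conc.shape:
            raise InputError("concentrations and survival must be 1-d and equal length")
        if conc.size < 3:
            raise InputError("need at least 3 concentrations besides the control")
        if np.any(conc < 0):
            raise InputError("concentrations must be non-negative")
        if np.any(np.diff(conc) <= 0):
            raise InputError("concentrations must be strictly increasing and unique")
        if np.any((surv < 0) | (surv > 1)):
            raise InputError("survival fractions must lie in [0, 1]")
        if not 0.0 <= self.control_survival <= 1.0:
            raise InputError("control survival must lie in [0, 1]")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            object.__setattr__(self, "weights", w)
            if w.shape != conc.shape or np.any(w <= 0):
                raise InputError("weights must be positive, one per concentration")

    @classmethod
    def from_counts(cls, concentrations, n_survived, n_total, control_survival):
        """Build a dataset from survived/total organism counts."""
        n_survived = np.asarray(n_survived, dtype=float)
        n_total = np.asarray(n_total, dtype=float)
        if np.any(n_total <= 0) or np.any(n_survived < 0) or np.any(n_survived > n_total):
            raise InputError("counts must satisfy 0 <= n_survived <= n_total, n_total > 0")
        return cls(
            concentrations=np.asarray(concentrations, dtype=float),
            survival=n_survived / n_total,
            control_survival=float(control_survival),
            weights=n_total,
        )


def _log_bracket(params: LL5Params, C):
    """log(1 + exp(b (ln C - ln e))), overflow-safe; C > 0 elementwise."""
    z = params.b * (np.log(C) - np.log(params.e))
    return np.logaddexp(0.0, z)


def ll5_survival(params: LL5Params, C):
    """Surviving fraction N(C) of the LL.5 curve; C = 0 returns d.

    Accepts scalars or arrays; non-increasing in C, bounded by [c, d].
    """
    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise ParameterDomainError("concentrations must be >= 0")
    out = np.full(C.shape, params.d, dtype=float)
    pos = C > 0
    if np.any(pos):
        # (d-c)/(1+t)^f computed as (d-c)*exp(-f*log(1+t)) to avoid overflow
        out[pos] = params.c + (params.d - params.c) * np.exp(
            -params.f * _log_bracket(params, C[pos])
        )
    return float(out) if out.ndim == 0 else out


def effect_mortality(params: LL5Params, C):
    """Control-normalised mortality 1 - N(C)/d, in [0, 1]; 0 at C = 0."""
    if params.d <= 0:
        raise DegenerateCurveError("upper limit d must be > 0 for a mortality scale")
    m = 1.0 - np.asarray(ll5_survival(params, C)) / params.d
    m = np.clip(m, 0.0, 1.0)
    return float(m) if m.ndim == 0 else m


def lc(params: LL5Params, x: float) -> float:
    """Lethal concentration LCx: the concentration with x% control-normalised
    mortality, by closed-form inversion of the LL.5 curve.

    ``x`` is an effect percentage in (0, 100), attainable only while
    ``x/100 < 1 - c/d`` (the asymptotic maximum effect).
    """
    if not 0.0 < x < 100.0:
        raise OutOfRangeError(f"effect percent must lie in (0, 100), got {x}")
    m = x / 100.0
    b, c, d, e, f = params.b, params.c, params.d, params.e, params.f
    target = d * (1.0 - m)  # absolute survival at LCx
    if target <= c:
        raise OutOfRangeError(
            f"effect {x}% unattainable: maximum effect is {100 * (1 - c / d):.4g}%"
        )
    A = ((d - c) / (target - c)) ** (1.0 / f) - 1.0
    if A <= 0.0:
        raise OutOfRangeError(f"effect {x}% unattainable on this curve")
    return float(e * A ** (1.0 / b))


def williams_transform(survival: Sequence[float], weights: Sequence[float] | None = None):
    """Monotonise a survival sequence (ordered by increasing concentration).

    Pool-adjacent-violators averaging in the non-increasing direction:
    runs that violate the expected downward trend are replaced by their
    (weighted) mean, preserving the overall weighted mean. Already
    monotone input is returned unchanged.
    """
    y = np.asarray(survival, dtype=float)
    if y.size == 0:
        raise InputError("cannot transform an empty survival sequence")
    w = None if weights is None else np.asarray(weights, dtype=float)
    # non-increasing isotonic fit == negated non-decreasing fit
    res = isotonic_regression(-y, weights=w, increasing=True)
    return -res.x


def interpolate_log(data: DoseResponseDataset, k: int = 10) -> DoseResponseDataset:
    """Resample an arm to ``k`` points equidistant in log-concentration.

    Survival is interpolated linearly between neighbouring observations in
    log-concentration space, so endpoint survivals are reproduced exactly.
    The control (C = 0) is passed through unchanged and never interpolated.
    """
    if k < 2:
        raise InputError("need k >= 2 interpolation points")
    pos = data.concentrations > 0
    conc = data.concentrations[pos]
    surv = data.survival[pos]
    if conc.size < 2:
        raise InputError("need at least 2 nonzero concentrations to interpolate")
    logc = np.log(conc)
    grid = np.linspace(logc[0], logc[-1], k)
    return DoseResponseDataset(
        concentrations=np.exp(grid),
        survival=np.interp(grid, logc, surv),
        control_survival=data.control_survival,
    )


# multi-start initialisation grids (shape and asymmetry), per-curve scale from data
_B_STARTS = (0.5, 1.0, 2.0, 4.0)
_F_STARTS = (0.5, 1.0, 2.0)
_LOG_LB, _LOG_UB = np.log(1e-6), np.log(1e6)


def fit_ll5(
    data: DoseResponseDataset,
    fix_c: bool = True,
    fix_d: bool = True,
    x0: LL5Params | None = None,
) -> LL5Params:
    """Least-squares fit of the LL.5 curve to one arm.

    By default the lower limit ``c`` is fixed to 0 and the upper limit ``d``
    to the control survival; ``b``, ``e`` and ``f`` are optimised in log
    space under a multi-start scheme (scale ``e`` started at the observed
    concentration nearest 50% effect; shape/asymmetry on a small grid),
    keeping the best residual sum of squares. ``x0`` overrides the grid
    with a single user-supplied start.
    """
    conc = data.concentrations
    surv = data.survival
    ctrl = data.control_survival
    vals = np.append(surv, ctrl)
    if np.ptp(vals) < 1e-8:
        raise DegenerateDataError("no concentration effect: all survivals equal the control")

    d_fixed = ctrl if fix_d else None
    c_fixed = 0.0 if fix_c else None
    if fix_d and ctrl <= 0:
        raise DegenerateDataError("control survival is 0; cannot anchor the upper limit")
    # plain (unweighted) nonlinear least squares on the survival scale,
    # as in classic dose-response fitting; counts still matter for the
    # Williams transformation upstream
    w = np.ones_like(surv)

    pos = conc > 0
    if pos.sum() < 3:
        raise InputError("need at least 3 nonzero concentrations to fit")
    cfit, sfit, wfit = conc[pos], surv[pos], w[pos]

    def unpack(theta):
        i = 0
        b = np.exp(theta[i]); i += 1
        c = c_fixed if fix_c else theta[i]
        i += 0 if fix_c else 1
        d = d_fixed if fix_d else theta[i]
        i += 0 if fix_d else 1
        e = np.exp(theta[i]); i += 1
        f = np.exp(theta[i])
        return b, c, d, e, f

    def residuals(theta):
        b, c, d, e, f = unpack(theta)
        pred = c + (d - c) * np.exp(-f * np.logaddexp(0.0, b * (np.log(cfit) - np.log(e))))
        return wfit * (pred - sfit)

    def pack(b, c, d, e, f):
        theta = [np.log(b)]
        if not fix_c:
            theta.append(c)
        if not fix_d:
            theta.append(d)
        theta += [np.log(e), np.log(f)]
        return np.array(theta)

    lo = [_LOG_LB] + ([0.0] if not fix_c else []) + ([1e-6] if not fix_d else []) + [_LOG_LB, _LOG_LB]
    hi = [_LOG_UB] + ([1.0 - 1e-6] if not fix_c else []) + ([1.0] if not fix_d else []) + [_LOG_UB, _LOG_UB]

    d_guess = d_fixed if fix_d else max(ctrl, float(np.max(vals)), 1e-3)
    half = 0.5 * d_guess
    e_guess = float(cfit[np.argmin(np.abs(sfit - half))])
    e_guess = min(max(e_guess, 1e-6), 1e6)

    if x0 is not None:
        starts = [pack(x0.b, x0.c, x0.d, x0.e, x0.f)]
    else:
        starts = [
            pack(b0, 0.25 if not fix_c else 0.0, d_guess, e_guess, f0)
            for b0 in _B_STARTS
            for f0 in _F_STARTS
        ]

    best = None
    diagnostics = []
    for theta0 in starts:
        theta0 = np.clip(theta0, lo, hi)
        try:
            res = least_squares(
                residuals, theta0, bounds=(lo, hi), method="trf",
                xtol=1e-10, ftol=1e-10, gtol=1e-10,
            )
        except Exception as err:  # pragma: no cover - defensive
            diagnostics.append(str(err))
            continue
        if not np.all(np.isfinite(res.x)):
            diagnostics.append("non-finite solution")
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitFailureError("LL.5 fit failed from every start", diagnostics)
    b, c, d, e, f = unpack(best.x)
    return LL5Params(b=float(b), c=float(c), d=float(d), e=float(e), f=float(f))


def fit_dose_response(
    data: DoseResponseDataset,
    fix_c: bool = True,
    fix_d: bool = True,
    williams: bool = True,
    interpolate: int | None = 10,
) -> LL5Params:
    """Standard fitting pipeline: Williams transformation, log-scale
    interpolation to ``interpolate`` smoothing points (skipped when None),
    then the LL.5 least-squares fit."""
    if williams:
        data = replace(
            data,
            survival=williams_transform(data.survival, data.weights),
        )
    if interpolate is not None:
        data = interpolate_log(data, interpolate)
    return fit_ll5(data, fix_c=fix_c, fix_d=fix_d)


def rss(params: LL5Params, data: DoseResponseDataset) -> float:
    """Residual sum of squares of a fitted curve on an arm's nonzero
    concentrations (unweighted)."""
    pos = data.concentrations > 0
    pred = ll5_survival(params, data.concentrations[pos])
    return float(np.sum((pred - data.survival[pos]) ** 2))
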