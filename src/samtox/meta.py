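"""Meta-analysis layer: curve normalisation and averaging, observed and
predicted LCx-shift tables, shape-parameter calibration and goodness of
fit, and the overall shift-vs-environmental-stress prediction table.

A *study pair* is one published experiment digitised twice: the toxicant
concentration-response without (``tox_arm``) and with (``combined_arm``)
an additional environmental stressor, plus the mortality the environmental
stressor causes on its own (``m_env``, Abbott-corrected against the clean
control).

Shift conventions. The observed sensitivity shift at effect level x is
LCx / LCx*, where LCx comes from the toxicant-alone fit and LCx* from the
combined-arm fit, each taken at x% mortality relative to the curve's OWN
fitted control (the combined arm's upper limit is its environmentally
stressed control). Model-predicted shifts use the same Abbott-corrected
scale, so effect addition predicts exactly no shift and every
environmental stress level in [0, 1) has a defined LCx*.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from . import baselines
from .dose_response import (
    DoseResponseDataset,
    LL5Params,
    fit_dose_response,
    lc,
    ll5_survival,
)
from .errors import (
    CalibrationError,
    EffectLevelUnreachableError,
    InputError,
    OutOfRangeError,
)
from .sam import StressCapacityDistribution, sam_lcx_shift

logger = logging.getLogger(__name__)

__all__ = [
    "StudyPair",
    "FittedPair",
    "ShiftRecord",
    "NormalizedCurve",
    "AverageCurve",
    "CalibrationResult",
    "compute_env_mortality",
    "normalize_curve",
    "average_curves",
    "fit_study_pair",
    "observed_shift",
    "observed_shifts",
    "calibrate_shape",
    "predicted_shifts_refit",
    "model_r2",
    "overall_prediction",
]

DEFAULT_X_LEVELS = (10.0, 50.0)
DEFAULT_ENV_GRID = (0.01, 0.02, 0.05, 0.10, 0.15, 0.20, 0.30, 0.40, 0.50, 0.60, 0.70, 0.80, 0.90)


@dataclass(frozen=True)
class StudyPair:
    """One experiment with and without the environmental stressor."""

    study_id: str
    tox_arm: DoseResponseDataset
    combined_arm: DoseResponseDataset
    m_env: float

    def __post_init__(self):
        if not 0.0 <= self.m_env < 1.0:
            raise InputError(f"environmental mortality must lie in [0, 1), got {self.m_env}")


@dataclass(frozen=True)
class FittedPair:
    """LL.5 fits of both arms of a study pair."""

    study_id: str
    tox_params: LL5Params
    combined_params: LL5Params
    m_env: float


@dataclass(frozen=True)
class ShiftRecord:
    """LCx without stress, LCx* with stress, and their ratio."""

    study_id: str
    x: float
    lcx: float
    lcx_star: float
    shift: float
    model: str = "observed"

    def __post_init__(self):
        if not (self.lcx > 0 and self.lcx_star > 0 and self.shift > 0):
            raise InputError("lethal concentrations and shift must be positive")


@dataclass(frozen=True)
class NormalizedCurve:
    """An LL.5 curve re-expressed on the normalised concentration axis.

    The axis is affine in log concentration: log LC1 maps to 0 and
    log LC99 to 1, so by construction the curve shows 1% effect at 0 and
    99% at 1. Survival here is control-normalised (1 at zero effect).
    """

    params: LL5Params
    log_lc1: float
    log_lc99: float

    def concentration(self, u):
        """Raw concentration corresponding to normalised position u."""
        u = np.asarray(u, dtype=float)
        c = np.exp(self.log_lc1 + u * (self.log_lc99 - self.log_lc1))
        return float(c) if c.ndim == 0 else c

    def survival(self, u):
        """Control-normalised survival at normalised position u."""
        s = np.asarray(ll5_survival(self.params, self.concentration(u))) / self.params.d
        return float(s) if s.ndim == 0 else s

    def mortality(self, u):
        m = 1.0 - np.asarray(self.survival(u))
        return float(m) if m.ndim == 0 else m


@dataclass(frozen=True)
class AverageCurve:
    """Median concentration-response across normalised curves.

    ``levels`` are the 10 equidistant normalised concentrations (endpoints
    included); ``median_survival``/``se_survival`` the pointwise median and
    standard error; the three LL5Params are fits to the median and the
    median ± SE bands, all on the normalised axis (the normalised
    coordinate is treated as the concentration of the fit).
    """

    levels: np.ndarray
    median_survival: np.ndarray
    se_survival: np.ndarray
    median_params: LL5Params
    upper_params: LL5Params
    lower_params: LL5Params


def compute_env_mortality(env_control_survival: float, control_survival: float) -> float:
    """Mortality caused by the environmental stressor alone, Abbott-
    corrected against the unstressed control and clamped to [0, 1]."""
    if env_control_survival is None:
        raise InputError("environmental-stress-only control survival is missing")
    if control_survival <= 0:
        raise InputError("unstressed control survival must be > 0")
    return float(np.clip(1.0 - env_control_survival / control_survival, 0.0, 1.0))


def normalize_curve(params: LL5Params) -> NormalizedCurve:
    """Map a fitted curve to the normalised [0, 1] axis spanning LC1–LC99
    in log concentration."""
    try:
        lc1 = lc(params, 1.0)
        lc99 = lc(params, 99.0)
    except OutOfRangeError as err:
        raise OutOfRangeError(f"curve cannot be normalised: {err}") from err
    return NormalizedCurve(params=params, log_lc1=math.log(lc1), log_lc99=math.log(lc99))


def average_curves(curves, n_levels: int = 10) -> AverageCurve:
    """Median (and SE) survival of normalised curves at ``n_levels``
    equidistant normalised concentrations, each refitted with LL.5.

    The level-0 point anchors the fitted upper limit (the fit's control);
    the remaining levels are the fit's concentrations.
    """
    curves = list(curves)
    if len(curves) < 2:
        raise InputError("need at least 2 curves to average")
    levels = np.linspace(0.0, 1.0, n_levels)
    surv = np.array([[c.survival(u) for u in levels] for c in curves])
    median = np.median(surv, axis=0)
    se = np.std(surv, axis=0, ddof=1) / math.sqrt(len(curves))

    def _fit(values):
        values = np.clip(values, 0.0, 1.0)
        data = DoseResponseDataset(
            concentrations=levels[1:],
            survival=values[1:],
            control_survival=float(values[0]),
        )
        return fit_dose_response(data, williams=True, interpolate=None)

    return AverageCurve(
        levels=levels,
        median_survival=median,
        se_survival=se,
        median_params=_fit(median),
        upper_params=_fit(median + se),
        lower_params=_fit(median - se),
    )


def fit_study_pair(
    pair: StudyPair,
    williams: bool = True,
    interpolate: int | None = 10,
) -> FittedPair:
    """Fit both arms of a study pair with the standard pipeline (lower
    limit fixed to 0, upper limit fixed to each arm's own control)."""
    return FittedPair(
        study_id=pair.study_id,
        tox_params=fit_dose_response(pair.tox_arm, williams=williams, interpolate=interpolate),
        combined_params=fit_dose_response(
            pair.combined_arm, williams=williams, interpolate=interpolate
        ),
        m_env=pair.m_env,
    )


def _observed_shift_from_fit(fitted: FittedPair, x: float) -> ShiftRecord:
    lcx = lc(fitted.tox_params, x)
    lcx_star = lc(fitted.combined_params, x)  # x% of the combined arm's own control
    return ShiftRecord(
        study_id=fitted.study_id, x=x, lcx=lcx, lcx_star=lcx_star, shift=lcx / lcx_star
    )


def observed_shift(
    pair: StudyPair,
    x: float,
    williams: bool = True,
    interpolate: int | None = 10,
) -> ShiftRecord:
    """Observed sensitivity shift LCx/LCx* of one study pair at effect
    level ``x`` percent (fits both arms; see module docstring for the
    effect-scale convention)."""
    return _observed_shift_from_fit(fit_study_pair(pair, williams, interpolate), x)


def observed_shifts(
    pairs,
    x_levels=DEFAULT_X_LEVELS,
    williams: bool = True,
    interpolate: int | None = 10,
):
    """Observed shifts for many pairs at several effect levels.

    Returns ``(records, fitted_pairs, flagged)``; studies whose combined
    arm cannot reach an effect level are flagged (study_id, x, reason) and
    excluded from the records rather than raising.
    """
    records, fitted_pairs, flagged = [], [], []
    for pair in pairs:
        fitted = fit_study_pair(pair, williams, interpolate)
        fitted_pairs.append(fitted)
        for x in x_levels:
            try:
                records.append(_observed_shift_from_fit(fitted, x))
            except (EffectLevelUnreachableError, OutOfRangeError) as err:
                logger.info("study %s excluded at LC%g: %s", pair.study_id, x, err)
                flagged.append((pair.study_id, x, str(err)))
    return records, fitted_pairs, flagged


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of the shape calibration."""

    shape: float
    objective: float
    n_records: int
    r2_by_level: dict = field(default_factory=dict)
    residuals: pd.DataFrame | None = None


def predicted_shifts_refit(
    dist: StressCapacityDistribution,
    fitted: FittedPair,
    design_concentrations,
    x_levels=DEFAULT_X_LEVELS,
    williams: bool = True,
    interpolate: int | None = 10,
):
    """SAM-predicted shifts read off a refitted predicted curve.

    Applies SAM to the fitted toxicant-alone curve at the study's actual
    design concentrations, runs the resulting predicted combined response
    through the same fitting pipeline as the observations, and inverts the
    fitted curve at each effect level. This readout sees the predicted
    curve exactly the way the observed combined arm is seen, so the
    log-logistic approximation error cancels between observed and
    predicted shifts (the closed-form :func:`~samtox.sam.sam_lcx_shift`
    is the model's exact prediction, but a combined-stress curve is not
    itself log-logistic, and the two readouts differ where the fit must
    extrapolate shallow low-effect regions).

    Returns ``{x: (lcx, lcx_star, shift)}``.
    """
    from .sam import predict_combined_curve  # local import avoids a cycle at import time

    conc = np.asarray(design_concentrations, dtype=float)
    conc = conc[conc > 0]
    pred_surv = predict_combined_curve(dist, fitted.tox_params, fitted.m_env, conc)
    data = DoseResponseDataset(
        concentrations=conc,
        survival=np.clip(pred_surv, 0.0, 1.0),
        control_survival=float(fitted.tox_params.d * (1.0 - fitted.m_env)),
    )
    # the predicted curve is monotone by construction, so the Williams
    # transformation is a no-op on it; interpolation is applied as for data
    if interpolate is not None:
        from .dose_response import interpolate_log

        data = interpolate_log(data, interpolate)
    from .dose_response import fit_ll5

    params = fit_ll5(data, x0=fitted.combined_params)
    out = {}
    for x in x_levels:
        lcx = lc(fitted.tox_params, x)
        lcx_star = lc(params, x)
        out[x] = (lcx, lcx_star, lcx / lcx_star)
    return out


def calibrate_shape(
    pairs,
    x_levels=DEFAULT_X_LEVELS,
    shape_bounds=(1.0, 20.0),
    grid_step: float = 0.1,
    williams: bool = True,
    interpolate: int | None = 10,
    predicted: str = "refit",
) -> CalibrationResult:
    """Calibrate the symmetric beta shape ``p = q`` against observed shifts.

    Minimises the sum of squared differences between log10 observed and
    log10 SAM-predicted LCx shifts over all studies with environmental
    mortality > 0 (studies without a measurable environmental effect carry
    no information about the stress transfer and are excluded, as are
    study × level combinations whose effect level is unreachable).
    Deterministic two-stage grid search plus bounded local refinement.

    ``predicted`` selects the predicted-shift readout: ``"refit"``
    (default) passes the per-study SAM-predicted curve through the same
    LL.5 pipeline as the data, which keeps observed and predicted shifts
    on the same footing; ``"exact"`` uses the closed-form model shift.
    """
    if predicted not in ("refit", "exact"):
        raise InputError("predicted must be 'refit' or 'exact'")
    active = [p for p in pairs if p.m_env > 0]
    if not active:
        raise CalibrationError("no study with environmental mortality > 0; cannot calibrate")
    records, fitted_pairs, flagged = observed_shifts(active, x_levels, williams, interpolate)
    fitted_by_id = {f.study_id: f for f in fitted_pairs}
    design_by_id = {p.study_id: p.combined_arm.concentrations for p in active}
    usable = records
    if not usable:
        raise CalibrationError("no usable (study, effect level) combination for calibration")

    log_obs = np.array([math.log10(r.shift) for r in usable])

    def predictions(shape):
        dist = StressCapacityDistribution(shape, shape)
        preds = {}
        for sid, fitted in fitted_by_id.items():
            if predicted == "refit":
                table = predicted_shifts_refit(
                    dist, fitted, design_by_id[sid], x_levels, williams, interpolate)
                preds[sid] = {x: table[x][2] for x in x_levels}
            else:
                preds[sid] = {
                    x: sam_lcx_shift(dist, fitted.tox_params, fitted.m_env, x)
                    for x in x_levels
                }
        return preds

    def objective(shape):
        preds = predictions(shape)
        return float(sum(
            (lo - math.log10(preds[r.study_id][r.x])) ** 2
            for r, lo in zip(usable, log_obs)
        ))

    # two-stage deterministic search: coarse grid, fine grid around the
    # best coarse point, then bounded scalar refinement
    coarse = np.arange(shape_bounds[0], shape_bounds[1] + 0.25, 0.5)
    coarse = np.clip(coarse, *shape_bounds)
    cvals = [objective(s) for s in coarse]
    ci = int(np.argmin(cvals))
    lo_c = max(shape_bounds[0], coarse[ci] - 0.5)
    hi_c = min(shape_bounds[1], coarse[ci] + 0.5)
    fine = np.arange(lo_c, hi_c + grid_step / 2, grid_step)
    fvals = [objective(s) for s in fine]
    fi = int(np.argmin(fvals))
    lo_b = fine[max(fi - 1, 0)]
    hi_b = fine[min(fi + 1, len(fine) - 1)]
    res = minimize_scalar(objective, bounds=(lo_b, hi_b), method="bounded",
                          options={"xatol": 1e-4})
    shape = float(res.x) if res.fun <= fvals[fi] else float(fine[fi])

    final_preds = predictions(shape)
    rows = []
    for r in usable:
        pred = final_preds[r.study_id][r.x]
        rows.append({
            "study_id": r.study_id, "x": r.x, "observed_shift": r.shift,
            "predicted_shift": pred,
            "log10_residual": math.log10(r.shift) - math.log10(pred),
        })
    residuals = pd.DataFrame(rows)
    r2_by_level = {}
    for x in x_levels:
        sub = residuals[residuals["x"] == x]
        if len(sub) >= 2 and sub["observed_shift"].nunique() > 1:
            r2_by_level[x] = model_r2(sub["observed_shift"], sub["predicted_shift"])
    return CalibrationResult(
        shape=shape,
        objective=float(objective(shape)),
        n_records=len(usable),
        r2_by_level=r2_by_level,
        residuals=residuals,
    )


def model_r2(observed_shifts, predicted_shifts, log_scale: bool = True) -> float:
    """Proportion of variance in observed shifts explained by the model,
    ``1 - SS_res/SS_tot``, computed on log10 shift factors by default
    (shifts span orders of magnitude); may be negative for a bad model."""
    obs = np.asarray(observed_shifts, dtype=float)
    pred = np.asarray(predicted_shifts, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise InputError("need equal-length vectors with at least 2 entries")
    if log_scale:
        obs, pred = np.log10(obs), np.log10(pred)
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise InputError("observed shifts have zero variance; R^2 undefined")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


def overall_prediction(
    avg: AverageCurve,
    dist: StressCapacityDistribution,
    env_grid=DEFAULT_ENV_GRID,
    x_levels=DEFAULT_X_LEVELS,
) -> pd.DataFrame:
    """Predicted sensitivity shift versus environmental stress on the
    average normalised curve, for SAM, adapted CA and EA.

    One row per (environmental mortality, effect level, model) with the
    shift on the median curve and the band from the upper/lower SE curves;
    unreachable combinations are flagged (``reachable=False``, NaN shift)
    rather than raised. EA predicts no shift, so its column is 1.
    """
    def _sam(params, m_env, x):
        return sam_lcx_shift(dist, params, m_env, x)

    def _ca(params, m_env, x):
        return baselines.ca_lcx_shift(params, m_env, x)

    models = {"sam": _sam, "ca": _ca, "ea": lambda params, m_env, x: 1.0}
    rows = []
    for m_env in env_grid:
        for x in x_levels:
            for name, fn in models.items():
                row = {"env_mortality": m_env, "x": x, "model": name,
                       "shift": np.nan, "shift_lower": np.nan, "shift_upper": np.nan,
                       "reachable": True}
                try:
                    row["shift"] = fn(avg.median_params, m_env, x)
                    # band: shifts on the SE-band curves (order not guaranteed)
                    band = []
                    for params in (avg.lower_params, avg.upper_params):
                        band.append(fn(params, m_env, x))
                    row["shift_lower"] = min(band)
                    row["shift_upper"] = max(band)
                except (EffectLevelUnreachableError, OutOfRangeError):
                    row["reachable"] = False
                rows.append(row)
    return pd.DataFrame(rows)
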