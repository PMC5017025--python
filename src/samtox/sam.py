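"""The Stress Addition Model (SAM).

Every individual is assumed to carry a *general stress capacity* drawn from
a Beta(p, q) distribution on [0, 1]; an individual dies when the total
general stress it experiences exceeds its capacity. Three rules follow:

1. survival under general stress S is the beta survival function
   ``N(S) = 1 - I(S; p, q)`` (regularised incomplete beta), with
   ``N(0) = 1`` and ``N(S) = 0`` for ``S >= 1``;
2. any stressor causing single-stressor mortality ``m`` exerts the general
   stress given by the beta quantile at ``m`` (mortality is the common
   currency linking heterogeneous stressors);
3. general stress levels of independent stressors add, and the beta CDF of
   the sum gives the combined mortality.

Because stresses add on the quantile scale of a bell-shaped capacity
distribution, two mild stressors jointly produce far more mortality than
either alone — the model's synergism. The calibrated symmetric shape
``p = q = 3.2`` is the package default.

The ``resolution`` argument of the mortality→stress transfer emulates a
tabulated calculator workflow: the stress axis is discretised in steps of
``resolution`` and a mortality maps to the first tabulated stress level
whose CDF reaches it (i.e. the quantile rounded up to the grid). With
``resolution=0.01`` this reproduces published worked-example values such as
m=0.10 → S=0.26 and m=0.15 → S=0.30, whose sum 0.56 yields 61.6% combined
mortality; the default (``resolution=None``) is the exact continuous
quantile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import beta as beta_dist

from .dose_response import LL5Params, effect_mortality, lc
from .errors import EffectLevelUnreachableError, OutOfRangeError, ParameterDomainError

__all__ = [
    "StressCapacityDistribution",
    "survival_at_stress",
    "mortality_to_stress",
    "add_stress",
    "sam_combined_mortality",
    "predict_combined_curve",
    "sam_lcx_shift",
    "sam_lcx_star",
]

DEFAULT_SHAPE = 3.2


@dataclass(frozen=True)
class StressCapacityDistribution:
    """Beta(p, q) distribution of individual general stress capacity.

    The symmetric default ``p = q = 3.2`` is the shape calibrated against
    observed LC10/LC50 shifts in paired toxicant × environmental-stress
    experiments.
    """

    p: float = DEFAULT_SHAPE
    q: float = DEFAULT_SHAPE

    def __post_init__(self):
        if not (self.p > 0 and self.q > 0):
            raise ParameterDomainError(f"shape parameters must be > 0 (p={self.p}, q={self.q})")

    def cdf(self, s):
        return beta_dist.cdf(s, self.p, self.q)

    def ppf(self, m):
        return beta_dist.ppf(m, self.p, self.q)


def survival_at_stress(dist: StressCapacityDistribution, S):
    """Surviving fraction of a population under total general stress S.

    ``N(0) = 1``, ``N(S) = 0`` for ``S >= 1``, strictly decreasing between.
    Accepts scalars or arrays; S must be non-negative.
    """
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise ParameterDomainError("general stress must be >= 0")
    out = 1.0 - dist.cdf(np.clip(S, 0.0, 1.0))
    out = np.where(S >= 1.0, 0.0, out)
    return float(out) if out.ndim == 0 else out


def mortality_to_stress(dist: StressCapacityDistribution, m, resolution: float | None = None):
    """General stress level exerted by a stressor causing mortality ``m``.

    The m-quantile of the capacity distribution (inverse of
    ``1 - survival_at_stress`` on (0, 1)); m = 0 and m = 1 map to the
    support endpoints 0 and 1. With ``resolution`` set, the quantile is
    rounded up to the tabulated stress grid (see module docstring).
    """
    m_arr = np.asarray(m, dtype=float)
    if np.any((m_arr < 0) | (m_arr > 1)):
        raise ParameterDomainError("mortality fractions must lie in [0, 1]")
    s = dist.ppf(m_arr)
    if resolution is not None:
        if not 0 < resolution < 1:
            raise ParameterDomainError("resolution must lie in (0, 1)")
        # first grid multiple whose CDF reaches m; the 1e-9 guards values
        # already sitting on the grid against a spurious extra step
        s = np.minimum(np.ceil(s / resolution - 1e-9) * resolution, 1.0)
    return float(s) if s.ndim == 0 else s


def add_stress(stresses: Iterable[float]) -> float:
    """Total general stress: the plain sum of independent stress levels.

    The sum is deliberately left uncapped; the ``S >= 1`` rule is applied
    only when survival is evaluated. An empty collection totals 0.
    """
    total = 0.0
    for s in stresses:
        if s < 0:
            raise ParameterDomainError("general stress must be >= 0")
        total += float(s)
    return total


def sam_combined_mortality(
    dist: StressCapacityDistribution,
    mortalities: Sequence[float],
    resolution: float | None = None,
) -> float:
    """Combined mortality of independent stressors given each stressor's
    single-stressor mortality: beta CDF of the summed stress quantiles."""
    total = add_stress(mortality_to_stress(dist, m, resolution) for m in mortalities)
    if total >= 1.0:
        return 1.0
    return float(dist.cdf(total))


def predict_combined_curve(
    dist: StressCapacityDistribution,
    tox_curve: LL5Params,
    m_env: float,
    grid,
):
    """SAM-predicted absolute survival of the toxicant + environmental
    stressor combination over a concentration grid.

    Per concentration the toxicant's control-normalised mortality and the
    environmental mortality are converted to general stress, summed, and
    the resulting stress-dependent survival is scaled back to the absolute
    scale by the toxicant arm's control level ``d``. At C = 0 this equals
    the environmental-stress-only survival ``d * (1 - m_env)``.
    """
    if not 0.0 <= m_env <= 1.0:
        raise ParameterDomainError("environmental mortality must lie in [0, 1]")
    grid = np.asarray(grid, dtype=float)
    if m_env >= 1.0:
        warnings.warn("environmental stress alone kills the whole population")
        return np.zeros(grid.shape)
    s_env = mortality_to_stress(dist, m_env)
    m_tox = np.asarray(effect_mortality(tox_curve, grid))
    s_tox = mortality_to_stress(dist, m_tox)
    return tox_curve.d * np.asarray(survival_at_stress(dist, s_env + s_tox))


def sam_lcx_star(
    dist: StressCapacityDistribution,
    tox_curve: LL5Params,
    m_env: float,
    x: float,
) -> float:
    """Shifted lethal concentration LCx*: the concentration at which the
    SAM-predicted combined curve reaches x% mortality relative to its own
    (environmentally stressed) control, by closed-form inversion on the
    stress scale.

    Each curve's lethal concentration is Abbott-corrected against its own
    control — the same scale on which fitted curves are read — so the
    effect-addition baseline predicts no shift and LCx* exists for every
    ``m_env`` in [0, 1). Solves
    ``1 - N(S_env + S_tox) / (1 - m_env) = x/100`` for the toxicant
    concentration.
    """
    if not 0.0 <= m_env < 1.0:
        raise ParameterDomainError("environmental mortality must lie in [0, 1)")
    m_total = m_env + (1.0 - m_env) * x / 100.0  # mortality vs unstressed control
    s_tox = mortality_to_stress(dist, m_total) - mortality_to_stress(dist, m_env)
    # floor keeps the inversion representable in extreme-synergy corners
    # where the toxicant contribution underflows
    m_tox = max(float(dist.cdf(max(s_tox, 0.0))), 1e-12)
    try:
        return lc(tox_curve, 100.0 * m_tox)
    except OutOfRangeError as err:
        raise EffectLevelUnreachableError(str(err)) from err


def sam_lcx_shift(
    dist: StressCapacityDistribution,
    tox_curve: LL5Params,
    m_env: float,
    x: float,
) -> float:
    """Sensitivity shift LCx / LCx* predicted by SAM; 1 when ``m_env = 0``
    and strictly increasing with the environmental stress level."""
    return lc(tox_curve, x) / sam_lcx_star(dist, tox_curve, m_env, x)
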