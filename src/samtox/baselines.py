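"""Traditional mixture-toxicity baselines: effect addition and adapted
concentration addition.

Effect addition (EA, Bliss independence) multiplies survival
probabilities: ``E_mix = 1 - prod(1 - E_i)``. It predicts no change of the
toxicant's concentration-response curve, hence no LCx shift.

Concentration addition (CA, Loewe additivity) treats all stressors as
dilutions of one another on a *common* concentration-response curve. The
adaptation for a non-chemical stressor maps its stand-alone mortality to
the equivalent concentration on the common curve (normally the averaged,
normalised toxicant curve of a meta-analysis) and adds concentrations.
"""

from __future__ import annotations

from typing import Sequence

from .dose_response import LL5Params, effect_mortality, lc
from .errors import EffectLevelUnreachableError, ParameterDomainError

__all__ = [
    "ea_combined_mortality",
    "ca_equivalent_concentration",
    "ca_combined_mortality",
    "ca_lcx_star",
    "ca_lcx_shift",
]


def ea_combined_mortality(mortalities: Sequence[float]) -> float:
    """Bliss effect addition: ``1 - prod(1 - m_i)``; symmetric, bounded by
    the largest single mortality from below and by 1 from above."""
    surv = 1.0
    for m in mortalities:
        if not 0.0 <= m <= 1.0:
            raise ParameterDomainError(f"mortality fractions must lie in [0, 1], got {m}")
        surv *= 1.0 - m
    return 1.0 - surv


def ca_equivalent_concentration(curve: LL5Params, m: float) -> float:
    """Concentration on the common curve producing control-normalised
    mortality ``m``; 0 for m = 0 by convention."""
    if not 0.0 <= m < 1.0:
        raise ParameterDomainError("mortality must lie in [0, 1)")
    if m == 0.0:
        return 0.0
    return lc(curve, 100.0 * m)


def ca_combined_mortality(curve: LL5Params, m_env: float, c_tox: float) -> float:
    """Adapted concentration addition: the environmental mortality is
    converted to its equivalent concentration on the common curve, added
    to the toxicant concentration, and the summed dose is evaluated."""
    if c_tox < 0:
        raise ParameterDomainError("toxicant concentration must be >= 0")
    return float(effect_mortality(curve, ca_equivalent_concentration(curve, m_env) + c_tox))


def ca_lcx_star(curve: LL5Params, m_env: float, x: float) -> float:
    """CA-shifted lethal concentration: the toxicant dose at which the
    CA combined curve reaches x% mortality relative to its own
    (environmentally stressed) control.

    On that Abbott-corrected scale the target total mortality is
    ``m_env + (1 - m_env) * x/100`` on the common curve, so
    ``LCx* = lc(m_total) - c_env_equivalent`` (positive for all
    ``m_env < 1`` whenever the total effect is attainable)."""
    m_total = m_env + (1.0 - m_env) * x / 100.0
    try:
        lc_total = lc(curve, 100.0 * m_total)
    except OutOfRangeError as err:
        raise EffectLevelUnreachableError(
            f"total effect {100 * m_total:.4g}% is beyond the curve's maximum: {err}"
        ) from err
    c_env = ca_equivalent_concentration(curve, m_env)
    if c_env >= lc_total:  # pragma: no cover - cannot occur for monotone curves
        raise EffectLevelUnreachableError("environmental equivalent dose exceeds the target dose")
    return lc_total - c_env


def ca_lcx_shift(curve: LL5Params, m_env: float, x: float) -> float:
    """Sensitivity shift LCx / LCx* under adapted concentration addition;
    1 at ``m_env = 0`` and always finite (unreachable levels raise)."""
    return lc(curve, x) / ca_lcx_star(curve, m_env, x)
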