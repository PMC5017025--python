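"""Synthetic study-pair generator with known ground truth.

Emulates the paired-design literature data the meta-analysis layer
consumes: per study a toxicant-alone concentration-response arm, the same
toxicant under an additional environmental stressor, and the mortality of
the environmental stressor alone. Combined-arm survival follows the
Stress Addition Model by construction (optionally CA or EA truth, to
check that the calibrator can tell generating models apart), with
binomial sampling noise at a configurable number of organisms per
concentration.

The default configuration mirrors the conditions of the published
meta-analysis: 23 study pairs, capacity shape p = q = 3.2, environmental
mortalities spread over (0, 0.5], and concentration designs that always
include a partial response and a near-complete kill (the grid spans the
drawn curve's LC1–LC99).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

from .dose_response import DoseResponseDataset, LL5Params, lc, ll5_survival
from .errors import InputError
from .meta import StudyPair
from .sam import StressCapacityDistribution, mortality_to_stress, survival_at_stress
from . import baselines

__all__ = ["GeneratorConfig", "generate_study_pair", "generate_meta_dataset"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of the synthetic meta-dataset.

    ``effect_span`` is the effect-percent range the log-spaced
    concentration grid covers on the drawn toxicant curve (1–99% keeps
    every design with a partial response and a near-total kill).
    ``curve_prior`` gives (low, high) ranges for the generating LL.5
    parameters; ``e`` is drawn log-uniformly.
    """

    seed: int = 0
    n_studies: int = 23
    organisms_per_concentration: int = 1000
    n_concentrations: int = 8
    effect_span: tuple = (1.0, 99.0)
    true_shape: float = 3.2
    env_mortality_range: tuple = (0.02, 0.5)
    # acute-toxicity curves are typically right-skewed in log concentration
    # (effect onset well before the LC50, long tail to complete kill): on
    # the normalised LC1-LC99 axis 10% mortality sits near position 0.1,
    # which corresponds to asymmetry f well below 1
    curve_prior: dict = field(default_factory=lambda: {
        "b": (0.8, 3.0),
        "d": (0.85, 1.0),
        "log10_e": (-1.0, 2.0),
        "f": (0.1, 0.5),
    })
    # designs whose LC1-LC99 range exceeds this many decades are rejected
    # and redrawn: no realistic bioassay spans 10 orders of magnitude, and
    # the cap couples strong right-skew (small f) to steep slopes (large
    # b), as observed in fitted literature curves
    max_span_decades: float = 5.0
    max_retries: int = 1000
    noise: str = "binomial"  # "binomial" | "none"
    truth_model: str = "sam"  # "sam" | "ca" | "ea"

    def __post_init__(self):
        if self.noise not in ("binomial", "none"):
            raise InputError(f"noise must be 'binomial' or 'none', got {self.noise!r}")
        if self.truth_model not in ("sam", "ca", "ea"):
            raise InputError(f"truth_model must be sam|ca|ea, got {self.truth_model!r}")
        if self.n_studies < 0 or self.organisms_per_concentration < 1:
            raise InputError("n_studies must be >= 0 and organisms_per_concentration >= 1")
        if not (0 <= self.env_mortality_range[0] <= self.env_mortality_range[1] <= 1):
            raise InputError("env_mortality_range must be an interval within [0, 1]")


def _combined_survival(cfg: GeneratorConfig, curve: LL5Params, m_env: float, grid):
    """Absolute combined-arm survival under the configured truth model."""
    m_tox = 1.0 - np.asarray(ll5_survival(curve, grid)) / curve.d
    if cfg.truth_model == "sam":
        dist = StressCapacityDistribution(cfg.true_shape, cfg.true_shape)
        s = mortality_to_stress(dist, m_env) + mortality_to_stress(dist, np.clip(m_tox, 0, 1))
        return curve.d * np.asarray(survival_at_stress(dist, s))
    if cfg.truth_model == "ca":
        c_env = baselines.ca_equivalent_concentration(curve, m_env)
        m = 1.0 - np.asarray(ll5_survival(curve, c_env + grid)) / curve.d
        return curve.d * (1.0 - m)
    # ea
    return curve.d * (1.0 - m_env) * (1.0 - m_tox)


def _combined_conc_at_effect(cfg: GeneratorConfig, curve: LL5Params, m_env: float, y: float):
    """Concentration at which the TRUE combined arm reaches effect ``y``
    on its own (env-stressed-control-normalised) scale; used to make the
    design cover the combined arm's transition as well."""
    if cfg.truth_model == "sam":
        dist = StressCapacityDistribution(cfg.true_shape, cfg.true_shape)
        s_total = float(dist.ppf(1.0 - (1.0 - m_env) * (1.0 - y)))
        m_tox = float(dist.cdf(max(s_total - float(dist.ppf(m_env)), 0.0)))
    elif cfg.truth_model == "ca":
        c_env = baselines.ca_equivalent_concentration(curve, m_env)
        return max(lc(curve, 100.0 * (m_env + y * (1.0 - m_env))) - c_env, 0.0)
    else:  # ea: combined transition coincides with the toxicant's
        m_tox = y
    m_tox = min(max(m_tox, 1e-4), 1.0 - 1e-6)
    return lc(curve, 100.0 * m_tox)


def _design_grid(cfg: GeneratorConfig, curve: LL5Params, m_env: float):
    """Log-spaced grid covering both arms: the toxicant's effect span and
    the combined arm's 5–95% (own scale) transition."""
    lo = min(lc(curve, cfg.effect_span[0]),
             _combined_conc_at_effect(cfg, curve, m_env, cfg.effect_span[0] / 100.0))
    hi = max(lc(curve, cfg.effect_span[1]),
             _combined_conc_at_effect(cfg, curve, m_env, cfg.effect_span[1] / 100.0))
    return np.exp(np.linspace(np.log(lo), np.log(hi), cfg.n_concentrations))


def _sample(rng, cfg: GeneratorConfig, p_true):
    """Observed survival fractions for true probabilities p_true."""
    p_true = np.clip(np.asarray(p_true, dtype=float), 0.0, 1.0)
    if cfg.noise == "none":
        return p_true.copy()
    n = cfg.organisms_per_concentration
    return rng.binomial(n, p_true) / n


def generate_study_pair(cfg: GeneratorConfig, rng, study_id: str = "S1"):
    """Draw one study pair; returns ``(StudyPair, truth)`` where ``truth``
    records every generating parameter for recovery tests."""
    prior = cfg.curve_prior
    for attempt in range(cfg.max_retries):
        curve = LL5Params(
            b=rng.uniform(*prior["b"]),
            c=0.0,
            d=rng.uniform(*prior["d"]),
            e=10.0 ** rng.uniform(*prior["log10_e"]),
            f=rng.uniform(*prior["f"]),
        )
        span = math.log10(lc(curve, 99.0) / lc(curve, 1.0))
        if span <= cfg.max_span_decades:
            break
        logger.debug("study %s: rejected draw %d (span %.1f decades)",
                     study_id, attempt + 1, span)
    else:
        raise InputError(
            f"no feasible design within {cfg.max_retries} draws; "
            "widen max_span_decades or narrow the curve prior")
    m_env = rng.uniform(*cfg.env_mortality_range)
    grid = _design_grid(cfg, curve, m_env)

    tox_true = np.asarray(ll5_survival(curve, grid))
    comb_true = _combined_survival(cfg, curve, m_env, grid)

    tox_surv = _sample(rng, cfg, tox_true)
    comb_surv = _sample(rng, cfg, comb_true)
    control = float(_sample(rng, cfg, np.array([curve.d]))[0])
    env_control = float(_sample(rng, cfg, np.array([curve.d * (1.0 - m_env)]))[0])
    if control <= 0:  # pragma: no cover - requires extreme draws
        raise InputError("degenerate control draw; increase organisms_per_concentration")
    m_env_obs = float(np.clip(1.0 - env_control / control, 0.0, 1.0 - 1e-9))

    n = float(cfg.organisms_per_concentration)
    weights = None if cfg.noise == "none" else np.full(grid.shape, n)
    pair = StudyPair(
        study_id=study_id,
        tox_arm=DoseResponseDataset(grid, tox_surv, control, weights),
        combined_arm=DoseResponseDataset(grid, comb_surv, env_control, weights),
        m_env=m_env_obs,
    )
    truth = {
        "study_id": study_id, "b": curve.b, "c": curve.c, "d": curve.d,
        "e": curve.e, "f": curve.f, "m_env": m_env,
        "true_shape": cfg.true_shape, "truth_model": cfg.truth_model,
    }
    return pair, truth


def generate_meta_dataset(cfg: GeneratorConfig):
    """Generate ``cfg.n_studies`` heterogeneous study pairs.

    Returns ``(pairs, manifest)``; the manifest DataFrame records the
    generating curve, environmental mortality and capacity shape of every
    study. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(cfg.seed)
    pairs, truths = [], []
    for i in range(cfg.n_studies):
        pair, truth = generate_study_pair(cfg, rng, study_id=f"S{i + 1:02d}")
        pairs.append(pair)
        truths.append(truth)
    columns = ["study_id", "b", "c", "d", "e", "f", "m_env", "true_shape", "truth_model"]
    manifest = pd.DataFrame(truths, columns=columns)
    return pairs, manifest
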