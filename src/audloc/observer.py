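"""Closed-form Bayesian observer for azimuthal localisation.

The observer combines a noisy sensory measurement of a sound (or light)
source's azimuth with a Gaussian prior over azimuth.  With Gaussian
likelihood and prior, the posterior mean is the reliability-weighted
average of the sensed azimuth and the prior mean, where the weight given
to the prior is

    w = sigma_like^2 / (sigma_like^2 + sigma_prior^2).

Averaged over sensory noise this produces a localisation bias that is
linear in the true azimuth A:

    b(A) = w * (p - A),

with p the prior's azimuth.  The slope of bias against azimuth is -w,
which is never positive for a valid prior weight — the key structural
constraint this package's critique module tests against data.

Angles are degrees of azimuth, 0 = straight ahead, positive rightward.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "GaussianPrior",
    "SensoryLikelihood",
    "FLAT_PRIOR",
    "prior_weight",
    "posterior_estimate",
    "predicted_bias",
    "bias_gradient",
    "robust_posterior_estimate",
]


@dataclass(frozen=True)
class GaussianPrior:
    """Gaussian prior over source azimuth.

    Parameters
    ----------
    mean_azimuth : float
        Azimuth of the prior (degrees).
    sd : float
        Prior standard deviation (degrees).  ``math.inf`` encodes a flat
        (uninformative) prior.
    """

    mean_azimuth: float
    sd: float

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError(f"prior sd must be > 0, got {self.sd}")

    @property
    def is_flat(self) -> bool:
        return math.isinf(self.sd)


@dataclass(frozen=True)
class SensoryLikelihood:
    """Noisy internal measurement of source azimuth.

    ``sensed_azimuth`` is one sample of the internal estimate; ``sd`` is
    the condition's sensory uncertainty (degrees).
    """

    sensed_azimuth: float
    sd: float

    def __post_init__(self) -> None:
        if not (self.sd > 0 and math.isfinite(self.sd)):
            raise ValueError(f"likelihood sd must be finite and > 0, got {self.sd}")


FLAT_PRIOR = GaussianPrior(0.0, math.inf)


def prior_weight(likelihood_sd: float, prior_sd: float) -> float:
    """Weight given to the prior in the posterior-mean estimate.

    w = likelihood_sd**2 / (likelihood_sd**2 + prior_sd**2); a flat prior
    (infinite sd) gets weight 0.  Strictly increasing in the sensory
    uncertainty for any fixed finite prior sd.
    """
    if not (likelihood_sd > 0 and math.isfinite(likelihood_sd)):
        raise ValueError(f"likelihood sd must be finite and > 0, got {likelihood_sd}")
    if not prior_sd > 0:
        raise ValueError(f"prior sd must be > 0, got {prior_sd}")
    if math.isinf(prior_sd):
        return 0.0
    lv = likelihood_sd**2
    return lv / (lv + prior_sd**2)


def posterior_estimate(like: SensoryLikelihood, prior: GaussianPrior) -> float:
    """Posterior-mean azimuth estimate.

    The reliability-weighted average (1-w)*sensed + w*prior_mean; always
    lies between the sensed azimuth and the prior mean.
    """
    w = prior_weight(like.sd, prior.sd)
    return (1.0 - w) * like.sensed_azimuth + w * prior.mean_azimuth


def predicted_bias(true_azimuth: float, w: float, prior_mean: float) -> float:
    """Expected localisation bias at a true azimuth A: b = w * (p - A).

    This is the sensory-noise average of ``posterior_estimate`` minus the
    true azimuth (exact, by linearity of the posterior mean in the
    sensed azimuth).
    """
    _check_weight(w)
    return w * (prior_mean - true_azimuth)


def bias_gradient(w: float) -> float:
    """Slope of predicted bias with respect to true azimuth: db/dA = -w.

    Non-positive for every valid prior weight, so a static Gaussian
    prior can never produce bias that grows with eccentricity.
    """
    _check_weight(w)
    return -w


def robust_posterior_estimate(
    like: SensoryLikelihood, prior: GaussianPrior, conflict_scale: float
) -> float:
    """Posterior estimate under robust cue integration.

    The prior weight is attenuated by a Gaussian falloff in the conflict
    between the sensed azimuth and the prior mean:

        w_eff = w * exp(-0.5 * ((sensed - p) / conflict_scale)**2)

    At zero conflict, or as ``conflict_scale -> inf``, this reduces to
    the plain ``posterior_estimate``.  Any attenuation that is 1 at zero
    conflict and decreases monotonically in |conflict|/scale would serve;
    the Gaussian form is chosen for smoothness.
    """
    if not conflict_scale > 0:
        raise ValueError(f"conflict_scale must be > 0, got {conflict_scale}")
    w = prior_weight(like.sd, prior.sd)
    conflict = like.sensed_azimuth - prior.mean_azimuth
    if math.isinf(conflict_scale):
        atten = 1.0
    else:
        atten = math.exp(-0.5 * (conflict / conflict_scale) ** 2)
    w_eff = w * atten
    return (1.0 - w_eff) * like.sensed_azimuth + w_eff * prior.mean_azimuth


def _check_weight(w: float) -> None:
    if not 0.0 <= w <= 1.0:
        raise ValueError(f"prior weight must lie in [0, 1], got {w}")
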