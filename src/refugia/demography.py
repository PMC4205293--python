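"""Closed-form conversions between coalescent and demographic parameters.

The scaled mutation parameter ``theta = 4*mu*Ne`` (diploid) links gene
diversity, effective population size, coalescence depth and migrant
numbers.  A moment estimator inverts the stepwise-mutation equilibrium
``He = 1 - 1/sqrt(1 + 2*theta)`` to obtain theta from observed diversity;
the remaining conversions are algebraic:

* ``Ne = theta / (4*mu)``
* ``E[TMRCA] = 4*Ne generations = theta/mu generations`` (large-sample
  expectation), converted to years by the generation time;
* ``theta_t = theta_now * exp(-g*t)`` for exponential growth at rate ``g``
  in mutational time units (``t`` backward);
* ``Nem = M * theta / 4`` from the scaled migration rate ``M = 4*Ne*m/theta``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class CoalescentParams:
    """Bundle of mutually consistent coalescent-scale parameters."""

    theta: float
    mu: float
    generation_time: float = 12.0
    g_rate: float = 0.0
    M: float = 0.0

    def __post_init__(self) -> None:
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        if self.mu <= 0:
            raise ValueError("mu must be > 0")

    @property
    def Ne(self) -> float:
        return ne_from_theta(self.theta, self.mu)

    @property
    def tmrca_years(self) -> float:
        return tmrca_from_theta(self.theta, self.mu, self.generation_time)

    @property
    def Nem(self) -> float:
        return nem_from_migration(self.M, self.theta)


def theta_from_he_smm(he: float) -> float:
    """Moment estimate of theta from gene diversity at SMM equilibrium.

    Inverts ``He = 1 - 1/sqrt(1 + 2*theta)``: ``theta = ((1/(1-He))^2 - 1)/2``.
    """
    if not (0.0 <= he < 1.0):
        raise ValueError("He must lie in [0, 1)")
    return ((1.0 / (1.0 - he)) ** 2 - 1.0) / 2.0


def ne_from_theta(theta: float, mu: float) -> float:
    """Diploid effective size from ``theta = 4*mu*Ne``."""
    if mu <= 0:
        raise ValueError("mu must be > 0")
    return theta / (4.0 * mu)


def tmrca_from_theta(theta: float, mu: float, generation_time: float = 12.0) -> float:
    """Expected coalescence depth in years.

    ``E[TMRCA] = 4*Ne = theta/mu`` generations, scaled by the generation
    time in years.
    """
    if mu <= 0:
        raise ValueError("mu must be > 0")
    return (theta / mu) * generation_time


def theta_at_time(theta_now: float, g_rate: float, t: float, backward_smaller: bool = True) -> float:
    """Theta ``t`` mutational time units in the past under exponential growth.

    The quoted convention is ``theta_t = theta_now * exp(-g*t)`` with ``t``
    backward, so a positive ``g`` means a smaller population in the past.
    ``backward_smaller=False`` flips the sign (the convention in which a
    negative growth parameter indicates expansion toward the present).
    """
    sign = -1.0 if backward_smaller else 1.0
    return theta_now * math.exp(sign * g_rate * t)


def nem_from_migration(M: float, theta: float) -> float:
    """Migrants per generation from the scaled migration rate.

    ``M = 4*Ne*m/theta`` implies ``Ne*m = M*theta/4``.
    """
    if M < 0 or theta < 0:
        raise ValueError("M and theta must be >= 0")
    return M * theta / 4.0
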