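"""From reaction-time distributions to visibility probabilities.

Reaction times are modelled as exponentially modified Gaussians
(ex-Gaussian: a Normal(mu, sigma) plus an independent Exponential(tau)
component), the standard parametric family for response-time data.  Player i
sees the partner j's choice when j commits sufficiently earlier, i.e. when

.. math:: T_j + \\delta < T_i

for a perception delay :math:`\\delta \\ge 0` (time needed to register and
exploit the partner's action).  The visibility probabilities are therefore

.. math::

   p_{see}^{12} = \\Pr(T_2 + \\delta < T_1), \\qquad
   p_{see}^{21} = \\Pr(T_1 + \\delta < T_2),

with :math:`p^{12} + p^{21} \\le 1`, the remainder being near-simultaneous
rounds where neither player sees the other.  Equal reaction-time
distributions give :math:`p^{12} = p^{21} \\le 0.5`, with equality at 0.5
only in the zero-delay limit.  The perception-delay parameterisation is one
admissible reading of how visibility arises from response timing; it is the
one implemented here and exposed through the ``delay`` parameter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy import stats

__all__ = ["ExGaussianRT", "p_see_from_rts"]


@dataclass(frozen=True)
class ExGaussianRT:
    """Ex-Gaussian reaction-time distribution (mu, sigma: Gaussian part;
    tau: exponential mean), all in the same time units."""

    mu: float
    sigma: float
    tau: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        if self.tau <= 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")

    def frozen(self):
        # exponnorm's shape K is the exponential-to-Gaussian scale ratio
        return stats.exponnorm(K=self.tau / self.sigma, loc=self.mu,
                               scale=self.sigma)

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return (rng.normal(self.mu, self.sigma, size)
                + rng.exponential(self.tau, size))


def _prob_exceeds(rt_fast: ExGaussianRT, rt_slow: ExGaussianRT,
                  delay: float) -> float:
    """Pr(rt_fast + delay < rt_slow) by quadrature over the slow density."""
    f_slow = rt_slow.frozen()
    F_fast = rt_fast.frozen()

    def integrand(t: float) -> float:
        return f_slow.pdf(t) * F_fast.cdf(t - delay)

    lo = min(rt_fast.mu, rt_slow.mu) - 12 * max(rt_fast.sigma, rt_slow.sigma)
    hi = (max(rt_fast.mu, rt_slow.mu)
          + 12 * max(rt_fast.sigma, rt_slow.sigma)
          + 30 * max(rt_fast.tau, rt_slow.tau))
    value, err = integrate.quad(integrand, lo, hi, limit=200)
    if not np.isfinite(value) or err > 1e-6:
        raise FloatingPointError(f"quadrature error {err} too large")
    return float(min(max(value, 0.0), 1.0))


def p_see_from_rts(
    rt_i: ExGaussianRT,
    rt_j: ExGaussianRT,
    perception_delay: float = 0.0,
    method: str = "quadrature",
    n_samples: int = 200_000,
    rng: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Visibility probabilities ``(p12, p21)`` for two reaction-time
    distributions.

    ``p12`` is the probability that player i (reaction time ``rt_i``) sees
    player j's choice: j must commit at least ``perception_delay`` earlier.
    ``method`` is ``"quadrature"`` (deterministic) or ``"monte_carlo"``;
    quadrature failures fall back to Monte-Carlo with a warning.
    """
    if perception_delay < 0:
        raise ValueError(f"perception_delay must be >= 0, got {perception_delay}")
    if method not in ("quadrature", "monte_carlo"):
        raise ValueError(f"unknown method {method!r}")
    if method == "quadrature":
        try:
            p12 = _prob_exceeds(rt_j, rt_i, perception_delay)
            p21 = _prob_exceeds(rt_i, rt_j, perception_delay)
            return p12, p21
        except (FloatingPointError, integrate.IntegrationWarning) as exc:
            warnings.warn(
                f"quadrature failed ({exc}); falling back to Monte-Carlo",
                RuntimeWarning, stacklevel=2)
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    ti = rt_i.sample(gen, n_samples)
    tj = rt_j.sample(gen, n_samples)
    p12 = float(np.mean(tj + perception_delay < ti))
    p21 = float(np.mean(ti + perception_delay < tj))
    return p12, p21
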