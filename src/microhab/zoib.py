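"""Zero-and-one-inflated beta (ZOIB) distribution.

A proportion observed on a quadrat can be exactly 0 (category absent), exactly 1
(category fills the quadrat), or anything in between. The ZOIB distribution
models this as a mixture: with probability ``alpha`` the value is an atom drawn
from a Bernoulli (1 with probability ``gamma``, else 0), and with probability
``1 - alpha`` it is drawn from a beta distribution on the open interval,
parameterised by its mean ``mu`` and precision ``phi``::

    f(y) = alpha * (1 - gamma)        if y == 0
         = alpha * gamma              if y == 1
         = (1 - alpha) * Beta(y; mu*phi, (1-mu)*phi)   if 0 < y < 1

When a dataset contains no ones, ``gamma`` is not identifiable and is fixed at
0 (and symmetrically fixed at 1 when there are no zeros); ``alpha`` then simply
gives the probability of the remaining atom.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats


class GammaMode(enum.Enum):
    """Whether the one-probability gamma is free or pinned by the data."""

    FREE = "free"
    FIXED_ZERO = "fixed_zero"  # no ones observed -> gamma = 0
    FIXED_ONE = "fixed_one"  # no zeros observed -> gamma = 1


@dataclass(frozen=True)
class ZOIBParams:
    """Mixture parameters for one observation group.

    Parameters
    ----------
    alpha : float
        Probability that the observation is an atom (0 or 1); in (0, 1).
    gamma : float
        Probability the atom equals 1; in [0, 1], with the endpoints allowed
        only when ``gamma_fixed`` pins them.
    mu : float
        Mean of the beta component; in (0, 1).
    phi : float
        Precision of the beta component; > 0. The beta shapes are
        ``a = mu * phi`` and ``b = (1 - mu) * phi``.
    """

    alpha: float
    gamma: float
    mu: float
    phi: float
    gamma_fixed: GammaMode = GammaMode.FREE

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"gamma must lie in [0, 1], got {self.gamma}")
        if self.gamma in (0.0, 1.0) and self.gamma_fixed is GammaMode.FREE:
            raise ValueError(
                "gamma may equal 0 or 1 only when gamma_fixed pins it "
                "(gamma_fixed=FIXED_ZERO or FIXED_ONE)"
            )
        if self.gamma_fixed is GammaMode.FIXED_ZERO and self.gamma != 0.0:
            raise ValueError("gamma_fixed=FIXED_ZERO requires gamma == 0")
        if self.gamma_fixed is GammaMode.FIXED_ONE and self.gamma != 1.0:
            raise ValueError("gamma_fixed=FIXED_ONE requires gamma == 1")
        if not 0.0 < self.mu < 1.0:
            raise ValueError(f"mu must lie in (0, 1), got {self.mu}")
        if not self.phi > 0.0:
            raise ValueError(f"phi must be positive, got {self.phi}")


def beta_density_mp(y: float, mu: float, phi: float) -> float:
    """Beta density in the mean/precision parameterisation.

    Evaluates ``Beta(y; a=mu*phi, b=(1-mu)*phi)``. The atoms at 0 and 1 belong
    to the mixture, not to this component, so ``y`` must be strictly interior.
    """
    if not 0.0 < y < 1.0:
        raise ValueError(f"y must lie strictly in (0, 1), got {y}")
    if not 0.0 < mu < 1.0:
        raise ValueError(f"mu must lie in (0, 1), got {mu}")
    if not phi > 0.0:
        raise ValueError(f"phi must be positive, got {phi}")
    return float(stats.beta.pdf(y, mu * phi, (1.0 - mu) * phi))


def zoib_logpdf(y, params: ZOIBParams):
    """Log density/mass of the ZOIB mixture at ``y`` (scalar or array).

    Returns ``log(alpha*(1-gamma))`` at 0, ``log(alpha*gamma)`` at 1 and
    ``log(1-alpha) + log Beta(y; mu*phi, (1-mu)*phi)`` in between. An atom
    whose probability is zero (a pinned gamma) yields ``-inf`` there.
    """
    y_arr = np.asarray(y, dtype=float)
    if np.any((y_arr < 0.0) | (y_arr > 1.0)):
        raise ValueError("y must lie in [0, 1]")
    a, g = params.alpha, params.gamma
    with np.errstate(divide="ignore"):
        log_p0 = math.log(a) + (math.log1p(-g) if g < 1.0 else -math.inf)
        log_p1 = (math.log(a) + math.log(g)) if g > 0.0 else -math.inf
        interior = (y_arr > 0.0) & (y_arr < 1.0)
        out = np.empty_like(y_arr)
        out[y_arr == 0.0] = log_p0
        out[y_arr == 1.0] = log_p1
        if np.any(interior):
            out[interior] = math.log1p(-a) + stats.beta.logpdf(
                y_arr[interior], params.mu * params.phi, (1.0 - params.mu) * params.phi
            )
    if np.isscalar(y) or y_arr.ndim == 0:
        return float(out)
    return out


def zoib_sample(n: int, params: ZOIBParams, seed) -> np.ndarray:
    """Draw ``n`` i.i.d. ZOIB values; reproducible for a given ``seed``.

    ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    y = rng.beta(params.mu * params.phi, (1.0 - params.mu) * params.phi, size=n)
    is_atom = rng.random(n) < params.alpha
    is_one = rng.random(n) < params.gamma
    y[is_atom] = 0.0
    y[is_atom & is_one] = 1.0
    return y


def zoib_mean(params: ZOIBParams) -> float:
    """Expected value of the mixture: ``alpha*gamma + (1-alpha)*mu``."""
    return params.alpha * params.gamma + (1.0 - params.alpha) * params.mu
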