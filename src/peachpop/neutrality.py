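"""Neutral mutation range for Tajima's D: the beta approximation.

Under neutrality and in the large-S limit, Tajima's D is confined to a
sample-size-dependent interval [d_min, d_max]: the minimum is attained when
every segregating site is a singleton, the maximum when every site is at
intermediate frequency (derived count n/2 for even n, (n±1)/2 for odd n).
Tajima (1989) approximates the null density of D by a beta distribution
rescaled to that support with mean 0 and variance 1; its equal-tail
quantiles give the "neutral mutation range" against which windowed D values
are judged. Windows whose D falls strictly outside the range are candidate
targets of selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

from scipy.stats import beta as _beta

from .diversity import tajima_constants


@dataclass(frozen=True)
class NeutralRange:
    """Confidence limits of Tajima's D under neutrality for sample size n."""

    n: int
    level: float
    d_min: float
    d_max: float
    alpha: float
    beta: float
    lower: float
    upper: float

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lower + self.upper)

    def cdf(self, d: float) -> float:
        """Null CDF of D under the rescaled beta approximation."""
        u = (d - self.d_min) / (self.d_max - self.d_min)
        return float(_beta.cdf(u, self.beta, self.alpha))


def d_bounds(n: int) -> tuple[float, float]:
    """Theoretical extremes of Tajima's D for n sequences (large-S limit).

    d_min = (2/n - 1/a1)/sqrt(e2); d_max uses the maximal per-site pairwise
    heterozygosity, n/(2(n-1)) for even n and (n+1)/(2n) for odd n.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    c = tajima_constants(n)
    sqrt_e2 = math.sqrt(c.e2)
    d_min = (2.0 / n - 1.0 / c.a1) / sqrt_e2
    pi_max = n / (2.0 * (n - 1.0)) if n % 2 == 0 else (n + 1.0) / (2.0 * n)
    d_max = (pi_max - 1.0 / c.a1) / sqrt_e2
    return d_min, d_max


def d_confidence_limits(n: int, level: float = 0.95) -> NeutralRange:
    """Equal-tail confidence limits of D from the rescaled beta density.

    The beta parameters are fixed by requiring mean 0 and variance 1 on the
    support [d_min, d_max]; limits are the (1-level)/2 and 1-(1-level)/2
    quantiles, computed numerically from the beta CDF.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    d_min, d_max = d_bounds(n)
    span = d_max - d_min
    alpha = -(1.0 + d_min * d_max) * d_max / span
    beta = (1.0 + d_min * d_max) * d_min / span
    if alpha <= 0 or beta <= 0:
        raise ValueError(f"beta approximation infeasible for n={n}")
    tail = (1.0 - level) / 2.0
    # D = d_min + span*U with U ~ Beta(beta, alpha)
    lower = d_min + span * float(_beta.ppf(tail, beta, alpha))
    upper = d_min + span * float(_beta.ppf(1.0 - tail, beta, alpha))
    return NeutralRange(n, level, d_min, d_max, alpha, beta, lower, upper)


def selective_judgment(neutral_range: NeutralRange) -> Callable[[float], bool]:
    """Predicate that is True exactly when D lies strictly outside the range.

    Undefined D (NaN/None) is never judged selected.
    """

    def judge(d: float | None) -> bool:
        if d is None or math.isnan(d):
            return False
        return d < neutral_range.lower or d > neutral_range.upper

    return judge
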