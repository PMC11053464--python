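"""Study-design arithmetic for a prevalence survey of an infinite population.

The recruitment target for a prevalence-based study is the smallest number of
participants ``n`` satisfying

    n >= z_alpha^2 * p * (1 - p) / d^2

where ``z_alpha`` is the standard-normal quantile of the confidence level,
``p`` the expected prevalence of the condition, and ``d`` the maximum
permissible error (all proportions).  A population headcount is obtained by
scaling a census figure by the prevalence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["DesignParams", "required_sample_size", "prevalence_count"]


@dataclass(frozen=True)
class DesignParams:
    """Inputs to the infinite-population sample-size formula.

    z_alpha : standard-normal quantile for the confidence level (1.96 for 95%)
    prevalence : expected proportion of the condition, in [0, 1]
    margin : maximum permissible error, a proportion in (0, 1]
    """

    z_alpha: float
    prevalence: float
    margin: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError(f"prevalence must lie in [0, 1], got {self.prevalence}")
        if self.margin <= 0.0:
            raise ValueError(f"margin must be positive, got {self.margin}")
        if self.z_alpha < 0.0:
            raise ValueError(f"z_alpha must be non-negative, got {self.z_alpha}")


def required_sample_size(params: DesignParams) -> int:
    """Smallest integer n with n >= z^2 p (1-p) / d^2.

    Rounds up: a fractional participant requirement always costs one more
    whole participant.
    """
    p = params.prevalence
    raw = params.z_alpha**2 * p * (1.0 - p) / params.margin**2
    # guard against floating-point values a hair above an exact integer
    return math.ceil(round(raw, 9))


def prevalence_count(population: int, prevalence: float) -> int:
    """Expected headcount of the condition in a finite population.

    Uses round-half-away-from-zero, i.e. 0.5 rounds up.
    """
    if population < 0:
        raise ValueError(f"population must be non-negative, got {population}")
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError(f"prevalence must lie in [0, 1], got {prevalence}")
    return int(math.floor(population * prevalence + 0.5))
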