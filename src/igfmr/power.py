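"""Power calculation for MR with a binary outcome, and unit conversions.

Uses the standard normal approximation for a two-sample MR analysis of a
case-control outcome: the IVW estimate of the log odds ratio per SD of
exposure has (approximate) variance 1 / (n · R² · K(1-K)), where n is the
total outcome sample size, K the case fraction and R² the exposure variance
explained by the instruments. Power against a two-sided test at level α is

    power = Φ( |ln OR| · sqrt(n · R² · K(1-K)) − z_{1−α/2} )

and inverting at a target power gives the minimum detectable odds ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats


class PowerDesignError(Exception):
    pass


@dataclass(frozen=True)
class PowerDesign:
    """Design inputs for a binary-outcome MR power calculation.

    n: total outcome sample size (cases + controls);
    k_frac: proportion of cases, in (0,1);
    r2: exposure variance explained by the instrument set, in (0,1);
    alpha: two-sided significance level; target_power: in (0,1).
    """

    n: int
    k_frac: float
    r2: float
    alpha: float = 0.05
    target_power: float = 0.80

    def __post_init__(self) -> None:
        if self.n < 1:
            raise PowerDesignError("n must be >= 1")
        for name in ("k_frac", "r2", "alpha", "target_power"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise PowerDesignError(f"{name} must be strictly inside (0,1), got {v}")

    @property
    def information(self) -> float:
        """n · R² · K(1-K): the Fisher-information proxy of the design."""
        return self.n * self.r2 * self.k_frac * (1 - self.k_frac)


def power_binary(design: PowerDesign, or_alt: float) -> float:
    """Power to detect an odds ratio ``or_alt`` per SD of exposure."""
    if or_alt <= 0:
        raise PowerDesignError(f"or_alt must be > 0, got {or_alt}")
    z_alpha = stats.norm.ppf(1 - design.alpha / 2)
    ncp = abs(math.log(or_alt)) * math.sqrt(design.information)
    return float(stats.norm.cdf(ncp - z_alpha))


def min_detectable_or(design: PowerDesign, direction: str = "protective") -> float:
    """Minimum detectable odds ratio at the design's target power.

    ``protective`` returns the OR below 1 (exp(-|ln OR|)); ``harmful`` the
    OR above 1. Under this approximation the two are exact reciprocals.
    """
    if direction not in ("protective", "harmful"):
        raise PowerDesignError(f"direction must be 'protective' or 'harmful', got {direction!r}")
    z_alpha = stats.norm.ppf(1 - design.alpha / 2)
    z_power = stats.norm.ppf(design.target_power)
    abs_log_or = (z_power + z_alpha) / math.sqrt(design.information)
    return math.exp(-abs_log_or) if direction == "protective" else math.exp(abs_log_or)


def sd_from_iqr(iqr: float) -> float:
    """SD from an interquartile range, assuming approximate normality.

    For a normal variable IQR = 2 Φ⁻¹(0.75) σ ≈ 1.349 σ, so SD ≈ IQR/1.35
    in large samples.
    """
    if iqr <= 0:
        raise PowerDesignError(f"iqr must be > 0, got {iqr}")
    return iqr / 1.35
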