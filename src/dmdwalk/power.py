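"""Two-arm trial sample size as a function of residual outcome variability.

Better prognosis shrinks the unexplained SD of the annualized 6MWD change,
and the required sample size of a two-arm trial falls with the square of that
SD.  The classical normal-approximation formula for a two-sided test with
equal allocation is

    n_per_arm = ceil( 2 sigma^2 (z_{1-alpha/2} + z_{power})^2 / delta^2 ),

where delta is the detectable between-arm difference in mean Δ6MWD.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import pandas as pd
from scipy import stats

from .errors import ConfigError

__all__ = ["PowerConfig", "PowerCurve", "required_n", "unrounded_n", "sample_size_curve"]


@dataclass(frozen=True)
class PowerConfig:
    alpha: float = 0.05  # two-sided significance level
    power: float = 0.80
    delta: float = 30.0  # detectable difference in mean Δ6MWD, m/year
    sigma_range: tuple[float, ...] = (50.0, 60.0, 70.0, 80.0, 90.0, 100.0)

    def validate(self) -> None:
        if not (0 < self.alpha < 1):
            raise ConfigError("alpha must lie in (0, 1)")
        if not (0 < self.power < 1):
            raise ConfigError("power must lie in (0, 1)")
        if self.delta <= 0:
            raise ConfigError("delta must be strictly positive")
        if not self.sigma_range or any(s <= 0 for s in self.sigma_range):
            raise ConfigError("sigma_range must be non-empty with positive entries")


def unrounded_n(sigma: float, config: PowerConfig | None = None) -> float:
    """Exact (real-valued) per-arm sample size before ceiling."""
    config = config or PowerConfig()
    config.validate()
    if sigma <= 0:
        raise ConfigError("sigma must be strictly positive")
    z_a = stats.norm.ppf(1.0 - config.alpha / 2.0)
    z_b = stats.norm.ppf(config.power)
    return 2.0 * sigma**2 * (z_a + z_b) ** 2 / config.delta**2


def required_n(sigma: float, config: PowerConfig | None = None) -> int:
    """Required patients per arm (ceiling of the normal-approximation formula)."""
    return int(ceil(unrounded_n(sigma, config)))


@dataclass
class PowerCurve:
    config: PowerConfig
    table: pd.DataFrame  # columns: sigma, n_per_arm, unrounded_n, ratio_vs_max_sigma


def sample_size_curve(config: PowerConfig | None = None) -> PowerCurve:
    """Per-arm sample size across a range of residual SDs.

    Ratios are relative to the largest sigma in the range and are computed on
    the unrounded n, so ratio(s1, s2) = (s1/s2)^2 exactly.
    """
    config = config or PowerConfig()
    config.validate()
    sigmas = sorted(config.sigma_range)
    ref = unrounded_n(max(sigmas), config)
    rows = [
        {
            "sigma": s,
            "n_per_arm": required_n(s, config),
            "unrounded_n": unrounded_n(s, config),
            "ratio_vs_max_sigma": unrounded_n(s, config) / ref,
        }
        for s in sigmas
    ]
    return PowerCurve(config=config, table=pd.DataFrame(rows))
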