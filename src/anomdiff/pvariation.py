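"""Dyadic p-variation statistic and the trend-based mechanism verdict.

For a series X_0 … X_{2^m} observed on [0, T], the level-n partial
p-variation at grid time t_j is

    V_p^n(t_j) = Σ_i |X_{i·2^{m−n}} − X_{(i−1)·2^{m−n}}|^p,

the sum running over complete dyadic blocks of span 2^{m−n} that end at or
before t_j.  Level n = 0 is the coarsest partition (one increment), level
n = m the finest (every grid step).  The level dependence of V_p^n(T)
discriminates mechanisms:

* FBM/FLSM with self-similarity H: V_p^n(T) is level-stable at p = 1/H
  (E V ≈ const) while at p = 2 it trends monotonically across levels
  (growing for H < 1/2, shrinking for H > 1/2);
* a trapped CTRW path is piecewise constant, so V_p^n(·) is step-like in
  t_j, with a large fraction of flat increments at the finest level.

Non-dyadic input is truncated from the end to the largest usable length
2^m + 1 — padding would fabricate increments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ParameterError
from .observables import TimeSeries

__all__ = [
    "PVariationProfile",
    "PVariationVerdict",
    "pvariation_profile",
    "pvariation_test",
]

TREND_THRESHOLD = 0.8   # |Spearman rho| above which V_p^n(T) counts as trending
FLAT_THRESHOLD = 0.5    # flat-increment fraction above which a path is step-dominated
MIN_TREND_LEVEL = 3     # levels with < 2^3 increments are single-draw noise


@dataclass
class PVariationProfile:
    """V_p^n(t_j) for n = 0 … levels on the (truncated) dyadic grid."""

    p: float
    levels: np.ndarray        # n = 0 … max level
    times: np.ndarray         # t_j, truncated dyadic grid (2^m + 1 points)
    values: np.ndarray        # shape (len(levels), len(times))
    m: int                    # dyadic exponent of the usable length
    n_truncated: int = 0      # trailing samples dropped to reach 2^m + 1

    def endpoint(self) -> np.ndarray:
        """V_p^n(T) across levels."""
        return self.values[:, -1]

    def to_long_frame(self):
        """Long-format view (p, n, t_j, value) for CSV serialization."""
        import pandas as pd

        n_levels, n_times = self.values.shape
        return pd.DataFrame(
            {
                "p": np.full(n_levels * n_times, self.p),
                "n": np.repeat(self.levels, n_times),
                "t": np.tile(self.times, n_levels),
                "value": self.values.ravel(),
            }
        )


@dataclass
class PVariationVerdict:
    """Outcome of the p-variation heuristics."""

    verdict: str              # fbm_flsm_like | ctrw_like | inconclusive
    rho_p2: float             # level trend of the p=2 profile
    rho_ph: float             # level trend of the p=1/h profile
    flat_fraction: float      # fraction of zero path increments (finest level)
    p_h: float                # the 1/h_hat order used
    profiles: tuple = ()


def pvariation_profile(series: TimeSeries, p: float, levels: int) -> PVariationProfile:
    """Exact partial dyadic p-variation sums at levels 0 … ``levels``."""
    if p <= 0:
        raise ParameterError(f"p must be positive, got {p}")
    if levels < 0:
        raise ParameterError(f"levels must be >= 0, got {levels}")
    x = np.asarray(series.values, dtype=float)
    length = len(x)
    m = int(np.floor(np.log2(length - 1)))
    usable = 2**m + 1
    if levels > m:
        raise ParameterError(
            f"levels ({levels}) exceeds log2 of usable length ({m})"
        )
    n_truncated = length - usable
    x = x[:usable]
    times = np.asarray(series.times, dtype=float)[:usable]
    values = np.empty((levels + 1, usable))
    for n in range(levels + 1):
        span = 2 ** (m - n)
        incs = x[span::span] - x[:-span:span]
        cum = np.concatenate([[0.0], np.cumsum(np.abs(incs) ** p)])
        values[n] = cum[np.arange(usable) // span]
    return PVariationProfile(
        p=p,
        levels=np.arange(levels + 1),
        times=times,
        values=values,
        m=m,
        n_truncated=n_truncated,
    )


def _level_trend(profile: PVariationProfile) -> float:
    """Spearman rank correlation of V_p^n(T) against n, over levels with at
    least 2^MIN_TREND_LEVEL increments (coarser levels are one or a few
    draws and carry no trend information)."""
    keep = profile.levels >= MIN_TREND_LEVEL
    if keep.sum() < 3:
        keep = np.ones(len(profile.levels), dtype=bool)
    v = profile.endpoint()[keep]
    n = profile.levels[keep]
    if len(v) < 3 or np.allclose(v, v[0]):
        return 0.0
    rho = stats.spearmanr(n, v).statistic
    return 0.0 if np.isnan(rho) else float(rho)


def pvariation_test(
    series: TimeSeries,
    h_hat: float,
    levels: int | None = None,
    trend_threshold: float = TREND_THRESHOLD,
    flat_threshold: float = FLAT_THRESHOLD,
) -> PVariationVerdict:
    """Trend/step heuristics on the p = 2 and p = 1/h_hat profiles.

    * *step-dominated* (CTRW-like): the fraction of exactly-flat path
      increments at the finest dyadic level exceeds ``flat_threshold`` —
      trapping leaves the rendered path constant most of the time;
    * *FBM/FLSM-like*: the p = 1/h_hat profile is level-stable
      (|ρ| ≤ ``trend_threshold``) while the p = 2 profile trends
      monotonically across levels;
    * otherwise inconclusive (including degenerate constant series).
    """
    if not 0 < h_hat < 1:
        raise ParameterError(f"h_hat must lie in (0,1), got {h_hat}")
    length = len(series)
    m = int(np.floor(np.log2(length - 1)))
    if levels is None:
        levels = m
    p_h = 1.0 / h_hat
    prof2 = pvariation_profile(series, 2.0, levels)
    profh = pvariation_profile(series, p_h, levels)
    x = np.asarray(series.values)[: 2**prof2.m + 1]
    dx = np.abs(np.diff(x))
    scale = dx.max() if dx.size else 0.0
    if scale == 0.0:
        return PVariationVerdict(
            verdict="inconclusive", rho_p2=0.0, rho_ph=0.0,
            flat_fraction=1.0, p_h=p_h, profiles=(prof2, profh),
        )
    flat_fraction = float(np.mean(dx <= 1e-12 * scale))
    rho2 = _level_trend(prof2)
    rhoh = _level_trend(profh)
    if flat_fraction > flat_threshold:
        verdict = "ctrw_like"
    elif abs(rhoh) <= trend_threshold and abs(rho2) > trend_threshold:
        verdict = "fbm_flsm_like"
    else:
        verdict = "inconclusive"
    return PVariationVerdict(
        verdict=verdict, rho_p2=rho2, rho_ph=rhoh,
        flat_fraction=flat_fraction, p_h=p_h, profiles=(prof2, profh),
    )
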