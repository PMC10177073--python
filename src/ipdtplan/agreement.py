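"""Lin's concordance correlation coefficient and the phantom benchmark.

The concordance correlation coefficient (CCC) measures agreement between
two paired series, penalizing both correlation loss and location/scale
shift:

    rho_c = 2 s_xy / (s_x^2 + s_y^2 + (xbar - ybar)^2)

with population (divide-by-n) moments. The confidence interval uses the
asymptotic normal approximation of the Fisher z-transform of rho_c
(Lin 1989); the CI method is recorded in the result metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

#: Solid-phantom dosimetry benchmark: isotropic-detector measurements at
#: radial distances from a 2 cm diffuser emitting 100 mW/cm in a block
#: with mu_a = 0.224 1/cm and mu_s' = 4.99 1/cm at 630 nm, alongside the
#: two published FEM solvers' computed irradiances at the same points.
PHANTOM_BENCHMARK = pd.DataFrame(
    {
        "distance_mm": [5.0, 10.0, 15.0, 20.0, 25.0],
        "measured_mW_cm2": [46.7, 15.1, 4.7, 1.4, 0.4],
        "measured_sd_mW_cm2": [3.4, 0.8, 0.2, 0.09, 0.03],
        "comsol_mW_cm2": [47.0, 13.6, 4.4, 1.5, 0.5],
        "dosie_mW_cm2": [50.5, 12.7, 4.0, 1.3, 0.5],
    }
)


@dataclass(frozen=True)
class PairedSeries:
    """Two equal-length paired measurement series (n >= 3, no missing)."""

    x: np.ndarray
    y: np.ndarray
    labels: list | None = None

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("x and y must be equal-length 1D series")
        if len(x) < 3:
            raise ValueError("need at least 3 pairs")
        if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
            raise ValueError("missing or non-finite values are not allowed")


@dataclass(frozen=True)
class CCCResult:
    ccc: float
    ci_low: float
    ci_high: float
    n: int
    level: float = 0.95
    method: str = "Lin z-transform"

    def __post_init__(self) -> None:
        if not (-1.0 <= self.ccc <= 1.0):
            raise ValueError("CCC must lie in [-1, 1]")
        if not (self.ci_low <= self.ccc <= self.ci_high):
            raise ValueError("CI must bracket the point estimate")


def _moments(pairs: PairedSeries):
    x, y = pairs.x, pairs.y
    mx, my = x.mean(), y.mean()
    sx2, sy2 = x.var(), y.var()  # population convention
    sxy = np.mean((x - mx) * (y - my))
    return mx, my, sx2, sy2, sxy


def ccc(pairs: PairedSeries) -> float:
    """Lin's concordance correlation coefficient (population moments)."""
    mx, my, sx2, sy2, sxy = _moments(pairs)
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0:
        raise ValueError("CCC undefined: both series are constant and equal")
    return float(2.0 * sxy / denom)


def ccc_ci(pairs: PairedSeries, level: float = 0.95) -> CCCResult:
    """CCC with its asymptotic confidence interval.

    Fisher z-transform of rho_c with Lin's (1989) variance, back-
    transformed and clamped to [-1, 1]; the interval degenerates to a
    point when rho_c = +-1 exactly.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    n = len(pairs.x)
    c = ccc(pairs)
    if abs(c) >= 1.0:
        return CCCResult(c, c, c, n, level)
    mx, my, sx2, sy2, sxy = _moments(pairs)
    if sx2 == 0 or sy2 == 0:
        raise ValueError("CI undefined when a series has zero variance")
    r = sxy / math.sqrt(sx2 * sy2)
    u = (mx - my) / (sx2 * sy2) ** 0.25
    z = math.atanh(c)
    var_z = (
        (1 - r * r) * c * c / ((1 - c * c) * r * r)
        + 2 * c**3 * (1 - c) * u * u / (r * (1 - c * c) ** 2)
        - c**4 * u**4 / (2 * r * r * (1 - c * c) ** 2)
    ) / (n - 2)
    half = norm.ppf(0.5 + level / 2.0) * math.sqrt(max(var_z, 0.0))
    lo = max(-1.0, math.tanh(z - half))
    hi = min(1.0, math.tanh(z + half))
    return CCCResult(c, lo, hi, n, level)


def phantom_validation_report(
    simulated,
    measured: list[tuple[float, float]] | None = None,
    distances_mm=None,
) -> tuple[pd.DataFrame, CCCResult]:
    """Per-distance comparison table and CCC between simulation and bench.

    ``measured`` is a list of (mean, sd) pairs; defaults to the published
    phantom benchmark, as do the distances.
    """
    simulated = np.asarray(simulated, dtype=float)
    if measured is None:
        measured = list(
            zip(
                PHANTOM_BENCHMARK["measured_mW_cm2"],
                PHANTOM_BENCHMARK["measured_sd_mW_cm2"],
            )
        )
    if distances_mm is None:
        distances_mm = PHANTOM_BENCHMARK["distance_mm"].to_numpy()
    means = np.array([m for m, _ in measured], dtype=float)
    sds = np.array([s for _, s in measured], dtype=float)
    if not (len(simulated) == len(means) == len(distances_mm)):
        raise ValueError("simulated, measured and distances must have equal length")
    table = pd.DataFrame(
        {
            "distance_mm": np.asarray(distances_mm, dtype=float),
            "measured_mW_cm2": means,
            "measured_sd_mW_cm2": sds,
            "simulated_mW_cm2": simulated,
        }
    )
    result = ccc_ci(PairedSeries(simulated, means))
    return table, result
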