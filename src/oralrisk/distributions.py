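"""Parametric sampling distributions fitted to printed summary statistics.

Field surveys of this kind publish quartiles (P25/median/P75) for
concentrations and median/mean pairs for exposure factors, not raw data.
To propagate uncertainty these summaries are turned into sampling
distributions.  The default family is the lognormal: concentrations and
intake rates are nonnegative and right-skewed, and the lognormal is the
conventional choice for environmental exposure variables.

Two fitting schemes are provided:

``fit_from_quartiles(p25, median, p75)``
    Lognormal with the log-median pinned to ln(median) and the log-sd set
    from the quartile spread: sigma = mean(ln(median/p25), ln(p75/median))
    / 0.6745, where 0.6745 is the standard normal upper quartile.  The
    median is honoured exactly; an asymmetric quartile spread is averaged
    (a least-squares alternative is available via ``method="lsq"``).

``fit_from_median_mean(median, mean)``
    Lognormal with ln(median) as log-median and log-variance
    2*ln(mean/median), which makes the analytic arithmetic mean equal the
    supplied mean exactly.  When mean < median (left skew, incompatible
    with a lognormal) the fit falls back to a truncated normal centred on
    the mean with sd = mean * sqrt(2*ln(median/mean)) — the mirror image of
    the lognormal spread-from-skew relation — and a warning is logged.

Degenerate inputs (zero spread) collapse to a point mass.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

_Z75 = 0.6744897501960817  # standard normal 75th percentile

__all__ = ["FittedDistribution", "fit_from_quartiles", "fit_from_median_mean", "sample"]


@dataclass(frozen=True)
class FittedDistribution:
    """A fitted sampling distribution.

    ``family`` is one of ``lognormal`` (location = log-median, scale =
    log-sd), ``normal`` (location = mean, scale = sd) or ``point_mass``
    (location = the value, scale = 0).  ``truncation`` is a lower bound
    enforced at sampling time (default 0, physical quantities cannot be
    negative); ``upper`` optionally bounds from above.
    """

    family: str
    location: float
    scale: float
    truncation: float = 0.0
    upper: float | None = None

    def __post_init__(self) -> None:
        if self.family not in ("lognormal", "normal", "point_mass"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.scale < 0:
            raise ValueError("scale must be >= 0")
        if self.family == "point_mass" and self.scale != 0:
            raise ValueError("a point mass has zero scale")

    # -- analytic summaries -------------------------------------------------
    def median(self) -> float:
        if self.family == "lognormal":
            return math.exp(self.location)
        return self.location

    def mean(self) -> float:
        """Analytic mean of the untruncated distribution."""
        if self.family == "lognormal":
            return math.exp(self.location + self.scale**2 / 2.0)
        return self.location

    def quantile(self, q: float) -> float:
        """Untruncated quantile (used to check fit fidelity)."""
        from scipy.stats import norm

        z = norm.ppf(q)
        if self.family == "lognormal":
            return math.exp(self.location + self.scale * z)
        if self.family == "normal":
            return self.location + self.scale * z
        return self.location

    def scaled(self, factor: float) -> "FittedDistribution":
        """The distribution of ``factor * X`` (factor > 0)."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        if self.family == "lognormal":
            return FittedDistribution(
                "lognormal",
                self.location + math.log(factor),
                self.scale,
                self.truncation * factor,
                None if self.upper is None else self.upper * factor,
            )
        return FittedDistribution(
            self.family,
            self.location * factor,
            self.scale * factor,
            self.truncation * factor,
            None if self.upper is None else self.upper * factor,
        )

    # -- sampling -----------------------------------------------------------
    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if n < 1:
            raise ValueError("n must be >= 1")
        if self.family == "point_mass" or self.scale == 0.0:
            return np.full(n, float(self.location))
        draws = np.empty(n)
        filled = 0
        # rejection sampling against the truncation bounds; the bounds are
        # far in the tails for every shipped calibration, so this rarely
        # loops more than once
        while filled < n:
            m = n - filled
            if self.family == "lognormal":
                block = np.exp(self.location + self.scale * rng.standard_normal(m))
            else:
                block = self.location + self.scale * rng.standard_normal(m)
            ok = block >= self.truncation
            if self.upper is not None:
                ok &= block <= self.upper
            accepted = block[ok]
            draws[filled : filled + accepted.size] = accepted
            filled += accepted.size
        return draws

    def to_spec(self, variable: str = "", source_row: str = "") -> dict:
        """JSON-serialisable spec: {variable, family, params, source_row}."""
        params = {
            "location": self.location,
            "scale": self.scale,
            "truncation": self.truncation,
        }
        if self.upper is not None:
            params["upper"] = self.upper
        return {
            "variable": variable,
            "family": self.family,
            "params": params,
            "source_row": source_row,
        }

    @classmethod
    def from_spec(cls, spec: dict) -> "FittedDistribution":
        p = spec["params"]
        return cls(
            spec["family"],
            p["location"],
            p["scale"],
            p.get("truncation", 0.0),
            p.get("upper"),
        )

    def to_json(self, variable: str = "", source_row: str = "") -> str:
        return json.dumps(self.to_spec(variable, source_row), indent=1)


def fit_from_quartiles(
    p25: float, median: float, p75: float, method: str = "average"
) -> FittedDistribution:
    """Fit a lognormal to printed quartiles (P25, median, P75).

    Three constraints, two parameters: the median is honoured exactly and the
    two half-spreads are combined.  ``method="average"`` (default) averages
    ln(median/p25) and ln(p75/median); ``method="lsq"`` is the least-squares
    fit on the log quartiles, which instead uses (ln p75 - ln p25)/2 for the
    spread and the mean log-quartile for the location.  Equal quartiles give
    a point mass.
    """
    if not (0 < p25 <= median <= p75):
        raise ValueError(
            f"quartiles must satisfy 0 < p25 <= median <= p75, got "
            f"({p25}, {median}, {p75})"
        )
    if p25 == p75:
        return FittedDistribution("point_mass", float(median), 0.0)
    if method == "average":
        mu = math.log(median)
        sigma = 0.5 * (math.log(median / p25) + math.log(p75 / median)) / _Z75
    elif method == "lsq":
        mu = (math.log(p25) + math.log(median) + math.log(p75)) / 3.0
        sigma = (math.log(p75) - math.log(p25)) / (2.0 * _Z75)
    else:
        raise ValueError(f"unknown fitting method {method!r}")
    return FittedDistribution("lognormal", mu, sigma)


def fit_from_median_mean(median: float, mean: float) -> FittedDistribution:
    """Fit a lognormal to a (median, mean) pair.

    Requires median > 0.  mean >= median (right skew) gives a lognormal whose
    analytic mean reproduces ``mean`` exactly; mean == median collapses to a
    point mass; mean < median falls back to a truncated normal (see module
    docstring) with a logged warning.
    """
    if median <= 0:
        raise ValueError(f"median must be positive, got {median}")
    if mean == median:
        return FittedDistribution("point_mass", float(median), 0.0)
    if mean < median:
        sd = mean * math.sqrt(2.0 * math.log(median / mean))
        logger.warning(
            "mean (%g) < median (%g) is incompatible with a lognormal; "
            "falling back to a truncated normal(mean=%g, sd=%g)",
            mean,
            median,
            mean,
            sd,
        )
        return FittedDistribution("normal", float(mean), sd)
    sigma = math.sqrt(2.0 * math.log(mean / median))
    return FittedDistribution("lognormal", math.log(median), sigma)


def sample(dist: FittedDistribution, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` reproducible samples from a fitted distribution."""
    return dist.sample(n, np.random.default_rng(seed))
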