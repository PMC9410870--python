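"""Baseline lifetime distributions for the TIHLBX-G family.

A baseline enters the family only through its cumulative hazard
``H(x) = -log(1 - G(x))`` because every transform the generator applies is a
function of the odds ``G/(1-G) = exp(H) - 1``.  Each member therefore needs
just three ingredients: ``H``, ``log H'`` and the inverse ``H^{-1}``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Baseline", "weibull", "exponential", "lomax", "BASELINE_NAMES"]

BASELINE_NAMES = ("weibull", "exponential", "lomax")

# number of free parameters and their conventional names
_PARAM_NAMES = {
    "weibull": ("beta", "delta"),
    "exponential": ("delta",),
    "lomax": ("a", "b"),
}


@dataclass(frozen=True)
class Baseline:
    """A baseline CDF ``G`` on (0, inf), identified by name and parameter vector.

    Parameterizations:

    * ``weibull``  -- theta = (beta, delta), G(x) = 1 - exp(-delta * x**beta)
    * ``exponential`` -- theta = (delta,),   G(x) = 1 - exp(-delta * x)
    * ``lomax``    -- theta = (a, b),        G(x) = 1 - (1 + x/b)**(-a)
    """

    name: str
    theta: tuple

    def __post_init__(self):
        if self.name not in BASELINE_NAMES:
            raise ValueError(
                f"unknown baseline {self.name!r}; choose from {BASELINE_NAMES}"
            )
        theta = tuple(float(t) for t in self.theta)
        if len(theta) != len(_PARAM_NAMES[self.name]):
            raise ValueError(
                f"baseline {self.name!r} takes {len(_PARAM_NAMES[self.name])} "
                f"parameter(s) {_PARAM_NAMES[self.name]}, got {len(theta)}"
            )
        if not all(np.isfinite(t) and t > 0 for t in theta):
            raise ValueError(f"baseline parameters must be finite and positive, got {theta}")
        object.__setattr__(self, "theta", theta)

    @property
    def param_names(self) -> tuple:
        return _PARAM_NAMES[self.name]

    # -- cumulative hazard H(x) = -log(1 - G(x)) and friends ----------------

    def cum_hazard(self, x):
        x = np.asarray(x, dtype=float)
        if self.name == "weibull":
            beta, delta = self.theta
            return delta * x**beta
        if self.name == "exponential":
            (delta,) = self.theta
            return delta * x
        a, b = self.theta
        return a * np.log1p(x / b)

    def log_hazard(self, x):
        """log H'(x), the log of the baseline hazard rate."""
        x = np.asarray(x, dtype=float)
        if self.name == "weibull":
            beta, delta = self.theta
            return np.log(beta * delta) + (beta - 1.0) * np.log(x)
        if self.name == "exponential":
            (delta,) = self.theta
            return np.full_like(x, np.log(delta))
        a, b = self.theta
        return np.log(a) - np.log(b + x)

    def inv_cum_hazard(self, y):
        """x such that H(x) = y, for y >= 0."""
        y = np.asarray(y, dtype=float)
        if self.name == "weibull":
            beta, delta = self.theta
            return (y / delta) ** (1.0 / beta)
        if self.name == "exponential":
            (delta,) = self.theta
            return y / delta
        a, b = self.theta
        return b * np.expm1(y / a)

    def cdf(self, x):
        return -np.expm1(-self.cum_hazard(x))

    def pdf(self, x):
        return np.exp(self.log_hazard(x) - self.cum_hazard(x))


def weibull(beta: float, delta: float) -> Baseline:
    """Weibull baseline with G(x) = 1 - exp(-delta * x**beta)."""
    return Baseline("weibull", (beta, delta))


def exponential(delta: float) -> Baseline:
    """Exponential baseline, the beta = 1 Weibull special case."""
    return Baseline("exponential", (delta,))


def lomax(a: float, b: float) -> Baseline:
    """Lomax (Pareto II) baseline with G(x) = 1 - (1 + x/b)**(-a)."""
    return Baseline("lomax", (a, b))
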