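"""Declarative random-variable specifications for life-history traits.

Every stochastic vital rate in the model (egg/larval durations, weights,
batch fecundity, mortality noise, ...) is declared as a
:class:`DistributionSpec` so that a configuration is a plain, serializable
document and sampling is centralized and reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["DistributionSpec", "sample", "constant", "normal", "uniform", "discrete_uniform"]

_FAMILIES = ("normal", "uniform", "discrete_uniform", "constant")

#: minimum probability mass a truncation region may retain before sampling
#: refuses to rejection-sample from it
_MIN_TRUNC_MASS = 1e-6


class DistributionError(ValueError):
    """Invalid distribution specification or degenerate truncation."""


@dataclass(frozen=True)
class DistributionSpec:
    """A univariate random variable: family, parameters, optional truncation.

    Parameters
    ----------
    family:
        One of ``normal`` (params: mean, sd), ``uniform`` (params: low, high),
        ``discrete_uniform`` (params: support values, optionally followed by
        ``probs`` weights) or ``constant`` (params: value).
    params:
        Ordered real parameters for the family.
    truncation:
        Optional ``(lower, upper)`` bounds; either may be ``None``. Sampling
        rejects draws outside the bounds.
    units:
        Free-text unit annotation, carried through serialization.
    """

    family: str
    params: tuple = ()
    truncation: tuple | None = None
    units: str = ""
    probs: tuple | None = None  # only for discrete_uniform with unequal weights

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise DistributionError(f"unknown family {self.family!r}; expected one of {_FAMILIES}")
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))
        if self.probs is not None:
            object.__setattr__(self, "probs", tuple(float(p) for p in self.probs))
        self._validate()

    def _validate(self) -> None:
        fam, p = self.family, self.params
        if fam == "normal":
            if len(p) != 2:
                raise DistributionError("normal requires (mean, sd)")
            if p[1] <= 0:
                raise DistributionError(f"normal sd must be > 0, got {p[1]}")
        elif fam == "uniform":
            if len(p) != 2:
                raise DistributionError("uniform requires (low, high)")
            if not p[0] < p[1]:
                raise DistributionError(f"uniform requires low < high, got {p}")
        elif fam == "constant":
            if len(p) != 1:
                raise DistributionError("constant requires a single value")
        elif fam == "discrete_uniform":
            if len(p) < 1:
                raise DistributionError("discrete_uniform requires a nonempty support")
            if self.probs is not None:
                if len(self.probs) != len(p):
                    raise DistributionError("probs length must match support length")
                if any(q < 0 for q in self.probs):
                    raise DistributionError("probs must be nonnegative")
                if abs(sum(self.probs) - 1.0) > 1e-12:
                    raise DistributionError("probs must sum to 1 within 1e-12")
        if self.truncation is not None:
            lo, hi = self.truncation
            if lo is not None and hi is not None and not lo < hi:
                raise DistributionError(f"truncation requires lower < upper, got {self.truncation}")

    # -- moments of the *untruncated* family (validation & diagnostics) -----
    @property
    def mean(self) -> float:
        fam, p = self.family, self.params
        if fam == "normal":
            return p[0]
        if fam == "uniform":
            return 0.5 * (p[0] + p[1])
        if fam == "constant":
            return p[0]
        w = self.probs if self.probs is not None else [1 / len(p)] * len(p)
        return float(np.dot(p, w))

    def truncation_mass(self) -> float:
        """Probability the untruncated draw lands inside the truncation bounds."""
        if self.truncation is None:
            return 1.0
        lo, hi = self.truncation
        lo = -np.inf if lo is None else lo
        hi = np.inf if hi is None else hi
        fam, p = self.family, self.params
        if fam == "normal":
            d = stats.norm(p[0], p[1])
            return float(d.cdf(hi) - d.cdf(lo))
        if fam == "uniform":
            a, b = p
            return max(0.0, (min(hi, b) - max(lo, a)) / (b - a))
        if fam == "constant":
            return 1.0 if lo <= p[0] <= hi else 0.0
        w = self.probs if self.probs is not None else [1 / len(p)] * len(p)
        return float(sum(wi for v, wi in zip(p, w) if lo <= v <= hi))

    def to_dict(self) -> dict:
        d = {"family": self.family, "params": list(self.params)}
        if self.truncation is not None:
            d["truncation"] = list(self.truncation)
        if self.units:
            d["units"] = self.units
        if self.probs is not None:
            d["probs"] = list(self.probs)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DistributionSpec":
        unknown = set(d) - {"family", "params", "truncation", "units", "probs"}
        if unknown:
            raise DistributionError(f"unknown distribution keys: {sorted(unknown)}")
        trunc = d.get("truncation")
        return cls(
            family=d["family"],
            params=tuple(d.get("params", ())),
            truncation=tuple(trunc) if trunc is not None else None,
            units=d.get("units", ""),
            probs=tuple(d["probs"]) if d.get("probs") is not None else None,
        )


def sample(spec: DistributionSpec, rng: np.random.Generator, size: int | None = None):
    """Draw from ``spec``, rejection-resampling until inside truncation bounds.

    Deterministic given the generator state. Raises
    :class:`DistributionError` when the truncation region retains less than
    1e-6 probability mass (which would make rejection sampling effectively
    an infinite loop).
    """
    if spec.truncation is not None and spec.truncation_mass() < _MIN_TRUNC_MASS:
        raise DistributionError(
            f"truncation {spec.truncation} retains <{_MIN_TRUNC_MASS} mass for {spec.family}{spec.params}"
        )
    n = 1 if size is None else int(size)
    out = _draw(spec, rng, n)
    if spec.truncation is not None:
        lo, hi = spec.truncation
        lo = -np.inf if lo is None else lo
        hi = np.inf if hi is None else hi
        bad = (out < lo) | (out > hi)
        while bad.any():
            out[bad] = _draw(spec, rng, int(bad.sum()))
            bad = (out < lo) | (out > hi)
    return float(out[0]) if size is None else out


def _draw(spec: DistributionSpec, rng: np.random.Generator, n: int) -> np.ndarray:
    fam, p = spec.family, spec.params
    if fam == "normal":
        return rng.normal(p[0], p[1], size=n)
    if fam == "uniform":
        return rng.uniform(p[0], p[1], size=n)
    if fam == "constant":
        return np.full(n, p[0])
    support = np.asarray(p)
    return rng.choice(support, size=n, p=spec.probs)


# -- convenience constructors ------------------------------------------------

def constant(value: float, units: str = "") -> DistributionSpec:
    return DistributionSpec("constant", (value,), units=units)


def normal(mean: float, sd: float, truncation: tuple | None = None, units: str = "") -> DistributionSpec:
    return DistributionSpec("normal", (mean, sd), truncation=truncation, units=units)


def uniform(low: float, high: float, units: str = "") -> DistributionSpec:
    return DistributionSpec("uniform", (low, high), units=units)


def discrete_uniform(values, probs=None, units: str = "") -> DistributionSpec:
    return DistributionSpec("discrete_uniform", tuple(values), units=units,
                            probs=tuple(probs) if probs is not None else None)
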