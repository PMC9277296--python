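"""Parameter-distribution specifications for population draws and bounds.

A spec is either a :class:`DistributionSpec` instance or a plain mapping such
as ``{"kind": "uniform", "low": 1, "high": 5}`` or ``{"kind": "normal",
"mean": 0, "variance": 4}``.  Normal specs accept either ``variance`` or
``std`` (exactly one); reported figures in the source experiments write
``N(m, v)`` with ``v`` a variance, which is the reading used by the presets.

Analytic CDFs (needed by the residual-error bound) are delegated to
``scipy.stats``.  A spec built from :meth:`DistributionSpec.from_sampler`
carries only a sampling callable; its CDF is then estimated by Monte Carlo.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
from scipy import stats

__all__ = ["DistributionSpec", "as_distribution"]


@dataclass(frozen=True)
class DistributionSpec:
    kind: str
    params: tuple[float, ...]
    _sampler: Callable | None = None

    # -- constructors -------------------------------------------------------
    @staticmethod
    def uniform(low: float, high: float) -> "DistributionSpec":
        if not (high > low):
            raise ValueError(f"uniform requires high > low, got [{low}, {high}]")
        return DistributionSpec("uniform", (float(low), float(high)))

    @staticmethod
    def normal(mean: float, variance: float | None = None, std: float | None = None) -> "DistributionSpec":
        if (variance is None) == (std is None):
            raise ValueError("normal requires exactly one of variance= or std=")
        if variance is not None:
            if variance <= 0:
                raise ValueError(f"variance must be > 0, got {variance}")
            std = float(np.sqrt(variance))
        if std <= 0:
            raise ValueError(f"std must be > 0, got {std}")
        return DistributionSpec("normal", (float(mean), float(std)))

    @staticmethod
    def from_sampler(sampler: Callable[[np.random.Generator, int], np.ndarray]) -> "DistributionSpec":
        """Wrap an arbitrary ``sampler(rng, n) -> array``; CDF via Monte Carlo."""
        return DistributionSpec("custom", (), sampler)

    # -- behaviour ----------------------------------------------------------
    def _frozen(self):
        if self.kind == "uniform":
            low, high = self.params
            return stats.uniform(loc=low, scale=high - low)
        if self.kind == "normal":
            mean, std = self.params
            return stats.norm(loc=mean, scale=std)
        raise ValueError(f"no analytic form for kind={self.kind!r}")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.kind == "uniform":
            low, high = self.params
            return rng.uniform(low, high, size=n)
        if self.kind == "normal":
            mean, std = self.params
            return rng.normal(mean, std, size=n)
        if self.kind == "custom":
            out = np.asarray(self._sampler(rng, n), dtype=float)
            if out.shape != (n,):
                raise ValueError("custom sampler returned wrong shape")
            return out
        raise ValueError(f"unknown distribution kind {self.kind!r}")

    def cdf(self, x: float, mc_samples: int = 10**6, seed: int = 0) -> float:
        """P[X <= x]; analytic where possible, Monte Carlo for custom specs."""
        if self.kind in ("uniform", "normal"):
            return float(self._frozen().cdf(x))
        if self.kind == "custom":
            rng = np.random.default_rng(seed)
            draws = self.sample(rng, mc_samples)
            return float(np.mean(draws <= x))
        raise ValueError(f"unknown distribution kind {self.kind!r}")

    def sf(self, x: float, **kw) -> float:
        """P[X > x]."""
        return 1.0 - self.cdf(x, **kw)


def as_distribution(spec, variance_convention: bool = True) -> DistributionSpec:
    """Coerce a mapping / tuple / DistributionSpec into a DistributionSpec.

    ``variance_convention`` controls how a bare second normal parameter is
    read when the mapping uses the positional form ``("normal", m, s2)``.
    """
    if isinstance(spec, DistributionSpec):
        return spec
    if isinstance(spec, Mapping):
        kind = spec.get("kind")
        if kind == "uniform":
            _check_keys(spec, {"kind", "low", "high"})
            return DistributionSpec.uniform(spec["low"], spec["high"])
        if kind == "normal":
            _check_keys(spec, {"kind", "mean", "variance", "std"})
            return DistributionSpec.normal(
                spec["mean"], variance=spec.get("variance"), std=spec.get("std")
            )
        raise ValueError(f"unknown distribution kind {kind!r}")
    if isinstance(spec, (tuple, list)) and len(spec) == 3:
        kind, a, b = spec
        if kind == "uniform":
            return DistributionSpec.uniform(a, b)
        if kind == "normal":
            if variance_convention:
                return DistributionSpec.normal(a, variance=b)
            return DistributionSpec.normal(a, std=b)
    raise TypeError(f"cannot interpret distribution spec {spec!r}")


def _check_keys(mapping: Mapping, allowed: set) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ValueError(f"unknown distribution keys: {sorted(unknown)}")
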