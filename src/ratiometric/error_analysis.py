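"""Event-driven error maps and the residual steady-state error bound.

Between membership events the control error ``e = r_d - r_B`` is constant;
at an event it changes by exactly ``1/N`` (down for an A->B switch, up for
B->A).  Combining this quantized update with each feedback law yields a
one-dimensional discrete map for the error sampled at event times:

* relay with shutdown (and PI): ``e -> e - sgn(e)/N`` with fixed point 0;
* bang-bang relay: as above for ``e != 0`` but ``0 -> -1/N``, so iterates end
  on the period-2 orbit ``{0, -1/N}``.

When part of the population cannot be switched by any admissible input, the
error cannot reach zero from a worst-case initial configuration; the residual
bound ``e_r = e_r0 + e_ru`` quantifies this from the eta distribution alone:
``e_r0`` is the monostable fraction ``P[eta <= 0]`` and ``e_ru`` accounts for
unswitchable cells (``eta > eta_hat``) stuck in the wrong group, in the
worst case where all of them start there.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .distributions import as_distribution
from .memory_model import eta_hat

__all__ = [
    "ResidualBound",
    "error_map_relay1",
    "error_map_relay2",
    "error_map_generic",
    "residual_bound",
    "EquivalenceReport",
    "verify_event_equivalence",
]


def error_map_relay1(e: float, n: int) -> float:
    """One event under the relay-with-shutdown law: ``e - sgn(e)/N``."""
    if n <= 0:
        raise ValueError("N must be positive")
    if e > 0:
        return e - 1.0 / n
    if e < 0:
        return e + 1.0 / n
    return e


def error_map_relay2(e: float, n: int) -> float:
    """One event under the bang-bang relay: zero maps to ``-1/N``."""
    if n <= 0:
        raise ValueError("N must be positive")
    if e > 0:
        return e - 1.0 / n
    if e < 0:
        return e + 1.0 / n
    return -1.0 / n


def error_map_generic(e: float, n: int, direction: str) -> float:
    """Controller-agnostic event update: A->B lowers e by 1/N, B->A raises it."""
    if direction == "A->B":
        return e - 1.0 / n
    if direction == "B->A":
        return e + 1.0 / n
    raise ValueError(f"direction must be 'A->B' or 'B->A', got {direction!r}")


@dataclass(frozen=True)
class ResidualBound:
    """Worst-case steady-state error bound and its two components."""

    e_r0: float
    e_ru: float
    eta_hat: float
    p_unswitchable: float
    u_max: float
    r_d: float

    @property
    def e_r(self) -> float:
        return self.e_r0 + self.e_ru

    def to_json(self) -> str:
        d = asdict(self)
        d["e_r"] = self.e_r
        return json.dumps(d, indent=2, sort_keys=True)


def residual_bound(eta_dist, u_max: float, r_d: float, **cdf_kw) -> ResidualBound:
    """Residual steady-state error bound for a given eta distribution.

    ``e_r0 = P[eta <= 0]`` (monostable fraction); with
    ``p = P[eta > eta_hat(u_max)]`` the unswitchable component is
    ``e_ru = max(0, p - r_d, p - (1 - r_d))`` — nonzero exactly when the
    unswitchable cells alone can overfill one of the two target groups.
    Both are population-fraction limits for N -> infinity.  ``cdf_kw`` is
    forwarded to the distribution's CDF (Monte Carlo controls for custom
    specs).
    """
    if not 0.0 <= r_d <= 1.0:
        raise ValueError(f"r_d must lie in [0, 1], got {r_d}")
    dist = as_distribution(eta_dist)
    thresh = eta_hat(u_max)
    e_r0 = dist.cdf(0.0, **cdf_kw)
    p_unsw = dist.sf(thresh, **cdf_kw)
    e_ru = max(0.0, p_unsw - r_d, p_unsw - (1.0 - r_d))
    return ResidualBound(e_r0=float(e_r0), e_ru=float(e_ru), eta_hat=float(thresh),
                         p_unswitchable=float(p_unsw), u_max=float(u_max), r_d=float(r_d))


@dataclass(frozen=True)
class EquivalenceReport:
    passed: bool
    n_events: int
    first_mismatch: int | None = None
    expected: float | None = None
    observed: float | None = None

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.passed


def verify_event_equivalence(trajectory, controller: str | None = None) -> EquivalenceReport:
    """Replay a run's event log through the matching discrete error map.

    Starting from the initial error, each logged event advances the map
    prediction, which must agree with the error the simulator sampled just
    after that event to within half a quantum ``1/(2N)``.  ``controller``
    defaults to the one recorded in the trajectory metadata; the relay maps
    are used for the relay laws and the PI (whose event map coincides with
    the shutdown relay's), the direction-based generic map otherwise.
    """
    n = int(trajectory.meta["N"])
    kind = controller or trajectory.meta.get("controller", "open_loop")
    tol = 0.5 / n

    def predict(e: float, direction: str) -> float:
        if kind in ("relay_shutdown", "pi"):
            return error_map_relay1(0.0 if abs(e) < tol else e, n)
        if kind == "relay_bangbang":
            return error_map_relay2(0.0 if abs(e) < tol else e, n)
        return error_map_generic(e, n, direction)

    e = float(trajectory.meta.get("e0", trajectory.samples["e"].iloc[0]))
    for k, ev in enumerate(trajectory.events):
        e_pred = predict(e, ev.direction)
        if abs(e_pred - ev.e_after) > tol:
            return EquivalenceReport(False, len(trajectory.events), k, e_pred, ev.e_after)
        e = ev.e_after
    return EquivalenceReport(True, len(trajectory.events))
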