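"""Feedback laws for ratiometric control: two relays and an anti-windup PI.

All three act on the scalar control error ``e = r_d - r_B`` and emit a shared
input bounded by ``u_max``:

* relay with shutdown: ``u = u_max*sgn(e)``, and 0 when the error is zero
  (the loop can be switched off once the target ratio is reached, so the
  error then stays at zero indefinitely);
* bang-bang relay: ``u = u_max`` for ``e >= 0`` and ``-u_max`` otherwise —
  never silent, so the closed loop ends up oscillating within one quantum
  ``1/N`` of the target;
* PI with saturation and an anti-windup reset that zeroes the integrator
  whenever the error vanishes or changes sign.

The relays are pure functions; the PI carries its integrator in a
:class:`ControllerState` and is advanced with :func:`pi_step` (forward Euler
on the integrator, reset applied before the accumulation of the current
step).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

__all__ = [
    "ControllerState",
    "relay_with_shutdown",
    "relay_bang_bang",
    "pi_step",
    "make_controller",
    "Controller",
]


@dataclass(frozen=True)
class ControllerState:
    """Integrator state of the PI law; ``z(0) = 0`` by construction."""

    z: float = 0.0
    e_prev: float | None = None
    t_last_switch: float = 0.0


def relay_with_shutdown(e: float, u_max: float, dead_zone: float = 0.0) -> float:
    """Three-level relay: ``u_max`` if ``e > 0``, ``-u_max`` if ``e < 0``, else 0.

    ``dead_zone`` widens the shutdown branch to ``|e| <= dead_zone``; the
    closed-loop simulators pass ``1/(2N)`` there so the quantized error is
    recognized as zero robustly in floating point.
    """
    if u_max <= 0:
        raise ValueError(f"u_max must be > 0, got {u_max}")
    if abs(e) <= dead_zone:
        return 0.0
    return u_max if e > 0 else -u_max


def relay_bang_bang(e: float, u_max: float) -> float:
    """Two-level relay: ``u_max`` if ``e >= 0`` else ``-u_max`` (never zero)."""
    if u_max <= 0:
        raise ValueError(f"u_max must be > 0, got {u_max}")
    return u_max if e >= 0 else -u_max


def pi_step(
    e: float,
    state: ControllerState,
    k_p: float,
    k_i: float,
    u_max: float,
    dt: float,
    zero_tol: float = 0.0,
) -> tuple[float, ControllerState]:
    """One sampled PI update: reset-if-needed, integrate, saturate.

    The anti-windup reset zeroes ``z`` when ``|e| <= zero_tol`` or when the
    error changed sign since the previous call; the integrator is then
    advanced by forward Euler (``z += e*dt``) and the output clamped to
    ``[-u_max, u_max]``.
    """
    if k_p < 0 or k_i < 0:
        raise ValueError("gains must be nonnegative")
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    z = state.z
    sign_change = state.e_prev is not None and (
        (e > 0 > state.e_prev) or (e < 0 < state.e_prev)
    )
    if abs(e) <= zero_tol or sign_change:
        z = 0.0
    z = z + e * dt
    u = k_p * e + k_i * z
    u = min(u_max, max(-u_max, u))
    return u, replace(state, z=z, e_prev=e)


class Controller:
    """Stateful adapter used by the closed-loop simulators.

    ``step(e, dt)`` returns the input to hold over the next interval of
    length ``dt``; relays ignore ``dt``.  ``zero_tol`` is the half-quantum
    threshold used both for the shutdown branch and the PI reset.
    """

    def __init__(self, kind: str, u_max: float, k_p: float = 0.0, k_i: float = 0.0,
                 dead_zone: float = 0.0, zero_tol: float = 0.0, u_const: float = 0.0):
        kinds = {"relay_shutdown", "relay_bangbang", "pi", "open_loop", "constant"}
        if kind not in kinds:
            raise ValueError(f"controller kind must be one of {sorted(kinds)}, got {kind!r}")
        self.kind = kind
        self.u_max = u_max
        self.k_p = k_p
        self.k_i = k_i
        self.dead_zone = dead_zone
        self.zero_tol = zero_tol
        self.u_const = u_const
        self.state = ControllerState()

    def reset(self) -> None:
        self.state = ControllerState()

    def step(self, e: float, dt: float) -> float:
        if self.kind == "open_loop":
            return 0.0
        if self.kind == "constant":
            return self.u_const
        if abs(e) <= self.zero_tol:
            # e is quantized in steps of 1/N; anything inside the half-quantum
            # band is the zero state up to floating-point accumulation.
            e = 0.0
        if self.kind == "relay_shutdown":
            return relay_with_shutdown(e, self.u_max, self.dead_zone)
        if self.kind == "relay_bangbang":
            return relay_bang_bang(e, self.u_max)
        u, self.state = pi_step(
            e, self.state, self.k_p, self.k_i, self.u_max, dt, zero_tol=self.zero_tol
        )
        return u

    def copy(self) -> "Controller":
        c = Controller(self.kind, self.u_max, self.k_p, self.k_i,
                       self.dead_zone, self.zero_tol, self.u_const)
        c.state = self.state
        return c


def make_controller(spec, u_max: float | None = None, n_cells: int | None = None) -> Controller:
    """Build a :class:`Controller` from a name or config mapping.

    When ``n_cells`` is given, the zero tolerance defaults to ``1/(2N)`` —
    half the quantum by which the measured ratio error can change — so exact
    shutdown/reset conditions trigger reliably on the quantized error.
    """
    if isinstance(spec, Controller):
        return spec
    if isinstance(spec, str):
        spec = {"kind": spec}
    spec = dict(spec)
    kind = spec.pop("kind")
    umax = spec.pop("u_max", u_max)
    if umax is None:
        if kind in ("open_loop", "constant"):
            umax = max(1.0, abs(spec.get("u_const", 0.0)))
        else:
            raise ValueError("u_max must be given in the mapping or as an argument")
    zero_tol = spec.pop("zero_tol", None)
    if zero_tol is None:
        zero_tol = 0.5 / n_cells if n_cells else 0.0
    ctrl = Controller(
        kind,
        umax,
        k_p=spec.pop("k_p", 0.0),
        k_i=spec.pop("k_i", 0.0),
        dead_zone=spec.pop("dead_zone", 0.0),
        zero_tol=zero_tol,
        u_const=spec.pop("u_const", 0.0),
    )
    if spec:
        raise ValueError(f"unknown controller keys: {sorted(spec)}")
    return ctrl
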