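"""Scalar bistable normal form of a reversible differentiable cell.

Each cell carries a one-dimensional memory element

    dx/dt = eta * x - x**3 + u,

where ``x`` is the macroscopic state (phenotype readout), ``eta`` the
cell-specific bifurcation parameter and ``u`` a bounded input shared by the
whole population.  For ``eta > 0`` and ``u = 0`` the system is bistable with
stable equilibria at ``-sqrt(eta)`` (phenotype A) and ``+sqrt(eta)``
(phenotype B), separated by the unstable equilibrium at the origin.  Sweeping
``u`` past the saddle-node (fold) input ``2*(eta/3)**1.5`` annihilates one of
the stable branches, which is what lets an external signal flip the memory.

Given an input bound ``u_max``, the eta axis splits into three regimes:

* ``eta <= 0``             -- monostable: the memory is lost;
* ``0 < eta < eta_hat``    -- controllable: an admissible input can switch it;
* ``eta >= eta_hat``       -- unswitchable: bistable for every admissible input,

with ``eta_hat = (27 * u_max**2 / 4) ** (1/3)`` the controllability threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "CellParams",
    "EquilibriumSet",
    "MONOSTABLE",
    "CONTROLLABLE",
    "UNSWITCHABLE",
    "equilibria",
    "eta_hat",
    "fold_input",
    "classify_cell",
    "classify_population",
    "drift",
]

#: Tolerance on |eta - 3 x^2| below which a root is labelled a fold point.
FOLD_TOL = 1e-9

MONOSTABLE = "monostable"
CONTROLLABLE = "controllable"
UNSWITCHABLE = "unswitchable"


@dataclass(frozen=True)
class CellParams:
    """Per-cell bistability parameter and identifier."""

    eta: float
    id: int = 0

    def __post_init__(self) -> None:
        if not math.isfinite(self.eta):
            raise ValueError(f"eta must be finite, got {self.eta!r}")


@dataclass(frozen=True)
class EquilibriumSet:
    """Real equilibria of the cubic at a fixed input, with stability labels.

    ``roots`` are sorted ascending; ``stability`` holds one of ``"stable"``,
    ``"unstable"`` or ``"fold"`` per root, determined by the sign of the
    linearization ``eta - 3 x**2``.
    """

    roots: tuple[float, ...]
    stability: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if len(self.roots) != len(self.stability):
            raise ValueError("roots and stability must have equal length")

    @property
    def stable_roots(self) -> tuple[float, ...]:
        return tuple(r for r, s in zip(self.roots, self.stability) if s == "stable")

    @property
    def n_roots(self) -> int:
        return len(self.roots)


def drift(x, eta, u):
    """Right-hand side ``eta*x - x**3 + u`` (vectorized)."""
    return eta * x - x * x * x + u


def _stability_label(eta: float, x: float, tol: float) -> str:
    slope = eta - 3.0 * x * x
    if abs(slope) <= tol:
        return "fold"
    return "stable" if slope < 0.0 else "unstable"


def equilibria(eta: float, u: float, fold_tol: float = FOLD_TOL) -> EquilibriumSet:
    """All real roots of ``eta*x - x**3 + u = 0`` with stability labels.

    The depressed cubic ``x**3 - eta*x - u = 0`` is solved in closed form
    (trigonometric method for three real roots, Cardano branch otherwise) so
    the result is deterministic.  Root multiplicity is decided from the
    discriminant ``4*eta**3 - 27*u**2``; the tangency (fold) case returns two
    roots, the double one labelled ``"fold"``.
    """
    if not (math.isfinite(eta) and math.isfinite(u)):
        raise ValueError("eta and u must be finite")

    disc = 4.0 * eta**3 - 27.0 * u**2
    scale = max(1.0, abs(eta) ** 3, u * u)
    disc_tol = 1e-12 * scale

    if eta > 0.0 and abs(disc) <= disc_tol:
        if abs(u) <= disc_tol:
            # eta == 0 boundary handled below; here u ~ 0 with eta > 0 tiny.
            roots = sorted((-math.sqrt(eta), 0.0, math.sqrt(eta)))
            labels = tuple(_stability_label(eta, r, fold_tol) for r in roots)
            return EquilibriumSet(tuple(roots), labels)
        # For t^3 + p t + q with p = -eta, q = -u the double root is -3q/(2p);
        # the remaining simple root is -2 times it.
        x_d = -3.0 * u / (2.0 * eta)
        x_s = -2.0 * x_d
        roots = sorted((x_d, x_s))
        labels = tuple(
            "fold" if math.isclose(r, x_d, rel_tol=0.0, abs_tol=1e-12 * max(1.0, abs(x_d)))
            else _stability_label(eta, r, fold_tol)
            for r in roots
        )
        return EquilibriumSet(tuple(roots), labels)

    if disc > disc_tol:
        # Three distinct real roots (requires eta > 0): Viete's formula.
        m = 2.0 * math.sqrt(eta / 3.0)
        arg = 3.0 * u / (eta * m)  # = cos(3 theta)
        arg = min(1.0, max(-1.0, arg))
        theta = math.acos(arg) / 3.0
        roots = sorted(m * math.cos(theta - 2.0 * math.pi * k / 3.0) for k in range(3))
    else:
        # Single real root: Cardano with the numerically stable branch.
        p, q = -eta, -u
        # t = cbrt(-q/2 + sqrt(q^2/4 + p^3/27)) + cbrt(-q/2 - sqrt(...))
        half_q = q / 2.0
        inner = half_q * half_q + (p / 3.0) ** 3
        s = math.sqrt(max(inner, 0.0))
        t1 = math.copysign(abs(-half_q + s) ** (1.0 / 3.0), -half_q + s)
        t2 = math.copysign(abs(-half_q - s) ** (1.0 / 3.0), -half_q - s)
        root = t1 + t2
        # One Newton polish step keeps the closed form at full precision.
        f = root**3 + p * root + q
        fp = 3.0 * root * root + p
        if fp != 0.0:
            root -= f / fp
        roots = [root]

    labels = tuple(_stability_label(eta, r, fold_tol) for r in roots)
    return EquilibriumSet(tuple(roots), labels)


def eta_hat(u_max: float) -> float:
    """Controllability threshold ``(27 * u_max**2 / 4) ** (1/3)``.

    Cells with ``0 < eta < eta_hat(u_max)`` can be switched between their two
    stable states by some admissible input ``|u| <= u_max``; monotone
    nondecreasing in ``u_max`` with ``eta_hat(0) = 0``.
    """
    if u_max < 0:
        raise ValueError(f"u_max must be >= 0, got {u_max}")
    return (27.0 * u_max * u_max / 4.0) ** (1.0 / 3.0)


def fold_input(eta: float) -> float:
    """Saddle-node input magnitude ``2*(eta/3)**1.5`` for a bistable cell.

    Inverse of :func:`eta_hat` on the positive reals: an input of magnitude
    greater than ``fold_input(eta)`` leaves a single, globally attracting
    equilibrium whose sign is the sign of the input.
    """
    if eta <= 0:
        raise ValueError(f"fold_input requires eta > 0 (no fold exists), got {eta}")
    return 2.0 * (eta / 3.0) ** 1.5


def classify_cell(eta: float, u_max: float) -> str:
    """Controllability class of a cell under input bound ``u_max``.

    Returns one of :data:`MONOSTABLE` (``eta <= 0``), :data:`CONTROLLABLE`
    (``0 < eta < eta_hat``) or :data:`UNSWITCHABLE` (``eta >= eta_hat``).
    """
    if u_max < 0:
        raise ValueError(f"u_max must be >= 0, got {u_max}")
    if eta <= 0.0:
        return MONOSTABLE
    if eta < eta_hat(u_max):
        return CONTROLLABLE
    return UNSWITCHABLE


def classify_population(etas: Sequence[float] | np.ndarray, u_max: float) -> np.ndarray:
    """Vectorized :func:`classify_cell`; returns an array of class labels."""
    etas = np.asarray(etas, dtype=float)
    thresh = eta_hat(u_max)
    out = np.where(etas <= 0.0, MONOSTABLE, np.where(etas < thresh, CONTROLLABLE, UNSWITCHABLE))
    return out
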