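"""Agent-based, well-mixed chamber of E. coli cells carrying an inducible
toggle switch, controlled in closed loop through aTc/IPTG actuation.

Each cell is a six-state ODE: two mRNAs and two proteins of the mutually
repressing LacI/TetR pair, plus internal concentrations of the two inducers
(aTc, which sequesters TetR and so de-represses LacI; IPTG, which sequesters
LacI and de-represses TetR) relaxing toward the chamber concentrations by
first-order membrane exchange.  Kinetic defaults are the parameter set of the
Lugagne et al. (2017) inducible toggle switch, the circuit this layer models;
all are overridable.  Units: minutes, a.u. for mRNA/protein, ng/ml for aTc,
mM for IPTG.

Population dynamics: cells advance a division clock at a phenotype-dependent
rate, divide when it elapses (daughter inherits the mother's concentrations),
and the chamber removes uniformly random cells above its capacity, emulating
flush-out from a microfluidic trap.  Flush-out is the dominant source of
steady-state ratio fluctuations; their magnitude scales like
``1/sqrt(capacity)``.  Multiplicative biochemical noise on the production
terms (Euler-Maruyama) is on by default, mirroring the stochastic regime of
the microfluidic experiments this layer emulates; it also desynchronizes
lineages, which otherwise would respond to the shared input in lockstep.

The closed loop samples the phenotype ratio every ``sampling_period`` minutes
and actuates through one of two hardware models: a T-junction (one inducer at
a time, driven by a relay) or a dial-a-wave mixer (convex combination of the
two inducers, driven by a two-channel PI with anti-windup).  Input changes
take effect after ``actuation_delay`` and, for the T-junction, no sooner than
``min_dwell`` after the previous change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .controllers import pi_step, relay_with_shutdown, ControllerState
from .population_sim import Trajectory, PopulationState

__all__ = [
    "ToggleParams",
    "ToggleCell",
    "ActuationConstraints",
    "Chamber",
    "toggle_derivatives",
    "reference_states",
    "classify_phenotype",
    "actuate_t_junction",
    "actuate_dial_a_wave",
    "step_chamber",
    "run_closed_loop",
    "fluctuation_scan",
]

# State column layout of the 6-ODE cell model.
MRNA_L, MRNA_T, LACI, TETR, ATC_IN, IPTG_IN = range(6)


@dataclass(frozen=True)
class ToggleParams:
    """Kinetics of the inducible LacI/TetR toggle switch (per-minute rates)."""

    k_m0_L: float = 3.20e-2   # basal lacI transcription
    k_m_L: float = 8.30       # regulated lacI transcription
    k_m0_T: float = 1.19e-1   # basal tetR transcription
    k_m_T: float = 2.06       # regulated tetR transcription
    g_m: float = 1.386e-1     # mRNA degradation (half-life ~5 min)
    k_p_L: float = 9.726e-1   # LacI translation
    k_p_T: float = 1.170      # TetR translation
    g_p: float = 1.65e-2      # protein degradation + dilution
    theta_LacI: float = 31.94
    theta_TetR: float = 30.00
    theta_IPTG: float = 9.06e-2
    theta_aTc: float = 11.65
    n_LacI: float = 2.0
    n_TetR: float = 2.0
    n_IPTG: float = 2.0
    n_aTc: float = 2.0
    k_in_aTc: float = 2.75e-2   # membrane exchange, inward
    k_out_aTc: float = 2.00e-2  # membrane exchange, outward
    k_in_IPTG: float = 1.62e-1
    k_out_IPTG: float = 1.11e-1


@dataclass
class ToggleCell:
    """Snapshot view of one cell (the chamber stores cells as arrays)."""

    mRNA_lacI: float
    mRNA_tetR: float
    LacI: float
    TetR: float
    aTc_int: float
    IPTG_int: float
    length_fraction: float
    label: str  # "A" (LacI-high) or "B" (TetR-high)


@dataclass(frozen=True)
class ActuationConstraints:
    """Hardware limits of the microfluidic actuation chain."""

    U_aTc: float = 60.0          # ng/ml
    U_IPTG: float = 0.5          # mM
    sampling_period: float = 5.0  # min between ratio measurements
    actuation_delay: float = 1.0  # min before an input change reaches cells
    min_dwell: float = 15.0       # min between T-junction switches
    mode: str = "t_junction"      # or "dial_a_wave"

    def __post_init__(self) -> None:
        for name in ("U_aTc", "U_IPTG", "sampling_period", "actuation_delay", "min_dwell"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.mode not in ("t_junction", "dial_a_wave"):
            raise ValueError(f"mode must be t_junction or dial_a_wave, got {self.mode!r}")


def toggle_derivatives(
    y: np.ndarray,
    u_aTc: float,
    u_IPTG: float,
    p: ToggleParams = ToggleParams(),
    mult: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Time derivatives of the 6 cell states; vectorized over rows of ``y``.

    ``y`` is ``(6,)`` or ``(n_cells, 6)``; ``mult`` optionally scales the four
    production rates (lacI/tetR transcription, LacI/TetR translation) per
    cell, modelling heritable cell-to-cell variability.  ``u_aTc``/``u_IPTG``
    may be scalars or per-cell arrays (per-cell effective exposures).
    """
    if np.any(np.asarray(u_aTc) < 0) or np.any(np.asarray(u_IPTG) < 0):
        raise ValueError("inducer concentrations must be nonnegative")
    y = np.asarray(y, dtype=float)
    single = y.ndim == 1
    Y = y[None, :] if single else y

    m_l, m_t = Y[:, MRNA_L], Y[:, MRNA_T]
    laci, tetr = Y[:, LACI], Y[:, TETR]
    atc, iptg = Y[:, ATC_IN], Y[:, IPTG_IN]

    # Free-repressor attenuation by the bound inducer.
    tetr_eff = (tetr / p.theta_TetR) / (1.0 + (atc / p.theta_aTc) ** p.n_aTc)
    laci_eff = (laci / p.theta_LacI) / (1.0 + (iptg / p.theta_IPTG) ** p.n_IPTG)

    tx_l = p.k_m0_L + p.k_m_L / (1.0 + tetr_eff**p.n_TetR)
    tx_t = p.k_m0_T + p.k_m_T / (1.0 + laci_eff**p.n_LacI)
    tl_l = p.k_p_L * m_l
    tl_t = p.k_p_T * m_t
    if mult is not None:
        tx_l = tx_l * mult[:, 0]
        tx_t = tx_t * mult[:, 1]
        tl_l = tl_l * mult[:, 2]
        tl_t = tl_t * mult[:, 3]

    d = np.empty_like(Y)
    d[:, MRNA_L] = tx_l - p.g_m * m_l
    d[:, MRNA_T] = tx_t - p.g_m * m_t
    d[:, LACI] = tl_l - p.g_p * laci
    d[:, TETR] = tl_t - p.g_p * tetr
    d[:, ATC_IN] = np.where(u_aTc > atc, p.k_in_aTc, p.k_out_aTc) * (u_aTc - atc)
    d[:, IPTG_IN] = np.where(u_IPTG > iptg, p.k_in_IPTG, p.k_out_IPTG) * (u_IPTG - iptg)
    return d[0] if single else d


def _production_terms(y: np.ndarray, p: ToggleParams, mult: Optional[np.ndarray]) -> np.ndarray:
    """Production components (transcription x2, translation x2) for the noise."""
    atc, iptg = y[:, ATC_IN], y[:, IPTG_IN]
    tetr_eff = (y[:, TETR] / p.theta_TetR) / (1.0 + (atc / p.theta_aTc) ** p.n_aTc)
    laci_eff = (y[:, LACI] / p.theta_LacI) / (1.0 + (iptg / p.theta_IPTG) ** p.n_IPTG)
    prod = np.stack(
        [
            p.k_m0_L + p.k_m_L / (1.0 + tetr_eff**p.n_TetR),
            p.k_m0_T + p.k_m_T / (1.0 + laci_eff**p.n_LacI),
            p.k_p_L * y[:, MRNA_L],
            p.k_p_T * y[:, MRNA_T],
        ],
        axis=1,
    )
    if mult is not None:
        prod = prod * mult
    return prod


_REFERENCE_CACHE: dict[tuple, dict[str, float]] = {}


def reference_states(params: ToggleParams = ToggleParams()) -> dict[str, float]:
    """High-expression levels of the two zero-input attractors (cached).

    Obtained by integrating a nominal cell to steady state from each side of
    the separatrix.  Used to normalize LacI/TetR when classifying phenotypes.
    """
    key = tuple(getattr(params, f) for f in params.__dataclass_fields__)
    if key in _REFERENCE_CACHE:
        return _REFERENCE_CACHE[key]
    out = {}
    for name, y0 in (("A", [10.0, 0.0, 1000.0, 0.0, 0.0, 0.0]),
                     ("B", [0.0, 10.0, 0.0, 1000.0, 0.0, 0.0])):
        y = np.asarray([y0], dtype=float)
        for _ in range(4000):
            y = _rk4_cells(y, 0.0, 0.0, params, None, 1.0)
        out[name] = y[0]
    ref = {
        "LacI_high": float(out["A"][LACI]),
        "TetR_high": float(out["B"][TETR]),
        "LacI_low": float(out["B"][LACI]),
        "TetR_low": float(out["A"][TETR]),
        "A_state": out["A"],
        "B_state": out["B"],
    }
    if not (ref["LacI_high"] > 5 * ref["LacI_low"] and ref["TetR_high"] > 5 * ref["TetR_low"]):
        raise RuntimeError("toggle parameters do not yield two distinct attractors at zero input")
    _REFERENCE_CACHE[key] = ref
    return ref


def classify_phenotype(
    y: np.ndarray,
    reference: dict[str, float],
    previous: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Boolean in-B vector: True where normalized TetR exceeds normalized LacI.

    Exact ties keep the previous label (or A if there is none).
    """
    y = np.asarray(y, dtype=float)
    Y = y[None, :] if y.ndim == 1 else y
    t_norm = Y[:, TETR] / reference["TetR_high"]
    l_norm = Y[:, LACI] / reference["LacI_high"]
    if previous is None:
        previous = np.zeros(Y.shape[0], dtype=bool)
    out = np.where(t_norm == l_norm, previous, t_norm > l_norm)
    return out[0] if y.ndim == 1 else out


def actuate_t_junction(
    u_scalar: float,
    c: ActuationConstraints,
    prev: Optional[tuple[float, float]] = None,
    elapsed: Optional[float] = None,
) -> tuple[float, float]:
    """Map the scalar command to a one-inducer-at-a-time output.

    Positive command (more B wanted) injects IPTG, negative injects aTc, zero
    injects neither.  If ``prev``/``elapsed`` are given and the dwell time has
    not elapsed since the last change, the previous output is held.
    """
    if u_scalar > 0:
        out = (0.0, c.U_IPTG)
    elif u_scalar < 0:
        out = (c.U_aTc, 0.0)
    else:
        out = (0.0, 0.0)
    if prev is not None and elapsed is not None and out != tuple(prev):
        if elapsed < c.min_dwell:
            return tuple(prev)
    return out


def actuate_dial_a_wave(u_scalar: float, u_max: float, c: ActuationConstraints) -> tuple[float, float]:
    """Map a bounded scalar command to a convex mixture of the two inducers.

    ``f = (u + u_max) / (2 u_max)`` selects the IPTG fraction; the outputs
    always satisfy ``u_aTc/U_aTc + u_IPTG/U_IPTG = 1``.
    """
    if u_max <= 0:
        raise ValueError("u_max must be positive")
    u = min(u_max, max(-u_max, u_scalar))
    f = (u + u_max) / (2.0 * u_max)
    return ((1.0 - f) * c.U_aTc, f * c.U_IPTG)


def _rk4_cells(Y, u_aTc, u_IPTG, params, mult, dt):
    k1 = toggle_derivatives(Y, u_aTc, u_IPTG, params, mult)
    k2 = toggle_derivatives(Y + 0.5 * dt * k1, u_aTc, u_IPTG, params, mult)
    k3 = toggle_derivatives(Y + 0.5 * dt * k2, u_aTc, u_IPTG, params, mult)
    k4 = toggle_derivatives(Y + dt * k3, u_aTc, u_IPTG, params, mult)
    return Y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)


class Chamber:
    """Capacity-limited, well-mixed pool of toggle-switch cells.

    Parameters
    ----------
    capacity : maximum number of cells retained after flush-out.
    params : toggle-switch kinetics shared by all cells.
    div_rate_A, div_rate_B : division-clock rates (1/min) of the LacI-high
        and TetR-high phenotypes; the default corresponds to a ~42 min
        doubling time, matching the protein dilution rate.
    div_jitter : half-width of the uniform per-cell division-rate jitter.
    noise_sigma : multiplicative biochemical noise intensity on production
        terms (0 disables it).
    param_cv : coefficient of variation of heritable per-cell lognormal
        multipliers on the four production rates (0 disables heterogeneity).
        Defaults to 0.2.
    exposure_sigma : log-standard-deviation of the per-cell lognormal
        attenuation factor applied to the external inducer concentrations
        (median 1, redrawn for the daughter at each division).  This is the
        well-mixed surrogate for diffusion shielding in a packed microfluidic
        trap, where interior cells see far less inducer than cells at the
        opening.  It matters qualitatively: a shared input switches identical
        fully exposed cells in lockstep, so each corrective pulse would flip
        essentially the whole population; graded exposure makes every pulse
        move only the most exposed cohort, which is what lets feedback steer
        the ratio in partial steps, as in the spatial system this layer
        emulates.  Set to 0 for uniform exposure.
    """

    def __init__(
        self,
        capacity: int = 200,
        params: ToggleParams = ToggleParams(),
        div_rate_A: float = 1.0 / 42.0,
        div_rate_B: float = 1.0 / 42.0,
        div_jitter: float = 0.1,
        noise_sigma: float = 0.05,
        param_cv: float = 0.2,
        exposure_sigma: float = 1.0,
        seed: int | np.random.Generator = 0,
    ):
        if capacity < 2:
            raise ValueError("capacity must be at least 2")
        self.capacity = int(capacity)
        self.params = params
        self.div_rate = {"A": div_rate_A, "B": div_rate_B}
        self.div_jitter = div_jitter
        self.noise_sigma = noise_sigma
        self.param_cv = param_cv
        self.exposure_sigma = exposure_sigma
        self.rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        self.t = 0.0
        self.reference = reference_states(params)
        self._warned_clip = False

        self.Y = np.zeros((0, 6))
        self.length_fraction = np.zeros(0)
        self.jitter = np.zeros(0)
        self.mult = None
        self.exposure = np.ones(0)
        self.in_b = np.zeros(0, dtype=bool)

    # -- construction -------------------------------------------------------
    def seed_cells(self, n: Optional[int] = None, frac_b: float = 0.5, state_jitter: float = 0.1) -> "Chamber":
        """Populate with ``n`` cells (default: capacity) near the two attractors.

        ``frac_b`` sets the initial TetR-high fraction; states are jittered
        multiplicatively and division clocks start uniformly spread so
        divisions are desynchronized.
        """
        n = self.capacity if n is None else int(n)
        n_b = int(round(frac_b * n))
        ref = self.reference
        Y = np.vstack([np.tile(ref["A_state"], (n - n_b, 1)),
                       np.tile(ref["B_state"], (n_b, 1))])
        Y *= np.exp(state_jitter * self.rng.standard_normal(Y.shape))
        self.Y = Y
        self.length_fraction = self.rng.uniform(0.0, 1.0, size=n)
        self.jitter = 1.0 + self.rng.uniform(-self.div_jitter, self.div_jitter, size=n)
        if self.param_cv > 0:
            self.mult = self._draw_mult(n)
        self.exposure = self._draw_exposure(n)
        self.in_b = classify_phenotype(self.Y, ref)
        return self

    def _draw_exposure(self, n: int) -> np.ndarray:
        if self.exposure_sigma <= 0:
            return np.ones(n)
        return self.rng.lognormal(mean=0.0, sigma=self.exposure_sigma, size=n)

    def _draw_mult(self, n: int) -> np.ndarray:
        # lognormal with unit mean and sd = cv
        cv = self.param_cv
        sigma = np.sqrt(np.log(1.0 + cv * cv))
        return self.rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=(n, 4))

    # -- basic queries -------------------------------------------------------
    @property
    def n(self) -> int:
        return self.Y.shape[0]

    def ratio_b(self) -> float:
        if self.n == 0:
            raise RuntimeError("chamber is extinct")
        return float(np.count_nonzero(self.in_b)) / self.n

    @property
    def cells(self) -> list[ToggleCell]:
        return [
            ToggleCell(*self.Y[i], self.length_fraction[i], "B" if self.in_b[i] else "A")
            for i in range(self.n)
        ]

    def snapshot(self) -> pd.DataFrame:
        cols = ["mRNA_lacI", "mRNA_tetR", "LacI", "TetR", "aTc_int", "IPTG_int"]
        df = pd.DataFrame(self.Y, columns=cols)
        df["length_fraction"] = self.length_fraction
        df["label"] = np.where(self.in_b, "B", "A")
        return df

    # -- dynamics ------------------------------------------------------------
    def step(self, u_aTc: float, u_IPTG: float, dt: float) -> None:
        """Advance all cells by ``dt`` minutes: ODEs, noise, growth, division,
        flush-out."""
        if dt <= 0:
            raise ValueError("dt must be positive")
        if self.n == 0:
            raise RuntimeError("chamber is extinct; cannot step")
        Y = _rk4_cells(self.Y, u_aTc * self.exposure, u_IPTG * self.exposure,
                       self.params, self.mult, dt)
        if self.noise_sigma > 0:
            prod = _production_terms(self.Y, self.params, self.mult)
            noise = self.noise_sigma * prod * np.sqrt(dt) * self.rng.standard_normal(prod.shape)
            Y[:, :4] += noise
        if np.any(Y < 0):
            if not self._warned_clip:
                warnings.warn("negative concentrations clipped to 0", RuntimeWarning,
                              stacklevel=2)
                self._warned_clip = True
            np.clip(Y, 0.0, None, out=Y)
        self.Y = Y
        self.in_b = classify_phenotype(self.Y, self.reference, previous=self.in_b)

        rates = np.where(self.in_b, self.div_rate["B"], self.div_rate["A"]) * self.jitter
        self.length_fraction = self.length_fraction + rates * dt
        self._divide()
        self._flush()
        self.t += dt

    def _divide(self) -> None:
        ready = np.nonzero(self.length_fraction >= 1.0)[0]
        if ready.size == 0:
            return
        self.length_fraction[ready] -= 1.0
        daughters_Y = self.Y[ready].copy()
        self.Y = np.vstack([self.Y, daughters_Y])
        self.length_fraction = np.concatenate(
            [self.length_fraction, np.zeros(ready.size)]
        )
        new_jitter = 1.0 + self.rng.uniform(-self.div_jitter, self.div_jitter, size=ready.size)
        self.jitter = np.concatenate([self.jitter, new_jitter])
        if self.mult is not None:
            self.mult = np.vstack([self.mult, self.mult[ready]])
        # daughters land elsewhere in the trap: exposure is redrawn, kinetics
        # (mult) are inherited
        self.exposure = np.concatenate([self.exposure, self._draw_exposure(ready.size)])
        self.in_b = np.concatenate([self.in_b, self.in_b[ready]])

    def _flush(self) -> None:
        excess = self.n - self.capacity
        if excess <= 0:
            return
        drop = self.rng.choice(self.n, size=excess, replace=False)
        keep = np.ones(self.n, dtype=bool)
        keep[drop] = False
        self.Y = self.Y[keep]
        self.length_fraction = self.length_fraction[keep]
        self.jitter = self.jitter[keep]
        if self.mult is not None:
            self.mult = self.mult[keep]
        self.exposure = self.exposure[keep]
        self.in_b = self.in_b[keep]


def step_chamber(chamber: Chamber, inputs: tuple[float, float], dt: float) -> Chamber:
    """Functional-style wrapper around :meth:`Chamber.step` (mutates and
    returns the chamber)."""
    chamber.step(inputs[0], inputs[1], dt)
    return chamber


@dataclass
class _TwoChannelPI:
    """One PI per inducer channel (aTc on e_A, IPTG on e_B), outputs
    normalized by the channel maxima and projected onto the dial-a-wave
    convex constraint."""

    k_p1: float = 100.0
    k_i1: float = 1.5
    k_p2: float = 1.5
    k_i2: float = 0.05
    zero_tol: float = 0.0
    s_a: ControllerState = field(default_factory=ControllerState)
    s_b: ControllerState = field(default_factory=ControllerState)

    def step(self, e_b: float, c: ActuationConstraints, dt: float) -> float:
        e_a = -e_b
        v_a, self.s_a = pi_step(e_a, self.s_a, self.k_p1, self.k_i1, c.U_aTc, dt,
                                zero_tol=self.zero_tol)
        v_b, self.s_b = pi_step(e_b, self.s_b, self.k_p2, self.k_i2, c.U_IPTG, dt,
                                zero_tol=self.zero_tol)
        # normalized channel commands in [-1, 1]; their difference is the
        # scalar dial-a-wave command
        return max(0.0, v_b) / c.U_IPTG - max(0.0, v_a) / c.U_aTc


def run_closed_loop(
    chamber: Chamber,
    constraints: ActuationConstraints,
    r_d: float = 0.5,
    t_end: float = 2000.0,
    dt: float = 0.5,
    controller: str = "relay",
    pi_gains: tuple[float, float, float, float] = (100.0, 1.5, 1.5, 0.05),
    dead_zone: float = 0.0,
    snapshot_final: bool = False,
) -> Trajectory:
    """Closed-loop regulation of the chamber's TetR-high fraction to ``r_d``.

    ``controller="relay"`` pairs the shutdown relay with T-junction actuation;
    ``controller="pi"`` pairs the two-channel PI with dial-a-wave actuation.
    The ratio is sampled every ``constraints.sampling_period`` minutes; input
    changes are applied ``actuation_delay`` later and T-junction switches
    respect ``min_dwell``.  Returns a trajectory sampled at measurement times
    with columns ``t, r_A, r_B, e, u, N, e_A, e_B, u_aTc, u_IPTG`` and an
    event log of actuation changes.
    """
    if controller not in ("relay", "pi"):
        raise ValueError("controller must be 'relay' or 'pi'")
    if chamber.n == 0:
        chamber.seed_cells()
    zero_tol = 0.5 / chamber.capacity
    pi = _TwoChannelPI(*pi_gains, zero_tol=zero_tol)

    current = (0.0, 0.0)        # inputs the cells currently see
    pending: Optional[tuple[float, tuple[float, float]]] = None  # (t_on, value)
    t_last_change = -np.inf
    rows = []
    switch_log = []

    n_samples = int(round(t_end / constraints.sampling_period))
    sub_steps = max(1, int(round(constraints.sampling_period / dt)))
    dt_eff = constraints.sampling_period / sub_steps

    for k in range(n_samples + 1):
        t_s = k * constraints.sampling_period
        r_b = chamber.ratio_b()
        e = r_d - r_b
        # controller + actuation at the sample instant
        if controller == "relay":
            u_scalar = relay_with_shutdown(e, 1.0, max(dead_zone, zero_tol))
            elapsed = t_s - t_last_change
            target = actuate_t_junction(u_scalar, constraints, prev=current, elapsed=elapsed)
        else:
            u_scalar = pi.step(e, constraints, constraints.sampling_period)
            target = actuate_dial_a_wave(u_scalar, 1.0, constraints)
        if target != current and (pending is None or pending[1] != target):
            pending = (t_s + constraints.actuation_delay, target)

        rows.append((
            t_s, 1.0 - r_b, r_b, e, u_scalar, chamber.n,
            -e, e, current[0], current[1],
        ))
        if k == n_samples:
            break
        # integrate to the next sample, applying any pending change on time
        for j in range(sub_steps):
            t_now = t_s + j * dt_eff
            if pending is not None and t_now >= pending[0]:
                if pending[1] != current:
                    t_last_change = t_now
                    switch_log.append((t_now, pending[1]))
                current = pending[1]
                pending = None
            chamber.step(current[0], current[1], dt_eff)

    samples = pd.DataFrame(
        rows,
        columns=["t", "r_A", "r_B", "e", "u", "N", "e_A", "e_B", "u_aTc", "u_IPTG"],
    )
    samples["u_aTc_norm"] = samples["u_aTc"] / constraints.U_aTc if constraints.U_aTc else 0.0
    samples["u_IPTG_norm"] = samples["u_IPTG"] / constraints.U_IPTG if constraints.U_IPTG else 0.0
    final = PopulationState(
        np.where(chamber.in_b, 1.0, -1.0), np.ones(chamber.n), chamber.t
    )
    meta = {
        "r_d": r_d, "t_end": t_end, "dt": dt, "controller": controller,
        "N": chamber.capacity, "mode": constraints.mode,
        "switches": switch_log,
    }
    if snapshot_final:
        meta["final_snapshot"] = chamber.snapshot()
    return Trajectory(samples, [], final, meta)


def fluctuation_scan(
    capacities: list[int],
    reps: int,
    seed: int,
    t_end: float = 1500.0,
    window_fraction: float = 0.5,
    r_d: float = 0.5,
    constraints: Optional[ActuationConstraints] = None,
    chamber_kwargs: Optional[dict] = None,
) -> pd.DataFrame:
    """Steady-state ratio fluctuation versus chamber capacity.

    For each capacity, runs ``reps`` independent relay-controlled simulations
    and records the standard deviation of ``r_B`` over the trailing
    ``window_fraction`` of each run.  Because the flush-out noise on the
    ratio scales like ``1/sqrt(capacity)`` (chamber side ~ sqrt(capacity)),
    quadrupling the capacity should halve the fluctuation.
    """
    if any(c < 10 for c in capacities):
        raise ValueError("capacities must be >= 10")
    constraints = constraints or ActuationConstraints()
    chamber_kwargs = dict(chamber_kwargs or {})
    ss = np.random.SeedSequence(seed)
    rows = []
    for cap in capacities:
        for rep in range(reps):
            child = ss.spawn(1)[0]
            rng = np.random.default_rng(child)
            chamber = Chamber(capacity=cap, seed=rng, **chamber_kwargs)
            chamber.seed_cells()
            traj = run_closed_loop(chamber, constraints, r_d=r_d, t_end=t_end)
            rb = traj.samples["r_B"].to_numpy()
            k = max(2, int(round(window_fraction * rb.size)))
            tail = rb[-k:]
            rows.append((cap, rep, float(tail.std(ddof=1)), float(tail.mean())))
    return pd.DataFrame(rows, columns=["capacity", "rep", "std_rB", "mean_rB"])
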