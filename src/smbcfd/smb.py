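"""Closed-loop simulated-moving-bed process simulation.

A four-zone SMB ring (desorbent -> extract -> feed -> raffinate, with the
recycle closing zone IV back into the desorbent node) is simulated by
integrating every column's transport-dispersive LDF model over one
switching period, advancing the ports by one column, and repeating until
the profiles become periodic (cyclic steady state, CSS).

Internally the columns are kept in the *port-fixed* frame: position 0 is
always the first column of zone I, and a port switch rotates the
concentration fields one position upstream (``new[p] = old[p + 1]``),
which is the same rotation as advancing every inlet/outlet port one
column downstream.  End-of-period states of consecutive switches are
then directly comparable, which is what both the CSS criterion and the
continuous-prediction extrapolation

    u_css(m) = u(m) + theta * [u(m) - u_css(m-1)]

operate on.  The prediction is an elementwise affine extrapolation of
the full state (both solutes, both phases, all columns) toward the
cyclic steady state; it shortens the transient without changing the
fixed point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.integrate import simpson, solve_ivp

from .column import interstitial_velocity
from .isotherms import IsothermSpec
from .operators import (
    BoundaryMethod,
    ColumnOperator,
    Coupling,
    GridSpec,
    TransportParams,
    assemble_operator,
)

__all__ = [
    "SMBConfig",
    "SMBState",
    "PeriodRecord",
    "CSSResult",
    "node_balances",
    "simulate_period",
    "port_shift",
    "continuous_prediction",
    "css_converged",
    "purity_recovery",
    "run_smb",
]

logger = logging.getLogger(__name__)

_ZONE_NAMES = ("I", "II", "III", "IV")


@dataclass(frozen=True)
class SMBConfig:
    """Full definition of a four-zone SMB process.

    Units are fixed: cm, min, mL/min, g/L, cm^2/min.  ``zone_flows`` and
    ``zone_dispersion`` are ordered zone I..IV; ``feed_conc`` and ``ke``
    are ordered (A, B) with A the more-retained component (collected at
    the extract).
    """

    column_length: float
    inner_diameter: float
    eps_b: float
    switching_time: float
    zone_flows: tuple[float, float, float, float]
    zone_dispersion: tuple[float, float, float, float]
    feed_conc: tuple[float, float]
    ke: tuple[float, float]
    isotherm: IsothermSpec
    columns_per_zone: tuple[int, int, int, int] = (2, 2, 2, 2)
    grid_points_per_column: int = 65
    boundary_method: BoundaryMethod = BoundaryMethod.PSEUDO
    css_rel_tol: float = 1e-4
    theta: float = 0.0
    max_switches: int = 300
    rtol: float = 1e-8
    atol: float = 1e-8
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "zone_flows", tuple(float(q) for q in self.zone_flows))
        object.__setattr__(self, "zone_dispersion", tuple(float(d) for d in self.zone_dispersion))
        object.__setattr__(self, "feed_conc", tuple(float(c) for c in self.feed_conc))
        object.__setattr__(self, "ke", tuple(float(k) for k in self.ke))
        object.__setattr__(self, "columns_per_zone", tuple(int(c) for c in self.columns_per_zone))
        object.__setattr__(self, "boundary_method", BoundaryMethod(self.boundary_method))
        checks = [
            (self.column_length > 0, "column_length", "must be positive"),
            (self.inner_diameter > 0, "inner_diameter", "must be positive"),
            (0 < self.eps_b < 1, "eps_b", "bed porosity must be in (0, 1)"),
            (self.switching_time >= 0, "switching_time", "must be nonnegative"),
            (min(self.zone_flows) > 0, "zone_flows", "all zone flows must be positive"),
            (min(self.zone_dispersion) > 0, "zone_dispersion", "must be positive"),
            (min(self.feed_conc) >= 0, "feed_conc",
             "feed concentrations must be nonnegative"),
            (min(self.ke) >= 0, "ke", "mass-transfer coefficients must be nonnegative"),
            (min(self.columns_per_zone) >= 1, "columns_per_zone", "each zone needs a column"),
            (self.grid_points_per_column >= 5, "grid_points_per_column", "needs at least 5"),
            (0 <= self.theta < 1, "theta", "acceleration factor must satisfy 0 <= theta < 1"),
            (self.css_rel_tol > 0, "css_rel_tol", "must be positive"),
            (self.rtol > 0 and self.atol > 0, "tolerances", "must be positive"),
        ]
        for ok, name, msg in checks:
            if not ok:
                raise ValueError(f"{name}: {msg}")
        q1, q2, q3, q4 = self.zone_flows
        for val, name in (
            (q1 - q4, "desorbent flow Q_I - Q_IV"),
            (q1 - q2, "extract flow Q_I - Q_II"),
            (q3 - q2, "feed flow Q_III - Q_II"),
            (q3 - q4, "raffinate flow Q_III - Q_IV"),
        ):
            if val <= 0:
                raise ValueError(f"zone_flows: derived {name} = {val:.4g} must be positive")

    # -- derived quantities ------------------------------------------------

    @property
    def n_columns(self) -> int:
        return sum(self.columns_per_zone)

    @property
    def desorbent_flow(self) -> float:
        return self.zone_flows[0] - self.zone_flows[3]

    @property
    def extract_flow(self) -> float:
        return self.zone_flows[0] - self.zone_flows[1]

    @property
    def feed_flow(self) -> float:
        return self.zone_flows[2] - self.zone_flows[1]

    @property
    def raffinate_flow(self) -> float:
        return self.zone_flows[2] - self.zone_flows[3]

    @property
    def phase_ratio(self) -> float:
        return (1.0 - self.eps_b) / self.eps_b

    @property
    def cross_section(self) -> float:
        return float(np.pi * (self.inner_diameter / 2.0) ** 2)

    @property
    def grid(self) -> GridSpec:
        return GridSpec(n=self.grid_points_per_column, L=self.column_length)

    @property
    def zone_velocities(self) -> tuple[float, ...]:
        return tuple(
            interstitial_velocity(q, self.eps_b, self.inner_diameter) for q in self.zone_flows
        )

    @property
    def zone_peclets(self) -> tuple[float, ...]:
        return tuple(
            v * self.column_length / d for v, d in zip(self.zone_velocities, self.zone_dispersion)
        )

    @property
    def zone_of_position(self) -> tuple[int, ...]:
        out = []
        for z, count in enumerate(self.columns_per_zone):
            out.extend([z] * count)
        return tuple(out)

    @property
    def zone_starts(self) -> tuple[int, int, int, int]:
        starts = np.concatenate([[0], np.cumsum(self.columns_per_zone)[:-1]])
        return tuple(int(s) for s in starts)

    @property
    def feed_position(self) -> int:
        return self.zone_starts[2]

    @property
    def extract_outlet(self) -> int:
        """Ring position of the column whose effluent feeds the extract draw."""
        return self.zone_starts[1] - 1

    @property
    def raffinate_outlet(self) -> int:
        return self.zone_starts[3] - 1

    def build_operators(self) -> list[ColumnOperator]:
        """One Danckwerts-coupled operator per zone (zone I..IV)."""
        grid = self.grid
        return [
            assemble_operator(
                grid,
                TransportParams(v=v, Da=d),
                self.boundary_method,
                Coupling.SMB_INLET,
            )
            for v, d in zip(self.zone_velocities, self.zone_dispersion)
        ]


@dataclass
class SMBState:
    """Liquid and solid fields for every column, in the port-fixed frame.

    ``c`` and ``q`` have shape (n_columns, 2, n): ring position (position
    0 = first column of zone I), component (A, B), grid point.
    ``switch_index`` counts completed port switches; the absolute zone
    assignment of physical column j is the initial layout rotated by
    ``switch_index`` (the fields here are already expressed relative to
    the ports, so position p always sees zone ``zone_of_position[p]``).
    """

    c: np.ndarray
    q: np.ndarray
    switch_index: int = 0

    @classmethod
    def zeros(cls, config: SMBConfig) -> "SMBState":
        shape = (config.n_columns, 2, config.grid_points_per_column)
        return cls(c=np.zeros(shape), q=np.zeros(shape), switch_index=0)

    def copy(self) -> "SMBState":
        return SMBState(self.c.copy(), self.q.copy(), self.switch_index)

    def max_liquid_diff(self, other: "SMBState") -> float:
        return float(np.max(np.abs(self.c - other.c)))


@dataclass(frozen=True)
class PeriodRecord:
    """Effluent history at the product ports over one switching period."""

    times: np.ndarray  # (nt,), covers [0, t_s] including both endpoints
    extract: np.ndarray  # (2, nt) concentrations at the extract draw
    raffinate: np.ndarray  # (2, nt)
    port_masses: np.ndarray  # (4,) integrated masses: ext A, ext B, raf A, raf B
    mid_state: SMBState | None = None  # snapshot at t_s/2


@dataclass(frozen=True)
class SwitchLog:
    switch: int
    max_change: float  # max liquid-phase change vs previous simulated period
    mass_residual: float  # period mass-balance residual relative to feed mass


@dataclass(frozen=True)
class CSSResult:
    """Outcome of a run to cyclic steady state."""

    switches_to_css: int
    converged: bool
    purities: dict
    recoveries: dict
    record: PeriodRecord
    state: SMBState  # converged (pre-prediction) state
    logs: tuple[SwitchLog, ...]
    config: SMBConfig


# ---------------------------------------------------------------------------
# Node mass balances.


def node_balances(c_out: np.ndarray, config: SMBConfig) -> np.ndarray:
    """Inlet concentrations per ring position from the current effluents.

    ``c_out`` has shape (n_columns, 2).  Within a zone a column is fed by
    its upstream neighbour unchanged; the desorbent node dilutes the
    recycle by Q_IV/Q_I; the feed node mixes Q_II of upstream effluent
    with Q_F of fresh feed into Q_III.  The extract and raffinate draws
    change flow, not composition.
    """
    q1, q2, q3, q4 = config.zone_flows
    n = config.n_columns
    c_in = np.empty_like(c_out)
    feed = np.asarray(config.feed_conc)
    for p in range(n):
        up = (p - 1) % n
        if p == 0:
            c_in[p] = q4 * c_out[up] / q1
        elif p == config.feed_position:
            c_in[p] = (q2 * c_out[up] + config.feed_flow * feed) / q3
        else:
            c_in[p] = c_out[up]
    return c_in


# ---------------------------------------------------------------------------
# Period integration engine.


class _Engine:
    """Precomputed per-zone operators and the flattened ODE right-hand side."""

    def __init__(self, config: SMBConfig):
        self.config = config
        self.n = config.grid_points_per_column
        self.ncol = config.n_columns
        ops = config.build_operators()
        self.operators = ops
        self.M = [op.system_matrix() for op in ops]
        # response of A^{-1} g to a unit inlet concentration
        self.a_in = [op.load_response()[0][1] for op in ops]
        self.zone_groups = [
            [p for p, z in enumerate(config.zone_of_position) if z == zone] for zone in range(4)
        ]
        self.ke = np.asarray(config.ke)
        self.phi = config.phase_ratio
        self.nfield = self.ncol * 2 * self.n
        self.feed = np.asarray(config.feed_conc)

    def _inlets(self, c_out: np.ndarray) -> np.ndarray:
        """Vectorized node balances (same arithmetic as :func:`node_balances`)."""
        cfg = self.config
        q1, q2, q3, q4 = cfg.zone_flows
        c_in = np.roll(c_out, 1, axis=0)
        c_in[0] *= q4 / q1
        fp = cfg.feed_position
        c_in[fp] = (q2 * c_out[fp - 1] + cfg.feed_flow * self.feed) / q3
        return c_in

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        cfg = self.config
        n, ncol = self.n, self.ncol
        c = y[: self.nfield].reshape(ncol, 2, n)
        q = y[self.nfield : 2 * self.nfield].reshape(ncol, 2, n)
        c_in = self._inlets(c[:, :, -1])
        qA, qB = cfg.isotherm.evaluate(c[:, 0, :], c[:, 1, :])
        driving = np.stack([qA, qB], axis=1) - q
        dc = np.empty_like(c)
        for zone, cols in enumerate(self.zone_groups):
            X = c[cols].reshape(-1, n).T  # (n, len(cols)*2)
            Y = self.M[zone] @ X + np.outer(self.a_in[zone], c_in[cols].ravel())
            dc[cols] = Y.T.reshape(len(cols), 2, n)
        dc -= self.phi * self.ke[None, :, None] * driving
        dq = self.ke[None, :, None] * driving
        dm = np.concatenate(
            [
                cfg.extract_flow * c[cfg.extract_outlet, :, -1],
                cfg.raffinate_flow * c[cfg.raffinate_outlet, :, -1],
            ]
        )
        return np.concatenate([dc.ravel(), dq.ravel(), dm])

    def pack(self, state: SMBState) -> np.ndarray:
        return np.concatenate([state.c.ravel(), state.q.ravel(), np.zeros(4)])

    def unpack(self, y: np.ndarray, switch_index: int) -> tuple[SMBState, np.ndarray]:
        c = y[: self.nfield].reshape(self.ncol, 2, self.n).copy()
        q = y[self.nfield : 2 * self.nfield].reshape(self.ncol, 2, self.n).copy()
        return SMBState(c, q, switch_index), y[2 * self.nfield :].copy()


def simulate_period(
    state: SMBState,
    config: SMBConfig,
    engine: _Engine | None = None,
    n_samples: int = 201,
) -> tuple[SMBState, PeriodRecord]:
    """Integrate the full coupled system over one switching period.

    Returns the end state (ports unchanged) and the effluent record,
    sampled at ``n_samples`` uniformly spaced times including both
    period endpoints.  Deterministic for fixed tolerances.
    """
    if engine is None:
        engine = _Engine(config)
    ts = config.switching_time
    if ts == 0.0:
        rec = PeriodRecord(
            times=np.zeros(1),
            extract=state.c[config.extract_outlet, :, -1:].copy(),
            raffinate=state.c[config.raffinate_outlet, :, -1:].copy(),
            port_masses=np.zeros(4),
            mid_state=state.copy(),
        )
        return state.copy(), rec
    t_eval = np.linspace(0.0, ts, n_samples)
    sol = solve_ivp(
        engine.rhs,
        (0.0, ts),
        engine.pack(state),
        method="RK45",
        t_eval=t_eval,
        rtol=config.rtol,
        atol=config.atol,
    )
    if not sol.success:
        raise RuntimeError(
            f"period integration failed at switch {state.switch_index}: {sol.message}"
        )
    end_state, masses = engine.unpack(sol.y[:, -1], state.switch_index)
    nf = engine.nfield
    csamp = sol.y[:nf].reshape(engine.ncol, 2, engine.n, n_samples)
    mid_state, _ = engine.unpack(sol.y[:, n_samples // 2], state.switch_index)
    rec = PeriodRecord(
        times=t_eval,
        extract=csamp[config.extract_outlet, :, -1, :].copy(),
        raffinate=csamp[config.raffinate_outlet, :, -1, :].copy(),
        port_masses=masses,
        mid_state=mid_state,
    )
    return end_state, rec


def port_shift(state: SMBState) -> SMBState:
    """Advance all ports one column downstream.

    In the port-fixed frame the fields rotate one position upstream; the
    physical column profiles themselves are untouched.  n_columns
    consecutive shifts restore the original arrangement.
    """
    return SMBState(
        c=np.roll(state.c, -1, axis=0),
        q=np.roll(state.q, -1, axis=0),
        switch_index=state.switch_index + 1,
    )


def continuous_prediction(u_m: SMBState, u_css_prev: SMBState, theta: float) -> SMBState:
    """Affine extrapolation of the full state toward the cyclic steady state.

    Elementwise ``u + theta (u - u_prev)`` on both phases and components;
    negative extrapolated concentrations are floored at zero so they never
    reach the isotherm.  ``theta = 0`` returns ``u_m`` unchanged.
    """
    if theta < 0:
        raise ValueError(f"acceleration factor must be nonnegative, got theta={theta}")
    c = np.maximum(u_m.c + theta * (u_m.c - u_css_prev.c), 0.0)
    q = np.maximum(u_m.q + theta * (u_m.q - u_css_prev.q), 0.0)
    return SMBState(c=c, q=q, switch_index=u_m.switch_index)


def css_converged(
    u_m: SMBState, u_prev: SMBState, feed_conc: Sequence[float], rel_tol: float
) -> bool:
    """CSS criterion: max liquid-phase change < rel_tol * max feed concentration.

    The comparison is strict; states must already be aligned in the
    port-fixed (moving-bed) frame, which consecutive end-of-period states
    of the run loop are.
    """
    return u_m.max_liquid_diff(u_prev) < rel_tol * float(np.max(feed_conc))


# ---------------------------------------------------------------------------
# Accounting.


def holdup(state: SMBState, config: SMBConfig) -> np.ndarray:
    """Total solute mass (mg if g/L and mL) held per component."""
    x = config.grid.x
    area = config.cross_section
    liq = config.eps_b * area * simpson(state.c, x=x, axis=-1).sum(axis=0)
    sol = (1 - config.eps_b) * area * simpson(state.q, x=x, axis=-1).sum(axis=0)
    return liq + sol


def period_mass_residual(
    before: SMBState, after: SMBState, port_masses: np.ndarray, config: SMBConfig
) -> float:
    """Per-period solute conservation residual, relative to the feed mass.

    residual = (holdup change) - (feed in - extract out - raffinate out),
    summed over components and scaled by the total feed mass per period.
    """
    feed_in = config.feed_flow * np.asarray(config.feed_conc) * config.switching_time
    out = np.array(
        [port_masses[0] + port_masses[2], port_masses[1] + port_masses[3]]
    )  # per component
    resid = (holdup(after, config) - holdup(before, config)) - (feed_in - out)
    scale = feed_in.sum()
    return float(np.abs(resid).sum() / scale)


def purity_recovery(record: PeriodRecord, config: SMBConfig) -> tuple[dict, dict]:
    """Time-averaged port purities and recoveries (%) over one CSS period.

    Component A (more retained) is the extract product, B the raffinate
    product.  Purity is the product fraction of total solute at the port;
    recovery is the product mass drawn at its port over the product mass
    fed.  A port with no solute has undefined purity (nan).
    """
    ts = record.times[-1] - record.times[0]
    if ts <= 0:
        raise ValueError("record does not span a full period")
    avg_ext = np.trapezoid(record.extract, record.times, axis=1) / ts
    avg_raf = np.trapezoid(record.raffinate, record.times, axis=1) / ts
    with np.errstate(invalid="ignore", divide="ignore"):
        pur_ext = 100.0 * avg_ext[0] / (avg_ext[0] + avg_ext[1])
        pur_raf = 100.0 * avg_raf[1] / (avg_raf[0] + avg_raf[1])
    feed_A = config.feed_flow * config.feed_conc[0]
    feed_B = config.feed_flow * config.feed_conc[1]
    rec_ext = 100.0 * config.extract_flow * avg_ext[0] / feed_A if feed_A > 0 else np.nan
    rec_raf = 100.0 * config.raffinate_flow * avg_raf[1] / feed_B if feed_B > 0 else np.nan
    purities = {"extract": float(pur_ext), "raffinate": float(pur_raf)}
    recoveries = {"extract": float(rec_ext), "raffinate": float(rec_raf)}
    return purities, recoveries


# ---------------------------------------------------------------------------
# The outer run loop.


def run_smb(config: SMBConfig, theta: float | None = None) -> CSSResult:
    """Run from the empty initial state to cyclic steady state.

    Loop: integrate one period, shift ports, test the CSS criterion, and
    (for theta > 0) extrapolate the state with the continuous-prediction
    factor before starting the next period.  The criterion compares the
    post-shift simulated state against the state the period started from:
    without acceleration that is exactly the classical "two consecutive
    iterations" test, and with acceleration it additionally requires the
    extrapolated CSS guess to be self-consistent.  After convergence one
    clean period (no prediction) is integrated to record the product
    chromatograms and the mid-period profile.
    """
    if theta is not None:
        config = replace(config, theta=float(theta))
    engine = _Engine(config)
    state = SMBState.zeros(config)  # initial condition of the upcoming period
    css_prev = state.copy()  # u_css^(0): the (empty) initial state
    logs: list[SwitchLog] = []
    converged = False
    switches = config.max_switches
    css_state = state

    for m in range(1, config.max_switches + 1):
        end, rec = simulate_period(state, config, engine=engine)
        shifted = port_shift(end)
        delta = shifted.max_liquid_diff(state)
        resid = period_mass_residual(state, end, rec.port_masses, config)
        logs.append(SwitchLog(switch=m, max_change=delta, mass_residual=resid))
        logger.info(
            "switch %3d  max|dc| = %.3e g/L  mass residual = %.2e (of feed)", m, delta, resid
        )
        if m >= 2 and css_converged(shifted, state, config.feed_conc, config.css_rel_tol):
            converged = True
            switches = m
            css_state = shifted
            break
        if config.theta > 0:
            pred = continuous_prediction(shifted, css_prev, config.theta)
            css_prev = pred
            state = pred
        else:
            state = shifted

    if not converged:
        css_state = shifted
        logger.warning("CSS not reached within %d switches", config.max_switches)

    _, record = simulate_period(css_state, config, engine=engine)
    purities, recoveries = purity_recovery(record, config)
    return CSSResult(
        switches_to_css=switches,
        converged=converged,
        purities=purities,
        recoveries=recoveries,
        record=record,
        state=css_state,
        logs=tuple(logs),
        config=config,
    )
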