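"""Transport-dispersive LDF column model.

One chromatographic column is described by the coupled balances

    dc/dt + v dc/dx = Da d2c/dx2 - phi * ke * (q* - q)
    dq/dt = ke * (q* - q)

per component, with phase ratio phi = (1 - eps_b)/eps_b, a Danckwerts
inlet dc/dx = (v/Da)(c - c_in) and a zero outlet gradient.  Spatial
discretization by the compact operator turns the liquid balance into

    A c'(t) = B c(t) - phi * ke * A (q* - q) + g(c_in)

so that, after the (once-factorized) mass-matrix solve, the linear
driving force term enters the liquid derivative pointwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .isotherms import IsothermSpec
from .operators import ColumnOperator, Coupling

__all__ = ["ColumnPhysics", "column_rhs", "interstitial_velocity"]


def interstitial_velocity(Q: float, eps_b: float, inner_diameter: float) -> float:
    """Interstitial velocity (cm/min) from volumetric flow Q (mL/min).

    v = Q / (eps_b * pi * (d/2)^2); with eps_b = 1 this degenerates to the
    superficial velocity.
    """
    if Q <= 0:
        raise ValueError(f"flow rate must be positive, got Q={Q}")
    area = np.pi * (inner_diameter / 2.0) ** 2
    return Q / (eps_b * area)


@dataclass(frozen=True)
class ColumnPhysics:
    """Everything needed to evaluate one column's right-hand side."""

    eps_b: float
    ke: np.ndarray  # per-component LDF coefficient, 1/min
    operator: ColumnOperator
    isotherm: IsothermSpec

    def __post_init__(self) -> None:
        if not 0.0 < self.eps_b < 1.0:
            raise ValueError(f"bed porosity must be in (0, 1), got {self.eps_b}")
        if self.operator.coupling is not Coupling.SMB_INLET:
            raise ValueError("column model requires an smb_inlet-coupled operator")
        object.__setattr__(self, "ke", np.asarray(self.ke, dtype=float))

    @property
    def phase_ratio(self) -> float:
        return (1.0 - self.eps_b) / self.eps_b


def column_rhs(
    c: np.ndarray,
    q: np.ndarray,
    physics: ColumnPhysics,
    c_in: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Time derivatives (c', q') for liquid and solid fields.

    ``c`` and ``q`` have shape (2, n) (components A, B on the grid);
    ``c_in`` holds the two inlet concentrations.  Components couple only
    through the competitive isotherm; the single LU factorization of the
    mass matrix is reused for both.
    """
    op = physics.operator
    n = op.n
    c = np.asarray(c, dtype=float)
    q = np.asarray(q, dtype=float)
    if c.shape != (2, n) or q.shape != (2, n):
        raise ValueError(f"fields must have shape (2, {n}); got {c.shape} and {q.shape}")
    qA, qB = physics.isotherm.evaluate(c[0], c[1])
    qstar = np.stack([qA, qB])
    driving = qstar - q
    rhs = c @ op.B.T  # (2, n): B c per component
    for comp in range(2):
        rhs[comp] += op.load(c_in[comp])
    dc = op.solve_mass(rhs.T).T - physics.phase_ratio * physics.ke[:, None] * driving
    dq = physics.ke[:, None] * driving
    return dc, dq
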