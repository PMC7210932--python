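"""Competitive adsorption equilibrium models.

Two families cover the packaged case studies:

* ``linear_coupled`` -- nearly linear isotherms of the glucose/fructose
  system, q*_A = H_A c_A and q*_B = H_B c_B + k_AB c_A c_B, with
  component A (fructose) the more retained species;
* ``bi_langmuir`` -- two-site competitive Langmuir isotherms of the
  1,1'-bi-2-naphthol enantiomers,
  q*_i = a1_i c_i / (1 + b1_A c_A + b1_B c_B)
       + a2_i c_i / (1 + b2_A c_A + b2_B c_B).

Concentrations are g/L in the liquid phase; loadings are g/L of solid.
Small negative concentrations produced by the spatial scheme's
undershoot are clipped to zero before evaluation (and only there).
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType
from typing import Mapping

import numpy as np

__all__ = ["IsothermSpec", "isotherm_eval", "SUGAR_ISOTHERM", "BINAPHTHOL_ISOTHERM"]

_REQUIRED = {
    "linear_coupled": ("H_A", "H_B", "k_AB"),
    "bi_langmuir": ("a1_A", "a1_B", "b1_A", "b1_B", "a2_A", "a2_B", "b2_A", "b2_B"),
}


@dataclass(frozen=True)
class IsothermSpec:
    """An isotherm family plus its named coefficients."""

    kind: str
    coefficients: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.kind not in _REQUIRED:
            raise ValueError(f"unknown isotherm kind {self.kind!r}")
        missing = [k for k in _REQUIRED[self.kind] if k not in self.coefficients]
        if missing:
            raise ValueError(f"isotherm {self.kind!r} missing coefficients {missing}")
        object.__setattr__(self, "coefficients", MappingProxyType(dict(self.coefficients)))

    def evaluate(self, cA, cB):
        """Equilibrium loadings (q*_A, q*_B); vectorizes over grid fields."""
        cA = np.maximum(np.asarray(cA, dtype=float), 0.0)
        cB = np.maximum(np.asarray(cB, dtype=float), 0.0)
        k = self.coefficients
        if self.kind == "linear_coupled":
            qA = k["H_A"] * cA
            qB = k["H_B"] * cB + k["k_AB"] * cA * cB
        else:
            site1 = 1.0 + k["b1_A"] * cA + k["b1_B"] * cB
            site2 = 1.0 + k["b2_A"] * cA + k["b2_B"] * cB
            qA = k["a1_A"] * cA / site1 + k["a2_A"] * cA / site2
            qB = k["a1_B"] * cB / site1 + k["a2_B"] * cB / site2
        return qA, qB


def isotherm_eval(spec: IsothermSpec, cA, cB):
    """Functional wrapper over :meth:`IsothermSpec.evaluate`."""
    return spec.evaluate(cA, cB)


#: Glucose/fructose separation on ion-exchange resin (A = fructose).
SUGAR_ISOTHERM = IsothermSpec("linear_coupled", {"H_A": 0.675, "H_B": 0.32, "k_AB": 0.000457})

#: 1,1'-bi-2-naphthol enantioseparation (A = more retained enantiomer).
BINAPHTHOL_ISOTHERM = IsothermSpec(
    "bi_langmuir",
    {
        "a1_A": 3.73, "a1_B": 2.69,
        "b1_A": 0.0466, "b1_B": 0.0336,
        "a2_A": 0.3, "a2_B": 0.1,
        "b2_A": 3.0, "b2_B": 1.0,
    },
)
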