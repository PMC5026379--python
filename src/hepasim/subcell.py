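"""Per-hepatocyte Phase I/II metabolism and glutathione turnover.

Each hepatocyte is a well-stirred reactor with six species (mmol/L):
APAP, NAPQI, GSH, NAPQI-GSH, APAPG and APAPS.  Five reactions act on them:

* CYP2E1 oxidation   APAP -> NAPQI          (Michaelis-Menten, zonated)
* conjugation        NAPQI + GSH -> NAPQI-GSH  (second order)
* glucuronidation    APAP -> APAPG          (Michaelis-Menten)
* sulfation          APAP -> APAPS          (Michaelis-Menten)
* GSH synthesis      0 -> GSH               (first order in the deficit
                                             GSHmax - GSH)

Everything except GSH synthesis conserves APAP equivalents, so
APAP + NAPQI + NAPQI-GSH + APAPG + APAPS is invariant in a closed cell.

Units at this scale are mmol/L and seconds.

A note on two rate constants: the canonical parameter table prints
``sc_kNAPQIGSH`` and ``sc_kGsh`` with the units of a rate (mmol/L/s), but
the corresponding rate laws are second order in concentrations and first
order in a concentration deficit respectively.  For dimensional
consistency this implementation interprets ``sc_kNAPQIGSH`` as
0.1 L/mmol/s and ``sc_kGsh`` as 1e-4 1/s, keeping the printed numerical
values.

Zonation: CYP2E1 activity rises linearly from 80 % of ``sc_Vmax_2E1_APAP``
at the periportal inlet to 100 % at the pericentral outlet; the Phase II
capacities are not zonated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .params import ParameterSet

__all__ = [
    "SPECIES",
    "SubcellParams",
    "SubcellState",
    "subcell_params_from",
    "subcell_derivatives",
    "derivatives_vec",
    "zonation_scale",
    "integrate_subcell",
    "integrate_cells",
    "gsh_closed_form",
]

SPECIES = ("APAP", "NAPQI", "GSH", "NAPQI_GSH", "APAPG", "APAPS")
_S = {name: i for i, name in enumerate(SPECIES)}


@dataclass(frozen=True)
class SubcellParams:
    """Kinetic constants of the six-species reaction network."""

    Vmax_GLUC: float    # mmol/L/s
    Km_GLUC: float      # mmol/L
    Vmax_SULF: float    # mmol/L/s
    Km_SULF: float      # mmol/L
    Vmax_2E1: float     # mmol/L/s
    Km_2E1: float       # mmol/L
    kNAPQIGSH: float    # L/mmol/s (see module docstring)
    kGsh: float         # 1/s, acting on the deficit GSHmax - GSH
    GSH0: float         # mmol/L
    GSHmax: float       # mmol/L

    def __post_init__(self) -> None:
        for f in self.__dataclass_fields__:
            if getattr(self, f) < 0:
                raise ValueError(f"SubcellParams.{f} must be >= 0")
        if self.GSH0 > self.GSHmax:
            raise ValueError("GSH0 must not exceed GSHmax")


def subcell_params_from(params: ParameterSet) -> SubcellParams:
    return SubcellParams(
        Vmax_GLUC=params["sc_Vmax_GLUC"], Km_GLUC=params["sc_Km_GLUC"],
        Vmax_SULF=params["sc_Vmax_SULF"], Km_SULF=params["sc_Km_SULF"],
        Vmax_2E1=params["sc_Vmax_2E1_APAP"], Km_2E1=params["sc_Km_2E1_APAP"],
        kNAPQIGSH=params["sc_kNAPQIGSH"], kGsh=params["sc_kGsh"],
        GSH0=params["sc_GSH0"], GSHmax=params["sc_GSHmax"])


@dataclass
class SubcellState:
    """Species concentrations (mmol/L) in one hepatocyte."""

    APAP: float = 0.0
    NAPQI: float = 0.0
    GSH: float = 9.9
    NAPQI_GSH: float = 0.0
    APAPG: float = 0.0
    APAPS: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, s) for s in SPECIES], dtype=float)

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "SubcellState":
        return cls(**{s: float(v) for s, v in zip(SPECIES, arr)})

    @property
    def apap_equivalents(self) -> float:
        """Conserved total: APAP + NAPQI + NAPQI-GSH + APAPG + APAPS."""
        return self.APAP + self.NAPQI + self.NAPQI_GSH + self.APAPG + self.APAPS


def zonation_scale(cell_index: int, n_cells: int, lo: float = 0.8,
                   hi: float = 1.0, *, ranks_per_side: int | None = None,
                   ) -> float:
    """CYP2E1 capacity multiplier for the cell at axial rank ``cell_index``.

    Cells are arranged in axial ranks along the periportal-to-pericentral
    axis; paired cells across the channel share a rank and hence a scale.
    The scale is linear in rank: ``lo`` at rank 0 rising to ``hi`` at the
    last rank.  A single-rank sinusoid (degenerate case) uses ``hi``.
    """
    n_ranks = ranks_per_side if ranks_per_side is not None else n_cells
    if not 0 <= cell_index < n_cells:
        raise IndexError(f"cell_index {cell_index} out of range")
    rank = cell_index % n_ranks
    if n_ranks < 2:
        return hi
    return lo + (hi - lo) * rank / (n_ranks - 1)


def derivatives_vec(conc: np.ndarray, p: SubcellParams,
                    zone_scale: np.ndarray | float = 1.0,
                    source: np.ndarray | float = 0.0) -> np.ndarray:
    """Vectorised rate function over an array of cells.

    ``conc`` has shape ``(..., 6)`` in the :data:`SPECIES` order;
    ``zone_scale`` broadcasts over the leading axes; ``source`` is an
    optional external flux (mmol/L/s) added elementwise, used by the
    coupled model to feed blood-side exchange into each cell.
    """
    conc = np.asarray(conc, dtype=float)
    apap = conc[..., _S["APAP"]]
    napqi = conc[..., _S["NAPQI"]]
    gsh = conc[..., _S["GSH"]]
    v_cyp = zone_scale * p.Vmax_2E1 * apap / (p.Km_2E1 + apap)
    v_gluc = p.Vmax_GLUC * apap / (p.Km_GLUC + apap)
    v_sulf = p.Vmax_SULF * apap / (p.Km_SULF + apap)
    v_conj = p.kNAPQIGSH * napqi * gsh
    v_gsh = p.kGsh * (p.GSHmax - gsh)
    out = np.zeros_like(conc)
    out[..., _S["APAP"]] = -(v_cyp + v_gluc + v_sulf)
    out[..., _S["NAPQI"]] = v_cyp - v_conj
    out[..., _S["GSH"]] = v_gsh - v_conj
    out[..., _S["NAPQI_GSH"]] = v_conj
    out[..., _S["APAPG"]] = v_gluc
    out[..., _S["APAPS"]] = v_sulf
    return out + source


def subcell_derivatives(state: SubcellState | np.ndarray, p: SubcellParams,
                        zone_scale: float = 1.0) -> SubcellState:
    """Time derivative (mmol/L/s) for a single hepatocyte."""
    arr = state.as_array() if isinstance(state, SubcellState) else np.asarray(
        state, dtype=float)
    if arr.shape != (len(SPECIES),):
        raise ValueError(f"state must have {len(SPECIES)} species")
    if np.any(arr < 0):
        raise ValueError("negative concentrations are not a valid state")
    if not 0 < zone_scale <= 1:
        raise ValueError("zone_scale must lie in (0, 1]")
    return SubcellState.from_array(derivatives_vec(arr, p, zone_scale))


def integrate_subcell(state: SubcellState, p: SubcellParams,
                      zone_scale: float = 1.0, dt: float = 1.0,
                      rtol: float = 1e-9, atol: float = 1e-12,
                      ) -> SubcellState:
    """Advance one hepatocyte by ``dt`` seconds (adaptive stiff solver)."""
    if dt < 0:
        raise ValueError("dt must be >= 0")
    if dt == 0:
        return SubcellState.from_array(state.as_array())
    sol = solve_ivp(lambda t, y: derivatives_vec(y, p, zone_scale),
                    (0.0, dt), state.as_array(), method="LSODA",
                    rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"subcellular integration failed: {sol.message}")
    return SubcellState.from_array(np.clip(sol.y[:, -1], 0.0, None))


def integrate_cells(conc: np.ndarray, p: SubcellParams,
                    zone_scale: np.ndarray, dt: float,
                    source: np.ndarray | float = 0.0,
                    rtol: float = 1e-8, atol: float = 1e-11) -> np.ndarray:
    """Advance ``n`` independent hepatocytes jointly by ``dt`` seconds.

    The cells do not interact, but solving them in one call amortises
    solver overhead inside the multiscale coupling loop.  ``source`` is a
    constant external flux array (mmol/L/s) applied over the step.
    """
    n = conc.shape[0]
    if dt == 0:
        return conc.copy()
    zs = np.broadcast_to(np.asarray(zone_scale, dtype=float), (n,)).copy()

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        c = y.reshape(n, len(SPECIES))
        return derivatives_vec(c, p, zs, source).ravel()

    sol = solve_ivp(rhs, (0.0, dt), conc.ravel(), method="LSODA",
                    rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"subcellular integration failed: {sol.message}")
    return np.clip(sol.y[:, -1].reshape(n, len(SPECIES)), 0.0, None)


def gsh_closed_form(t_s: np.ndarray | float, p: SubcellParams) -> np.ndarray:
    """GSH trajectory with no NAPQI present:
    ``GSHmax - (GSHmax - GSH0) * exp(-kGsh * t)``."""
    return p.GSHmax - (p.GSHmax - p.GSH0) * np.exp(-p.kGsh * np.asarray(t_s))
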