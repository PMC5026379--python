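"""Whole-body physiologically based pharmacokinetic (PBPK) compartment model.

Ten compartments per compound track the molar amount (mmol) of
acetaminophen (APAP) or one of its Phase II conjugates (APAPG, APAPS)
through gut lumen, gut, liver, venous blood, lung, arterial blood, kidney,
rest-of-body, kidney tubules (urinary sink) and a lumped metabolic sink.
All transfers are first-order in the source amount with flow/volume and
partition-coefficient algebra; see :data:`TRANSFERS` for the full network.

Units at this scale: amounts mmol, volumes L, flows L/h, time h.  The model
is linear for first-order gut absorption, and every transfer appears once
as a loss and once as a gain, so total moles are conserved exactly by
construction.

The same model, instantiated once per compound, is reused as the outer
scale of the coupled multiscale simulator (:mod:`hepasim.coupler`), where
the liver compartment is bypassed in favour of the explicit sinusoid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .params import COMPOUNDS, MOLAR_MASS, REFERENCE_BW, ParameterSet

__all__ = [
    "STATE_FIELDS",
    "BodyParams",
    "CompoundParams",
    "GutUptakeModel",
    "PBPKState",
    "PBPKResult",
    "body_params_from",
    "compound_params_from",
    "gut_uptake_rate",
    "pbpk_derivatives",
    "pbpk_matrix",
    "simulate_pbpk",
    "dose_to_mmol",
]

#: State-vector ordering shared by every routine in this module.
STATE_FIELDS = (
    "AGutlumen", "CGut", "CLiver", "CVen", "CLung",
    "CArt", "CKidney", "CRest", "CTubules", "CMetabolized",
)
_IDX = {name: i for i, name in enumerate(STATE_FIELDS)}
N_STATES = len(STATE_FIELDS)

#: Compartments without a perfusable volume (amount-only bookkeeping).
VOLUMELESS = ("AGutlumen", "CTubules", "CMetabolized")


@dataclass(frozen=True)
class BodyParams:
    """Compound-independent physiology: flows (L/h) and volumes (L)."""

    bw: float
    QCardiac: float
    QGut: float
    QLiver: float
    QKidney: float
    QRest: float
    VArt: float
    VVen: float
    VGut: float
    VLiver: float
    VKidney: float
    VLung: float
    VRest: float
    hematocrit: float = 0.45

    def __post_init__(self) -> None:
        for name in ("bw", "QCardiac", "QGut", "QLiver", "QKidney", "QRest",
                     "VArt", "VVen", "VGut", "VLiver", "VKidney", "VLung",
                     "VRest"):
            if getattr(self, name) <= 0:
                raise ValueError(f"BodyParams.{name} must be positive")
        if not 0 < self.hematocrit < 1:
            raise ValueError("hematocrit must lie in (0, 1)")

    def volume_of(self, compartment: str) -> float:
        return {
            "CGut": self.VGut, "CLiver": self.VLiver, "CVen": self.VVen,
            "CLung": self.VLung, "CArt": self.VArt, "CKidney": self.VKidney,
            "CRest": self.VRest,
        }[compartment]


@dataclass(frozen=True)
class CompoundParams:
    """Compound-dependent disposition parameters for one compound."""

    kGutabs: float      # 1/h, first-order gut absorption
    Fup: float          # fraction unbound in plasma
    Kr2p: float         # rest-of-body : plasma partition coefficient
    Kk2p: float         # kidney : plasma
    Kl2p: float         # liver : plasma
    Rb2p: float         # blood : plasma concentration ratio
    Qgfr: float         # L/h, glomerular filtration into the tubules
    CLmetab: float = 0.0  # L/h, lumped hepatic metabolic clearance

    def __post_init__(self) -> None:
        if not 0 < self.Fup <= 1:
            raise ValueError("Fup must lie in (0, 1]")
        for name in ("kGutabs", "Kr2p", "Kk2p", "Kl2p", "Rb2p", "Qgfr",
                     "CLmetab"):
            if getattr(self, name) < 0:
                raise ValueError(f"CompoundParams.{name} must be >= 0")


@dataclass(frozen=True)
class GutUptakeModel:
    """Gut-lumen absorption law.

    ``first_order`` is the classical ``kGutabs * AGutlumen`` law.
    ``zero_order_lagged`` models saturable, transporter-mediated uptake:
    zero flux during a gastric-emptying ``lag``, then Michaelis-Menten
    uptake which, for ``Km_gut`` small against the lumen load, is constant
    at ``Vmax_gut`` (effectively zeroth order) until the lumen empties.
    """

    variant: str = "first_order"
    Vmax_gut: float = 0.0   # mmol/h
    Km_gut: float = 1e-3    # mmol
    lag: float = 0.0        # h

    def __post_init__(self) -> None:
        if self.variant not in ("first_order", "zero_order_lagged"):
            raise ValueError(f"unknown gut-uptake variant {self.variant!r}")
        if self.lag < 0 or self.Vmax_gut < 0 or self.Km_gut < 0:
            raise ValueError("gut-uptake parameters must be >= 0")


@dataclass
class PBPKState:
    """Molar amounts (mmol) in the ten compartments of one compound."""

    AGutlumen: float = 0.0
    CGut: float = 0.0
    CLiver: float = 0.0
    CVen: float = 0.0
    CLung: float = 0.0
    CArt: float = 0.0
    CKidney: float = 0.0
    CRest: float = 0.0
    CTubules: float = 0.0
    CMetabolized: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in STATE_FIELDS], dtype=float)

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "PBPKState":
        return cls(**{f: float(v) for f, v in zip(STATE_FIELDS, arr)})

    @property
    def total(self) -> float:
        return float(sum(getattr(self, f) for f in STATE_FIELDS))


# ---------------------------------------------------------------------------
# Parameter derivation
# ---------------------------------------------------------------------------

def body_params_from(params: ParameterSet) -> BodyParams:
    """Build :class:`BodyParams`, allometrically rescaled by body weight.

    The canonical flow and volume values describe a 70 kg adult.  When
    ``pbpk_bw`` differs, compartment volumes scale linearly with body mass
    and blood flows with the standard 3/4 allometric exponent, so body
    weight acts as a genuine physiological parameter rather than a label.
    """
    s = params["pbpk_bw"] / REFERENCE_BW
    sv, sq = s, s ** 0.75
    return BodyParams(
        bw=params["pbpk_bw"],
        QCardiac=params["pbpk_QCardiac"] * sq,
        QGut=params["pbpk_QGut"] * sq,
        QLiver=params["pbpk_QLiver"] * sq,
        QKidney=params["pbpk_QKidney"] * sq,
        QRest=params["pbpk_QRest"] * sq,
        VArt=params["pbpk_VArt"] * sv,
        VVen=params["pbpk_VVen"] * sv,
        VGut=params["pbpk_VGut"] * sv,
        VLiver=params["pbpk_VLiver"] * sv,
        VKidney=params["pbpk_VKidney"] * sv,
        VLung=params["pbpk_VLung"] * sv,
        VRest=params["pbpk_VRest"] * sv,
        hematocrit=params["pbpk_hemat"],
    )


def compound_params_from(params: ParameterSet, compound: str,
                         CLmetab: float = 0.0) -> CompoundParams:
    """Extract one compound's :class:`CompoundParams` from a parameter set."""
    return CompoundParams(CLmetab=CLmetab, **params.compound_params(compound))


# ---------------------------------------------------------------------------
# Rate equations
# ---------------------------------------------------------------------------

def _rate_coefficients(body: BodyParams, compound: CompoundParams,
                       ) -> list[tuple[str, str, float]]:
    """First-order coefficients (1/h) for each transfer except absorption.

    Each entry ``(src, dst, k)`` contributes ``k * amount[src]`` mmol/h,
    debited from ``src`` and credited to ``dst``.
    """
    b, c = body, compound
    return [
        ("CGut", "CLiver", b.QGut / b.VGut),
        ("CLiver", "CVen",
         (b.QLiver + b.QGut) * c.Rb2p / (c.Kl2p * c.Fup * b.VLiver)),
        ("CLiver", "CMetabolized", c.CLmetab / (c.Kl2p * c.Fup)),
        ("CVen", "CLung", b.QCardiac / b.VVen),
        ("CLung", "CArt", b.QCardiac / b.VLung),
        ("CArt", "CGut", b.QGut / b.VArt),
        ("CArt", "CLiver", b.QLiver / b.VArt),
        ("CArt", "CKidney", b.QKidney / b.VArt),
        ("CArt", "CRest", b.QRest / b.VArt),
        ("CKidney", "CVen",
         b.QKidney * c.Rb2p / (c.Kk2p * c.Fup * b.VKidney)),
        ("CKidney", "CTubules", c.Qgfr / (c.Kk2p * b.VKidney)),
        ("CRest", "CVen", b.QRest * c.Rb2p / (c.Kr2p * c.Fup * b.VRest)),
    ]


#: Human-readable transfer network (for SBML export and documentation).
TRANSFERS = tuple(src + " -> " + dst for src, dst, _ in _rate_coefficients(
    BodyParams(bw=70, QCardiac=1, QGut=1, QLiver=1, QKidney=1, QRest=1,
               VArt=1, VVen=1, VGut=1, VLiver=1, VKidney=1, VLung=1, VRest=1),
    CompoundParams(kGutabs=1, Fup=1, Kr2p=1, Kk2p=1, Kl2p=1, Rb2p=1, Qgfr=1,
                   CLmetab=1)))


def pbpk_matrix(body: BodyParams, compound: CompoundParams,
                *, kGutabs: float | None = None,
                bypass_liver: bool = False) -> np.ndarray:
    """Linear system matrix ``A`` (1/h) such that ``d amount/dt = A @ amount``.

    ``kGutabs`` overrides the compound's absorption rate (``None`` keeps it).
    With ``bypass_liver`` the liver compartment is cut out of the network:
    its inflows and outflows are removed so an external liver model (the
    sinusoid) can take over hepatic transit.
    """
    A = np.zeros((N_STATES, N_STATES))
    ka = compound.kGutabs if kGutabs is None else kGutabs
    A[_IDX["AGutlumen"], _IDX["AGutlumen"]] -= ka
    A[_IDX["CGut"], _IDX["AGutlumen"]] += ka
    for src, dst, k in _rate_coefficients(body, compound):
        if bypass_liver and "CLiver" in (src, dst):
            continue
        A[_IDX[src], _IDX[src]] -= k
        A[_IDX[dst], _IDX[src]] += k
    return A


def gut_uptake_rate(AGutlumen: float, uptake: GutUptakeModel, t: float,
                    kGutabs: float) -> float:
    """Absorption flux (mmol/h) out of the gut lumen at time ``t`` (h)."""
    if AGutlumen < 0:
        raise ValueError("AGutlumen must be >= 0")
    if uptake.variant == "first_order":
        return kGutabs * AGutlumen
    if t < uptake.lag:
        return 0.0
    return uptake.Vmax_gut * AGutlumen / (uptake.Km_gut + AGutlumen)


def pbpk_derivatives(state: PBPKState | np.ndarray, body: BodyParams,
                     compound: CompoundParams,
                     uptake: GutUptakeModel | None = None,
                     t: float = 0.0) -> PBPKState:
    """Time derivative (mmol/h per field) of the ten-compartment system.

    Raises ``ValueError`` on negative amounts.  The derivative of the total
    over all fields is identically zero: the tubules and metabolic sink are
    part of the state, so nothing leaves the bookkeeping.
    """
    arr = state.as_array() if isinstance(state, PBPKState) else np.asarray(
        state, dtype=float)
    if arr.shape != (N_STATES,):
        raise ValueError(f"state must have {N_STATES} fields")
    if np.any(arr < 0):
        raise ValueError("negative amounts are not a valid PBPK state")
    uptake = uptake or GutUptakeModel()
    A = pbpk_matrix(body, compound, kGutabs=0.0)
    deriv = A @ arr
    absorb = gut_uptake_rate(arr[_IDX["AGutlumen"]], uptake, t,
                             compound.kGutabs)
    deriv[_IDX["AGutlumen"]] -= absorb
    deriv[_IDX["CGut"]] += absorb
    return PBPKState.from_array(deriv)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def dose_to_mmol(dose_mg_per_kg: float, bw_kg: float,
                 compound: str = "APAP") -> float:
    """Convert an oral dose (mg/kg body weight) to mmol of compound."""
    return dose_mg_per_kg * bw_kg / MOLAR_MASS[compound]


@dataclass
class PBPKResult:
    """Per-compound amount trajectories on a shared time grid."""

    times: np.ndarray                      # h
    amounts: dict[str, np.ndarray]         # compound -> (n_t, 10) mmol
    body: BodyParams
    compounds: dict[str, CompoundParams]
    meta: dict = field(default_factory=dict)

    def amount(self, compound: str, compartment: str) -> np.ndarray:
        return self.amounts[compound][:, _IDX[compartment]]

    def concentration(self, compound: str, compartment: str) -> np.ndarray:
        """Blood/tissue concentration (mmol/L) in a volume compartment."""
        if compartment in VOLUMELESS:
            raise ValueError(f"{compartment} has no defined volume")
        return self.amount(compound, compartment) / self.body.volume_of(
            compartment)

    def serum_concentration(self, compound: str) -> np.ndarray:
        """Venous plasma concentration (mmol/L): (CVen/VVen) / Rb2p."""
        return (self.concentration(compound, "CVen")
                / self.compounds[compound].Rb2p)

    def total(self, compound: str) -> np.ndarray:
        return self.amounts[compound].sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: time_h, compartment, compound, amount_mmol,
        concentration_mmol_per_L (empty for volume-less compartments)."""
        rows = []
        for comp, arr in self.amounts.items():
            for cname in STATE_FIELDS:
                amt = arr[:, _IDX[cname]]
                if cname in VOLUMELESS:
                    conc = np.full_like(amt, np.nan)
                else:
                    conc = amt / self.body.volume_of(cname)
                rows.append(pd.DataFrame({
                    "time_h": self.times, "compartment": cname,
                    "compound": comp, "amount_mmol": amt,
                    "concentration_mmol_per_L": conc}))
        return pd.concat(rows, ignore_index=True)


def simulate_pbpk(body: BodyParams,
                  compounds: Mapping[str, CompoundParams],
                  dose_mg_per_kg: float,
                  duration_h: float = 8.0,
                  t_grid: Sequence[float] | None = None,
                  uptake: GutUptakeModel | None = None,
                  metabolite_split: tuple[float, float] = (0.60, 0.33),
                  dose_bw_kg: float | None = None,
                  rtol: float = 1e-8, atol: float = 1e-10) -> PBPKResult:
    """Standalone simulation of the three linked PBPK replicates.

    The full molar dose starts in the parent compound's gut lumen; the
    metabolite replicates start empty.  In this standalone mode the
    parent's metabolic flux (``CLmetab`` law) is routed into the
    glucuronide and sulfate replicates' liver compartments at fractions
    ``metabolite_split = (fG, fS)``; the remainder accumulates in the
    parent's metabolic sink.  Moles are therefore conserved across the
    three replicate systems jointly.

    ``dose_bw_kg`` fixes the body weight used for the mg/kg dose
    conversion (defaults to the physiological ``body.bw``), so a
    prescribed absolute dose can be held fixed while physiology varies.
    """
    if dose_mg_per_kg < 0:
        raise ValueError("dose must be >= 0")
    fG, fS = metabolite_split
    if fG < 0 or fS < 0 or fG + fS > 1 + 1e-12:
        raise ValueError("metabolite split fractions must be >= 0, sum <= 1")
    uptake = uptake or GutUptakeModel()
    order = [c for c in COMPOUNDS if c in compounds]
    if order[0] != "APAP":
        raise ValueError("compounds must include APAP")
    n = len(order)

    mats = {c: pbpk_matrix(body, compounds[c], kGutabs=0.0) for c in order}
    liver_metab_k = {
        c: compounds[c].CLmetab / (compounds[c].Kl2p * compounds[c].Fup)
        for c in order}

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        dy = np.empty_like(y)
        blocks = y.reshape(n, N_STATES)
        for i, c in enumerate(order):
            dy[i * N_STATES:(i + 1) * N_STATES] = mats[c] @ blocks[i]
        # parent absorption (possibly nonlinear)
        absorb = gut_uptake_rate(max(blocks[0][_IDX["AGutlumen"]], 0.0),
                                 uptake, t, compounds["APAP"].kGutabs)
        dy[_IDX["AGutlumen"]] -= absorb
        dy[_IDX["CGut"]] += absorb
        # standalone metabolite production: split the parent's metabolic
        # flux between the conjugate replicates' livers
        flux = liver_metab_k["APAP"] * blocks[0][_IDX["CLiver"]]
        if flux != 0.0 and n > 1:
            dy[_IDX["CMetabolized"]] -= (fG + fS) * flux
            for frac, met in ((fG, "APAPG"), (fS, "APAPS")):
                if met in compounds:
                    j = order.index(met)
                    dy[j * N_STATES + _IDX["CLiver"]] += frac * flux
        return dy

    y0 = np.zeros(n * N_STATES)
    bw_for_dose = body.bw if dose_bw_kg is None else dose_bw_kg
    y0[_IDX["AGutlumen"]] = dose_to_mmol(dose_mg_per_kg, bw_for_dose)

    if t_grid is None:
        t_grid = np.linspace(0.0, duration_h, 481)
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")

    sol = solve_ivp(rhs, (float(t_grid[0]), float(t_grid[-1])), y0,
                    method="LSODA", t_eval=t_grid, rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(
            f"PBPK integration failed at t = {sol.t[-1] if len(sol.t) else 0}"
            f" h: {sol.message}")
    amounts = {c: sol.y[i * N_STATES:(i + 1) * N_STATES].T.copy()
               for i, c in enumerate(order)}
    # integration can leave harmless -1e-15 excursions; clip but flag big ones
    for c, arr in amounts.items():
        low = arr.min()
        if low < -1e3 * atol:
            raise RuntimeError(
                f"negative-amount excursion {low:.3e} mmol for {c}")
        np.clip(arr, 0.0, None, out=arr)
    return PBPKResult(times=t_grid, amounts=amounts, body=body,
                      compounds=dict(compounds),
                      meta={"dose_mg_per_kg": dose_mg_per_kg,
                            "dose_mmol": float(y0[_IDX["AGutlumen"]]),
                            "metabolite_split": (fG, fS)})
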