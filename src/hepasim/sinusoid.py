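"""Tissue-scale model of one representative hepatic sinusoid.

Blood is represented as discrete moving parcels — red blood cells (RBCs)
and serum portions — advected in plug flow at 200 um/s past two rows of
fixed hepatocytes (10 axial ranks x 2 sides for the reference geometry).
Compound moves between parcels and hepatocytes by reversible first-order
passive transfer, saturable active import of APAP from serum into
hepatocytes, and first-order export of the Phase II conjugates from
hepatocytes into passing blood.  Parcels reaching the central-vein end are
deleted and their content collected in an outflow accumulator.

The model is fully deterministic: parcel creation uses volume-credit
accumulators rather than random sampling, so identical inputs give
bit-identical outputs.  This replaces a stochastic cellular-automaton
realisation of blood flow whose run-to-run variation is negligible for
every aggregate output of interest.

Units at this scale: lengths um, volumes um^3, time s, concentrations
mmol/L.  One um^3 is 1e-15 L, so a parcel's molar content is
``conc * volume * 1e-15`` mmol.

Transfer conventions (kept exactly as tabulated):

* passive rates ``k_PD_X2Y`` apply to APAP only and are divided by the
  source entity's neighbour count;
* the active Michaelis-Menten import applies per serum-hepatocyte contact
  pair and is *not* divided by the neighbour count;
* metabolite export ``k_AT_APAPG/APAPS`` applies per hepatocyte-parcel
  contact pair, also undivided.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .params import ParameterSet
from .subcell import SPECIES, SubcellParams, derivatives_vec, subcell_params_from
from .subcell import zonation_scale

__all__ = [
    "UM3_TO_L",
    "SinusoidConfig",
    "TransferRates",
    "ContactGraph",
    "SinusoidState",
    "build_sinusoid",
    "spawn_parcels",
    "advect",
    "contact_graph",
    "transfer_step",
    "run_pulse_experiment",
    "heatmap_grid",
    "quasi_steady_exchange",
]

UM3_TO_L = 1e-15
#: Hepatocyte species indices that exchange with blood, in parcel order
#: (APAP, APAPG, APAPS).
_EXCHANGE_IDX = np.array([SPECIES.index("APAP"), SPECIES.index("APAPG"),
                          SPECIES.index("APAPS")])
_GAP_CUTOFF_UM = 10.0   # parcel-parcel contact range, about one RBC length
_MIN_SUBSTEP_S = 1e-6


@dataclass(frozen=True)
class SinusoidConfig:
    """Geometry, flow and scheduling of the representative sinusoid."""

    l_SIN: float = 200.0         # um
    d_SIN: float = 20.0          # um
    h_SIN: float = 4.0           # um
    Vol_HEP: float = 8000.0      # um^3
    n_hepatocytes: int = 20      # 2 sides x 10 axial ranks
    flow_speed: float = 200.0    # um/s
    Vol_RBC: float = 400.0       # um^3
    Vol_SP: float = 100.0        # um^3
    hematocrit: float = 0.45
    arterial_fraction: float = 0.25   # arterial : venous = 1 : 3
    mcs2sec: float = 1.0 / 600.0
    freq_bloodInflow: int = 20   # mcs between parcel-creation events
    freq_transport: int = 10     # mcs between transfer/flow steps
    freq_SBML: int = 10          # mcs between subcellular updates
    zonation_lo: float = 0.8
    zonation_hi: float = 1.0

    def __post_init__(self) -> None:
        if self.n_hepatocytes < 2 or self.n_hepatocytes % 2:
            raise ValueError("n_hepatocytes must be an even integer >= 2")
        if not 0 < self.hematocrit < 1:
            raise ValueError("hematocrit must lie in (0, 1)")

    @classmethod
    def from_params(cls, params: ParameterSet) -> "SinusoidConfig":
        return cls(
            l_SIN=params["l_SIN"], d_SIN=params["d_SIN"],
            h_SIN=params["h_SIN"], Vol_HEP=params["Vol_HEP"],
            flow_speed=params["flow_speed"], Vol_RBC=params["Vol_RBC"],
            Vol_SP=params["Vol_SP"], hematocrit=params["pbpk_hemat"],
            arterial_fraction=params["arterial_fraction"],
            mcs2sec=params["mcs2sec"],
            freq_bloodInflow=int(params["freq_bloodInflow"]),
            freq_transport=int(params["freq_transport"]),
            freq_SBML=int(params["freq_SBML"]))

    @property
    def n_ranks(self) -> int:
        return self.n_hepatocytes // 2

    @property
    def rank_span(self) -> float:
        """Axial extent (um) of one hepatocyte rank; ranks tile [0, l_SIN]."""
        return self.l_SIN / self.n_ranks

    @property
    def lumen_volume(self) -> float:
        """Lumen volume l * d * h (um^3)."""
        return self.l_SIN * self.d_SIN * self.h_SIN

    @property
    def volumetric_flow(self) -> float:
        """Plug-flow volumetric throughput d*h*v (um^3/s)."""
        return self.d_SIN * self.h_SIN * self.flow_speed

    @property
    def transit_time(self) -> float:
        return self.l_SIN / self.flow_speed

    @property
    def dt_transport(self) -> float:
        return self.freq_transport * self.mcs2sec

    @property
    def dt_inflow(self) -> float:
        return self.freq_bloodInflow * self.mcs2sec

    def zone_scales(self) -> np.ndarray:
        """CYP2E1 multiplier per rank (periportal 0.8 -> pericentral 1.0)."""
        return np.array([
            zonation_scale(r, self.n_ranks, self.zonation_lo,
                           self.zonation_hi) for r in range(self.n_ranks)])


@dataclass(frozen=True)
class TransferRates:
    """Blood-hepatocyte transfer constants (all 1/s except the active pair)."""

    k_PD: Mapping[str, float]   # keys "R2R", "R2S", ... "H2H"
    Vmax_AT_APAP: float         # mmol/L/s
    Km_AT_APAP: float           # mmol/L
    k_AT_APAPG: float           # 1/s
    k_AT_APAPS: float           # 1/s

    def __post_init__(self) -> None:
        for key in [f"{a}2{b}" for a in "RSH" for b in "RSH"]:
            if key not in self.k_PD:
                raise ValueError(f"missing passive rate k_PD_{key}")
            if self.k_PD[key] < 0:
                raise ValueError(f"k_PD_{key} must be >= 0")
        for name in ("Vmax_AT_APAP", "Km_AT_APAP", "k_AT_APAPG",
                     "k_AT_APAPS"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def from_params(cls, params: ParameterSet) -> "TransferRates":
        return cls(
            k_PD={f"{a}2{b}": params[f"cc3d_k_PD_{a}2{b}"]
                  for a in "RSH" for b in "RSH"},
            Vmax_AT_APAP=params["cc3d_Vmax_AT_APAP"],
            Km_AT_APAP=params["cc3d_Km_AT_APAP"],
            k_AT_APAPG=params["cc3d_k_AT_APAPG"],
            k_AT_APAPS=params["cc3d_k_AT_APAPS"])


class SinusoidState:
    """Mutable state: resident parcels, hepatocytes and the outflow ledger.

    Parcels are stored as parallel arrays sorted by increasing axial
    position ``x``; hepatocytes as a ``(n_hepatocytes, 6)`` concentration
    array in :data:`hepasim.subcell.SPECIES` order.  Hepatocyte ``i`` has
    side ``i // n_ranks`` and axial rank ``i % n_ranks``.
    """

    def __init__(self, config: SinusoidConfig,
                 subcell_params: SubcellParams | None = None,
                 rb2p: Sequence[float] = (1.09, 0.55, 0.55),
                 Fup: float = 0.8):
        self.config = config
        self.subcell_params = subcell_params
        self.rb2p = np.asarray(rb2p, dtype=float)
        self.Fup = float(Fup)
        n = config.n_hepatocytes
        gsh0 = subcell_params.GSH0 if subcell_params is not None else 0.0
        self.hep_conc = np.zeros((n, len(SPECIES)))
        self.hep_conc[:, SPECIES.index("GSH")] = gsh0
        self.hep_side = np.repeat([0, 1], config.n_ranks)
        self.hep_rank = np.tile(np.arange(config.n_ranks), 2)
        self.zone_scale = config.zone_scales()[self.hep_rank]
        # parcels, sorted ascending by x
        self.x = np.empty(0)
        self.vol = np.empty(0)
        self.kind = np.empty(0, dtype=np.int8)        # 0 = RBC, 1 = serum
        self.provenance = np.empty(0, dtype=np.int8)  # 0 = arterial, 1 = venous
        self.conc = np.empty((0, 3))
        self.birth_time = np.empty(0)
        # deterministic spawn accumulators (um^3 of volume credit)
        self._credit = {"RBC": 0.0, "SP": 0.0}
        self._arterial_credit = 0.0
        self._next_parcel_id = 0
        self.parcel_id = np.empty(0, dtype=np.int64)
        # ledgers
        self.time_s = 0.0
        self.outflow = np.zeros(3)        # mmol collected since last drain
        self.total_injected = np.zeros(3)  # mmol ever spawned
        self.total_drained = np.zeros(3)   # mmol ever collected
        self.exit_count = 0
        self.residence_sum = 0.0

    # -- bookkeeping helpers ------------------------------------------------
    @property
    def n_parcels(self) -> int:
        return self.x.size

    def parcel_moles(self) -> np.ndarray:
        """Total resident parcel content per compound (mmol)."""
        if self.n_parcels == 0:
            return np.zeros(3)
        return (self.conc * self.vol[:, None]).sum(axis=0) * UM3_TO_L

    def hepatocyte_moles(self) -> np.ndarray:
        """Exchangeable hepatocyte content (APAP, APAPG, APAPS; mmol)."""
        return (self.hep_conc[:, _EXCHANGE_IDX].sum(axis=0)
                * self.config.Vol_HEP * UM3_TO_L)

    def drain(self) -> np.ndarray:
        """Empty the outflow accumulator, returning its content (mmol)."""
        out = self.outflow.copy()
        self.outflow[:] = 0.0
        return out

    def mean_residence_time(self) -> float:
        """Mean transit time (s) of parcels that have exited so far."""
        if self.exit_count == 0:
            raise RuntimeError("no parcel has exited yet")
        return self.residence_sum / self.exit_count


def build_sinusoid(config: SinusoidConfig,
                   subcell_params: SubcellParams | None = None,
                   rb2p: Sequence[float] = (1.09, 0.55, 0.55),
                   Fup: float = 0.8) -> SinusoidState:
    """Create an empty sinusoid: hepatocytes in place, no parcels.

    Raises on geometric inconsistency (the axial ranks must tile the lumen
    exactly, which the derived span guarantees only for even, positive
    hepatocyte counts).
    """
    span_total = config.rank_span * config.n_ranks
    if abs(span_total - config.l_SIN) > 1e-9 * config.l_SIN:
        raise ValueError("hepatocyte spans do not tile the sinusoid length")
    return SinusoidState(config, subcell_params, rb2p, Fup)


def build_from_params(params: ParameterSet) -> SinusoidState:
    """Convenience: sinusoid with configuration and rates from one set."""
    return build_sinusoid(SinusoidConfig.from_params(params),
                          subcell_params_from(params),
                          rb2p=(params["pbpk_Rb2p"], params["pbpk_Rb2pG"],
                                params["pbpk_Rb2pS"]),
                          Fup=params["pbpk_Fup"])


# ---------------------------------------------------------------------------
# Parcel creation
# ---------------------------------------------------------------------------

def _partition_load(blood_conc: np.ndarray, rb2p: np.ndarray,
                    hct: float) -> tuple[np.ndarray, np.ndarray]:
    """Split a blood concentration into plasma and RBC phase concentrations.

    Plasma sees ``C_blood / Rb2p``; the RBC concentration is fixed by
    requiring that the volume-weighted recombination returns the blood
    value.  Compounds with ``Rb2p = 1 - hematocrit`` carry nothing in the
    RBC phase (no binding to red cells).
    """
    c_plasma = blood_conc / rb2p
    c_rbc = np.clip((rb2p - (1.0 - hct)) * c_plasma / hct, 0.0, None)
    return c_plasma, c_rbc


def spawn_parcels(state: SinusoidState,
                  inflow_conc: Mapping[str, Sequence[float]] | Sequence[float],
                  dt: float | None = None) -> np.ndarray:
    """Create the parcels for one inflow interval; returns moles added.

    ``inflow_conc`` gives per-compound *blood* concentrations (mmol/L) for
    the two inflow streams as ``{"arterial": (3,), "venous": (3,)}``; a
    bare array applies to both streams.  Volume credit accumulators make
    the long-run RBC volume fraction equal the hematocrit and the
    arterial:venous volume split equal ``arterial_fraction``, with no
    randomness.  New parcels are staggered over the interval's inflow
    column so they tile space exactly as plug flow would have placed them.
    """
    cfg = state.config
    if dt is None:
        dt = cfg.dt_inflow
    if isinstance(inflow_conc, Mapping):
        c_art = np.clip(np.asarray(inflow_conc["arterial"], float), 0, None)
        c_ven = np.clip(np.asarray(inflow_conc["venous"], float), 0, None)
    else:
        c_art = c_ven = np.clip(np.asarray(inflow_conc, float), 0, None)

    v_in = cfg.volumetric_flow * dt
    state._credit["RBC"] += v_in * cfg.hematocrit
    state._credit["SP"] += v_in * (1.0 - cfg.hematocrit)

    new: list[tuple[float, int, int, np.ndarray]] = []  # (vol, kind, prov, conc)
    # interleave creation so RBCs and serum portions mix along the column
    while state._credit["RBC"] >= cfg.Vol_RBC or state._credit["SP"] >= cfg.Vol_SP:
        if state._credit["RBC"] / cfg.Vol_RBC >= state._credit["SP"] / cfg.Vol_SP:
            vol, kind = cfg.Vol_RBC, 0
            state._credit["RBC"] -= vol
        else:
            vol, kind = cfg.Vol_SP, 1
            state._credit["SP"] -= vol
        state._arterial_credit += vol * cfg.arterial_fraction
        if state._arterial_credit >= vol:
            prov = 0
            state._arterial_credit -= vol
        else:
            prov = 1
        blood = c_art if prov == 0 else c_ven
        c_plasma, c_rbc = _partition_load(blood, state.rb2p, cfg.hematocrit)
        new.append((vol, kind, prov, c_rbc if kind == 0 else c_plasma))

    if not new:
        return np.zeros(3)

    vols = np.array([p[0] for p in new])
    kinds = np.array([p[1] for p in new], dtype=np.int8)
    provs = np.array([p[2] for p in new], dtype=np.int8)
    concs = np.array([p[3] for p in new])
    # all new parcels enter at the periportal mouth; keeping them at x = 0
    # gives every axial rank identical contact coverage per parcel
    xs = np.zeros(len(new))
    births = np.full(len(new), state.time_s)
    ids = state._next_parcel_id + np.arange(len(new))
    state._next_parcel_id += len(new)

    state.x = np.concatenate([xs, state.x])
    state.vol = np.concatenate([vols, state.vol])
    state.kind = np.concatenate([kinds, state.kind])
    state.provenance = np.concatenate([provs, state.provenance])
    state.conc = np.concatenate([concs, state.conc])
    state.birth_time = np.concatenate([births, state.birth_time])
    state.parcel_id = np.concatenate([ids, state.parcel_id])
    added = (concs * vols[:, None]).sum(axis=0) * UM3_TO_L
    state.total_injected += added
    return added


# ---------------------------------------------------------------------------
# Advection
# ---------------------------------------------------------------------------

def advect(state: SinusoidState, dt: float) -> np.ndarray:
    """Move every parcel downstream by ``flow_speed * dt``.

    Parcels crossing the central-vein end are deleted; their full molar
    content is added to the outflow accumulator.  Returns the moles that
    exited during this call.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    cfg = state.config
    state.x = state.x + cfg.flow_speed * dt
    state.time_s += dt
    exited = state.x > cfg.l_SIN
    out = np.zeros(3)
    if np.any(exited):
        out = (state.conc[exited] * state.vol[exited, None]).sum(axis=0) \
            * UM3_TO_L
        state.outflow += out
        state.total_drained += out
        # exact plug-flow crossing time relative to (back-dated) birth
        state.residence_sum += float(np.sum(
            state.time_s - (state.x[exited] - cfg.l_SIN) / cfg.flow_speed
            - state.birth_time[exited]))
        state.exit_count += int(exited.sum())
        keep = ~exited
        for name in ("x", "vol", "kind", "provenance", "birth_time",
                     "parcel_id"):
            setattr(state, name, getattr(state, name)[keep])
        state.conc = state.conc[keep]
    return out


# ---------------------------------------------------------------------------
# Contact graph
# ---------------------------------------------------------------------------

@dataclass
class ContactGraph:
    """Symmetric neighbour structure over parcels and hepatocytes.

    ``parcel_rank`` maps each parcel to its axial hepatocyte rank; a
    parcel contacts both hepatocytes of that rank plus its axial
    predecessor/successor parcels within the gap cutoff.  Hepatocytes
    additionally contact their same-side axial neighbours.
    """

    parcel_rank: np.ndarray          # (n_parcels,) int
    parcel_left: np.ndarray          # bool, contact with predecessor
    parcel_right: np.ndarray         # bool, contact with successor
    parcels_per_rank: np.ndarray     # (n_ranks,) int
    n_parcel: np.ndarray             # neighbour count per parcel
    n_hep: np.ndarray                # neighbour count per hepatocyte
    hep_side: np.ndarray
    hep_rank: np.ndarray
    n_ranks: int

    def neighbors(self, entity: tuple[str, int]) -> list[tuple[str, int]]:
        """Neighbour list for ``("parcel", i)`` or ``("hep", j)`` (tests/IO)."""
        kind, i = entity
        out: list[tuple[str, int]] = []
        if kind == "parcel":
            if self.parcel_left[i]:
                out.append(("parcel", i - 1))
            if self.parcel_right[i]:
                out.append(("parcel", i + 1))
            r = self.parcel_rank[i]
            for j in np.nonzero(self.hep_rank == r)[0]:
                out.append(("hep", int(j)))
        elif kind == "hep":
            r = self.hep_rank[i]
            for p in np.nonzero(self.parcel_rank == r)[0]:
                out.append(("parcel", int(p)))
        else:
            raise KeyError(entity)
        return out


def contact_graph(state: SinusoidState) -> ContactGraph:
    """Build the instantaneous contact graph (parcels must be x-sorted)."""
    cfg = state.config
    n = state.n_parcels
    # small tolerance so accumulated rounding in x cannot flip the rank of
    # a parcel sitting exactly on a span boundary
    rank = np.clip(((state.x + 1e-6) / cfg.rank_span).astype(int),
                   0, cfg.n_ranks - 1)
    gaps = np.diff(state.x) if n > 1 else np.empty(0)
    touch = gaps <= _GAP_CUTOFF_UM
    left = np.zeros(n, dtype=bool)
    right = np.zeros(n, dtype=bool)
    if n > 1:
        right[:-1] = touch
        left[1:] = touch
    per_rank = np.bincount(rank, minlength=cfg.n_ranks) if n else np.zeros(
        cfg.n_ranks, dtype=int)
    n_parcel = left.astype(int) + right.astype(int) + 2  # 2 hepatocytes
    # hepatocytes contact only the parcels passing their span; the fixed
    # cells do not form contact edges with each other in this geometry,
    # so the tabulated H->H passive pathway has no active pairs here
    n_hep = per_rank[state.hep_rank]
    return ContactGraph(parcel_rank=rank, parcel_left=left,
                        parcel_right=right, parcels_per_rank=per_rank,
                        n_parcel=n_parcel, n_hep=n_hep,
                        hep_side=state.hep_side, hep_rank=state.hep_rank,
                        n_ranks=cfg.n_ranks)


# ---------------------------------------------------------------------------
# Transfer kinetics
# ---------------------------------------------------------------------------

def transfer_step(state: SinusoidState, graph: ContactGraph,
                  rates: TransferRates, Fup: float | None = None,
                  dt: float | None = None) -> None:
    """Exchange compound between contacting entities over ``dt`` seconds.

    Explicit Euler on the pairwise fluxes with conservative sub-stepping:
    if any entity would lose more than 20 % of a compound in one step the
    step is halved recursively.  Total moles over parcels plus hepatocytes
    are conserved to rounding.
    """
    cfg = state.config
    if dt is None:
        dt = cfg.dt_transport
    if Fup is None:
        Fup = state.Fup
    if dt <= 0:
        raise ValueError("dt must be > 0")
    _transfer_once(state, graph, rates, Fup, dt, depth=0)


def _transfer_once(state: SinusoidState, graph: ContactGraph,
                   rates: TransferRates, Fup: float, dt: float,
                   depth: int) -> None:
    cfg = state.config
    n = state.n_parcels
    hep = state.hep_conc
    VH = cfg.Vol_HEP
    k = rates.k_PD

    # molar deltas (units: um^3 * mmol/L; convert only at the ledger edges)
    d_parcel = np.zeros((max(n, 1), 3))[:n]
    d_hep = np.zeros((hep.shape[0], 3))

    hep_apap = hep[:, _EXCHANGE_IDX[0]]
    hep_g = hep[:, _EXCHANGE_IDX[1]]
    hep_s = hep[:, _EXCHANGE_IDX[2]]
    n_hep = np.maximum(graph.n_hep, 1)
    # mean per-rank hepatocyte APAP "pair rate" for parcel gains: each
    # parcel in rank r receives one pair flux from each of the 2 cells
    rank_cells = [np.nonzero(state.hep_rank == r)[0]
                  for r in range(cfg.n_ranks)]

    if n:
        ca = state.conc[:, 0]
        is_s = state.kind == 1
        np_i = graph.n_parcel.astype(float)

        # --- parcel -> hepatocyte (passive + active), per pair, 2 cells ---
        k_to_h = np.where(is_s, k["S2H"], k["R2H"])
        pass_rate = k_to_h * ca / np_i                      # mmol/L/s per pair
        act_rate = np.where(
            is_s,
            rates.Vmax_AT_APAP * ca / (ca + rates.Km_AT_APAP * Fup),
            0.0)
        per_pair = (pass_rate + act_rate) * state.vol * dt  # um^3*mmol/L
        d_parcel[:, 0] -= 2.0 * per_pair
        for r in range(cfg.n_ranks):
            sel = graph.parcel_rank == r
            if np.any(sel):
                gain = per_pair[sel].sum()
                d_hep[rank_cells[r], 0] += gain

        # --- hepatocyte -> parcel (passive APAP + metabolite export) ------
        # per-parcel gains: one pair flux from each of the 2 cells of its rank
        k_h2p = np.where(is_s, k["H2S"], k["H2R"])
        for r in range(cfg.n_ranks):
            sel = graph.parcel_rank == r
            if not np.any(sel):
                continue
            cells = rank_cells[r]
            # APAP passive, per (cell, parcel) pair, divided by cell's n
            apap_pair = (hep_apap[cells] / n_hep[cells])  # per cell
            for c_i, c_pair in zip(cells, apap_pair):
                flux = k_h2p[sel] * c_pair * VH * dt
                d_parcel[sel, 0] += flux
                d_hep[c_i, 0] -= flux.sum()
            # metabolite export, per pair, undivided
            n_sel = int(sel.sum())
            for c_i in cells:
                fg = rates.k_AT_APAPG * hep_g[c_i] * VH * dt
                fs = rates.k_AT_APAPS * hep_s[c_i] * VH * dt
                d_parcel[sel, 1] += fg
                d_parcel[sel, 2] += fs
                d_hep[c_i, 1] -= fg * n_sel
                d_hep[c_i, 2] -= fs * n_sel

        # --- parcel <-> parcel passive APAP -------------------------------
        if n > 1:
            k_pp = np.array([[k["R2R"], k["R2S"]],
                             [k["S2R"], k["S2S"]]])
            li = np.nonzero(graph.parcel_left)[0]     # pairs (i-1, i)
            if li.size:
                src, dst = li, li - 1
                for a, b in ((src, dst), (dst, src)):
                    kk = k_pp[state.kind[a], state.kind[b]]
                    flux = kk * ca[a] / np_i[a] * state.vol[a] * dt
                    np.add.at(d_parcel[:, 0], a, -flux)
                    np.add.at(d_parcel[:, 0], b, flux)

    # --- sub-stepping guard ------------------------------------------------
    content_p = state.conc * state.vol[:, None] if n else np.zeros((0, 3))
    content_h = hep[:, _EXCHANGE_IDX] * VH
    with np.errstate(divide="ignore", invalid="ignore"):
        frac_p = np.where(content_p > 0, -d_parcel / content_p, 0.0) if n \
            else np.zeros((0, 3))
        frac_h = np.where(content_h > 0, -d_hep / content_h, 0.0)
    worst = max(frac_p.max(initial=0.0), frac_h.max(initial=0.0))
    if worst > 0.2:
        if dt / 2 < _MIN_SUBSTEP_S:
            raise RuntimeError(
                "transfer sub-stepping reached the minimum step size")
        _transfer_once(state, graph, rates, Fup, dt / 2, depth + 1)
        _transfer_once(state, graph, rates, Fup, dt / 2, depth + 1)
        return

    if n:
        state.conc = np.clip(state.conc + d_parcel / state.vol[:, None],
                             0.0, None)
    hep[:, _EXCHANGE_IDX] = np.clip(hep[:, _EXCHANGE_IDX] + d_hep / VH,
                                    0.0, None)


# ---------------------------------------------------------------------------
# Standalone pulse experiment
# ---------------------------------------------------------------------------

def run_pulse_experiment(config: SinusoidConfig, rates: TransferRates,
                         pulse_conc: float, pulse_start: float = 1.0,
                         pulse_duration: float = 3.0,
                         total_time: float = 10.0,
                         subcell_params: SubcellParams | None = None,
                         rb2p: Sequence[float] = (1.09, 0.55, 0.55),
                         Fup: float = 0.8,
                         record_every: int = 10) -> pd.DataFrame:
    """Square-pulse loading of a standalone sinusoid.

    A blood APAP concentration of ``pulse_conc`` mmol/L is pushed into the
    periportal end for ``pulse_duration`` seconds starting at
    ``pulse_start``; inflow is zero otherwise.  Hepatocyte APAP rises
    while the pulse passes (passive plus active import) and decays more
    slowly afterwards (passive efflux only).  Returns a tidy entity trace
    ``time_s, entity_id, entity_type, x_um, compound, conc_mmol_per_L``.
    """
    state = build_sinusoid(config, subcell_params, rb2p, Fup)
    dt = config.dt_transport
    n_steps = int(round(total_time / dt))
    spawn_every = max(1, int(round(config.dt_inflow / dt)))
    rows: list[pd.DataFrame] = []

    def record() -> None:
        for ci, comp in enumerate(("APAP", "APAPG", "APAPS")):
            if state.n_parcels:
                rows.append(pd.DataFrame({
                    "time_s": state.time_s,
                    "entity_id": [f"P{i}" for i in state.parcel_id],
                    "entity_type": np.where(state.kind == 0, "RBC", "serum"),
                    "x_um": state.x, "compound": comp,
                    "conc_mmol_per_L": state.conc[:, ci]}))
            rows.append(pd.DataFrame({
                "time_s": state.time_s,
                "entity_id": [f"H{s}_{r}" for s, r in
                              zip(state.hep_side, state.hep_rank)],
                "entity_type": "hepatocyte",
                "x_um": (state.hep_rank + 0.5) * config.rank_span,
                "compound": comp,
                "conc_mmol_per_L": state.hep_conc[:, _EXCHANGE_IDX[ci]]}))

    record()
    for step in range(n_steps):
        t = step * dt
        if step % spawn_every == 0:
            in_pulse = pulse_start <= t < pulse_start + pulse_duration
            conc = np.array([pulse_conc if in_pulse else 0.0, 0.0, 0.0])
            spawn_parcels(state, conc, dt=config.dt_inflow)
        transfer_step(state, contact_graph(state), rates, Fup, dt)
        if subcell_params is not None:
            state.hep_conc += derivatives_vec(
                state.hep_conc, subcell_params, state.zone_scale) * dt
            np.clip(state.hep_conc, 0.0, None, out=state.hep_conc)
        advect(state, dt)
        if (step + 1) % record_every == 0:
            record()
    return pd.concat(rows, ignore_index=True)


def heatmap_grid(trace: pd.DataFrame, compound: str = "APAP",
                 entity_type: str = "hepatocyte",
                 n_bins: int = 10, l_SIN: float = 200.0) -> pd.DataFrame:
    """Pivot an entity trace into a time x axial-position concentration grid.

    Rows are recorded times, columns the centres of ``n_bins`` axial bins
    (um); values are mean concentrations (mmol/L) of the selected entity
    type — a rendering-ready dump for the usual space-time heat maps.
    """
    sel = trace[(trace["compound"] == compound)
                & (trace["entity_type"].isin(
                    ["RBC", "serum"] if entity_type == "blood"
                    else [entity_type]))].copy()
    edges = np.linspace(0.0, l_SIN, n_bins + 1)
    centres = (edges[:-1] + edges[1:]) / 2.0
    sel["x_bin"] = pd.cut(sel["x_um"], edges, labels=centres,
                          include_lowest=True)
    grid = sel.pivot_table(index="time_s", columns="x_bin",
                           values="conc_mmol_per_L", aggfunc="mean",
                           observed=True)
    grid.columns = [float(c) for c in grid.columns]
    return grid


# ---------------------------------------------------------------------------
# Quasi-steady exchange (used by the multiscale coupler)
# ---------------------------------------------------------------------------

def quasi_steady_exchange(config: SinusoidConfig, rates: TransferRates,
                          hep_conc: np.ndarray,
                          inflow_blood_conc: np.ndarray,
                          rb2p: np.ndarray, Fup: float,
                          dt_sub: float | None = None) -> dict:
    """Steady-state blood-cell exchange rates for frozen hepatocytes.

    Because a parcel's one-second transit is far shorter than any
    whole-body timescale, the sinusoid relaxes to a quasi-steady profile
    for the current inflow within each coupling step.  This routine
    marches one representative RBC/serum parcel pair down the axis
    (explicit Euler at the transport step ``dt_sub``, expected neighbour
    composition) and aggregates, per hepatocyte rank and side:

    * ``uptake`` (n_ranks, 3): gross blood -> cell molar rate, mmol/s
      per single sinusoid per cell;
    * ``export`` (n_ranks, 3): gross cell -> blood rate, same units;
    * ``inflow`` / ``outflow`` (3,): molar throughput rates, mmol/s.

    ``outflow == inflow - 2*sum(uptake) + 2*sum(export)`` holds to
    rounding, which the coupler uses for exact mole bookkeeping.
    ``hep_conc`` holds the (side-symmetric) per-rank hepatocyte
    concentrations of APAP, APAPG, APAPS, shape (n_ranks, 3).
    """
    cfg = config
    if dt_sub is None:
        dt_sub = cfg.dt_transport
    n_ranks = cfg.n_ranks
    k = rates.k_PD
    hct = cfg.hematocrit
    q_um3 = cfg.volumetric_flow                     # um^3/s
    rho_R = q_um3 * hct / cfg.Vol_RBC               # RBC parcels / s
    rho_S = q_um3 * (1 - hct) / cfg.Vol_SP          # serum parcels / s
    p_R = rho_R / (rho_R + rho_S)
    p_S = 1.0 - p_R
    residence = cfg.rank_span / cfg.flow_speed      # s per rank
    parcels_per_rank = (rho_R + rho_S) * residence
    n_hep = np.full(n_ranks, parcels_per_rank)      # expected neighbour count
    n_parcel = 4.0                                  # 2 parcels + 2 cells

    c_plasma, c_rbc = _partition_load(
        np.clip(np.asarray(inflow_blood_conc, float), 0, None), rb2p, hct)
    cs = c_plasma.copy()        # serum cohort concentration (3,)
    cr = c_rbc.copy()           # RBC cohort concentration (3,)
    VS, VR, VH = cfg.Vol_SP, cfg.Vol_RBC, cfg.Vol_HEP

    inflow = (rho_S * VS * cs + rho_R * VR * cr) * UM3_TO_L   # mmol/s
    uptake = np.zeros((n_ranks, 3))
    export = np.zeros((n_ranks, 3))

    h_apap = hep_conc[:, 0]
    h_g = hep_conc[:, 1]
    h_s = hep_conc[:, 2]

    n_sub = max(1, int(round(cfg.transit_time / dt_sub)))
    dt = cfg.transit_time / n_sub
    kmf = rates.Km_AT_APAP * Fup
    pair_sr = 2.0 * p_R     # expected RBC neighbours of a serum parcel
    for i in range(n_sub):
        tau = (i + 0.5) * dt
        r = min(int(tau * cfg.flow_speed / cfg.rank_span), n_ranks - 1)
        # blood -> cell, per pair, one cell; both sides identical
        s2h = (k["S2H"] * cs[0] / n_parcel
               + rates.Vmax_AT_APAP * cs[0] / (cs[0] + kmf)) * VS * dt
        r2h = k["R2H"] * cr[0] / n_parcel * VR * dt
        # cell -> blood per pair
        h2s = k["H2S"] * h_apap[r] / n_hep[r] * VH * dt
        h2r = k["H2R"] * h_apap[r] / n_hep[r] * VH * dt
        exg = rates.k_AT_APAPG * h_g[r] * VH * dt
        exs = rates.k_AT_APAPS * h_s[r] * VH * dt
        # RBC <-> serum passive APAP via expected pairs
        s2r = k["S2R"] * cs[0] / n_parcel * VS * dt
        r2s = k["R2S"] * cr[0] / n_parcel * VR * dt

        # per-cell uptake/export accumulation, scaled by parcel throughput
        uptake[r, 0] += (rho_S * s2h + rho_R * r2h) * UM3_TO_L
        export[r, 0] += (rho_S * h2s + rho_R * h2r) * UM3_TO_L
        export[r, 1] += (rho_S + rho_R) * exg * UM3_TO_L
        export[r, 2] += (rho_S + rho_R) * exs * UM3_TO_L

        # cohort updates (2 cells contacted; both sides)
        # expected cross-kind pairs satisfy rho_S*2*p_R == rho_R*2*p_S,
        # so the per-parcel pair counts below conserve moles exactly
        cs[0] += (2.0 * (h2s - s2h) + pair_sr * (r2s - s2r)) / VS
        cr[0] += (2.0 * (h2r - r2h) + 2.0 * p_S * (s2r - r2s)) / VR
        cs[1] += 2.0 * exg / VS
        cr[1] += 2.0 * exg / VR
        cs[2] += 2.0 * exs / VS
        cr[2] += 2.0 * exs / VR
        np.clip(cs, 0.0, None, out=cs)
        np.clip(cr, 0.0, None, out=cr)

    outflow = (rho_S * VS * cs + rho_R * VR * cr) * UM3_TO_L
    return {"uptake": uptake, "export": export,
            "inflow": inflow, "outflow": outflow,
            "outflow_conc_serum": cs.copy(), "outflow_conc_rbc": cr.copy()}
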