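"""Coupling of the whole-body, sinusoid and subcellular scales.

Three replicates of the whole-body PBPK model (APAP, APAPG, APAPS) run
with their liver compartments bypassed: the hepatic inflows
(``CArt -> CLiver`` and ``CGut -> CLiver`` of the compartment network) are
diverted into a representative sinusoid, which carries the compound past
20 zonated hepatocytes, each integrating its own Phase I/II reaction
network; whatever reaches the central vein — unabsorbed compound plus
exported conjugates — is returned to the venous compartment of the
matching PBPK replicate.

Scale bridging.  The liver is represented as ``S`` parallel copies of the
simulated sinusoid, with ``S = VLiver * lumen_fraction / V_sinusoid``
(about 7.9e9 for the reference liver, :func:`liver_scale_factor`).  The
bank of ``S`` sinusoids, each carrying plug flow at 200 um/s, implies an
effective hepatic perfusion ``S * Q_sinusoid`` (about 456 L/h); the
arterial and portal compartments are debited at that effective rate,
split in the QLiver:QGut proportion of the compartment model's flows, and
everything reaching the central vein is returned (scaled by ``S``) to the
venous compartment, so moles balance exactly even though the effective
perfusion exceeds the nominal hepatic blood flow — a direct consequence
of fixing both the lumen fraction and the flow speed.

Two coupling modes:

* ``quasi_steady_state`` (default): each coupling step (default 10 s)
  propagates the PBPK replicates with a precomputed matrix exponential,
  computes steady-state blood-cell exchange rates for the current inflow
  (:func:`hepasim.sinusoid.quasi_steady_exchange`) and applies them as
  constant sources over the step while the hepatocytes integrate their
  reaction networks.  Justified because a parcel's 1 s transit is four
  orders of magnitude below the whole-body dynamics.
* ``explicit``: the discrete parcel engine runs at its native cadence
  (transport and subcellular updates every 10 Monte-Carlo-step
  equivalents = 16.7 ms, parcel creation every 33 ms), which makes it
  practical only for sub-hour horizons.

Both modes conserve total moles exactly by construction: every diverted
mole ends up in a parcel, a hepatocyte (scaled by the replicate count), a
PBPK compartment or the inflow reservoir.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from .params import COMPOUNDS, ParameterSet
from .pbpk import (BodyParams, CompoundParams, GutUptakeModel,
                   body_params_from, compound_params_from, dose_to_mmol,
                   pbpk_matrix, N_STATES, STATE_FIELDS)
from .sinusoid import (SinusoidConfig, TransferRates, UM3_TO_L,
                       build_sinusoid, advect, contact_graph, spawn_parcels,
                       transfer_step, quasi_steady_exchange)
from .subcell import (SPECIES, SubcellParams, derivatives_vec,
                      integrate_cells, subcell_params_from)

__all__ = [
    "ScaleBridge",
    "MultiscaleResult",
    "liver_scale_factor",
    "run_multiscale",
]

_IDX = {name: i for i, name in enumerate(STATE_FIELDS)}
_EX = np.array([SPECIES.index("APAP"), SPECIES.index("APAPG"),
                SPECIES.index("APAPS")])


def liver_scale_factor(VLiver_L: float, lumen_fraction: float,
                       V_sinusoid_L: float) -> float:
    """Volume-derived sinusoid replicate count:
    ``VLiver * lumen_fraction / V_sinusoid``."""
    if V_sinusoid_L <= 0:
        raise ValueError("sinusoid volume must be positive")
    return VLiver_L * lumen_fraction / V_sinusoid_L


@dataclass(frozen=True)
class ScaleBridge:
    """Scale factors and cadence linking the PBPK and sinusoid scales."""

    S: float                    # sinusoid replicate count (volume-derived)
    hepatic_flow: float = 0.0   # effective diverted blood flow, L/h = S*Q_sin
    lumen_fraction: float = 0.074
    dt_coupling: float = 10.0   # s
    mode: str = "quasi_steady_state"

    def __post_init__(self) -> None:
        if self.S <= 0 or self.dt_coupling <= 0:
            raise ValueError("scale factors and dt_coupling must be positive")
        if self.mode not in ("quasi_steady_state", "explicit"):
            raise ValueError(f"unknown coupling mode {self.mode!r}")

    @classmethod
    def for_model(cls, body: BodyParams, config: SinusoidConfig,
                  lumen_fraction: float = 0.074,
                  mode: str = "quasi_steady_state",
                  dt_coupling: float | None = None) -> "ScaleBridge":
        v_sin = config.lumen_volume * UM3_TO_L
        q_sin = config.volumetric_flow * UM3_TO_L          # L/s
        if dt_coupling is None:
            dt_coupling = (10.0 if mode == "quasi_steady_state"
                           else config.dt_transport)
        S = liver_scale_factor(body.VLiver, lumen_fraction, v_sin)
        return cls(S=S, hepatic_flow=S * q_sin * 3600.0,
                   lumen_fraction=lumen_fraction,
                   dt_coupling=dt_coupling, mode=mode)


@dataclass
class MultiscaleResult:
    """Trajectories of an 8-hour (or shorter) coupled simulation."""

    times: np.ndarray                    # h, coupling/recording grid
    amounts: dict[str, np.ndarray]       # compound -> (n_t, 10) mmol
    hep_traces: np.ndarray               # (n_t, n_hepatocytes, 6) mmol/L
    hep_side: np.ndarray
    hep_rank: np.ndarray
    body: BodyParams
    compounds: dict[str, CompoundParams]
    bridge: ScaleBridge
    config: SinusoidConfig
    subcell: SubcellParams
    dose_mmol: float
    reservoir: np.ndarray = field(default_factory=lambda: np.zeros(3))
    parcel_moles: np.ndarray = field(default_factory=lambda: np.zeros(3))
    meta: dict = field(default_factory=dict)

    def amount(self, compound: str, compartment: str) -> np.ndarray:
        return self.amounts[compound][:, _IDX[compartment]]

    def serum_concentration(self, compound: str) -> np.ndarray:
        """Venous plasma concentration (mmol/L): (CVen/VVen)/Rb2p."""
        return (self.amount(compound, "CVen") / self.body.VVen
                / self.compounds[compound].Rb2p)

    def tubule_amounts(self, t_index: int = -1) -> dict[str, float]:
        return {c: float(self.amount(c, "CTubules")[t_index])
                for c in self.amounts}

    def hepatocyte_moles(self, t_index: int = -1) -> np.ndarray:
        """Scaled liver content of the exchange species (mmol)."""
        return (self.hep_traces[t_index][:, _EX].sum(axis=0)
                * self.config.Vol_HEP * UM3_TO_L * self.bridge.S)

    def napqigsh_sum(self, t_index: int = -1) -> float:
        """Total NAPQI-GSH across the scaled liver (mmol)."""
        i = SPECIES.index("NAPQI_GSH")
        return float(self.hep_traces[t_index][:, i].sum()
                     * self.config.Vol_HEP * UM3_TO_L * self.bridge.S)

    def total_moles(self, t_index: int = -1) -> float:
        """Global mole ledger: PBPK + scaled hepatocytes + blood in transit.

        Phase II conjugation is 1:1 molar, so the sum is conserved and
        equals the dose for the parent-compound bookkeeping.
        """
        tot = sum(self.amounts[c][t_index].sum() for c in self.amounts)
        tot += self.hepatocyte_moles(t_index).sum()
        # NAPQI pathway species also carry APAP equivalents
        for sp in ("NAPQI", "NAPQI_GSH"):
            i = SPECIES.index(sp)
            tot += (self.hep_traces[t_index][:, i].sum()
                    * self.config.Vol_HEP * UM3_TO_L * self.bridge.S)
        tot += self.reservoir.sum() + self.parcel_moles.sum()
        return float(tot)

    def conservation_error(self) -> float:
        """|final total - dose| / dose."""
        if self.dose_mmol == 0:
            return 0.0
        return abs(self.total_moles(-1) - self.dose_mmol) / self.dose_mmol


def _coupled_matrix(body: BodyParams, comp: CompoundParams,
                    kGutabs: float, hepatic_flow: float) -> np.ndarray:
    """11-state linear system: bypassed PBPK + hepatic inflow buffer.

    ``hepatic_flow`` (L/h) is the effective diverted perfusion of the
    scaled sinusoid bank, split between the arterial and portal sources
    in the QLiver:QGut proportion.
    """
    A = np.zeros((N_STATES + 1, N_STATES + 1))
    A[:N_STATES, :N_STATES] = pbpk_matrix(body, comp, kGutabs=kGutabs,
                                          bypass_liver=True)
    ia, ig, ibuf = _IDX["CArt"], _IDX["CGut"], N_STATES
    w = hepatic_flow / (body.QLiver + body.QGut)
    for src, q in ((ia, w * body.QLiver / body.VArt),
                   (ig, w * body.QGut / body.VGut)):
        A[src, src] -= q
        A[ibuf, src] += q
    return A


def run_multiscale(params: ParameterSet, dose_mg_per_kg: float = 20.0,
                   duration_h: float = 8.0,
                   bridge: ScaleBridge | None = None,
                   mode: str = "quasi_steady_state",
                   dt_coupling: float | None = None,
                   uptake: GutUptakeModel | None = None,
                   dose_bw_kg: float | None = None,
                   record_every: int | None = None,
                   check_conservation: bool = True) -> MultiscaleResult:
    """Run the fully coupled three-scale model.

    The molar dose (``dose_mg_per_kg`` times ``dose_bw_kg``, defaulting to
    the physiological body weight) starts in the parent's gut lumen.  See
    the module docstring for the coupling cycle; ``record_every`` thins
    the stored trajectory (default keeps roughly 1000 frames).
    """
    body = body_params_from(params)
    compounds = {c: compound_params_from(params, c) for c in COMPOUNDS}
    config = SinusoidConfig.from_params(params)
    sc_params = subcell_params_from(params)
    rb2p = np.array([compounds[c].Rb2p for c in COMPOUNDS])
    if bridge is None:
        bridge = ScaleBridge.for_model(
            body, config, lumen_fraction=params["lumen_fraction"],
            mode=mode, dt_coupling=dt_coupling)
    uptake = uptake or GutUptakeModel()

    if bridge.mode == "quasi_steady_state":
        return _run_qss(params, body, compounds, config, sc_params, rb2p,
                        bridge, dose_mg_per_kg, duration_h, uptake,
                        dose_bw_kg, record_every, check_conservation)
    return _run_explicit(params, body, compounds, config, sc_params, rb2p,
                         bridge, dose_mg_per_kg, duration_h, uptake,
                         dose_bw_kg, record_every, check_conservation)


def _nonlinear_absorption(y: np.ndarray, uptake: GutUptakeModel, t_h: float,
                          dt_h: float) -> None:
    """Advance saturable gut uptake over one step (sub-Euler), in place."""
    a = y[_IDX["AGutlumen"]]
    n_sub = 8
    h = dt_h / n_sub
    absorbed = 0.0
    for i in range(n_sub):
        t = t_h + i * h
        if t < uptake.lag:
            continue
        rate = uptake.Vmax_gut * a / (uptake.Km_gut + a)
        da = min(rate * h, a)
        a -= da
        absorbed += da
    y[_IDX["AGutlumen"]] = a
    y[_IDX["CGut"]] += absorbed


def _run_qss(params, body, compounds, config, sc_params, rb2p, bridge,
             dose_mg_per_kg, duration_h, uptake, dose_bw_kg, record_every,
             check_conservation) -> MultiscaleResult:
    dt = bridge.dt_coupling
    dt_h = dt / 3600.0
    n_steps = int(round(duration_h * 3600.0 / dt))
    if record_every is None:
        record_every = max(1, n_steps // 1000)
    first_order = uptake.variant == "first_order"

    phi, gcol = {}, {}
    for c in COMPOUNDS:
        ka = compounds[c].kGutabs if first_order else 0.0
        A = _coupled_matrix(body, compounds[c], ka, bridge.hepatic_flow)
        phi[c] = expm(A * dt_h)
        # G = int_0^dt exp(A s) ds by series (||A dt|| < 1 here); its CVen
        # column turns a constant venous-return rate into an exact update
        G = np.eye(A.shape[0]) * dt_h
        term = np.eye(A.shape[0]) * dt_h
        for k in range(2, 25):
            term = term @ (A * dt_h) / k
            G += term
        gcol[c] = G[:, _IDX["CVen"]]

    y = {c: np.zeros(N_STATES + 1) for c in COMPOUNDS}
    bw_for_dose = body.bw if dose_bw_kg is None else dose_bw_kg
    dose = dose_to_mmol(dose_mg_per_kg, bw_for_dose)
    y["APAP"][_IDX["AGutlumen"]] = dose

    n_ranks = config.n_ranks
    hep = np.zeros((n_ranks, len(SPECIES)))          # side-symmetric
    hep[:, SPECIES.index("GSH")] = sc_params.GSH0
    zone = config.zone_scales()
    VH_L = config.Vol_HEP * UM3_TO_L
    q_hepatic_h = body.QLiver + body.QGut            # L/h

    rates = TransferRates.from_params(params)
    times, recs, hep_recs = [], {c: [] for c in COMPOUNDS}, []

    def record(t_h: float) -> None:
        times.append(t_h)
        for c in COMPOUNDS:
            recs[c].append(y[c][:N_STATES].copy())
        hep_recs.append(hep.copy())

    record(0.0)
    def mixed_conc() -> np.ndarray:
        return np.array([
            (body.QLiver * y[c][_IDX["CArt"]] / body.VArt
             + body.QGut * y[c][_IDX["CGut"]] / body.VGut) / q_hepatic_h
            for c in COMPOUNDS])

    # venous return is applied as a continuous source during propagation
    # (previous step's rate); only the step-to-step rate change remains a
    # small end-of-step lump, making the splitting second order
    ret_rate = np.zeros(len(COMPOUNDS))     # mmol per step

    for step in range(n_steps):
        t_h = step * dt_h
        c_pre = mixed_conc()
        # 1) whole-body propagation with hepatic flows into the buffer
        for i, c in enumerate(COMPOUNDS):
            if not first_order and c == "APAP":
                _nonlinear_absorption(y[c], uptake, t_h, dt_h)
            y[c] = phi[c] @ y[c] + (ret_rate[i] / dt_h) * gcol[c]
        buffers = np.array([y[c][N_STATES] for c in COMPOUNDS])
        for c in COMPOUNDS:
            y[c][N_STATES] = 0.0
        # midpoint inflow concentration (flow-weighted mix) cancels the
        # leading operator-splitting error of the coupling step
        c_in = 0.5 * (c_pre + mixed_conc())

        # 2-5) quasi-steady sinusoid exchange for the current inflow
        ex = quasi_steady_exchange(config, rates, hep[:, _EX], c_in, rb2p,
                                   compounds["APAP"].Fup)
        net = ex["uptake"] - ex["export"]            # (n_ranks, 3) mmol/s
        applied = 2.0 * net.sum(axis=0) * dt * bridge.S
        # guard: never draw more than the buffer provides
        scale = 1.0
        over = applied > buffers + 1e-30
        if np.any(over & (applied > 0)):
            scale = float(np.min(np.where(
                over & (applied > 0), buffers / np.maximum(applied, 1e-300),
                1.0)))
            net = net * scale
            applied = 2.0 * net.sum(axis=0) * dt * bridge.S

        # 6) subcellular step with the exchange flux as a constant source
        source = np.zeros((n_ranks, len(SPECIES)))
        source[:, _EX] = net / VH_L                  # mmol/L/s per cell
        hep = integrate_cells(hep, sc_params, zone, dt, source=source)

        # 7) return the remainder to the venous compartment: reconcile the
        # continuous source already applied against this step's actual
        # return so that moles balance exactly
        for i, c in enumerate(COMPOUNDS):
            ret = buffers[i] - applied[i]
            already = (ret_rate[i] / dt_h) * gcol[c].sum()
            y[c][_IDX["CVen"]] += ret - already
            ret_rate[i] = ret

        if check_conservation and (step % 200 == 199 or step == n_steps - 1):
            tot = sum(y[c][:N_STATES].sum() + y[c][N_STATES]
                      for c in COMPOUNDS)
            tot += 2.0 * hep[:, [SPECIES.index(s) for s in
                                 ("APAP", "NAPQI", "NAPQI_GSH",
                                  "APAPG", "APAPS")]].sum() \
                * VH_L * bridge.S
            if dose > 0 and abs(tot - dose) / dose > 1e-6:
                raise RuntimeError(
                    f"mole conservation violated at t = {t_h:.3f} h: "
                    f"ledger {tot:.9g} mmol vs dose {dose:.9g} mmol")

        if (step + 1) % record_every == 0 or step == n_steps - 1:
            record((step + 1) * dt_h)

    # mirror the side-symmetric ranks onto the full 2 x n_ranks layout
    hep_side = np.repeat([0, 1], n_ranks)
    hep_rank = np.tile(np.arange(n_ranks), 2)
    hep_arr = np.asarray(hep_recs)
    hep_full = hep_arr[:, hep_rank, :]   # sides are identical by symmetry
    return MultiscaleResult(
        times=np.asarray(times),
        amounts={c: np.asarray(recs[c]) for c in COMPOUNDS},
        hep_traces=hep_full, hep_side=hep_side, hep_rank=hep_rank,
        body=body, compounds=compounds, bridge=bridge, config=config,
        subcell=sc_params, dose_mmol=dose,
        reservoir=np.zeros(3), parcel_moles=np.zeros(3),
        meta={"mode": "quasi_steady_state", "dt_coupling_s": dt,
              "n_steps": n_steps, "dose_mg_per_kg": dose_mg_per_kg})


def _run_explicit(params, body, compounds, config, sc_params, rb2p, bridge,
                  dose_mg_per_kg, duration_h, uptake, dose_bw_kg,
                  record_every, check_conservation) -> MultiscaleResult:
    rates = TransferRates.from_params(params)
    dt = config.dt_transport
    dt_h = dt / 3600.0
    n_steps = int(round(duration_h * 3600.0 / dt))
    if record_every is None:
        record_every = max(1, n_steps // 1000)
    spawn_every = max(1, int(round(config.dt_inflow / dt)))
    first_order = uptake.variant == "first_order"

    phi = {}
    for c in COMPOUNDS:
        ka = compounds[c].kGutabs if first_order else 0.0
        phi[c] = expm(_coupled_matrix(body, compounds[c], ka,
                                      bridge.hepatic_flow) * dt_h)

    y = {c: np.zeros(N_STATES + 1) for c in COMPOUNDS}
    bw_for_dose = body.bw if dose_bw_kg is None else dose_bw_kg
    dose = dose_to_mmol(dose_mg_per_kg, bw_for_dose)
    y["APAP"][_IDX["AGutlumen"]] = dose

    sin = build_sinusoid(config, sc_params, rb2p, compounds["APAP"].Fup)
    reservoir = np.zeros(3)     # diverted moles awaiting parcel loading
    zone = sin.zone_scale

    times, recs, hep_recs = [], {c: [] for c in COMPOUNDS}, []

    def record(t_h: float) -> None:
        times.append(t_h)
        for c in COMPOUNDS:
            recs[c].append(y[c][:N_STATES].copy())
        hep_recs.append(sin.hep_conc.copy())

    record(0.0)
    for step in range(n_steps):
        t_h = step * dt_h
        for c in COMPOUNDS:
            if not first_order and c == "APAP":
                _nonlinear_absorption(y[c], uptake, t_h, dt_h)
            y[c] = phi[c] @ y[c]
        for i, c in enumerate(COMPOUNDS):
            reservoir[i] += y[c][N_STATES]
            y[c][N_STATES] = 0.0

        if step % spawn_every == 0:
            # parcels load the flow-weighted mixed inflow concentration so
            # that loading matches the QLiver:QGut-weighted debit exactly;
            # the 1:3 arterial:venous split only labels parcel provenance
            c_mix = np.array([
                (body.QLiver * y[c][_IDX["CArt"]] / body.VArt
                 + body.QGut * y[c][_IDX["CGut"]] / body.VGut)
                / (body.QLiver + body.QGut) for c in COMPOUNDS])
            added = spawn_parcels(sin, c_mix, dt=config.dt_inflow)
            reservoir -= added * bridge.S

        transfer_step(sin, contact_graph(sin), rates,
                      compounds["APAP"].Fup, dt)
        sin.hep_conc = _rk4_subcell(sin.hep_conc, sc_params, zone, dt)
        advect(sin, dt)
        drained = sin.drain()
        for i, c in enumerate(COMPOUNDS):
            y[c][_IDX["CVen"]] += drained[i] * bridge.S

        if (step + 1) % record_every == 0 or step == n_steps - 1:
            record((step + 1) * dt_h)

    hep_full = np.asarray(hep_recs)
    result = MultiscaleResult(
        times=np.asarray(times),
        amounts={c: np.asarray(recs[c]) for c in COMPOUNDS},
        hep_traces=hep_full, hep_side=sin.hep_side, hep_rank=sin.hep_rank,
        body=body, compounds=compounds, bridge=bridge, config=config,
        subcell=sc_params, dose_mmol=dose,
        reservoir=reservoir.copy(),
        parcel_moles=sin.parcel_moles() * bridge.S,
        meta={"mode": "explicit", "dt_coupling_s": dt, "n_steps": n_steps,
              "dose_mg_per_kg": dose_mg_per_kg})
    if check_conservation and dose > 0:
        err = result.conservation_error()
        if err > 1e-4:
            raise RuntimeError(
                f"mole conservation violated: relative error {err:.3e}")
    return result


def _rk4_subcell(conc: np.ndarray, p: SubcellParams, zone: np.ndarray,
                 dt: float) -> np.ndarray:
    """One classical Runge-Kutta step for all hepatocytes (16.7 ms scale)."""
    k1 = derivatives_vec(conc, p, zone)
    k2 = derivatives_vec(np.clip(conc + 0.5 * dt * k1, 0, None), p, zone)
    k3 = derivatives_vec(np.clip(conc + 0.5 * dt * k2, 0, None), p, zone)
    k4 = derivatives_vec(np.clip(conc + dt * k3, 0, None), p, zone)
    return np.clip(conc + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4), 0, None)
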