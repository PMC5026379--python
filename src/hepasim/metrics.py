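"""Model outputs: RMSE against reference ADME curves, Cmax/Tmax/AUC,
excreted metabolic ratio, NAPQI-GSH burden and zonal summaries.

The 15-entry output vector (:class:`ModelOutputs`) is the quantity that
the sensitivity and population analyses operate on: four root-mean-square
errors (one per compound plus their sum), peak concentration, time of
peak and area under the curve for each of APAP, APAPG and APAPS, the
excreted metabolic ratio and the scaled total NAPQI-GSH formed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .params import COMPOUNDS, MOLAR_MASS

__all__ = [
    "ReferenceADME",
    "ModelOutputs",
    "OUTPUT_NAMES",
    "rmse",
    "adme_descriptors",
    "metab_ratio",
    "zonal_summary",
    "model_outputs",
]

#: Canonical ordering of the 15 model outputs.
OUTPUT_NAMES = (
    "RMSEa", "RMSEg", "RMSEs", "RMSEsum",
    "CmaxA", "CmaxG", "CmaxS",
    "TmaxA", "TmaxG", "TmaxS",
    "AUCA", "AUCG", "AUCS",
    "metabRatio", "NAPQIGSH_Sum",
)


@dataclass(frozen=True)
class ReferenceADME:
    """Reference serum concentration points per compound.

    ``points`` maps compound name to ``(times_h, concentrations)`` arrays;
    ``unit`` is either ``mmol/L`` or ``ug/mL`` (converted on comparison
    using the fixed molar masses).
    """

    points: Mapping[str, tuple[np.ndarray, np.ndarray]]
    unit: str = "mmol/L"

    def __post_init__(self) -> None:
        if self.unit not in ("mmol/L", "ug/mL"):
            raise ValueError(f"unsupported unit {self.unit!r}")
        for comp, (t, yv) in self.points.items():
            t = np.asarray(t)
            if t.size == 0:
                raise ValueError(f"{comp}: at least one point required")
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"{comp}: times must be strictly increasing")
            if len(t) != len(np.asarray(yv)):
                raise ValueError(f"{comp}: time/value length mismatch")

    def in_mmol_per_L(self, compound: str) -> tuple[np.ndarray, np.ndarray]:
        t, yv = self.points[compound]
        t = np.asarray(t, float)
        yv = np.asarray(yv, float)
        if self.unit == "ug/mL":
            yv = yv / MOLAR_MASS[compound]  # ug/mL = mg/L -> mmol/L
        return t, yv

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for comp, (t, yv) in self.points.items():
            rows.append(pd.DataFrame({
                "time_h": np.asarray(t), "compound": comp,
                "concentration": np.asarray(yv), "unit": self.unit}))
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ReferenceADME":
        units = df["unit"].unique()
        if len(units) != 1:
            raise ValueError("mixed units in reference table")
        pts = {}
        for comp, grp in df.groupby("compound"):
            grp = grp.sort_values("time_h")
            pts[comp] = (grp["time_h"].to_numpy(),
                         grp["concentration"].to_numpy())
        return cls(points=pts, unit=str(units[0]))

    @classmethod
    def read_csv(cls, path: str | Path) -> "ReferenceADME":
        return cls.from_frame(pd.read_csv(path))

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class ModelOutputs:
    """The 15-entry output vector consumed by the analyses.

    RMSE entries are ``nan`` sentinels when no reference data were
    supplied; downstream consumers exclude undefined entries.
    """

    RMSEa: float
    RMSEg: float
    RMSEs: float
    RMSEsum: float
    CmaxA: float
    CmaxG: float
    CmaxS: float
    TmaxA: float
    TmaxG: float
    TmaxS: float
    AUCA: float
    AUCG: float
    AUCS: float
    metabRatio: float
    NAPQIGSH_Sum: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in OUTPUT_NAMES])


def rmse(sim_times: Sequence[float], sim_values: Sequence[float],
         ref_times: Sequence[float], ref_values: Sequence[float]) -> float:
    """Root-mean-square error of a simulated curve against reference points.

    The simulated curve is interpolated linearly onto the reference times,
    which must lie inside the simulated span.
    """
    st = np.asarray(sim_times, float)
    sv = np.asarray(sim_values, float)
    rt = np.asarray(ref_times, float)
    rv = np.asarray(ref_values, float)
    if rt.min() < st.min() - 1e-12 or rt.max() > st.max() + 1e-12:
        raise ValueError("reference times fall outside the simulated span")
    y = np.interp(rt, st, sv)
    return float(np.sqrt(np.mean((y - rv) ** 2)))


def adme_descriptors(times: Sequence[float], values: Sequence[float],
                     ) -> tuple[float, float, float]:
    """(Cmax, Tmax, AUC) of a concentration-time series.

    Tmax is the earliest time attaining the maximum; AUC is trapezoidal
    over the full window.
    """
    t = np.asarray(times, float)
    v = np.asarray(values, float)
    if t.size == 0:
        raise ValueError("empty series")
    i = int(np.argmax(v))          # argmax returns the first maximum
    auc = float(np.trapezoid(v, t)) if t.size > 1 else 0.0
    return float(v[i]), float(t[i]), auc


def metab_ratio(apap: float, apapg: float, apaps: float) -> float:
    """Excreted metabolic ratio (G + S) / (A + G + S) of tubule amounts."""
    if min(apap, apapg, apaps) < 0:
        raise ValueError("amounts must be >= 0")
    total = apap + apapg + apaps
    if total == 0:
        raise ZeroDivisionError("metabRatio undefined for all-zero amounts")
    return (apapg + apaps) / total


def zonal_summary(hep_traces: np.ndarray, hep_side: np.ndarray,
                  hep_rank: np.ndarray, cells_per_zone: int = 4,
                  ) -> dict[str, dict[str, np.ndarray]]:
    """Periportal / midzonal / perivenous group means and SDs.

    Monitors ``cells_per_zone`` cells of one side in each of three axial
    regions: the most periportal ranks (PP), the middle ranks (MZ) and the
    most pericentral ranks (PV).  ``hep_traces`` has shape
    ``(n_t, n_cells, n_species)``.  Returns
    ``{zone: {"mean": (n_t, n_species), "sd": ...}}``.
    """
    n_cells = hep_traces.shape[1]
    if n_cells < 3 * cells_per_zone:
        raise ValueError(
            f"need at least {3 * cells_per_zone} cells, got {n_cells}")
    side0 = np.nonzero(hep_side == 0)[0]
    order = side0[np.argsort(hep_rank[side0])]
    n_ranks = order.size
    mid0 = (n_ranks - cells_per_zone) // 2
    zones = {
        "PP": order[:cells_per_zone],
        "MZ": order[mid0:mid0 + cells_per_zone],
        "PV": order[-cells_per_zone:],
    }
    return {z: {"mean": hep_traces[:, idx, :].mean(axis=1),
                "sd": hep_traces[:, idx, :].std(axis=1)}
            for z, idx in zones.items()}


def model_outputs(result, ref: ReferenceADME | None = None) -> ModelOutputs:
    """Aggregate a multiscale (or PBPK-only) result into the 15 outputs.

    ``result`` must expose ``times`` (h), ``serum_concentration(compound)``
    (mmol/L) and, for the tubule/NAPQI entries, ``tubule_amounts()`` and
    ``napqigsh_sum()``; the PBPK-only result lacks the latter, for which
    a sentinel 0 is reported.
    """
    rmses = {}
    for comp, key in zip(COMPOUNDS, ("RMSEa", "RMSEg", "RMSEs")):
        if ref is None or comp not in ref.points:
            rmses[key] = math.nan
        else:
            rt, rv = ref.in_mmol_per_L(comp)
            rmses[key] = rmse(result.times,
                              result.serum_concentration(comp), rt, rv)
    vals = [v for v in rmses.values() if not math.isnan(v)]
    rmses["RMSEsum"] = sum(vals) if vals else math.nan

    desc = {}
    for comp, suf in zip(COMPOUNDS, "AGS"):
        cmax, tmax, auc = adme_descriptors(
            result.times, result.serum_concentration(comp))
        desc[f"Cmax{suf}"] = cmax
        desc[f"Tmax{suf}"] = tmax
        desc[f"AUC{suf}"] = auc

    if hasattr(result, "tubule_amounts"):
        tub = result.tubule_amounts()
    else:
        tub = {c: float(result.amount(c, "CTubules")[-1]) for c in COMPOUNDS}
    total = sum(tub.values())
    ratio = (metab_ratio(tub["APAP"], tub["APAPG"], tub["APAPS"])
             if total > 0 else math.nan)
    napqigsh = (result.napqigsh_sum()
                if hasattr(result, "napqigsh_sum") else 0.0)
    return ModelOutputs(**rmses, **desc, metabRatio=ratio,
                        NAPQIGSH_Sum=napqigsh)
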