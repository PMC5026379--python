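"""Named parameter sets spanning the three model scales.

A :class:`ParameterSet` is a flat, immutable mapping from parameter name to
value.  Names follow the scale-prefix convention used throughout the model:
``pbpk_`` for whole-body pharmacokinetic parameters, ``cc3d_`` for
sinusoid-scale transfer parameters and ``sc_`` for subcellular reaction
parameters; geometric and scheduling constants of the sinusoid keep their
bare names (``l_SIN``, ``Vol_HEP``, ``mcs2sec`` ...).

The built-in reference set ``REFSIM`` describes a 70 kg human given an oral
acetaminophen dose and is the fixed point around which sensitivity and
population analyses operate.
"""

from __future__ import annotations

import json
import math
from collections.abc import Mapping
from pathlib import Path
from typing import Iterator

import yaml

__all__ = [
    "ParameterSet",
    "REFSIM",
    "MOLAR_MASS",
    "COMPOUNDS",
    "SENSITIVITY_SUBSET",
    "registry",
    "load_parameter_set",
    "save_parameter_set",
    "ParameterValidationError",
]

#: Compounds tracked by every scale of the model.
COMPOUNDS = ("APAP", "APAPG", "APAPS")

#: Molar masses (g/mol) used only for dose and unit conversions; internal
#: bookkeeping is molar so each Phase II conjugation is 1:1.
MOLAR_MASS = {"APAP": 151.16, "APAPG": 327.29, "APAPS": 231.23}

#: Reference body weight (kg) to which the tabulated flows/volumes apply.
REFERENCE_BW = 70.0

# ---------------------------------------------------------------------------
# Canonical values: whole-body scale (flows L/h, volumes L), sinusoid scale
# (lengths um, volumes um^3, rates 1/s or mmol/L/s), subcellular scale
# (mmol/L and mmol/L/s).
# ---------------------------------------------------------------------------
_REFSIM_VALUES: dict[str, float] = {
    # -- whole body: compound independent -----------------------------------
    "pbpk_bw": 70.0,
    "pbpk_hemat": 0.45,
    "pbpk_QCardiac": 363.01,
    "pbpk_QGut": 74.42,
    "pbpk_QLiver": 19.42,
    "pbpk_QKidney": 80.37,
    "pbpk_QRest": 188.80,
    "pbpk_VArt": 1.50,
    "pbpk_VVen": 3.41,
    "pbpk_VGut": 1.10,
    "pbpk_VLiver": 1.71,
    "pbpk_VKidney": 0.29,
    "pbpk_VLung": 0.51,
    "pbpk_VRest": 33.47,
    # -- whole body: compound dependent -------------------------------------
    "pbpk_kGutabs": 1.5,
    "pbpk_Fup": 0.8,
    "pbpk_FupG": 1.0,
    "pbpk_FupS": 1.0,
    "pbpk_Kr2p": 1.6,
    "pbpk_Kr2pG": 0.4,
    "pbpk_Kr2pS": 0.2,
    "pbpk_Kk2p": 1.0,
    "pbpk_Kk2pG": 1.0,
    "pbpk_Kk2pS": 1.0,
    "pbpk_Kl2p": 1.0,
    "pbpk_Kl2pG": 1.0,
    "pbpk_Kl2pS": 1.0,
    "pbpk_Rb2p": 1.09,
    "pbpk_Rb2pG": 0.55,
    "pbpk_Rb2pS": 0.55,
    "pbpk_Qgfr": 0.714,
    "pbpk_QgfrG": 7.86,
    "pbpk_QgfrS": 9.96,
    # -- sinusoid: geometry, flow and scheduling ----------------------------
    "mcs2sec": 1.0 / 600.0,
    "Vol_HEP": 8000.0,       # um^3, 20*20*20
    "l_SIN": 200.0,          # um
    "d_SIN": 20.0,           # um
    "h_SIN": 4.0,            # um
    "Vol_RBC": 400.0,        # um^3, 100 px * 4 um depth
    "Vol_SP": 100.0,         # um^3, 25 px * 4 um depth
    "freq_bloodInflow": 20.0,  # mcs
    "freq_transport": 10.0,    # mcs
    "freq_SBML": 10.0,         # mcs
    "flow_speed": 200.0,       # um/s
    "arterial_fraction": 0.25,  # arterial:venous inflow = 1:3
    "lumen_fraction": 0.074,    # sinusoid lumen fraction of liver volume
    # -- sinusoid: compound dependent transfer ------------------------------
    "cc3d_k_AT_APAPG": 0.00045,
    "cc3d_k_AT_APAPS": 0.0019,
    "cc3d_Km_AT_APAP": 0.01,
    "cc3d_Vmax_AT_APAP": 0.01,
    "cc3d_k_PD_R2R": 0.001,
    "cc3d_k_PD_R2S": 0.001,
    "cc3d_k_PD_R2H": 0.001,
    "cc3d_k_PD_S2R": 0.0012,
    "cc3d_k_PD_S2S": 0.010,
    "cc3d_k_PD_S2H": 0.001,
    "cc3d_k_PD_H2R": 0.001,
    "cc3d_k_PD_H2S": 0.001,
    "cc3d_k_PD_H2H": 0.001,
    # -- subcellular ---------------------------------------------------------
    "sc_Vmax_GLUC": 0.001,
    "sc_Km_GLUC": 1.0,
    "sc_Vmax_SULF": 0.000175,
    "sc_Km_SULF": 0.2,
    "sc_Vmax_2E1_APAP": 0.00002,
    "sc_Km_2E1_APAP": 1.29,
    "sc_kNAPQIGSH": 0.1,
    "sc_kGsh": 0.0001,
    "sc_GSH0": 9.9,
    "sc_GSHmax": 10.0,
}

#: Units for every canonical key (documentation and file round-trip checks).
UNITS: dict[str, str] = {
    "pbpk_bw": "kg",
    "pbpk_hemat": "1",
    **{k: "L/h" for k in ("pbpk_QCardiac", "pbpk_QGut", "pbpk_QLiver",
                          "pbpk_QKidney", "pbpk_QRest",
                          "pbpk_Qgfr", "pbpk_QgfrG", "pbpk_QgfrS")},
    **{k: "L" for k in ("pbpk_VArt", "pbpk_VVen", "pbpk_VGut", "pbpk_VLiver",
                        "pbpk_VKidney", "pbpk_VLung", "pbpk_VRest")},
    "pbpk_kGutabs": "1/h",
    **{k: "1" for k in ("pbpk_Fup", "pbpk_FupG", "pbpk_FupS",
                        "pbpk_Kr2p", "pbpk_Kr2pG", "pbpk_Kr2pS",
                        "pbpk_Kk2p", "pbpk_Kk2pG", "pbpk_Kk2pS",
                        "pbpk_Kl2p", "pbpk_Kl2pG", "pbpk_Kl2pS",
                        "pbpk_Rb2p", "pbpk_Rb2pG", "pbpk_Rb2pS",
                        "arterial_fraction", "lumen_fraction")},
    "mcs2sec": "s/mcs",
    **{k: "um^3" for k in ("Vol_HEP", "Vol_RBC", "Vol_SP")},
    **{k: "um" for k in ("l_SIN", "d_SIN", "h_SIN")},
    **{k: "mcs" for k in ("freq_bloodInflow", "freq_transport", "freq_SBML")},
    "flow_speed": "um/s",
    "cc3d_k_AT_APAPG": "1/s",
    "cc3d_k_AT_APAPS": "1/s",
    "cc3d_Km_AT_APAP": "mmol/L",
    "cc3d_Vmax_AT_APAP": "mmol/L/s",
    **{f"cc3d_k_PD_{a}2{b}": "1/s"
       for a in "RSH" for b in "RSH"},
    "sc_Vmax_GLUC": "mmol/L/s",
    "sc_Km_GLUC": "mmol/L",
    "sc_Vmax_SULF": "mmol/L/s",
    "sc_Km_SULF": "mmol/L",
    "sc_Vmax_2E1_APAP": "mmol/L/s",
    "sc_Km_2E1_APAP": "mmol/L",
    "sc_kNAPQIGSH": "L/mmol/s",
    "sc_kGsh": "1/s",
    "sc_GSH0": "mmol/L",
    "sc_GSHmax": "mmol/L",
}

REQUIRED_KEYS = frozenset(_REFSIM_VALUES)

#: Default parameter subset for sensitivity and population analyses: every
#: compound-dependent parameter at each scale plus body weight and
#: hematocrit.  Structural constants (geometry, scheduling, flow speed) are
#: excluded.  The exact membership used in the original analyses is not
#: published; callers may pass any explicit name list instead.
SENSITIVITY_SUBSET: tuple[str, ...] = tuple(
    k for k in _REFSIM_VALUES
    if k in ("pbpk_bw", "pbpk_hemat")
    or (k.startswith("pbpk_") and k not in (
        "pbpk_QCardiac", "pbpk_QGut", "pbpk_QLiver", "pbpk_QKidney",
        "pbpk_QRest", "pbpk_VArt", "pbpk_VVen", "pbpk_VGut", "pbpk_VLiver",
        "pbpk_VKidney", "pbpk_VLung", "pbpk_VRest"))
    or k.startswith("cc3d_")
    or k.startswith("sc_")
)


class ParameterValidationError(ValueError):
    """Raised when a parameter set is incomplete or contains bad values.

    Carries the full list of problems so a malformed file is reported in
    one pass.
    """

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("invalid parameter set:\n  " + "\n  ".join(problems))


# Parameters that may legitimately be zero (rates that can be switched off).
_MAY_BE_ZERO = frozenset(
    k for k in _REFSIM_VALUES
    if k.startswith(("cc3d_", "sc_")) or k in (
        "pbpk_Qgfr", "pbpk_QgfrG", "pbpk_QgfrS", "pbpk_kGutabs",
        "arterial_fraction", "lumen_fraction")
)
_FRACTIONS = ("pbpk_hemat", "pbpk_Fup", "pbpk_FupG", "pbpk_FupS",
              "arterial_fraction", "lumen_fraction")


def _validate(values: Mapping[str, float]) -> list[str]:
    problems: list[str] = []
    for key in sorted(REQUIRED_KEYS - set(values)):
        problems.append(f"missing required key: {key}")
    for key, val in values.items():
        if not isinstance(val, (int, float)) or isinstance(val, bool):
            problems.append(f"{key}: non-numeric value {val!r}")
            continue
        if math.isnan(val) or math.isinf(val):
            problems.append(f"{key}: non-finite value {val!r}")
        elif val < 0:
            problems.append(f"{key}: negative value {val!r}")
        elif val == 0 and key in REQUIRED_KEYS and key not in _MAY_BE_ZERO:
            problems.append(f"{key}: must be positive, got 0")
    for key in _FRACTIONS:
        v = values.get(key)
        if isinstance(v, (int, float)) and not (0 <= v <= 1):
            problems.append(f"{key}: must lie in [0, 1], got {v!r}")
    return problems


class ParameterSet(Mapping[str, float]):
    """Immutable named vector of all tunable model parameters."""

    __slots__ = ("_values", "name")

    def __init__(self, values: Mapping[str, float], *, name: str = "custom",
                 validate: bool = True):
        vals = {str(k): float(v) for k, v in values.items()}
        if validate:
            problems = _validate(vals)
            if problems:
                raise ParameterValidationError(problems)
        self._values = vals
        self.name = name

    # Mapping protocol ------------------------------------------------------
    def __getitem__(self, key: str) -> float:
        return self._values[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self._values)

    def __len__(self) -> int:
        return len(self._values)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ParameterSet({self.name!r}, {len(self)} parameters)"

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ParameterSet) and self._values == other._values

    # Convenience -----------------------------------------------------------
    def as_dict(self) -> dict[str, float]:
        return dict(self._values)

    def with_updates(self, updates: Mapping[str, float], *,
                     name: str | None = None) -> "ParameterSet":
        """Return a copy with ``updates`` applied (unknown keys rejected)."""
        unknown = set(updates) - set(self._values)
        if unknown:
            raise KeyError(f"unknown parameter(s): {sorted(unknown)}")
        merged = dict(self._values)
        merged.update({k: float(v) for k, v in updates.items()})
        return ParameterSet(merged, name=name or f"{self.name}+mod")

    def scaled(self, multipliers: Mapping[str, float], *,
               name: str | None = None) -> "ParameterSet":
        """Return a copy with named parameters multiplied elementwise."""
        return self.with_updates(
            {k: self._values[k] * m for k, m in multipliers.items()},
            name=name)

    def compound_params(self, compound: str) -> dict[str, float]:
        """Whole-body compound-dependent values for one compound.

        Metabolite keys use the G/S suffix convention of the canonical
        table (``pbpk_FupG`` ...); the parent compound uses the bare names.
        Absorption applies only to the parent: metabolites are formed in
        the liver, so their gut-absorption rate is zero.
        """
        if compound not in COMPOUNDS:
            raise KeyError(f"unknown compound {compound!r}")
        suffix = {"APAP": "", "APAPG": "G", "APAPS": "S"}[compound]
        return {
            "kGutabs": self._values["pbpk_kGutabs"] if compound == "APAP" else 0.0,
            "Fup": self._values[f"pbpk_Fup{suffix}"],
            "Kr2p": self._values[f"pbpk_Kr2p{suffix}"],
            "Kk2p": self._values[f"pbpk_Kk2p{suffix}"],
            "Kl2p": self._values[f"pbpk_Kl2p{suffix}"],
            "Rb2p": self._values[f"pbpk_Rb2p{suffix}"],
            "Qgfr": self._values[f"pbpk_Qgfr{suffix}"],
        }


def apply_physical_caps(values: dict[str, float],
                        base: Mapping[str, float]) -> dict[str, float]:
    """Clamp perturbed values to their physical domains, in place.

    Multiplicative perturbation schemes (population multipliers,
    log-scale scans) can push fraction-type parameters past 1 or the
    initial GSH past its ceiling; the induced distributions are
    truncated at those physical boundaries.
    """
    for key in ("pbpk_Fup", "pbpk_FupG", "pbpk_FupS", "pbpk_hemat"):
        if key in values:
            values[key] = min(values[key], 1.0)
    if "sc_GSH0" in values or "sc_GSHmax" in values:
        gmax = values.get("sc_GSHmax", base["sc_GSHmax"])
        values["sc_GSH0"] = min(values.get("sc_GSH0", base["sc_GSH0"]), gmax)
    return values


REFSIM = ParameterSet(_REFSIM_VALUES, name="REFSIM")

_REGISTRY: dict[str, ParameterSet] = {"refsim": REFSIM, "REFSIM": REFSIM}


def registry() -> dict[str, ParameterSet]:
    """Mapping of registered parameter-set names (read-only copy)."""
    return dict(_REGISTRY)


def load_parameter_set(source: str | Path) -> ParameterSet:
    """Load a parameter set by registered name or from a key-value file.

    Files may be JSON or YAML, flat ``name: value`` mappings using the
    canonical parameter names.  Every required key must be present; extra
    keys are accepted (they travel with the set but are ignored by the
    simulators).
    """
    key = str(source)
    if key in _REGISTRY:
        return _REGISTRY[key]
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(
            f"{source!r} is neither a registered parameter-set name "
            f"({sorted(set(_REGISTRY))}) nor an existing file")
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, Mapping):
        raise ParameterValidationError(
            [f"{path}: expected a flat key-value mapping, got {type(raw).__name__}"])
    return ParameterSet(raw, name=path.stem)


def save_parameter_set(params: ParameterSet, path: str | Path) -> Path:
    """Write a parameter set to a flat JSON or YAML file (by extension)."""
    path = Path(path)
    data = params.as_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=1, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))
    return path
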