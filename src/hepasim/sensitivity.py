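"""Local sensitivity and pairwise-interaction analysis.

The sensitivity coefficient of output ``y_k`` to parameter ``x_i`` is the
one-sided finite-difference estimate of the log-log Jacobian,

    J_k(x_i) = [(y_k(x_i + D) - y_k(x_i)) / D] * [x_i / y_k(x_i)],

with D = 25 % of ``x_i`` by default, i.e. the relative output change
divided by the 0.25 relative parameter change.  For a power law
``y = x**p`` this evaluates exactly to ``((1.25)**p - 1) / 0.25``.

Pairwise interaction coefficients compare the relative output change when
two parameters are varied together with the sum of the two
single-parameter relative changes; additively separable responses give
zero, interacting pairs do not.

A ``runner`` is any callable mapping a :class:`~hepasim.params.ParameterSet`
to a :class:`~hepasim.metrics.ModelOutputs`; the analyses are agnostic to
whether it wraps the full multiscale model, the standalone whole-body
model or an analytic test response.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .metrics import OUTPUT_NAMES, ModelOutputs
from .params import SENSITIVITY_SUBSET, ParameterSet, apply_physical_caps

__all__ = [
    "Runner",
    "SensitivityMatrix",
    "single_param_sensitivity",
    "sensitivity_matrix",
    "pairwise_interaction",
    "pairwise_interaction_matrix",
    "lognormal_scan",
    "matrix_correlation",
]

Runner = Callable[[ParameterSet], ModelOutputs]

_RMSE_ROWS = ("RMSEa", "RMSEg", "RMSEs", "RMSEsum")


@dataclass
class SensitivityMatrix:
    """Outputs x parameters sensitivity table with an ``Average`` row.

    ``values`` has shape ``(15, n_params)``; entries are ``nan`` where the
    base output is zero (sensitivity undefined) or a run failed.  The
    ``Average`` row is the column mean over the defined entries.
    """

    outputs: tuple[str, ...]
    parameters: tuple[str, ...]
    values: np.ndarray

    @property
    def average_row(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.values, axis=0)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=list(self.outputs),
                          columns=list(self.parameters))
        df.loc["Average"] = self.average_row
        return df

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="output")

    @classmethod
    def read_csv(cls, path: str | Path) -> "SensitivityMatrix":
        df = pd.read_csv(path, index_col="output")
        body = df.drop(index="Average", errors="ignore")
        return cls(outputs=tuple(body.index), parameters=tuple(body.columns),
                   values=body.to_numpy(float))

    def ranked_parameters(self) -> pd.Series:
        """Parameters ordered by |Average| sensitivity, largest first."""
        avg = pd.Series(np.abs(self.average_row), index=self.parameters)
        return avg.sort_values(ascending=False)


def _relative_changes(base: ModelOutputs, pert: ModelOutputs) -> np.ndarray:
    y0 = base.as_vector()
    y1 = pert.as_vector()
    out = np.full(y0.shape, np.nan)
    ok = np.isfinite(y0) & np.isfinite(y1) & (y0 != 0)
    out[ok] = (y1[ok] - y0[ok]) / y0[ok]
    return out


def single_param_sensitivity(base: ParameterSet, param_name: str,
                             runner: Runner, delta_frac: float = 0.25,
                             base_outputs: ModelOutputs | None = None,
                             central: bool = False) -> np.ndarray:
    """Sensitivity coefficients J_k for one parameter (length-15 vector).

    One perturbed run at ``x*(1+delta_frac)`` (the one-sided definition);
    ``central=True`` adds a run at ``x*(1-delta_frac)`` and averages the
    two one-sided coefficients.  Entries are ``nan`` for outputs whose
    base value is zero.
    """
    if delta_frac <= 0:
        raise ValueError("delta_frac must be positive")
    y0 = base_outputs if base_outputs is not None else runner(base)
    up = runner(base.scaled({param_name: 1.0 + delta_frac}))
    j = _relative_changes(y0, up) / delta_frac
    if central:
        dn = runner(base.scaled({param_name: 1.0 - delta_frac}))
        j_dn = _relative_changes(y0, dn) / (-delta_frac)
        j = 0.5 * (j + j_dn)
    return j


def sensitivity_matrix(base: ParameterSet, runner: Runner,
                       subset: Sequence[str] | None = None,
                       delta_frac: float = 0.25,
                       central: bool = False) -> SensitivityMatrix:
    """One perturbed run per parameter; failures leave ``nan`` columns."""
    subset = tuple(subset if subset is not None else SENSITIVITY_SUBSET)
    y0 = runner(base)
    values = np.full((len(OUTPUT_NAMES), len(subset)), np.nan)
    for i, name in enumerate(subset):
        try:
            values[:, i] = single_param_sensitivity(
                base, name, runner, delta_frac, base_outputs=y0,
                central=central)
        except Exception:
            pass  # recorded as a missing (nan) column
    return SensitivityMatrix(outputs=OUTPUT_NAMES, parameters=subset,
                             values=values)


def pairwise_interaction(base: ParameterSet, runner: Runner,
                         param_i: str, param_j: str,
                         output: str = "RMSEsum",
                         delta_frac: float = 0.25,
                         _cache: dict | None = None) -> float:
    """Interaction coefficient for one parameter pair and one output.

    ``relD(i,j together) - [relD(i) + relD(j)]`` where relD is the
    relative change of the chosen output under a +25 % variation.  Zero
    for additively separable responses; symmetric in (i, j).
    """
    if param_i == param_j:
        raise ValueError("pairwise interaction is undefined on the diagonal")
    k = OUTPUT_NAMES.index(output)
    cache = _cache if _cache is not None else {}

    def run(names: tuple[str, ...]) -> float:
        key = tuple(sorted(names))
        if key not in cache:
            scaled = base.scaled({n: 1.0 + delta_frac for n in names})
            cache[key] = runner(scaled).as_vector()[k]
        return cache[key]

    y0 = run(())
    if y0 == 0 or not math.isfinite(y0):
        return math.nan
    rel = lambda y: (y - y0) / y0
    return rel(run((param_i, param_j))) - (rel(run((param_i,)))
                                           + rel(run((param_j,))))


def pairwise_interaction_matrix(base: ParameterSet, runner: Runner,
                                subset: Sequence[str] | None = None,
                                output: str = "RMSEsum",
                                delta_frac: float = 0.25) -> pd.DataFrame:
    """Symmetric interaction matrix over a parameter subset.

    Single-parameter runs are cached, so ``n*(n-1)/2 + n + 1`` model
    evaluations cover the full matrix.  The diagonal is ``nan``.
    """
    subset = tuple(subset if subset is not None else SENSITIVITY_SUBSET)
    cache: dict = {}
    n = len(subset)
    mat = np.full((n, n), np.nan)
    for a in range(n):
        for b in range(a + 1, n):
            v = pairwise_interaction(base, runner, subset[a], subset[b],
                                     output, delta_frac, _cache=cache)
            mat[a, b] = mat[b, a] = v
    return pd.DataFrame(mat, index=list(subset), columns=list(subset))


def lognormal_scan(base: ParameterSet, sigma_log10: float, n: int,
                   seed: int, subset: Sequence[str] | None = None,
                   ) -> list[ParameterSet]:
    """Parameter sets spread across orders of magnitude.

    Each selected parameter of each replicate is multiplied by
    ``10**eps`` with ``eps ~ Normal(0, sigma_log10)``, independently per
    parameter and replicate; reproducible under a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    subset = tuple(subset if subset is not None else SENSITIVITY_SUBSET)
    rng = np.random.default_rng(seed)
    out = []
    for r in range(n):
        eps = rng.normal(0.0, sigma_log10, size=len(subset))
        updates = apply_physical_caps(
            {name: base[name] * 10.0 ** e for name, e in zip(subset, eps)},
            base)
        out.append(base.with_updates(updates, name=f"{base.name}-ln{r}"))
    return out


def matrix_correlation(a: SensitivityMatrix, b: SensitivityMatrix,
                       mode: str = "all") -> tuple[float, float]:
    """Pearson r and R^2 between two sensitivity matrices.

    ``mode`` selects the compared entries: ``all`` flattens the full
    15-row tables, ``average_row`` compares only the Average rows, and
    ``without_rmse_rows`` drops the four RMSE rows (and the Average row is
    never part of the stored table).  Entries undefined in either matrix
    are excluded pairwise.
    """
    if a.outputs != b.outputs or a.parameters != b.parameters:
        raise ValueError("matrices must share row and column labels")
    if mode == "all":
        x, y = a.values.ravel(), b.values.ravel()
    elif mode == "average_row":
        x, y = a.average_row, b.average_row
    elif mode == "without_rmse_rows":
        keep = [i for i, name in enumerate(a.outputs)
                if name not in _RMSE_ROWS]
        x, y = a.values[keep].ravel(), b.values[keep].ravel()
    else:
        raise ValueError(f"unknown mode {mode!r}")
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 2:
        raise ValueError("not enough defined entries to correlate")
    r = float(np.corrcoef(x[ok], y[ok])[0, 1])
    return r, r * r
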