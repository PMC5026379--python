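import math

import numpy as np
import pytest

import hepasim as h
from hepasim.metrics import OUTPUT_NAMES, ModelOutputs
from hepasim.sensitivity import (SensitivityMatrix, lognormal_scan,
                                 matrix_correlation, pairwise_interaction,
                                 pairwise_interaction_matrix,
                                 sensitivity_matrix,
                                 single_param_sensitivity)

PARAMS = ("pbpk_kGutabs", "pbpk_Fup", "sc_Km_GLUC")


def analytic_runner(fn):
    """Wrap a scalar function of a parameter set into a constant-vector
    ModelOutputs runner (every output equal, so any row can be checked)."""

    def run(params):
        v = float(fn(params))
        return ModelOutputs(**{name: v for name in OUTPUT_NAMES})

    return run


class TestSingleParameter:
    @pytest.mark.parametrize("p", [-1.0, 0.5, 1.0, 2.0])
    def test_power_law_oracle(self, p):
        """For y = x**p the one-sided coefficient is ((1.25)^p - 1)/0.25
        exactly; the implementation must match to 1e-12."""
        runner = analytic_runner(lambda ps: ps["pbpk_kGutabs"] ** p)
        j = single_param_sensitivity(h.REFSIM, "pbpk_kGutabs", runner)
        expected = (1.25 ** p - 1.0) / 0.25
        assert abs(j[0] - expected) < 1e-12

    def test_linear_response_gives_one_for_any_scale(self):
        for c in (0.1, 3.0):
            runner = analytic_runner(lambda ps, c=c: c * ps["pbpk_Fup"])
            j = single_param_sensitivity(h.REFSIM, "pbpk_Fup", runner)
            assert j[0] == pytest.approx(1.0)

    def test_independent_output_gives_zero(self):
        runner = analytic_runner(lambda ps: 42.0)
        j = single_param_sensitivity(h.REFSIM, "pbpk_Fup", runner)
        assert j[0] == 0.0

    def test_square_law(self):
        runner = analytic_runner(lambda ps: ps["sc_Km_GLUC"] ** 2)
        j = single_param_sensitivity(h.REFSIM, "sc_Km_GLUC", runner)
        assert j[0] == pytest.approx(2.25)

    def test_zero_base_output_flagged_undefined(self):
        runner = analytic_runner(lambda ps: 0.0)
        j = single_param_sensitivity(h.REFSIM, "pbpk_Fup", runner)
        assert np.all(np.isnan(j))


class TestMatrix:
    def test_linear_runner_gives_unit_column(self):
        runner = analytic_runner(lambda ps: ps["pbpk_kGutabs"])
        mat = sensitivity_matrix(h.REFSIM, runner, ("pbpk_kGutabs",))
        assert mat.values.shape == (15, 1)
        assert np.allclose(mat.values, 1.0)

    def test_constant_runner_gives_zero_matrix(self):
        runner = analytic_runner(lambda ps: 7.0)
        mat = sensitivity_matrix(h.REFSIM, runner, PARAMS)
        assert np.all(mat.values == 0.0)

    def test_average_row_is_column_mean(self):
        runner = analytic_runner(lambda ps: ps["pbpk_Fup"] ** 2)
        mat = sensitivity_matrix(h.REFSIM, runner, PARAMS)
        assert np.allclose(mat.average_row, np.nanmean(mat.values, axis=0))

    def test_csv_round_trip(self, tmp_path):
        runner = analytic_runner(
            lambda ps: ps["pbpk_Fup"] * ps["sc_Km_GLUC"])
        mat = sensitivity_matrix(h.REFSIM, runner, PARAMS)
        path = tmp_path / "matrix.csv"
        mat.write_csv(path)
        back = SensitivityMatrix.read_csv(path)
        assert back.parameters == mat.parameters
        assert np.allclose(back.values, mat.values)


class TestPairwiseInteraction:
    def test_additive_response_has_zero_interaction(self):
        runner = analytic_runner(
            lambda ps: 2.0 * ps["pbpk_kGutabs"] + 5.0 * ps["pbpk_Fup"])
        v = pairwise_interaction(h.REFSIM, runner, "pbpk_kGutabs",
                                 "pbpk_Fup")
        assert abs(v) < 1e-12

    def test_product_response_interaction_value(self):
        runner = analytic_runner(
            lambda ps: ps["pbpk_kGutabs"] * ps["pbpk_Fup"])
        v = pairwise_interaction(h.REFSIM, runner, "pbpk_kGutabs",
                                 "pbpk_Fup")
        assert v == pytest.approx((1.25 ** 2 - 1) - 0.5, abs=1e-12)  # 0.0625

    def test_symmetry_and_cached_single_runs(self):
        calls = []

        def runner(ps):
            calls.append(ps.name)
            v = ps["pbpk_kGutabs"] ** 2 * ps["pbpk_Fup"]
            return ModelOutputs(**{n: v for n in OUTPUT_NAMES})

        df = pairwise_interaction_matrix(h.REFSIM, runner,
                                         ("pbpk_kGutabs", "pbpk_Fup"))
        assert df.loc["pbpk_kGutabs", "pbpk_Fup"] == \
            df.loc["pbpk_Fup", "pbpk_kGutabs"]
        assert math.isnan(df.loc["pbpk_Fup", "pbpk_Fup"])
        assert len(calls) == 4     # base, two singles, one pair

    def test_diagonal_rejected(self):
        runner = analytic_runner(lambda ps: 1.0)
        with pytest.raises(ValueError):
            pairwise_interaction(h.REFSIM, runner, "pbpk_Fup", "pbpk_Fup")


class TestLognormalScan:
    def test_zero_sigma_copies_base(self):
        sets = lognormal_scan(h.REFSIM, 0.0, 3, seed=1)
        assert all(s["pbpk_Fup"] == h.REFSIM["pbpk_Fup"] for s in sets)

    def test_fixed_seed_reproduces(self):
        a = lognormal_scan(h.REFSIM, 0.5, 5, seed=9)
        b = lognormal_scan(h.REFSIM, 0.5, 5, seed=9)
        for sa, sb in zip(a, b):
            assert sa == sb

    def test_geometric_mean_is_centered(self):
        sets = lognormal_scan(h.REFSIM, 0.3, 2000, seed=2,
                              subset=("pbpk_kGutabs",))
        logs = np.log10([s["pbpk_kGutabs"] for s in sets])
        base = np.log10(h.REFSIM["pbpk_kGutabs"])
        se = 0.3 / np.sqrt(len(sets))
        assert abs(logs.mean() - base) < 3 * se


class TestMatrixCorrelation:
    def _matrix(self, values):
        return SensitivityMatrix(outputs=OUTPUT_NAMES,
                                 parameters=PARAMS,
                                 values=values)

    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        a = self._matrix(rng.normal(size=(15, 3)))
        r, r2 = matrix_correlation(a, a)
        assert (r, r2) == (pytest.approx(1.0), pytest.approx(1.0))

    def test_negated_matrix(self):
        rng = np.random.default_rng(1)
        a = self._matrix(rng.normal(size=(15, 3)))
        b = self._matrix(-a.values)
        assert matrix_correlation(a, b)[0] == pytest.approx(-1.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        a = self._matrix(rng.normal(size=(15, 3)))
        b = self._matrix(2.0 * a.values + 3.0)
        assert matrix_correlation(a, b)[0] == pytest.approx(1.0)

    def test_without_rmse_rows_ignores_rmse_entries(self):
        rng = np.random.default_rng(3)
        a = self._matrix(rng.normal(size=(15, 3)))
        b = self._matrix(a.values.copy())
        b.values[:4] = rng.normal(size=(4, 3))     # corrupt only RMSE rows
        r, _ = matrix_correlation(a, b, mode="without_rmse_rows")
        assert r == pytest.approx(1.0)

    def test_shape_mismatch_rejected(self):
        a = self._matrix(np.zeros((15, 3)))
        b = SensitivityMatrix(outputs=OUTPUT_NAMES,
                              parameters=("pbpk_Fup",),
                              values=np.zeros((15, 1)))
        with pytest.raises(ValueError):
            matrix_correlation(a, b)


class TestFullModelRanking:
    def test_dominant_parameters_outrank_passive_transfer_rates(self):
        """Scaled-down reproduction of the fixed-point sensitivity scan:
        body weight and the active-transport Michaelis-Menten pair are
        among the strongest drivers of the fit error against a synthetic
        reference, while passive inter-parcel transfer rates (apart from
        the hepatocyte-to-serum efflux) rank below the median."""
        subset = ("pbpk_bw", "cc3d_Vmax_AT_APAP", "cc3d_Km_AT_APAP",
                  "pbpk_kGutabs", "cc3d_k_PD_H2S", "cc3d_k_PD_S2R",
                  "cc3d_k_PD_R2R", "cc3d_k_PD_R2S", "cc3d_k_PD_R2H",
                  "sc_Km_GLUC")
        ref = h.generate_reference(h.REFSIM, duration_h=2.0, noise_cv=0.05,
                                   seed=11, times=np.arange(0.25, 2.01, 0.25))
        runner = h.multiscale_runner(20.0, 2.0, ref, dose_bw_kg=70.0)
        mat = sensitivity_matrix(h.REFSIM, runner, subset)
        row = np.abs(mat.values[OUTPUT_NAMES.index("RMSEsum")])
        ranks = {name: row[i] for i, name in enumerate(subset)}
        median = np.median(row)
        weak_names = ("cc3d_k_PD_S2R", "cc3d_k_PD_R2R", "cc3d_k_PD_R2S",
                      "cc3d_k_PD_R2H")
        weak_max = max(ranks[w] for w in weak_names)
        for strong in ("pbpk_bw", "cc3d_Vmax_AT_APAP", "cc3d_Km_AT_APAP"):
            assert ranks[strong] > 100 * weak_max
        for weak in weak_names:
            assert ranks[weak] <= median
        # the two strongest drivers overall are body weight and the
        # active-transport capacity
        top2 = sorted(ranks, key=ranks.get, reverse=True)[:2]
        assert set(top2) == {"pbpk_bw", "cc3d_Vmax_AT_APAP"}
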