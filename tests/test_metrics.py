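import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import hepasim as h
from hepasim.metrics import (ReferenceADME, adme_descriptors, metab_ratio,
                             rmse, zonal_summary)


class TestRmse:
    def test_identical_curves_give_zero(self):
        t = np.linspace(0, 8, 20)
        y = np.sin(t) + 2
        assert rmse(t, y, t, y) == 0.0

    def test_constant_offset_returns_offset(self):
        t = np.linspace(0, 8, 50)
        y = np.cos(t) + 2
        assert rmse(t, y, t[::5], y[::5] + 0.3) == pytest.approx(0.3)

    def test_hand_computed_example(self):
        assert rmse([0, 1, 2], [1, 2, 3], [0, 1, 2], [1, 2, 4]) == \
            pytest.approx(np.sqrt(1 / 3))

    def test_reference_outside_span_rejected(self):
        with pytest.raises(ValueError):
            rmse([0, 1], [1, 1], [0, 2], [1, 1])


class TestAdmeDescriptors:
    def test_constant_series(self):
        t = np.linspace(0, 8, 9)
        cmax, tmax, auc = adme_descriptors(t, np.full(9, 3.0))
        assert (cmax, tmax, auc) == (3.0, 0.0, pytest.approx(24.0))

    def test_triangle(self):
        t = np.array([0.0, 1.0, 2.0])
        cmax, tmax, auc = adme_descriptors(t, np.array([0.0, 2.0, 0.0]))
        assert (cmax, tmax) == (2.0, 1.0)
        assert auc == pytest.approx(2.0)

    def test_tie_breaks_to_earliest_peak(self):
        t = np.arange(5.0)
        cmax, tmax, _ = adme_descriptors(t, np.array([0, 2, 1, 2, 0.0]))
        assert tmax == 1.0

    def test_auc_additive_over_adjacent_windows(self):
        rng = np.random.default_rng(5)
        t = np.sort(rng.uniform(0, 8, 41))
        y = rng.uniform(0, 1, 41)
        _, _, total = adme_descriptors(t, y)
        _, _, left = adme_descriptors(t[:21], y[:21])
        _, _, right = adme_descriptors(t[20:], y[20:])
        assert left + right == pytest.approx(total)

    def test_cmax_invariant_under_refinement(self):
        t = np.linspace(0, 8, 17)
        y = np.exp(-((t - 2) ** 2))
        fine_t = np.linspace(0, 8, 161)
        fine_y = np.interp(fine_t, t, y)
        assert adme_descriptors(fine_t, fine_y)[0] == pytest.approx(
            adme_descriptors(t, y)[0])


class TestMetabRatio:
    @pytest.mark.parametrize("a,g,s,expected", [
        (1.0, 0.0, 0.0, 0.0),
        (1.0, 1.0, 1.0, 2 / 3),
        (0.0, 0.3, 0.2, 1.0),
    ])
    def test_examples(self, a, g, s, expected):
        assert metab_ratio(a, g, s) == pytest.approx(expected)

    def test_all_zero_is_undefined(self):
        with pytest.raises(ZeroDivisionError):
            metab_ratio(0.0, 0.0, 0.0)

    @given(a=st.floats(0.01, 10), g=st.floats(0.01, 10),
           s=st.floats(0.01, 10), scale=st.floats(0.01, 100))
    @settings(max_examples=50, deadline=None)
    def test_invariant_to_uniform_rescaling(self, a, g, s, scale):
        assert metab_ratio(a * scale, g * scale, s * scale) == \
            pytest.approx(metab_ratio(a, g, s), rel=1e-9)


class TestZonalSummary:
    def _fake_traces(self, values_by_rank):
        n_t, n_cells = 3, 20
        traces = np.zeros((n_t, n_cells, 6))
        rank = np.tile(np.arange(10), 2)
        side = np.repeat([0, 1], 10)
        for cell in range(n_cells):
            traces[:, cell, :] = values_by_rank[rank[cell]]
        return traces, side, rank

    def test_identical_cells_have_zero_sd(self):
        traces, side, rank = self._fake_traces(np.ones(10))
        zs = zonal_summary(traces, side, rank)
        for zone in ("PP", "MZ", "PV"):
            assert np.all(zs[zone]["sd"] == 0.0)
            assert np.all(zs[zone]["mean"] == 1.0)

    def test_groups_are_four_cells_each(self):
        traces, side, rank = self._fake_traces(np.arange(10.0))
        zs = zonal_summary(traces, side, rank)
        # group means identify the axial thirds
        assert zs["PP"]["mean"][0, 0] == pytest.approx(np.mean([0, 1, 2, 3]))
        assert zs["MZ"]["mean"][0, 0] == pytest.approx(np.mean([3, 4, 5, 6]))
        assert zs["PV"]["mean"][0, 0] == pytest.approx(np.mean([6, 7, 8, 9]))

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            zonal_summary(np.zeros((2, 8, 6)), np.repeat([0, 1], 4),
                          np.tile(np.arange(4), 2))


class TestModelOutputs:
    def test_rmsesum_is_sum_of_components(self, coupled_run_8h):
        ref = h.generate_reference(h.REFSIM, model="pbpk", CLmetab=10.0,
                                   noise_cv=0.1, seed=3)
        out = h.model_outputs(coupled_run_8h, ref)
        assert out.RMSEsum == pytest.approx(out.RMSEa + out.RMSEg + out.RMSEs)

    def test_self_reference_gives_zero_rmse(self, coupled_run_8h):
        pts = {c: (coupled_run_8h.times[1:],
                   coupled_run_8h.serum_concentration(c)[1:])
               for c in h.COMPOUNDS}
        ref = ReferenceADME(points=pts)
        out = h.model_outputs(coupled_run_8h, ref)
        assert out.RMSEsum == pytest.approx(0.0, abs=1e-12)

    def test_missing_reference_yields_nan_sentinels(self, coupled_run_8h):
        out = h.model_outputs(coupled_run_8h)
        assert np.isnan(out.RMSEa) and np.isnan(out.RMSEsum)
        assert out.CmaxA > 0

    def test_reference_unit_conversion(self):
        t = np.array([1.0, 2.0])
        ref = ReferenceADME(points={"APAP": (t, np.array([15.116, 15.116]))},
                            unit="ug/mL")
        _, y = ref.in_mmol_per_L("APAP")
        assert y == pytest.approx([0.1, 0.1])

    def test_reference_csv_round_trip(self, tmp_path):
        t = np.array([0.5, 1.0, 2.0])
        ref = ReferenceADME(points={c: (t, np.array([1.0, 2.0, 1.5]))
                                    for c in h.COMPOUNDS})
        path = tmp_path / "ref.csv"
        ref.write_csv(path)
        back = ReferenceADME.read_csv(path)
        for c in h.COMPOUNDS:
            assert np.allclose(back.points[c][0], t)
            assert np.allclose(back.points[c][1], ref.points[c][1])
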