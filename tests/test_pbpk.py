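import numpy as np
import pytest

import hepasim as h
from hepasim.pbpk import (STATE_FIELDS, GutUptakeModel, PBPKState,
                          pbpk_derivatives, gut_uptake_rate)

DOSE_MMOL = 1400.0 / 151.16     # 20 mg/kg x 70 kg of acetaminophen


@pytest.fixture(scope="module")
def body():
    return h.body_params_from(h.REFSIM)


@pytest.fixture(scope="module")
def apap():
    return h.compound_params_from(h.REFSIM, "APAP", CLmetab=5.0)


def reference_derivative(state: dict, b, c) -> dict:
    """Independent, literal transcription of the compartment rate table."""
    flows = {
        ("AGutlumen", "CGut"): c.kGutabs * state["AGutlumen"],
        ("CGut", "CLiver"): b.QGut * state["CGut"] / b.VGut,
        ("CLiver", "CVen"): (b.QLiver + b.QGut) * state["CLiver"] * c.Rb2p
        / (c.Kl2p * c.Fup * b.VLiver),
        ("CLiver", "CMetabolized"): c.CLmetab * state["CLiver"]
        / (c.Kl2p * c.Fup),
        ("CVen", "CLung"): b.QCardiac * state["CVen"] / b.VVen,
        ("CLung", "CArt"): b.QCardiac * state["CLung"] / b.VLung,
        ("CArt", "CGut"): b.QGut * state["CArt"] / b.VArt,
        ("CArt", "CLiver"): b.QLiver * state["CArt"] / b.VArt,
        ("CArt", "CKidney"): b.QKidney * state["CArt"] / b.VArt,
        ("CArt", "CRest"): b.QRest * state["CArt"] / b.VArt,
        ("CKidney", "CVen"): b.QKidney * state["CKidney"] * c.Rb2p
        / (c.Kk2p * c.Fup * b.VKidney),
        ("CKidney", "CTubules"): c.Qgfr * state["CKidney"]
        / (c.Kk2p * b.VKidney),
        ("CRest", "CVen"): b.QRest * state["CRest"] * c.Rb2p
        / (c.Kr2p * c.Fup * b.VRest),
    }
    deriv = {f: 0.0 for f in STATE_FIELDS}
    for (src, dst), rate in flows.items():
        deriv[src] -= rate
        deriv[dst] += rate
    return deriv


class TestDerivatives:
    def test_matches_independent_transcription_at_random_states(self, body,
                                                                apap):
        rng = np.random.default_rng(42)
        for _ in range(100):
            arr = rng.uniform(0.0, 5.0, size=len(STATE_FIELDS))
            state = dict(zip(STATE_FIELDS, arr))
            expect = reference_derivative(state, body, apap)
            got = pbpk_derivatives(arr, body, apap)
            for f in STATE_FIELDS:
                ref = expect[f]
                tol = 1e-12 * max(abs(ref), 1.0)
                assert abs(getattr(got, f) - ref) <= tol

    def test_gut_absorption_flux(self, body, apap):
        state = PBPKState(AGutlumen=DOSE_MMOL)
        d = pbpk_derivatives(state, body, apap)
        assert d.CGut == pytest.approx(1.5 * DOSE_MMOL)   # 13.89 mmol/h
        assert d.AGutlumen == pytest.approx(-1.5 * DOSE_MMOL)

    def test_zero_state_gives_zero_derivative(self, body, apap):
        d = pbpk_derivatives(PBPKState(), body, apap)
        assert all(getattr(d, f) == 0.0 for f in STATE_FIELDS)

    def test_total_derivative_is_zero(self, body, apap):
        rng = np.random.default_rng(3)
        arr = rng.uniform(0, 10, size=len(STATE_FIELDS))
        d = pbpk_derivatives(arr, body, apap)
        assert abs(d.total) < 1e-10

    def test_negative_state_rejected(self, body, apap):
        arr = np.zeros(len(STATE_FIELDS))
        arr[0] = -1.0
        with pytest.raises(ValueError):
            pbpk_derivatives(arr, body, apap)


class TestGutUptake:
    def test_first_order_is_linear(self):
        m = GutUptakeModel()
        assert gut_uptake_rate(2.0, m, 0.0, kGutabs=1.5) == pytest.approx(3.0)

    def test_zero_order_respects_lag(self):
        m = GutUptakeModel(variant="zero_order_lagged", Vmax_gut=6.0,
                           Km_gut=1e-3, lag=0.15)
        assert gut_uptake_rate(5.0, m, 0.1, kGutabs=1.5) == 0.0
        # saturation: far above Km the rate approaches Vmax
        rate = gut_uptake_rate(5.0, m, 0.2, kGutabs=1.5)
        assert rate == pytest.approx(6.0, rel=1e-3)

    def test_invalid_variant_rejected(self):
        with pytest.raises(ValueError):
            GutUptakeModel(variant="second_order")


class TestSimulate:
    def test_initial_condition_places_full_dose_in_gut_lumen(self, body):
        comps = {c: h.compound_params_from(h.REFSIM, c)
                 for c in h.COMPOUNDS}
        res = h.simulate_pbpk(body, comps, 20.0, 1.0)
        assert res.amount("APAP", "AGutlumen")[0] == pytest.approx(DOSE_MMOL)
        for met in ("APAPG", "APAPS"):
            assert np.all(res.amounts[met][0] == 0.0)

    def test_closed_system_conserves_moles(self, body):
        # no metabolism, no filtration: the dose just redistributes
        comps = {}
        for c in h.COMPOUNDS:
            kw = h.REFSIM.compound_params(c)
            kw["Qgfr"] = 0.0
            comps[c] = h.CompoundParams(CLmetab=0.0, **kw)
        res = h.simulate_pbpk(body, comps, 20.0, 8.0)
        totals = sum(res.total(c) for c in h.COMPOUNDS)
        assert np.max(np.abs(totals - DOSE_MMOL)) / DOSE_MMOL < 1e-6

    def test_metabolite_split_conserves_joint_total(self, body):
        comps = {c: h.compound_params_from(
            h.REFSIM, c, CLmetab=10.0 if c == "APAP" else 0.0)
            for c in h.COMPOUNDS}
        res = h.simulate_pbpk(body, comps, 20.0, 8.0,
                              metabolite_split=(0.60, 0.33))
        joint = sum(res.total(c) for c in h.COMPOUNDS)
        assert np.max(np.abs(joint - DOSE_MMOL)) / DOSE_MMOL < 1e-6
        # conjugates actually appear
        assert res.amount("APAPG", "CVen")[-1] > 0
        assert res.amount("APAPS", "CVen")[-1] > 0

    def test_sinks_are_monotone(self, body):
        comps = {c: h.compound_params_from(
            h.REFSIM, c, CLmetab=10.0 if c == "APAP" else 0.0)
            for c in h.COMPOUNDS}
        res = h.simulate_pbpk(body, comps, 20.0, 8.0)
        for c in h.COMPOUNDS:
            for sink in ("CTubules", "CMetabolized"):
                assert np.all(np.diff(res.amount(c, sink)) >= -1e-12)

    def test_fast_absorption_limit(self, body):
        params = h.REFSIM.with_updates({"pbpk_kGutabs": 1000.0})
        comps = {c: h.compound_params_from(params, c) for c in h.COMPOUNDS}
        res = h.simulate_pbpk(body, comps, 20.0, 2.0,
                              t_grid=np.linspace(0, 2.0, 1201))
        gut = res.amount("APAP", "CGut")
        # gut peaks within the first minutes ...
        assert res.times[np.argmax(gut)] < 5.0 / 60.0
        # ... then, with renal filtration on, total burden declines
        body_burden = res.total("APAP") - res.amount("APAP", "CTubules")
        late = body_burden[res.times > 0.2]
        assert np.all(np.diff(late) <= 1e-9)

    def test_bad_dose_and_grid_rejected(self, body):
        comps = {c: h.compound_params_from(h.REFSIM, c) for c in h.COMPOUNDS}
        with pytest.raises(ValueError):
            h.simulate_pbpk(body, comps, -1.0, 1.0)
        with pytest.raises(ValueError):
            h.simulate_pbpk(body, comps, 20.0, 1.0, t_grid=[0.0, 0.5, 0.5])


class TestAllometry:
    def test_reference_weight_is_identity(self, refsim):
        b = h.body_params_from(refsim)
        assert b.QCardiac == refsim["pbpk_QCardiac"]
        assert b.VLiver == refsim["pbpk_VLiver"]

    def test_lighter_subject_scales_down(self, refsim):
        b = h.body_params_from(refsim.with_updates({"pbpk_bw": 57.0}))
        assert b.VLiver == pytest.approx(1.71 * 57.0 / 70.0)
        assert b.QCardiac == pytest.approx(363.01 * (57.0 / 70.0) ** 0.75)
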