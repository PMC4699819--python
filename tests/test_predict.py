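"""The Rh scaling relation, reference baselines and dataset evaluation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ppiirh
from ppiirh.predict import (
    apparent_fppii,
    chain_fppii,
    denatured_rh,
    evaluate_dataset,
    marsh_forman_kay_r0,
    marsh_forman_kay_rh,
    predict_rh,
    predict_sequence,
    random_coil_rh,
)
from ppiirh.sequences import SequenceRecord


@pytest.mark.parametrize(
    "n,f,expected,tol",
    [
        (87, 0.012, 20.5, 0.05),  # random-coil references for N = 87..97
        (97, 0.012, 21.7, 0.05),
        (1, 0.0, 2.16, 1e-12),
        (100, 0.364, 27.5, 0.1),
    ],
)
def test_predict_rh_reference_points(n, f, expected, tol):
    assert predict_rh(n, f) == pytest.approx(expected, abs=tol)


def test_predict_rh_domain_errors():
    with pytest.raises(ValueError):
        predict_rh(100, 1.0)
    with pytest.raises(ValueError):
        predict_rh(0, 0.1)
    with pytest.raises(ValueError):
        predict_rh(10, -0.1)


def test_zero_ppii_closed_form():
    n = np.array([5, 50, 500])
    assert np.allclose(predict_rh(n, 0.0), 2.16 * n**0.503, rtol=0, atol=1e-12)


@settings(deadline=None, max_examples=200)
@given(
    st.integers(min_value=2, max_value=2000),
    st.floats(min_value=0, max_value=0.98),
    st.floats(min_value=0, max_value=0.98),
)
def test_monotonic_in_n_and_f(n, f1, f2):
    lo, hi = sorted([f1, f2])
    assert predict_rh(n + 1, f1) > predict_rh(n, f1)
    assert predict_rh(n, hi) >= predict_rh(n, lo)
    if hi - lo > 1e-9:  # below float resolution the exponent cannot move
        assert predict_rh(n, hi) > predict_rh(n, lo)


@settings(deadline=None, max_examples=200)
@given(
    st.integers(min_value=2, max_value=2000),
    st.floats(min_value=0, max_value=0.98),
)
def test_inversion_round_trip(n, f):
    """apparent_fppii is the exact inverse of the scaling relation."""
    assert apparent_fppii(predict_rh(n, f), n) == pytest.approx(f, abs=1e-10)


@pytest.mark.parametrize(
    "f_pro,q,expected",
    [
        (0.0, 0, 2.17),  # baseline prefactor, printed at 2 dp
        (0.1, 5, 2.562),  # (1.028)(1.00095)(2.49)
    ],
)
def test_marsh_forman_kay_prefactor(f_pro, q, expected):
    assert marsh_forman_kay_r0(f_pro, q) == pytest.approx(expected, abs=5e-3)


def test_baselines_monotone_and_denatured():
    assert marsh_forman_kay_r0(0.2, 3) > marsh_forman_kay_r0(0.1, 3)
    assert marsh_forman_kay_r0(0.1, 7) > marsh_forman_kay_r0(0.1, 3)
    assert marsh_forman_kay_rh(100, 0, 0) == pytest.approx(2.17 * 100**0.509, rel=5e-3)
    assert denatured_rh(100) == pytest.approx(2.2 * 100**0.57)
    with pytest.raises(ValueError):
        marsh_forman_kay_r0(1.5, 0)


def test_chain_fppii(builtin_scales):
    assert chain_fppii("P" * 30, builtin_scales["hilser"]) == pytest.approx(1.0)
    # (0.50 + 0.818 + 0.50) / 3 from the packaged table
    assert chain_fppii("GAG", builtin_scales["kallenbach"]) == pytest.approx(0.606)
    rec = SequenceRecord("x", "GAG")
    assert chain_fppii(rec, builtin_scales["kallenbach"]) == pytest.approx(0.606)


def test_predict_sequence_result(builtin_scales):
    res = predict_sequence(SequenceRecord("x", "ASDF" * 10), builtin_scales["hilser"])
    assert res.n == 40
    assert res.rh_pred == pytest.approx(predict_rh(40, res.f_ppii_chain))
    assert res.v >= 0.503


def test_evaluate_dataset_perfect_predictions(builtin_scales):
    """When observed equals predicted: zero error, unit correlation."""
    records = [
        SequenceRecord(f"s{i}", ppiirh.random_idp_sequence(n, np.random.default_rng(i)))
        for i, n in enumerate((80, 120, 160, 200))
    ]
    hilser = builtin_scales["hilser"]
    obs = {r.id: predict_sequence(r, hilser).rh_pred for r in records}
    ev = evaluate_dataset(records, obs, hilser)
    assert ev.mean_abs_error == pytest.approx(0.0, abs=1e-12)
    assert ev.r2_pred_obs == pytest.approx(1.0)
    assert np.allclose(ev.table["norm_error"], 0.0)


def test_evaluate_dataset_structure(synthetic_dataset, builtin_scales):
    records, obs = synthetic_dataset
    ev = evaluate_dataset(records, obs, builtin_scales["hilser"])
    t = ev.table
    assert len(t) == len(records)
    # Eq-8 ncd is zero iff |Q| is zero
    assert ((t["ncd"] == 0) == (t["net_charge"] == 0)).all()
    # normalized error sign matches prediction error sign
    assert np.allclose(
        np.sign(t["rh_pred"] - t["rh_obs"]), np.sign(t["norm_error"])
    )
    assert np.allclose(t["random_coil_rh"], random_coil_rh(t["n"].to_numpy()))
    assert ev.dataset_charge_bias > 1.0
    with pytest.raises(ValueError):
        evaluate_dataset([], obs, builtin_scales["hilser"])


def test_evaluate_composite_close_to_hilser(synthetic_dataset):
    """Composite lookup deviates from Hilser only at G-X-G / P-X-P contexts."""
    records, obs = synthetic_dataset
    ev_h = evaluate_dataset(records, obs, ppiirh.load_builtin_scale("hilser"))
    ev_c = evaluate_dataset(records, obs, "composite")
    diff = np.abs(ev_c.table["f_ppii_chain"] - ev_h.table["f_ppii_chain"])
    assert (diff < 0.05).all()
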