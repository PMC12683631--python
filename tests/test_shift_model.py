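"""The empirical shift equations and their composition."""

import dataclasses
import random

import numpy as np
import pytest
from hypothesis import given, strategies as st

from conftest import direct_formula_shift, random_profile
from o17shift.geometry_io import MoleculeKind
from o17shift.hbond_topology import HydrogenBond, WaterHBondProfile
from o17shift.shift_model import (
    DEFAULT_PARAMS,
    ShiftModelParams,
    acceptor_term,
    additivity_estimate,
    bond_length_correction,
    calibrated_water_shift,
    dmso_terms,
    donor_term,
    gas_to_liquid_shift,
    methane_base_term,
    per_hbond_trend,
    raw_water_sum,
    rereference_to_bulk,
    shielding_to_shift,
)


def _wbond(r, donor_kind=MoleculeKind.WATER, acceptor_kind=MoleculeKind.WATER,
           conventional=True):
    return HydrogenBond(0, 1, 2, float(r), 165.0, donor_kind, acceptor_kind,
                        0, 1, conventional)


def _profile(n_accept=0, n_donate=0, r=1.70, accept_kinds=None, donate_kinds=None,
             ch=(), oh=(0.962, 0.962)):
    prof = WaterHBondProfile(water=0, oh_lengths=oh)
    accept_kinds = accept_kinds or [MoleculeKind.WATER] * n_accept
    donate_kinds = donate_kinds or [MoleculeKind.WATER] * n_donate
    for k in accept_kinds:
        prof.accepted.append(_wbond(r, donor_kind=k))
    for k in donate_kinds:
        prof.donated.append(_wbond(r, acceptor_kind=k))
    for rc, k in ch:
        prof.ch_contacts.append(_wbond(rc, donor_kind=k, conventional=False))
    return prof


# ---------------------------------------------------------------------------
# individual terms (expected values from independent arithmetic)
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("fn,r,expected", [
    (acceptor_term, 1.70, 16.4126),   # 137.08 / 1.7^4
    (acceptor_term, 2.00, 8.5675),    # 137.08 / 16
    (donor_term, 1.70, 7.3012),       # 60.98 / 1.7^4
    (donor_term, 2.00, 3.8113),       # 60.98 / 16
])
def test_distance_term_values(fn, r, expected):
    assert fn(r) == pytest.approx(expected, abs=1e-4)


def test_acceptor_donor_ratio_constant():
    for r in (1.7, 2.0, 2.5, 3.3):
        assert acceptor_term(r) / donor_term(r) == pytest.approx(137.08 / 60.98, rel=1e-12)


@pytest.mark.parametrize("fn", [acceptor_term, donor_term, methane_base_term])
def test_nonpositive_distance_rejected(fn):
    with pytest.raises(ValueError):
        fn(0.0)
    with pytest.raises(ValueError):
        fn(-1.3)


@given(st.floats(min_value=1.5, max_value=20.0),
       st.floats(min_value=0.01, max_value=2.0))
def test_terms_strictly_decreasing_and_vanishing(r, dr):
    for fn in (acceptor_term, donor_term, methane_base_term):
        assert fn(r) > fn(r + dr) > 0.0
        assert fn(1e6) < 1e-12


# ---------------------------------------------------------------------------
# raw sums and calibration
# ---------------------------------------------------------------------------

def test_raw_sum_1a1d():
    assert raw_water_sum(_profile(1, 1)) == pytest.approx(23.7138, abs=1e-4)


def test_raw_sum_2a2d():
    assert raw_water_sum(_profile(2, 2)) == pytest.approx(47.4276, abs=1e-4)


def test_raw_sum_empty_profile():
    assert raw_water_sum(_profile()) == 0.0


def test_raw_sum_excludes_dmso_but_scales_glycerol():
    prof = _profile(n_accept=1, donate_kinds=[MoleculeKind.DMSO, MoleculeKind.GLYCEROL])
    expected = 137.08 / 1.7**4 + 0.9 * 60.98 / 1.7**4
    assert raw_water_sum(prof) == pytest.approx(expected, rel=1e-12)


def test_calibrated_nodangling_2a2d():
    bd = calibrated_water_shift(_profile(2, 2))
    assert bd.calibration == "nodangling"
    assert bd.delta_isolated_ref == pytest.approx(1.38 * 47.42759 - 0.78, abs=1e-3)
    assert bd.delta_isolated_ref == pytest.approx(64.67, abs=1e-2)


def test_calibrated_dangling_1a1d():
    bd = calibrated_water_shift(_profile(1, 1))
    assert bd.calibration == "dangling"
    assert bd.delta_isolated_ref == pytest.approx(27.82, abs=1e-2)


def test_isolated_water_returns_zero_not_intercept():
    bd = calibrated_water_shift(_profile())
    assert bd.delta_isolated_ref == 0.0
    assert bd.calibration == "isolated"
    assert bd.delta_bulk_ref == pytest.approx(-36.1)


def test_bond_order_invariance():
    prof = _profile(2, 2, r=1.70)
    prof.accepted[0] = _wbond(1.9)
    prof.donated[1] = _wbond(2.2)
    ref = calibrated_water_shift(prof).delta_isolated_ref
    rng = random.Random(0)
    for _ in range(5):
        rng.shuffle(prof.accepted)
        rng.shuffle(prof.donated)
        assert calibrated_water_shift(prof).delta_isolated_ref == pytest.approx(ref, abs=1e-12)


def test_raw_sum_additive_over_single_bond_subprofiles():
    prof = _profile(2, 1, r=1.70)
    prof.accepted[1] = _wbond(1.85)
    total = raw_water_sum(prof)
    parts = 0.0
    for b in prof.accepted:
        parts += raw_water_sum(WaterHBondProfile(water=0, accepted=[b]))
    for b in prof.donated:
        parts += raw_water_sum(WaterHBondProfile(water=0, donated=[b]))
    assert total == pytest.approx(parts, abs=1e-12)


def test_bulk_reference_offset_consistency():
    rng = np.random.default_rng(7)
    for _ in range(20):
        bd = calibrated_water_shift(random_profile(rng))
        assert bd.delta_isolated_ref - bd.delta_bulk_ref == pytest.approx(36.1, abs=1e-12)


def test_bond_length_corrected_calibration():
    prof = _profile(1, 1, oh=(0.968, 0.962))
    blc = 579.36 / 2 * 0.006
    expected = 0.95 * (23.71379 + blc)  # dangling zero-intercept slope
    bd = calibrated_water_shift(prof, bond_length_corrected=True)
    assert bd.calibration == "dangling_blcorr"
    assert bd.delta_isolated_ref == pytest.approx(expected, abs=1e-3)


def test_oracle_equivalence_on_random_profiles():
    rng = np.random.default_rng(42)
    for k in range(200):
        prof = random_profile(rng)
        blc = bool(k % 2)
        got = calibrated_water_shift(prof, bond_length_corrected=blc).delta_isolated_ref
        assert got == pytest.approx(direct_formula_shift(prof, blc), abs=1e-10)


# ---------------------------------------------------------------------------
# DMSO / methane / bond-length terms
# ---------------------------------------------------------------------------

def test_dmso_terms_symmetric_case():
    assert dmso_terms(1.8, [2.4, 2.4]) == pytest.approx(26.78, abs=1e-2)


def test_dmso_terms_ch_only_and_empty():
    assert dmso_terms(None, [3.0]) == pytest.approx(1799.10 / 729, rel=1e-12)
    assert dmso_terms(None, []) == 0.0
    with pytest.raises(ValueError):
        dmso_terms(-1.0, [])


def test_methane_base_term_value_and_composition():
    assert methane_base_term(2.6) == pytest.approx(5.4843, abs=1e-3)
    # 1694.2 * 1.13 * 0.94 ~ 1799.6, agreeing with the printed 1799.10
    # only to rounding of the intermediate scale factors
    composed = 1694.2 * 1.13 * 0.94
    assert composed == pytest.approx(DEFAULT_PARAMS.coeff_ch_contact, abs=1.0)
    assert methane_base_term(2.6, scaled=True) == pytest.approx(5.4843 * 1.13, abs=1e-3)


@pytest.mark.parametrize("lengths,expected", [
    ((0.962, 0.962), 0.0),
    ((0.968, 0.962), 579.36 / 2 * 0.006),
    ((0.972, 0.972), 579.36 * 0.010),
])
def test_bond_length_correction_values(lengths, expected):
    assert bond_length_correction(lengths) == pytest.approx(expected, abs=1e-9)


def test_bond_length_correction_warns_outside_physical_range():
    with pytest.warns(UserWarning, match="mis-assigned"):
        bond_length_correction((1.4, 0.962))


# ---------------------------------------------------------------------------
# cluster constants, references, parameter set
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("na,nd,expected", [
    (1, 1, 23.9), (2, 0, 33.0), (0, 2, 14.8),
    (2, 1, 40.4), (1, 2, 31.3), (2, 2, 47.8), (0, 0, 0.0),
])
def test_additivity_estimate_table(na, nd, expected):
    assert additivity_estimate(na, nd) == pytest.approx(expected, abs=1e-9)


def test_shielding_conversion_and_rereferencing():
    assert shielding_to_shift(326.14) == 0.0
    assert shielding_to_shift(316.14) == pytest.approx(10.0)
    assert shielding_to_shift(336.14) == pytest.approx(-10.0)
    assert rereference_to_bulk(36.1) == pytest.approx(0.0)
    assert rereference_to_bulk(0.0) == pytest.approx(-36.1)
    assert gas_to_liquid_shift() == pytest.approx(36.1, abs=1e-9)
    assert per_hbond_trend(3.5) == pytest.approx(35.0)


def test_params_round_trip_and_presets(tmp_path):
    p = tmp_path / "params.json"
    DEFAULT_PARAMS.to_json(p)
    back = ShiftModelParams.from_json(p)
    assert back == DEFAULT_PARAMS
    unrelaxed = DEFAULT_PARAMS.preset("unrelaxed")
    assert unrelaxed.slope_acceptor == 120.0 and unrelaxed.slope_donor == 40.0
    pooled = DEFAULT_PARAMS.preset("global")
    assert pooled.scale_dangling == pooled.scale_nodangling == 1.43
    with pytest.raises(ValueError):
        DEFAULT_PARAMS.preset("nope")


def test_structural_consistency_with_additivity_constants():
    # swapping the fitted 1.7-A term values (16.41/7.30) for the cluster
    # constants (16.5/7.4) must reduce the raw sum to the additivity estimate
    params = dataclasses.replace(
        DEFAULT_PARAMS,
        slope_acceptor=16.5 * 1.7**4, slope_donor=7.4 * 1.7**4)
    for na, nd in ((1, 1), (2, 1), (2, 2)):
        prof = _profile(na, nd, r=1.70)
        assert raw_water_sum(prof, params) == pytest.approx(
            additivity_estimate(na, nd), abs=1e-9)
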