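"""Volumetric index formulas against hand-computed values and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from frfx.types import PatientMeta
from frfx.volumetry import (
    bsa_m2,
    compute_volumetry,
    frfxv_pct,
    frlv_pct,
    growth_pct,
    kgr_pct_per_day,
    mask_volume_cc,
    sflr_pct,
    volumetry_for_case,
)

# hand-computed oracles: (args, expected)
FRLV_CASES = [
    ((500.0, 1500.0, 500.0), 50.0),
    ((901.0, 1681.0, 0.0), 901.0 / 1681.0 * 100.0),
    ((456.0, 1884.0, 200.0), 456.0 / 1684.0 * 100.0),
    ((0.0, 1000.0, 0.0), 0.0),
    ((870.0, 1450.0, 50.0), 870.0 / 1400.0 * 100.0),
    ((1023.48, 1500.0, 100.0), 1023.48 / 1400.0 * 100.0),
    ((350.0, 1318.0, 72.0), 350.0 / 1246.0 * 100.0),
    ((649.0, 1480.0, 59.0), 649.0 / 1421.0 * 100.0),
    ((1200.0, 1200.5, 0.0), 1200.0 / 1200.5 * 100.0),
    ((715.2, 1930.4, 310.9), 715.2 / 1619.5 * 100.0),
]

GROWTH_CASES = [
    ((700.0, 350.0), 100.0),
    ((64.0, 128.0), -50.0),
    ((941.0, 536.0), 405.0 / 536.0 * 100.0),
    ((536.0, 536.0), 0.0),
    ((1055.0, 649.0), 406.0 / 649.0 * 100.0),
    ((901.0, 350.0), 551.0 / 350.0 * 100.0),
    ((124.0, 312.0), -188.0 / 312.0 * 100.0),
    ((1651.0, 839.0), 812.0 / 839.0 * 100.0),
    ((0.0, 50.0), -100.0),
    ((417.5, 312.25), 105.25 / 312.25 * 100.0),
]

BSA_CASES = [
    ((180.0, 80.0), 2.0),
    ((160.0, 56.25), np.sqrt(2.5)),
    ((175.0, 70.0), np.sqrt(175.0 * 70.0 / 3600.0)),
    ((170.0, 75.0), np.sqrt(170.0 * 75.0 / 3600.0)),
    ((150.0, 48.0), np.sqrt(2.0)),
    ((190.0, 94.7), np.sqrt(190.0 * 94.7 / 3600.0)),
    ((120.0, 30.0), 1.0),
    ((200.0, 100.0), np.sqrt(200.0 * 100.0 / 3600.0)),
    ((165.5, 62.3), np.sqrt(165.5 * 62.3 / 3600.0)),
    ((144.0, 100.0), 2.0),
]

SFLR_CASES = [
    ((870.075, 2.0), 50.0),
    ((0.0, 1.0), 0.0),
    ((472.87, 1.0), 472.87 / (-794.41 + 1267.28) * 100.0),
    ((500.0, 1.8), 500.0 / (-794.41 + 1267.28 * 1.8) * 100.0),
    ((901.0, 1.9), 901.0 / (-794.41 + 1267.28 * 1.9) * 100.0),
    ((649.0, 1.7), 649.0 / (-794.41 + 1267.28 * 1.7) * 100.0),
    ((1023.0, 2.2), 1023.0 / (-794.41 + 1267.28 * 2.2) * 100.0),
    ((350.5, 1.65), 350.5 / (-794.41 + 1267.28 * 1.65) * 100.0),
    ((1200.0, 2.4), 1200.0 / (-794.41 + 1267.28 * 2.4) * 100.0),
    ((75.0, 0.85), 75.0 / (-794.41 + 1267.28 * 0.85) * 100.0),
]

KGR_CASES = [
    ((70.0, 30.0, 20), 2.0),
    ((63.0, 34.0, 66), 29.0 / 66.0),
    ((50.0, 50.0, 10), 0.0),
    ((71.0, 29.0, 14), 3.0),
    ((63.0, 34.0, 71), 29.0 / 71.0),
    ((45.0, 52.0, 7), -1.0),
    ((120.0, 20.0, 40), 2.5),
    ((33.3, 11.1, 3), 22.2 / 3.0),
    ((80.0, 30.0, 106), 50.0 / 106.0),
    ((29.5, 29.0, 1), 0.5),
]


@pytest.mark.parametrize("args,expected", FRLV_CASES)
def test_frlv_matches_hand_oracle(args, expected):
    assert frlv_pct(*args) == pytest.approx(expected, rel=1e-9)


@pytest.mark.parametrize("args,expected", GROWTH_CASES)
def test_growth_matches_hand_oracle(args, expected):
    assert growth_pct(*args) == pytest.approx(expected, rel=1e-9, abs=1e-12)


@pytest.mark.parametrize("args,expected", BSA_CASES)
def test_bsa_matches_hand_oracle(args, expected):
    assert bsa_m2(*args) == pytest.approx(expected, rel=1e-9)


@pytest.mark.parametrize("args,expected", SFLR_CASES)
def test_sflr_matches_hand_oracle(args, expected):
    assert sflr_pct(*args) == pytest.approx(expected, rel=1e-9, abs=1e-12)


@pytest.mark.parametrize("args,expected", KGR_CASES)
def test_kgr_matches_hand_oracle(args, expected):
    assert kgr_pct_per_day(*args) == pytest.approx(expected, rel=1e-9)


def test_frfxv_equals_frlv_when_fully_functional():
    assert frfxv_pct(500.0, 1500.0, 500.0) == frlv_pct(500.0, 1500.0, 500.0)
    assert frfxv_pct(250.0, 1500.0, 500.0) == pytest.approx(25.0)


@pytest.mark.parametrize(
    "fn,args",
    [
        (frlv_pct, (100.0, 100.0, 100.0)),
        (growth_pct, (100.0, 0.0)),
        (growth_pct, (100.0, -5.0)),
        (bsa_m2, (0.0, 70.0)),
        (bsa_m2, (170.0, -1.0)),
        (sflr_pct, (500.0, 0.5)),
        (kgr_pct_per_day, (70.0, 30.0, 0)),
    ],
)
def test_domain_errors(fn, args):
    with pytest.raises(ValueError):
        fn(*args)


def test_mask_volume_counts_voxels():
    grid = np.zeros((10, 10, 10), dtype=int)
    grid[:10, 0, 0] = 2
    assert mask_volume_cc(grid, 2, (1.0, 1.0, 1.0)) == pytest.approx(0.01)
    grid = np.ones((10, 10, 10), dtype=int)
    assert mask_volume_cc(grid, 1, (1.0, 1.0, 1.0)) == pytest.approx(1.0)
    assert mask_volume_cc(grid, 5, (1.0, 1.0, 1.0)) == 0.0
    grid2 = np.zeros((4, 4, 4), dtype=int)
    grid2[:2, :2, :2] = 3
    assert mask_volume_cc(grid2, 3, (2.0, 2.0, 2.0)) == pytest.approx(0.064)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    frl=st.floats(1.0, 2000.0),
    tlv=st.floats(500.0, 4000.0),
    tv=st.floats(0.0, 400.0),
    c=st.floats(0.01, 100.0),
)
def test_percentages_scale_invariant(frl, tlv, tv, c):
    """Multiplying all volumes by c leaves every percentage unchanged."""
    assert frlv_pct(frl * c, tlv * c, tv * c) == pytest.approx(
        frlv_pct(frl, tlv, tv), rel=1e-9
    )
    assert growth_pct(tlv * c, frl * c) == pytest.approx(
        growth_pct(tlv, frl), rel=1e-9, abs=1e-9
    )


def _meta(days=20):
    return PatientMeta("t", 175.0, 70.0, "ALPPS", days)


def test_compute_volumetry_internally_consistent():
    rec = compute_volumetry(_meta(), 1500.0, 100.0, 400.0, 900.0, 380.0, 500.0)
    assert rec.frlv_post_pct == pytest.approx(900.0 / 1400.0 * 100.0, rel=1e-9)
    assert rec.frfxv_post_pct == pytest.approx(500.0 / 1400.0 * 100.0, rel=1e-9)
    assert rec.ifrl_pct == pytest.approx(125.0, rel=1e-9)
    assert rec.kgr_pct_per_day == pytest.approx(
        (rec.frlv_post_pct - rec.frlv_pre_pct) / 20.0, rel=1e-9
    )
    assert rec.frfxv_post_pct <= rec.frlv_post_pct
    # sFLR basis for KGR is exposed as a config switch
    rec2 = compute_volumetry(
        _meta(), 1500.0, 100.0, 400.0, 900.0, 380.0, 500.0, kgr_basis="sflr"
    )
    assert rec2.kgr_pct_per_day == pytest.approx(
        (rec2.sflr_post_pct - rec2.sflr_pre_pct) / 20.0, rel=1e-9
    )


def test_compute_volumetry_rejects_functional_exceeding_anatomic():
    with pytest.raises(ValueError):
        compute_volumetry(_meta(), 1500.0, 100.0, 400.0, 900.0, 500.0, 950.0)


def test_phantom_case_record_all_finite(sample_case):
    rec = volumetry_for_case(sample_case)
    vals = [getattr(rec, f) for f in vars(rec) if f != "case_id"]
    assert np.all(np.isfinite(vals))
    assert rec.frfx_post_cc <= rec.frl_post_cc
    assert rec.frfx_post_cc == pytest.approx(sample_case.truth_frfx_cc)
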