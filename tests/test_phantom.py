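"""Phantom generator: geometry targets, texture statistics, truth bookkeeping."""

import numpy as np
import pytest

from frfx.phantom import (
    CaseParams,
    CohortParams,
    DEFAULT_TEXTURES,
    GeometryInfeasibleError,
    OutcomeCoeffs,
    TissueTexture,
    assign_phlf,
    cohort_manifest,
    generate_case,
    generate_cohort,
    make_liver_geometry,
    synth_texture,
)
from frfx.types import Label, PhlfGrade, SegMaskSet, Technique, Truth

VOX_CC = 2.5**3 / 1000.0  # default voxel volume


class TestGeometry:
    def test_liver_volume_hits_target(self):
        seg = make_liver_geometry(
            (64, 64, 64), (2.5, 2.5, 2.5), target_tlv_cc=1400.0, seed=5
        )
        liver_cc = np.count_nonzero(seg.observed) * VOX_CC
        assert 1330.0 <= liver_cc <= 1470.0

    def test_flr_fraction_within_tolerance(self):
        seg = make_liver_geometry(target_flr_fraction=0.3, seed=2)
        liver = np.count_nonzero(seg.observed)
        flr = np.count_nonzero(seg.observed == Label.FLR)
        vessels_in = np.count_nonzero(seg.observed == Label.VESSEL)
        # plane cut is checked before vessel carving; allow vessel share on top
        assert abs((flr + 0.3 * vessels_in) / liver - 0.3) < 0.05

    def test_deterministic_given_seed(self):
        a = make_liver_geometry(seed=11)
        b = make_liver_geometry(seed=11)
        assert np.array_equal(a.observed, b.observed)
        assert not np.array_equal(a.observed, make_liver_geometry(seed=12).observed)

    def test_zero_flr_fraction_rejected(self):
        with pytest.raises(GeometryInfeasibleError, match="FLR"):
            make_liver_geometry(target_flr_fraction=0.0)

    def test_oversized_liver_rejected(self):
        with pytest.raises(GeometryInfeasibleError, match="infeasible"):
            make_liver_geometry(target_tlv_cc=3000.0)

    def test_tumour_disjoint_from_flr(self):
        seg = make_liver_geometry(seed=3, _post_flr_fraction=0.66)
        assert np.count_nonzero(seg.observed == Label.TUMOUR) > 0
        # tumour entirely on the non-remnant side even for the enlarged remnant
        post = make_liver_geometry(seed=3, target_flr_fraction=0.66, _post_flr_fraction=0.66)
        assert not np.any(
            (post.observed == Label.FLR) & (seg.observed == Label.TUMOUR)
        )


class TestTexture:
    def test_zero_sigma_gives_piecewise_constant(self):
        seg = make_liver_geometry(seed=4)
        flat = {k: TissueTexture(v.mu, 0.0, v.corr_len) for k, v in DEFAULT_TEXTURES.items()}
        img = synth_texture(seg, flat, seed=0)
        for lbl, cls in [(Label.LIVER, "liver"), (Label.FLR, "functional"),
                         (Label.VESSEL, "vessel"), (Label.TUMOUR, "tumour")]:
            vals = img.voxels[seg.observed == lbl]
            assert np.all(vals == flat[cls].mu)

    def test_class_means_and_contrast(self, sample_case):
        img, seg = sample_case.post
        fun = img.voxels[(seg.observed == Label.FLR) & (seg.truth == Truth.FUNCTIONAL)]
        oed = img.voxels[(seg.observed == Label.FLR) & (seg.truth == Truth.OEDEMA)]
        assert fun.size > 1e4 and oed.size > 1e4
        assert fun.mean() - oed.mean() == pytest.approx(35.0, abs=1.0)
        # per-class renormalisation pins mean and sd exactly (float32 grid)
        assert fun.mean() == pytest.approx(105.0, abs=1e-2)
        assert fun.std() == pytest.approx(12.0, abs=1e-2)
        assert oed.std() == pytest.approx(20.0, abs=1e-2)

    def test_deterministic(self):
        seg = make_liver_geometry(seed=6)
        a = synth_texture(seg, DEFAULT_TEXTURES, seed=9)
        b = synth_texture(seg, DEFAULT_TEXTURES, seed=9)
        assert np.array_equal(a.voxels, b.voxels)

    def test_missing_params_name_the_label(self):
        seg = make_liver_geometry(seed=6)
        params = {k: v for k, v in DEFAULT_TEXTURES.items() if k != "vessel"}
        with pytest.raises(KeyError, match="vessel"):
            synth_texture(seg, params, seed=0)


class TestCase:
    def test_zero_theta_all_functional(self):
        case = generate_case(CaseParams(theta=0.0), seed=21)
        assert case.truth_frfx_cc == pytest.approx(case.truth_frl_cc)

    def test_theta_half_splits_volume(self):
        case = generate_case(CaseParams(theta=0.5), seed=22)
        assert case.truth_frfx_cc == pytest.approx(
            0.5 * case.truth_frl_cc, abs=VOX_CC
        )

    @pytest.mark.parametrize("theta", [0.1, 0.25, 0.45, 0.7])
    def test_theta_recovered_from_truth_mask(self, theta):
        """Voxel-counting the truth mask returns the requested oedema share."""
        case = generate_case(CaseParams(theta=theta), seed=int(theta * 100))
        seg = case.post[1]
        par = seg.observed == Label.FLR
        got = np.count_nonzero(seg.truth == Truth.OEDEMA) / np.count_nonzero(par)
        assert par.sum() >= 500
        assert abs(got - theta) <= 0.02

    def test_volume_conservation(self, sample_case):
        seg = sample_case.post[1]
        par = np.count_nonzero(seg.observed == Label.FLR)
        fun = np.count_nonzero(seg.truth == Truth.FUNCTIONAL)
        oed = np.count_nonzero(seg.truth == Truth.OEDEMA)
        assert fun + oed == par
        assert fun * VOX_CC == pytest.approx(sample_case.truth_frfx_cc)

    def test_post_flr_not_smaller_than_pre(self, sample_case):
        pre = np.count_nonzero(sample_case.pre[1].observed == Label.FLR)
        post = np.count_nonzero(sample_case.post[1].observed == Label.FLR)
        assert post >= pre

    def test_pre_truth_entirely_functional(self, sample_case):
        seg = sample_case.pre[1]
        flr = seg.observed == Label.FLR
        assert np.all(seg.truth[flr] == Truth.FUNCTIONAL)
        assert np.all(seg.truth[~flr] == Truth.NA)

    @pytest.mark.parametrize(
        "technique,lo,hi", [(Technique.ALPPS, 7, 22), (Technique.PVE, 36, 106)]
    )
    def test_days_elapsed_range(self, technique, lo, hi):
        for seed in range(5):
            case = generate_case(CaseParams(technique=technique), seed=seed)
            assert lo <= case.meta.days_elapsed <= hi

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            CaseParams(theta=1.2)
        with pytest.raises(ValueError):
            CaseParams(growth=-0.1)


class TestOutcomeModel:
    def test_logistic_closed_form(self):
        c = OutcomeCoeffs(a0=2.0, a1=0.08)
        assert c.p_severe(25.0) == pytest.approx(0.5)
        assert c.p_severe(50.0) == pytest.approx(1.0 / (1.0 + np.exp(2.0)), rel=1e-9)
        assert c.p_severe(1e6) == pytest.approx(0.0, abs=1e-12)

    def test_negative_slope_rejected(self):
        with pytest.raises(ValueError):
            OutcomeCoeffs(a1=-0.01)

    def test_probability_monotone_in_functional_volume(self):
        """Empirical severe rate is non-increasing across the FRFxV grid."""
        rng = np.random.default_rng(77)
        rates = []
        for frfxv in (10.0, 25.0, 40.0, 60.0):
            draws = sum(
                PhlfGrade.is_severe(assign_phlf(frfxv, seed=rng))
                for _ in range(10_000)
            )
            rates.append(draws / 10_000)
        assert all(a >= b for a, b in zip(rates, rates[1:]))

    def test_grade_split_probabilities(self):
        rng = np.random.default_rng(5)
        grades = [assign_phlf(0.0, seed=rng) for _ in range(4000)]  # p_severe ~ 0.88
        n_c = grades.count(PhlfGrade.C)
        n_b = grades.count(PhlfGrade.B)
        assert n_c / (n_b + n_c) == pytest.approx(1.0 / 3.0, abs=0.05)


class TestCohort:
    def test_manifest_deterministic(self):
        p = CohortParams(n=4, n_alpps=2, render_texture=False)
        a = cohort_manifest(generate_cohort(p, seed=42))
        b = cohort_manifest(generate_cohort(p, seed=42))
        assert a.equals(b)

    def test_all_pve_split(self):
        cases = generate_cohort(
            CohortParams(n=3, n_alpps=0, render_texture=False), seed=1
        )
        assert all(c.meta.technique == Technique.PVE for c in cases)

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(CohortParams(n=1, n_alpps=1), seed=0)

    def test_severe_count_in_expected_band(self):
        """Mean PHLF >= B count per 24-case cohort under the default link."""
        p = CohortParams(render_texture=False)
        counts = [
            sum(
                PhlfGrade.is_severe(c.meta.phlf_grade)
                for c in generate_cohort(p, seed=9000 + r)
            )
            for r in range(20)
        ]
        assert 4.0 <= np.mean(counts) <= 9.0

    def test_technique_specific_growth_direction(self):
        """ALPPS grows faster but with more oedema than PVE on average."""
        p = CohortParams(n=16, n_alpps=8, render_texture=False)
        m = cohort_manifest(generate_cohort(p, seed=33))
        a = m[m.technique == "ALPPS"]
        v = m[m.technique == "PVE"]
        assert a.theta.mean() > v.theta.mean()
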