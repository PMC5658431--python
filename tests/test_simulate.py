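from dataclasses import replace

import numpy as np
import pytest

from adcrepeat.adcmap import compute_adc_map, summarise_roi
from adcrepeat.io import pair_sessions
from adcrepeat.metrics import make_records
from adcrepeat.simulate import (LesionSpec, SyntheticConfig, generate_cohort,
                                generate_dwi_phantom, load_phantom_nifti,
                                recovery_study, save_phantom_nifti)


def test_config_validation():
    with pytest.raises(ValueError):
        SyntheticConfig(motion_fraction=1.5, seed=0)
    with pytest.raises(ValueError):
        SyntheticConfig(adc_range=(200, 100), seed=0)
    with pytest.raises(ValueError):
        SyntheticConfig(beta=-1, seed=0)


def test_cohort_deterministic_from_seed():
    cfg = SyntheticConfig(n_patients=6, seed=99)
    assert generate_cohort(cfg) == generate_cohort(cfg)
    other = generate_cohort(replace(cfg, seed=100))
    assert other != generate_cohort(cfg)


def test_cohort_marginals_match_config():
    cfg = SyntheticConfig(n_patients=200, motion_fraction=0.25, seed=5)
    cohort = generate_cohort(cfg)
    assert len(cohort) == 200 * 4 * 2
    n = np.array([m.n_voxels for m in cohort
                  if m.roi_kind != "parenchyma"])
    assert n.min() >= 100 and n.max() <= 10000
    d = np.array([m.mean_adc for m in cohort])
    assert d.min() > 0
    assert 76 < np.median(d) < 198  # bulk sits in the true ADC range
    # motion fraction of patients within binomial error (3 sigma)
    flagged_patients = {m.patient_id for m in cohort if m.motion_flag}
    frac = len(flagged_patients) / 200
    assert abs(frac - 0.25) < 3 * np.sqrt(0.25 * 0.75 / 200)


def test_sys_only_cohort_r12_spread():
    """With beta and sigma_fix silenced, the SD of R12 over many pairs
    approaches eps_sys (distributional oracle from the construction)."""
    cfg = SyntheticConfig(n_patients=2500, roi_kinds=("whole_3d",),
                          width_range=(0.0, 0.0), sigma_fix=0.0, beta=0.0,
                          epsilon_sys=5.0, motion_fraction=0.0,
                          width_jitter=False, seed=31)
    recs = make_records(pair_sessions(generate_cohort(cfg)).pairs)
    sd = np.std([r.r12 for r in recs])
    assert sd == pytest.approx(5.0, rel=0.05)


def test_zero_noise_cohort_gives_zero_r12():
    cfg = SyntheticConfig(n_patients=10, beta=0.0, sigma_fix=0.0,
                          epsilon_sys=0.0, width_range=(0, 0),
                          motion_fraction=0.0, width_jitter=False, seed=1)
    recs = make_records(pair_sessions(generate_cohort(cfg)).pairs)
    assert all(r.r12 == pytest.approx(0.0, abs=1e-9) for r in recs)


def test_phantom_noiseless_recovers_adc_exactly():
    spec = LesionSpec(mean_adc=109.0, adc_sd=15.0)
    stack, mask = generate_dwi_phantom(spec, noise_sigma=0.0, seed=2)
    amap = compute_adc_map(stack)
    truth_mean = np.nanmean(np.where(mask, amap.values, np.nan))
    m = summarise_roi(amap, mask, patient_id="P", roi_kind="whole_3d",
                      session="test")
    assert m.n_voxels == int(mask.sum())
    assert m.mean_adc == pytest.approx(truth_mean, rel=1e-9)


def test_phantom_end_to_end_roi_mean():
    """Lesion with mean 109, width 20, ~2000 voxels: pipeline ROI mean
    lands within 3 w / sqrt(N) of truth (sampling oracle)."""
    spec = LesionSpec(shape=(24, 24, 16), radius_vox=7.8, mean_adc=109.0,
                      adc_sd=20.0, s0=2000.0)
    stack, mask = generate_dwi_phantom(spec, noise_sigma=2.0, seed=8)
    n = int(mask.sum())
    assert n > 1500
    amap = compute_adc_map(stack)
    m = summarise_roi(amap, mask, patient_id="P", roi_kind="whole_3d",
                      session="test")
    assert abs(m.mean_adc - 109.0) < 3 * 20.0 / np.sqrt(n) + 1.0


def test_phantom_nifti_roundtrip(tmp_path):
    spec = LesionSpec(shape=(12, 12, 6), radius_vox=3.5)
    stack, mask = generate_dwi_phantom(spec, noise_sigma=1.0, seed=3)
    save_phantom_nifti(stack, mask, tmp_path / "dwi.nii.gz",
                       tmp_path / "mask.nii.gz")
    stack2, mask2 = load_phantom_nifti(tmp_path / "dwi.nii.gz",
                                       tmp_path / "mask.nii.gz",
                                       stack.b_values, 1.0)
    assert np.allclose(stack2.signals, stack.signals, atol=1e-4)
    assert np.array_equal(mask2, mask)


def test_recovery_single_replicate():
    cfg = SyntheticConfig(n_patients=10, roi_kinds=("whole_3d",),
                          motion_fraction=0.0, seed=17)
    rep = recovery_study(cfg, 1, n_starts=2)
    assert len(rep.fits) == 1
    assert rep.fits["error"].isna().all()


def test_recovery_sys_only_truth_silences_other_terms():
    """Data generated with only systematic error, fitted with the full
    model: the width- and fixed-fitting-error contributions collapse."""
    cfg = SyntheticConfig(n_patients=150, roi_kinds=("whole_3d",),
                          beta=0.0, sigma_fix=0.0, epsilon_sys=5.0,
                          motion_fraction=0.0, seed=23)
    rep = recovery_study(cfg, 3, variant="three_param", n_starts=6)
    ok = rep.fits[rep.fits["error"].isna()]
    assert len(ok) == 3
    # contribution of the non-systematic terms at a typical ROI
    # (w=35, N=1000, D=137) must be tiny relative to eps_sys
    from adcrepeat.error_model import model_uncertainty, ErrorModelParams

    for _, row in ok.iterrows():
        p = ErrorModelParams(row.beta, row.sigma_fix, row.epsilon_sys)
        eps = model_uncertainty(137, 137, 35, 35, 1000, 1000, p)
        assert eps == pytest.approx(row.epsilon_sys, rel=0.05)
        assert eps == pytest.approx(5.0, rel=0.10)
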