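"""Synthetic cohort generator: calibration, determinism, composition."""

from dataclasses import replace

import numpy as np
import pytest

from noisematch.core import PROFILES, ReconProfile
from noisematch.phantom import (
    CohortSpec,
    LesionSpec,
    PhantomSpec,
    calibrate_noise_amplitude,
    generate_cohort,
    generate_phantom,
    gold_threshold,
    partition_lesions,
    sample_lesions,
)
from noisematch.noise import subject_background_cov


def test_registered_profile_cov_targets():
    targets = {
        "Set1-QClear": 0.091,
        "Set1-VPFXS-5min": 0.098,
        "Set1-VPFXS-4min": 0.102,
        "Set1-VPFXS-3min": 0.110,
        "Set1-VPFXS-2min": 0.121,
        "Set2-OSEM": 0.198,
    }
    for name, cov in targets.items():
        assert PROFILES[name].target_cov == cov


def test_calibration_identity_filter():
    """With no smoothing there is no variance reduction: the amplitude
    is COV times the background mean."""
    prof = ReconProfile("ident", 5.0, 0.1, 0.0)
    amp = calibrate_noise_amplitude(prof, background_suv_mean=1.0)
    assert amp == pytest.approx(0.1)


def test_calibration_monotone_in_target_cov():
    """Amplitude grows monotonically with the COV target, all else
    equal (brute-force sweep)."""
    amps = [
        calibrate_noise_amplitude(
            ReconProfile("p", 5.0, cov, 5.0),
            grid_shape=(64, 64),
            spacing=(2.5, 2.5),
        )
        for cov in (0.091, 0.121, 0.198)
    ]
    assert amps[0] < amps[1] < amps[2]


def test_phantom_normal_subject():
    img, gold = generate_phantom(
        PhantomSpec(grid_shape=(64, 64), spacing=(2.5, 2.5), seed=4)
    )
    assert gold.n_components == 0
    center = img.voxels[24:40, 24:40]
    assert np.all(center > 0)


def test_phantom_component_count_matches_lesions():
    spec = PhantomSpec(
        grid_shape=(64, 64), spacing=(2.5, 2.5),
        profile=PROFILES["Set1-VPFXS-2min"], seed=11,
    )
    lesions = sample_lesions(np.random.default_rng(42), spec, 3)
    assert all(l.radius >= 4.0 for l in lesions)
    img, gold = generate_phantom(replace(spec, lesions=lesions))
    assert gold.n_components == 3


def test_phantom_deterministic():
    spec = PhantomSpec(grid_shape=(64, 64), spacing=(2.5, 2.5), seed=5)
    img1, gold1 = generate_phantom(spec)
    img2, gold2 = generate_phantom(spec)
    np.testing.assert_array_equal(img1.voxels, img2.voxels)
    np.testing.assert_array_equal(gold1.labels, gold2.labels)


def test_lesion_spec_validation():
    with pytest.raises(ValueError):
        LesionSpec(center=(5, 5), radius=-1.0, peak_contrast=3.0)
    with pytest.raises(ValueError):
        LesionSpec(center=(5, 5), radius=5.0, peak_contrast=0.9)


def test_gold_lesions_are_annotatable():
    """Every gold lesion peak exceeds the noise-free background
    threshold, so the PERCIST rule can recover it by construction."""
    spec = PhantomSpec(
        grid_shape=(64, 64), spacing=(2.5, 2.5),
        profile=PROFILES["Set2-OSEM"], seed=2,
    )
    lesions = sample_lesions(np.random.default_rng(0), spec, 4)
    img, gold = generate_phantom(replace(spec, lesions=lesions))
    assert gold.n_components == 4
    thr = gold_threshold(spec)
    assert thr == pytest.approx(7.5)


# -- cohorts ---------------------------------------------------------------


def test_partition_lesions_bounds():
    counts = partition_lesions(134, 41, base_seed=0)
    assert sum(counts) == 134
    assert all(1 <= c <= 10 for c in counts)
    counts = partition_lesions(233, 56, base_seed=0)
    assert sum(counts) == 233
    assert all(1 <= c <= 10 for c in counts)


def test_partition_infeasible():
    with pytest.raises(ValueError):
        partition_lesions(11, 1, base_seed=0)


def test_cohort_spec_validation():
    with pytest.raises(ValueError):
        CohortSpec(
            n_subjects=5, n_normal=2, n_abnormal=2, total_lesions=4,
            profiles=("Set1-QClear",),
        )
    with pytest.raises(ValueError):
        CohortSpec(
            n_subjects=2, n_normal=1, n_abnormal=1, total_lesions=11,
            profiles=("Set1-QClear",),
        )


def test_default_cohort_compositions():
    s1 = CohortSpec.set1()
    assert (s1.n_subjects, s1.n_normal, s1.n_abnormal, s1.total_lesions) == (
        83, 42, 41, 134,
    )
    assert len(s1.profiles) == 5
    s2 = CohortSpec.set2()
    assert (s2.n_subjects, s2.n_normal, s2.n_abnormal, s2.total_lesions) == (
        123, 67, 56, 233,
    )


def test_tiny_cohort_lesion_total(tiny_cohort):
    spec, cohort = tiny_cohort
    assert len(cohort) == spec.n_subjects
    for prof in spec.profiles:
        total = sum(s.gold[prof].n_components for s in cohort)
        assert total == spec.total_lesions
    for s in cohort:
        if s.is_abnormal:
            assert 1 <= s.n_lesions <= 10
        else:
            assert s.n_lesions == 0


def test_paired_rendering_shares_signal(tiny_cohort):
    """For a multi-profile subject the noise-free signal is shared:
    profiles with the same smoothing differ by a pure noise term with
    spatial mean ~0, and lesion positions coincide."""
    spec, cohort = tiny_cohort
    s = next(s for s in cohort if s.is_abnormal)
    a = s.images["Set1-QClear"].voxels.astype(float)
    b = s.images["Set1-VPFXS-2min"].voxels.astype(float)
    assert not np.allclose(a, b)
    # gold masks overlap strongly (same lesions, slightly different blur)
    ga = np.asarray(s.gold["Set1-QClear"].labels) > 0
    gb = np.asarray(s.gold["Set1-VPFXS-2min"].labels) > 0
    inter = np.count_nonzero(ga & gb)
    union = np.count_nonzero(ga | gb)
    assert inter / union > 0.5


def test_cohort_deterministic(tiny_cohort):
    spec, cohort = tiny_cohort
    again = generate_cohort(spec)
    for s, t in zip(cohort, again):
        assert s.subject_id == t.subject_id
        for prof in spec.profiles:
            np.testing.assert_array_equal(
                s.images[prof].voxels, t.images[prof].voxels
            )
            np.testing.assert_array_equal(
                s.gold[prof].labels, t.gold[prof].labels
            )


def test_measured_cov_near_target_small_sample(tiny_cohort):
    """Even 10 subjects land in the right COV neighbourhood."""
    spec, cohort = tiny_cohort
    for prof, tol in (("Set1-QClear", 0.35), ("Set1-VPFXS-2min", 0.35)):
        covs = [
            subject_background_cov(s.images[prof], gold=s.gold[prof])
            for s in cohort
        ]
        mean = float(np.mean(covs))
        assert abs(mean / PROFILES[prof].target_cov - 1) < tol
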