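"""Phantom cohorts: physicality, structure, determinism, misregistration."""

import dataclasses

import numpy as np
import pytest

from mmpol import mueller
from mmpol.classifier import PixelMLP
from mmpol.evaluate import roc_auc
from mmpol.features import build_feature_table
from mmpol.phantom import (
    ABNORMAL,
    NORMAL,
    UNLABELED,
    CohortConfig,
    PhantomLayout,
    TissueClassSpec,
    abnormal_tissue_spec,
    corrupt_registration,
    generate_cohort,
    load_cohort,
    normal_tissue_spec,
    sample_pixel_matrix,
    save_cohort,
)


def degenerate_spec(**overrides):
    """All spreads zero: the drawn matrix is deterministic."""
    base = dict(
        name="degenerate",
        retardance_mean=0.0,
        retardance_sd=0.0,
        fast_axis_mean=0.0,
        fast_axis_spread=0.0,
        depol_mean=(1.0, 1.0, 1.0),
        depol_sd=0.0,
        diattenuation_mean=0.0,
        diattenuation_sd=0.0,
        diattenuation_axis=0.0,
        m00_mean=0.7,
        m00_sd=0.0,
        depol_dispersion=0.0,
    )
    base.update(overrides)
    return TissueClassSpec(**base)


class TestSamplePixelMatrix:
    def test_degenerate_spec_gives_scaled_identity(self):
        spec = degenerate_spec()
        m = sample_pixel_matrix(spec, spec.reference_wavelength, rng=np.random.default_rng(0))
        assert np.allclose(m, 0.7 * np.eye(4), atol=1e-12)

    def test_degenerate_quarter_wave(self):
        spec = degenerate_spec(retardance_mean=np.pi / 2)
        m = sample_pixel_matrix(spec, spec.reference_wavelength, rng=np.random.default_rng(0))
        assert np.allclose(m, 0.7 * mueller.retarder(np.pi / 2, 0.0), atol=1e-12)

    def test_retardance_scales_inversely_with_wavelength(self):
        spec = degenerate_spec(retardance_mean=1.0)
        rng = np.random.default_rng(0)
        m_500 = sample_pixel_matrix(spec, 500.0, rng=rng)
        expected = spec.m00_mean * mueller.retarder(spec.reference_wavelength / 500.0, 0.0)
        assert np.allclose(m_500, expected, atol=1e-12)

    @pytest.mark.parametrize("spec_fn", [normal_tissue_spec, abnormal_tissue_spec])
    def test_thousand_draws_all_physical(self, spec_fn):
        spec = spec_fn()
        rng = np.random.default_rng(1234)
        for wavelength in (450.0, 625.0):
            for _ in range(500):
                m = sample_pixel_matrix(spec, wavelength, rng=rng)
                ok, diag = mueller.is_physical(m)
                assert ok, diag

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            degenerate_spec(depol_mean=(1.5, 0.0, 0.0))
        with pytest.raises(ValueError):
            degenerate_spec(m00_sd=-0.1)


class TestGenerateCohort:
    def test_study_shape_category_counts(self):
        """The default config mirrors the study: 11 patients, 15 samples, 2 mixed."""
        config = CohortConfig(seed=5, image_shape=(12, 12))
        cohort = generate_cohort(config)
        assert len(cohort.samples) == 15
        assert len(cohort.patient_ids) == 11
        cats = [s.layout.category for s in cohort.samples]
        assert cats.count("mixed") == 2
        assert cats.count("normal") == 7
        assert cats.count("abnormal") == 6
        # samples *containing* each tissue type, as the study tabulates them
        with_normal = sum(1 for s in cohort.samples if (s.region_mask == NORMAL).any())
        with_abnormal = sum(1 for s in cohort.samples if (s.region_mask == ABNORMAL).any())
        assert with_normal == 9
        assert with_abnormal == 8

    def test_mixed_samples_have_both_labels_and_border(self):
        config = CohortConfig(
            n_patients=2, n_samples=2, frac_mixed=1.0, frac_normal=0.0, frac_abnormal=0.0,
            image_shape=(24, 24), seed=3,
        )
        cohort = generate_cohort(config)
        for s in cohort.samples:
            mask = s.layout.label_mask
            assert (mask == NORMAL).any() and (mask == ABNORMAL).any()
            assert (mask == UNLABELED).any()  # border band

    def test_deterministic_under_seed(self):
        config = CohortConfig(n_patients=3, n_samples=4, image_shape=(10, 10), seed=9)
        a = generate_cohort(config)
        b = generate_cohort(config)
        for sa, sb in zip(a.samples, b.samples):
            assert np.array_equal(sa.mm_image.matrices, sb.mm_image.matrices)
            assert np.array_equal(sa.layout.label_mask, sb.layout.label_mask)
        c = generate_cohort(dataclasses.replace(config, seed=10))
        assert not np.array_equal(a.samples[0].mm_image.matrices, c.samples[0].mm_image.matrices)

    def test_intensity_matched_equalizes_m00(self):
        config = CohortConfig(
            n_patients=6, n_samples=8, frac_mixed=1.0, frac_normal=0.0, frac_abnormal=0.0,
            image_shape=(32, 32), intensity_matched=True, seed=21,
        )
        cohort = generate_cohort(config)
        m00 = {NORMAL: [], ABNORMAL: []}
        for s in cohort.samples:
            for code in (NORMAL, ABNORMAL):
                m00[code].append(s.mm_image.matrices[s.region_mask == code][:, :, 0, 0])
        for li in range(len(config.wavelengths)):
            mean_n = np.concatenate([x[:, li] for x in m00[NORMAL]]).mean()
            mean_a = np.concatenate([x[:, li] for x in m00[ABNORMAL]]).mean()
            assert abs(mean_a - mean_n) / mean_n < 0.02

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(frac_mixed=0.5, frac_normal=0.5, frac_abnormal=0.5)

    def test_hotspots_exceed_normal_reflectance(self):
        config = CohortConfig(
            n_patients=2, n_samples=2, image_shape=(32, 32), hotspot_fraction=0.05,
            frac_mixed=1.0, frac_normal=0.0, frac_abnormal=0.0, seed=2,
        )
        cohort = generate_cohort(config)
        m00 = cohort.samples[0].mm_image.matrices[:, :, 0, 0, 0]
        assert m00.max() > 5.0  # boosted far beyond tissue reflectance


class TestSeparabilityDial:
    def test_retardance_contrast_increases_pol_auc(self):
        """More polarimetric contrast between classes -> higher pixel AUC."""
        aucs = []
        for contrast_retardance in (0.6, 0.9, 1.2):  # normal class sits at 0.6
            config = CohortConfig(
                n_patients=4, n_samples=4, frac_mixed=1.0, frac_normal=0.0,
                frac_abnormal=0.0, image_shape=(24, 24), intensity_matched=True, seed=31,
            )
            cohort = generate_cohort(
                config,
                abnormal_spec=abnormal_tissue_spec(retardance_mean=contrast_retardance),
            )
            images = [s.mm_image for s in cohort.samples]
            layouts = [s.layout for s in cohort.samples]
            table = build_feature_table(images, layouts, "pol")
            train = table[table.patient_id.isin(["P00", "P01"])]
            test = table[~table.patient_id.isin(["P00", "P01"])]
            feat = [c for c in table.columns if c.startswith("f")]
            model = PixelMLP(random_state=5).fit(
                train[feat].to_numpy(), train["label"].to_numpy()
            )
            _, auc = roc_auc(model.predict_proba(test[feat].to_numpy())[:, 1], test["label"])
            aucs.append(auc)
        assert aucs[0] < aucs[1] < aucs[2]
        assert aucs[2] > 0.9

    def test_intensity_matched_nopol_features_carry_no_signal(self):
        config = CohortConfig(
            n_patients=4, n_samples=6, frac_mixed=1.0, frac_normal=0.0, frac_abnormal=0.0,
            image_shape=(32, 32), intensity_matched=True, seed=13,
        )
        cohort = generate_cohort(config)
        table = build_feature_table(
            [s.mm_image for s in cohort.samples], [s.layout for s in cohort.samples], "nopol"
        )
        table = table.sample(n=min(5000, len(table)), random_state=0)
        # direct separation probe on the raw intensity features
        score = table[[c for c in table.columns if c.startswith("f")]].mean(axis=1)
        _, auc = roc_auc(score, table["label"])
        assert abs(auc - 0.5) < 0.07


class TestCorruptRegistration:
    def half_and_half(self, width=64, height=16):
        mask = np.full((height, width), NORMAL, dtype=np.uint8)
        mask[:, width // 2 :] = ABNORMAL
        return PhantomLayout("P0", "S0", mask, "mixed")

    def test_zero_shift_is_identity(self):
        layout = self.half_and_half()
        out = corrupt_registration(layout, (0, 0))
        assert np.array_equal(out.label_mask, layout.label_mask)

    def test_flip_fraction_matches_shift(self):
        layout = self.half_and_half(width=64)
        out = corrupt_registration(layout, (5, 0))
        both_labeled = (layout.label_mask != UNLABELED) & (out.label_mask != UNLABELED)
        flipped = both_labeled & (layout.label_mask != out.label_mask)
        # 5 of the 64 labeled columns change tissue code
        assert flipped.sum() / layout.label_mask.shape[0] == 5
        cols_labeled_both = both_labeled.any(axis=0).sum()
        assert flipped.any(axis=0).sum() / cols_labeled_both == pytest.approx(5 / (64 - 5))

    def test_all_normal_stays_normal(self):
        mask = np.full((16, 16), NORMAL, dtype=np.uint8)
        layout = PhantomLayout("P0", "S0", mask, "normal")
        out = corrupt_registration(layout, (4, -3))
        assert not (out.label_mask == ABNORMAL).any()

    def test_shifted_in_pixels_become_unlabeled(self):
        layout = self.half_and_half()
        out = corrupt_registration(layout, (5, 0))
        assert (out.label_mask[:, :5] == UNLABELED).all()

    def test_oversized_shift_rejected(self):
        layout = self.half_and_half(width=16)
        with pytest.raises(ValueError):
            corrupt_registration(layout, (16, 0))


def test_cohort_round_trip(tmp_path, tiny_cohort):
    cohort, _, _ = tiny_cohort
    save_cohort(cohort, tmp_path / "cohort")
    loaded = load_cohort(tmp_path / "cohort")
    assert len(loaded.samples) == len(cohort.samples)
    for a, b in zip(cohort.samples, loaded.samples):
        assert a.layout.patient_id == b.layout.patient_id
        assert np.array_equal(a.layout.label_mask, b.layout.label_mask)
        assert np.allclose(a.mm_image.matrices, b.mm_image.matrices, atol=1e-5)
    assert loaded.config == cohort.config
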