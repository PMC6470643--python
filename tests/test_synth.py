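"""Synthetic cohort generator: determinism, calibration, and class contrasts."""

from __future__ import annotations

import numpy as np
import pytest

from eegfuse.entropy import PEConfig, permutation_entropy
from eegfuse.preprocess import DEFAULT_BANDS
from eegfuse.spectral import WORKING_FS, psd_ar, relative_band_power
from eegfuse.synth import (
    SynthCohortSpec,
    calibrate_band_gains,
    cohort_array,
    generate_cohort,
    read_cohort,
    reduced_cohort_spec,
    write_cohort,
)


class TestSpecValidation:
    @pytest.mark.parametrize(
        "field,kwargs",
        [
            ("n_subjects_per_class", dict(n_subjects_per_class=0)),
            ("fs", dict(fs=-1.0)),
            ("epochs_per_subject", dict(epochs_per_subject=0)),
            ("class_profiles", dict(class_profiles=((0.5, 0.5, 0.0, 0.0, 0.0, 0.0),))),
            ("class_noise_fraction", dict(class_noise_fraction=(0.1, 1.4))),
        ],
    )
    def test_invalid_field_named_in_error(self, field, kwargs):
        with pytest.raises(ValueError, match=field):
            SynthCohortSpec(**kwargs)

    def test_profile_sum_checked(self):
        bad = ((0.9, 0.2, 0.0, 0.0, 0.0, 0.0), (0.5, 0.5, 0.0, 0.0, 0.0, 0.0))
        with pytest.raises(ValueError, match="sum to 1"):
            SynthCohortSpec(class_profiles=bad)


class TestGeneration:
    def test_same_seed_is_bit_identical(self, tiny_cohort):
        spec, recs = tiny_cohort
        again = generate_cohort(spec)
        for a, b in zip(recs, again):
            np.testing.assert_array_equal(a.data, b.data)
            assert a.subject_id == b.subject_id and a.label == b.label

    def test_output_shape_contract(self, tiny_cohort):
        spec, recs = tiny_cohort
        arr = cohort_array(recs, spec.epochs_per_subject)
        assert arr.shape == (
            2 * spec.n_subjects_per_class,
            spec.n_channels,
            spec.epochs_per_subject,
            int(spec.fs * spec.epoch_seconds),
        )

    def test_labels_and_ids(self, tiny_cohort):
        spec, recs = tiny_cohort
        labels = [r.label for r in recs]
        assert labels == [0] * spec.n_subjects_per_class + [1] * spec.n_subjects_per_class
        assert len({r.subject_id for r in recs}) == len(recs)


class TestCalibration:
    def test_realized_fractions_track_requested_weights(self):
        w = np.array([0.8, 0.10, 0.05, 0.03, 0.01, 0.01])
        _, fracs = calibrate_band_gains(w)
        # exactness is limited by resonator power in the inter-band gaps
        assert abs(fracs[0] - w[0]) < 0.06
        assert np.all(np.abs(fracs - w) < 0.06)

    def test_single_band_profile_concentrates_power(self):
        # alpha-only profile: spectral power should sit inside 8-12 Hz (+/- 1 Hz)
        spec = SynthCohortSpec(
            n_subjects_per_class=1,
            n_channels=1,
            fs=WORKING_FS,
            epoch_seconds=60.0,
            epochs_per_subject=1,
            class_profiles=((0.0, 0.0, 1.0, 0.0, 0.0, 0.0),) * 2,
            class_noise_fraction=(0.0, 0.0),
            between_subject_sd=0.0,
            noise_fraction_sd=0.0,
            amplitude_sigma=0.0,
            seed=5,
        )
        rec = generate_cohort(spec)[0]
        psd = psd_ar(rec.data[0], fs=WORKING_FS)
        band = (psd.freqs >= DEFAULT_BANDS["alpha"].f_low - 1.0) & (
            psd.freqs <= DEFAULT_BANDS["alpha"].f_high + 1.0
        )
        frac = np.trapezoid(psd.power[band], psd.freqs[band]) / np.trapezoid(
            psd.power, psd.freqs
        )
        assert frac >= 0.90


class TestClassContrasts:
    def test_delta_weights_order_preserved_on_every_channel(self):
        spec = SynthCohortSpec(
            n_subjects_per_class=6,
            n_channels=3,
            fs=250.0,
            epoch_seconds=12.0,
            epochs_per_subject=1,
            class_profiles=(
                (0.85, 0.06, 0.04, 0.03, 0.01, 0.01),
                (0.60, 0.12, 0.12, 0.10, 0.03, 0.03),
            ),
            class_noise_fraction=(0.05, 0.05),
            between_subject_sd=0.15,
            noise_fraction_sd=0.0,
            amplitude_sigma=0.1,
            seed=17,
        )
        recs = generate_cohort(spec)
        delta = {0: [], 1: []}
        for rec in recs:
            psd = psd_ar(rec.data, fs=250.0)
            delta[rec.label].append(relative_band_power(psd, DEFAULT_BANDS["delta"]))
        d0 = np.mean(delta[0], axis=0)
        d1 = np.mean(delta[1], axis=0)
        assert np.all(d0 > d1)  # per channel

    def test_pe_monotone_in_noise_fraction(self):
        cfg = PEConfig(m=4)
        means = []
        for nu in (0.0, 0.2, 0.6):
            spec = SynthCohortSpec(
                n_subjects_per_class=5,
                n_channels=1,
                fs=250.0,
                epoch_seconds=8.0,
                epochs_per_subject=2,
                class_noise_fraction=(nu, nu),
                between_subject_sd=0.0,
                noise_fraction_sd=0.0,
                amplitude_sigma=0.0,
                seed=23,
            )
            vals = [
                permutation_entropy(chunk, cfg)
                for rec in generate_cohort(spec)
                for chunk in rec.data[0].reshape(spec.epochs_per_subject, -1)
            ]
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_noisier_class_has_higher_pe(self):
        spec = SynthCohortSpec(
            n_subjects_per_class=10,
            n_channels=1,
            fs=250.0,
            epoch_seconds=8.0,
            epochs_per_subject=1,
            class_profiles=(SynthCohortSpec().class_profiles[0],) * 2,
            class_noise_fraction=(0.1, 0.6),
            between_subject_sd=0.1,
            noise_fraction_sd=0.0,
            amplitude_sigma=0.1,
            seed=31,
        )
        cfg = PEConfig(m=4)
        pes = {0: [], 1: []}
        for rec in generate_cohort(spec):
            pes[rec.label].append(permutation_entropy(rec.data[0], cfg))
        assert np.mean(pes[1]) > np.mean(pes[0])


class TestPersistence:
    def test_matrix_cohort_round_trip(self, tmp_path):
        spec = SynthCohortSpec(
            n_subjects_per_class=2,
            n_channels=2,
            fs=250.0,
            epoch_seconds=2.0,
            epochs_per_subject=1,
            seed=3,
        )
        recs = generate_cohort(spec)
        manifest = write_cohort(recs, tmp_path / "cohort")
        back = read_cohort(manifest)
        assert len(back) == len(recs)
        for a, b in zip(recs, back):
            assert a.subject_id == b.subject_id and a.label == b.label
            np.testing.assert_allclose(a.data, b.data, rtol=1e-6)

    def test_reduced_spec_is_valid_and_harder(self):
        spec = reduced_cohort_spec(seed=1)
        assert spec.fs == 250.0
        full = SynthCohortSpec()
        # attenuated contrast relative to the full study conditions
        assert spec.class_profiles[0][0] - spec.class_profiles[1][0] < (
            full.class_profiles[0][0] - full.class_profiles[1][0]
        )
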