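"""Filtering/referencing, blink detection, SSP, epoching, and rejection."""
import numpy as np
import pandas as pd
import pytest
from dataclasses import replace
from scipy import signal

from volmmn import labeling, preprocessing, simulate
from volmmn.preprocessing import PipelineVariant


def _toy_raw(montage, data, sfreq=500.0, onsets_ms=None):
    n = data.shape[1]
    onsets = onsets_ms if onsets_ms is not None else np.array([n / sfreq * 500.0 / 2])
    return simulate.RawRecording(
        data=data,
        ch_names=montage.all_names,
        sfreq=sfreq,
        onsets_ms=np.atleast_1d(onsets),
        tones=np.ones(np.atleast_1d(onsets).size, dtype=np.int8),
        subject=simulate.SubjectRecord(id="t", study=1, group="PLA"),
        montage=montage,
    )


class TestFilterAndReference:
    def test_dc_offset_removed_and_zero_mean(self, montage):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((64, 5000)) + 40.0
        raw = _toy_raw(montage, data)
        out = preprocessing.filter_and_reference(raw, PipelineVariant.main())
        scalp = out.data[:63]
        assert np.abs(scalp.mean(axis=0)).max() < 1e-9
        assert abs(scalp.mean()) < 0.5  # DC removed by the high-pass

    def test_50hz_attenuated_20db(self, montage):
        t = np.arange(20000) / 500.0
        tone = 10.0 * np.sin(2 * np.pi * 50.0 * t)
        data = np.tile(tone, (64, 1))
        # add a distinguishing channel so average reference keeps signal
        data[0] *= 2
        raw = _toy_raw(montage, data)
        out = preprocessing.filter_and_reference(raw, PipelineVariant.main())
        mid = slice(2000, out.n_samples - 2000)
        in_rms = np.sqrt(np.mean((data[0] - data[:63].mean(axis=0)) ** 2))
        out_rms = np.sqrt(np.mean(out.data[0, mid] ** 2))
        assert out_rms < in_rms / 10  # >= 20 dB

    def test_downsampled_to_half(self, montage):
        data = np.random.default_rng(1).standard_normal((64, 4000))
        out = preprocessing.filter_and_reference(_toy_raw(montage, data), PipelineVariant.main())
        assert out.sfreq == 250.0
        assert out.n_samples == 2000

    def test_linked_mastoid_requires_mastoids(self, montage):
        from volmmn.montage import make_montage

        data = np.zeros((64, 1000))
        raw = _toy_raw(montage, data)
        out = preprocessing.filter_and_reference(raw, PipelineVariant.control())
        assert out.sfreq == 250.0
        # a montage without mastoids cannot even be built
        with pytest.raises(ValueError):
            make_montage(drop=("TP9",))


class TestVeogAndBlinks:
    def test_identical_channels_zero_trace(self, montage):
        data = np.zeros((64, 1000))
        data[montage.index("Fp1")] = 3.0
        data[63] = 3.0  # EOG
        veog = preprocessing.compute_veog(_toy_raw(montage, data))
        assert np.allclose(veog, 0.0)

    def test_blink_arithmetic(self, montage):
        data = np.zeros((64, 1000))
        data[montage.index("Fp1"), 500] = 80.0
        data[63, 500] = -40.0
        veog = preprocessing.compute_veog(_toy_raw(montage, data))
        assert veog[500] == pytest.approx(120.0)

    def test_no_events_on_zero_trace(self):
        assert preprocessing.detect_blinks(np.zeros(1000), 250.0).size == 0

    def test_injected_blinks_counted(self):
        rng = np.random.default_rng(2)
        veog = rng.standard_normal(250 * 60)
        where = np.arange(10) * 1500 + 400
        for w in where:
            veog[w : w + 50] += 60.0
        events = preprocessing.detect_blinks(veog, 250.0)
        assert events.size == 10

    def test_pathological_threshold_warns(self):
        rng = np.random.default_rng(3)
        with pytest.warns(UserWarning, match="pathologically low"):
            preprocessing.detect_blinks(rng.standard_normal(25000), 250.0, threshold_sd=0.1)

    def test_blink_free_noise_below_threshold(self, montage):
        rng = np.random.default_rng(4)
        data = rng.standard_normal((64, 25000))
        veog = preprocessing.compute_veog(_toy_raw(montage, data))
        assert preprocessing.detect_blinks(veog, 500.0).size == 0


class TestSSP:
    def test_rank1_blink_annihilated(self, montage):
        rng = np.random.default_rng(5)
        topo = simulate.blink_topography(montage)[:63]
        wave = np.zeros(5000)
        for s in (500, 1500, 2500, 3500):
            wave[s : s + 100] = 50.0 * np.hanning(100)
        data = np.zeros((64, 5000))
        data[:63] = np.outer(topo, wave)
        data[63] = -1.5 * wave
        raw = _toy_raw(montage, data)
        events = np.array([550, 1550, 2550, 3550])
        proj = preprocessing.compute_ssp(raw, events)
        cleaned = proj.apply(data[:63])
        assert np.abs(cleaned).max() < 1e-9

    def test_projector_idempotent_symmetric_rank(self, short_recording):
        _, raw = short_recording
        filt = preprocessing.filter_and_reference(raw, PipelineVariant.main())
        events = preprocessing.detect_blinks(preprocessing.compute_veog(filt), filt.sfreq)
        proj = preprocessing.compute_ssp(filt, events)
        P = proj.matrix
        assert np.abs(P @ P - P).max() < 1e-12
        assert np.abs(P - P.T).max() < 1e-12
        assert np.linalg.matrix_rank(P) == 63 - proj.rank

    def test_no_blink_epochs_raises(self, montage):
        raw = _toy_raw(montage, np.zeros((64, 1000)))
        with pytest.raises(ValueError, match="blink"):
            preprocessing.compute_ssp(raw, np.array([], dtype=int))

    def test_blink_field_suppression_and_erp_preservation(self, short_params):
        """With default settings the projector removes >= 90% of the blink
        field's variance while distorting the evoked template by <= 10% RMS."""
        from volmmn import paradigm

        sched = paradigm.build_schedule(short_params, seed=3)
        seq = paradigm.generate_sequence(sched, seed=3)
        subj = simulate.SubjectRecord(id="s1", study=1, group="PLA")
        noise = simulate.NoiseSpec()
        raw = simulate.simulate_recording(seq, subj, noise=noise, seed=5)
        quiet = simulate.simulate_recording(
            seq, subj, noise=replace(noise, blink_rate_per_min=0.0), seed=5
        )
        variant = PipelineVariant.main()
        filt = preprocessing.filter_and_reference(raw, variant)
        filt_quiet = preprocessing.filter_and_reference(quiet, variant)
        blink_field = filt.data[:63] - filt_quiet.data[:63]

        events = preprocessing.detect_blinks(preprocessing.compute_veog(filt), filt.sfreq)
        proj = preprocessing.compute_ssp(filt, events)

        resid = proj.apply(blink_field)
        assert 1 - resid.var() / blink_field.var() >= 0.90

        erp_clean = preprocessing.filter_and_reference(
            simulate.simulate_recording(seq, subj, noise=simulate.NOISELESS, seed=5),
            variant,
        ).data[:63]
        erp_proj = proj.apply(erp_clean)
        rms = np.sqrt(np.mean(erp_clean**2))
        assert np.sqrt(np.mean((erp_proj - erp_clean) ** 2)) <= 0.10 * rms


class TestEpochAndReject:
    def _clean_raw(self, montage, n_trials=10):
        sf = 500.0
        soa = 570.0
        n = int((n_trials * soa / 1000 + 2) * sf)
        data = np.zeros((64, n))
        onsets = 1000.0 + np.arange(n_trials) * soa
        return _toy_raw(montage, data, onsets_ms=onsets), onsets

    def test_spike_trial_removed(self, montage):
        raw, onsets = self._clean_raw(montage)
        s = int(round((onsets[3] + 50) / 1000 * raw.sfreq))
        raw.data[10, s] = 100.0
        ep = preprocessing.epoch_and_reject(raw, PipelineVariant.main())
        assert ep.rejected.sum() == 1 and ep.rejected[3]
        assert ep.n_trials == 9

    def test_clean_data_all_retained(self, montage):
        raw, _ = self._clean_raw(montage)
        ep = preprocessing.epoch_and_reject(raw, PipelineVariant.main())
        assert ep.n_trials == 10
        assert ep.times_ms[0] == -100.0 and ep.times_ms[-1] == 400.0

    def test_baseline_zeroes_prestim(self, montage):
        raw, _ = self._clean_raw(montage)
        raw.data[:, :] = 7.5  # constant offset
        ep = preprocessing.epoch_and_reject(raw, PipelineVariant.control())
        pre = ep.times_ms < 0
        assert np.abs(ep.data[:, :, pre].mean(axis=2)).max() < 1e-12

    def test_metadata_alignment_under_rejection(self, montage):
        raw, onsets = self._clean_raw(montage)
        s = int(round(onsets[5] / 1000 * raw.sfreq))
        raw.data[0, s] = 200.0
        meta = pd.DataFrame({"trial": np.arange(10), "tag": list("abcdefghij")})
        ep = preprocessing.epoch_and_reject(raw, PipelineVariant.main(), metadata=meta)
        assert ep.metadata["tag"].tolist() == list("abcdeghij")
        assert ep.n_trials + ep.rejected.sum() == 10

    def test_event_outside_recording_raises(self, montage):
        data = np.zeros((64, 100))
        raw = _toy_raw(montage, data, onsets_ms=np.array([10.0]))
        with pytest.raises(ValueError, match="outside"):
            preprocessing.epoch_and_reject(raw, PipelineVariant.main())

    def test_retained_fraction_on_default_subject(self, short_recording):
        """On the default synthetic subject the retained fraction matches the
        expected high yield (here: >= 94% of trials)."""
        seq, raw = short_recording
        table = labeling.label_trials_init(seq).frame
        epochs, _ = preprocessing.preprocess(raw, metadata=table)
        assert epochs.n_trials >= 0.94 * seq.n_trials


def test_brainvision_roundtrip(tmp_path, short_recording):
    """The BrainVision writer produces files MNE reads back verbatim."""
    mne = pytest.importorskip("mne")
    _, raw = short_recording
    vhdr = __import__("volmmn.io", fromlist=["io"]).write_brainvision(raw, tmp_path / "rec")
    back = mne.io.read_raw_brainvision(vhdr, preload=True, verbose="error")
    assert back.info["sfreq"] == raw.sfreq
    assert back.ch_names == list(raw.ch_names)
    np.testing.assert_allclose(back.get_data() * 1e6, raw.data, rtol=0, atol=1e-3)
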