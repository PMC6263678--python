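"""Domain types, WAV reading, CSV round-trips, length summaries, splits."""

import numpy as np
import pytest
from scipy.io import wavfile

from barkline import (
    FormatError,
    IntensitySequence,
    LabeledDataset,
    ValidationError,
    Waveform,
    read_intensity_csv,
    read_wav,
    split_dataset,
    summarize_lengths,
    write_intensity_csv,
    write_wav,
)


class TestWaveform:
    def test_duration_follows_header_rate(self, tmp_path):
        # a 5327-sample mono 16-bit clip at 22,050 Hz lasts 0.24 s
        pcm = np.zeros(5327, dtype=np.int16)
        wavfile.write(tmp_path / "clip.wav", 22050, pcm)
        wave = read_wav(tmp_path / "clip.wav")
        assert wave.sample_rate == 22050
        assert len(wave) == 5327
        assert round(wave.duration_seconds, 2) == 0.24

    def test_silence_reads_as_zeros(self, tmp_path):
        wavfile.write(tmp_path / "z.wav", 8000, np.zeros(100, dtype=np.int16))
        wave = read_wav(tmp_path / "z.wav")
        assert len(wave) == 100
        assert np.all(wave.samples == 0.0)

    def test_stereo_averaged_to_mono(self, tmp_path):
        left = np.full(50, 0.5)
        right = np.full(50, -0.5)
        pcm = np.round(np.stack([left, right], axis=1) * 32767).astype(np.int16)
        wavfile.write(tmp_path / "st.wav", 8000, pcm)
        wave = read_wav(tmp_path / "st.wav")
        assert wave.samples.ndim == 1
        assert np.allclose(wave.samples, 0.0, atol=1e-4)

    def test_non_wav_raises_format_error(self, tmp_path):
        bad = tmp_path / "not_audio.wav"
        bad.write_bytes(b"this is not a RIFF file")
        with pytest.raises(FormatError, match="not_audio"):
            read_wav(bad)

    def test_write_read_roundtrip_within_one_lsb(self, tmp_path, rng):
        samples = rng.uniform(-1, 1, size=500)
        wave = Waveform(samples, 22050, "rt")
        back = read_wav(write_wav(wave, tmp_path / "rt.wav"))
        assert np.abs(back.samples - samples).max() <= 1.0 / 32768

    def test_amplitude_range_enforced(self):
        with pytest.raises(ValidationError):
            Waveform(np.array([0.0, 1.5]), 8000)


class TestIntensitySequence:
    def test_volt_range_enforced(self):
        with pytest.raises(ValidationError):
            IntensitySequence(np.array([1.0, 5.5]))

    def test_unknown_label_rejected(self):
        with pytest.raises(ValidationError):
            IntensitySequence(np.array([1.0]), label="mooing")


class TestIntensityCsv:
    def test_packaged_example_shape(self, example_ds):
        assert len(example_ds) == 4
        assert sorted(s.label for s in example_ds) == [
            "barking", "growling", "howling", "whining"]
        assert all(len(s) == 64 for s in example_ds)
        bark = next(s for s in example_ds if s.label == "barking")
        assert bark.values[0] == pytest.approx(4.82)
        assert bark.values[15] == pytest.approx(2.38)

    def test_roundtrip_is_lossless(self, tmp_path, example_ds):
        path = write_intensity_csv(example_ds, tmp_path / "ds.csv")
        back = read_intensity_csv(path)
        assert len(back) == len(example_ds)
        for a, b in zip(example_ds, back):
            assert a.event_id == b.event_id
            assert a.label == b.label
            assert np.array_equal(a.values, b.values)

    def test_synthetic_roundtrip_preserves_counts(self, tmp_path, small_synth_ds):
        path = write_intensity_csv(small_synth_ds, tmp_path / "s.csv")
        back = read_intensity_csv(path)
        assert back.class_counts() == small_synth_ds.class_counts()
        assert back.total_values() == small_synth_ds.total_values()

    def test_header_only_file_gives_empty_dataset(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("event_id,label,index,volts\n")
        assert len(read_intensity_csv(p)) == 0

    def test_out_of_range_value_rejected_with_row(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("event_id,label,index,volts\ne1,barking,0,5.5\n")
        with pytest.raises(ValidationError, match="row 2"):
            read_intensity_csv(p)

    def test_wide_dialect_accepted_on_read(self, tmp_path):
        p = tmp_path / "wide.csv"
        p.write_text("event_id,label,values\n"
                     "e1,barking,1.0,2.0,3.0\n"
                     "e2,whining,0.5,0.25\n")
        ds = read_intensity_csv(p)
        assert [len(s) for s in ds] == [3, 2]

    def test_empty_dataset_refused_on_write(self, tmp_path):
        with pytest.raises(ValidationError):
            write_intensity_csv(LabeledDataset([]), tmp_path / "e.csv")


class TestLengthSummary:
    def test_order_statistics(self):
        seqs = [IntensitySequence(np.ones(n), label="barking",
                                  event_id=f"b{n}{i}")
                for i, n in enumerate([5, 47, 19, 19])]
        summary = summarize_lengths(LabeledDataset(seqs))
        stats = summary.per_class["barking"]
        assert (stats.minimum, stats.maximum) == (5, 47)
        assert stats.mean == pytest.approx(22.5)
        assert stats.median == pytest.approx(19)

    def test_single_event_collapses_stats(self):
        ds = LabeledDataset([IntensitySequence(np.ones(64), label="howling")])
        stats = summarize_lengths(ds).per_class["howling"]
        assert stats.minimum == stats.maximum == stats.mean == stats.median == 64

    def test_absent_class_marked_none(self):
        ds = LabeledDataset([IntensitySequence(np.ones(3), label="howling")])
        assert summarize_lengths(ds).per_class["whining"] is None


class TestSplit:
    def test_70_30_split_of_1200_events(self, tmp_path):
        seqs = [IntensitySequence(np.ones(4), label=lab, event_id=f"{lab}{i}")
                for lab in ("barking", "growling", "howling", "whining")
                for i in range(300)]
        ds = LabeledDataset(seqs)
        train, test = split_dataset(ds, 0.7, seed=17)
        assert (len(train), len(test)) == (840, 360)
        assert set(train.class_counts().values()) == {210}
        assert set(test.class_counts().values()) == {90}

    def test_split_partitions_dataset(self, small_synth_ds):
        train, test = split_dataset(small_synth_ds, 0.7, seed=5)
        ids_train = {s.event_id for s in train}
        ids_test = {s.event_id for s in test}
        assert not ids_train & ids_test
        assert len(ids_train | ids_test) == len(small_synth_ds)

    def test_split_deterministic_given_seed(self, small_synth_ds):
        t1, _ = split_dataset(small_synth_ds, 0.7, seed=9)
        t2, _ = split_dataset(small_synth_ds, 0.7, seed=9)
        assert [s.event_id for s in t1] == [s.event_id for s in t2]

    def test_half_split_of_two_events(self):
        ds = LabeledDataset([
            IntensitySequence(np.ones(3), label="barking", event_id="a"),
            IntensitySequence(np.ones(3), label="barking", event_id="b")])
        train, test = split_dataset(ds, 0.5, seed=0)
        assert len(train) == len(test) == 1

    def test_singleton_class_cannot_stratify(self):
        ds = LabeledDataset([IntensitySequence(np.ones(3), label="barking")])
        with pytest.raises(ValidationError, match="stratify"):
            split_dataset(ds, 0.7, seed=0)


def test_read_24bit_pcm_wav(tmp_path):
    # 24-bit PCM: three little-endian bytes per sample
    import struct
    values = [0, 1 << 22, -(1 << 22), (1 << 23) - 1]
    data = b"".join(struct.pack("<i", v)[:3] for v in values)
    hdr = (b"RIFF" + struct.pack("<I", 36 + len(data)) + b"WAVEfmt " +
           struct.pack("<IHHIIHH", 16, 1, 1, 8000, 8000 * 3, 3, 24) +
           b"data" + struct.pack("<I", len(data)))
    path = tmp_path / "t24.wav"
    path.write_bytes(hdr + data)
    wave = read_wav(path)
    assert wave.sample_rate == 8000
    assert np.allclose(wave.samples, [0.0, 0.5, -0.5, 1.0], atol=1e-6)
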