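"""Ground-truth fidelity and determinism of the synthetic generator."""

import numpy as np
import pytest

import woodstrid as ws
from woodstrid.audio_io import STUDY_DISTANCES_CM
from woodstrid.segmentation import SegmentInterval


class TestGenerateRecording:
    def test_source_level_without_propagation(self, default_profile):
        """At negligible distance without noise, measured band power sits
        at the configured source level within 0.5 dB."""
        scen = ws.PropagationScenario(alpha_slope_per_khz_cm=0.0)
        rec, truth = ws.generate_recording(
            default_profile, scen, z=1e-9, duration_s=5.0, seed=0, noise=False
        )
        base_rms = 0.05  # generator full-scale convention
        for chirp in truth:
            x = rec.samples[chirp.start_sample : chirp.end_sample]
            level = 20 * np.log10(np.sqrt(np.mean(x**2)) / base_rms)
            assert level == pytest.approx(
                default_profile.source_level_db, abs=0.5
            )

    def test_bandwidth_constant_without_compression(self, default_profile):
        scen = ws.PropagationScenario(alpha_slope_per_khz_cm=0.0)
        bws = {}
        for z in (5.0, 60.0):
            rec, truth = ws.generate_recording(
                default_profile, scen, z, duration_s=5.0, seed=13, noise=False
            )
            spec = ws.compute_spectrogram(rec)
            seg = SegmentInterval(
                truth[0].start_frame, truth[0].end_frame, 0.0, 1.0
            )
            from woodstrid.features import mean_segment_spectrum

            bw, _ = ws.bandwidth_3db(mean_segment_spectrum(spec, seg))
            bws[z] = bw
        assert bws[60.0] == pytest.approx(bws[5.0], rel=0.15)

    def test_bandwidth_compresses_with_default_slope(self, default_profile):
        """Default compression shrinks the -3 dB bandwidth ~40% by 60 cm."""
        from woodstrid.features import mean_segment_spectrum

        scen = ws.PropagationScenario()
        bws = {}
        for z in (5.0, 60.0):
            rec, truth = ws.generate_recording(
                default_profile, scen, z, duration_s=5.0, seed=13, noise=False
            )
            spec = ws.compute_spectrogram(rec)
            med = []
            for c in truth:
                seg = SegmentInterval(c.start_frame, c.end_frame, 0.0, 1.0)
                med.append(ws.bandwidth_3db(mean_segment_spectrum(spec, seg))[0])
            bws[z] = np.median(med)
        shrink = 1 - bws[60.0] / bws[5.0]
        assert 0.25 <= shrink <= 0.55

    def test_band_above_nyquist_rejected(self):
        prof = ws.SpeciesProfile(name="x", band_center_hz=21500.0,
                                 band_halfwidth_hz=1500.0)
        with pytest.raises(ValueError, match="Nyquist"):
            ws.generate_recording(prof, ws.PropagationScenario(), 5.0, 2.0, 0)

    def test_bit_identical_regeneration(self, default_profile):
        scen = ws.PropagationScenario()
        a, ta = ws.generate_recording(default_profile, scen, 10.0, 3.0, seed=42)
        b, tb = ws.generate_recording(default_profile, scen, 10.0, 3.0, seed=42)
        assert np.array_equal(a.samples, b.samples)
        assert ta == tb

    def test_end_to_end_attenuation_recovery(self, default_profile):
        """Mean segment power vs distance refits the generating decay
        parameters (compression off isolates the decay chain)."""
        scen = ws.PropagationScenario(
            psi_db=18.604, alpha_base=0.211, c_db=24.998,
            alpha_slope_per_khz_cm=0.0,
        )
        obs = []
        for z in STUDY_DISTANCES_CM:
            rec, truth = ws.generate_recording(
                default_profile, scen, float(z), duration_s=6.0,
                seed=100 + z, noise=False,
            )
            spec = ws.compute_spectrogram(rec)
            powers = []
            for c in truth:
                cols = spec.power[:, c.start_frame : c.end_frame]
                powers.append(cols.mean())
            # dB relative to the z=0 chirp power implied by the model
            obs.append((float(z), 10 * np.log10(np.mean(powers))))
        p0 = obs[0][1] - (ws.predict_power(scen.model, obs[0][0])
                          - ws.predict_power(scen.model, 0.0))
        decay = [
            ws.PowerDecayObservation(z, p - p0 + (scen.psi_db - scen.c_db))
            for z, p in obs
        ]
        fit = ws.fit_exponential_decay(decay)
        assert fit.alpha == pytest.approx(scen.alpha_base, rel=0.10)
        assert fit.psi == pytest.approx(scen.psi_db, rel=0.10)
        assert fit.c == pytest.approx(scen.c_db, rel=0.10)


class TestDecaySeries:
    def test_noiseless_series_is_exact_model_curve(self):
        scen = ws.PropagationScenario()
        obs = ws.generate_decay_series(scen)
        for o in obs:
            assert o.power_dbfs == pytest.approx(
                ws.predict_power(scen.model, o.distance_cm)
            )

    def test_noise_floor_reached_at_100cm(self):
        # H. ater / bark / 0.33: psi 18.139, alpha 0.234, c 25.118
        scen = ws.PropagationScenario(
            tissue=ws.Tissue.BARK, width_cm=0.33,
            psi_db=18.139, alpha_base=0.234, c_db=25.118,
        )
        obs = {o.distance_cm: o.power_dbfs for o in ws.generate_decay_series(scen)}
        assert obs[100] == pytest.approx(-25.118, abs=1e-6)

    def test_fixed_seed_reproducible(self):
        scen = ws.PropagationScenario()
        a = ws.generate_decay_series(scen, noise_sd_db=0.3, n_replicates=3, seed=5)
        b = ws.generate_decay_series(scen, noise_sd_db=0.3, n_replicates=3, seed=5)
        assert a == b


class TestFeatureBenchmark:
    def test_schedule_shape_and_labels(self):
        tables = ws.generate_feature_benchmark(n_per_species=50, seed=0)
        assert set(tables) == set(ws.DEFAULT_SEPARATION_SCHEDULE)
        for t in tables.values():
            assert sorted(t.data["species"].unique()) == ["H_ater", "H_ligniperda"]
            assert len(t.data) == 100

    def test_separation_matches_schedule(self):
        tables = ws.generate_feature_benchmark(
            separation_schedule={5.0: 6.0, 60.0: 0.0},
            n_per_species=2000,
            seed=1,
        )
        for z, d in ((5.0, 6.0), (60.0, 0.0)):
            df = tables[z].data
            a = df[df.species == "H_ligniperda"].iloc[:, 2:].to_numpy()
            b = df[df.species == "H_ater"].iloc[:, 2:].to_numpy()
            sep = np.linalg.norm(a.mean(axis=0) - b.mean(axis=0))
            assert sep == pytest.approx(d, abs=0.25)

    def test_regeneration_identical(self):
        a = ws.generate_feature_benchmark(n_per_species=20, seed=3)
        b = ws.generate_feature_benchmark(n_per_species=20, seed=3)
        for z in a:
            assert a[z].data.equals(b[z].data)


class TestDataset:
    def test_dataset_covers_design_with_truth(self):
        ds = ws.generate_dataset(
            distances_cm=(5.0, 20.0), n_subjects=1, duration_s=2.0, seed=0
        )
        assert len(ds.recordings) == 4  # 2 species x 1 subject x 2 distances
        assert len(ds.truth) == 4
        for rec, t in zip(ds.recordings, ds.truth):
            assert rec.meta.species == t["species"]
            assert t["chirps"]

    def test_dataset_bit_identical(self):
        kw = dict(distances_cm=(5.0,), n_subjects=1, duration_s=2.0, seed=9)
        a = ws.generate_dataset(**kw)
        b = ws.generate_dataset(**kw)
        for ra, rb in zip(a.recordings, b.recordings):
            assert np.array_equal(ra.samples, rb.samples)
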