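"""Synthesize a stridulation recording and segment the calls back out.

Generates a 6 s train of band-limited chirps at 5 cm from the source,
runs the spectrogram-energy threshold segmenter, and compares the
detected call boundaries against the generator's ground truth.
"""

import woodstrid as ws

profile = ws.DEFAULT_PROFILES["H_ligniperda"]
scenario = ws.PropagationScenario(
    tissue=ws.Tissue.BARK, width_cm=0.84,
    psi_db=7.560, alpha_base=0.096, c_db=25.274,
)

rec, truth = ws.generate_recording(profile, scenario, z=5.0,
                                   duration_s=6.0, seed=1)
spec = ws.compute_spectrogram(rec)
segments = ws.segment_stridulations(ws.energy_envelope(spec))

print(f"ground-truth chirps: {len(truth)}, detected: {len(segments)}")
for seg, chirp in zip(segments, truth):
    print(
        f"  detected frames [{seg.start_frame:4d}, {seg.end_frame:4d})"
        f"  truth [{chirp.start_frame:4d}, {chirp.end_frame:4d})"
        f"  duration {ws.duration(seg) * 1000:.1f} ms"
    )
# Matching counts and near-identical frame boundaries show the
# mean-energy threshold recovers each call at high SNR.
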