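"""Distance-wise power decay in 2 kHz frequency bands.

Synthesizes recordings of one species at three distances, estimates
Welch power spectral densities, and tabulates the mean power per 2 kHz
band in dB full scale.  The band containing the emitted energy
(4-6 kHz) decays with distance; empty bands sit at the noise floor.
"""

import woodstrid as ws

profile = ws.DEFAULT_PROFILES["H_ligniperda"]
scenario = ws.PropagationScenario()

psds = []
for z in (5.0, 20.0, 60.0):
    meta = ws.RecordingMetadata(
        species=profile.name, distance_cm=z,
        tissue=scenario.tissue, tissue_width_cm=scenario.width_cm,
    )
    rec, _ = ws.generate_recording(profile, scenario, z,
                                   duration_s=5.0, seed=2, meta=meta)
    psds.append((meta, ws.compute_psd_welch(rec)))

table = ws.band_power_decay(psds)
df = table.to_frame()
pivot = df.pivot(index=["band_low_hz", "band_high_hz"],
                 columns="distance_cm", values="mean_power_dbfs")
print(pivot.round(1).to_string())
# Each cell is the linear-mean band power in dBFS (0 dBFS = loudest
# observed power).  Cells fall with distance in every band carrying
# signal; the 4-6 kHz band stays detectable the farthest.
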