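"""Time-frequency cross-correlation between calcium and EEG band energy.

Builds the band x lag Spearman heatmap (500-ms TFROIs on a 250-ms grid,
calcium slow-band energy over the 4-s search window) for a recording in
which every spindle triggers a calcium transient exactly 1 s later, and
locates the map's peak.
"""

import numpy as np

import spindleca as sc

TF_BANDS = {k: v for k, v in sc.DEFAULT_EEG_BANDS.items() if k != "so"}

cfg = sc.SimConfig(
    seed=3, duration_s=1800, coupling_strength=1.0,
    coupling_lag_s=(1.0, 1.0), ca_transient_duration_s=(1.5, 2.0),
    spindle_duration_s=(1.5, 2.0), ca_transient_rate_per_min=0.5,
)
rec = sc.simulate_recording(cfg)

hm = sc.tf_heatmap(
    rec.eeg, rec.ca, TF_BANDS, eeg_channel="EEG-FP",
    h=rec.hypnogram, states=sc.SWS_STATES,
)
band, lag, rho = hm.peak()
print(f"map peak: band = {band}, lag = {lag:+.2f} s, rho = {rho:.3f}")
print(f"(negative lag: the EEG event precedes the calcium event)")

print("\nsigma row of the heatmap (lag in s -> Spearman rho):")
row = hm.rho.loc["sigma"]
for lag_s in (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0):
    print(f"  {lag_s:+.2f}: {row[lag_s]:+.3f}")
# The peak sits in the spindle-locked sigma-beta rows at -1 s (to within
# one 0.25-s grid step), recovering the planted spindle-to-transient delay.
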