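"""Behavioural episodes and within-episode PD dynamics (thirds / dPD).

Detects WAKE / SWS / REM episodes (>= 13 epochs, <= 30% interruption),
splits each episode into thirds of normalised duration and reports the
calcium PD change dPD = PD(3rd) - PD(1st) per pooled state.
"""

import spindleca as sc

rec = sc.simulate_recording(sc.SimConfig(seed=1, duration_s=7200))
episodes = sc.detect_episodes(rec.hypnogram)
print(f"found {len(episodes)} episodes:")
print(episodes.to_frame().groupby("state").agg(
    n=("state", "size"), mean_s=("n_epochs", lambda s: 4 * s.mean())
).round(1))

ca = sc.epoch_band_power(rec.ca, {"ca": sc.CA_BAND}, channels=["CA"])
ca_norm = sc.normalize_to_state_mean(ca, rec.hypnogram)
thirds = sc.episode_thirds(ca_norm.power("CA", "ca").to_numpy(), episodes)

print("\nmean dPD (3rd - 1st third of normalised calcium PD) per state:")
for state in ("WAKE", "SWS", "REM"):
    sel = thirds.per_episode[thirds.per_episode["state"] == state]
    if len(sel):
        print(f"  {state}: {sel['delta_pd'].mean():+.3f}  (n = {len(sel)} episodes)")
# With spindles driving calcium transients, SWS episodes accumulate sigma
# activity towards the transition and dPD for calcium tends positive.
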