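"""From raw ABR sweeps to wave features.

Simulates 2400 single sweeps containing planted wave I (1.8 ms, 0.10 µV)
and wave V (6.05 ms, 0.23 µV) complexes in 2 µV noise with 5% large
artifacts, then runs the analysis chain: reject sweeps exceeding 23.8 µV,
average, bandpass 100-3000 Hz (zero phase), and pick peaks in the
1.3-2.3 ms and 5.1-6.4 ms windows. (At the default 5 µV single-sweep
noise the averaged noise floor ~0.05 µV rivals wave I itself, as it can
in real recordings; 2 µV keeps both waves clearly resolvable here.)
"""

from abrcog import EpochParams, generate_epoch_set, reject_artifacts, average_and_filter, extract_features

params = EpochParams(
    waves=((1.8, 0.10, 0.3), (6.05, 0.23, 0.5)),
    noise_sd=2.0, artifact_rate=0.05, n_sweeps=2400, seed=7,
)
epochs = generate_epoch_set(params)
kept = reject_artifacts(epochs)
print(f"sweeps: {epochs.n_sweeps}, rejected as artifacts: {int((~kept.accepted_mask).sum())} "
      f"(generator planted {int(epochs.meta['artifact_mask'].sum())})")

waveform = average_and_filter(kept)
features = extract_features(waveform)
print(f"wave I : latency {features.wave_i_latency:.2f} ms, amplitude {features.wave_i_amplitude:.3f} uV")
print(f"wave V : latency {features.wave_v_latency:.2f} ms, amplitude {features.wave_v_amplitude:.3f} uV")
print(f"I-V latency difference: {features.iv_latency_difference:.2f} ms; "
      f"log V/I ratio: {features.log_vi_amplitude_ratio:.2f}; QC: {features.qc_flags}")
print("planted wave V was 6.05 ms / 0.23 uV; the residual averaged noise "
      "(~0.02 uV) explains the remaining wobble")
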