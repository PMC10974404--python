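"""Synthesize one noisy eight-channel PPG record and denoise a channel.

Prints the estimated cardiac frequency against the ground truth and the
per-channel AC/DC read-out against the generator's closed-form values.
"""

import numpy as np

from hemoppg import (
    NoiseConfig,
    PhysioState,
    Signal1D,
    estimate_period,
    generate_ppg,
    lowpass_filter,
    modulation_depth,
    record_perfusions,
    remove_baseline,
)
from hemoppg.optics import OpticalConfig

state = PhysioState(hb_total=13.5, spo2=0.96, heart_rate=68.0)
optics = OpticalConfig()
ppg = generate_ppg(state, optics, NoiseConfig(), duration=120.0, seed=7)
print(f"record: {ppg.n_samples} samples x {ppg.channels.shape[1]} channels "
      f"at {ppg.fs:g} Hz")

channel = Signal1D(ppg.channels[:, 0], ppg.fs)
denoised = remove_baseline(lowpass_filter(channel))
period, f0 = estimate_period(denoised)
print(f"estimated pulse: {f0:.3f} Hz ({60 * f0:.1f} bpm), "
      f"true heart rate {state.heart_rate:.1f} bpm")

r_hat = record_perfusions(ppg)
r_true = modulation_depth(state, optics)
print("\nchannel   AC/DC extracted   AC/DC true   error")
for wl, rh, rt in zip(ppg.wavelengths, r_hat, r_true):
    print(f"{int(wl):>6} nm   {rh:.5f}          {rt:.5f}      {100*(rh/rt-1):+5.1f}%")
print("\nThe small common positive bias comes from defining DC as the mean of "
      "the low-pass signal (which still carries the pulse); being common to "
      "all channels it cancels in the ratio features.")
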