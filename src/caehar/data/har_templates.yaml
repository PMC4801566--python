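# Default synthetic activity templates.
#
# Each activity class is a quasi-periodic signal: a class-specific DC offset
# pattern across the 45 channels, plus a sinusoid at a class-specific
# frequency, plus Gaussian noise, clamped to the physical sensor ranges.
#
# The offset pattern across channels is a rank-3 mixture: three fixed channel
# basis functions (sin(2*pi*ch/45), cos(2*pi*ch/45), sin(4*pi*ch/45)) mixed
# with the per-activity weights below and scaled per sensor type.  This keeps
# the cross-channel mean structure exactly rank 3 while giving every class a
# distinct signature.
#
# Frequencies are multiples of the 0.2 Hz DFT bin width of a 125-sample
# window at 25 Hz, so each class drives one exact frequency bin; all are
# below the 12.5 Hz Nyquist limit.

sensor_ranges:         # clamp limits per sensor type
  acc: 49.0333         # +-5 g, g = 9.806665 m/s^2
  gyro: 1200.0         # deg/s
  mag: 75.0            # microtesla

sensor_amplitude:      # sinusoid amplitude per sensor type
  acc: 6.0
  gyro: 150.0
  mag: 12.0

sensor_offset_scale:   # scale of the DC offset pattern per sensor type
  acc: 12.0
  gyro: 300.0
  mag: 30.0

noise_fraction: 0.05   # noise sd as a fraction of the channel amplitude
phase_jitter_sd: 0.1   # per-channel phase jitter (radians)

frequencies_hz: [0.4, 1.0, 1.6, 2.2, 2.8, 3.4, 4.0, 4.6, 5.2, 5.8,
                 6.4, 7.0, 7.6, 8.2, 8.8, 9.4, 10.0, 10.6, 11.2]

# per-activity multiplier on the sinusoid amplitude (drives the deviation,
# FFT-peak and cepstrum features apart between classes)
amp_scales: [0.5, 0.6, 0.7, 0.8, 0.9, 1.0, 1.1, 1.2, 1.3, 1.4,
             1.5, 1.6, 1.7, 1.8, 1.9, 2.0, 2.1, 2.2, 2.3]

# per-activity phase lag between successive axes of a sensor triad
# (radians); the inter-axis correlation of a lag d is ~cos(d)
phase_lags: [0.0, 0.1745, 0.3491, 0.5236, 0.6981, 0.8727, 1.0472, 1.2217,
             1.3963, 1.5708, 1.7453, 1.9199, 2.0944, 2.2689, 2.4435,
             2.618, 2.7925, 2.9671, 3.1416]

offset_weights:        # one [w1, w2, w3] triple per activity class
  - [1.0, 0.0, 1.0]
  - [0.9458, 0.3247, 0.7891]
  - [0.7891, 0.6142, 0.2455]
  - [0.5469, 0.8372, -0.4017]
  - [0.2455, 0.9694, -0.8795]
  - [-0.0826, 0.9966, -0.9864]
  - [-0.4017, 0.9158, -0.6773]
  - [-0.6773, 0.7357, -0.0826]
  - [-0.8795, 0.4759, 0.5469]
  - [-0.9864, 0.1646, 0.9458]
  - [-0.9864, -0.1646, 0.9458]
  - [-0.8795, -0.4759, 0.5469]
  - [-0.6773, -0.7357, -0.0826]
  - [-0.4017, -0.9158, -0.6773]
  - [-0.0826, -0.9966, -0.9864]
  - [0.2455, -0.9694, -0.8795]
  - [0.5469, -0.8372, -0.4017]
  - [0.7891, -0.6142, 0.2455]
  - [0.9458, -0.3247, 0.7891]
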