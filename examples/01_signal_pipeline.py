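"""From raw wrist-band readings to the controller inputs w and avgHR.

Builds a one-minute 1 Hz stream that mixes the two physical bands, a dropped
reading and an artifact, then runs the full ingest pipeline: inter-device
calibration (band 2 reads 9.13 bpm high), outlier suppression, [0,1]
scaling over 60-200 bpm, and the 20-sample rolling window.
"""

import math

from hradapt import (
    CalibrationConfig,
    Device,
    HRSample,
    ScaledWindow,
    apply_calibration,
    avg_hr,
    clean_stream,
    push_sample,
    window_weight,
)

# a child warming up: HR climbs 82 -> 100 bpm; band 2 took over halfway
raw = []
for t in range(60):
    bpm = 82.0 + 18.0 * t / 59.0
    device = Device.BAND1 if t < 30 else Device.BAND2
    if device is Device.BAND2:
        bpm += 9.13  # band 2's systematic offset
    raw.append(HRSample(float(t), bpm, device))
raw[10] = HRSample(10.0, math.nan, Device.BAND1)  # dropped reading
raw[40] = HRSample(40.0, 300.0, Device.BAND2)  # motion artifact

# drop empty records, calibrate, then suppress out-of-range readings
no_gaps, gap_report = clean_stream(raw)
calibrated = [apply_calibration(s) for s in no_gaps]
cleaned, bounds_report = clean_stream(calibrated)
print(f"cleaning: {gap_report.n_in} in, {len(cleaned)} kept, "
      f"{gap_report.n_missing} missing, "
      f"{gap_report.n_outliers + bounds_report.n_outliers} outliers")

window = ScaledWindow()
for s in cleaned:
    push_sample(window, s)

print(f"w     = {window_weight(window):.4f}   (mean of last 20 scaled readings, in [0,1])")
print(f"avgHR = {avg_hr(window):.2f} bpm  (mean of the same 20 raw readings)")
print()
print("avgHR is what the difficulty rules compare against the 95 bpm threshold;")
print("w sets how strongly the flying-character scenario rescales its speed.")
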