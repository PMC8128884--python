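"""Measure the cells/colony motion speed (MS/MMS) of a capture.

Computes dense optical flow between consecutive frames, averages the
displacement magnitude over the segmented cell area of each pair (MS,
converted to μm/h via the calibration), and summarizes the capture by the
mean motion speed (MMS).  The generator's imposed speed is the ground
truth the measurement should recover.
"""

from colonyflow import (
    SimulationSpec,
    compute_motion_record,
    segment_sequence,
    simulate_sequence,
)

spec = SimulationSpec(height=192, width=192, n_frames=8, speed_um_per_h=45.0,
                      seed=5)
seq, truth = simulate_sequence(spec)

masks = segment_sequence(seq)
record = compute_motion_record(seq, masks)

print("pair   MS (px/frame)   MS (μm/h)")
for i, (px, um) in enumerate(zip(record.ms_series_px_per_frame,
                                 record.ms_series_um_per_h)):
    print(f"{i:4d}   {px:12.3f}   {um:9.2f}")
print(f"\nMMS = {record.mms:.2f} μm/h  (imposed speed {truth.true_mean_speed:.2f})")
print("Each MS is the mean optical-flow vector length over the cell mask of")
print("the pair's first frame; MMS averages the pairs and is the capture's")
print("motion index. Here the pipeline recovers the imposed speed to a few %.")
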