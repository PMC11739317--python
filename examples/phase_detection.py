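"""Locate the plateau phase on the breast-ROI time-intensity curve.

The mean fluorescence over the breast ROI rises during arterial inflow,
plateaus, then decays during venous washout.  The plateau window (after the
arterial phase, before the venous phase) supplies the perfusion map.
"""

from icgflap import detect_phases, extract_perfusion_map, mean_roi_curve, simulate_case

case = simulate_case(height=96, width=112, target_dropout_fraction=10.0, seed=7)
curve = mean_roi_curve(case.frames, case.breast_mask)
seg = detect_phases(curve)          # 0.95 rise / 0.90 fall fractions of max
times = case.frames.times

print(f"frames: {case.frames.n_frames}, recording {times[-1]:.0f} s")
print(f"arterial phase ends at frame {seg.arterial_end_index} "
      f"(t = {times[seg.arterial_end_index]:.0f} s)")
print(f"venous phase starts at frame {seg.venous_start_index} "
      f"(t = {times[seg.venous_start_index]:.0f} s)")

pmap = extract_perfusion_map(case.frames, seg, aggregator="median")
print(f"plateau map: median over {len(seg.plateau_indices)} frames, "
      f"max intensity {pmap.values.max():.0f} (absolute units)")
# The detected window brackets the simulator's true plateau (30-120 s); the
# per-pixel median over it is the image that gets normalized to RPU.
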