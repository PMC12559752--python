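"""Extract a participant's functional base of support from a standing trial.

Generates a synthetic two-plate standing trial (slow COP loops with the
feet flat, 150 Hz markers / 900 Hz plates), writes and re-reads it in
the TSV trial layout, runs the full extraction pipeline and compares
the recovered polygon with the generator's ground truth.
"""
import tempfile
from pathlib import Path

from fbos import process_standing_trial, read_trial, write_trial
from fbos.synthetic import StandingTrialConfig, generate_standing_trial

cfg = StandingTrialConfig(duration=60.0, seed=42)
trial = generate_standing_trial(cfg)

with tempfile.TemporaryDirectory() as tmp:
    path = write_trial(trial, Path(tmp) / "standing_trial")
    markers, plates = read_trial(path)

participant, reports = process_standing_trial(markers, plates)
m = participant.metrics
truth = trial.truth["fbos"]["left"]

print(f"feet used:            {participant.feet_used}")
print(f"retained samples:     left {reports['left']['retained_samples']}, "
      f"right {reports['right']['retained_samples']}")
print(f"fBOS area ratio:      {m.area_ratio:.3f}   (true {0.33 * 0.60:.3f})")
print(f"normalised length:    {m.norm_length:.3f}   (true 0.600)")
print(f"normalised width:     {m.norm_width:.3f}   (true 0.330)")
print(f"toe inward distance:  {m.d_toe:.3f} of foot length")
print(f"heel inward distance: {m.d_heel:.3f} of foot length")
# The area ratio says how much of the footprint hexagon can actually
# bear >=40% body weight with a flat foot; ~0.2 means only a fifth.
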