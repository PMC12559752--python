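"""Build an age-group fBOS template and scale it to a new foot.

Extracts normalised fBOS polygons from several synthetic participants,
averages them arc-length-wise into a group template, serialises the
template to JSON and scales it to a 30 cm x 10 cm foot.
"""
import tempfile
from pathlib import Path

from fbos import (make_group_template, process_standing_trial,
                  read_polygon_model, scale_template, write_polygon_model)
from fbos.synthetic import standing_config_for_participant, \
    generate_standing_trial

polys = []
for i, (area, length) in enumerate([(0.20, 0.62), (0.24, 0.66),
                                    (0.18, 0.58), (0.22, 0.64)]):
    cfg = standing_config_for_participant(area, length, seed=100 + i,
                                          duration=45.0)
    trial = generate_standing_trial(cfg)
    participant, _ = process_standing_trial(trial.markers, trial.plates)
    polys.append(participant.polygon_normalized)

template = make_group_template("young", polys)
with tempfile.TemporaryDirectory() as tmp:
    path = write_polygon_model(template, Path(tmp) / "young_template.json")
    template = read_polygon_model(path)

scaled = scale_template(template, foot_length=0.30, foot_width=0.10)
v = scaled.vertices
print(f"participants averaged:   {template.n_participants}")
print(f"template area (norm.):   {template.polygon.area:.3f}")
print(f"mean boundary dispersion:{template.dispersion.mean():.4f}")
print(f"toe margin on 30 cm foot: {(0.30 - v[:, 1].max()) * 100:.1f} cm")
print(f"heel margin:              {v[:, 1].min() * 100:.1f} cm")
# The toe margin is how far inside the toe marker the functional
# support boundary really sits - the error made when the footprint is
# used as the base of support in a margin-of-stability analysis.
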