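"""Validate the marker-based models against the simulated dummy-foot rig.

Sweeps each end plate from -90 to 90 degrees in 5-degree steps in every
anatomical plane (noiseless), runs the full marker pipeline for all three
registered models, and prints the per-cell Pearson r and Bland-Altman bias
classification against the plate-derived true values.
"""

from footkin import run_validation

table = run_validation(models=("new", "new_2", "rizzoli"))
print(table.to_string(index=False, float_format=lambda v: f"{v:.4f}"))

# Each row is one (model, joint, plane) validation cell over 37 sweep
# positions. r is the standard-related validity against the plate truth
# (ideal geometry: r ~ 1 everywhere); bias/LoA quantify agreement in
# degrees, and bias_class reports whether the Bland-Altman battery flags a
# fixed offset, a magnitude-dependent (proportional) bias, or neither.
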