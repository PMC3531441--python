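"""Fold a hairpin and inspect its stack-face free-energy profile.

Generates one synthetic miRNA-like hairpin, folds it, walks the stem from
the terminal loop to the stem-ssRNA junction, and prints the energy of each
stack face relative to the planted Drosha cut. Negative energies mark
stabilizing stacks; positive values are the (equally split) penalties of
bulges and internal loops. Face 0 spans the cut itself; positive indices
run downstream, away from the loop.
"""

from mircleave import drosha
from mircleave.energy import profile_window
from mircleave.synthetic import GenParams, plant_hairpin

rec = plant_hairpin(GenParams(seed=1, signal_strength=1.0), seed=4)
rec.structure = None  # fold from sequence
hp = drosha.prepare(rec)

print(f"hairpin: {len(rec.sequence)} nt, stem of {hp.path.n_pairs} bp")
print(f"planted Drosha cut boundary: {rec.truth[0]}")

energies, padded = profile_window(hp.profile, rec.truth[0], lo=-5, hi=19)
print("\nface  dG(kcal/mol)")
for k, (e, pad) in enumerate(zip(energies, padded), start=-5):
    marker = " (beyond the structured stem, 0-padded)" if pad else ""
    print(f"{k:+3d}   {e:6.2f}{marker}")

print(
    "\nAt full signal strength the trough of strongly negative (GC) faces"
    "\naround +10..+14 and the weak faces at +15..+19 mimic the conserved"
    "\nvertebrate energy pattern the Drosha stage learns from."
)
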