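"""Derive an affective control scale from a rated stimulus catalog.

Generates a synthetic valence/arousal/dominance catalog (stand-in for licensed
affective picture/sound rating tables), derives the summed scale with arousal
inverted (low scale = unhappy, arousing, controlled = more stressful), and
looks up the stimulus nearest to a requested scale value.
"""

from stressloop import make_catalog, nearest_stimulus

catalog = make_catalog(12, dimensions=("valence", "arousal", "dominance"), seed=4)
print(catalog.table.head(5).to_string(index=False))
lo, hi = catalog.scale_range
print(f"derived scale spans [{lo:.2f}, {hi:.2f}] (low = most aversive)")

for x in (lo, 0.5 * (lo + hi), hi):
    stim = nearest_stimulus(catalog, x)
    row = catalog.table.set_index("stimulus_id").loc[stim]
    print(f"requested x = {x:5.2f} -> {stim} (scale {row['derived_scale']:.2f}, "
          f"valence {row['valence']}, arousal {row['arousal']})")
# The controller asks for a scale value x; the catalog answers with the
# concrete stimulus whose derived scale is closest to it.
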