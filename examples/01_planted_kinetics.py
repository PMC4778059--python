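"""Build the ground-truth jump model and inspect its planted kinetics.

The "paper-hierarchy" preset is a four-state chain (lower leaflet <-> upper
leaflet <-> membrane vestibule <-> bound pose) whose exchange rates are
calibrated so the exact relaxation times are 100 us, 5 us and 500 ns, and
whose bound basin sits 2.0 kcal/mol below the membrane leaflets.
"""

import numpy as np

import lipidmsm as lm

model = lm.build_preset_generator("paper-hierarchy", kT=0.596)

print("states:", model.state_names)
print("exact relaxation timescales (ns):", model.exact_timescales)
print("stationary distribution:", np.round(model.stationary, 5))
ratio = model.stationary[3] / model.stationary[1]
print(f"bound/upper-leaflet population ratio: {ratio:.2f} "
      f"(= exp(2.0 kcal/mol / kT) = {np.exp(2.0 / 0.596):.2f})")

# relaxation toward equilibrium: start everything in the upper leaflet
p0 = np.array([0.0, 1.0, 0.0, 0.0])
for t in (100.0, 1_000.0, 10_000.0, 100_000.0, 1_000_000.0):
    p = lm.propagate(model, p0, t)
    print(f"P(t={t:>9.0f} ns) =", np.round(p, 4))
# after ~10 relaxation times of the slowest process the distribution is pi
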