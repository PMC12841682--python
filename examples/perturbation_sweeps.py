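"""Which stage would pest control (or its absence) have to move?

Sweeps each survival transition over 0.1–1.0 and fecundity over 50–500,
one at a time, and reports where the growth rate first exceeds 1 — the
point at which the population would stop declining.
"""

from pinedemog import crossing_report, default_model, sweep_all

model = default_model()
results = sweep_all(model)
print(crossing_report(results).to_string(index=False))
print()
print("Only full survival into L1 or into L3, or a fecundity above 420")
print("eggs per 1000 cm², lifts lambda above 1; the other three survivals")
print("cannot rescue the population even at 1.0.")

# uncomment to save the sweep curves:
# from pinedemog import plot_sweeps
# plot_sweeps(results, "sweeps.svg")
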