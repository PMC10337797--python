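"""Leave-one-out input construction vs the plain rounded mean.

The plug-in input (the rounded mean of all five ratings) contains the very
rating it is paired with, which inflates mutual information.  The
leave-one-out construction pairs each rating with the rounded mean of the
other four.  On simulated raters the two plateaus agree closely, showing
the inflation is modest at this design size.
"""

from ratecap import (
    ChannelSpec,
    ExperimentDesign,
    aggregate_curve,
    loo_inputs,
    rounded_mean_input,
    simulate_dataset,
)

ratings = (2, 3, 3, 4, 5)
print(f"ratings {ratings}: plug-in input = {rounded_mean_input(ratings)}, "
      f"leave-one-out inputs = {loo_inputs(ratings)}")

dataset = simulate_dataset(ExperimentDesign(), ChannelSpec(), seed=1)
plugin = aggregate_curve(dataset, mode="plugin")
loo = aggregate_curve(dataset, mode="loo")

print("\n  k   plug-in MI     leave-one-out MI   (bits, mean +- SD)")
for a, b in zip(plugin, loo):
    print(f" {a.n_stimuli:3d}   {a.mi_mean_bits:.3f} +- {a.mi_sd_bits:.3f} "
          f"   {b.mi_mean_bits:.3f} +- {b.mi_sd_bits:.3f}")

diff = plugin[-1].mi_mean_bits - loo[-1].mi_mean_bits
print(f"\nplateau difference (plug-in - leave-one-out): {diff:+.3f} bits")
print("a small difference means the self-dependence of the plug-in input "
      "barely inflates the capacity estimate")
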