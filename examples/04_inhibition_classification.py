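"""Classify inhibition in a small mixed population and recover prevalence.

Simulates 30 UV cells with 70% inhibition prevalence at realistic noise and
compares recovered labels against the generator's truth table.
"""

import numpy as np
import pandas as pd

from specsense import (
    GroupSpec,
    SimExperimentSpec,
    analyze_experiment,
    cells_table,
    proportion_with_sem,
    simulate_experiment,
)

rng = np.random.default_rng(2)
spec = SimExperimentSpec(groups=(GroupSpec("demo", 5, 30, 0.7),))
recordings, truth = simulate_experiment(spec, rng)
cells = cells_table(analyze_experiment(recordings))

merged = cells.merge(
    truth[["cell_id", "inhibited"]].rename(columns={"inhibited": "true_inhibited"}),
    on="cell_id",
)
acc = (merged.inhibited.astype(bool) == merged.true_inhibited).mean()
gp = proportion_with_sem(int(merged.inhibited.sum()), len(merged))
print(f"label accuracy: {100*acc:.1f}%")
print(f"recovered prevalence: {gp.percent:.1f}% +/- {gp.percent_sem:.1f}% "
      f"(generating probability 70%)")
print("-> the probe-wavelength criterion (hyperpolarization at 530 nm beyond")
print("   5 sigma of baseline noise) recovers the opponent subpopulation.")
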